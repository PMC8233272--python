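"""Core domain containers.

All volumetric data uses a fixed axis order ``(z, y, x)`` with 0-based,
voxel-centered indices; the physical position of voxel ``i`` along an axis
is ``i * spacing_um``.  Intensities are non-negative and finite; the
canonical on-disk intensity type is 16-bit unsigned, but in-memory arrays
may be wider (float during computation).
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

SpacingLike = Union[float, Sequence[float]]


def as_spacing(spacing_um: SpacingLike) -> tuple[float, float, float]:
    """Normalize a scalar or 3-sequence spacing to a ``(z, y, x)`` tuple of floats."""
    arr = np.asarray(spacing_um, dtype=float).ravel()
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.size != 3:
        raise ValueError(f"spacing must be scalar or length 3, got {arr.size} values")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"spacing must be finite and positive, got {tuple(arr)}")
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclasses.dataclass
class Volume:
    """A 3-D scalar image on a regular grid.

    Parameters
    ----------
    data
        3-D array indexed ``(z, y, x)`` of finite, non-negative intensities.
    spacing_um
        Voxel edge length in micrometres; a scalar means isotropic, a
        3-sequence is interpreted as ``(z, y, x)``.
    """

    data: np.ndarray
    spacing_um: SpacingLike = 20.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3-D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("all volume dimensions must be >= 1")
        if np.issubdtype(self.data.dtype, np.floating):
            if not np.all(np.isfinite(self.data)):
                raise ValueError("volume intensities must be finite")
        if self.data.size and self.data.min() < 0:
            raise ValueError("volume intensities must be non-negative")
        self.spacing_um = as_spacing(self.spacing_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    @property
    def is_isotropic(self) -> bool:
        s = self.spacing_um
        return s[0] == s[1] == s[2]

    def with_data(self, data: np.ndarray) -> "Volume":
        """A copy of this volume carrying new intensity data on the same grid."""
        return Volume(data, self.spacing_um)

    def astype(self, dtype) -> "Volume":
        return Volume(self.data.astype(dtype), self.spacing_um)


class Ontology:
    """Hierarchical brain-region table: id, acronym, name, parent.

    Region ids are unique positive integers; parent links must form a rooted
    forest (roots carry a null parent).  Leaves are nodes that never appear
    as another node's parent.
    """

    COLUMNS = ("region_id", "acronym", "name", "parent_id")

    def __init__(self, table: pd.DataFrame):
        df = table.copy()
        missing = [c for c in ("region_id", "acronym", "name", "parent_id") if c not in df.columns]
        if missing:
            raise ValueError(f"ontology table missing columns: {missing}")
        df["region_id"] = df["region_id"].astype(np.int64)
        df["parent_id"] = df["parent_id"].astype("Int64")
        self.table = df.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        ids = self.table["region_id"]
        if (ids <= 0).any():
            raise ValueError("region ids must be positive integers (0 is reserved for background)")
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate region ids: {dups}")
        id_set = set(ids.tolist())
        parent = self.parent_map()
        for rid, pid in parent.items():
            if pid is not None and pid not in id_set:
                raise ValueError(f"dangling parent_id {pid} for region {rid}")
        # cycle check by walking to a root from every node
        for rid in id_set:
            seen = set()
            node: Optional[int] = rid
            while node is not None:
                if node in seen:
                    raise ValueError(f"cycle in parent links involving region {node}")
                seen.add(node)
                node = parent[node]

    def parent_map(self) -> dict[int, Optional[int]]:
        out: dict[int, Optional[int]] = {}
        for rid, pid in zip(self.table["region_id"], self.table["parent_id"]):
            out[int(rid)] = None if pd.isna(pid) else int(pid)
        return out

    @property
    def region_ids(self) -> list[int]:
        return [int(r) for r in self.table["region_id"]]

    @property
    def roots(self) -> list[int]:
        return [rid for rid, pid in self.parent_map().items() if pid is None]

    @property
    def leaves(self) -> list[int]:
        parents = {pid for pid in self.parent_map().values() if pid is not None}
        return [rid for rid in self.region_ids if rid not in parents]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def children_map(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {rid: [] for rid in self.region_ids}
        for rid, pid in self.parent_map().items():
            if pid is not None:
                out[pid].append(rid)
        return out

    def ancestors(self, region_id: int) -> list[int]:
        """Ancestor chain from the node's parent up to its root."""
        parent = self.parent_map()
        if region_id not in parent:
            raise KeyError(f"unknown region id {region_id}")
        chain = []
        node = parent[region_id]
        while node is not None:
            chain.append(node)
            node = parent[node]
        return chain

    def acronym(self, region_id: int) -> str:
        row = self.table.loc[self.table["region_id"] == region_id]
        if row.empty:
            raise KeyError(f"unknown region id {region_id}")
        return str(row["acronym"].iloc[0])

    def __len__(self) -> int:
        return len(self.table)

    def __repr__(self) -> str:
        return f"Ontology({len(self)} regions, {self.n_leaves} leaves)"


@dataclasses.dataclass
class LabelVolume:
    """Integer region map on a regular grid; 0 marks voxels outside the tissue mask."""

    labels: np.ndarray
    spacing_um: SpacingLike = 20.0
    ontology: Optional[Ontology] = None
    tissue_mask: Optional[np.ndarray] = None
    ventricular_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing_um = as_spacing(self.spacing_um)
        for name in ("tissue_mask", "ventricular_mask"):
            m = getattr(self, name)
            if m is not None:
                m = np.asarray(m).astype(bool)
                if m.shape != self.labels.shape:
                    raise ValueError(f"{name} shape {m.shape} != labels shape {self.labels.shape}")
                setattr(self, name, m)
        if self.ontology is not None:
            known = set(self.ontology.region_ids)
            present = set(np.unique(self.labels).tolist()) - {0}
            unknown = present - known
            if unknown:
                raise ValueError(f"labels not in ontology: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)  # type: ignore[return-value]

    def present_labels(self) -> list[int]:
        vals = np.unique(self.labels)
        return [int(v) for v in vals if v != 0]

    def mask(self) -> np.ndarray:
        """Tissue mask; defaults to the nonzero-label support."""
        if self.tissue_mask is not None:
            return self.tissue_mask
        return self.labels > 0


class LandmarkSet:
    """Named point landmarks in voxel coordinates (possibly fractional)."""

    def __init__(self, table: pd.DataFrame):
        df = table.copy()
        for c in ("name", "z", "y", "x"):
            if c not in df.columns:
                raise ValueError(f"landmark table missing column {c!r}")
        df["name"] = df["name"].astype(str)
        for c in ("z", "y", "x"):
            df[c] = pd.to_numeric(df[c], errors="raise").astype(float)
        if df["name"].duplicated().any():
            dups = sorted(df.loc[df["name"].duplicated(), "name"].unique())
            raise ValueError(f"duplicate landmark names: {dups}")
        if not np.all(np.isfinite(df[["z", "y", "x"]].to_numpy())):
            raise ValueError("landmark coordinates must be finite")
        self.table = df.reset_index(drop=True)

    @property
    def names(self) -> list[str]:
        return self.table["name"].tolist()

    def coordinates(self, order: Optional[Iterable[str]] = None) -> np.ndarray:
        """(n, 3) array of (z, y, x) coordinates, optionally in a given name order."""
        df = self.table.set_index("name")
        if order is not None:
            df = df.loc[list(order)]
        return df[["z", "y", "x"]].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)


CELL_COLUMNS = ("z", "y", "x", "size", "intensity", "region_id")


def make_cell_table(
    centers: np.ndarray,
    sizes: Optional[np.ndarray] = None,
    intensities: Optional[np.ndarray] = None,
    region_ids: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Assemble a cell table (one row per detected cell) from parallel arrays.

    ``region_id`` 0 means unassigned.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    n = len(centers) if centers.size else 0
    if centers.size and centers.shape[1] != 3:
        raise ValueError("cell centers must be (n, 3) in (z, y, x)")
    df = pd.DataFrame(
        {
            "z": centers[:, 0] if n else np.array([], dtype=float),
            "y": centers[:, 1] if n else np.array([], dtype=float),
            "x": centers[:, 2] if n else np.array([], dtype=float),
            "size": np.asarray(sizes, dtype=np.int64) if sizes is not None else np.zeros(n, np.int64),
            "intensity": np.asarray(intensities, dtype=float) if intensities is not None else np.zeros(n),
            "region_id": np.asarray(region_ids, dtype=np.int64) if region_ids is not None else np.zeros(n, np.int64),
        }
    )
    return df


def validate_count_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-animal per-region count table.

    Expected columns: ``animal_id, group, region_id, count`` with one row per
    animal x region and non-negative integral counts.
    """
    for c in ("animal_id", "group", "region_id", "count"):
        if c not in counts.columns:
            raise ValueError(f"count table missing column {c!r}")
    df = counts.copy()
    df["count"] = pd.to_numeric(df["count"], errors="raise")
    if (df["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(df["count"], np.round(df["count"])):
        raise ValueError("counts must be integral")
    df["count"] = df["count"].round().astype(np.int64)
    if df.duplicated(subset=["animal_id", "region_id"]).any():
        raise ValueError("count table must have one row per animal x region")
    return df
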