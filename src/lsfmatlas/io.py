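"""Readers and writers for volumes, ontologies, landmark and cell tables.

Volumes are exchanged as multi-page TIFF stacks, directories of per-slice
TIFFs, or NIfTI-1 files; tables are UTF-8 CSV with a header row.  All
round-trips are lossless for integer volumes and full-precision for tables.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .types import LabelVolume, LandmarkSet, Ontology, Volume, validate_count_table

PathLike = Union[str, Path]

_TIFF_SUFFIXES = {".tif", ".tiff"}
_NIFTI_SUFFIXES = {".nii", ".nii.gz"}


def _is_nifti(path: Path) -> bool:
    return path.name.endswith(".nii") or path.name.endswith(".nii.gz")


def read_volume(path: PathLike, spacing_um: float = 20.0) -> Volume:
    """Read a 3-D volume with axis order (z, y, x).

    ``path`` may be a multi-page TIFF, a directory of same-shape per-slice
    TIFFs (sorted by filename, one slice per z plane), or a NIfTI file.  For
    NIfTI the header spacing overrides the ``spacing_um`` argument.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    if path.is_dir():
        slices = sorted(p for p in path.iterdir() if p.suffix.lower() in _TIFF_SUFFIXES)
        if not slices:
            raise FileNotFoundError(f"no TIFF slices in directory {path}")
        planes = [tifffile.imread(p) for p in slices]
        shapes = {p.shape for p in planes}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent slice shapes in {path}: {sorted(shapes)}")
        return Volume(np.stack(planes, axis=0), spacing_um)
    if _is_nifti(path):
        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj)
        if arr.ndim != 3:
            raise ValueError(f"expected 3-D NIfTI, got ndim={arr.ndim}")
        # NIfTI stores (x, y, z); transpose to (z, y, x) and reverse zooms.
        arr = np.ascontiguousarray(arr.transpose(2, 1, 0))
        zooms = img.header.get_zooms()[:3]
        return Volume(arr, tuple(float(z) for z in reversed(zooms)))
    if path.suffix.lower() in _TIFF_SUFFIXES:
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"expected a 3-D TIFF stack, got ndim={arr.ndim}")
        return Volume(arr, spacing_um)
    raise ValueError(f"unrecognized volume format: {path}")


def write_volume(vol: Volume, path: PathLike) -> None:
    """Write a volume as multi-page TIFF or NIfTI-1 depending on the suffix."""
    path = Path(path)
    if _is_nifti(path):
        affine = np.diag(list(reversed(vol.spacing_um)) + [1.0])
        img = nib.Nifti1Image(np.asarray(vol.data).transpose(2, 1, 0), affine)
        img.header.set_zooms(tuple(reversed(vol.spacing_um)))
        nib.save(img, str(path))
        return
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(path, np.asarray(vol.data))
        return
    raise ValueError(f"unrecognized volume format: {path}")


def read_label_volume(path: PathLike, spacing_um: float = 20.0, ontology: Optional[Ontology] = None) -> LabelVolume:
    vol = read_volume(path, spacing_um)
    labels = np.asarray(vol.data)
    if not np.issubdtype(labels.dtype, np.integer):
        rounded = np.rint(labels)
        if not np.allclose(labels, rounded):
            raise ValueError("label volume contains non-integer values")
        labels = rounded.astype(np.int64)
    return LabelVolume(labels, vol.spacing_um, ontology=ontology)


def write_label_volume(lab: LabelVolume, path: PathLike) -> None:
    write_volume(Volume(np.asarray(lab.labels, dtype=np.uint32), lab.spacing_um), path)


def _ontology_from_tree(tree: dict) -> pd.DataFrame:
    rows: list[dict] = []

    def walk(node: dict, parent_id):
        rows.append(
            {
                "region_id": node["id"],
                "acronym": node.get("acronym", str(node["id"])),
                "name": node.get("name", str(node["id"])),
                "parent_id": parent_id,
            }
        )
        for child in node.get("children", []):
            walk(child, node["id"])

    walk(tree, None)
    return pd.DataFrame(rows)


def read_ontology(path: PathLike) -> Ontology:
    """Read a region ontology from CSV (region_id, acronym, name, parent_id) or a nested JSON tree."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            tree = json.load(fh)
        if isinstance(tree, dict) and "msg" in tree:  # tolerate API-style wrapping
            tree = tree["msg"][0]
        return Ontology(_ontology_from_tree(tree))
    df = pd.read_csv(path)
    return Ontology(df)


def write_ontology(ont: Ontology, path: PathLike) -> None:
    ont.table.to_csv(path, index=False)


def read_landmarks(path: PathLike) -> LandmarkSet:
    """Read a landmark table (name, z, y, x) from CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    try:
        return LandmarkSet(df)
    except ValueError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise ValueError(f"malformed landmark table {path}: {exc}") from exc


def write_landmarks(lms: LandmarkSet, path: PathLike) -> None:
    # %.17g keeps doubles bit-exact across the round trip
    lms.table.to_csv(path, index=False, float_format="%.17g")


def read_cell_table(path: PathLike) -> pd.DataFrame:
    """Read a detected-cell table (z, y, x, size, intensity, region_id) from CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    for c in ("z", "y", "x"):
        if c not in df.columns:
            raise ValueError(f"cell table missing column {c!r}")
        bad = pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"non-numeric coordinate in column {c!r} at row {row}")
        df[c] = pd.to_numeric(df[c])
    for c, dtype in (("size", np.int64), ("intensity", float), ("region_id", np.int64)):
        if c in df.columns:
            df[c] = pd.to_numeric(df[c], errors="raise").astype(dtype)
        else:
            df[c] = np.zeros(len(df), dtype=dtype)
    return df[list(("z", "y", "x", "size", "intensity", "region_id"))]


def write_cell_table(cells: pd.DataFrame, path: PathLike) -> None:
    cells.to_csv(path, index=False, float_format="%.17g")


def read_count_table(path: PathLike) -> pd.DataFrame:
    return validate_count_table(pd.read_csv(path))


def write_count_table(counts: pd.DataFrame, path: PathLike) -> None:
    counts.to_csv(path, index=False)


def read_design(path: PathLike) -> pd.DataFrame:
    """Read a group-design table (animal_id, group) from CSV."""
    df = pd.read_csv(path)
    for c in ("animal_id", "group"):
        if c not in df.columns:
            raise ValueError(f"design table missing column {c!r}")
    if df["animal_id"].duplicated().any():
        raise ValueError("duplicate animal_id in design table")
    return df
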