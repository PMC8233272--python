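"""Registration-quality evaluation.

Three complementary measures: the voxelwise magnitude of the deformation a
registration had to apply, the per-region intensity variance across a set
of registered volumes (the NIREP criterion — lower variance means tighter
alignment), and Euclidean distances between corresponding landmarks with a
two-tailed Welch's t-test for comparing two atlas conditions.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import LabelVolume, LandmarkSet, Volume, as_spacing


def deformation_magnitude(field: np.ndarray) -> np.ndarray:
    """Per-voxel Euclidean norm of a (z, y, x, 3) displacement field, in voxel units."""
    field = np.asarray(field, dtype=np.float64)
    if field.ndim != 4 or field.shape[-1] != 3:
        raise ValueError("field must have shape (z, y, x, 3)")
    if not np.all(np.isfinite(field)):
        raise ValueError("field components must be finite")
    return np.sqrt((field**2).sum(axis=-1))


@dataclasses.dataclass
class RegionIV:
    """Per-region and per-block mean intensity variance."""

    per_region: pd.DataFrame  # region_id, mean_iv, n_voxels
    per_block: Optional[pd.DataFrame] = None  # block, mean_iv

    def region_value(self, region_id: int) -> float:
        row = self.per_region.loc[self.per_region["region_id"] == region_id]
        if row.empty:
            raise KeyError(f"region {region_id} not present")
        return float(row["mean_iv"].iloc[0])


def intensity_variance(
    registered_vols: Sequence[Volume],
    labels: LabelVolume,
    blocks: Optional[Mapping[str, Sequence[int]]] = None,
) -> RegionIV:
    """NIREP intensity variance per region.

    The voxelwise unbiased (n-1) sample variance is taken across the
    registered volumes; a region's IV is the mean of that variance map over
    the region's voxels.  Optional ``blocks`` (name -> member region ids)
    aggregate member-region voxels into per-block means.
    """
    if len(registered_vols) < 2:
        raise ValueError("intensity variance needs >= 2 registered volumes")
    shapes = {v.shape for v in registered_vols}
    if len(shapes) > 1 or registered_vols[0].shape != labels.shape:
        raise ValueError("volumes and labels must share one grid")
    stack = np.stack([np.asarray(v.data, dtype=np.float64) for v in registered_vols])
    var_map = stack.var(axis=0, ddof=1)
    lab = np.asarray(labels.labels)
    rows = []
    for rid in labels.present_labels():
        sel = lab == rid
        rows.append({"region_id": rid, "mean_iv": float(var_map[sel].mean()), "n_voxels": int(sel.sum())})
    per_region = pd.DataFrame(rows)
    per_block = None
    if blocks is not None:
        brows = []
        for name, ids in blocks.items():
            sel = np.isin(lab, np.asarray(sorted(ids)))
            if sel.any():
                brows.append({"block": name, "mean_iv": float(var_map[sel].mean()), "n_voxels": int(sel.sum())})
        per_block = pd.DataFrame(brows)
    return RegionIV(per_region, per_block)


def landmark_distances(
    registered: LandmarkSet, atlas: LandmarkSet, spacing_um=20.0
) -> pd.DataFrame:
    """Per-landmark Euclidean distance in micrometres (spacing-aware).

    Landmarks are matched by name; a name present in only one set is an
    error.
    """
    names_r, names_a = set(registered.names), set(atlas.names)
    if names_r != names_a:
        raise ValueError(
            f"landmark name mismatch: only-registered {sorted(names_r - names_a)}, "
            f"only-atlas {sorted(names_a - names_r)}"
        )
    order = sorted(names_r)
    spacing = np.asarray(as_spacing(spacing_um))
    delta = (registered.coordinates(order) - atlas.coordinates(order)) * spacing[None, :]
    dist = np.sqrt((delta**2).sum(axis=1))
    return pd.DataFrame({"name": order, "distance_um": dist})


def welch_ttest(sample_a: np.ndarray, sample_b: np.ndarray) -> dict:
    """Two-tailed Welch's t-test with the Welch-Satterthwaite degrees of freedom."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return {"t": float(res.statistic), "p": float(res.pvalue), "df": float(df)}


def landmark_eval(
    distances_condition_a: pd.DataFrame, distances_condition_b: pd.DataFrame
) -> pd.DataFrame:
    """Per-landmark Welch comparison of distance samples from two atlas conditions.

    Each input holds one row per (landmark name, subject) with a
    ``distance_um`` column; the output has one row per landmark with the
    mean distances, the t statistic and the two-tailed p value.
    """
    rows = []
    for name in sorted(set(distances_condition_a["name"]) & set(distances_condition_b["name"])):
        da = distances_condition_a.loc[distances_condition_a["name"] == name, "distance_um"].to_numpy()
        db = distances_condition_b.loc[distances_condition_b["name"] == name, "distance_um"].to_numpy()
        res = welch_ttest(da, db)
        rows.append(
            {
                "name": name,
                "mean_a_um": float(da.mean()),
                "mean_b_um": float(db.mean()),
                "t": res["t"],
                "p": res["p"],
                "df": res["df"],
            }
        )
    return pd.DataFrame(rows)
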