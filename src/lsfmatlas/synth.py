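"""Synthetic phantom brains with known ground truth.

Every generator is a pure function of its parameters and seed; repeated
calls are bit-identical.  The phantoms emulate the features the analysis
pipeline must cope with — an ellipsoidal "brain" carved into labeled
subregions, point-like bright cells in a marker-specific channel, bright
artifacts shared between both channels, and smooth random deformations with
a known displacement field — without attempting photorealistic light-sheet
physics (no stripes, attenuation, or vasculature).
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .types import LabelVolume, Ontology, Volume

# Default phantom geometry: large enough to host six regions with hundreds
# of voxels each, small enough that registration runs in seconds.
DEFAULT_SHAPE = (96, 128, 128)
DEFAULT_SPACING_UM = 20.0


@dataclasses.dataclass
class PhantomTruth:
    """Ground truth attached to a generated phantom."""

    cell_centers: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros((0, 3)))
    cell_region_ids: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(0, np.int64))
    artifact_centers: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros((0, 3)))
    applied_field: Optional[np.ndarray] = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.cell_centers = np.atleast_2d(np.asarray(self.cell_centers, dtype=float)).reshape(-1, 3)
        self.cell_region_ids = np.asarray(self.cell_region_ids, dtype=np.int64)
        self.artifact_centers = np.atleast_2d(np.asarray(self.artifact_centers, dtype=float)).reshape(-1, 3)
        if len(self.cell_centers) != len(self.cell_region_ids):
            raise ValueError("cell_centers and cell_region_ids must be aligned")


def _named_rng(seed: int, stream_id: int) -> np.random.Generator:
    """One generator per operation (fixed stream id) so stages do not share draw counts."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream_id)]))


_STREAMS = {"phantom": 11, "cells": 12, "artifacts": 13, "warp": 14, "counts": 15}


def make_phantom(
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    n_regions: int = 6,
    seed: int = 0,
    spacing_um: float = DEFAULT_SPACING_UM,
    base_intensity: float = 5000.0,
    region_offset: float = 400.0,
    noise_sd: float = 100.0,
    texture_sd: float = 1500.0,
    texture_sigma_vox: float = 6.0,
) -> tuple[Volume, LabelVolume, Ontology]:
    """Generate an ellipsoidal phantom brain with nested labeled regions.

    The tissue mask is a smooth ellipsoid; its interior is partitioned into
    ``n_regions`` adjacent subregions (nearest-seed-point partition), each
    guaranteed to hold at least 100 voxels.  The autofluorescence channel is
    a smooth base intensity plus a mild per-region offset plus spatially
    correlated texture (Gaussian-filtered noise, correlation length
    ``texture_sigma_vox``) plus white Gaussian noise.  The texture stands in
    for the rich anatomical structure of real autofluorescence volumes;
    without it, deformable registration of the phantom would be ill-posed
    (a smooth symmetric blob carries no tangential information).  The
    ontology has a root node plus one node per region.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 32:
        raise ValueError(f"shape must be >= (32, 32, 32), got {shape}")
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")

    rng = _named_rng(seed, _STREAMS["phantom"])
    zz, yy, xx = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    center = [(s - 1) / 2.0 for s in shape]
    semi = [0.42 * s for s in shape]
    r2 = sum(((c - m) / a) ** 2 for c, m, a in zip((zz, yy, xx), center, semi))
    mask = r2 <= 1.0

    # nearest-seed partition of the mask interior; retry until every region
    # clears the 100-voxel floor (seeds drawn well inside the ellipsoid)
    coords = np.stack([zz[mask], yy[mask], xx[mask]], axis=1)
    for _attempt in range(50):
        inner = np.flatnonzero(r2[mask] <= 0.6)
        if len(inner) < n_regions:
            raise ValueError(f"shape {shape} too small to host {n_regions} regions")
        pick = rng.choice(inner, size=n_regions, replace=False)
        seeds = coords[pick]
        d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        sizes = np.bincount(assign, minlength=n_regions)
        if sizes.min() >= 100:
            break
    else:
        raise ValueError(f"could not place {n_regions} regions of >= 100 voxels in shape {shape}")

    labels = np.zeros(shape, dtype=np.int32)
    region_ids = np.arange(2, n_regions + 2)
    labels[mask] = region_ids[assign]

    rows = [{"region_id": 1, "acronym": "root", "name": "phantom brain", "parent_id": None}]
    for i, rid in enumerate(region_ids):
        rows.append(
            {"region_id": int(rid), "acronym": f"R{i + 1}", "name": f"phantom region {i + 1}", "parent_id": 1}
        )
    ontology = Ontology(pd.DataFrame(rows))

    # smooth base: ellipsoid profile falling off toward the rim
    base = base_intensity * np.clip(1.0 - 0.6 * r2, 0.0, None) * mask
    offsets = rng.uniform(-region_offset, region_offset, size=n_regions)
    off_vol = np.zeros(shape)
    off_vol[mask] = offsets[assign]
    auto = base + off_vol
    auto = ndi.gaussian_filter(auto, sigma=1.5)
    if texture_sd > 0:
        tex = ndi.gaussian_filter(rng.normal(size=shape), texture_sigma_vox)
        auto = auto + (texture_sd / tex.std()) * tex * mask
    auto = auto + rng.normal(0.0, noise_sd, size=shape)
    auto = np.clip(auto, 0.0, None).astype(np.float32)

    label_vol = LabelVolume(labels, spacing_um, ontology=ontology, tissue_mask=mask)
    return Volume(auto, spacing_um), label_vol, ontology


def implant_cells(
    label_volume: LabelVolume,
    per_region_counts: Mapping[int, int],
    peak_intensity: float = 3000.0,
    radius_vox: float = 1.5,
    min_sep: float = 6.0,
    seed: int = 0,
    background: float = 200.0,
    noise_sd: float = 20.0,
    anatomy: Optional[Volume] = None,
    anatomy_bleed: float = 0.2,
    max_tries: int = 20000,
) -> tuple[Volume, PhantomTruth]:
    """Implant Gaussian-profile point cells into a marker-specific channel.

    Centers are rejection-sampled on the voxel lattice inside the requested
    region, pairwise separated by at least ``min_sep`` voxels.  Each cell is
    an isotropic Gaussian of peak ``peak_intensity`` and sigma
    ``radius_vox``, added onto a flat noisy background.  When ``anatomy``
    is given (normally the autofluorescence channel), a fraction
    ``anatomy_bleed`` of it is added to the specific channel, emulating the
    residual tissue signal that makes the two channels alignable in real
    acquisitions.
    """
    shape = label_volume.shape
    rng = _named_rng(seed, _STREAMS["cells"])
    centers: list[np.ndarray] = []
    region_of: list[int] = []
    for rid, want in sorted(per_region_counts.items()):
        if want == 0:
            continue
        locs = np.argwhere(label_volume.labels == rid)
        if len(locs) == 0:
            raise ValueError(f"region {rid} absent from label volume")
        placed = 0
        tries = 0
        while placed < want:
            tries += 1
            if tries > max_tries:
                raise ValueError(
                    f"could not place {want} cells in region {rid} with min_sep={min_sep}"
                )
            cand = locs[rng.integers(len(locs))].astype(float)
            if all(np.linalg.norm(cand - c) >= min_sep for c in centers):
                centers.append(cand)
                region_of.append(int(rid))
                placed += 1

    spec = np.full(shape, float(background))
    if anatomy is not None:
        if anatomy.shape != tuple(shape):
            raise ValueError("anatomy volume shape mismatch")
        spec = spec + anatomy_bleed * np.asarray(anatomy.data, dtype=np.float64)
    if centers:
        arr = np.asarray(centers)
        rad = int(np.ceil(3 * radius_vox))
        offs = np.mgrid[-rad : rad + 1, -rad : rad + 1, -rad : rad + 1].reshape(3, -1).T
        kernel = peak_intensity * np.exp(-(offs**2).sum(axis=1) / (2 * radius_vox**2))
        for c in arr:
            pts = c.astype(int) + offs
            ok = np.all((pts >= 0) & (pts < np.asarray(shape)), axis=1)
            np.add.at(spec, tuple(pts[ok].T), kernel[ok])
    spec = spec + rng.normal(0.0, noise_sd, size=shape)
    spec = np.clip(spec, 0.0, None).astype(np.float32)
    truth = PhantomTruth(
        cell_centers=np.asarray(centers) if centers else np.zeros((0, 3)),
        cell_region_ids=np.asarray(region_of, dtype=np.int64),
        rng_seed=seed,
    )
    return Volume(spec, label_volume.spacing_um), truth


def add_shared_artifacts(
    auto: Volume,
    spec: Volume,
    n: int,
    intensity: float = 2500.0,
    seed: int = 0,
    radius_vox: float = 2.0,
    min_sep: float = 10.0,
    avoid: Optional[np.ndarray] = None,
) -> tuple[Volume, Volume, PhantomTruth]:
    """Add ``n`` bright blobs at identical coordinates in both channels.

    Emulates autofluorescent tissue artifacts that appear in the
    autofluorescence and the marker-specific channel alike and must be
    vetoed by the detector.  Blob centers are drawn inside the brighter half
    of the autofluorescence support, mutually separated by ``min_sep`` and,
    when ``avoid`` coordinates are given (typically implanted cell
    centers), also ``min_sep`` away from those — an artifact on top of a
    cell would make the ground-truth cell/artifact distinction meaningless.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if auto.shape != spec.shape:
        raise ValueError("channel shapes differ")
    a = np.asarray(auto.data, dtype=np.float32).copy()
    s = np.asarray(spec.data, dtype=np.float32).copy()
    if n == 0:
        return Volume(a, auto.spacing_um), Volume(s, spec.spacing_um), PhantomTruth(rng_seed=seed)

    rng = _named_rng(seed, _STREAMS["artifacts"])
    support = np.argwhere(a > np.median(a[a > 0]) if np.any(a > 0) else a >= 0)
    if len(support) == 0:
        raise ValueError("no tissue support to place artifacts in")
    keep_out = [] if avoid is None else [np.asarray(c, float) for c in np.atleast_2d(avoid)]
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > 20000:
            raise ValueError(f"could not place {n} artifacts with min_sep={min_sep}")
        cand = support[rng.integers(len(support))].astype(float)
        if all(np.linalg.norm(cand - c) >= min_sep for c in centers) and all(
            np.linalg.norm(cand - c) >= min_sep for c in keep_out
        ):
            centers.append(cand)

    rad = int(np.ceil(3 * radius_vox))
    offs = np.mgrid[-rad : rad + 1, -rad : rad + 1, -rad : rad + 1].reshape(3, -1).T
    kernel = intensity * np.exp(-(offs**2).sum(axis=1) / (2 * radius_vox**2))
    shape = np.asarray(a.shape)
    for c in centers:
        pts = c.astype(int) + offs
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        np.add.at(a, tuple(pts[ok].T), kernel[ok])
        np.add.at(s, tuple(pts[ok].T), kernel[ok])
    truth = PhantomTruth(artifact_centers=np.asarray(centers), rng_seed=seed)
    return Volume(a, auto.spacing_um), Volume(s, spec.spacing_um), truth


def random_displacement_field(
    shape: tuple[int, int, int], amplitude_vox: float, smoothness: float = 12.0, seed: int = 0
) -> np.ndarray:
    """Smooth random displacement field, shape (z, y, x, 3), max norm <= amplitude."""
    if amplitude_vox < 0:
        raise ValueError("amplitude_vox must be >= 0")
    if amplitude_vox == 0:
        return np.zeros(tuple(shape) + (3,), dtype=np.float64)
    rng = _named_rng(seed, _STREAMS["warp"])
    field = rng.normal(size=(3,) + tuple(shape))
    field = np.stack([ndi.gaussian_filter(f, sigma=smoothness) for f in field])
    mags = np.sqrt((field**2).sum(axis=0))
    peak = mags.max()
    if peak > 0:
        field *= amplitude_vox / peak
    return np.moveaxis(field, 0, -1)


def apply_displacement(vol: Volume, field: np.ndarray, order: int = 1) -> Volume:
    """Warp a volume with a dense field: out(x) = vol(x + d(x)), linear interpolation."""
    field = np.asarray(field, dtype=np.float64)
    if field.shape != tuple(vol.shape) + (3,):
        raise ValueError(f"field shape {field.shape} incompatible with volume {vol.shape}")
    grid = np.mgrid[[slice(s) for s in vol.shape]].astype(np.float64)
    coords = grid + np.moveaxis(field, -1, 0)
    warped = ndi.map_coordinates(np.asarray(vol.data, dtype=np.float64), coords, order=order, mode="nearest")
    return Volume(np.clip(warped, 0.0, None).astype(np.float32), vol.spacing_um)


def warp_phantom(
    vol: Volume, amplitude_vox: float, smoothness: float = 12.0, seed: int = 0
) -> tuple[Volume, np.ndarray]:
    """Apply a smooth random deformation; return the warped volume and the exact field."""
    field = random_displacement_field(vol.shape, amplitude_vox, smoothness, seed)
    if amplitude_vox == 0:
        return Volume(np.asarray(vol.data).copy(), vol.spacing_um), field
    return apply_displacement(vol, field), field


def simulate_counts(
    region_ids,
    groups_design: pd.DataFrame,
    baseline_mean: float = 100.0,
    log2fc_map: Optional[Mapping[str, float]] = None,
    dispersion: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-region per-animal cell counts from a negative binomial.

    Counts for an animal in group g are NB with mean
    ``mu = baseline_mean * 2**log2fc_map[g]`` and variance ``mu + mu**2 /
    dispersion`` (mean/theta parameterization, matching the GLM fitter).
    """
    if baseline_mean <= 0:
        raise ValueError("baseline_mean must be > 0")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    for c in ("animal_id", "group"):
        if c not in groups_design.columns:
            raise ValueError(f"design missing column {c!r}")
    group_sizes = groups_design.groupby("group").size()
    if len(group_sizes) < 2:
        raise ValueError("design must contain >= 2 groups")
    if (group_sizes == 0).any():
        raise ValueError("every group needs >= 1 animal")
    log2fc_map = dict(log2fc_map or {})

    rng = _named_rng(seed, _STREAMS["counts"])
    rows = []
    for rid in region_ids:
        for _, animal in groups_design.iterrows():
            g = animal["group"]
            mu = baseline_mean * 2.0 ** float(log2fc_map.get(g, 0.0))
            p = dispersion / (dispersion + mu)
            count = int(rng.negative_binomial(dispersion, p))
            rows.append(
                {"animal_id": animal["animal_id"], "group": g, "region_id": int(rid), "count": count}
            )
    return pd.DataFrame(rows)


def make_reference_ontology() -> tuple[Ontology, dict[int, int], pd.DataFrame]:
    """Synthetic stand-in for a full-brain atlas ontology.

    Builds, deterministically and without randomness, a hierarchy with the
    documented shape of the published LSFM atlas ontology: a root, six
    parental blocks (cerebral cortex, cerebral nuclei, hindbrain,
    cerebellum, septal regions, interbrain+midbrain), 284 analysis-level
    regions below them, and 666 leaf segmentations below those.  This is a
    synthetic object standing in for the atlas's own supplementary ontology
    file, which ships with the atlas, not with this package; the hierarchy
    shape is real, the node names are generated.

    Returns ``(ontology, collapse_map, partition)`` where ``collapse_map``
    maps every leaf id to its analysis-level ancestor and ``partition`` is a
    DataFrame (parent_name, region_id) assigning each leaf to one of the six
    parental blocks.
    """
    blocks = [
        ("cerebral cortex", "CTX", 80),
        ("cerebral nuclei", "CNU", 40),
        ("hindbrain", "HB", 60),
        ("cerebellum", "CB", 24),
        ("septal regions", "SEP", 20),
        ("interbrain and midbrain", "IB-MB", 60),
    ]
    assert sum(b[2] for b in blocks) == 284
    rows = [{"region_id": 1, "acronym": "root", "name": "brain", "parent_id": None}]
    next_id = 2
    block_ids = []
    analysis_ids: list[int] = []
    for name, acr, n_analysis in blocks:
        bid = next_id
        next_id += 1
        block_ids.append((bid, name))
        rows.append({"region_id": bid, "acronym": acr, "name": name, "parent_id": 1})
        for j in range(n_analysis):
            aid = next_id
            next_id += 1
            analysis_ids.append(aid)
            rows.append(
                {"region_id": aid, "acronym": f"{acr}-{j + 1}", "name": f"{name} region {j + 1}", "parent_id": bid}
            )
    # 666 leaves over 284 analysis regions: 98 regions carry 3 leaves, 186 carry 2
    leaves_per = [3] * 98 + [2] * 186
    assert sum(leaves_per) == 666
    collapse_map: dict[int, int] = {}
    partition_rows = []
    block_of = {}
    for r in rows:
        if r["parent_id"] == 1:
            block_of[r["region_id"]] = r["name"]
    for aid, k in zip(analysis_ids, leaves_per):
        parent_row = next(r for r in rows if r["region_id"] == aid)
        for j in range(k):
            lid = next_id
            next_id += 1
            rows.append(
                {
                    "region_id": lid,
                    "acronym": f"{parent_row['acronym']}.{j + 1}",
                    "name": f"{parent_row['name']} segment {j + 1}",
                    "parent_id": aid,
                }
            )
            collapse_map[lid] = aid
            partition_rows.append(
                {"parent_name": block_of[parent_row["parent_id"]], "region_id": lid}
            )
    ontology = Ontology(pd.DataFrame(rows))
    return ontology, collapse_map, pd.DataFrame(partition_rows)
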