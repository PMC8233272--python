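"""Dual-channel c-Fos cell detection.

The detector follows the adapted ClearMap chain: slice-wise 2-D affine
alignment of the marker channel onto the autofluorescence channel,
slice-wise top-hat background subtraction, removal of signal shared with
the autofluorescence channel (false-positive veto), local-maxima seeding
with a 5x5x3 filter cube, seeded watershed above an intensity cutoff of
800, and size filtering to [8, 194] voxels.  Cell centers are the seed
(peak) coordinates.

All stages are deterministic; plateau local maxima break ties to the
lexicographically first (z, y, x) voxel.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Optional

import numpy as np
import pandas as pd
import SimpleITK as sitk
from scipy import ndimage as ndi
from skimage.morphology import disk
from skimage.segmentation import watershed

from .registration import Transform, apply_transform
from .types import LabelVolume, Volume, make_cell_table


@dataclasses.dataclass
class DetectConfig:
    """Detector parameters.

    ``filter_cube`` is the local-maximum neighborhood in (z, y, x) voxels;
    its z-extent is smaller because light-sheet axial resolution is coarser
    than in-plane.  ``intensity_cutoff`` applies to the corrected specific
    channel (after background subtraction and autofluorescence removal).
    """

    filter_cube: tuple[int, int, int] = (3, 5, 5)
    intensity_cutoff: float = 800.0
    min_size_vox: int = 8
    max_size_vox: int = 194
    opening_disk_radius_vox: int = 7
    autofluor_removal: bool = True
    autofluor_scale: Optional[float] = None  # None = robust estimate
    align: bool = True

    def __post_init__(self) -> None:
        if any(c < 1 or c % 2 == 0 for c in self.filter_cube):
            raise ValueError("filter cube dimensions must be odd and >= 1")
        if not (0 < self.min_size_vox <= self.max_size_vox):
            raise ValueError("need 0 < min_size_vox <= max_size_vox")
        if self.intensity_cutoff < 0:
            raise ValueError("intensity_cutoff must be >= 0")


def _mi_2d(fixed_img: sitk.Image, moving_img: sitk.Image, tx: Optional[sitk.Transform]) -> float:
    r = sitk.ImageRegistrationMethod()
    r.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    r.SetInterpolator(sitk.sitkLinear)
    r.SetInitialTransform(tx if tx is not None else sitk.Transform(2, sitk.sitkIdentity), inPlace=False)
    return float(r.MetricEvaluate(fixed_img, moving_img))


def _run_slice_reg(fimg: sitk.Image, mimg: sitk.Image, initial: sitk.Transform, iterations: int) -> sitk.Transform:
    r = sitk.ImageRegistrationMethod()
    r.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    r.SetInterpolator(sitk.sitkLinear)
    r.SetShrinkFactorsPerLevel([2, 1])
    r.SetSmoothingSigmasPerLevel([1.0, 0.0])
    r.SetInitialTransform(initial, inPlace=True)
    r.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-5, numberOfIterations=iterations, relaxationFactor=0.6
    )
    r.SetOptimizerScalesFromPhysicalShift()
    return r.Execute(fimg, mimg)


def _register_slice_2d(
    moving: np.ndarray, fixed: np.ndarray, seed: int = 0, affine_deviation_cap_vox: float = 3.0
) -> sitk.Transform:
    """2-D affine registration of one slice pair (Mattes mutual information).

    Two stages: a translation fit (2 DOF, stable even when the two channels
    share little structure), then a full affine refinement.  The affine is
    accepted only if it improves the metric over the translation fit *and*
    moves no sampled point more than ``affine_deviation_cap_vox`` away from
    the translation solution — an unconstrained affine on a near-featureless
    slice can drift while still nominally improving mutual information.
    """
    fimg = sitk.GetImageFromArray(fixed.astype(np.float32))
    mimg = sitk.GetImageFromArray(moving.astype(np.float32))
    try:
        t_trans = _run_slice_reg(fimg, mimg, sitk.TranslationTransform(2), iterations=100)
    except RuntimeError:
        t_trans = sitk.Transform(2, sitk.sitkIdentity)
    try:
        init = sitk.CenteredTransformInitializer(
            fimg, mimg, sitk.AffineTransform(2), sitk.CenteredTransformInitializerFilter.GEOMETRY
        )
        t_aff = _run_slice_reg(fimg, mimg, init, iterations=100)
    except RuntimeError:
        return t_trans
    h, w = fixed.shape
    probes = [(0.0, 0.0), (w - 1.0, 0.0), (0.0, h - 1.0), (w - 1.0, h - 1.0), ((w - 1) / 2.0, (h - 1) / 2.0)]
    deviation = max(
        float(np.hypot(*(np.subtract(t_aff.TransformPoint(p), t_trans.TransformPoint(p)))))
        for p in probes
    )
    if deviation <= affine_deviation_cap_vox and _mi_2d(fimg, mimg, t_aff) < _mi_2d(fimg, mimg, t_trans):
        return t_aff
    return t_trans


def align_channels(auto: Volume, spec: Volume, seed: int = 0) -> Volume:
    """Slice-by-slice 2-D affine alignment of the specific channel onto the autofluorescence channel.

    Slices are processed independently; each aligned slice is the specific
    slice resampled through its own recovered transform.
    """
    if auto.shape != spec.shape:
        raise ValueError(f"channel shape mismatch: {auto.shape} vs {spec.shape}")
    a = np.asarray(auto.data, dtype=np.float32)
    s = np.asarray(spec.data, dtype=np.float32)
    out = np.empty_like(s)
    for z in range(a.shape[0]):
        if a[z].max() == a[z].min() or s[z].max() == s[z].min():
            out[z] = s[z]
            continue
        tx = _register_slice_2d(s[z], a[z], seed=seed)
        fimg = sitk.GetImageFromArray(a[z])
        mimg = sitk.GetImageFromArray(s[z])
        res = sitk.Resample(mimg, fimg, tx, sitk.sitkLinear, 0.0)
        out[z] = sitk.GetArrayFromImage(res)
    return Volume(np.clip(out, 0.0, None), spec.spacing_um)


def slice_shift_2d(moving_slice: np.ndarray, fixed_slice: np.ndarray, seed: int = 0) -> tuple[float, float]:
    """Recovered (dy, dx) of the affine mapping fixed->moving at the slice center (diagnostic)."""
    tx = _register_slice_2d(moving_slice, fixed_slice, seed=seed)
    cy, cx = [(n - 1) / 2.0 for n in fixed_slice.shape]
    qx, qy = tx.TransformPoint((cx, cy))
    return (qy - cy, qx - cx)


def subtract_background(vol: Volume, disk_radius: int = 7) -> Volume:
    """Per-slice top-hat: subtract the grayscale opening with a disk element.

    The disk radius must exceed the cell radius so point-like cells survive
    while smooth background is removed; output is everywhere in
    ``[0, input]``.
    """
    if disk_radius < 1:
        raise ValueError("disk_radius must be >= 1")
    footprint = disk(disk_radius)
    data = np.asarray(vol.data)
    out = np.empty_like(data, dtype=np.float32)
    for z in range(data.shape[0]):
        opened = ndi.grey_opening(data[z], footprint=footprint, mode="reflect")
        out[z] = data[z] - opened
    return Volume(np.clip(out, 0.0, None), vol.spacing_um)


def estimate_autofluor_scale(
    spec_bg: np.ndarray,
    auto_bg: np.ndarray,
    quantile: float = 0.99,
    ratio_quantile: float = 0.9,
) -> float:
    """Robust shared-signal scale from the spec/auto ratio over bright shared voxels.

    Candidate voxels exceed the autofluorescence channel's ``quantile``;
    among those, the estimate prefers voxels that are also bright in the
    specific channel (above its own ``quantile``), which targets genuinely
    shared structures — an artifact present in both channels at equal
    height yields a scale near 1 even when the autofluorescence channel has
    abundant marker-free texture.  The scale is the ``ratio_quantile`` of
    the ratio distribution rather than its midpoint: the veto should err on
    the side of removing shared signal, and over-subtraction is harmless
    where the autofluorescence channel is dark (marker-only cells).  Falls
    back to all bright-autofluorescence voxels when no shared-bright voxels
    exist.
    """
    bright_auto = (auto_bg > max(float(np.quantile(auto_bg, quantile)), 0.0)) & (auto_bg > 0)
    if not bright_auto.any():
        warnings.warn("autofluorescence channel has no bright voxels; using scale 1.0")
        return 1.0
    shared = bright_auto & (spec_bg > max(float(np.quantile(spec_bg, quantile)), 0.0))
    sel = shared if shared.sum() >= 20 else bright_auto
    return float(np.quantile(spec_bg[sel] / auto_bg[sel], ratio_quantile))


def remove_autofluorescence(spec_bg: Volume, auto_bg: Volume, config: Optional[DetectConfig] = None) -> Volume:
    """Veto signal shared between the channels: clamp(spec - s * auto, 0).

    ``s`` is the robust ratio estimate unless the config fixes it.  The
    output is voxelwise <= the input specific channel and >= 0, so genuine
    marker-only cells are at most mildly attenuated while shared artifacts
    are suppressed.
    """
    if spec_bg.shape != auto_bg.shape:
        raise ValueError("inputs must share one grid")
    config = config or DetectConfig()
    s_arr = np.asarray(spec_bg.data, dtype=np.float64)
    a_arr = np.asarray(auto_bg.data, dtype=np.float64)
    if config.autofluor_scale is not None:
        scale = float(config.autofluor_scale)
    elif not np.any(a_arr > 0):
        warnings.warn("autofluorescence channel all zero; falling back to scale 1.0")
        scale = 1.0
    else:
        scale = estimate_autofluor_scale(s_arr, a_arr)
    out = np.clip(s_arr - scale * a_arr, 0.0, None)
    return Volume(out.astype(np.float32), spec_bg.spacing_um)


def detect_maxima(vol: Volume, filter_cube: tuple[int, int, int] = (3, 5, 5)) -> np.ndarray:
    """Local-maxima seeds: (n, 3) integer (z, y, x) coordinates.

    A voxel is a seed iff its value equals the maximum of its (clipped)
    filter-cube neighborhood, is positive, and it is the lexicographically
    first voxel of its plateau-connected component.  Adjacent candidate
    maxima necessarily share one value, so plateau components are the
    26-connected components of the candidate mask.
    """
    if any(c < 1 or c % 2 == 0 for c in filter_cube):
        raise ValueError("filter cube dimensions must be odd and >= 1")
    data = np.asarray(vol.data)
    if data.size == 0:
        return np.zeros((0, 3), dtype=np.int64)
    neigh_max = ndi.maximum_filter(data, size=filter_cube, mode="constant", cval=0)
    cand = (data >= neigh_max) & (data > 0)
    if not cand.any():
        return np.zeros((0, 3), dtype=np.int64)
    lab, n = ndi.label(cand, structure=np.ones((3, 3, 3), dtype=bool))
    flat = np.flatnonzero(cand.ravel())
    comp = lab.ravel()[flat]
    order = np.argsort(comp, kind="stable")  # flat indices are ascending within each component
    first_of = np.searchsorted(comp[order], np.arange(1, n + 1))
    seeds_flat = flat[order][first_of]
    seeds = np.column_stack(np.unravel_index(np.sort(seeds_flat), data.shape))
    return seeds.astype(np.int64)


def watershed_segment(vol: Volume, seeds: np.ndarray, intensity_cutoff: float = 800.0) -> np.ndarray:
    """Seeded watershed on the inverted intensity above the cutoff.

    Seeds below the cutoff are dropped with a warning.  Returns an integer
    label volume; label i belongs to the i-th surviving seed (1-based),
    voxels below the cutoff carry 0.  Segments are 26-connected and each
    contains its seed.
    """
    data = np.asarray(vol.data, dtype=np.float64)
    seeds = np.atleast_2d(np.asarray(seeds, dtype=np.int64)).reshape(-1, 3)
    if seeds.size and (
        (seeds < 0).any() or (seeds >= np.asarray(data.shape)[None, :]).any()
    ):
        raise ValueError("seeds outside the volume")
    mask = data >= intensity_cutoff
    keep = np.array([mask[tuple(s)] for s in seeds], dtype=bool) if len(seeds) else np.zeros(0, bool)
    if len(seeds) and not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} seeds below the intensity cutoff")
    seeds = seeds[keep]
    markers = np.zeros(data.shape, dtype=np.int32)
    for i, s in enumerate(seeds, start=1):
        markers[tuple(s)] = i
    if not len(seeds) or not mask.any():
        return np.zeros(data.shape, dtype=np.int32)
    return watershed(-data, markers=markers, mask=mask, connectivity=np.ones((3, 3, 3), bool)).astype(np.int32)


def segment_sizes(segments: np.ndarray) -> np.ndarray:
    """Voxel count per nonzero label (index i-1 holds label i's size)."""
    segments = np.asarray(segments)
    n = int(segments.max())
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    return np.bincount(segments.ravel(), minlength=n + 1)[1:].astype(np.int64)


def filter_by_size(segments: np.ndarray, min_size: int = 8, max_size: int = 194) -> np.ndarray:
    """Keep exactly the segments whose size lies in [min_size, max_size] (inclusive)."""
    segments = np.asarray(segments)
    sizes = segment_sizes(segments)
    out = segments.copy()
    for lab, size in enumerate(sizes, start=1):
        if size < min_size or size > max_size:
            out[segments == lab] = 0
    return out


def detect_cells(auto: Volume, spec: Volume, config: Optional[DetectConfig] = None, seed: int = 0) -> pd.DataFrame:
    """Full detection chain on one subject's channel pair.

    Returns a cell table with one row per surviving watershed segment:
    seed coordinate (z, y, x), segment size, peak intensity in the
    corrected channel, and ``region_id`` 0 (assignment is a separate step).
    """
    config = config or DetectConfig()
    if auto.shape != spec.shape:
        raise ValueError("channel shapes differ")
    spec_aligned = align_channels(auto, spec, seed=seed) if config.align else spec
    spec_bg = subtract_background(spec_aligned, config.opening_disk_radius_vox)
    auto_bg = subtract_background(auto, config.opening_disk_radius_vox)
    corrected = (
        remove_autofluorescence(spec_bg, auto_bg, config) if config.autofluor_removal else spec_bg
    )
    seeds = detect_maxima(corrected, config.filter_cube)
    corr = np.asarray(corrected.data)
    # sub-cutoff maxima are background texture, not cell candidates
    above = [s for s in seeds if corr[tuple(s)] >= config.intensity_cutoff]
    seeds_above = np.asarray(above, dtype=np.int64) if above else np.zeros((0, 3), np.int64)
    segments = watershed_segment(corrected, seeds_above, config.intensity_cutoff)
    kept = filter_by_size(segments, config.min_size_vox, config.max_size_vox)
    surviving = set(np.unique(kept).tolist()) - {0}
    all_sizes = segment_sizes(segments)
    rows_c, rows_s, rows_i = [], [], []
    for lab, s in enumerate(above, start=1):
        if lab in surviving:
            rows_c.append(s)
            rows_s.append(all_sizes[lab - 1])
            rows_i.append(corr[tuple(s)])
    return make_cell_table(
        np.asarray(rows_c, dtype=float) if rows_c else np.zeros((0, 3)),
        sizes=np.asarray(rows_s, dtype=np.int64) if rows_s else None,
        intensities=np.asarray(rows_i, dtype=float) if rows_i else None,
    )


def assign_cells(
    cells: pd.DataFrame,
    atlas_labels: LabelVolume,
    transform_to_subject: Optional[Transform] = None,
) -> pd.DataFrame:
    """Count cells per atlas region.

    If ``transform_to_subject`` is given (fixed = subject grid, moving =
    atlas), the atlas labels are warped into subject space with nearest
    neighbor first.  Cells landing on label 0 are reported in an explicit
    ``unassigned`` row (region_id 0); the per-region counts plus the
    unassigned count always total the number of cells.  Returns the cell
    table with region ids filled plus a per-region count table.
    """
    if transform_to_subject is not None:
        atlas_labels = apply_transform(atlas_labels, transform_to_subject, interpolation="nearest")
    labels = np.asarray(atlas_labels.labels)
    out = cells.copy()
    region_ids = []
    for _, row in cells.iterrows():
        idx = tuple(int(round(row[c])) for c in ("z", "y", "x"))
        if all(0 <= i < s for i, s in zip(idx, labels.shape)):
            region_ids.append(int(labels[idx]))
        else:
            region_ids.append(0)
    out["region_id"] = np.asarray(region_ids, dtype=np.int64)
    counts = out.groupby("region_id", as_index=False).size().rename(columns={"size": "count"})
    return out, counts
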