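"""Volume conditioning before registration.

The fixed pipeline order is: isotropic down-sampling, multiplicative
bias-field correction, histogram normalization / contrast-limited adaptive
histogram equalization.  Every operation is deterministic and, except for
down-sampling, shape-preserving.
"""
from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure, transform

from .types import Volume

U16_MAX = 2**16 - 1


@dataclasses.dataclass
class PreprocessConfig:
    """Tunables for the conditioning pipeline.

    ``target_spacing_um`` defaults to 20 (the template's working
    resolution).  CLAHE defaults are mild: 8-voxel tiles, clip limit 0.01 of
    the tile histogram mass.
    """

    target_spacing_um: float = 20.0
    bias_correction_on: bool = True
    clahe_tile_vox: int = 8
    clahe_clip: float = 0.01
    reference_histogram: Optional[np.ndarray] = None  # reference intensities for matching

    def __post_init__(self) -> None:
        if self.target_spacing_um <= 0:
            raise ValueError("target_spacing_um must be > 0")
        if self.clahe_tile_vox < 4:
            raise ValueError("clahe_tile_vox must be >= 4")
        if self.clahe_clip <= 0:
            raise ValueError("clahe_clip must be > 0")


def downsample_isotropic(vol: Volume, target_spacing_um: float = 20.0) -> Volume:
    """Anti-aliased resampling onto an isotropic grid at ``target_spacing_um``.

    Handles anisotropic native acquisition (e.g. finer in-plane than axial
    sampling) by computing a per-axis factor; upsampling requests are
    rejected.
    """
    if target_spacing_um <= 0:
        raise ValueError("target_spacing_um must be > 0")
    factors = np.array([target_spacing_um / s for s in vol.spacing_um])
    if np.any(factors < 1.0 - 1e-9):
        raise ValueError(
            f"refusing to upsample: target {target_spacing_um} um finer than native {vol.spacing_um}"
        )
    out_shape = tuple(max(1, int(round(s / f))) for s, f in zip(vol.shape, factors))
    data = np.asarray(vol.data, dtype=np.float64)
    out = transform.resize(data, out_shape, order=1, anti_aliasing=True, preserve_range=True, mode="reflect")
    return Volume(np.clip(out, 0.0, None).astype(np.float32), target_spacing_um)


def correct_bias(vol: Volume, sigma_vox: float = 16.0, mask: Optional[np.ndarray] = None) -> Volume:
    """Remove a smooth multiplicative intensity bias field.

    The field is estimated in the log domain: the log image is smoothed
    with a wide Gaussian (normalized convolution over the foreground mask)
    and the zero-mean part of that smooth surface is divided out.  The
    output is rescaled to the input's foreground mean, so only the
    inhomogeneity changes, not the overall brightness.

    Returns the corrected volume; the estimated field is available via
    :func:`estimate_bias_field`.
    """
    field = estimate_bias_field(vol, sigma_vox, mask)
    data = np.asarray(vol.data, dtype=np.float64)
    if not np.any(data > 0):
        raise ValueError("cannot correct bias of an all-zero volume")
    m = (data > 0) if mask is None else np.asarray(mask, bool)
    out = data / field
    out *= data[m].mean() / out[m].mean()
    return Volume(np.clip(out, 0.0, None).astype(np.float32), vol.spacing_um)


def estimate_bias_field(vol: Volume, sigma_vox: float = 16.0, mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Estimate the smooth multiplicative bias field (unit geometric mean on the mask)."""
    data = np.asarray(vol.data, dtype=np.float64)
    if not np.any(data > 0):
        raise ValueError("cannot estimate bias of an all-zero volume")
    m = (data > 0) if mask is None else np.asarray(mask, bool)
    log_img = np.zeros_like(data)
    log_img[m] = np.log(data[m])
    w = m.astype(np.float64)
    num = ndi.gaussian_filter(log_img * w, sigma=sigma_vox)
    den = ndi.gaussian_filter(w, sigma=sigma_vox)
    smooth = np.where(den > 1e-12, num / np.maximum(den, 1e-12), 0.0)
    smooth -= smooth[m].mean()
    field = np.exp(smooth)
    field[~m] = 1.0
    return field


def match_histogram(vol: Volume, reference: np.ndarray) -> Volume:
    """Monotone intensity remap so the volume's histogram matches a reference sample."""
    ref = np.sort(np.asarray(reference, dtype=np.float64).ravel())
    data = np.asarray(vol.data, dtype=np.float64)
    order = np.argsort(data.ravel(), kind="stable")
    quantiles = (np.arange(data.size) + 0.5) / data.size
    mapped = np.empty(data.size)
    mapped[order] = np.interp(quantiles, (np.arange(ref.size) + 0.5) / ref.size, ref)
    return Volume(np.clip(mapped.reshape(data.shape), 0.0, None).astype(np.float32), vol.spacing_um)


def equalize(vol: Volume, config: Optional[PreprocessConfig] = None) -> Volume:
    """Histogram normalization followed by contrast-limited adaptive equalization.

    If the config carries a reference histogram sample, the volume is first
    histogram-matched to it; CLAHE then operates on tiles of
    ``clahe_tile_vox`` voxels with clip limit ``clahe_clip``.  Output covers
    the 16-bit range [0, 65535].  A degenerate (single-valued) volume is
    returned unchanged.
    """
    config = config or PreprocessConfig()
    data = np.asarray(vol.data, dtype=np.float64)
    if data.max() == data.min():
        return Volume(data.astype(np.float32), vol.spacing_um)
    if config.reference_histogram is not None:
        data = np.asarray(match_histogram(Volume(data, vol.spacing_um), config.reference_histogram).data, dtype=np.float64)
        if data.max() == data.min():
            return Volume(data.astype(np.float32), vol.spacing_um)
    lo, hi = data.min(), data.max()
    unit = (data - lo) / (hi - lo)
    kernel = tuple(min(config.clahe_tile_vox, s) for s in vol.shape)
    eq = exposure.equalize_adapthist(unit, kernel_size=kernel, clip_limit=config.clahe_clip)
    out = np.clip(eq * U16_MAX, 0.0, U16_MAX)
    return Volume(out.astype(np.float32), vol.spacing_um)


def preprocess(vol: Volume, config: Optional[PreprocessConfig] = None) -> Volume:
    """Full conditioning pipeline: downsample -> bias correction -> equalize."""
    config = config or PreprocessConfig()
    out = vol
    if any(s < config.target_spacing_um - 1e-9 for s in out.spacing_um):
        out = downsample_isotropic(out, config.target_spacing_um)
    if config.bias_correction_on:
        out = correct_bias(out)
    return equalize(out, config)
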