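"""Iterative population-average template construction and symmetrization.

The template is built by the register-then-average iteration: every subject
volume is registered to the current reference (the chosen subject in
iteration 1, the previous iteration's average afterwards) and the
registered volumes are averaged voxelwise.  The default schedule is six
iterations — one affine followed by five B-spline refinements.
"""
from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .preprocess import match_histogram
from .registration import Transform, apply_transform, identity_transform, register
from .types import Volume


@dataclasses.dataclass
class TemplateBuildConfig:
    """Schedule and options for iterative template averaging.

    ``iteration_models`` defaults to one affine step followed by five
    B-spline steps; ``reference_index`` selects the starting subject (or is
    drawn with ``reference_seed`` when None).  Averaging is the voxelwise
    arithmetic mean of the registered (optionally histogram-normalized)
    volumes.
    """

    iteration_models: Sequence[str] = ("affine",) + ("bspline",) * 5
    reference_index: Optional[int] = 0
    reference_seed: int = 0
    histogram_normalize: bool = True
    levels: int = 3
    iterations_per_model: int = 60
    control_spacing_vox: float = 8.0
    sampling_fraction: float = 0.25
    seed: int = 0

    @property
    def n_iterations(self) -> int:
        return len(self.iteration_models)

    def __post_init__(self) -> None:
        if len(self.iteration_models) < 1:
            raise ValueError("need at least one iteration model")
        for m in self.iteration_models:
            if m not in ("affine", "bspline"):
                raise ValueError(f"unknown model {m!r}")


def build_template(
    volumes: Sequence[Volume], config: Optional[TemplateBuildConfig] = None
) -> tuple[Volume, list[Transform]]:
    """Build a population-average template.

    Iteration 1 registers every volume to the reference subject with the
    first model and averages; iteration k >= 2 registers every *original*
    volume to the iteration-(k-1) average with the k-th model and averages.
    Returns the final average and the final per-subject transforms
    (fixed = template grid, moving = subject).
    """
    if len(volumes) == 0:
        raise ValueError("need at least one volume")
    config = config or TemplateBuildConfig()
    shapes = {v.shape for v in volumes}
    spacings = {v.spacing_um for v in volumes}
    if len(shapes) > 1 or len(spacings) > 1:
        raise ValueError("all volumes must share one grid (shape and spacing)")

    if config.reference_index is None:
        rng = np.random.default_rng(config.reference_seed)
        ref_idx = int(rng.integers(len(volumes)))
    else:
        ref_idx = int(config.reference_index)
    reference = volumes[ref_idx]

    transforms: list[Transform] = [identity_transform(reference.shape) for _ in volumes]
    average = reference
    for it, model in enumerate(config.iteration_models):
        registered: list[Volume] = []
        new_transforms: list[Transform] = []
        ref_sample = np.asarray(average.data).ravel()
        for i, vol in enumerate(volumes):
            if it == 0 and i == ref_idx:
                t: Transform = identity_transform(reference.shape)
                reg = vol
            else:
                t, _ = register(
                    vol,
                    average,
                    model=model,
                    levels=config.levels,
                    seed=config.seed + i,
                    iterations=config.iterations_per_model,
                    control_spacing_vox=config.control_spacing_vox,
                    sampling_fraction=config.sampling_fraction,
                )
                reg = apply_transform(vol, t)
            if config.histogram_normalize:
                reg = match_histogram(reg, ref_sample)
            registered.append(reg)
            new_transforms.append(t)
        stack = np.stack([np.asarray(r.data, dtype=np.float64) for r in registered])
        average = Volume(stack.mean(axis=0).astype(np.float32), reference.spacing_um)
        transforms = new_transforms
    return average, transforms


def registered_stack(volumes: Sequence[Volume], transforms: Sequence[Transform]) -> list[Volume]:
    """Resample every subject through its template transform."""
    return [apply_transform(v, t) for v, t in zip(volumes, transforms)]


def mirror(data: np.ndarray, axis: int) -> np.ndarray:
    return np.flip(data, axis=axis)


def symmetrize(template: Volume, midplane_axis: int = 2, blend_width_vox: float = 4.0) -> Volume:
    """Mirror one hemisphere onto the other and merge with a sigmoidal blend.

    The blend weight is a logistic function of the (signed) distance to the
    midplane with transition width ``blend_width_vox``; the weight array is
    constructed so that ``w(mirror(x)) = 1 - w(x)`` holds bit-exactly,
    which makes the output exactly invariant under mirroring about the
    midplane.  At the midplane the output is the exact hemisphere average.
    """
    data = np.asarray(template.data, dtype=np.float64)
    n = data.shape[midplane_axis]
    if n < 2:
        raise ValueError("template must have width >= 2 on the midplane axis")
    if blend_width_vox <= 0:
        raise ValueError("blend_width_vox must be > 0")
    c = (n - 1) / 2.0
    idx = np.arange(n, dtype=np.float64)
    w = 1.0 / (1.0 + np.exp((idx - c) / (blend_width_vox / 4.0)))
    # enforce exact antisymmetry: w[n-1-i] = 1 - w[i], and w = 0.5 at an integer midplane
    half = (n + 1) // 2
    w[n - 1 :: -1][:half] = 1.0 - w[:half]
    if n % 2 == 1:
        w[n // 2] = 0.5
    shape = [1, 1, 1]
    shape[midplane_axis] = n
    w = w.reshape(shape)
    mirrored = mirror(data, midplane_axis)
    out = w * data + (1.0 - w) * mirrored
    return Volume(out.astype(np.float64), template.spacing_um)
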