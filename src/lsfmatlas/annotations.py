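"""Atlas annotation transfer onto a template and hierarchical region collapsing.

Labels are moved from an annotated source atlas to a target template in two
registration passes: one whole-brain pass, then one pass per parental block
(cerebral cortex, cerebral nuclei, hindbrain, cerebellum, septal regions,
interbrain+midbrain by default) with the templates masked to the block.
Block-wise label volumes are recombined with a deterministic
nearest-claimed-voxel rule.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .registration import Transform, apply_transform, compose, register
from .types import LabelVolume, Ontology, Volume

DEFAULT_BLOCK_NAMES = (
    "cerebral cortex",
    "cerebral nuclei",
    "hindbrain",
    "cerebellum",
    "septal regions",
    "interbrain and midbrain",
)


@dataclasses.dataclass
class ParentalPartition:
    """Assignment of every labeled region to one parental block.

    ``blocks`` maps a parent block name to the set of region ids it owns;
    the sets must be disjoint and jointly cover the labels present in the
    source annotation.
    """

    blocks: dict[str, set[int]]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for name, ids in self.blocks.items():
            ids = set(int(i) for i in ids)
            overlap = seen & ids
            if overlap:
                raise ValueError(f"region ids {sorted(overlap)} appear in more than one block")
            seen |= ids
            self.blocks[name] = ids

    @property
    def all_ids(self) -> set[int]:
        out: set[int] = set()
        for ids in self.blocks.values():
            out |= ids
        return out

    def validate_against(self, labels: LabelVolume) -> None:
        present = set(labels.present_labels())
        uncovered = present - self.all_ids
        if uncovered:
            raise ValueError(f"partition does not cover labels: {sorted(uncovered)}")

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "ParentalPartition":
        """Build from a (parent_name, region_id) table."""
        for c in ("parent_name", "region_id"):
            if c not in table.columns:
                raise ValueError(f"partition table missing column {c!r}")
        blocks: dict[str, set[int]] = {}
        for name, sub in table.groupby("parent_name"):
            blocks[str(name)] = set(int(r) for r in sub["region_id"])
        return cls(blocks)

    @classmethod
    def single_block(cls, labels: LabelVolume, name: str = "whole brain") -> "ParentalPartition":
        return cls({name: set(labels.present_labels())})


def resolve_overlaps(
    block_label_volumes: Sequence[LabelVolume], tissue_mask: np.ndarray
) -> LabelVolume:
    """Recombine block-wise label volumes into one conflict-free annotation.

    A voxel claimed by exactly one block keeps that block's label.  Voxels
    claimed by several blocks, or claimed by none while inside the tissue
    mask, receive the label of the nearest uniquely-claimed voxel by
    Euclidean distance; exact distance ties break to the smaller region id
    (per-label distance transforms scanned in ascending id order).
    """
    if len(block_label_volumes) == 0:
        raise ValueError("need at least one block label volume")
    shape = block_label_volumes[0].shape
    spacing = block_label_volumes[0].spacing_um
    tissue_mask = np.asarray(tissue_mask, bool)
    if tissue_mask.shape != tuple(shape):
        raise ValueError("tissue mask shape mismatch")

    stack = np.stack([np.asarray(b.labels) for b in block_label_volumes])
    claims = (stack > 0).sum(axis=0)
    merged = stack.sum(axis=0)
    unique = claims == 1
    out = np.where(unique, merged, 0).astype(np.int64)
    if not unique.any():
        raise ValueError("no voxel is uniquely claimed by any block")

    todo = tissue_mask & ~unique
    if todo.any():
        labels_present = np.unique(out[unique])
        labels_present = labels_present[labels_present > 0]
        best_d = np.full(shape, np.inf)
        best_l = np.zeros(shape, dtype=np.int64)
        for lab in labels_present:  # ascending id order => ties keep the smaller id
            d = ndi.distance_transform_edt(out != lab)
            take = todo & (d < best_d)
            best_d[take] = d[take]
            best_l[take] = lab
        out[todo] = best_l[todo]

    out[~tissue_mask & ~unique] = 0
    ont = block_label_volumes[0].ontology
    return LabelVolume(out, spacing, ontology=ont, tissue_mask=tissue_mask)


def transfer_annotations(
    source_template: Volume,
    source_labels: LabelVolume,
    target_template: Volume,
    partition: Optional[ParentalPartition] = None,
    target_mask: Optional[np.ndarray] = None,
    mask_dilation_vox: int = 5,
    levels: int = 3,
    iterations: int = 60,
    seed: int = 0,
    patch: Optional[LabelVolume] = None,
) -> LabelVolume:
    """Map source-atlas labels onto a target template by multi-regional registration.

    Step 1 registers the whole source template to the target (affine, then
    B-spline).  Step 2 repeats the B-spline registration per parental
    block, with the metric restricted to the (dilated) block mask so each
    block's anatomy drives its own deformation.  Step 3 warps every block's
    labels with its block transform (nearest neighbor) and recombines them;
    every in-mask target voxel receives exactly one label.  An optional
    ``patch`` overlay (user-supplied label corrections) is applied last.
    """
    if partition is None:
        partition = ParentalPartition.single_block(source_labels)
    partition.validate_against(source_labels)

    t_aff, _ = register(source_template, target_template, model="affine", levels=levels, seed=seed, iterations=max(iterations, 100))
    src_affine = apply_transform(source_template, t_aff)
    t_bsp, _ = register(src_affine, target_template, model="bspline", levels=levels, seed=seed, iterations=iterations)
    global_t = compose(t_aff, t_bsp)

    if target_mask is None:
        thr = np.asarray(target_template.data)
        target_mask = thr > 0.05 * thr.max()
    target_mask = np.asarray(target_mask, bool)

    whole_labels = apply_transform(source_labels, global_t, interpolation="nearest")

    block_vols: list[LabelVolume] = []
    src_arr = np.asarray(source_labels.labels)
    for name in sorted(partition.blocks):
        ids = partition.blocks[name]
        block_src_mask = np.isin(src_arr, sorted(ids))
        if not block_src_mask.any():
            raise ValueError(f"block {name!r} is empty in the source labels")
        # the block's whereabouts in the target, from the whole-brain pass
        block_tgt_mask = np.isin(np.asarray(whole_labels.labels), sorted(ids))
        if not block_tgt_mask.any():
            raise ValueError(f"block {name!r} mapped to nothing in the target")
        dil = ndi.binary_dilation(block_tgt_mask, iterations=mask_dilation_vox)

        t_block, _ = register(
            src_affine,
            target_template,
            model="bspline",
            levels=levels,
            seed=seed,
            iterations=iterations,
            fixed_mask=dil,
        )
        t_total = compose(t_aff, t_block)
        masked_src = LabelVolume(
            np.where(block_src_mask, src_arr, 0).astype(src_arr.dtype),
            source_labels.spacing_um,
            ontology=source_labels.ontology,
        )
        block_vols.append(apply_transform(masked_src, t_total, interpolation="nearest"))

    out = resolve_overlaps(block_vols, target_mask)
    if patch is not None:
        patched = np.asarray(out.labels).copy()
        overlay = np.asarray(patch.labels)
        patched[overlay > 0] = overlay[overlay > 0]
        out = LabelVolume(patched, out.spacing_um, ontology=out.ontology, tissue_mask=out.tissue_mask)
    return out


def collapse_labels(labels: LabelVolume, level_map: Mapping[int, int]) -> LabelVolume:
    """Re-map every labeled voxel to its analysis-level ancestor."""
    arr = np.asarray(labels.labels)
    out = arr.copy()
    for leaf, anc in level_map.items():
        out[arr == leaf] = anc
    present = set(np.unique(arr).tolist()) - {0}
    unmapped = present - set(level_map) - set(level_map.values())
    if unmapped:
        raise ValueError(f"labels with no mapped ancestor: {sorted(unmapped)}")
    return LabelVolume(out, labels.spacing_um, ontology=labels.ontology, tissue_mask=labels.tissue_mask)


def collapse_counts(
    counts: pd.DataFrame, ontology: Ontology, level_map: Mapping[int, int]
) -> pd.DataFrame:
    """Sum per-leaf counts up to their analysis-level ancestors.

    Total count is conserved exactly; a leaf missing from ``level_map`` is
    an error unless it already is an analysis-level region (maps to
    itself).
    """
    df = counts.copy()
    mapped = []
    known = set(ontology.region_ids)
    for rid in df["region_id"]:
        rid = int(rid)
        if rid in level_map:
            mapped.append(int(level_map[rid]))
        elif rid in set(level_map.values()) or rid in known:
            mapped.append(rid)
        else:
            raise ValueError(f"leaf region {rid} has no mapped ancestor")
    df["region_id"] = mapped
    group_cols = [c for c in ("animal_id", "group") if c in df.columns]
    out = df.groupby(group_cols + ["region_id"], as_index=False, sort=True)["count"].sum()
    return out


def collapse_to_parents(
    counts_or_labels: Union[pd.DataFrame, LabelVolume],
    ontology: Ontology,
    level_map: Mapping[int, int],
):
    """Collapse leaf-level counts or labels to their parental analysis regions."""
    if isinstance(counts_or_labels, LabelVolume):
        return collapse_labels(counts_or_labels, level_map)
    return collapse_counts(counts_or_labels, ontology, level_map)


def n_analysis_regions(ontology: Ontology, level_map: Mapping[int, int]) -> int:
    """Number of distinct analysis-level regions the leaves collapse into."""
    targets = set()
    for leaf in ontology.leaves:
        targets.add(int(level_map.get(leaf, leaf)))
    return len(targets)
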