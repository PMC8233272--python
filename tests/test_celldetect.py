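"""Detector stages against brute-force oracles, plus chain-level properties.

The 50-seed oracle sweep and the full phantom recall/precision run live in
the acceptance suite; these tests keep each stage pinned at small sizes.
"""
import heapq

import numpy as np
import pytest
from scipy import ndimage as ndi

from lsfmatlas import celldetect
from lsfmatlas.celldetect import (
    DetectConfig,
    align_channels,
    detect_cells,
    detect_maxima,
    filter_by_size,
    remove_autofluorescence,
    subtract_background,
    watershed_segment,
)
from lsfmatlas.types import LabelVolume, Volume


# ---------------------------------------------------------------- oracles


def brute_force_maxima(data, cube):
    """Exhaustive neighborhood scan + plateau dedup by lexicographic first voxel."""
    rz, ry, rx = (c // 2 for c in cube)
    nz, ny, nx = data.shape
    cand = np.zeros(data.shape, bool)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                v = data[z, y, x]
                if v <= 0:
                    continue
                neigh = data[
                    max(0, z - rz) : z + rz + 1,
                    max(0, y - ry) : y + ry + 1,
                    max(0, x - rx) : x + rx + 1,
                ]
                if v >= neigh.max():
                    cand[z, y, x] = True
    lab, n = ndi.label(cand, structure=np.ones((3, 3, 3), bool))
    seeds = []
    for i in range(1, n + 1):
        vox = np.argwhere(lab == i)
        seeds.append(vox[np.lexsort((vox[:, 2], vox[:, 1], vox[:, 0]))][0])
    return np.array(sorted(map(tuple, seeds))) if seeds else np.zeros((0, 3), int)


def brute_force_tophat(plane, radius):
    """Erosion-then-dilation with a disk footprint, subtracted from the input."""
    from skimage.morphology import disk

    fp = disk(radius).astype(bool)
    r = radius
    padded = np.pad(plane, r, mode="reflect")
    eroded = np.zeros_like(plane, dtype=float)
    ny, nx = plane.shape
    for y in range(ny):
        for x in range(nx):
            eroded[y, x] = padded[y : y + 2 * r + 1, x : x + 2 * r + 1][fp].min()
    pad_e = np.pad(eroded, r, mode="reflect")
    opened = np.zeros_like(plane, dtype=float)
    for y in range(ny):
        for x in range(nx):
            opened[y, x] = pad_e[y : y + 2 * r + 1, x : x + 2 * r + 1][fp].max()
    return np.clip(plane - opened, 0, None)


def priority_flood_watershed(data, seeds, cutoff):
    """Heap-based priority flood on inverted intensity, restricted to data >= cutoff."""
    mask = data >= cutoff
    labels = np.zeros(data.shape, np.int32)
    heap = []
    counter = 0
    for i, s in enumerate(seeds, start=1):
        s = tuple(s)
        if mask[s]:
            labels[s] = i
            heapq.heappush(heap, (-data[s], counter, s, i))
            counter += 1
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    shape = data.shape
    while heap:
        _, _, vox, lab = heapq.heappop(heap)
        for off in offsets:
            n = tuple(v + o for v, o in zip(vox, off))
            if all(0 <= ni < si for ni, si in zip(n, shape)) and mask[n] and labels[n] == 0:
                labels[n] = lab
                heapq.heappush(heap, (-data[n], counter, n, lab))
                counter += 1
    return labels


# ---------------------------------------------------------------- stage tests


class TestDetectMaxima:
    def test_empty_volume_no_seeds(self):
        assert len(detect_maxima(Volume(np.zeros((8, 8, 8)), 20.0))) == 0

    def test_single_spike_single_seed(self):
        data = np.zeros((8, 8, 8), np.float32)
        data[4, 5, 6] = 10
        seeds = detect_maxima(Volume(data, 20.0))
        np.testing.assert_array_equal(seeds, [[4, 5, 6]])

    def test_matches_brute_force_scan(self, rng):
        for _ in range(5):
            data = rng.integers(0, 12, size=(10, 12, 12)).astype(np.float32)
            got = detect_maxima(Volume(data, 20.0), (3, 5, 5))
            want = brute_force_maxima(data, (3, 5, 5))
            np.testing.assert_array_equal(got, want)

    def test_plateau_takes_lexicographically_first(self):
        data = np.zeros((6, 6, 6), np.float32)
        data[2, 2, 2:5] = 7.0  # 3-voxel plateau
        seeds = detect_maxima(Volume(data, 20.0))
        np.testing.assert_array_equal(seeds, [[2, 2, 2]])

    def test_even_cube_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            detect_maxima(Volume(np.zeros((4, 4, 4)), 20.0), (2, 4, 4))


class TestSubtractBackground:
    def test_constant_slice_goes_to_zero(self):
        vol = Volume(np.full((3, 20, 20), 500.0, np.float32), 20.0)
        out = subtract_background(vol, disk_radius=3)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_isolated_spike_preserved(self):
        data = np.full((1, 21, 21), 100.0, np.float32)
        data[0, 10, 10] = 1100.0
        out = subtract_background(Volume(data, 20.0), disk_radius=3)
        assert out.data[0, 10, 10] == pytest.approx(1000.0)

    def test_bounded_by_input_and_zero(self, rng):
        vol = Volume(rng.uniform(0, 1000, (4, 24, 24)).astype(np.float32), 20.0)
        out = subtract_background(vol, disk_radius=3)
        assert (out.data >= 0).all()
        assert (out.data <= vol.data + 1e-3).all()

    def test_matches_brute_force_tophat(self, rng):
        data = rng.uniform(0, 1000, (2, 16, 16)).astype(np.float32)
        out = subtract_background(Volume(data, 20.0), disk_radius=2)
        for z in range(2):
            want = brute_force_tophat(data[z], 2)
            np.testing.assert_allclose(out.data[z], want, atol=1e-3)


class TestRemoveAutofluorescence:
    def test_zero_auto_leaves_spec_unchanged(self, rng):
        spec = Volume(rng.uniform(0, 1000, (6, 12, 12)).astype(np.float32), 20.0)
        auto = Volume(np.zeros((6, 12, 12), np.float32), 20.0)
        with pytest.warns(UserWarning, match="all zero"):
            out = remove_autofluorescence(spec, auto)
        np.testing.assert_allclose(out.data, spec.data)

    def test_clamp_contract(self, rng):
        spec = Volume(rng.uniform(0, 1000, (6, 12, 12)).astype(np.float32), 20.0)
        auto = Volume(rng.uniform(0, 1000, (6, 12, 12)).astype(np.float32), 20.0)
        out = remove_autofluorescence(spec, auto)
        assert (out.data >= 0).all()
        assert (out.data <= spec.data + 1e-3).all()

    def test_fixed_scale_used(self, rng):
        spec = Volume(rng.uniform(500, 1000, (4, 8, 8)).astype(np.float32), 20.0)
        auto = Volume(np.full((4, 8, 8), 100.0, np.float32), 20.0)
        out = remove_autofluorescence(spec, auto, DetectConfig(autofluor_scale=2.0))
        np.testing.assert_allclose(out.data, np.clip(spec.data - 200.0, 0, None), atol=1e-3)

    def test_shared_artifact_suppressed_cells_kept(self):
        """Equal-height shared artifact drops below the cutoff; marker-only cell survives."""
        shape = (8, 24, 24)
        spec = np.full(shape, 0.0, np.float32)
        auto = np.zeros(shape, np.float32)
        spec[4, 6, 6] = 3000.0  # marker-only cell
        spec[4, 16, 16] = 2500.0  # shared artifact
        auto[4, 16, 16] = 2500.0
        out = remove_autofluorescence(Volume(spec, 20.0), Volume(auto, 20.0))
        assert out.data[4, 16, 16] < 800.0
        assert out.data[4, 6, 6] >= 0.99 * 3000.0


class TestWatershed:
    def test_uniform_blob_single_segment(self):
        data = np.zeros((8, 8, 8), np.float32)
        data[2:5, 2:5, 2:5] = 1000.0
        labels = watershed_segment(Volume(data, 20.0), np.array([[3, 3, 3]]), 800.0)
        np.testing.assert_array_equal(labels > 0, data >= 800.0)

    def test_no_voxel_above_cutoff_no_segments(self):
        data = np.full((6, 6, 6), 100.0, np.float32)
        with pytest.warns(UserWarning, match="below the intensity cutoff"):
            labels = watershed_segment(Volume(data, 20.0), np.array([[3, 3, 3]]), 800.0)
        assert labels.max() == 0

    def test_two_peaks_split_in_valley(self):
        z, y, x = np.mgrid[0:5, 0:20, 0:9].astype(float)
        data = 2000 * np.exp(-((y - 5) ** 2) / 8) + 2000 * np.exp(-((y - 14) ** 2) / 8)
        vol = Volume(data.astype(np.float32), 20.0)
        seeds = np.array([[2, 5, 4], [2, 14, 4]])
        labels = watershed_segment(vol, seeds, 800.0)
        assert labels[2, 5, 4] == 1 and labels[2, 14, 4] == 2
        # the boundary lies in the valley between the peaks
        boundary_y = [y_ for y_ in range(20) if len(set(labels[2, y_, :][labels[2, y_, :] > 0])) > 1]
        assert all(8 <= y_ <= 11 for y_ in boundary_y)

    def test_matches_priority_flood_oracle(self, rng):
        for _ in range(3):
            data = rng.uniform(0, 2000, (8, 10, 10)).astype(np.float64)
            seeds = detect_maxima(Volume(data, 20.0), (3, 3, 3))
            got = watershed_segment(Volume(data, 20.0), seeds, 800.0)
            want = priority_flood_watershed(data, seeds, 800.0)
            np.testing.assert_array_equal(got, want)


class TestFilterBySize:
    def test_boundary_sizes_inclusive(self):
        segments = np.zeros((1, 1, 600), np.int32)
        start = 0
        for lab, size in enumerate([5, 8, 100, 194, 195], start=1):
            segments[0, 0, start : start + size] = lab
            start += size + 1
        out = filter_by_size(segments, 8, 194)
        assert sorted(set(out.ravel()) - {0}) == [2, 3, 4]

    def test_empty_input(self):
        out = filter_by_size(np.zeros((4, 4, 4), np.int32), 8, 194)
        assert out.max() == 0

    def test_matches_brute_force_size_scan(self, rng):
        data = rng.uniform(0, 2000, (10, 12, 12))
        seeds = detect_maxima(Volume(data, 20.0), (3, 3, 3))
        segments = watershed_segment(Volume(data, 20.0), seeds, 500.0)
        out = filter_by_size(segments, 5, 50)
        for lab in range(1, segments.max() + 1):
            size = int((segments == lab).sum())
            survived = lab in out
            assert survived == (5 <= size <= 50)


class TestAlignChannels:
    def test_self_alignment_near_identity(self, small_phantom):
        auto, _, _ = small_phantom
        sub = Volume(np.asarray(auto.data)[:4], auto.spacing_um)
        for z in range(4):
            dy, dx = celldetect.slice_shift_2d(
                np.asarray(sub.data)[z], np.asarray(sub.data)[z], seed=1
            )
            assert abs(dy) <= 0.25 and abs(dx) <= 0.25

    def test_known_shift_recovered(self, small_phantom):
        auto, _, _ = small_phantom
        a = np.asarray(auto.data)[10]
        shifted = np.roll(np.roll(a, 3, axis=0), -2, axis=1)
        dy, dx = celldetect.slice_shift_2d(shifted, a, seed=1)
        # moving(x) = fixed(x - shift) => transform maps fixed -> moving with +shift
        assert abs(dy - 3) <= 0.5 and abs(dx + 2) <= 0.5

    def test_slice_independence(self, small_phantom):
        auto, _, _ = small_phantom
        a = Volume(np.asarray(auto.data)[:6], auto.spacing_um)
        s = Volume(np.asarray(auto.data)[2:8], auto.spacing_um)
        out = align_channels(a, s, seed=2)
        perm = [3, 1, 4, 0, 5, 2]
        a_p = Volume(np.asarray(a.data)[perm], auto.spacing_um)
        s_p = Volume(np.asarray(s.data)[perm], auto.spacing_um)
        out_p = align_channels(a_p, s_p, seed=2)
        np.testing.assert_array_equal(np.asarray(out.data)[perm], out_p.data)


class TestDetectCells:
    def test_determinism(self, detection_phantom):
        auto, spec, *_ = detection_phantom
        cfg = DetectConfig(align=False)
        c1 = detect_cells(auto, spec, cfg, seed=1)
        c2 = detect_cells(auto, spec, cfg, seed=1)
        np.testing.assert_array_equal(c1.to_numpy(), c2.to_numpy())

    def test_cutoff_monotonicity(self, detection_phantom):
        """Raising the intensity cutoff never increases the number of cells."""
        auto, spec, *_ = detection_phantom
        previous = None
        for cutoff in (400.0, 800.0, 1600.0):
            cells = detect_cells(auto, spec, DetectConfig(align=False, intensity_cutoff=cutoff))
            if previous is not None:
                assert len(cells) <= previous
            previous = len(cells)

    def test_size_bound_monotonicity(self, detection_phantom):
        auto, spec, *_ = detection_phantom
        narrow = detect_cells(auto, spec, DetectConfig(align=False, min_size_vox=20, max_size_vox=100))
        wide = detect_cells(auto, spec, DetectConfig(align=False, min_size_vox=8, max_size_vox=194))
        assert len(wide) >= len(narrow)

    def test_sizes_within_bounds(self, detection_phantom):
        auto, spec, *_ = detection_phantom
        cells = detect_cells(auto, spec, DetectConfig(align=False))
        assert cells["size"].between(8, 194).all()


class TestAssignCells:
    def test_counts_by_lookup_and_conservation(self, small_phantom, rng):
        from lsfmatlas.celldetect import assign_cells
        from lsfmatlas.types import make_cell_table

        _, lab, _ = small_phantom
        n = 40
        centers = np.column_stack([rng.integers(0, s, n) for s in lab.shape]).astype(float)
        cells = make_cell_table(centers)
        out, counts = assign_cells(cells, lab)
        # conservation: per-region counts plus unassigned equals total
        assert counts["count"].sum() == n
        # brute-force lookup oracle
        for _, row in out.iterrows():
            idx = (int(row["z"]), int(row["y"]), int(row["x"]))
            assert row["region_id"] == lab.labels[idx]

    def test_all_cells_in_one_region(self, small_phantom):
        from lsfmatlas.celldetect import assign_cells
        from lsfmatlas.types import make_cell_table

        _, lab, _ = small_phantom
        rid = lab.present_labels()[0]
        vox = np.argwhere(lab.labels == rid)[:10].astype(float)
        out, counts = assign_cells(make_cell_table(vox), lab)
        assert counts.loc[counts["region_id"] == rid, "count"].item() == 10
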