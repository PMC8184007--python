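"""Volume preprocessing: resampling, thresholding, neighborhood filtering,
small-object removal, and labeling."""

import numpy as np
import pytest

from polkadots.preprocess import (
    BinaryVolume,
    IntensityVolume,
    binarize_channel,
    label_components,
    neighbor_filter,
    preprocess_channel,
    remove_small_noise,
    resample_isotropic,
)


class TestResampleIsotropic:
    def test_isotropic_input_unchanged(self, rng):
        v = IntensityVolume(rng.random((8, 8, 8)), (25.0, 25.0, 25.0))
        out = resample_isotropic(v, 25.0)
        assert out.voxel_size == (25.0, 25.0, 25.0)
        np.testing.assert_allclose(out.values, v.values, atol=1e-9)

    def test_linear_ramp_exact_in_interior(self):
        # z-ramp sampled at 200 nm, resampled to 25 nm: cubic splines
        # reproduce linear fields exactly away from the boundary
        nz = 48
        vals = np.broadcast_to(
            np.arange(nz, dtype=float)[:, None, None] * 200.0, (nz, 6, 6)
        ).copy()
        v = IntensityVolume(vals, (200.0, 25.0, 25.0))
        out = resample_isotropic(v, 25.0)
        assert out.values.shape[0] == (nz - 1) * 8 + 1
        z = np.arange(out.values.shape[0]) * 25.0
        # spline-prefilter boundary effects decay as (2 - sqrt(3))^d; 20
        # input planes leave < 1e-6 in the interior
        interior = slice(160, -160)
        np.testing.assert_allclose(
            out.values[interior, 3, 3], z[interior], atol=1e-6)

    def test_constant_field_constant(self):
        v = IntensityVolume(np.full((6, 6, 10), 7.0), (200.0, 50.0, 25.0))
        out = resample_isotropic(v, 25.0)
        np.testing.assert_allclose(out.values, 7.0, atol=1e-9)

    def test_pitch_exceeding_extent_raises(self):
        v = IntensityVolume(np.ones((4, 4, 4)), (25.0, 25.0, 25.0))
        with pytest.raises(ValueError):
            resample_isotropic(v, 1e6)


class TestBinarize:
    def test_zero_volume_empty(self):
        v = IntensityVolume(np.zeros((5, 5, 5)), (25.0,) * 3)
        assert binarize_channel(v, 0.5).n_occupied == 0

    def test_threshold_at_min_fills(self, rng):
        vals = rng.random((5, 5, 5)) + 1.0
        v = IntensityVolume(vals, (25.0,) * 3)
        assert binarize_channel(v, vals.min()).n_occupied == 125

    def test_occupancy_equals_exceedance_count(self, rng):
        vals = rng.random((10, 10, 10))
        v = IntensityVolume(vals, (25.0,) * 3)
        out = binarize_channel(v, 0.6)
        assert out.n_occupied == int((vals >= 0.6).sum())


def _brute_force_neighbor_filter(occ, min_neighbors=8, include_center=True):
    out = np.zeros_like(occ)
    nz, ny, nx = occ.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not occ[z, y, x]:
                    continue
                cnt = 0
                for dz in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            if not include_center and dz == dy == dx == 0:
                                continue
                            zz, yy, xx = z + dz, y + dy, x + dx
                            if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                                cnt += occ[zz, yy, xx]
                out[z, y, x] = cnt >= min_neighbors
    return out


class TestNeighborFilter:
    def test_exactly_eight_retained_seven_removed(self):
        # center voxel plus k neighbors: count includes the center, so the
        # (2/3)^3 kernel cutoff keeps the center iff k >= 7
        for k, kept in ((7, True), (6, False)):
            occ = np.zeros((5, 5, 5), dtype=bool)
            occ[2, 2, 2] = True
            nbrs = [(1, 1, 1), (1, 2, 2), (2, 1, 2), (2, 2, 1),
                    (3, 2, 2), (2, 3, 2), (2, 2, 3)]
            for p in nbrs[:k]:
                occ[p] = True
            out = neighbor_filter(BinaryVolume(occ))
            assert bool(out.occupancy[2, 2, 2]) is kept

    def test_solid_cube_interior_unchanged(self):
        occ = np.zeros((7, 7, 7), dtype=bool)
        occ[1:6, 1:6, 1:6] = True
        out = neighbor_filter(BinaryVolume(occ))
        assert out.occupancy[2:5, 2:5, 2:5].all()

    def test_matches_brute_force_on_random_volume(self, rng):
        occ = rng.random((20, 20, 20)) < 0.4
        out = neighbor_filter(BinaryVolume(occ))
        np.testing.assert_array_equal(
            out.occupancy, _brute_force_neighbor_filter(occ))

    def test_exclude_center_reading(self, rng):
        occ = rng.random((12, 12, 12)) < 0.5
        out = neighbor_filter(BinaryVolume(occ), include_center=False)
        np.testing.assert_array_equal(
            out.occupancy,
            _brute_force_neighbor_filter(occ, include_center=False))

    def test_never_adds_voxels(self, rng):
        occ = rng.random((15, 15, 15)) < 0.6
        out = neighbor_filter(BinaryVolume(occ))
        assert not (out.occupancy & ~occ).any()

    def test_idempotent_on_convex_solid(self):
        from skimage.morphology import ball

        occ = np.pad(ball(6).astype(bool), 2)
        once = neighbor_filter(BinaryVolume(occ))
        twice = neighbor_filter(once)
        np.testing.assert_array_equal(once.occupancy, twice.occupancy)


def _flood_components(occ):
    """Pure-python 26-connected labeling (oracle)."""
    from collections import deque

    labels = np.zeros(occ.shape, dtype=int)
    nxt = 0
    for start in zip(*np.nonzero(occ)):
        if labels[start]:
            continue
        nxt += 1
        q = deque([start])
        labels[start] = nxt
        while q:
            z, y, x = q.popleft()
            for dz in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        p = (z + dz, y + dy, x + dx)
                        if all(0 <= pi < si for pi, si in zip(p, occ.shape)) \
                                and occ[p] and not labels[p]:
                            labels[p] = nxt
                            q.append(p)
    return labels, nxt


class TestComponents:
    def test_single_voxel_removed(self):
        occ = np.zeros((5, 5, 5), dtype=bool)
        occ[2, 2, 2] = True
        assert remove_small_noise(BinaryVolume(occ), 2).n_occupied == 0

    def test_component_at_threshold_kept(self):
        occ = np.zeros((5, 5, 5), dtype=bool)
        occ[1, 1, 1:4] = True
        assert remove_small_noise(BinaryVolume(occ), 3).n_occupied == 3

    def test_mixed_sizes_match_oracle(self, rng):
        occ = rng.random((15, 15, 15)) < 0.2
        out = remove_small_noise(BinaryVolume(occ), 5)
        labels, n = _flood_components(occ)
        sizes = np.bincount(labels.ravel())
        expect = np.isin(labels, np.nonzero(sizes >= 5)[0][1:] if n else [])
        expect &= occ
        np.testing.assert_array_equal(out.occupancy, expect)

    def test_two_cubes_two_labels(self):
        occ = np.zeros((10, 10, 10), dtype=bool)
        occ[1:3, 1:3, 1:3] = True
        occ[6:9, 6:9, 6:9] = True
        _, n = label_components(BinaryVolume(occ))
        assert n == 2

    def test_empty_zero_labels(self):
        _, n = label_components(BinaryVolume(np.zeros((4, 4, 4), dtype=bool)))
        assert n == 0

    def test_label_count_matches_oracle(self, rng):
        occ = rng.random((12, 12, 12)) < 0.15
        _, n = label_components(BinaryVolume(occ))
        _, n_oracle = _flood_components(occ)
        assert n == n_oracle


def test_pipeline_output_subset_of_binarization(rng):
    vals = rng.random((10, 12, 14))
    v = IntensityVolume(vals, (25.0,) * 3)
    labels, n, cleaned = preprocess_channel(v, threshold=0.4, min_voxels=4)
    binarized = binarize_channel(resample_isotropic(v, 25.0), 0.4)
    assert not (cleaned.occupancy & ~binarized.occupancy).any()
    assert (labels > 0).sum() == cleaned.n_occupied
    if n:
        assert set(np.unique(labels)) == set(range(n + 1))
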