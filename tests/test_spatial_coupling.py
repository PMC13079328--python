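"""Distance search exactness, binning rules and profile bookkeeping."""

import math

import numpy as np
import pytest

from pvspatial.grid import VoxelGrid3D
from pvspatial.morphology import connected_components
from pvspatial.spatial_coupling import (
    BIN_LABELS,
    EmptyBoundaryError,
    bin_distance,
    brute_force_min_distance,
    min_distance_to_boundary,
    proximity_category,
    subject_distance_profile,
)
from conftest import grid_from_voxels


@pytest.mark.parametrize(
    "d, label",
    [
        (0.0, "WITHIN"), (5.0, "B5"), (5.0001, "B10"), (10.0, "B10"),
        (25.0001, "B30"), (30.0, "B30"), (30.5, "OVER30"), (math.inf, "OVER30"),
    ],
)
def test_bin_distance_half_open_above(d, label):
    assert bin_distance(d) == label


@pytest.mark.parametrize(
    "d, label",
    [(0.0, "WITHIN"), (3.0, "NEAR"), (5.0, "NEAR"), (5.1, "FAR"), (math.inf, "FAR")],
)
def test_proximity_category(d, label):
    assert proximity_category(d) == label


def test_proximity_is_coarsening_of_bins():
    coarse = {"WITHIN": "WITHIN", "B5": "NEAR"}
    for d in [0.0, 0.5, 3.2, 5.0, 5.0001, 7.7, 12.0, 22.5, 30.0, 31.0, 200.0]:
        expected = coarse.get(bin_distance(d), "FAR")
        assert proximity_category(d) == expected
    with pytest.raises(ValueError):
        bin_distance(-1.0)
    with pytest.raises(ValueError):
        proximity_category(-0.1)


def test_min_distance_simple_cases():
    g = grid_from_voxels([(3, 0, 0)])
    assert min_distance_to_boundary((0, 0, 0), g) == pytest.approx(3.0)
    g2 = grid_from_voxels([(1, 1, 0)])
    assert min_distance_to_boundary((0, 0, 0), g2) == pytest.approx(math.sqrt(2))
    g3 = grid_from_voxels([(2, 2, 2)])
    assert min_distance_to_boundary((2.0, 2.0, 2.0), g3) == 0.0


def test_first_window_hit_is_not_accepted_blindly():
    """The r=2 window hits (2,2,2) first, but (3,0,0) is Euclidean-nearer."""
    g = grid_from_voxels([(2, 2, 2), (3, 0, 0)])
    assert min_distance_to_boundary((0, 0, 0), g) == pytest.approx(3.0)
    assert brute_force_min_distance((0, 0, 0), g) == pytest.approx(3.0)


def test_empty_boundary_signals_no_wml():
    with pytest.raises(EmptyBoundaryError):
        min_distance_to_boundary((0, 0, 0), grid_from_voxels([]))
    with pytest.raises(EmptyBoundaryError):
        brute_force_min_distance((0, 0, 0), grid_from_voxels([]))


def test_window_equals_bruteforce_randomized(rng):
    """Exact equality of the expanding-window search and the exhaustive
    minimum on random masks, anisotropic spacing included."""
    spacings = [(1, 1, 1), (0.7, 1.0, 1.3), (0.5, 0.5, 2.0)]
    for trial in range(200):
        spacing = spacings[trial % len(spacings)]
        arr = (rng.random((16, 16, 16)) < 0.02).astype(np.uint8)
        if not arr.any():
            arr[tuple(rng.integers(0, 16, 3))] = 1
        g = VoxelGrid3D(arr, spacing)
        centroid = tuple(rng.random(3) * 15 * np.asarray(spacing))
        assert min_distance_to_boundary(centroid, g) == brute_force_min_distance(centroid, g)


def test_profile_within_and_near(rng):
    wml = grid_from_voxels([(5, 5, 5), (5, 5, 6), (5, 6, 5), (6, 5, 5)], shape=(16, 16, 16))
    epvs = grid_from_voxels([(5, 5, 5), (5, 5, 9)], shape=(16, 16, 16))
    comps = connected_components(epvs)
    profile = subject_distance_profile(comps, wml, subject_id="s")
    assert profile.histogram["WITHIN"] == 1
    assert profile.histogram["B5"] == 1
    assert profile.has_wml
    within = [r for r in profile.records if r.within_wml]
    assert len(within) == 1 and within[0].distance_mm == 0.0


def test_profile_no_wml_and_empty_epvs():
    empty_wml = grid_from_voxels([], shape=(8, 8, 8))
    epvs = grid_from_voxels([(1, 1, 1), (6, 6, 6)], shape=(8, 8, 8))
    comps = connected_components(epvs)
    profile = subject_distance_profile(comps, empty_wml)
    assert not profile.has_wml
    assert profile.histogram["OVER30"] == 2
    assert all(math.isinf(r.distance_mm) for r in profile.records)
    # no components at all
    p0 = subject_distance_profile([], empty_wml)
    assert p0.n_components() == 0 and sum(p0.histogram.values()) == 0


def test_histogram_conservation_and_method_agreement(rng):
    arr = (rng.random((20, 20, 20)) < 0.01).astype(np.uint8)
    wml = np.zeros((20, 20, 20), np.uint8)
    wml[8:12, 8:12, 8:12] = 1
    epvs = VoxelGrid3D((arr & ~wml.astype(bool)).astype(np.uint8) | 0)
    comps = connected_components(epvs)
    kd = subject_distance_profile(comps, VoxelGrid3D(wml), method="kdtree")
    win = subject_distance_profile(comps, VoxelGrid3D(wml), method="window")
    assert sum(kd.histogram.values()) == len(comps)
    assert kd.histogram == win.histogram
    for a, b in zip(kd.records, win.records):
        assert a.distance_mm == pytest.approx(b.distance_mm, abs=0)


def test_translation_invariance(rng):
    base_epvs = [(2, 2, 2), (3, 9, 4)]
    base_wml = [(7, 7, 7), (7, 7, 8)]
    shift = np.array([3, 1, 2])
    p1 = subject_distance_profile(
        connected_components(grid_from_voxels(base_epvs, shape=(16, 16, 16))),
        grid_from_voxels(base_wml, shape=(16, 16, 16)),
    )
    p2 = subject_distance_profile(
        connected_components(grid_from_voxels([tuple(np.array(v) + shift) for v in base_epvs], shape=(16, 16, 16))),
        grid_from_voxels([tuple(np.array(v) + shift) for v in base_wml], shape=(16, 16, 16)),
    )
    d1 = sorted(r.distance_mm for r in p1.records)
    d2 = sorted(r.distance_mm for r in p2.records)
    assert d1 == pytest.approx(d2)
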