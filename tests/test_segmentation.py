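"""Cutoff selection, lesion extraction and layering against brute-force oracles."""

import itertools

import numpy as np
import pytest

from fusdwi import (
    TreatmentCell,
    extract_lesion,
    histology_volume,
    make_layers,
    mask_volume,
    select_cutoff,
    treatment_cell_volume,
)
from fusdwi.exceptions import DegenerateImageError, NoLesionFoundError
from fusdwi.tensor import ScalarMap


def _map(data):
    return ScalarMap(np.asarray(data, dtype=float), "MDWI", "intensity")


def _cutoff_oracle(values, fraction):
    """Enumerate every present intensity; smallest with count-above < fraction."""
    values = np.asarray(values, dtype=float).ravel()
    n = values.size
    for c in sorted(set(values)):
        if np.sum(values > c) / n < fraction:
            return c
    raise AssertionError("unreachable: the maximum always qualifies")


class TestSelectCutoff:
    def test_distinct_intensities_enumeration(self):
        data = np.arange(1, 1001, dtype=float).reshape(10, 10, 10)
        brain = np.ones((10, 10, 10), dtype=bool)
        c = select_cutoff(_map(data), brain, fraction=0.011)
        assert c == 990.0
        assert int(np.sum(data > c)) == 10

    def test_fraction_one_keeps_all_but_minimum(self):
        data = np.arange(1, 28, dtype=float).reshape(3, 3, 3)
        c = select_cutoff(_map(data), np.ones((3, 3, 3), bool), fraction=1.0)
        assert c == 1.0

    def test_constant_image_degenerate(self):
        data = np.full((4, 4, 4), 7.0)
        with pytest.raises(DegenerateImageError):
            select_cutoff(_map(data), np.ones((4, 4, 4), bool), fraction=0.011)

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_invalid_fraction(self, fraction):
        with pytest.raises(ValueError):
            select_cutoff(_map(np.ones((2, 2, 2))), np.ones((2, 2, 2), bool), fraction)

    def test_matches_enumeration_oracle_on_random_images(self, rng):
        for _ in range(5):
            data = rng.integers(0, 40, size=(6, 6, 6)).astype(float)
            brain = rng.random((6, 6, 6)) < 0.8
            if not brain.any():
                continue
            for fraction in (0.02, 0.1, 0.5):
                expected = _cutoff_oracle(data[brain], fraction)
                if np.sum(data[brain] > expected) == 0:
                    # empty candidate set: no lesion voxel can be delineated
                    with pytest.raises(DegenerateImageError):
                        select_cutoff(_map(data), brain, fraction)
                else:
                    assert select_cutoff(_map(data), brain, fraction) == expected

    def test_threshold_monotone_in_fraction(self, rng):
        data = rng.random((8, 8, 8)) * 100
        brain = np.ones((8, 8, 8), bool)
        cuts = [select_cutoff(_map(data), brain, f) for f in (0.01, 0.05, 0.2, 0.8)]
        assert all(a >= b for a, b in zip(cuts, cuts[1:]))


class TestExtractLesion:
    def test_component_with_global_max_only(self):
        data = np.zeros((12, 6, 6))
        data[1:3, 1:3, 1:3] = 50.0  # blob B
        data[8:11, 1:4, 1:4] = 60.0  # blob A holds the global max
        data[9, 2, 2] = 100.0
        brain = np.ones(data.shape, bool)
        mask = extract_lesion(_map(data), cutoff=40.0, brain=brain)
        assert mask[9, 2, 2]
        assert mask.sum() == 27
        assert not mask[1:3, 1:3, 1:3].any()

    def test_single_supra_cutoff_voxel(self):
        data = np.zeros((4, 4, 4))
        data[2, 2, 2] = 5.0
        mask = extract_lesion(_map(data), cutoff=1.0, brain=np.ones(data.shape, bool))
        assert mask.sum() == 1 and mask[2, 2, 2]

    def test_diagonal_contiguity_is_26_connected(self):
        data = np.zeros((4, 4, 4))
        data[1, 1, 1] = 5.0
        data[2, 2, 2] = 9.0  # touches only at a corner
        mask = extract_lesion(_map(data), cutoff=1.0, brain=np.ones(data.shape, bool))
        assert mask.sum() == 2

    def test_empty_candidate_set(self):
        data = np.ones((3, 3, 3))
        with pytest.raises(NoLesionFoundError):
            extract_lesion(_map(data), cutoff=5.0, brain=np.ones(data.shape, bool))

    def test_recovers_phantom_lesion(self, noisy_phantom):
        from fusdwi.tensor import compute_mdwi

        brain = noisy_phantom.masks["brain"]
        lesion = noisy_phantom.masks["lesion"]
        mdwi = compute_mdwi(noisy_phantom.post)
        region = extract_lesion(mdwi, select_cutoff(mdwi, brain), brain)
        inter = (region & lesion).sum()
        dice = 2 * inter / (region.sum() + lesion.sum())
        assert dice > 0.8


def _erode_oracle(mask):
    """Brute-force 6-neighborhood erosion (out-of-grid counts as background)."""
    out = np.zeros_like(mask)
    for idx in np.argwhere(mask):
        keep = True
        for axis, d in itertools.product(range(3), (-1, 1)):
            nb = idx.copy()
            nb[axis] += d
            if np.any(nb < 0) or np.any(nb >= np.array(mask.shape)):
                keep = False
                break
            if not mask[tuple(nb)]:
                keep = False
                break
        out[tuple(idx)] = keep
    return out


def _dilate_oracle(mask):
    out = mask.copy()
    for idx in np.argwhere(mask):
        for axis, d in itertools.product(range(3), (-1, 1)):
            nb = idx.copy()
            nb[axis] += d
            if np.all(nb >= 0) and np.all(nb < np.array(mask.shape)):
                out[tuple(nb)] = True
    return out


class TestMakeLayers:
    def test_solid_cube(self):
        region = np.zeros((5, 5, 5), bool)
        region[1:4, 1:4, 1:4] = True
        layers = make_layers(region)
        assert layers.core.sum() == 1 and layers.core[2, 2, 2]
        assert layers.boundary_shell.sum() == 26

    def test_single_voxel(self):
        region = np.zeros((5, 5, 5), bool)
        region[2, 2, 2] = True
        with pytest.warns(RuntimeWarning, match="core is empty"):
            layers = make_layers(region)
        assert layers.core.sum() == 0
        assert layers.outer_shell.sum() == 6  # the six face neighbors

    def test_matches_brute_force_oracles(self, rng):
        for _ in range(5):
            region = rng.random((7, 7, 7)) < 0.35
            region[3, 3, 3] = True  # nonempty
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                layers = make_layers(region)
            assert np.array_equal(layers.core, _erode_oracle(region))
            assert np.array_equal(layers.nested_outer, _dilate_oracle(region))

    def test_partition_and_nesting_invariants(self, rng):
        region = rng.random((8, 8, 8)) < 0.4
        region[4, 4, 4] = True
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            layers = make_layers(region)
        assert np.array_equal(layers.core | layers.boundary_shell, layers.region)
        assert not np.any(layers.core & layers.boundary_shell)
        assert not np.any(layers.region & layers.outer_shell)
        assert np.all(layers.region <= layers.nested_outer)
        # morphological opening: dilation(erosion(region)) stays inside region
        assert not np.any(_dilate_oracle(layers.core) & ~region)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            make_layers(np.zeros((3, 3, 3), bool))


class TestVolumes:
    def test_voxel_count_times_voxel_volume(self):
        mask = np.zeros((20, 20, 20), bool)
        mask.ravel()[:302] = True
        assert mask_volume(mask, 1.0) == 302.0
        assert mask_volume(np.zeros((3, 3, 3), bool), 1.0) == 0.0
        mask2 = np.zeros((10, 10, 10), bool)
        mask2.ravel()[:347] = True
        assert mask_volume(mask2, 2.0) == 2776.0

    def test_treatment_cell_closed_forms(self):
        assert treatment_cell_volume(TreatmentCell(4.0, 10.0)) == pytest.approx(83.78, abs=0.005)
        assert treatment_cell_volume(TreatmentCell(2.0, 2.0)) == pytest.approx(4.18879, abs=1e-4)
        assert treatment_cell_volume(TreatmentCell(4.0, 4.0)) == pytest.approx(33.510, abs=1e-3)

    def test_invalid_cell(self):
        with pytest.raises(ValueError):
            TreatmentCell(0.0, 10.0)

    def test_histology_volume(self):
        assert histology_volume([10, 20, 30], 0.2) == pytest.approx(12.0)
        assert histology_volume([]) == 0.0
        v = histology_volume([35.0] * 50, 0.2)
        assert v == pytest.approx(350.0)
        assert 297.0 <= v <= 418.0

    def test_histology_negative_area_rejected(self):
        with pytest.raises(ValueError):
            histology_volume([10.0, -1.0])
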