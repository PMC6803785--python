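"""Tensor fitting and scalar metric maps, checked against closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fusdwi
from fusdwi import (
    DiffusionTensorModel,
    DwiVolume,
    GradientTable,
    compute_adc,
    compute_mdwi,
    make_gradient_table,
    tensor_signal,
)
from fusdwi.exceptions import InsufficientDataError, UnsupportedShellStructureError
from fusdwi.tensor import ScalarMap, TensorFitResults
from fusdwi.validation import random_spd_tensors, tensor_recovery_error


def _fit_single(D, s0=1000.0, n_dirs=32, sigma=0.0, n_voxels=1, seed=0):
    gt = make_gradient_table(n_dirs, 800.0)
    clean = tensor_signal(s0, D, gt)
    data = np.tile(clean, (n_voxels, 1, 1, 1))
    if sigma > 0:
        rng = np.random.default_rng(seed)
        n1 = rng.normal(0, sigma, data.shape)
        n2 = rng.normal(0, sigma, data.shape)
        data = np.sqrt((data + n1) ** 2 + n2**2)
    dwi = DwiVolume(data, 1.0, gt)
    return DiffusionTensorModel(dwi).fit()


class TestLogLinearFit:
    def test_noiseless_recovery_to_machine_precision(self):
        assert tensor_recovery_error(n=100, seed=0) < 1e-9

    def test_isotropic_voxel(self):
        res = _fit_single(1.0e-3 * np.eye(3))
        assert res.eigenvalues[0, 0, 0] == pytest.approx([1e-3] * 3, rel=1e-9)
        assert res.fa().data[0, 0, 0] == pytest.approx(0.0, abs=1e-9)
        assert res.s0_map[0, 0, 0] == pytest.approx(1000.0, rel=1e-12)

    def test_tensor_elements_match_truth(self):
        D = random_spd_tensors(1, seed=3)[0]
        res = _fit_single(D)
        assert np.allclose(res.tensors[0, 0, 0], D, rtol=1e-9, atol=1e-18)

    def test_eigenvector_orthonormality(self):
        for D in random_spd_tensors(5, seed=9):
            v = _fit_single(D).eigenvectors[0, 0, 0]
            assert np.allclose(v.T @ v, np.eye(3), atol=1e-6)

    def test_noisy_md_unbiased_within_2pct(self):
        """Monte-Carlo: 1000 noisy tract voxels at sigma = s0/50."""
        D = np.diag([1.7e-3, 0.3e-3, 0.3e-3])
        res = _fit_single(D, sigma=20.0, n_voxels=1000, seed=11)
        md = res.md().data[res.valid_mask]
        assert md.mean() == pytest.approx(0.76667e-3, rel=0.02)

    def test_nonpositive_intensity_marks_invalid(self):
        gt = make_gradient_table(8, 800.0)
        data = np.tile(tensor_signal(1000.0, 1e-3 * np.eye(3), gt), (2, 1, 1, 1))
        data[1, 0, 0, 3] = 0.0
        res = DiffusionTensorModel(DwiVolume(data, 1.0, gt)).fit()
        assert res.valid_mask[0, 0, 0]
        assert not res.valid_mask[1, 0, 0]
        assert np.isnan(res.md().data[1, 0, 0])

    def test_too_few_volumes_rejected(self):
        gt = GradientTable(
            bvals=[0.0] + [800.0] * 5,
            bvecs=np.vstack([np.zeros(3), np.eye(3), [[1, 0, 0], [0, 1, 0]]]),
        )
        data = np.ones((1, 1, 1, 6))
        with pytest.raises(InsufficientDataError):
            DiffusionTensorModel(DwiVolume(data, 1.0, gt))


def _results_from_eigenvalues(lam):
    lam = np.asarray(lam, dtype=float).reshape(1, 1, 1, 3)
    shape = (1, 1, 1)
    return TensorFitResults(
        tensors=np.zeros(shape + (3, 3)),
        s0_map=np.ones(shape),
        eigenvalues=lam,
        eigenvectors=np.broadcast_to(np.eye(3), shape + (3, 3)).copy(),
        valid_mask=np.ones(shape, dtype=bool),
        n_clamped=0,
    )


class TestEigenMetrics:
    def test_tract_eigenvalues_closed_form(self):
        res = _results_from_eigenvalues([1.7e-3, 0.3e-3, 0.3e-3])
        assert res.ad().data[0, 0, 0] == pytest.approx(1.7e-3, rel=1e-12)
        assert res.rd().data[0, 0, 0] == pytest.approx(0.3e-3, rel=1e-12)
        assert res.md().data[0, 0, 0] == pytest.approx(0.76667e-3, rel=1e-4)
        assert res.fa().data[0, 0, 0] == pytest.approx(0.799, abs=5e-4)

    def test_isotropy_gives_zero_fa(self):
        res = _results_from_eigenvalues([1e-3, 1e-3, 1e-3])
        assert res.fa().data[0, 0, 0] == 0.0

    def test_stick_limit_gives_unit_fa(self):
        res = _results_from_eigenvalues([1.0, 0.0, 0.0])
        assert res.fa().data[0, 0, 0] == pytest.approx(1.0, rel=1e-12)

    def test_zero_tensor_fa_defined_as_zero(self):
        res = _results_from_eigenvalues([0.0, 0.0, 0.0])
        assert res.fa().data[0, 0, 0] == 0.0

    @given(
        lam=st.tuples(*[st.floats(1e-5, 3e-3)] * 3),
        scale=st.floats(0.1, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_fa_scale_invariant_and_bounded(self, lam, scale):
        lam = np.sort(lam)[::-1]
        fa1 = _results_from_eigenvalues(lam).fa().data[0, 0, 0]
        fa2 = _results_from_eigenvalues(np.asarray(lam) * scale).fa().data[0, 0, 0]
        assert 0.0 <= fa1 <= 1.0
        assert fa1 == pytest.approx(fa2, abs=1e-9)

    def test_md_identity_on_phantom(self, small_phantom):
        res = DiffusionTensorModel(
            small_phantom.post, small_phantom.masks["brain"]
        ).fit()
        ad = res.ad().data[res.valid_mask]
        rd = res.rd().data[res.valid_mask]
        md = res.md().data[res.valid_mask]
        assert np.allclose(md, (ad + 2 * rd) / 3.0, rtol=1e-12, atol=0)
        fa = res.fa().data[res.valid_mask]
        assert np.all((fa >= 0) & (fa <= 1))


class TestMdwi:
    def test_arithmetic_mean_includes_b0(self):
        gt = GradientTable(
            bvals=[0, 800, 800],
            bvecs=[[0, 0, 0], [1, 0, 0], [0, 1, 0]],
        )
        dwi = DwiVolume(np.array([[[[1000.0, 400.0, 400.0]]]]), 1.0, gt)
        assert compute_mdwi(dwi).data[0, 0, 0] == 600.0

    def test_all_zero_voxel(self):
        gt = make_gradient_table(6, 800.0)
        dwi = DwiVolume(np.zeros((1, 1, 1, 7)), 1.0, gt)
        assert compute_mdwi(dwi).data[0, 0, 0] == 0.0


class TestAdc:
    def test_inverse_exponential(self):
        gt = GradientTable(bvals=[0, 800], bvecs=[[0, 0, 0], [1, 0, 0]])
        dwi = DwiVolume(np.array([[[[1000.0, 1000.0 * np.exp(-0.8)]]]]), 1.0, gt)
        assert compute_adc(dwi).data[0, 0, 0] == pytest.approx(1.0e-3, rel=1e-9)

    def test_no_attenuation_gives_zero(self):
        gt = GradientTable(bvals=[0, 800], bvecs=[[0, 0, 0], [1, 0, 0]])
        dwi = DwiVolume(np.full((1, 1, 1, 2), 700.0), 1.0, gt)
        assert compute_adc(dwi).data[0, 0, 0] == 0.0

    def test_matches_md_for_isotropic_tensor(self):
        gt = make_gradient_table(32, 800.0)
        D = 0.8e-3 * np.eye(3)
        dwi = DwiVolume(
            tensor_signal(1000.0, D, gt).reshape(1, 1, 1, -1), 1.0, gt
        )
        adc = compute_adc(dwi).data[0, 0, 0]
        md = DiffusionTensorModel(dwi).fit().md().data[0, 0, 0]
        assert adc == pytest.approx(md, rel=1e-6)

    def test_adc_at_most_md_for_anisotropic_phantom(self, small_phantom):
        """Signal-averaging convexity: ADC <= MD up to direction-lattice wobble."""
        brain = small_phantom.masks["brain"]
        adc = compute_adc(small_phantom.pre).data[brain]
        md = DiffusionTensorModel(small_phantom.pre, brain).fit().md().data[brain]
        assert np.all(adc <= md * (1 + 1e-3))
        tract = small_phantom.masks["tract"][brain]
        assert np.all(adc[tract] < md[tract])  # strictly, for high anisotropy

    def test_multi_shell_rejected(self):
        gt = GradientTable(
            bvals=[0, 800, 1000],
            bvecs=[[0, 0, 0], [1, 0, 0], [0, 1, 0]],
        )
        dwi = DwiVolume(np.ones((1, 1, 1, 3)), 1.0, gt)
        with pytest.raises(UnsupportedShellStructureError):
            compute_adc(dwi)


class TestScalarMap:
    def test_rejects_unknown_kind(self):
        with pytest.raises(ValueError):
            ScalarMap(np.zeros((2, 2, 2)), "XX", "mm^2/s")

    def test_valid_mask_tracks_nan(self):
        data = np.array([[[1.0, np.nan]]])
        sm = ScalarMap(data, "MD", "mm^2/s")
        assert sm.valid_mask.sum() == 1
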