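"""Solver building blocks: proxes, objective, adjointness, FCSA, coil compression."""

import numpy as np
import pytest

import csmra
from csmra.errors import InvalidArgumentError, NumericError
from csmra.phantom import ifftc
from csmra.recon import (
    adjoint_op,
    forward_op,
    objective,
    reconstruct_per_coil,
    soft_threshold,
    total_variation,
    tv_prox,
    wavelet_l1,
    wavelet_prox,
)

from conftest import random_sampling_mask
from _oracles import soft_threshold_oracle, tv1d_exact


class TestSoftThreshold:
    def test_closed_forms(self):
        assert soft_threshold(np.array(0.5), 0.2) == pytest.approx(0.3)
        assert soft_threshold(np.array(-0.1), 0.2) == 0.0
        assert soft_threshold(np.array(-0.7), 0.2) == pytest.approx(-0.5)

    def test_complex_phase_preserved(self):
        z = 0.5 * np.exp(1j * 0.7)
        out = soft_threshold(np.array(z), 0.2)
        assert np.angle(out) == pytest.approx(0.7)
        assert np.abs(out) == pytest.approx(0.3)

    def test_negative_threshold_rejected(self):
        with pytest.raises(InvalidArgumentError):
            soft_threshold(np.zeros(3), -0.1)

    def test_matches_per_element_numeric_minimization(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal((4, 4))
        ours = soft_threshold(z, 0.3)
        oracle = soft_threshold_oracle(z, 0.3)
        assert np.abs(ours - oracle).max() < 1e-6


class TestWaveletProx:
    def test_zero_weight_is_identity(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal((16, 16, 8)) + 1j * rng.standard_normal((16, 16, 8))
        assert np.abs(wavelet_prox(z, 0.0) - z).max() < 1e-10

    def test_large_weight_annihilates_impulse(self):
        z = np.zeros((16, 16, 8))
        z[8, 8, 4] = 1.0
        out = wavelet_prox(z, 100.0, 1.0)
        assert np.abs(out).max() < 1e-12

    def test_output_is_local_minimum_of_prox_objective(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal((8, 8, 8))
        w = 0.1
        out = wavelet_prox(z, w, 1.0, levels=2)

        def prox_obj(u):
            return 0.5 * np.sum((u - z) ** 2) + w * wavelet_l1(u, levels=2)

        val = prox_obj(out)
        assert val <= prox_obj(z) + 1e-12
        for _ in range(20):
            pert = out + 0.01 * rng.standard_normal(out.shape)
            assert val <= prox_obj(pert) + 1e-12


class TestTVProx:
    def test_zero_weight_is_identity(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal((8, 8, 8))
        assert np.array_equal(tv_prox(z, 0.0), z)

    def test_constant_input_unchanged(self):
        z = np.full((8, 8, 8), 1.7)
        assert np.abs(tv_prox(z, 0.5, 1.0, 50) - z).max() < 1e-12

    def test_staircase_matches_exact_1d_solution(self):
        z = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        ours = tv_prox(z.reshape(-1, 1, 1), 0.25, 1.0, inner_iters=500).ravel()
        exact = tv1d_exact(z, 0.25)
        assert np.abs(ours - exact).max() < 1e-3

    @pytest.mark.parametrize("lam", [0.1, 0.4])
    def test_random_1d_matches_exact_solution(self, lam):
        rng = np.random.default_rng(4)
        z = rng.standard_normal(12)
        ours = tv_prox(z.reshape(-1, 1, 1), lam, 1.0, inner_iters=2000).ravel()
        assert np.abs(ours - tv1d_exact(z, lam)).max() < 1e-3

    def test_tv_value_of_constant_is_zero(self):
        assert total_variation(np.full((6, 6, 6), 2.0)) == 0.0


def _tiny_problem(alpha=0.0, beta=0.0, n_coils=3, seed=0, rate=0.4, n_iter=15):
    shape = (16, 16, 8)
    rng = np.random.default_rng(seed)
    vol = csmra.Volume(rng.random(shape))
    coils = csmra.simulate_coils(shape, n_coils, seed=seed)
    k = csmra.forward_kspace(vol, coils)
    sm = random_sampling_mask(shape[1:], rate, seed=seed)
    y = csmra.apply_mask(k, sm)
    params = csmra.ReconParams(alpha=alpha, beta=beta, n_iter=n_iter, wavelet_levels=2)
    return csmra.ReconProblem(y, sm, coils, params), vol


class TestObjective:
    def test_zero_everywhere(self):
        prob, _ = _tiny_problem()
        prob.y.data[:] = 0
        assert objective(np.zeros((16, 16, 8)), prob) == 0.0

    def test_zero_image_gives_data_energy(self):
        prob, _ = _tiny_problem()
        expect = 0.5 * np.sum(np.abs(prob.y.data) ** 2)
        assert objective(np.zeros((16, 16, 8)), prob) == pytest.approx(expect)

    def test_constant_image_has_zero_tv_term(self):
        prob, _ = _tiny_problem(alpha=0.0, beta=5.0)
        x = np.full((16, 16, 8), 0.3)
        data_only = 0.5 * np.sum(
            np.abs(prob.y.data - forward_op(x, prob.coils.sensitivities, prob.mask.mask)) ** 2
        )
        assert objective(x, prob) == pytest.approx(data_only)


class TestAdjointness:
    def test_dot_product_identity(self):
        prob, _ = _tiny_problem(n_coils=3)
        rng = np.random.default_rng(5)
        shape = (16, 16, 8)
        x = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        k = rng.standard_normal((3,) + shape) + 1j * rng.standard_normal((3,) + shape)
        s = prob.coils.sensitivities
        lhs = np.vdot(forward_op(x, s, prob.mask.mask), k)
        rhs = np.vdot(x, adjoint_op(k, s, prob.mask.mask))
        assert abs(lhs - rhs) / abs(lhs) < 1e-8


class TestFCSA:
    def test_full_sampling_unregularized_recovers_truth(self):
        shape = (16, 16, 8)
        rng = np.random.default_rng(6)
        vol = csmra.Volume(rng.random(shape))
        coils = csmra.CoilSet(np.ones((1,) + shape, dtype=complex))
        k = csmra.forward_kspace(vol, coils)
        full = csmra.SamplingMask(np.ones(shape[1:], bool), 1.0, 1.0, {}, 0)
        prob = csmra.ReconProblem(k, full, coils,
                                  csmra.ReconParams(0.0, 0.0, wavelet_levels=2))
        res = csmra.fcsa_reconstruct(prob)
        rel = np.linalg.norm(res.image.data - vol.data) / np.linalg.norm(vol.data)
        assert rel < 1e-6

    def test_unregularized_single_coil_stays_at_zero_filled_solution(self):
        # with a unit coil, A A* = mask, so x0 = A*y already satisfies A x = y:
        # the unregularized iteration must stay at the zero-filled solution
        shape = (16, 16, 8)
        rng = np.random.default_rng(7)
        vol = csmra.Volume(rng.random(shape))
        coils = csmra.CoilSet(np.ones((1,) + shape, dtype=complex))
        k = csmra.forward_kspace(vol, coils)
        sm = random_sampling_mask(shape[1:], 0.4, seed=8)
        y = csmra.apply_mask(k, sm)
        prob = csmra.ReconProblem(y, sm, coils, csmra.ReconParams(0.0, 0.0, wavelet_levels=2))
        res = csmra.fcsa_reconstruct(prob)
        x0 = adjoint_op(y.data, coils.sensitivities, sm.mask)
        assert np.abs(res.image.data - x0).max() < 1e-10
        assert res.objective_trace[-1] <= res.objective_trace[0] + 1e-12

    def test_objective_trace_non_increasing_first_to_last(self):
        prob, _ = _tiny_problem(alpha=1e-3, beta=1e-3)
        res = csmra.fcsa_reconstruct(prob)
        assert len(res.objective_trace) == prob.params.n_iter + 1
        assert all(np.isfinite(res.objective_trace))
        assert res.objective_trace[-1] <= res.objective_trace[0]

    def test_bit_identical_rerun(self):
        prob, _ = _tiny_problem(alpha=1e-3, beta=1e-3)
        r1 = csmra.fcsa_reconstruct(prob)
        r2 = csmra.fcsa_reconstruct(prob)
        assert np.array_equal(r1.image.data, r2.image.data)
        assert r1.objective_trace == r2.objective_trace

    def test_non_finite_data_raises_numeric_error(self):
        prob, _ = _tiny_problem()
        prob.y.data[0, 0, 0, 0] = np.nan
        with pytest.raises(NumericError):
            csmra.fcsa_reconstruct(prob)

    def test_per_coil_path_returns_magnitude_image(self):
        prob, _ = _tiny_problem(alpha=1e-4, beta=1e-4, n_coils=2)
        res = reconstruct_per_coil(prob.y, prob.mask, prob.params)
        assert np.all(res.image.data >= 0)
        assert res.objective_trace[-1] <= res.objective_trace[0]

    def test_tv_shrinks_with_increasing_beta(self):
        # on a noiseless phantom at alpha = 0, stronger TV weight cannot
        # increase the total variation of the reconstruction
        shape = (32, 32, 16)
        vol, _ = csmra.generate_phantom(shape=shape, noise_sd=0.0, seed=5)
        coils = csmra.simulate_coils(shape, 2, seed=5)
        k = csmra.forward_kspace(vol, coils)
        sm = random_sampling_mask(shape[1:], 0.3, seed=5)
        y = csmra.apply_mask(k, sm)
        scale = float(np.linalg.norm(y.data))
        y = csmra.KSpace(y.data / scale)
        tvs = []
        for beta in [0.0, 3.2e-5, 3.2e-4, 3.2e-3]:
            prob = csmra.ReconProblem(
                y, sm, coils, csmra.ReconParams(0.0, beta, wavelet_levels=2)
            )
            res = csmra.fcsa_reconstruct(prob)
            tvs.append(total_variation(res.image.data))
        assert all(a >= b - 1e-9 for a, b in zip(tvs, tvs[1:]))


class TestCoilCompress:
    def test_full_basis_preserves_energy(self, noiseless_phantom, small_coils):
        vol, _ = noiseless_phantom
        k = csmra.forward_kspace(vol, small_coils)
        comp = csmra.coil_compress(k, small_coils.n_coils)
        e0 = np.sum(np.abs(k.data) ** 2)
        e1 = np.sum(np.abs(comp.data) ** 2)
        assert abs(e1 - e0) / e0 < 1e-8

    def test_single_coil_identity_up_to_phase(self):
        rng = np.random.default_rng(9)
        k = csmra.KSpace((rng.standard_normal((1, 8, 8, 8))
                          + 1j * rng.standard_normal((1, 8, 8, 8))))
        comp = csmra.coil_compress(k, 1)
        ratio = comp.data / k.data
        assert np.abs(np.abs(ratio) - 1.0).max() < 1e-10
        assert np.abs(ratio - ratio.flat[0]).max() < 1e-10

    def test_rank2_coils_compress_to_two_virtual_coils(self, noiseless_phantom):
        vol, _ = noiseless_phantom
        rng = np.random.default_rng(10)
        base = csmra.simulate_coils(vol.shape, 2, seed=11).sensitivities
        mix = rng.standard_normal((4, 2)) + 1j * rng.standard_normal((4, 2))
        maps = np.tensordot(mix, base, axes=(1, 0))
        k = csmra.forward_kspace(vol, csmra.CoilSet(maps))
        comp = csmra.coil_compress(k, 2)
        e_kept = np.sum(np.abs(comp.data) ** 2)
        e_all = np.sum(np.abs(k.data) ** 2)
        assert e_kept / e_all > 0.99

    def test_out_of_range_rejected(self, noiseless_phantom, small_coils):
        vol, _ = noiseless_phantom
        k = csmra.forward_kspace(vol, small_coils)
        with pytest.raises(InvalidArgumentError):
            csmra.coil_compress(k, 5)
        with pytest.raises(InvalidArgumentError):
            csmra.coil_compress(k, 0)
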