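import math

import numpy as np
import pytest

from mcdiff import bayes, simstudy
from mcdiff.sampler import (Chain, ProposalState, SamplerConfig, adapt_amwg,
                            adapt_fsl, adapt_scam, amwg_delta, fold_axis,
                            fsl_multiplier, metropolis_accept,
                            mwg_sweep, propose_component, run_chain, run_mwg,
                            sample_volume, scam_std)
from mcdiff.acquisition import sphere_to_cart


def _state(sigma, families=None, **kw):
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    p = len(sigma)
    return ProposalState(sigma=sigma,
                         families=list(families or ["normal"] * p),
                         partners=np.full(p, -1, dtype=int), **kw)


class TestMetropolisAccept:
    def test_better_candidate_always_accepted(self):
        assert metropolis_accept(-10.0, -5.0, 0.999999)
        assert metropolis_accept(-10.0, -10.0, 0.999999)

    def test_infeasible_candidate_always_rejected(self):
        assert not metropolis_accept(-10.0, -math.inf, 1e-12)

    def test_non_finite_current_raises(self):
        with pytest.raises(ValueError):
            metropolis_accept(-math.inf, -1.0, 0.5)

    def test_acceptance_frequency_matches_ratio(self):
        """log-difference −ln2 accepts with probability 1/2."""
        rng = np.random.default_rng(123)
        diff = -math.log(2.0)
        hits = sum(metropolis_accept(0.0, diff, rng.random())
                   for _ in range(100000))
        assert hits / 100000 == pytest.approx(0.5, abs=0.01)


class TestProposeComponent:
    def test_zero_std_returns_current_point(self):
        state = _state([0.0, 0.0])
        x = np.array([0.4, 1.3])
        rng = np.random.default_rng(0)
        np.testing.assert_array_equal(
            propose_component(0, x, state, rng), x)

    def test_psi_wraps_modulo_pi(self):
        state = _state([1.0], families=["circular_pi"])

        class FixedRng:
            def standard_normal(self):
                return -0.3

        y = propose_component(0, np.array([0.1]), state, FixedRng())
        assert y[0] == pytest.approx((0.1 - 0.3) % math.pi)
        assert y[0] == pytest.approx(2.941593, abs=1e-6)

    def test_angle_fold_preserves_axis(self):
        state = ProposalState(sigma=np.array([0.5, 0.5]),
                              families=["polar", "azimuth"],
                              partners=np.array([1, 0]))
        rng = np.random.default_rng(5)
        x = np.array([1.2, 0.4])
        for _ in range(50):
            y = propose_component(int(rng.integers(2)), x, state, rng)
            assert 0 <= y[0] <= math.pi
            assert -math.pi / 2 <= y[1] <= math.pi / 2
            x = y

    def test_fold_axis_is_signal_invariant(self, tiny_scheme, ballstick):
        from mcdiff.compartments import composite_signal
        theta, phi = 2.2, 2.8  # axis with negative x component
        ftheta, fphi = fold_axis(theta, phi)
        n = sphere_to_cart(theta, phi)
        fn = sphere_to_cart(ftheta, fphi)
        assert fn[0] >= 0
        assert abs(float(n @ fn)) == pytest.approx(1.0, abs=1e-12)
        a = composite_signal(ballstick, [1e4, 0.6, theta, phi], tiny_scheme)
        b = composite_signal(ballstick, [1e4, 0.6, ftheta, fphi], tiny_scheme)
        np.testing.assert_allclose(a, b, atol=1e-12 * 1e4)

    def test_tensor_fold_cotransforms_psi_and_preserves_signal(
            self, tiny_scheme):
        """Folding the tensor axis also maps ψ → −ψ (mod π); the candidate
        then predicts exactly the same signal as the unfolded frame."""
        from mcdiff.compartments import build_model, tensor_signal
        model = build_model("Tensor")
        state = ProposalState(
            sigma=np.zeros(7),
            families=["normal", "normal", "normal", "normal",
                      "polar", "azimuth", "circular_pi"],
            partners=np.array([-1, -1, -1, -1, 5, 4, -1]),
            psi_partners=np.array([-1, -1, -1, -1, 6, -1, -1]))
        # axis in the negative-x hemisphere: canonicalising must flip it
        x = np.array([1e4, 1.7e-9, 8e-10, 3e-10, 2.2, 2.8, 0.6])
        from mcdiff.sampler import canonicalize
        y = canonicalize(x, state)
        assert sphere_to_cart(y[4], y[5])[0] >= 0
        assert y[6] == pytest.approx((-0.6) % math.pi)
        np.testing.assert_allclose(
            tensor_signal(tiny_scheme, *y[1:]),
            tensor_signal(tiny_scheme, *x[1:]), rtol=1e-12)


class TestMwgSweep:
    def test_all_rejected_keeps_position(self):
        x0 = np.array([0.5, 0.5])

        def logpost(x):
            return 0.0 if np.array_equal(x, x0) else -math.inf

        state = _state([1.0, 1.0])
        rng = np.random.default_rng(2)
        x, lx, acc = mwg_sweep(x0.copy(), 0.0, state, logpost, rng)
        np.testing.assert_array_equal(x, x0)
        assert not acc.any()

    def test_flat_posterior_accepts_everything(self):
        def logpost(x):
            return 0.0 if np.all(np.abs(x) < 100) else -math.inf

        state = _state([0.5, 0.5])
        rng = np.random.default_rng(3)
        x = np.zeros(2)
        lx = 0.0
        n_acc = 0
        for _ in range(200):
            x, lx, acc = mwg_sweep(x, lx, state, logpost, rng)
            n_acc += acc.sum()
        assert n_acc == 400  # α = 1 everywhere inside the box


class TestAdaptation:
    def test_scam_frozen_before_start(self):
        state = _state([0.3], strategy="scam", t_start=100)
        rng = np.random.default_rng(0)
        for x in rng.standard_normal(50):
            state.observe(np.array([x]))
        adapt_scam(state, t=50)
        assert state.sigma[0] == 0.3

    def test_scam_tracks_unit_variance(self):
        # empirical variance 1 with negligible ε gives σ = 2.4
        state = _state([1e-3], strategy="scam", t_start=100)
        history = np.random.default_rng(1).standard_normal((200000, 1))
        adapt_scam(state, t=200000, history=history)
        assert state.sigma[0] == pytest.approx(2.4, rel=0.01)

    def test_scam_floor_prevents_collapse(self):
        state = _state([0.3], strategy="scam", t_start=10)
        history = np.full((500, 1), 1.234)  # constant chain, Var = 0
        adapt_scam(state, t=500, history=history)
        assert state.sigma[0] == pytest.approx(2.4 * math.sqrt(1e-5 * 0.3))
        assert state.sigma[0] > 0

    def test_scam_literal_reading_is_available(self):
        assert scam_std(0.3, 1.0, 0.0, literal=True) == pytest.approx(2.4)
        assert scam_std(0.3, 4.0, 0.0) == pytest.approx(4.8)

    @pytest.mark.parametrize("a, b, expected", [
        (25, 50, 1.0), (49, 50, 25.0), (0, 50, 1.0 / 51.0)])
    def test_fsl_multiplier_values(self, a, b, expected):
        assert fsl_multiplier(a, b) == pytest.approx(expected)

    def test_fsl_batch_update_rescales_and_resets(self):
        state = _state([0.2, 0.2], strategy="fsl")
        state.batch_accepts[:] = [49, 0]
        state.batch_proposals = 50
        adapt_fsl(state)
        assert state.sigma[0] == pytest.approx(0.2 * 25.0)
        assert state.sigma[1] == pytest.approx(0.2 / 51.0)
        assert state.batch_proposals == 0
        assert state.n_batches == 1

    def test_amwg_first_batch_with_printed_schedule(self):
        # δ(1) = 1 under the 1/n schedule: σ 0.25 → 0.25·e when ar > 0.44
        state = _state([0.25], strategy="amwg", amwg_schedule="paper")
        state.batch_accepts[:] = 25
        state.batch_proposals = 50
        adapt_amwg(state)
        assert state.sigma[0] == pytest.approx(0.25 * math.e)
        assert state.sigma[0] == pytest.approx(0.679570, abs=1e-6)

    def test_amwg_tie_takes_division_branch(self):
        state = _state([0.25], strategy="amwg", amwg_schedule="paper")
        state.batch_accepts[:] = 22  # 22/50 = 0.44 exactly
        state.batch_proposals = 50
        adapt_amwg(state)
        assert state.sigma[0] == pytest.approx(0.25 / math.e)

    def test_amwg_delta_diminishes(self):
        deltas = [amwg_delta(n, "paper") for n in range(1, 200)]
        assert all(a >= b for a, b in zip(deltas, deltas[1:]))
        assert amwg_delta(10**8, "paper") < 1e-7
        assert amwg_delta(1, "sqrt") == pytest.approx(0.01)
        assert amwg_delta(10**6, "sqrt") == pytest.approx(1e-3)


class TestRunChain:
    def test_sample_bookkeeping(self, ballstick, ballstick_voxel):
        voxel, truth = ballstick_voxel
        config = SamplerConfig(n_samples=10, burn_in=0, thinning=1,
                               strategy="none", seed=1)
        chain = run_chain(ballstick, voxel, config, init=truth)
        assert chain.samples.shape == (10, 4)
        assert chain.accepted.shape == (10, 4)
        assert chain.log_posterior.shape == (10,)

    def test_same_seed_gives_identical_chains(self, ballstick,
                                              ballstick_voxel):
        voxel, truth = ballstick_voxel
        config = SamplerConfig(n_samples=50, burn_in=10, strategy="amwg",
                               seed=9)
        a = run_chain(ballstick, voxel, config, init=truth)
        b = run_chain(ballstick, voxel, config, init=truth)
        np.testing.assert_array_equal(a.samples, b.samples)
        np.testing.assert_array_equal(a.accepted, b.accepted)

    def test_burn_in_discards_exactly_first_sweeps(self):
        """With identical RNG streams, a burned-in run stores exactly the
        post-burn-in positions of the unburned run."""
        def logpost(x):
            return -0.5 * float(x @ x)

        a = run_mwg(logpost, [0.1], 0.7, 15, burn_in=0, strategy="none",
                    rng=np.random.default_rng(4))
        b = run_mwg(logpost, [0.1], 0.7, 10, burn_in=5, strategy="none",
                    rng=np.random.default_rng(4))
        np.testing.assert_array_equal(a.samples[5:], b.samples)

    def test_thinning_keeps_every_kth_position(self):
        def logpost(x):
            return -0.5 * float(x @ x)

        a = run_mwg(logpost, [0.1], 0.7, 12, thinning=1, strategy="none",
                    rng=np.random.default_rng(8))
        b = run_mwg(logpost, [0.1], 0.7, 4, thinning=3, strategy="none",
                    rng=np.random.default_rng(8))
        np.testing.assert_array_equal(a.samples[2::3], b.samples)

    def test_infeasible_init_raises(self, ballstick, ballstick_voxel):
        voxel, _ = ballstick_voxel
        config = SamplerConfig(n_samples=5, burn_in=0, strategy="none")
        with pytest.raises(ValueError, match="infeasible"):
            run_chain(ballstick, voxel, config,
                      init=np.array([1e4, 1.4, 1.0, 0.3]))

    def test_stored_samples_respect_constraints(self, ballstick_voxel):
        from mcdiff.compartments import build_model
        model = build_model("BallStick_in2")
        voxel, _ = ballstick_voxel
        config = SamplerConfig(n_samples=300, burn_in=0, strategy="amwg",
                               seed=2, init="default")
        chain = run_chain(model, voxel, config)
        priors = bayes.default_priors(model)
        assert all(priors.feasible(x) for x in chain.samples)
        assert np.all(np.isfinite(chain.log_posterior))


@pytest.fixture(scope="module")
def slab(rls_scheme):
    phantom = simstudy.simulate_ground_truth(
        "BallStick_in1", 4, rls_scheme, snr=30, seed=13)
    data = phantom.noisy_signals.reshape(2, 2, 1, -1)
    return phantom, data


class TestSampleVolume:
    def test_single_voxel_mask_equals_run_chain(self, ballstick, rls_scheme,
                                                slab):
        phantom, data = slab
        mask = np.zeros((2, 2, 1), dtype=bool)
        mask[1, 0, 0] = True
        config = SamplerConfig(n_samples=150, burn_in=0, strategy="amwg",
                               seed=3, init="default")
        result = sample_volume(ballstick, data, mask, rls_scheme,
                               phantom.sigma, config, keep_chains=True)
        flat = int(np.ravel_multi_index((1, 0, 0), mask.shape))
        voxel_seed = int(np.random.SeedSequence(
            entropy=3, spawn_key=(flat,)).generate_state(1)[0] % (2**31))
        import dataclasses
        direct = run_chain(ballstick,
                           bayes.VoxelData(data[1, 0, 0], phantom.sigma,
                                           rls_scheme),
                           dataclasses.replace(config, seed=voxel_seed))
        np.testing.assert_array_equal(
            result["chains"][(1, 0, 0)].samples, direct.samples)
        assert np.isnan(result["mean"][0, 0, 0]).all()

    def test_results_independent_of_voxel_order(self, ballstick, rls_scheme,
                                                slab):
        """Maps must be identical whichever subsets of voxels are run."""
        phantom, data = slab
        config = SamplerConfig(n_samples=100, burn_in=0, strategy="amwg",
                               seed=7, init="default")
        full = np.ones((2, 2, 1), dtype=bool)
        whole = sample_volume(ballstick, data, full, rls_scheme,
                              phantom.sigma, config)
        for i, j in [(0, 0), (1, 1)]:
            single = np.zeros_like(full)
            single[i, j, 0] = True
            part = sample_volume(ballstick, data, single, rls_scheme,
                                 phantom.sigma, config)
            np.testing.assert_array_equal(part["mean"][i, j, 0],
                                          whole["mean"][i, j, 0])

    def test_empty_mask_raises(self, ballstick, rls_scheme, slab):
        phantom, data = slab
        with pytest.raises(ValueError, match="empty mask"):
            sample_volume(ballstick, data, np.zeros((2, 2, 1), bool),
                          rls_scheme, phantom.sigma, SamplerConfig())

    def test_nonpositive_sigma_raises(self, ballstick, rls_scheme, slab):
        phantom, data = slab
        with pytest.raises(ValueError, match="sigma"):
            sample_volume(ballstick, data, np.ones((2, 2, 1), bool),
                          rls_scheme, 0.0, SamplerConfig())
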