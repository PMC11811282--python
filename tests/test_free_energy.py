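"""Free-energy terms, gradients, optimiser, and training behaviour."""
import numpy as np
import pytest

from neurotwin import (AdaptiveState, GaussianParams, HierarchicalVRNN,
                       NetworkSpec, OptimizerConfig, RAdam, free_energy_step,
                       gaussian_kl, train, training_loss, window_loss)


@pytest.fixture()
def toy_model():
    spec = NetworkSpec.desk_scale(n_regions=2, d1_dim=4, d2_dim=4,
                                  z2_dim=2, z3_dim=2)
    return HierarchicalVRNN(spec, np.random.default_rng(0))


class TestGaussianKL:
    def test_identical_distributions_give_zero(self):
        q = GaussianParams(np.array([0.2, -0.4]), np.array([0.5, 2.0]))
        assert gaussian_kl(q, q) == pytest.approx(0.0, abs=1e-14)

    def test_hand_evaluated_value(self):
        # q = N(0,1), p = N(0, e): KL = log(e) + 1/(2 e^2) - 1/2
        q = GaussianParams(np.zeros(1), np.ones(1))
        p = GaussianParams(np.zeros(1), np.array([np.e]))
        expect = 1.0 + 1.0 / (2.0 * np.e ** 2) - 0.5
        assert gaussian_kl(q, p) == pytest.approx(expect)

    def test_non_negative_on_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            q = GaussianParams(rng.uniform(-0.9, 0.9, 3),
                               rng.uniform(0.1, 3.0, 3))
            p = GaussianParams(rng.uniform(-0.9, 0.9, 3),
                               rng.uniform(0.1, 3.0, 3))
            assert gaussian_kl(q, p) >= 0.0

    def test_matches_monte_carlo_oracle(self):
        """Closed form agrees with a sampling estimate of E_q[log q - log p]."""
        rng = np.random.default_rng(2)
        n = 200_000
        for _ in range(5):
            mq, sq = rng.uniform(-0.5, 0.5), rng.uniform(0.3, 2.0)
            mp, sp = rng.uniform(-0.5, 0.5), rng.uniform(0.3, 2.0)
            z = rng.normal(mq, sq, n)
            logq = -0.5 * ((z - mq) / sq) ** 2 - np.log(sq)
            logp = -0.5 * ((z - mp) / sp) ** 2 - np.log(sp)
            diffs = logq - logp
            mc = diffs.mean()
            se = diffs.std() / np.sqrt(n)
            kl = gaussian_kl(GaussianParams([mq], [sq]),
                             GaussianParams([mp], [sp]))
            assert abs(kl - mc) < 3 * se + 1e-12


class TestFreeEnergyStep:
    def test_perfect_match_gives_zero(self):
        q = GaussianParams(np.zeros(2), np.ones(2))
        fb = free_energy_step(np.zeros(4), np.zeros(4),
                              {"local": q, "network": q, "global": q},
                              {"local": q, "network": q, "global": q})
        assert fb.weighted_total == pytest.approx(0.0)

    def test_zero_meta_prior_leaves_reconstruction(self):
        q = GaussianParams(np.zeros(1), np.ones(1))
        p = GaussianParams(np.array([0.5]), np.array([2.0]))
        fb = free_energy_step(np.array([1.0]), np.array([0.0]),
                              {"local": q}, {"local": p},
                              meta_prior=(0.0, 0.0, 0.0))
        assert fb.weighted_total == pytest.approx(0.5)
        assert fb.kl_per_level[0] > 0

    def test_hand_evaluated_reconstruction(self):
        fb = free_energy_step(np.array([0.5]), np.array([0.1]), {}, {})
        assert fb.reconstruction == pytest.approx(0.08)

    def test_breakdown_invariant(self):
        q = GaussianParams(np.zeros(1), np.ones(1))
        p = GaussianParams(np.array([0.3]), np.array([0.7]))
        fb = free_energy_step(np.array([0.2]), np.array([-0.1]),
                              {"local": q, "network": q},
                              {"local": p, "network": p},
                              meta_prior=(0.01, 0.02, 0.03))
        expect = fb.reconstruction + sum(
            w * k for w, k in zip(fb.meta_prior, fb.kl_per_level))
        assert fb.weighted_total == pytest.approx(expect)
        assert all(k >= 0 for k in fb.kl_per_level)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            free_energy_step(np.zeros(3), np.zeros(4), {}, {})


class TestWindowLoss:
    def test_window_sum_equals_per_step_sum(self, toy_model):
        rng = np.random.default_rng(3)
        s = toy_model.spec
        T = 5
        x = rng.uniform(-0.5, 0.5, (T, s.n_regions, s.channels_per_region))
        state = AdaptiveState.zeros(s, T)
        for a in state.arrays():
            a += rng.normal(0, 0.3, a.shape)
        total = window_loss(toy_model, x, state)
        trace = toy_model.forward_window(x, state, sample=False)
        assert total == pytest.approx(trace.free_energy_steps().sum())

    def test_full_window_equals_training_loss(self, toy_model):
        rng = np.random.default_rng(4)
        s = toy_model.spec
        x = rng.uniform(-0.5, 0.5, (6, s.n_regions, s.channels_per_region))
        state = AdaptiveState.zeros(s, 6)
        assert window_loss(toy_model, x, state) == pytest.approx(
            training_loss(toy_model, [(x, state)]))

    def test_empty_dataset_loss_is_zero(self, toy_model):
        assert training_loss(toy_model, []) == 0.0

    def test_two_identical_sequences_double_the_loss(self, toy_model):
        rng = np.random.default_rng(5)
        s = toy_model.spec
        x = rng.uniform(-0.5, 0.5, (4, s.n_regions, s.channels_per_region))
        state = AdaptiveState.zeros(s, 4)
        single = training_loss(toy_model, [(x, state)])
        double = training_loss(toy_model, [(x, state), (x, state.copy())])
        assert double == pytest.approx(2 * single)


class TestGradients:
    def test_adaptive_state_gradients_match_finite_differences(self, toy_model):
        """BPTT gradients of the windowed loss vs central differences."""
        rng = np.random.default_rng(6)
        s = toy_model.spec
        T = 6
        x = rng.uniform(-0.5, 0.5, (T, s.n_regions, s.channels_per_region))
        state = AdaptiveState.zeros(s, T)
        for a in state.arrays():
            a += rng.normal(0, 0.3, a.shape)
        eps = toy_model._draw_eps(T, rng, True)
        _, _, agrads = toy_model.loss_and_grads(x, state, eps=eps)
        h = 1e-6
        check_rng = np.random.default_rng(7)
        for arr, grad in zip(state.arrays(), agrads.arrays()):
            flat_idx = check_rng.choice(arr.size,
                                        size=min(8, arr.size), replace=False)
            for fi in flat_idx:
                ix = np.unravel_index(fi, arr.shape)
                old = arr[ix]
                arr[ix] = old + h
                fp = toy_model.forward_window(x, state, eps=eps).weighted_total
                arr[ix] = old - h
                fm = toy_model.forward_window(x, state, eps=eps).weighted_total
                arr[ix] = old
                num = (fp - fm) / (2 * h)
                denom = max(abs(num), abs(grad[ix]), 1e-6)
                assert abs(num - grad[ix]) / denom < 1e-4

    def test_weight_gradients_match_finite_differences(self, toy_model):
        rng = np.random.default_rng(8)
        s = toy_model.spec
        T = 5
        x = rng.uniform(-0.5, 0.5, (T, s.n_regions, s.channels_per_region))
        state = AdaptiveState.zeros(s, T)
        for a in state.arrays():
            a += rng.normal(0, 0.3, a.shape)
        eps = toy_model._draw_eps(T, rng, True)
        _, wgrads, _ = toy_model.loss_and_grads(x, state, eps=eps)
        h = 1e-6
        check_rng = np.random.default_rng(9)
        for key in ("Wd2d2", "Wd1d2", "Wout", "W2pm", "W1ps", "b1"):
            arr = toy_model.w[key]
            for fi in check_rng.choice(arr.size, size=6, replace=False):
                ix = np.unravel_index(fi, arr.shape)
                old = arr[ix]
                arr[ix] = old + h
                fp = toy_model.forward_window(x, state, eps=eps).weighted_total
                arr[ix] = old - h
                fm = toy_model.forward_window(x, state, eps=eps).weighted_total
                arr[ix] = old
                num = (fp - fm) / (2 * h)
                denom = max(abs(num), abs(wgrads[key][ix]), 1e-6)
                assert abs(num - wgrads[key][ix]) / denom < 1e-4


class TestRAdam:
    def test_minimises_quadratic(self):
        p = [np.array([5.0])]
        opt = RAdam(p, OptimizerConfig(alpha=0.05))
        for _ in range(500):
            opt.step(p, [2.0 * p[0]])
        assert abs(p[0][0]) < 0.1

    def test_windowed_update_touches_only_slice(self):
        p = [np.arange(10.0)]
        opt = RAdam(p)
        before = p[0].copy()
        g = [np.ones(10)]
        opt.step(p, g, windows=[slice(3, 6)])
        assert np.array_equal(p[0][:3], before[:3])
        assert np.array_equal(p[0][6:], before[6:])
        assert not np.array_equal(p[0][3:6], before[3:6])

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            OptimizerConfig(beta1=1.5)
        with pytest.raises(ValueError):
            OptimizerConfig(alpha=-1.0)


class TestTraining:
    def test_zero_updates_leave_model_unchanged(self, toy_model):
        before = toy_model.weights_flat()
        x = np.zeros((4, 2, 2))
        train(toy_model, [x], n_updates=0, rng=np.random.default_rng(0))
        assert np.array_equal(before, toy_model.weights_flat())

    def test_convergence_on_deterministic_sinusoid(self):
        """A one-region toy fits a sinusoid: final loss well below initial."""
        spec = NetworkSpec(n_regions=1, channels_per_region=2, z1_dim=1,
                           z2_dim=1, z3_dim=1, d1_dim=8, d2_dim=8,
                           meta_prior=(0.001,) * 3)
        model = HierarchicalVRNN(spec, np.random.default_rng(1))
        t = np.arange(120)
        x = np.stack([0.6 * np.sin(2 * np.pi * t / 25),
                      0.6 * np.cos(2 * np.pi * t / 25)],
                     axis=1).reshape(-1, 1, 2)
        res = train(model, [x], n_updates=2000,
                    rng=np.random.default_rng(2), log_every=100)
        first = res.loss_trace["total"].iloc[0]
        assert res.final_loss < 0.1 * first

    def test_large_meta_prior_suppresses_kl_at_cost_of_reconstruction(self):
        """Direction of effect: heavier KL weighting collapses posteriors
        toward priors while reconstruction stays worse."""
        rng_data = np.random.default_rng(3)
        t = np.arange(60)
        base = np.stack([0.5 * np.sin(2 * np.pi * t / 17 + p)
                         for p in rng_data.uniform(0, 6, 4)], axis=1)
        x = (base + rng_data.normal(0, 0.15, base.shape)).reshape(-1, 2, 2)
        results = {}
        for W in (0.001, 0.3):
            spec = NetworkSpec.desk_scale(n_regions=2, meta_prior=(W,) * 3)
            model = HierarchicalVRNN(spec, np.random.default_rng(4))
            res = train(model, [x], n_updates=1500,
                        rng=np.random.default_rng(5), log_every=1499)
            row = res.loss_trace.iloc[-1]
            results[W] = (row["reconstruction"],
                          row["kl_local"] + row["kl_network"])
        assert results[0.3][1] < results[0.001][1]      # KL collapsed
        assert results[0.3][0] > results[0.001][0]      # recon worse

    def test_training_is_reproducible(self, toy_model):
        x = np.random.default_rng(0).uniform(-0.5, 0.5, (20, 2, 2))
        spec = toy_model.spec
        m1 = HierarchicalVRNN(spec, np.random.default_rng(10))
        m2 = HierarchicalVRNN(spec, np.random.default_rng(10))
        train(m1, [x], n_updates=30, rng=np.random.default_rng(11))
        train(m2, [x], n_updates=30, rng=np.random.default_rng(11))
        assert np.array_equal(m1.weights_flat(), m2.weights_flat())
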