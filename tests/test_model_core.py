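"""Unit tests for the generative core: priors, posteriors, dynamics, output."""
import numpy as np
import pytest

from neurotwin import (AdaptiveState, GaussianParams, HierarchicalVRNN,
                       ModelState, NetworkSpec, compute_output,
                       compute_posterior, compute_prior, sample_latent,
                       step_deterministic)
from neurotwin.model import ConfigurationError


@pytest.fixture()
def tiny_spec():
    return NetworkSpec.desk_scale(n_regions=2, d1_dim=4, d2_dim=4,
                                  z2_dim=2, z3_dim=2)


@pytest.fixture()
def tiny_model(tiny_spec):
    return HierarchicalVRNN(tiny_spec, np.random.default_rng(0))


class TestComputePrior:
    def test_zero_weights_give_unit_gaussian(self):
        p = compute_prior(np.array([1.0, -2.0]), np.zeros((3, 2)),
                          np.zeros((3, 2)))
        assert np.allclose(p.mu, 0.0)
        assert np.allclose(p.sigma, 1.0)

    def test_initial_step_is_standard_normal(self):
        p = compute_prior(None, np.ones((4, 2)), np.ones((4, 2)),
                          initial=True)
        assert np.allclose(p.mu, 0.0)
        assert np.allclose(p.sigma, 1.0)

    def test_hand_evaluated_single_unit(self):
        p = compute_prior(np.array([1.0, 1.0]),
                          np.array([[0.5, -0.5]]), np.array([[0.1, 0.1]]))
        assert p.mu[0] == pytest.approx(np.tanh(0.0))
        assert p.sigma[0] == pytest.approx(np.exp(0.2))

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ConfigurationError):
            compute_prior(np.ones(3), np.ones((2, 2)), np.ones((2, 2)))


class TestSampleLatent:
    def test_small_sigma_returns_mu(self):
        p = GaussianParams(np.array([0.3]), np.array([1e-300]))
        z = sample_latent(p, eps=np.array([123.0]))
        assert z[0] == pytest.approx(0.3)

    def test_identity_mapping(self):
        p = GaussianParams(np.zeros(1), np.ones(1))
        assert sample_latent(p, eps=np.array([0.3]))[0] == pytest.approx(0.3)

    def test_deterministic_given_seed(self):
        p = GaussianParams(np.zeros(5), np.full(5, 2.0))
        z1 = sample_latent(p, rng=np.random.default_rng(7))
        z2 = sample_latent(p, rng=np.random.default_rng(7))
        assert np.array_equal(z1, z2)


class TestComputePosterior:
    def test_zero_adaptive_state_is_standard_normal(self):
        q = compute_posterior(np.zeros(3), np.zeros(3))
        assert np.allclose(q.mu, 0.0) and np.allclose(q.sigma, 1.0)

    def test_saturation_stays_inside_bounds(self):
        q = compute_posterior(np.array([20.0]), np.array([50.0]))
        assert q.mu[0] < 1.0              # clamped below 1 at machine eps
        assert q.mu[0] > 1.0 - 1e-12
        assert np.isfinite(q.sigma[0])

    def test_hand_evaluation(self):
        q = compute_posterior(np.array([0.5]), np.array([-1.0]))
        assert q.mu[0] == pytest.approx(0.46211715726)
        assert q.sigma[0] == pytest.approx(0.36787944117)


class TestStepDeterministic:
    W = {"recurrent": np.zeros((1, 1)), "latent": np.zeros((1, 1)),
         "bias": np.zeros(1)}

    def test_tau_one_has_no_leak(self):
        w = {"recurrent": np.array([[2.0]]), "latent": np.array([[1.0]]),
             "bias": np.array([0.5])}
        h, d = step_deterministic(np.array([10.0]), np.array([1.0]),
                                  np.array([1.0]), w, tau=1.0)
        assert h[0] == pytest.approx(3.5)  # no h_prev contribution

    def test_leak_term_hand_value(self):
        h, d = step_deterministic(np.array([1.0]), np.array([0.0]),
                                  np.array([0.0]), self.W, tau=2.0)
        assert h[0] == pytest.approx(0.5)
        assert d[0] == pytest.approx(np.tanh(0.5))

    def test_larger_tau_changes_more_slowly(self):
        w = {"recurrent": np.zeros((1, 1)), "latent": np.array([[1.0]]),
             "bias": np.zeros(1)}
        h0 = np.zeros(1)
        z = np.array([1.0])  # step input
        h_fast, _ = step_deterministic(h0, np.zeros(1), z, w, tau=2.0)
        h_slow, _ = step_deterministic(h0, np.zeros(1), z, w, tau=4.0)
        assert abs(h_slow[0]) < abs(h_fast[0])


class TestComputeOutput:
    def test_zero_weights(self):
        assert np.allclose(compute_output(np.ones(4), np.zeros((2, 4))), 0.0)

    def test_bounded(self):
        rng = np.random.default_rng(0)
        out = compute_output(rng.normal(0, 100, 4), rng.normal(0, 10, (2, 4)))
        assert np.all(np.abs(out) < 1.0)

    def test_identity_weights_hand_value(self):
        out = compute_output(np.array([0.2, -0.3]), np.eye(2))
        assert np.allclose(out, np.tanh([0.2, -0.3]))


def _reference_forward(model, x, state, eps):
    """Hand-composed forward pass from the public fine-grained ops."""
    s = model.spec
    w = model.w
    eps3, eps2, eps1 = eps
    T = x.shape[0]
    q3 = compute_posterior(state.a3m, state.a3s)
    z3 = sample_latent(q3, eps=eps3)
    h2 = np.zeros(s.d2_dim)
    d2 = np.zeros(s.d2_dim)
    h1 = np.zeros((s.n_regions, s.d1_dim))
    d1 = np.zeros((s.n_regions, s.d1_dim))
    recon = 0.0
    kls = [0.0, 0.0]
    from neurotwin import gaussian_kl
    kl3 = gaussian_kl(q3, GaussianParams(np.zeros(s.z3_dim),
                                         np.ones(s.z3_dim)))
    xhat = np.empty_like(x)
    for t in range(T):
        p2 = compute_prior(d2, w["W2pm"], w["W2ps"], initial=(t == 0))
        q2 = compute_posterior(state.a2m[t], state.a2s[t])
        z2 = sample_latent(q2, eps=eps2[t])
        kls[1] += gaussian_kl(q2, p2)
        net_w = {"recurrent": w["Wd2d2"], "latent": w["Wd2z2"],
                 "topdown": w["Wd2z3"], "bias": w["b2"]}
        h2, d2_new = step_deterministic(h2, d2, z2, net_w,
                                        tau=s.tau_network, topdown=z3)
        for r in range(s.n_regions):
            p1 = compute_prior(d1[r], w["W1pm"][r], w["W1ps"][r],
                               initial=(t == 0))
            q1 = compute_posterior(state.a1m[t, r], state.a1s[t, r])
            z1 = sample_latent(q1, eps=eps1[t, r])
            kls[0] += gaussian_kl(q1, p1)
            loc_w = {"recurrent": w["Wd1d1"][r], "latent": w["Wd1z1"][r],
                     "topdown": w["Wd1d2"][r], "bias": w["b1"][r]}
            h1[r], d1_new = step_deterministic(h1[r], d1[r], z1, loc_w,
                                               tau=s.tau_local,
                                               topdown=d2_new)
            d1[r] = d1_new
            xhat[t, r] = compute_output(d1[r], w["Wout"][r])
        d2 = d2_new
        recon += 0.5 * np.sum((x[t] - xhat[t]) ** 2)
    return xhat, recon, (kls[0], kls[1], kl3)


class TestForwardWindow:
    def test_matches_hand_composed_ops(self, tiny_model):
        """The compiled window pass equals composing the public operations."""
        rng = np.random.default_rng(3)
        T = 6
        s = tiny_model.spec
        x = rng.uniform(-0.5, 0.5, (T, s.n_regions, s.channels_per_region))
        state = AdaptiveState.zeros(s, T)
        for a in state.arrays():
            a += rng.normal(0, 0.4, a.shape)
        eps = tiny_model._draw_eps(T, rng, True)
        trace = tiny_model.forward_window(x, state, eps=eps)
        xhat_ref, recon_ref, kl_ref = _reference_forward(
            tiny_model, x, state, eps)
        assert np.allclose(trace.xhat, xhat_ref, atol=1e-12)
        assert trace.recon == pytest.approx(recon_ref)
        assert trace.kl_per_level == pytest.approx(kl_ref)

    def test_single_step_window_is_one_pass(self, tiny_model):
        rng = np.random.default_rng(4)
        s = tiny_model.spec
        x = rng.uniform(-0.5, 0.5, (1, s.n_regions, s.channels_per_region))
        state = AdaptiveState.zeros(s, 1)
        eps = tiny_model._draw_eps(1, rng, True)
        trace = tiny_model.forward_window(x, state, eps=eps)
        xhat_ref, recon_ref, _ = _reference_forward(tiny_model, x, state, eps)
        assert np.allclose(trace.xhat, xhat_ref)

    def test_deterministic_given_seed(self, tiny_model):
        s = tiny_model.spec
        x = np.zeros((5, s.n_regions, s.channels_per_region))
        state = AdaptiveState.zeros(s, 5)
        t1 = tiny_model.forward_window(x, state,
                                       rng=np.random.default_rng(9))
        t2 = tiny_model.forward_window(x, state,
                                       rng=np.random.default_rng(9))
        assert np.array_equal(t1.xhat, t2.xhat)

    def test_mean_pass_ignores_rng(self, tiny_model):
        s = tiny_model.spec
        x = np.zeros((5, s.n_regions, s.channels_per_region))
        state = AdaptiveState.zeros(s, 5)
        t1 = tiny_model.forward_window(x, state, sample=False,
                                       rng=np.random.default_rng(1))
        t2 = tiny_model.forward_window(x, state, sample=False,
                                       rng=np.random.default_rng(2))
        assert np.array_equal(t1.xhat, t2.xhat)

    def test_bounded_outputs_and_positive_sigmas(self, tiny_model):
        rng = np.random.default_rng(5)
        s = tiny_model.spec
        T = 20
        x = rng.uniform(-1, 1, (T, s.n_regions, s.channels_per_region))
        state = AdaptiveState.zeros(s, T)
        for a in state.arrays():
            a += rng.normal(0, 1.0, a.shape)
        trace = tiny_model.forward_window(x, state, rng=rng)
        assert np.all(np.abs(trace.xhat) < 1.0)
        assert np.all(np.abs(trace.mu1q) < 1.0)
        assert np.all(np.abs(trace.mu2q) < 1.0)
        assert np.all(np.abs(trace.d1) <= 1.0)
        for sg in (trace.sg1q, trace.sg2q, trace.sg3q, trace.sg1p,
                   trace.sg2p):
            assert np.all(sg > 0)

    def test_global_latent_constant_within_generation(self, tiny_model):
        gen = tiny_model.generate(10, np.random.default_rng(0))
        assert gen.z3.shape == (tiny_model.spec.z3_dim,)


class TestNetworkSpec:
    def test_invalid_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            NetworkSpec(n_regions=0)
        with pytest.raises(ConfigurationError):
            NetworkSpec(tau_local=0.5)
        with pytest.raises(ConfigurationError):
            NetworkSpec(meta_prior=(-1, 0.001, 0.001))

    def test_output_dimension(self):
        spec = NetworkSpec()
        assert spec.n_channels == 20

    def test_yaml_round_trip(self, tmp_path, tiny_spec):
        path = tmp_path / "spec.yaml"
        tiny_spec.to_yaml(path)
        loaded = NetworkSpec.from_yaml(path)
        assert loaded == tiny_spec

    def test_model_save_load_round_trip(self, tmp_path, tiny_model):
        path = tmp_path / "model.npz"
        tiny_model.save(path)
        loaded = HierarchicalVRNN.load(path)
        for k in tiny_model.w:
            assert np.array_equal(loaded.w[k], tiny_model.w[k])
        x = np.zeros((3, 2, 2))
        st = AdaptiveState.zeros(tiny_model.spec, 3)
        a = tiny_model.forward_window(x, st, sample=False)
        b = loaded.forward_window(x, st, sample=False)
        assert np.array_equal(a.xhat, b.xhat)
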