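"""Three-level hierarchical variational RNN for multichannel cortical signals.

The generative model has a spatial and temporal hierarchy:

* **Local region level** — one module per cortical region, each with its own
  stochastic latent units ``z1``, fast deterministic units ``d1``
  (time constant ``tau_local``), and a ``tanh`` read-out producing that
  region's channels.
* **Functional network level** — a single module (``z2``, ``d2``) with a
  slower time constant ``tau_network`` whose deterministic output feeds every
  region module top-down.
* **Global state level** — latent-only units ``z3`` that are held constant
  across a sequence and enter the network-level dynamics directly; they
  abstractly encode the sequence-wide brain state.

Latent priors are diagonal Gaussians whose mean/SD are ``tanh``/``exp``
read-outs of the previous deterministic state of the same module;
posteriors are parameterised by per-time-step adaptive states
``(a_mu, a_sigma)`` via the same ``tanh``/``exp`` link, and samples use the
reparameterisation ``z = mu + sigma * eps`` with standard-normal ``eps``.
At the first time step of a sequence all priors are ``N(0, 1)``.
"""
from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import _core
from .signals import SignalSequence, region_names

WEIGHT_KEYS = (
    "W2pm", "W2ps", "Wd2d2", "Wd2z2", "Wd2z3", "b2",
    "W1pm", "W1ps", "Wd1d1", "Wd1z1", "Wd1d2", "b1", "Wout",
)


class ConfigurationError(ValueError):
    """Raised for inconsistent architecture descriptions or inputs."""


#: Largest double strictly below 1; tanh outputs are clamped to +-_BOUND in
#: the fine-grained ops so the open-interval invariant survives float64
#: rounding at extreme pre-activations.
_BOUND = float(np.nextafter(1.0, 0.0))


# --------------------------------------------------------------------------
# architecture description
# --------------------------------------------------------------------------
@dataclass
class NetworkSpec:
    """Full architecture description of the hierarchical V-RNN.

    Defaults follow the reference configuration for 20-channel recordings
    from 10 regions: one latent per region module, three network-level and
    two global latents, 15 deterministic units per module, time constants
    2 (local) and 4 (network), and a uniform meta-prior of 0.001.
    """

    n_regions: int = 10
    channels_per_region: int = 2
    z1_dim: int = 1
    z2_dim: int = 3
    z3_dim: int = 2
    d1_dim: int = 15
    d2_dim: int = 15
    tau_local: float = 2.0
    tau_network: float = 4.0
    meta_prior: tuple[float, float, float] = (0.001, 0.001, 0.001)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_regions, self.channels_per_region, self.z1_dim,
            self.z2_dim, self.z3_dim, self.d1_dim, self.d2_dim,
        )
        if any(int(c) < 1 for c in counts):
            raise ConfigurationError("all unit counts must be >= 1")
        if self.tau_local < 1 or self.tau_network < 1:
            raise ConfigurationError("time constants must be >= 1")
        self.meta_prior = tuple(float(w) for w in self.meta_prior)
        if len(self.meta_prior) != 3 or any(w < 0 for w in self.meta_prior):
            raise ConfigurationError("meta_prior must be three non-negative reals")

    @property
    def n_channels(self) -> int:
        return self.n_regions * self.channels_per_region

    @property
    def regions(self) -> tuple[str, ...]:
        return region_names(self.n_regions)

    @classmethod
    def desk_scale(cls, n_regions: int = 2, **kw) -> "NetworkSpec":
        """Small configuration for laptop-scale experiments and tests."""
        defaults = dict(
            n_regions=n_regions, channels_per_region=2, z1_dim=1,
            z2_dim=2, z3_dim=2, d1_dim=8, d2_dim=8,
        )
        defaults.update(kw)
        return cls(**defaults)

    def to_dict(self) -> dict:
        return {
            "n_regions": self.n_regions,
            "channels_per_region": self.channels_per_region,
            "latent_dims": {"local": self.z1_dim, "network": self.z2_dim,
                            "global": self.z3_dim},
            "det_dims": {"local": self.d1_dim, "network": self.d2_dim},
            "tau": {"local": self.tau_local, "network": self.tau_network},
            "meta_prior": list(self.meta_prior),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(
            n_regions=d["n_regions"],
            channels_per_region=d["channels_per_region"],
            z1_dim=d["latent_dims"]["local"],
            z2_dim=d["latent_dims"]["network"],
            z3_dim=d["latent_dims"]["global"],
            d1_dim=d["det_dims"]["local"],
            d2_dim=d["det_dims"]["network"],
            tau_local=d["tau"]["local"],
            tau_network=d["tau"]["network"],
            meta_prior=tuple(d["meta_prior"]),
            seed=d.get("seed", 0),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "NetworkSpec":
        if hasattr(source, "read"):
            return cls.from_dict(yaml.safe_load(source))
        try:
            with open(source) as fh:
                return cls.from_dict(yaml.safe_load(fh))
        except (OSError, TypeError):
            return cls.from_dict(yaml.safe_load(str(source)))


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------
@dataclass
class GaussianParams:
    """Diagonal Gaussian with ``|mu| < 1`` (tanh link) and ``sigma > 0``."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != self.sigma.shape:
            raise ConfigurationError("mu and sigma must have matching shapes")
        if np.any(self.sigma <= 0):
            raise ConfigurationError("sigma must be strictly positive")


@dataclass
class AdaptiveState:
    """Per-sequence adaptive posterior states at all three levels.

    ``a3*`` are single vectors (the global posterior is shared across all
    time steps of the sequence); ``a2*``/``a1*`` carry one entry per step.
    """

    a3m: np.ndarray
    a3s: np.ndarray
    a2m: np.ndarray
    a2s: np.ndarray
    a1m: np.ndarray
    a1s: np.ndarray

    @classmethod
    def zeros(cls, spec: NetworkSpec, T: int) -> "AdaptiveState":
        return cls(
            a3m=np.zeros(spec.z3_dim), a3s=np.zeros(spec.z3_dim),
            a2m=np.zeros((T, spec.z2_dim)), a2s=np.zeros((T, spec.z2_dim)),
            a1m=np.zeros((T, spec.n_regions, spec.z1_dim)),
            a1s=np.zeros((T, spec.n_regions, spec.z1_dim)),
        )

    @property
    def n_steps(self) -> int:
        return self.a2m.shape[0]

    def arrays(self) -> list[np.ndarray]:
        return [self.a3m, self.a3s, self.a2m, self.a2s, self.a1m, self.a1s]

    def copy(self) -> "AdaptiveState":
        return AdaptiveState(*(a.copy() for a in self.arrays()))

    def window(self, t0: int, t1: int) -> "AdaptiveState":
        """View onto steps ``[t0, t1)`` (global states shared, not sliced)."""
        return AdaptiveState(
            self.a3m, self.a3s,
            self.a2m[t0:t1], self.a2s[t0:t1],
            self.a1m[t0:t1], self.a1s[t0:t1],
        )

    # posterior accessors (Eqs. of the tanh/exp link)
    def posterior_global(self) -> GaussianParams:
        return compute_posterior(self.a3m, self.a3s)

    def posterior_network(self) -> GaussianParams:
        return compute_posterior(self.a2m, self.a2s)

    def posterior_local(self) -> GaussianParams:
        return compute_posterior(self.a1m, self.a1s)


@dataclass
class ModelState:
    """Recurrent boundary state (deterministic units) at a point in time."""

    h2: np.ndarray
    d2: np.ndarray
    h1: np.ndarray
    d1: np.ndarray

    @classmethod
    def zeros(cls, spec: NetworkSpec) -> "ModelState":
        return cls(
            h2=np.zeros(spec.d2_dim), d2=np.zeros(spec.d2_dim),
            h1=np.zeros((spec.n_regions, spec.d1_dim)),
            d1=np.zeros((spec.n_regions, spec.d1_dim)),
        )

    def copy(self) -> "ModelState":
        return ModelState(self.h2.copy(), self.d2.copy(),
                          self.h1.copy(), self.d1.copy())


@dataclass
class ForwardTrace:
    """All trajectories and loss terms from one top-down window pass."""

    xhat: np.ndarray          # (T, R, C)
    z1: np.ndarray            # (T, R, L1) samples
    z2: np.ndarray            # (T, L2)
    z3: np.ndarray            # (L3,)
    mu1q: np.ndarray
    sg1q: np.ndarray
    mu2q: np.ndarray
    sg2q: np.ndarray
    mu3q: np.ndarray
    sg3q: np.ndarray
    mu1p: np.ndarray
    sg1p: np.ndarray
    mu2p: np.ndarray
    sg2p: np.ndarray
    h1: np.ndarray
    d1: np.ndarray
    h2: np.ndarray
    d2: np.ndarray
    recon: float
    kl_per_level: tuple[float, float, float]
    fsteps: np.ndarray        # (T, 3): recon_t, kl1_t, kl2_t
    meta_prior: tuple[float, float, float]
    is_start: bool

    @property
    def weighted_total(self) -> float:
        w1, w2, w3 = self.meta_prior
        k1, k2, k3 = self.kl_per_level
        return self.recon + w1 * k1 + w2 * k2 + w3 * k3

    def free_energy_steps(self) -> np.ndarray:
        """Meta-prior-weighted free energy per step (global KL on step 0)."""
        w1, w2, w3 = self.meta_prior
        f = self.fsteps[:, 0] + w1 * self.fsteps[:, 1] + w2 * self.fsteps[:, 2]
        if self.is_start:
            f = f.copy()
            f[0] += w3 * self.kl_per_level[2]
        return f

    def state_at(self, t: int) -> ModelState:
        return ModelState(self.h2[t].copy(), self.d2[t].copy(),
                          self.h1[t].copy(), self.d1[t].copy())


# --------------------------------------------------------------------------
# fine-grained operations (pure numpy; the compiled kernels mirror these)
# --------------------------------------------------------------------------
def compute_prior(d_prev, W_mu, W_sigma, initial: bool = False) -> GaussianParams:
    """Prior Gaussian from the previous deterministic output of a module.

    ``mu = tanh(W_mu @ d_prev)``, ``sigma = exp(W_sigma @ d_prev)``; at the
    first step of a sequence (``initial=True``) the prior is ``N(0, 1)``.
    """
    W_mu = np.asarray(W_mu, dtype=float)
    W_sigma = np.asarray(W_sigma, dtype=float)
    if initial:
        n = W_mu.shape[0]
        return GaussianParams(np.zeros(n), np.ones(n))
    d_prev = np.asarray(d_prev, dtype=float)
    if W_mu.shape[1] != d_prev.shape[-1] or W_sigma.shape != W_mu.shape:
        raise ConfigurationError("prior weight shape does not match d_prev")
    pre_s = np.clip(W_sigma @ d_prev, -_core.SIGMA_CLIP, _core.SIGMA_CLIP)
    mu = np.clip(np.tanh(W_mu @ d_prev), -_BOUND, _BOUND)
    return GaussianParams(mu, np.exp(pre_s))


def compute_posterior(a_mu, a_sigma) -> GaussianParams:
    """Posterior Gaussian from adaptive states: ``tanh(a_mu)``, ``exp(a_sigma)``."""
    a_mu = np.asarray(a_mu, dtype=float)
    a_sigma = np.clip(np.asarray(a_sigma, dtype=float),
                      -_core.SIGMA_CLIP, _core.SIGMA_CLIP)
    mu = np.clip(np.tanh(a_mu), -_BOUND, _BOUND)
    return GaussianParams(mu, np.exp(a_sigma))


def sample_latent(params: GaussianParams, eps=None, rng=None) -> np.ndarray:
    """Reparameterised draw ``z = mu + sigma * eps`` with ``eps ~ N(0, 1)``."""
    if eps is None:
        if rng is None:
            raise ValueError("provide either eps or a seeded rng")
        eps = rng.standard_normal(params.mu.shape)
    return params.mu + params.sigma * np.asarray(eps, dtype=float)


def step_deterministic(h_prev, d_prev, z_now, weights: dict, tau: float,
                       topdown=None):
    """One leaky-integrator update of a deterministic unit bank.

    ``h = (1/tau) * (Wr@d_prev + Wz@z + Wt@topdown + b) + (1 - 1/tau) * h_prev``
    and ``d = tanh(h)``.  ``weights`` holds ``recurrent``, ``latent``,
    ``bias`` and (optionally) ``topdown`` matrices.
    """
    h_prev = np.asarray(h_prev, dtype=float)
    pre = weights["recurrent"] @ np.asarray(d_prev, dtype=float)
    pre = pre + weights["latent"] @ np.asarray(z_now, dtype=float)
    if topdown is not None:
        pre = pre + weights["topdown"] @ np.asarray(topdown, dtype=float)
    pre = pre + weights["bias"]
    h = pre / tau + (1.0 - 1.0 / tau) * h_prev
    return h, np.tanh(h)


def compute_output(d_local, W_out) -> np.ndarray:
    """Channel prediction of one region module: ``tanh(W_out @ d1)``."""
    out = np.tanh(np.asarray(W_out) @ np.asarray(d_local, dtype=float))
    return np.clip(out, -_BOUND, _BOUND)


# --------------------------------------------------------------------------
# the model
# --------------------------------------------------------------------------
@dataclass
class GeneratedTrace:
    """Output of a prior-driven (possibly clamped) generation rollout."""

    xhat: np.ndarray
    z1: np.ndarray
    z2: np.ndarray
    z3: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    final_state: ModelState


class HierarchicalVRNN:
    """Hierarchical V-RNN: weights plus forward/backward machinery.

    Parameters
    ----------
    spec
        Architecture description.
    rng
        Seeded generator for weight initialisation; defaults to
        ``default_rng(spec.seed)``.
    """

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator | None = None):
        self.spec = spec
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        self.w: dict[str, np.ndarray] = {}
        self._init_weights(rng)

    # -- weight management -------------------------------------------------
    def _glorot(self, rng, *shape) -> np.ndarray:
        fan_in, fan_out = shape[-1], shape[-2]
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape)

    def _init_weights(self, rng) -> None:
        s = self.spec
        R, C = s.n_regions, s.channels_per_region
        L1, L2, L3 = s.z1_dim, s.z2_dim, s.z3_dim
        D1, D2 = s.d1_dim, s.d2_dim
        g = self._glorot
        self.w = {
            "W2pm": g(rng, L2, D2), "W2ps": g(rng, L2, D2),
            "Wd2d2": g(rng, D2, D2), "Wd2z2": g(rng, D2, L2),
            "Wd2z3": g(rng, D2, L3), "b2": np.zeros(D2),
            "W1pm": g(rng, R, L1, D1), "W1ps": g(rng, R, L1, D1),
            "Wd1d1": g(rng, R, D1, D1), "Wd1z1": g(rng, R, D1, L1),
            "Wd1d2": g(rng, R, D1, D2), "b1": np.zeros((R, D1)),
            "Wout": g(rng, R, C, D1),
        }
        for k in WEIGHT_KEYS:
            self.w[k] = np.ascontiguousarray(self.w[k], dtype=float)

    def weight_arrays(self) -> list[np.ndarray]:
        return [self.w[k] for k in WEIGHT_KEYS]

    def weights_flat(self) -> np.ndarray:
        return np.concatenate([self.w[k].ravel() for k in WEIGHT_KEYS])

    def set_weights_flat(self, vec: np.ndarray) -> None:
        off = 0
        for k in WEIGHT_KEYS:
            n = self.w[k].size
            self.w[k][...] = vec[off:off + n].reshape(self.w[k].shape)
            off += n
        if off != vec.size:
            raise ConfigurationError("flat weight vector has wrong length")

    def grad_template(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.w.items()}

    # -- data layout -------------------------------------------------------
    def channels_to_model(self, values: np.ndarray) -> np.ndarray:
        """(n_channels, T) region-major channels -> (T, R, C) model input."""
        s = self.spec
        if values.shape[0] != s.n_channels:
            raise ConfigurationError(
                f"expected {s.n_channels} channels, got {values.shape[0]}")
        return np.ascontiguousarray(
            values.T.reshape(-1, s.n_regions, s.channels_per_region))

    def model_to_channels(self, x: np.ndarray) -> np.ndarray:
        """(T, R, C) -> (n_channels, T)."""
        T = x.shape[0]
        return np.ascontiguousarray(x.reshape(T, -1).T)

    def sequence_to_input(self, seq: SignalSequence) -> np.ndarray:
        return self.channels_to_model(seq.values)

    # -- noise -------------------------------------------------------------
    def _draw_eps(self, T, rng, sample):
        s = self.spec
        if sample:
            return (rng.standard_normal(s.z3_dim),
                    rng.standard_normal((T, s.z2_dim)),
                    rng.standard_normal((T, s.n_regions, s.z1_dim)))
        return (np.zeros(s.z3_dim), np.zeros((T, s.z2_dim)),
                np.zeros((T, s.n_regions, s.z1_dim)))

    def _alloc_trace(self, T):
        s = self.spec
        R, C = s.n_regions, s.channels_per_region
        L1, L2, L3, D1, D2 = s.z1_dim, s.z2_dim, s.z3_dim, s.d1_dim, s.d2_dim
        return dict(
            mu2p=np.empty((T, L2)), sg2p=np.empty((T, L2)),
            mu2q=np.empty((T, L2)), sg2q=np.empty((T, L2)),
            z2=np.empty((T, L2)), h2=np.empty((T, D2)), d2=np.empty((T, D2)),
            mu1p=np.empty((T, R, L1)), sg1p=np.empty((T, R, L1)),
            mu1q=np.empty((T, R, L1)), sg1q=np.empty((T, R, L1)),
            z1=np.empty((T, R, L1)), h1=np.empty((T, R, D1)),
            d1=np.empty((T, R, D1)), xhat=np.empty((T, R, C)),
            mu3q=np.empty(L3), sg3q=np.empty(L3), z3=np.empty(L3),
            fsteps=np.empty((T, 3)),
        )

    # -- forward / backward ------------------------------------------------
    def forward_window(self, x: np.ndarray, state: AdaptiveState, *,
                       rng=None, sample=True, eps=None,
                       init_state: ModelState | None = None,
                       is_start: bool = True) -> ForwardTrace:
        """Posterior-driven top-down pass over a window.

        ``x`` is ``(T, R, C)``; ``state`` must cover exactly the window.
        With ``sample=False`` latent samples collapse to posterior means,
        making the pass deterministic.
        """
        x = np.ascontiguousarray(x, dtype=float)
        T = x.shape[0]
        if state.n_steps != T:
            raise ConfigurationError(
                f"adaptive state covers {state.n_steps} steps, window has {T}")
        if x.shape[1:] != (self.spec.n_regions, self.spec.channels_per_region):
            raise ConfigurationError("window shape does not match architecture")
        if eps is None:
            eps = self._draw_eps(T, rng, sample)
        eps3, eps2, eps1 = eps
        if init_state is None:
            init_state = ModelState.zeros(self.spec)
        tr = self._alloc_trace(T)
        recon, kl1, kl2, kl3 = _core.forward(
            self.spec.tau_local, self.spec.tau_network, is_start,
            *self.weight_arrays(),
            state.a3m, state.a3s, state.a2m, state.a2s, state.a1m, state.a1s,
            x, eps3, eps2, eps1,
            init_state.h2, init_state.d2, init_state.h1, init_state.d1,
            tr["mu2p"], tr["sg2p"], tr["mu2q"], tr["sg2q"], tr["z2"],
            tr["h2"], tr["d2"],
            tr["mu1p"], tr["sg1p"], tr["mu1q"], tr["sg1q"], tr["z1"],
            tr["h1"], tr["d1"],
            tr["xhat"], tr["mu3q"], tr["sg3q"], tr["z3"], tr["fsteps"],
        )
        return ForwardTrace(
            xhat=tr["xhat"], z1=tr["z1"], z2=tr["z2"], z3=tr["z3"],
            mu1q=tr["mu1q"], sg1q=tr["sg1q"], mu2q=tr["mu2q"],
            sg2q=tr["sg2q"], mu3q=tr["mu3q"], sg3q=tr["sg3q"],
            mu1p=tr["mu1p"], sg1p=tr["sg1p"], mu2p=tr["mu2p"],
            sg2p=tr["sg2p"], h1=tr["h1"], d1=tr["d1"], h2=tr["h2"],
            d2=tr["d2"], recon=recon, kl_per_level=(kl1, kl2, kl3),
            fsteps=tr["fsteps"], meta_prior=self.spec.meta_prior,
            is_start=is_start,
        )

    def loss_and_grads(self, x, state: AdaptiveState, *, rng=None, sample=True,
                       eps=None, init_state: ModelState | None = None,
                       is_start: bool = True,
                       weight_grads: dict | None = None,
                       a_grads: AdaptiveState | None = None,
                       zero_grads: bool = True):
        """Window free energy plus gradients w.r.t. weights and adaptive states.

        Returns ``(trace, weight_grads, a_grads)``; gradient containers are
        allocated when not supplied and accumulated into otherwise.
        """
        x = np.ascontiguousarray(x, dtype=float)
        T = x.shape[0]
        if eps is None:
            eps = self._draw_eps(T, rng, sample)
        eps3, eps2, eps1 = eps
        if init_state is None:
            init_state = ModelState.zeros(self.spec)
        if weight_grads is None:
            weight_grads = self.grad_template()
        elif zero_grads:
            for v in weight_grads.values():
                v[...] = 0.0
        if a_grads is None:
            a_grads = AdaptiveState.zeros(self.spec, T)
        elif zero_grads:
            for a in a_grads.arrays():
                a[...] = 0.0
        trace = self.forward_window(
            x, state, eps=eps, init_state=init_state, is_start=is_start)
        w1, w2, w3 = self.spec.meta_prior
        _core.backward(
            self.spec.tau_local, self.spec.tau_network, is_start, w1, w2, w3,
            *self.weight_arrays(),
            state.a3s, state.a2s, state.a1s,
            x, eps3, eps2, eps1,
            init_state.d2, init_state.d1,
            trace.mu2p, trace.sg2p, trace.mu2q, trace.sg2q, trace.z2,
            trace.h2, trace.d2,
            trace.mu1p, trace.sg1p, trace.mu1q, trace.sg1q, trace.z1,
            trace.h1, trace.d1,
            trace.xhat, trace.mu3q, trace.sg3q, trace.z3,
            *(weight_grads[k] for k in WEIGHT_KEYS),
            a_grads.a3m, a_grads.a3s, a_grads.a2m, a_grads.a2s,
            a_grads.a1m, a_grads.a1s,
        )
        return trace, weight_grads, a_grads

    # -- prior-driven generation -------------------------------------------
    def generate(self, T: int, rng: np.random.Generator, *,
                 z3=None, clamp_z2: dict | None = None,
                 clamp_z1: dict | None = None, sample: bool = True,
                 clamp_sample: bool | None = None,
                 init_state: ModelState | None = None,
                 is_start: bool = True) -> GeneratedTrace:
        """Generate a window top-down from priors, with optional clamping.

        ``z3`` fixes the global latent (a length-``z3_dim`` vector); when
        ``None`` and ``is_start``, z3 is drawn from its ``N(0,1)`` initial
        prior.  ``clamp_z2`` maps network-latent unit index -> ``(mu, sigma)``
        trajectories of shape ``(T,)``; ``clamp_z1`` maps region index ->
        ``(mu, sigma)`` of shape ``(T, z1_dim)``.  Clamped units replay the
        stored posterior (sampled when ``clamp_sample``, default follows
        ``sample``); free units draw from their priors (means if
        ``sample=False``).
        """
        s = self.spec
        R, C = s.n_regions, s.channels_per_region
        clamp_z2 = clamp_z2 or {}
        clamp_z1 = clamp_z1 or {}
        if clamp_sample is None:
            clamp_sample = sample
        for j, (mu_c, sg_c) in clamp_z2.items():
            if len(np.atleast_1d(mu_c)) != T:
                raise ConfigurationError(
                    f"z2 clamp for unit {j} has length "
                    f"{len(np.atleast_1d(mu_c))}, expected {T}")
        for r, (mu_c, sg_c) in clamp_z1.items():
            if np.asarray(mu_c).shape[0] != T:
                raise ConfigurationError(
                    f"z1 clamp for region {r} does not span {T} steps")

        if init_state is None:
            st = ModelState.zeros(s)
        else:
            st = init_state.copy()
        if z3 is None:
            if not is_start:
                raise ConfigurationError(
                    "continuing generation requires an explicit z3")
            prior3 = GaussianParams(np.zeros(s.z3_dim), np.ones(s.z3_dim))
            z3v = sample_latent(prior3, rng=rng) if sample else prior3.mu.copy()
        else:
            z3v = np.asarray(z3, dtype=float).copy()

        xhat = np.empty((T, R, C))
        z1s = np.empty((T, R, s.z1_dim))
        z2s = np.empty((T, s.z2_dim))
        d1s = np.empty((T, R, s.d1_dim))
        d2s = np.empty((T, s.d2_dim))
        w = self.w
        for t in range(T):
            initial = t == 0 and is_start
            p2 = compute_prior(st.d2, w["W2pm"], w["W2ps"], initial=initial)
            eps2 = rng.standard_normal(s.z2_dim)
            z2 = sample_latent(p2, eps=eps2) if sample else p2.mu.copy()
            for j, (mu_c, sg_c) in clamp_z2.items():
                mu_t = np.atleast_1d(np.asarray(mu_c, dtype=float))[t]
                sg_t = np.atleast_1d(np.asarray(sg_c, dtype=float))[t]
                z2[j] = mu_t + sg_t * eps2[j] if clamp_sample else mu_t
            pre2 = (w["Wd2d2"] @ st.d2 + w["Wd2z2"] @ z2
                    + w["Wd2z3"] @ z3v + w["b2"])
            h2 = pre2 / s.tau_network + (1 - 1 / s.tau_network) * st.h2
            d2 = np.tanh(h2)
            for r in range(R):
                p1 = compute_prior(st.d1[r], w["W1pm"][r], w["W1ps"][r],
                                   initial=initial)
                eps1 = rng.standard_normal(s.z1_dim)
                z1 = sample_latent(p1, eps=eps1) if sample else p1.mu.copy()
                if r in clamp_z1:
                    mu_c, sg_c = clamp_z1[r]
                    mu_t = np.asarray(mu_c, dtype=float)[t]
                    sg_t = np.asarray(sg_c, dtype=float)[t]
                    z1 = mu_t + sg_t * eps1 if clamp_sample else np.array(mu_t, ndmin=1).copy()
                pre1 = (w["Wd1d1"][r] @ st.d1[r] + w["Wd1z1"][r] @ z1
                        + w["Wd1d2"][r] @ d2 + w["b1"][r])
                h1 = pre1 / s.tau_local + (1 - 1 / s.tau_local) * st.h1[r]
                d1 = np.tanh(h1)
                xhat[t, r] = np.tanh(w["Wout"][r] @ d1)
                z1s[t, r] = z1
                d1s[t, r] = d1
                st.h1[r] = h1
                st.d1[r] = d1
            z2s[t] = z2
            d2s[t] = d2
            st.h2 = h2
            st.d2 = d2
        return GeneratedTrace(xhat=xhat, z1=z1s, z2=z2s, z3=z3v,
                              d1=d1s, d2=d2s, final_state=st)

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"weights/{k}": v for k, v in self.w.items()}
        np.savez(path, spec_yaml=np.array(self.spec.to_yaml()), **arrays)

    @classmethod
    def load(cls, path) -> "HierarchicalVRNN":
        with np.load(path, allow_pickle=False) as data:
            spec = NetworkSpec.from_yaml(_io.StringIO(str(data["spec_yaml"])))
            model = cls(spec)
            for k in WEIGHT_KEYS:
                model.w[k][...] = data[f"weights/{k}"]
        return model
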