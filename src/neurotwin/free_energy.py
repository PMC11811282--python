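"""Variational free energy (negative ELBO) and its minimisation.

The per-step loss is

    F_t = 1/2 * sum_channels (x_t - xhat_t)^2
          + sum_l W^(l) * D_KL[ q(z_t^(l)) || p(z_t^(l)) ]

with diagonal-Gaussian KL terms summed over the units of each level and
weighted by the per-level meta-prior ``W^(l)``.  Training minimises the sum
of ``F_t`` over all sequences and steps jointly over network weights and
the adaptive posterior states; data assimilation minimises the windowed sum
over posterior states only.  Updates use Rectified Adam (plain Adam is
available as a config switch).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (WEIGHT_KEYS, AdaptiveState, GaussianParams,
                    HierarchicalVRNN, ModelState)
from .signals import SignalSequence


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite during optimisation."""


# --------------------------------------------------------------------------
# free energy terms
# --------------------------------------------------------------------------
def gaussian_kl(q: GaussianParams, p: GaussianParams) -> float:
    """Closed-form KL divergence between diagonal Gaussians, summed over units.

    ``KL(q||p) = sum_i log(sp/sq) + (sq^2 + (mq - mp)^2) / (2 sp^2) - 1/2``;
    non-negative, zero iff ``q == p``.
    """
    if q.mu.shape != p.mu.shape:
        raise ValueError("q and p must have matching dimensions")
    sq, sp = q.sigma, p.sigma
    return float(np.sum(np.log(sp / sq)
                        + (sq ** 2 + (q.mu - p.mu) ** 2) / (2.0 * sp ** 2)
                        - 0.5))


@dataclass
class FreeEnergyBreakdown:
    """One time step of the loss, split into its terms."""

    reconstruction: float
    kl_per_level: tuple[float, float, float]
    meta_prior: tuple[float, float, float]
    time_step: int = 0

    @property
    def weighted_total(self) -> float:
        return self.reconstruction + sum(
            w * k for w, k in zip(self.meta_prior, self.kl_per_level))


LEVEL_ORDER = ("local", "network", "global")


def free_energy_step(x_t, xhat_t, posteriors: dict, priors: dict,
                     meta_prior=(0.001, 0.001, 0.001),
                     time_step: int = 0) -> FreeEnergyBreakdown:
    """Per-step free energy from observed/predicted channels and latents.

    ``posteriors`` and ``priors`` map level names (``local``, ``network``,
    ``global``) to :class:`GaussianParams`; levels may be omitted (KL 0),
    e.g. the global level outside the first step.
    """
    x_t = np.asarray(x_t, dtype=float)
    xhat_t = np.asarray(xhat_t, dtype=float)
    if x_t.shape != xhat_t.shape:
        raise ValueError("x and xhat must have the same shape")
    recon = 0.5 * float(np.sum((x_t - xhat_t) ** 2))
    kls = []
    for level in LEVEL_ORDER:
        q = posteriors.get(level)
        p = priors.get(level)
        if q is None or p is None:
            kls.append(0.0)
        else:
            kls.append(gaussian_kl(q, p))
    return FreeEnergyBreakdown(recon, tuple(kls), tuple(meta_prior), time_step)


def window_loss(model: HierarchicalVRNN, x_window, state: AdaptiveState, *,
                init_state: ModelState | None = None, is_start: bool = True,
                rng=None, sample: bool = False) -> float:
    """Meta-prior-weighted free energy summed over a window (weights fixed).

    By default evaluated at posterior means (deterministic); pass a seeded
    ``rng`` with ``sample=True`` for a single-sample ELBO estimate.
    """
    trace = model.forward_window(np.asarray(x_window, dtype=float), state,
                                 rng=rng, sample=sample,
                                 init_state=init_state, is_start=is_start)
    return trace.weighted_total


def training_loss(model: HierarchicalVRNN, dataset, *, rng=None,
                  sample: bool = False) -> float:
    """Sum of window losses over a dataset of ``(x, AdaptiveState)`` pairs."""
    total = 0.0
    for x, state in dataset:
        if isinstance(x, SignalSequence):
            x = model.sequence_to_input(x)
        total += window_loss(model, x, state, rng=rng, sample=sample)
    return total


# --------------------------------------------------------------------------
# optimiser
# --------------------------------------------------------------------------
@dataclass
class OptimizerConfig:
    """Rectified-Adam settings (``algorithm='adam'`` disables rectification)."""

    algorithm: str = "radam"
    alpha: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.algorithm not in ("radam", "adam"):
            raise ValueError("algorithm must be 'radam' or 'adam'")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("betas must lie in (0, 1)")
        if self.alpha <= 0:
            raise ValueError("learning rate must be positive")


class RAdam:
    """Rectified Adam over a list of parameter arrays.

    The variance-rectification term switches the update to plain momentum
    while the second-moment estimate is still unreliable (warm-up), and to
    a rectified adaptive step afterwards.  ``step`` accepts optional
    first-axis slices so that a sliding window can update only part of a
    trajectory array while moments persist across window moves.
    """

    def __init__(self, params: list[np.ndarray],
                 cfg: OptimizerConfig | None = None):
        self.cfg = cfg or OptimizerConfig()
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self._rho_inf = 2.0 / (1.0 - self.cfg.beta2) - 1.0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray],
             windows=None) -> None:
        cfg = self.cfg
        self.t += 1
        t = self.t
        b1, b2 = cfg.beta1, cfg.beta2
        bc1 = 1.0 - b1 ** t
        bc2 = 1.0 - b2 ** t
        rho = self._rho_inf - 2.0 * t * (b2 ** t) / bc2
        rectify = cfg.algorithm == "radam"
        if rectify and rho > 4.0:
            r_num = (rho - 4.0) * (rho - 2.0) * self._rho_inf
            r_den = (self._rho_inf - 4.0) * (self._rho_inf - 2.0) * rho
            r_t = float(np.sqrt(r_num / r_den))
            adaptive = True
        elif rectify:
            r_t = 1.0
            adaptive = False
        else:
            r_t = 1.0
            adaptive = True
        for i, (p, g) in enumerate(zip(params, grads)):
            sl = slice(None) if windows is None else windows[i]
            if sl is None:
                continue
            m, v = self.m[i], self.v[i]
            gs = g[sl]
            m[sl] = b1 * m[sl] + (1.0 - b1) * gs
            mh = m[sl] / bc1
            if adaptive:
                v[sl] = b2 * v[sl] + (1.0 - b2) * gs ** 2
                p[sl] -= cfg.alpha * r_t * mh / (np.sqrt(v[sl] / bc2) + cfg.eps)
            else:
                v[sl] = b2 * v[sl] + (1.0 - b2) * gs ** 2
                p[sl] -= cfg.alpha * mh


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------
@dataclass
class TrainResult:
    model: HierarchicalVRNN
    states: list[AdaptiveState]
    loss_trace: pd.DataFrame
    final_loss: float = field(default=np.nan)


def train(model: HierarchicalVRNN, sequences, n_updates: int, *,
          optimizer: OptimizerConfig | None = None,
          rng: np.random.Generator | None = None, seed: int | None = None,
          states: list[AdaptiveState] | None = None,
          log_every: int = 50, sample: bool = True) -> TrainResult:
    """Jointly optimise weights and posterior states over full sequences.

    Full-batch BPTT: every update accumulates gradients over all sequences
    and applies one Rectified-Adam step to the weights and to every
    adaptive state.  Reproducible given ``rng``/``seed``.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    optimizer = optimizer or OptimizerConfig()
    inputs = [model.sequence_to_input(s) if isinstance(s, SignalSequence)
              else np.asarray(s, dtype=float) for s in sequences]
    if not inputs and n_updates > 0:
        raise ValueError("training requires at least one sequence")
    if states is None:
        states = [AdaptiveState.zeros(model.spec, x.shape[0]) for x in inputs]

    wgrads = model.grad_template()
    agrads = [AdaptiveState.zeros(model.spec, x.shape[0]) for x in inputs]
    # parameter list order: weights then each sequence's adaptive arrays
    params = model.weight_arrays()
    grad_list = [wgrads[k] for k in WEIGHT_KEYS]
    for st, gst in zip(states, agrads):
        params.extend(st.arrays())
        grad_list.extend(gst.arrays())
    opt = RAdam(params, optimizer)

    rows = []
    last = (np.nan,) * 5
    for n in range(n_updates):
        for v in wgrads.values():
            v[...] = 0.0
        recon = kl1 = kl2 = kl3 = 0.0
        for x, st, gst in zip(inputs, states, agrads):
            trace, _, _ = model.loss_and_grads(
                x, st, rng=rng, sample=sample, weight_grads=wgrads,
                a_grads=gst, zero_grads=False)
            # a-grads are per-sequence: zero them after use in opt.step below
            recon += trace.recon
            k1, k2, k3 = trace.kl_per_level
            kl1 += k1
            kl2 += k2
            kl3 += k3
        w1, w2, w3 = model.spec.meta_prior
        total = recon + w1 * kl1 + w2 * kl2 + w3 * kl3
        if not np.isfinite(total):
            raise TrainingDiverged(
                f"non-finite loss at update {n}: recon={recon}, "
                f"kl=({kl1}, {kl2}, {kl3})")
        opt.step(params, grad_list)
        for gst in agrads:
            for a in gst.arrays():
                a[...] = 0.0
        last = (recon, kl1, kl2, kl3, total)
        if n % log_every == 0 or n == n_updates - 1:
            rows.append((n, recon, kl1, kl2, kl3, total))
    trace_df = pd.DataFrame(
        rows, columns=["update", "reconstruction", "kl_local",
                       "kl_network", "kl_global", "total"])
    return TrainResult(model=model, states=states, loss_trace=trace_df,
                       final_loss=last[-1])
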