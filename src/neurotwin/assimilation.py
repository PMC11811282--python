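"""Real-time sliding-window data assimilation and ahead prediction.

For each incoming observation the assimilation loop (1) initialises the
newest posterior from the prior propagated off the previous posterior,
(2)–(6) alternates top-down window prediction with gradient updates of the
adaptive posterior states over the window minimising the windowed free
energy, then advances the window by one step.  Network weights stay frozen
throughout; posterior entries that leave the window are final.  At startup
the window grows from one step up to its nominal width, so output is
available from the very first observation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .free_energy import OptimizerConfig, RAdam, TrainingDiverged
from .model import (AdaptiveState, HierarchicalVRNN, ModelState)
from .signals import SignalSequence


@dataclass
class AssimilationConfig:
    """Sliding-window settings.

    ``window`` (H) and ``iterations`` (K) default to the reference values
    for real-time state estimation: a 500-step window whose posteriors are
    updated 100 times per incoming step, so the earliest step of a full
    window accumulates ``H * K`` updates before leaving it.
    """

    window: int = 500
    iterations: int = 100
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    seed: int = 0
    sample_updates: bool = True   # fresh eps per update iteration

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")


@dataclass
class AssimilationTrace:
    """Per-step record of one assimilation run.

    ``xhat``/latent trajectories hold the *final* (post-assimilation)
    values, re-recorded while a step remains inside the advancing window;
    ``xhat_online`` holds the value each step had when it was the window
    head (the real-time output).  ``z3_mu`` is the head-time global
    posterior mean, i.e. the real-time brain-state estimate.
    """

    x: np.ndarray
    xhat: np.ndarray
    xhat_online: np.ndarray
    recon_steps: np.ndarray
    free_energy: np.ndarray
    z1_mu: np.ndarray
    z1_sg: np.ndarray
    z2_mu: np.ndarray
    z2_sg: np.ndarray
    z3_mu: np.ndarray
    z3_sg: np.ndarray
    update_counts: np.ndarray
    state: AdaptiveState
    h2: np.ndarray
    d2: np.ndarray
    h1: np.ndarray
    d1: np.ndarray
    config: AssimilationConfig
    switch_step: int | None = None

    @property
    def n_steps(self) -> int:
        return self.x.shape[0]

    def model_state_at(self, t: int) -> ModelState:
        """Recurrent state after step ``t`` (from the final window passes)."""
        return ModelState(self.h2[t].copy(), self.d2[t].copy(),
                          self.h1[t].copy(), self.d1[t].copy())

    def summary_table(self) -> pd.DataFrame:
        cols = {
            "t": np.arange(1, self.n_steps + 1),   # 1-based, user-facing
            "recon_error": self.recon_steps,
            "free_energy": self.free_energy,
        }
        for i in range(self.z3_mu.shape[1]):
            cols[f"z3_mu_{i + 1}"] = self.z3_mu[:, i]
        return pd.DataFrame(cols)


def assimilate(model: HierarchicalVRNN, stream,
               cfg: AssimilationConfig | None = None,
               rng: np.random.Generator | None = None) -> AssimilationTrace:
    """Assimilate a signal stream step by step with frozen weights.

    ``stream`` is a :class:`SignalSequence` or a ``(T, R, C)`` array.
    Deterministic given the seeded ``rng`` (defaults to
    ``default_rng(cfg.seed)``).
    """
    cfg = cfg or AssimilationConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    switch = None
    if isinstance(stream, SignalSequence):
        switch = stream.switch_step
        x_full = model.sequence_to_input(stream)
    else:
        x_full = np.ascontiguousarray(stream, dtype=float)
    T = x_full.shape[0]
    if T < 1:
        raise ValueError("stream must contain at least one step")
    s = model.spec
    H, K = cfg.window, cfg.iterations

    state = AdaptiveState.zeros(s, T)
    agrads = AdaptiveState.zeros(s, T)
    wscratch = model.grad_template()   # weight grads discarded: weights frozen
    opt = RAdam(state.arrays(), cfg.optimizer)

    h2r = np.zeros((T, s.d2_dim))
    d2r = np.zeros((T, s.d2_dim))
    h1r = np.zeros((T, s.n_regions, s.d1_dim))
    d1r = np.zeros((T, s.n_regions, s.d1_dim))
    xhat = np.zeros_like(x_full)
    xhat_online = np.zeros_like(x_full)
    recon_steps = np.zeros(T)
    fe = np.zeros(T)
    z1mu = np.zeros((T, s.n_regions, s.z1_dim))
    z1sg = np.zeros((T, s.n_regions, s.z1_dim))
    z2mu = np.zeros((T, s.z2_dim))
    z2sg = np.zeros((T, s.z2_dim))
    z3mu = np.zeros((T, s.z3_dim))
    z3sg = np.zeros((T, s.z3_dim))
    counts = np.zeros(T, dtype=np.int64)

    w = model.w
    clip = 10.0
    for t in range(T):
        t0 = max(0, t - H + 1)
        # (1) newest posterior starts at the prior propagated from t-1
        if t > 0:
            state.a2m[t] = w["W2pm"] @ d2r[t - 1]
            state.a2s[t] = np.clip(w["W2ps"] @ d2r[t - 1], -clip, clip)
            for r in range(s.n_regions):
                state.a1m[t, r] = w["W1pm"][r] @ d1r[t - 1, r]
                state.a1s[t, r] = np.clip(w["W1ps"][r] @ d1r[t - 1, r],
                                          -clip, clip)
        is_start = t0 == 0
        init_state = (ModelState.zeros(s) if is_start
                      else ModelState(h2r[t0 - 1], d2r[t0 - 1],
                                      h1r[t0 - 1], d1r[t0 - 1]))
        xw = x_full[t0:t + 1]
        win = state.window(t0, t + 1)
        gwin = agrads.window(t0, t + 1)
        sl = slice(t0, t + 1)
        windows = [slice(None), slice(None), sl, sl, sl, sl]
        # (2)-(6) K cycles of prediction + posterior update
        for _ in range(K):
            trace, _, _ = model.loss_and_grads(
                xw, win, rng=rng, sample=cfg.sample_updates,
                init_state=init_state, is_start=is_start,
                weight_grads=wscratch, a_grads=gwin, zero_grads=True)
            if not np.isfinite(trace.weighted_total):
                raise TrainingDiverged(
                    f"non-finite window free energy at step {t + 1}")
            opt.step(state.arrays(), agrads.arrays(), windows=windows)
        counts[t0:t + 1] += K
        # record pass at posterior means (deterministic)
        tr = model.forward_window(xw, win, sample=False,
                                  init_state=init_state, is_start=is_start)
        h2r[sl] = tr.h2
        d2r[sl] = tr.d2
        h1r[sl] = tr.h1
        d1r[sl] = tr.d1
        xhat[sl] = tr.xhat
        xhat_online[t] = tr.xhat[-1]
        recon_steps[sl] = tr.fsteps[:, 0]
        fe[sl] = tr.free_energy_steps()
        z1mu[sl] = tr.mu1q
        z1sg[sl] = tr.sg1q
        z2mu[sl] = tr.mu2q
        z2sg[sl] = tr.sg2q
        z3mu[t] = tr.mu3q
        z3sg[t] = tr.sg3q

    return AssimilationTrace(
        x=x_full, xhat=xhat, xhat_online=xhat_online,
        recon_steps=recon_steps, free_energy=fe,
        z1_mu=z1mu, z1_sg=z1sg, z2_mu=z2mu, z2_sg=z2sg,
        z3_mu=z3mu, z3_sg=z3sg, update_counts=counts, state=state,
        h2=h2r, d2=d2r, h1=h1r, d1=d1r, config=cfg, switch_step=switch)


def predict_ahead(model: HierarchicalVRNN, trace: AssimilationTrace,
                  n_steps: int, *, at_step: int | None = None,
                  rng: np.random.Generator | None = None, seed: int = 0,
                  sample: bool = True) -> np.ndarray:
    """Roll the generative model ``n_steps`` beyond an assimilated step.

    Uses priors only (no observations): the global latent is held at its
    head-time posterior mean and lower levels sample from their priors.
    Returns predictions of shape ``(n_steps, R, C)``; deterministic given
    the seed.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if at_step is None:
        at_step = trace.n_steps - 1
    if rng is None:
        rng = np.random.default_rng(seed)
    st = trace.model_state_at(at_step)
    gen = model.generate(n_steps, rng, z3=trace.z3_mu[at_step],
                         init_state=st, is_start=False, sample=sample)
    return gen.xhat


@dataclass
class StateClassification:
    labels: np.ndarray
    proportion_before: float
    proportion_after: float
    k: int | None = None


def classify_trace_state(trace: AssimilationTrace, reference_points,
                         reference_labels, *, switch_step: int | None = None,
                         label_before=None, label_after=None,
                         method: str = "knn",
                         k_candidates=None) -> StateClassification:
    """Assign each step's global-state estimate to a reference cluster.

    ``reference_points`` are global posterior means from training (one per
    training sequence) with condition ``reference_labels``.  Returns
    per-step labels plus the proportion matching ``label_before`` /
    ``label_after`` on the two sides of the switch.
    """
    from . import metrics

    reference_points = np.asarray(reference_points, dtype=float)
    reference_labels = np.asarray(reference_labels)
    if reference_points.shape[0] == 0:
        raise ValueError("reference set is empty")
    queries = trace.z3_mu
    if method == "knn":
        res = metrics.knn_assign(queries, reference_points, reference_labels,
                                 k_candidates=k_candidates)
        labels = res.labels
        k = res.k
    elif method == "silhouette":
        labels = np.array([
            metrics.assign_by_silhouette(q, {
                lab: reference_points[reference_labels == lab]
                for lab in np.unique(reference_labels)})
            for q in queries])
        k = None
    else:
        raise ValueError("method must be 'knn' or 'silhouette'")

    if switch_step is None:
        switch_step = trace.switch_step
    if switch_step is None:
        switch_step = len(labels)
    before = labels[:switch_step]
    after = labels[switch_step:]
    p_before = float(np.mean(before == label_before)) if len(before) else np.nan
    p_after = float(np.mean(after == label_after)) if len(after) else np.nan
    return StateClassification(labels=labels, proportion_before=p_before,
                               proportion_after=p_after, k=k)
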