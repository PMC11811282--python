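"""Virtual interventions: clamp condition-specific posteriors while generating.

The posterior repertoire is built by full-sequence posterior estimation
(the window fixed to the whole sequence so the global latent stays
constant, summarising the sequence).  An intervention then generates a
virtual signal in which target latent units replay a stored posterior
(the global latent as a constant, network/region latents as trajectories)
while all non-target units generate top-down from their priors.  The
discriminator quantifies how often the generated signals carry the
intervention's target condition.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .free_energy import OptimizerConfig, RAdam, TrainingDiverged
from .model import AdaptiveState, GaussianParams, HierarchicalVRNN
from .signals import SignalSequence


@dataclass
class RepertoireEntry:
    """Estimated posterior of one labelled sequence at all three levels."""

    condition: str
    sequence_id: str
    individual: str
    state: AdaptiveState
    z3: GaussianParams
    z2: GaussianParams          # trajectories (T, L2)
    z1: GaussianParams          # trajectories (T, R, L1)
    free_energy: float

    @property
    def n_steps(self) -> int:
        return self.state.n_steps


@dataclass
class LatentRepertoire:
    entries: dict = field(default_factory=dict)   # (condition, seq_id) -> entry

    def add(self, entry: RepertoireEntry) -> None:
        self.entries[(entry.condition, entry.sequence_id)] = entry

    def by_condition(self, condition: str) -> list[RepertoireEntry]:
        return [e for (c, _), e in sorted(self.entries.items())
                if c == condition]

    def z3_points(self, condition: str | None = None):
        """Global posterior means with labels, for clustering/classification."""
        entries = (self.by_condition(condition) if condition
                   else [e for _, e in sorted(self.entries.items())])
        pts = np.array([e.z3.mu for e in entries])
        labels = np.array([e.condition for e in entries])
        return pts, labels


def estimate_condition_latents(model: HierarchicalVRNN, sequences, *,
                               iterations: int = 10000,
                               optimizer: OptimizerConfig | None = None,
                               rng: np.random.Generator | None = None,
                               seed: int = 0, sample_updates: bool = True
                               ) -> LatentRepertoire:
    """Full-window posterior estimation for labelled sequences.

    The time window spans each whole sequence and never advances, so the
    global latent remains a single constant abstractly representing the
    sequence; posteriors are updated ``iterations`` times with weights
    frozen.  Sequences must carry a non-``mixed`` condition label.

    Each sequence is optimised with its own generator seeded identically
    (derived from ``seed``/``rng``), so estimates depend only on the
    sequence content: duplicated sequences yield identical entries.
    """
    if rng is not None:
        seed = int(rng.integers(2 ** 31))
    optimizer = optimizer or OptimizerConfig()
    rep = LatentRepertoire()
    for si, seq in enumerate(sequences):
        rng = np.random.default_rng(seed)
        if isinstance(seq, SignalSequence):
            if seq.condition == "mixed":
                raise ValueError(
                    f"sequence {si} is 'mixed'; repertoire estimation "
                    "requires single-condition labels")
            x = model.sequence_to_input(seq)
            cond, ind = seq.condition, seq.individual
        else:
            raise ValueError("estimate_condition_latents expects "
                             "SignalSequence inputs (labels are required)")
        T = x.shape[0]
        state = AdaptiveState.zeros(model.spec, T)
        grads = AdaptiveState.zeros(model.spec, T)
        wscratch = model.grad_template()
        opt = RAdam(state.arrays(), optimizer)
        for k in range(iterations):
            trace, _, _ = model.loss_and_grads(
                x, state, rng=rng, sample=sample_updates,
                weight_grads=wscratch, a_grads=grads, zero_grads=True)
            if not np.isfinite(trace.weighted_total):
                raise TrainingDiverged(
                    f"non-finite free energy at iteration {k}, "
                    f"sequence {si}")
            opt.step(state.arrays(), grads.arrays())
        final = model.forward_window(x, state, sample=False)
        rep.add(RepertoireEntry(
            condition=cond, sequence_id=f"seq{si}", individual=ind,
            state=state,
            z3=GaussianParams(final.mu3q.copy(), final.sg3q.copy()),
            z2=GaussianParams(final.mu2q.copy(), final.sg2q.copy()),
            z1=GaussianParams(final.mu1q.copy(), final.sg1q.copy()),
            free_energy=final.weighted_total))
    return rep


@dataclass
class InterventionSpec:
    """Which latent units replay which stored posterior.

    ``clamp_z3`` is a repertoire entry (or ``None`` to leave the global
    level prior-driven); ``clamp_z2`` maps network-latent unit index to an
    entry; ``clamp_z1`` maps region index to an entry.  ``mode='sample'``
    replays the stored posterior distribution (fresh reparameterised
    draws); ``mode='mean'`` injects posterior means.
    """

    duration: int = 2000
    clamp_z3: RepertoireEntry | None = None
    clamp_z2: dict = field(default_factory=dict)
    clamp_z1: dict = field(default_factory=dict)
    mode: str = "sample"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("sample", "mean"):
            raise ValueError("mode must be 'sample' or 'mean'")
        for j, entry in {**self.clamp_z2, **self.clamp_z1}.items():
            if entry.n_steps != self.duration:
                raise ValueError(
                    f"clamp trajectory for target {j} spans "
                    f"{entry.n_steps} steps, intervention lasts "
                    f"{self.duration}")


@dataclass
class InterventionOutcome:
    signal: SignalSequence
    z3: np.ndarray
    z2: np.ndarray
    z1: np.ndarray


def intervene_generate(model: HierarchicalVRNN, spec: InterventionSpec,
                       rng: np.random.Generator | None = None
                       ) -> InterventionOutcome:
    """Generate a virtual signal under the requested clamping."""
    s = model.spec
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    sample = spec.mode == "sample"
    if spec.clamp_z3 is not None:
        z3p = spec.clamp_z3.z3
        z3v = (z3p.mu + z3p.sigma * rng.standard_normal(z3p.mu.shape)
               if sample else z3p.mu.copy())
    else:
        z3v = None
    clamp_z2 = {j: (e.z2.mu[:, j], e.z2.sigma[:, j])
                for j, e in spec.clamp_z2.items()}
    clamp_z1 = {r: (e.z1.mu[:, r], e.z1.sigma[:, r])
                for r, e in spec.clamp_z1.items()}
    gen = model.generate(spec.duration, rng, z3=z3v, clamp_z2=clamp_z2,
                         clamp_z1=clamp_z1, sample=True,
                         clamp_sample=sample)
    cond = spec.clamp_z3.condition if spec.clamp_z3 is not None else "mixed"
    ind = (spec.clamp_z3.individual if spec.clamp_z3 is not None
           else "virtual")
    values = model.model_to_channels(gen.xhat)
    sig = SignalSequence(
        values=values, sampling_rate=1000.0, condition=cond, individual=ind,
        region_map=tuple(r for r in s.regions
                         for _ in range(s.channels_per_region)),
        provenance=("virtual_intervention",))
    return InterventionOutcome(signal=sig, z3=gen.z3, z2=gen.z2, z1=gen.z1)


def evaluate_intervention(signals_by_target: dict, discriminator,
                          target_condition: str,
                          spectrogram_params=None) -> pd.DataFrame:
    """Proportion of generated signals classified as the target condition.

    ``signals_by_target`` maps an intervention label (e.g. the clamped
    unit/region) to the list of generated :class:`SignalSequence`; the
    table reports mean, SD and n of the per-sequence indicator.
    """
    from .discriminator import classify, multitaper_spectrogram

    rows = []
    for target, signals in signals_by_target.items():
        if len(signals) == 0:
            raise ValueError(f"no generated signals for target {target!r}")
        stacks = [multitaper_spectrogram(sig, params=spectrogram_params)
                  for sig in signals]
        res = classify(discriminator, stacks)
        hits = (res.labels == target_condition).astype(float)
        rows.append((target, float(hits.mean()),
                     float(hits.std()), len(hits)))
    return pd.DataFrame(rows, columns=["target", "proportion", "sd", "n"]
                        ).set_index("target")
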