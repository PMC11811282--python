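"""Desk-scale benchmark preset.

One named configuration that the examples, the test suite and the
acceptance script all share: a two-region, four-channel model trained on
short two-regime synthetic sequences.  Problem sizes are chosen so the
full pipeline (training, assimilation, interventions, discriminator) runs
on a single CPU in minutes while preserving the behaviour of interest —
regime-separated global latents and real-time state tracking.

Choices that differ from the full-scale reference configuration (documented
in the methods note):

* two region modules, 8 deterministic units, 200-step training sequences;
* a uniform meta-prior of 0.02 — at four channels and 200 steps the
  reconstruction term is roughly two orders of magnitude smaller than at
  full scale, so the KL weighting is raised accordingly to keep the same
  regularisation balance (too-small values make per-sequence posteriors
  idiosyncratic instead of regime-organised);
* 20,000 training updates;
* the discriminator trains for 400 updates on 500 ms segments (the small
  from-scratch network has no normalisation layers and needs more
  full-batch steps than the full-scale recipe's 100).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .discriminator import DiscriminatorConfig
from .model import NetworkSpec
from .preprocessing import (crossfade_concat, normalize_linear,
                            rereference_common_median)
from .signals import SignalSequence
from .synthetic import (IndividualParams, RegimeParams, default_regimes,
                        generate_sequence)


@dataclass
class DeskBench:
    """Desk-scale study conditions for the two-regime benchmark."""

    n_regions: int = 2
    seq_len: int = 200
    rate: float = 1000.0
    n_per_regime: int = 8
    n_individuals: int = 4          # last one is held out for testing
    meta_prior: float = 0.02
    train_updates: int = 20000
    assim_window: int = 60
    assim_iterations: int = 30
    repertoire_iterations: int = 10000
    disc_updates: int = 400
    disc_segment_ms: float = 500.0
    regimes: tuple[RegimeParams, RegimeParams] = field(default=None)

    def __post_init__(self) -> None:
        if self.regimes is None:
            self.regimes = default_regimes(self.n_regions)

    @property
    def n_channels(self) -> int:
        return 2 * self.n_regions

    def spec(self) -> NetworkSpec:
        return NetworkSpec.desk_scale(
            n_regions=self.n_regions, meta_prior=(self.meta_prior,) * 3)

    def individuals(self, rng: np.random.Generator) -> list[IndividualParams]:
        return [IndividualParams.sample(f"ind{i}", self.n_channels, rng)
                for i in range(self.n_individuals)]

    def preprocess(self, seq: SignalSequence) -> SignalSequence:
        # desk sequences are shorter than one outlier bin; the clean
        # generator cannot produce 8-SD excursions anyway
        return normalize_linear(rereference_common_median(seq))

    def sequence(self, regime, individual, length=None, *,
                 rng) -> SignalSequence:
        length = length or self.seq_len
        return self.preprocess(generate_sequence(
            regime, individual, length, n_channels=self.n_channels,
            rate=self.rate, rng=rng))

    def training_sequences(self, rng: np.random.Generator,
                           individuals=None) -> list[SignalSequence]:
        """Training set from the first three (training) individuals."""
        if individuals is None:
            individuals = self.individuals(rng)
        train_inds = individuals[:self.n_individuals - 1]
        seqs = []
        for k in range(self.n_per_regime):
            for regime in self.regimes:
                ind = train_inds[k % len(train_inds)]
                seqs.append(self.sequence(regime, ind, rng=rng))
        return seqs

    def switch_sequence(self, individual, rng: np.random.Generator, *,
                        first_len=500, second_len=500,
                        order=("awake", "anesthetized")) -> SignalSequence:
        """Held-out regime-switch sequence (crossfaded at the transition)."""
        by_name = {r.name: r for r in self.regimes}
        a = self.sequence(by_name[order[0]], individual, first_len, rng=rng)
        b = self.sequence(by_name[order[1]], individual, second_len, rng=rng)
        return crossfade_concat(a, b)

    def discriminator_config(self, seed: int = 0) -> DiscriminatorConfig:
        return DiscriminatorConfig(n_updates=self.disc_updates, seed=seed)
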