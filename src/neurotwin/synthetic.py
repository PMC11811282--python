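"""Synthetic two-regime multichannel signal generator.

Emulates the structure of awake vs. anesthetized cortical recordings at
desk scale: each channel is a sum of band-limited oscillations (randomised
phases, per-sequence amplitude jitter) plus AR(1) noise, in microvolt
units.  The "anesthetized" regime carries higher broad-band power than the
"awake" regime in all regions except the two visual regions (HV, V1),
where the difference is kept small.  Individuals differ by per-channel
gain multipliers and a mild spectral tilt — deliberately smaller than the
between-regime differences.

This generator is a study-condition definition, not a biophysical model:
oscillation frequencies sit well inside the 0–200 Hz analysis band and
amplitudes stay within the +-1000 uV normalization range.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .signals import SignalSequence, VISUAL_REGIONS, region_names


@dataclass
class RegimeParams:
    """Spectral content of one brain-state regime.

    ``band_amps`` maps region -> {frequency_hz: amplitude_uv}.
    """

    name: str
    band_amps: dict
    noise_sd: float = 25.0
    ar_coef: float = 0.9
    amp_jitter: float = 0.1   # per-sequence uniform amplitude jitter (+-)

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise SD must be positive")
        if not (0 <= self.ar_coef < 1):
            raise ValueError("AR coefficient must lie in [0, 1)")
        for region, bands in self.band_amps.items():
            if any(a < 0 for a in bands.values()):
                raise ValueError(f"negative amplitude in region {region}")


@dataclass
class IndividualParams:
    """Per-individual gain and spectral-tilt offsets."""

    name: str
    channel_gains: np.ndarray
    spectral_tilt: float = 0.0

    def __post_init__(self) -> None:
        self.channel_gains = np.asarray(self.channel_gains, dtype=float)
        if np.any(self.channel_gains <= 0):
            raise ValueError("channel gains must be positive")

    @classmethod
    def sample(cls, name: str, n_channels: int, rng: np.random.Generator,
               gain_sd: float = 0.08, tilt_sd: float = 0.05
               ) -> "IndividualParams":
        gains = np.exp(rng.normal(0.0, gain_sd, size=n_channels))
        return cls(name=name, channel_gains=gains,
                   spectral_tilt=float(rng.normal(0.0, tilt_sd)))


def default_regimes(n_regions: int = 10) -> tuple[RegimeParams, RegimeParams]:
    """Reference regime pair: broad-band power higher under anesthesia
    except in the visual regions, where the difference is small."""
    regions = region_names(n_regions)
    awake_bands = {12.0: 110.0, 25.0: 90.0, 40.0: 60.0}
    anes_bands = {4.0: 380.0, 9.0: 300.0, 18.0: 140.0}
    anes_visual = {4.0: 130.0, 9.0: 110.0, 18.0: 80.0}
    awake = RegimeParams(
        name="awake", band_amps={r: dict(awake_bands) for r in regions})
    anes = RegimeParams(
        name="anesthetized",
        band_amps={r: dict(anes_visual if r in VISUAL_REGIONS
                           else anes_bands) for r in regions})
    return awake, anes


def generate_sequence(regime: RegimeParams, individual: IndividualParams,
                      length: int, *, n_channels: int = 20,
                      rate: float = 1000.0,
                      rng: np.random.Generator | None = None,
                      seed: int = 0) -> SignalSequence:
    """One multichannel sequence of a given regime and individual (in uV)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if individual.channel_gains.shape[0] != n_channels:
        raise ValueError("individual gain vector does not match channels")
    n_regions = n_channels // 2 if n_channels % 2 == 0 else n_channels
    cpr = 2 if n_channels % 2 == 0 else 1
    regions = region_names(n_regions)
    t = np.arange(length) / rate
    values = np.empty((n_channels, length))
    for ch in range(n_channels):
        region = regions[ch // cpr]
        bands = regime.band_amps.get(region)
        if bands is None:
            raise ValueError(f"regime {regime.name!r} lacks region {region}")
        sig = np.zeros(length)
        for f, amp in bands.items():
            tilt = (f / 40.0) ** individual.spectral_tilt
            a = amp * tilt * (1.0 + regime.amp_jitter
                              * rng.uniform(-1.0, 1.0))
            sig += a * np.sin(2.0 * np.pi * f * t
                              + rng.uniform(0.0, 2.0 * np.pi))
        # AR(1) noise with stationary SD equal to noise_sd
        innov_sd = regime.noise_sd * np.sqrt(1.0 - regime.ar_coef ** 2)
        innov = rng.normal(0.0, innov_sd, length)
        innov[0] = rng.normal(0.0, regime.noise_sd)  # stationary start
        noise = lfilter([1.0], [1.0, -regime.ar_coef], innov)
        values[ch] = individual.channel_gains[ch] * (sig + noise)
    region_map = tuple(regions[ch // cpr] for ch in range(n_channels))
    return SignalSequence(values=values, sampling_rate=rate,
                          condition=regime.name,
                          individual=individual.name,
                          region_map=region_map)


@dataclass
class Fold:
    test_individual: str
    train_individuals: tuple[str, ...]


@dataclass
class Cohort:
    """Per-individual, per-condition sequence pools with LOO fold structure."""

    individuals: list[IndividualParams]
    sequences: dict = field(default_factory=dict)  # (individual, condition) -> list
    folds: list[Fold] = field(default_factory=list)
    rate: float = 1000.0

    def pool(self, individuals=None) -> dict:
        """Nested ``individual -> condition -> sequences`` mapping."""
        names = ([i.name for i in self.individuals]
                 if individuals is None else list(individuals))
        out: dict = {}
        for (ind, cond), seqs in self.sequences.items():
            if ind in names:
                out.setdefault(ind, {})[cond] = list(seqs)
        return out


def generate_cohort(n_individuals: int = 4, *, n_regions: int = 10,
                    sequences_per_condition: int = 12, seq_len: int = 2000,
                    rate: float = 1000.0, seed: int = 0,
                    regimes: tuple[RegimeParams, RegimeParams] | None = None
                    ) -> Cohort:
    """Cohort with leave-one-individual-out fold structure.

    Each fold holds one individual out for testing and trains on the rest
    (four-fold cross-validation for the default four individuals).
    """
    rng = np.random.default_rng(seed)
    n_channels = 2 * n_regions
    if regimes is None:
        regimes = default_regimes(n_regions)
    individuals = [IndividualParams.sample(f"ind{i}", n_channels, rng)
                   for i in range(n_individuals)]
    cohort = Cohort(individuals=individuals, rate=rate)
    for ind in individuals:
        for regime in regimes:
            seqs = [generate_sequence(regime, ind, seq_len,
                                      n_channels=n_channels, rate=rate,
                                      rng=rng)
                    for _ in range(sequences_per_condition)]
            cohort.sequences[(ind.name, regime.name)] = seqs
    names = [i.name for i in individuals]
    cohort.folds = [Fold(test_individual=nm,
                         train_individuals=tuple(n for n in names if n != nm))
                    for nm in names]
    return cohort
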