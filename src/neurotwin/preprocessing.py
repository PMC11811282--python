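"""Signal preprocessing chain and dataset assembly.

The canonical order is re-reference -> outlier exclusion -> linear
normalization (tracked through :attr:`SignalSequence.provenance`), followed
by segmentation into fixed-length training sequences or crossfaded
transition sequences.  Raw units are microvolts; normalization maps
[-1000, 1000] uV linearly onto [-0.8, 0.8] with no clipping, so that all
model inputs sit safely inside the (-1, 1) range of a tanh read-out.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .signals import SignalSequence

PREPROCESS_ORDER = ("common_median_reference", "outlier_exclusion",
                    "linear_normalization")


def rereference_common_median(seq: SignalSequence) -> SignalSequence:
    """Subtract the across-channel median from every channel per time step."""
    if seq.n_channels < 2:
        warnings.warn("common median reference needs >= 2 channels; no-op",
                      stacklevel=2)
        return seq.with_values(seq.values.copy(), "common_median_reference")
    med = np.median(seq.values, axis=0, keepdims=True)
    return seq.with_values(seq.values - med, "common_median_reference")


@dataclass
class OutlierResult:
    keep_mask: np.ndarray            # per-bin bool
    segments: list[SignalSequence]   # contiguous retained stretches
    sequence: SignalSequence         # retained samples concatenated
    n_bins: int
    n_excluded: int


def exclude_outlier_bins(seq: SignalSequence, bin_size: int = 2000,
                         threshold: float = 8.0) -> OutlierResult:
    """Drop fixed-size bins containing extreme samples, plus their neighbours.

    The SD is computed per channel over the whole recording (a spike cannot
    shrink its own reference that way); a bin is flagged when any sample of
    any channel deviates more than ``threshold`` SDs from that channel's
    mean, and flagged bins are removed together with both immediate
    neighbours.
    """
    v = seq.values
    T = v.shape[1]
    n_bins = int(np.ceil(T / bin_size))
    mean = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, keepdims=True)
    sd[sd == 0] = np.inf  # constant channel can never exceed the threshold
    flagged = np.zeros(n_bins, dtype=bool)
    dev = np.abs(v - mean) > threshold * sd
    for b in range(n_bins):
        if dev[:, b * bin_size:(b + 1) * bin_size].any():
            flagged[b] = True
    drop = flagged.copy()
    drop[:-1] |= flagged[1:]
    drop[1:] |= flagged[:-1]
    keep = ~drop
    if not keep.any():
        raise ValueError(
            f"all {n_bins} bins excluded ({flagged.sum()} flagged at "
            f"{threshold} SD)")
    segments = []
    start = None
    for b in range(n_bins + 1):
        if b < n_bins and keep[b]:
            if start is None:
                start = b
        elif start is not None:
            segments.append(seq.segment(start * bin_size,
                                        min(b * bin_size, T)))
            start = None
    kept_values = np.concatenate([s.values for s in segments], axis=1)
    out_seq = seq.with_values(kept_values, "outlier_exclusion")
    return OutlierResult(keep_mask=keep, segments=segments, sequence=out_seq,
                         n_bins=n_bins, n_excluded=int(drop.sum()))


def normalize_linear(data, in_range=(-1000.0, 1000.0),
                     out_range=(-0.8, 0.8)):
    """Affine map of ``in_range`` onto ``out_range`` (no clipping).

    With the default ranges this is ``y = 0.0008 * x``; values outside
    ``in_range`` follow the same affine map.  Accepts a
    :class:`SignalSequence` or a bare array.
    """
    (ilo, ihi), (olo, ohi) = in_range, out_range
    if not (ilo < ihi and olo < ohi):
        raise ValueError("ranges must satisfy lo < hi")
    scale = (ohi - olo) / (ihi - ilo)

    def _map(x):
        return (np.asarray(x, dtype=float) - ilo) * scale + olo

    if isinstance(data, SignalSequence):
        return data.with_values(_map(data.values), "linear_normalization")
    return _map(data)


def crossfade_concat(seq_a: SignalSequence, seq_b: SignalSequence,
                     taper_ms: float = 30.0) -> SignalSequence:
    """Concatenate with an overlapping linear crossfade.

    The last ``taper`` samples of A overlap the first ``taper`` samples of
    B with complementary linear ramps (summing to one), so the output is
    ``len(A) + len(B) - taper`` samples long.  ``taper = round(taper_ms *
    rate / 1000)``; a zero taper is plain concatenation.  The switch step
    recorded in the output metadata is ``len(A)`` (first index past the
    blend, where B is pure).
    """
    if seq_a.n_channels != seq_b.n_channels:
        raise ValueError("channel counts differ")
    if seq_a.sampling_rate != seq_b.sampling_rate:
        raise ValueError("sampling rates differ")
    taper = int(round(taper_ms * seq_a.sampling_rate / 1000.0))
    if taper > min(seq_a.n_steps, seq_b.n_steps):
        raise ValueError("taper longer than one of the sequences")
    a, b = seq_a.values, seq_b.values
    if taper == 0:
        values = np.concatenate([a, b], axis=1)
    else:
        up = np.arange(1, taper + 1) / (taper + 1)
        blend = a[:, a.shape[1] - taper:] * (1.0 - up) + b[:, :taper] * up
        values = np.concatenate([a[:, :a.shape[1] - taper], blend,
                                 b[:, taper:]], axis=1)
    condition = (seq_a.condition if seq_a.condition == seq_b.condition
                 else "mixed")
    return replace(seq_a, values=values, condition=condition,
                   switch_step=seq_a.n_steps,
                   provenance=seq_a.provenance + ("crossfade_concat",))


@dataclass
class AssembledDataset:
    sequences: list[SignalSequence]
    seed: int | None = None

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def total_steps(self) -> int:
        return sum(s.n_steps for s in self.sequences)


def assemble_training_set(pools: dict, n_per_condition: int = 12,
                          seq_len: int = 2000,
                          rng: np.random.Generator | None = None,
                          seed: int = 0) -> AssembledDataset:
    """Sample fixed-length training sequences from per-individual pools.

    ``pools`` maps individual -> condition -> list of candidate
    :class:`SignalSequence` (each at least ``seq_len`` steps; longer ones
    are truncated).  Sampling is seeded and without replacement.  The
    reference recipe (3 individuals x 2 conditions x 12 sequences x 2000
    steps) yields 72 sequences and 144,000 steps.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    out = []
    for ind in sorted(pools):
        for cond in sorted(pools[ind]):
            pool = pools[ind][cond]
            if len(pool) < n_per_condition:
                raise ValueError(
                    f"pool exhausted for individual={ind!r}, "
                    f"condition={cond!r}: {len(pool)} < {n_per_condition}")
            idx = rng.choice(len(pool), size=n_per_condition, replace=False)
            for i in idx:
                s = pool[int(i)]
                if s.n_steps < seq_len:
                    raise ValueError(
                        f"sequence shorter than seq_len={seq_len}")
                out.append(s.segment(0, seq_len))
    return AssembledDataset(sequences=out, seed=seed)


def assemble_transition_set(pools: dict, n_per_direction: int = 25,
                            first_len: int = 2500, second_len: int = 1500,
                            taper_ms: float = 30.0,
                            rng: np.random.Generator | None = None,
                            seed: int = 0) -> AssembledDataset:
    """Build condition-switch sequences in both directions.

    Each sequence crossfades ``first_len`` steps of one condition into
    ``second_len`` steps of the other (random picks from ``pools``:
    individual -> condition -> sequences).  Both directions are produced,
    ``2 * n_per_direction`` sequences in total, each with the switch step
    recorded in its metadata.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    by_cond: dict[str, list[SignalSequence]] = {}
    for ind in sorted(pools):
        for cond in sorted(pools[ind]):
            by_cond.setdefault(cond, []).extend(pools[ind][cond])
    conds = sorted(by_cond)
    if len(conds) != 2:
        raise ValueError("transition set needs exactly two conditions")
    out = []
    for first, second in ((conds[0], conds[1]), (conds[1], conds[0])):
        for _ in range(n_per_direction):
            a = by_cond[first][int(rng.integers(len(by_cond[first])))]
            b = by_cond[second][int(rng.integers(len(by_cond[second])))]
            if a.n_steps < first_len or b.n_steps < second_len:
                raise ValueError("pool sequences shorter than requested spans")
            out.append(crossfade_concat(a.segment(0, first_len),
                                        b.segment(0, second_len),
                                        taper_ms=taper_ms))
    return AssembledDataset(sequences=out, seed=seed)


def preprocess(seq: SignalSequence, bin_size: int = 2000,
               threshold: float = 8.0) -> SignalSequence:
    """Full chain: re-reference, outlier exclusion, linear normalization."""
    seq = rereference_common_median(seq)
    seq = exclude_outlier_bins(seq, bin_size=bin_size,
                               threshold=threshold).sequence
    return normalize_linear(seq)
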