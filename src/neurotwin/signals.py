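"""Core signal container and channel/region conventions.

Signals are multichannel continuous recordings (e.g. ECoG) stored as a
``channels x time`` float matrix with a fixed sampling rate.  Channels are
ordered region-major: two (or ``channels_per_region``) adjacent channels per
cortical region, regions in the canonical order below.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Canonical cortical region order used by all matrices in this package.
CANONICAL_REGIONS: tuple[str, ...] = (
    "FP", "DLPFC", "PM", "M1", "S1", "IPS", "AT", "AC", "HV", "V1",
)

#: Regions where the awake/anesthetized spectral-power difference is small.
VISUAL_REGIONS: tuple[str, ...] = ("HV", "V1")

CONDITIONS = ("awake", "anesthetized", "mixed")


def region_names(n_regions: int) -> tuple[str, ...]:
    """First ``n_regions`` entries of the canonical region list."""
    if n_regions <= len(CANONICAL_REGIONS):
        return CANONICAL_REGIONS[:n_regions]
    extra = tuple(f"R{i}" for i in range(len(CANONICAL_REGIONS), n_regions))
    return CANONICAL_REGIONS + extra


def channel_names(n_regions: int, channels_per_region: int = 2) -> tuple[str, ...]:
    """Region-major channel labels, e.g. ``FP_1, FP_2, DLPFC_1, ...``."""
    return tuple(
        f"{r}_{c + 1}"
        for r in region_names(n_regions)
        for c in range(channels_per_region)
    )


@dataclass
class SignalSequence:
    """A ``channels x time`` recording with metadata.

    Parameters
    ----------
    values
        Array of shape ``(n_channels, n_steps)``.  After preprocessing the
        values lie in ``[-1, 1]``.
    sampling_rate
        Sampling rate in Hz.
    condition
        One of ``awake``, ``anesthetized`` or ``mixed``.
    individual
        Identifier of the recorded individual.
    region_map
        Region label per channel (length ``n_channels``).
    switch_step
        For ``mixed`` sequences: index of the condition switch, else ``None``.
    provenance
        Ordered names of preprocessing steps already applied.
    """

    values: np.ndarray
    sampling_rate: float
    condition: str = "awake"
    individual: str = "ind0"
    region_map: tuple[str, ...] = ()
    switch_step: int | None = None
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (channels x time) array")
        if self.values.shape[1] < 1:
            raise ValueError("sequence must contain at least one time step")
        if np.isnan(self.values).any():
            raise ValueError("signal values contain NaN")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if not self.region_map:
            # default: two channels per region in canonical order
            n_ch = self.values.shape[0]
            if n_ch % 2 == 0:
                regs = region_names(n_ch // 2)
                self.region_map = tuple(r for r in regs for _ in range(2))
            else:
                self.region_map = tuple(f"R{i}" for i in range(n_ch))
        self.region_map = tuple(self.region_map)
        if len(self.region_map) != self.values.shape[0]:
            raise ValueError("region_map must cover every channel")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_steps / self.sampling_rate

    @property
    def regions(self) -> tuple[str, ...]:
        """Unique regions in first-appearance (canonical) order."""
        seen: dict[str, None] = {}
        for r in self.region_map:
            seen.setdefault(r)
        return tuple(seen)

    def with_values(self, values: np.ndarray, step: str | None = None) -> "SignalSequence":
        """Copy with new values, appending ``step`` to the provenance chain."""
        prov = self.provenance + ((step,) if step else ())
        return replace(self, values=values, provenance=prov)

    def segment(self, start: int, stop: int) -> "SignalSequence":
        return replace(self, values=self.values[:, start:stop].copy())
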