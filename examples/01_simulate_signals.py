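"""Generate two-regime synthetic cortical signals and inspect their spectra.

Builds one awake and one anesthetized sequence for the same individual,
runs the preprocessing chain (common-median re-reference, outlier
exclusion, linear normalization to [-0.8, 0.8]), and prints the
broadband power contrast per region.
"""
import numpy as np
from scipy.signal import welch

from neurotwin.preprocessing import preprocess
from neurotwin.signals import region_names
from neurotwin.synthetic import (IndividualParams, default_regimes,
                                 generate_sequence)

rng = np.random.default_rng(0)
n_regions = 10
awake, anes = default_regimes(n_regions)
individual = IndividualParams.sample("ind0", 2 * n_regions, rng)

sequences = {}
for regime in (awake, anes):
    raw = generate_sequence(regime, individual, length=4000,
                            n_channels=2 * n_regions, rng=rng)
    sequences[regime.name] = preprocess(raw)

print("normalized value range:",
      {k: (round(v.values.min(), 2), round(v.values.max(), 2))
       for k, v in sequences.items()})

print("\nbroadband power (1-150 Hz) ratio anesthetized / awake per region:")
for i, region in enumerate(region_names(n_regions)):
    powers = {}
    for name, seq in sequences.items():
        f, p = welch(seq.values[2 * i:2 * i + 2], fs=seq.sampling_rate,
                     nperseg=512, axis=1)
        powers[name] = p[:, (f >= 1) & (f <= 150)].mean()
    print(f"  {region:6s} {powers['anesthetized'] / powers['awake']:6.1f}"
          + ("   (visual region: difference kept small)"
             if region in ("HV", "V1") else ""))
# The anesthetized regime carries several-fold higher broadband power in
# every region except HV and V1, mirroring the structure the model is
# meant to pick up.
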