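"""Virtual drug administration and network-targeted interventions.

Using a trained desk model: estimates condition-specific posterior
repertoires from held-out labelled sequences, generates virtual signals
with the global latent (and, for the drug analogue, all posteriors)
clamped to each condition, and scores them with a spectrogram
discriminator.  Expects ``desk_model.npz`` from ``02_train_digital_twin``;
retrains otherwise.
"""
from pathlib import Path

import numpy as np

from neurotwin import HierarchicalVRNN, train
from neurotwin.discriminator import (stacks_from_sequences,
                                     train_discriminator)
from neurotwin.interventions import (InterventionSpec,
                                     estimate_condition_latents,
                                     evaluate_intervention,
                                     intervene_generate)
from neurotwin.presets import DeskBench

bench = DeskBench()
rng = np.random.default_rng(1)
individuals = bench.individuals(rng)

if Path("desk_model.npz").exists():
    model = HierarchicalVRNN.load("desk_model.npz")
else:
    model = HierarchicalVRNN(bench.spec(), np.random.default_rng(2))
    train(model, bench.training_sequences(rng, individuals),
          bench.train_updates, rng=np.random.default_rng(3))

# posterior repertoire of the held-out individual (500-step sequences)
test_seqs = []
for _ in range(2):
    for regime in bench.regimes:
        test_seqs.append(bench.sequence(regime, individuals[-1], 500,
                                        rng=rng))
repertoire = estimate_condition_latents(
    model, test_seqs, iterations=bench.repertoire_iterations, seed=4)

# condition discriminator on 500 ms synthetic segments
disc_seqs = []
disc_rng = np.random.default_rng(5)
for k in range(30):
    for regime in bench.regimes:
        disc_seqs.append(bench.sequence(regime, individuals[k % 3], 500,
                                        rng=disc_rng))
stacks, conds, _ = stacks_from_sequences(disc_seqs)
disc = train_discriminator(stacks, conds,
                           cfg=bench.discriminator_config(seed=6))
print(f"discriminator held-out accuracy: {disc.holdout_accuracy:.2f}")


def drug_intervention(entry, seed):
    """Virtual drug administration: replay all posterior levels."""
    return InterventionSpec(
        duration=entry.n_steps, clamp_z3=entry,
        clamp_z2={j: entry for j in range(model.spec.z2_dim)},
        clamp_z1={r: entry for r in range(model.spec.n_regions)},
        mode="sample", seed=seed)


signals = {"awake": [], "anesthetized": []}
for cond in signals:
    for i, entry in enumerate(repertoire.by_condition(cond)):
        for j in range(4):
            out = intervene_generate(model, drug_intervention(entry, 0),
                                     rng=np.random.default_rng(90 + 10 * i + j))
            signals[cond].append(out.signal)

for cond in signals:
    table = evaluate_intervention({"z3-drug": signals[cond]}, disc, cond)
    row = table.loc["z3-drug"]
    print(f"clamp to {cond:13s}: {row['proportion']:.2f} +- {row['sd']:.2f} "
          f"of {int(row['n'])} virtual signals classified as {cond}")

# network-targeted: awake global state, one network latent to anesthetized
aw = repertoire.by_condition("awake")[0]
an = repertoire.by_condition("anesthetized")[0]
targeted = [intervene_generate(
    model, InterventionSpec(duration=500, clamp_z3=aw, clamp_z2={0: an},
                            seed=0),
    rng=np.random.default_rng(200 + j)).signal for j in range(6)]
table = evaluate_intervention({"z2-unit0": targeted}, disc,
                              "anesthetized")
print(f"z2 unit 0 -> anesthetized (z3 awake): "
      f"{table.loc['z2-unit0', 'proportion']:.2f} classified anesthetized")
# A full-posterior clamp flips the classification with the clamp's
# condition; targeting a single network latent produces a partial shift.
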