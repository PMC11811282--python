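"""Shared fixtures: desk-scale study conditions and the trained system.

The expensive artefacts (trained model, assimilation trace, discriminator,
posterior repertoire) are built once per session and shared by the
behavioural and acceptance tests.
"""
import numpy as np
import pytest

from neurotwin import HierarchicalVRNN, train
from neurotwin.assimilation import (AssimilationConfig, assimilate)
from neurotwin.presets import DeskBench

SEED = 1


@pytest.fixture(scope="session")
def desk_conditions() -> DeskBench:
    """The desk-scale two-regime study conditions."""
    return DeskBench()


class TrainedSystem:
    """Trained desk-scale model plus its training data and latent summary."""

    def __init__(self, bench: DeskBench):
        self.bench = bench
        rng = np.random.default_rng(SEED)
        self.individuals = bench.individuals(rng)
        self.sequences = bench.training_sequences(rng, self.individuals)
        self.labels = np.array([s.condition for s in self.sequences])
        self.model = HierarchicalVRNN(bench.spec(),
                                      np.random.default_rng(SEED + 1))
        self.result = train(self.model, self.sequences, bench.train_updates,
                            rng=np.random.default_rng(SEED + 2),
                            log_every=1000)
        self.states = self.result.states
        self.z3_mu = np.array([st.posterior_global().mu
                               for st in self.states])

    @property
    def test_individual(self):
        return self.individuals[-1]


@pytest.fixture(scope="session")
def trained_system(desk_conditions) -> TrainedSystem:
    return TrainedSystem(desk_conditions)


@pytest.fixture(scope="session")
def switch_trace(trained_system):
    """Assimilation of a held-out awake-to-anesthetized switch sequence."""
    bench = trained_system.bench
    mix = bench.switch_sequence(trained_system.test_individual,
                                np.random.default_rng(SEED + 3))
    cfg = AssimilationConfig(window=bench.assim_window,
                             iterations=bench.assim_iterations, seed=SEED)
    trace = assimilate(trained_system.model, mix, cfg)
    return mix, trace


@pytest.fixture(scope="session")
def desk_discriminator(trained_system):
    """Condition discriminator trained on 500 ms synthetic segments."""
    from neurotwin.discriminator import (stacks_from_sequences,
                                         train_discriminator)

    bench = trained_system.bench
    rng = np.random.default_rng(SEED + 6)
    seqs = []
    for k in range(30):
        for regime in bench.regimes:
            ind = trained_system.individuals[k % 3]
            seqs.append(bench.sequence(regime, ind, 500, rng=rng))
    stacks, conds, _ = stacks_from_sequences(seqs)
    return train_discriminator(stacks, conds,
                               cfg=bench.discriminator_config(seed=SEED))


@pytest.fixture(scope="session")
def test_repertoire(trained_system):
    """Posterior repertoire of fresh labelled sequences (held-out individual)."""
    from neurotwin.interventions import estimate_condition_latents

    bench = trained_system.bench
    rng = np.random.default_rng(SEED + 7)
    seqs = []
    for _ in range(2):
        for regime in bench.regimes:
            seqs.append(bench.sequence(regime, trained_system.test_individual,
                                       500, rng=rng))
    return estimate_condition_latents(
        trained_system.model, seqs,
        iterations=bench.repertoire_iterations, seed=SEED + 8)
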