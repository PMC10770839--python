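import numpy as np
import pytest

from iterlearn.sequences import ChainDataset, ChainMeta, TrialRecord
from iterlearn.synthetic_chains import AgentHyperpriors, simulate_experiment


def make_random_dataset(
    seed: int = 0,
    n_chains: int = 2,
    generations: int = 3,
    trials: int = 4,
    length: int = 12,
    condition: int = 0,
    experiment_id: str = "fix",
) -> ChainDataset:
    """Small lineage-consistent random trial table (not agent-based)."""
    rng = np.random.default_rng(seed)
    letters = np.array(list("rgby"))

    def seq() -> str:
        return "".join(letters[rng.integers(0, 4, length)])

    records = []
    for chain in range(1, n_chains + 1):
        lineage = {s: seq() for s in range(1, trials + 1)}
        for gen in range(1, generations + 1):
            new = {}
            for trial, stim in enumerate(sorted(lineage), start=1):
                reproduced = seq()
                records.append(
                    TrialRecord(
                        experiment_id=experiment_id,
                        condition=condition,
                        chain_id=chain,
                        generation=gen,
                        trial_index=trial,
                        stimulus_id=stim,
                        presented=lineage[stim],
                        reproduced=reproduced,
                    )
                )
                new[stim] = reproduced
            lineage = new
    meta = ChainMeta(
        generations=generations,
        trials_per_generation=trials,
        sequence_length=length,
    )
    return ChainDataset(records, meta)


@pytest.fixture(scope="session")
def small_sim_dataset() -> ChainDataset:
    """One reduced-scale agent-based simulation shared across tests."""
    return simulate_experiment(
        n_transmission_chains=3, n_individual_chains=3, seed=11, generations=5
    )
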