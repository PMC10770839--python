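import numpy as np
import pytest
from scipy.stats import chisquare

from iterlearn.metrics import accuracy, measure_table
from iterlearn.sequences import INDIVIDUAL, TRANSMISSION, validate_dataset
from iterlearn.synthetic_chains import (
    AgentHyperpriors,
    AgentState,
    SimConfig,
    generate_betareg_oracle,
    generate_seed_sequences,
    run_individual_chain,
    run_transmission_chain,
    sample_agent,
    simulate_experiment,
    simulate_recall,
    update_agent,
)


class TestSeedSequences:
    def test_counts_and_lengths(self):
        seqs = generate_seed_sequences(60, 12, "rgby", np.random.default_rng(1))
        assert len(seqs) == 60
        assert all(len(s) == 12 for s in seqs)
        assert all(set(s) <= set("rgby") for s in seqs)

    def test_deterministic_given_seed(self):
        a = generate_seed_sequences(10, 12, "rgby", np.random.default_rng(5))
        b = generate_seed_sequences(10, 12, "rgby", np.random.default_rng(5))
        assert a == b

    def test_symbol_frequencies_uniform(self):
        seqs = generate_seed_sequences(10_000, 12, "rgby", np.random.default_rng(2))
        counts = [sum(s.count(c) for s in seqs) for c in "rgby"]
        assert chisquare(counts).pvalue > 0.001


class TestAgents:
    def test_degenerate_hyperpriors_give_near_identical_agents(self):
        hyper = AgentHyperpriors(
            p_unit_kappa=1e7, kappa_sd=0.0, extraction_kappa=1e7, intrusion_kappa=1e7
        )
        rng = np.random.default_rng(0)
        a, b = sample_agent(hyper, rng), sample_agent(hyper, rng)
        assert a.p_unit == pytest.approx(b.p_unit, abs=1e-2)
        assert a.kappa == b.kappa

    def test_different_seeds_differ(self):
        hyper = AgentHyperpriors()
        a = sample_agent(hyper, np.random.default_rng(1))
        b = sample_agent(hyper, np.random.default_rng(2))
        assert a.p_unit != b.p_unit

    def test_sampled_mean_matches_hyperprior_mean(self):
        hyper = AgentHyperpriors()
        rng = np.random.default_rng(3)
        draws = [sample_agent(hyper, rng).p_unit for _ in range(1000)]
        assert np.mean(draws) == pytest.approx(hyper.p_unit_mean, abs=0.02)

    def test_invalid_hyperpriors_rejected(self):
        with pytest.raises(ValueError):
            sample_agent(AgentHyperpriors(p_unit_mean=1.2), np.random.default_rng(0))


class TestRecall:
    def test_output_length_always_matches(self):
        agent = AgentState(p_unit=0.3, kappa=0.2, extraction_rate=0.5)
        update_agent(agent, ["rgrgrgrgrgrg"] * 5, np.random.default_rng(0))
        rng = np.random.default_rng(1)
        seqs = generate_seed_sequences(500, 12, "rgby", rng)
        assert all(len(simulate_recall(agent, s, rng)) == 12 for s in seqs)

    def test_high_fidelity_agent_reproduces_known_chunks(self):
        agent = AgentState(p_unit=0.99, kappa=0.0, extraction_rate=1.0)
        agent.chunk_inventory = {"rgb": 5.0, "yyrg": 5.0}
        rng = np.random.default_rng(2)
        stim = "rgbrgbyyrgrg"
        exact = sum(simulate_recall(agent, stim, rng) == stim for _ in range(200))
        assert exact > 150

    def test_zero_fidelity_empty_inventory_is_chance_level(self):
        """With no recall at all, accuracy matches the Monte-Carlo chance
        level of two independent random length-12 strings."""
        rng = np.random.default_rng(3)
        pairs = [
            generate_seed_sequences(2, 12, "rgby", rng) for _ in range(2000)
        ]
        chance = np.mean([accuracy(a, b) for a, b in pairs])
        agent = AgentState(p_unit=1e-9, kappa=0.0, extraction_rate=0.0, intrusion_rate=0.0)
        sims = []
        for _ in range(2000):
            s = generate_seed_sequences(1, 12, "rgby", rng)[0]
            sims.append(accuracy(s, simulate_recall(agent, s, rng)))
        assert np.mean(sims) == pytest.approx(chance, abs=0.02)


class TestChunkLearning:
    def test_dominant_digram_enters_inventory(self):
        agent = AgentState(p_unit=0.5, kappa=0.3, extraction_rate=1.0)
        update_agent(agent, ["rgrgrgrgrgrg"] * 30, np.random.default_rng(0))
        assert any("rg" in c for c in agent.chunk_inventory)

    def test_cap_never_exceeded(self):
        agent = AgentState(p_unit=0.5, kappa=0.3, extraction_rate=1.0, inventory_cap=8)
        rng = np.random.default_rng(1)
        for _ in range(20):
            update_agent(agent, generate_seed_sequences(30, 12, "rgby", rng), rng)
            assert len(agent.chunk_inventory) <= 8

    def test_inventory_only_admits_recurring_substrings(self):
        from collections import Counter

        observed = generate_seed_sequences(3, 12, "rgby", np.random.default_rng(2))
        agent = AgentState(p_unit=0.5, kappa=0.3, extraction_rate=1.0)
        update_agent(agent, observed, np.random.default_rng(3))
        # independent recurrence count over all length 2-4 substrings
        counts = Counter(
            s[i : i + k] for s in observed for k in (2, 3, 4)
            for i in range(len(s) - k + 1)
        )
        recurring = {c for c, n in counts.items() if n >= 2}
        assert set(agent.chunk_inventory) <= recurring


class TestChainRunners:
    def test_transmission_chain_shape_and_validity(self):
        config = SimConfig(condition=TRANSMISSION, generations=10)
        ds = run_transmission_chain(config, np.random.default_rng(0))
        assert len(ds) == 600  # 10 generations x 60 trials
        assert validate_dataset(ds).ok

    def test_individual_chain_shape_and_validity(self):
        config = SimConfig(condition=INDIVIDUAL, generations=10)
        ds = run_individual_chain(config, np.random.default_rng(0))
        assert len(ds) == 300  # 10 generations x 30 trials
        assert validate_dataset(ds).ok
        stim_ids = {r.stimulus_id for r in ds.records}
        assert len(stim_ids) == 30 and stim_ids <= set(range(1, 61))

    def test_condition_mismatch_rejected(self):
        with pytest.raises(ValueError):
            run_transmission_chain(
                SimConfig(condition=INDIVIDUAL), np.random.default_rng(0)
            )

    def test_experiment_is_seed_reproducible(self):
        a = simulate_experiment(2, 2, seed=9, generations=3)
        b = simulate_experiment(2, 2, seed=9, generations=3)
        assert a.records == b.records

    def test_randomized_order_changes_presentation(self):
        fixed = simulate_experiment(1, 0, seed=9, generations=2)
        rand = simulate_experiment(
            1, 0, seed=9, generations=2, presentation_order="randomized"
        )
        fixed_order = [r.stimulus_id for r in fixed.records if r.generation == 1]
        rand_order = [r.stimulus_id for r in rand.records if r.generation == 1]
        assert sorted(fixed_order) == sorted(rand_order)
        assert fixed_order != rand_order
        assert validate_dataset(rand).ok


class TestEmergentStructure:
    def test_accuracy_rises_and_chunk_learning_drives_compression(self):
        """Accuracy increases over generations, and switching chunk learning
        off (extraction and chunk bonus zero) abolishes the compression-ratio
        trend — the null control."""
        ds = simulate_experiment(4, 0, seed=17)
        mt = measure_table(ds, include_diversity=False)
        g = mt.groupby("generation")[["accuracy", "compression_ratio"]].mean()
        assert g.loc[10, "accuracy"] > g.loc[1, "accuracy"]
        drop = g.loc[1, "compression_ratio"] - g.loc[10, "compression_ratio"]
        assert drop > 0.02

        off = AgentHyperpriors(kappa_mean=0.0, kappa_sd=0.0, extraction_mean=1e-9)
        ds0 = simulate_experiment(4, 0, seed=17, hyperpriors=off)
        mt0 = measure_table(ds0, include_diversity=False)
        g0 = mt0.groupby("generation")["compression_ratio"].mean()
        assert abs(g0.loc[1] - g0.loc[10]) < 0.01


class TestBetaRegOracle:
    def test_deterministic_and_schema(self):
        a = generate_betareg_oracle(rng=np.random.default_rng(6))
        b = generate_betareg_oracle(rng=np.random.default_rng(6))
        assert a.equals(b)
        assert list(a.columns) == ["y", "condition", "generation", "chain", "stimulus"]
        assert ((a["y"] > 0) & (a["y"] < 1)).all()

    def test_zero_effects_center_on_logistic_intercept(self):
        tab = generate_betareg_oracle(
            n_chains=4, n_stimuli=4, generations=10,
            intercept=0.5, beta_condition=0.0, beta_generation=0.0,
            sd_chain=0.0, sd_stimulus=0.0, phi=50.0,
            rng=np.random.default_rng(7),
        )
        assert tab["y"].mean() == pytest.approx(1 / (1 + np.exp(-0.5)), abs=0.02)
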