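"""Agent-based generator of iterated-learning transmission chains.

The generator emulates the two-condition study design: color sequences of
length 12 over {r, g, b, y}, 10 generations per chain, 60 trials per
generation with a fresh participant each generation (transmission) or 30
trials per generation with one participant throughout (individual, 300
trials total).

The participant model is deliberately minimal: an agent carries a chunk
inventory (recurring 2–4-symbol substrings extracted from what it has seen)
and noisy unit-by-unit recall.  A stimulus is parsed greedily into the
longest known chunks; each parsed unit is reproduced faithfully with
probability ``p_unit`` plus a bonus ``kappa`` when the unit is a known
chunk, and replaced by a uniformly random same-length unit otherwise.
Chunkier sequences therefore parse into fewer, more reliable units and are
reproduced more accurately — the learnability pressure that drives chain
evolution.  The sole structural difference between conditions is whether
the agent (and its inventory) is replaced each generation or persists.

``generate_betareg_oracle`` is unrelated to the agents: it samples directly
from the multilevel beta-regression likelihood with known coefficients, as
ground truth for inference tests.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .sequences import (
    DEFAULT_ALPHABET,
    INDIVIDUAL,
    TRANSMISSION,
    ChainDataset,
    ChainMeta,
    SymbolString,
    TrialRecord,
)

__all__ = [
    "AgentState",
    "AgentHyperpriors",
    "SimConfig",
    "generate_seed_sequences",
    "sample_agent",
    "simulate_recall",
    "update_agent",
    "run_transmission_chain",
    "run_individual_chain",
    "simulate_experiment",
    "generate_betareg_oracle",
]

#: ceiling on per-unit recall probability, so recall is never error-free
MAX_UNIT_FIDELITY = 0.99


@dataclass
class AgentState:
    """One simulated participant.

    ``chunk_inventory`` maps substrings (length 2–4) to weights; recall of a
    parsed unit succeeds with probability ``min(p_unit + kappa * is_chunk,
    0.99)``.  ``extraction_rate`` is the per-exposure probability that a
    recurring substring is admitted to the inventory.
    """

    p_unit: float
    kappa: float
    extraction_rate: float
    intrusion_rate: float = 0.5
    chunk_inventory: dict[SymbolString, float] = field(default_factory=dict)
    inventory_cap: int = 8
    substring_counts: Counter = field(default_factory=Counter)

    def fidelity(self, unit: SymbolString) -> float:
        bonus = self.kappa if unit in self.chunk_inventory else 0.0
        return min(self.p_unit + bonus, MAX_UNIT_FIDELITY)


@dataclass(frozen=True)
class AgentHyperpriors:
    """Between-participant variation in the recall parameters.

    Defaults are the pinned calibration of the shipped generator: they were
    chosen so that, under the study design, the four directional phenomena
    hold (accuracy rises over generations; compression ratio falls — more
    under transmission; hierarchy depth rises — more under transmission;
    generation-10 diversity exceeds 0.5 in both conditions).
    """

    p_unit_mean: float = 0.5
    p_unit_kappa: float = 60.0  # beta concentration; higher = more similar agents
    kappa_mean: float = 0.35
    kappa_sd: float = 0.05
    extraction_mean: float = 0.5
    extraction_kappa: float = 12.0
    intrusion_mean: float = 0.5
    intrusion_kappa: float = 12.0
    inventory_cap: int = 8


@dataclass(frozen=True)
class SimConfig:
    """One simulated condition arm."""

    condition: int = TRANSMISSION
    n_chains: int = 10
    generations: int = 10
    sequence_length: int = 12
    alphabet: str = "rgby"
    presentation_order: str = "fixed"  # "fixed" (Exp1) or "randomized" (Exp2)
    hyperpriors: AgentHyperpriors = field(default_factory=AgentHyperpriors)
    experiment_id: str = "sim"

    @property
    def trials_per_generation(self) -> int:
        return 60 if self.condition == TRANSMISSION else 30

    @property
    def n_seed_sequences(self) -> int:
        # the individual condition draws its 30 seeds from the transmission
        # condition's pool of 60
        return 60


def generate_seed_sequences(
    n: int, length: int, alphabet: str, rng: np.random.Generator
) -> list[SymbolString]:
    """``n`` independent uniform-random sequences of exactly ``length``."""
    if n < 1 or length < 1:
        raise ValueError("n and length must be >= 1")
    letters = np.array(list(alphabet))
    picks = rng.integers(0, len(letters), size=(n, length))
    return ["".join(row) for row in letters[picks]]


def sample_agent(hyper: AgentHyperpriors, rng: np.random.Generator) -> AgentState:
    """Draw one participant from the population hyperpriors."""
    for name, v in (("p_unit_mean", hyper.p_unit_mean), ("extraction_mean", hyper.extraction_mean)):
        if not 0 < v < 1:
            raise ValueError(f"{name} must lie in (0, 1)")
    p_unit = rng.beta(
        hyper.p_unit_mean * hyper.p_unit_kappa,
        (1 - hyper.p_unit_mean) * hyper.p_unit_kappa,
    )
    kappa = max(0.0, rng.normal(hyper.kappa_mean, hyper.kappa_sd))
    extraction = rng.beta(
        hyper.extraction_mean * hyper.extraction_kappa,
        (1 - hyper.extraction_mean) * hyper.extraction_kappa,
    )
    intrusion = rng.beta(
        hyper.intrusion_mean * hyper.intrusion_kappa,
        (1 - hyper.intrusion_mean) * hyper.intrusion_kappa,
    )
    return AgentState(
        p_unit=float(np.clip(p_unit, 1e-3, MAX_UNIT_FIDELITY)),
        kappa=float(kappa),
        extraction_rate=float(extraction),
        intrusion_rate=float(intrusion),
        inventory_cap=hyper.inventory_cap,
    )


def _parse_units(agent: AgentState, s: SymbolString) -> list[SymbolString]:
    """Greedy left-to-right parse into longest known chunks, else singletons."""
    units = []
    i = 0
    while i < len(s):
        for k in (4, 3, 2):
            if s[i : i + k] in agent.chunk_inventory and i + k <= len(s):
                units.append(s[i : i + k])
                i += k
                break
        else:
            units.append(s[i])
            i += 1
    return units


def simulate_recall(
    agent: AgentState, stimulus: SymbolString, rng: np.random.Generator,
    alphabet: str = "rgby",
) -> SymbolString:
    """Noisy reproduction of one stimulus; output length equals input length.

    Each parsed unit is emitted verbatim with its fidelity probability.  A
    failed unit is filled in from the agent's chunk inventory (a
    pattern-completion intrusion, weight-proportional) with probability
    ``intrusion_rate``, otherwise replaced by uniform random symbols of the
    unit's length; the reproduction is finally trimmed or padded to the
    stimulus length, as the task forces exactly L taps.
    """
    L = len(stimulus)
    letters = list(alphabet)
    chunks = list(agent.chunk_inventory)
    weights = None
    if chunks:
        w = np.array([agent.chunk_inventory[c] for c in chunks], dtype=float)
        weights = w / w.sum()
    out: list[str] = []
    total = 0
    for unit in _parse_units(agent, stimulus):
        if total >= L:
            break
        if rng.uniform() < agent.fidelity(unit):
            piece = unit
        elif chunks and rng.uniform() < agent.intrusion_rate:
            piece = chunks[int(rng.choice(len(chunks), p=weights))]
        else:
            piece = "".join(letters[k] for k in rng.integers(0, len(letters), len(unit)))
        out.append(piece)
        total += len(piece)
    s = "".join(out)[:L]
    if len(s) < L:
        s += "".join(letters[k] for k in rng.integers(0, len(letters), L - len(s)))
    return s


def update_agent(
    agent: AgentState, observed: list[SymbolString], rng: np.random.Generator
) -> AgentState:
    """Accumulate substring statistics and (stochastically) extract chunks.

    All substrings of length 2–4 of the observed sequences are counted into
    the agent's running tally; substrings seen at least twice are candidate
    chunks, admitted with probability ``extraction_rate`` per update, and
    the inventory is capped at ``inventory_cap`` entries by weight (longer
    chunks win ties).  Mutates and returns the same agent.
    """
    for s in observed:
        for k in (2, 3, 4):
            for i in range(len(s) - k + 1):
                agent.substring_counts[s[i : i + k]] += 1
    # chance-corrected weight: under a uniform source a length-k substring is
    # 4^(k-2) times rarer than a digram, so recurring long substrings signal
    # genuine structure while ubiquitous digrams mostly signal chance
    recurring = [
        (w * 4.0 ** (len(c) - 2), len(c), c)
        for c, w in agent.substring_counts.items()
        if w >= 2
    ]
    recurring.sort(reverse=True)
    for w, _, chunk in recurring[: 4 * agent.inventory_cap]:
        if chunk in agent.chunk_inventory:
            agent.chunk_inventory[chunk] = float(w)
        elif rng.uniform() < agent.extraction_rate:
            agent.chunk_inventory[chunk] = float(w)
    if len(agent.chunk_inventory) > agent.inventory_cap:
        keep = sorted(
            agent.chunk_inventory.items(), key=lambda kv: (kv[1], len(kv[0]), kv[0])
        )[-agent.inventory_cap :]
        agent.chunk_inventory = dict(keep)
    return agent


def _presentation_order(
    config: SimConfig, n: int, participant_rng: np.random.Generator,
    fixed_order: np.ndarray,
) -> np.ndarray:
    if config.presentation_order == "randomized":
        return participant_rng.permutation(n)
    return fixed_order


def _run_chain(
    config: SimConfig,
    chain_id: int,
    seeds: list[SymbolString],
    stimulus_ids: list[int],
    rng: np.random.Generator,
    fixed_order: np.ndarray,
) -> list[TrialRecord]:
    """Common driver: one chain of ``generations`` participant-generations."""
    persistent = config.condition == INDIVIDUAL
    agent = sample_agent(config.hyperpriors, rng) if persistent else None
    lineage = list(seeds)
    records = []
    for gen in range(1, config.generations + 1):
        if not persistent:
            agent = sample_agent(config.hyperpriors, rng)
        order = _presentation_order(config, len(lineage), rng, fixed_order)
        reproduced: dict[int, SymbolString] = {}
        for trial, j in enumerate(order, start=1):
            stimulus = lineage[j]
            update_agent(agent, [stimulus], rng)
            resp = simulate_recall(agent, stimulus, rng, config.alphabet)
            reproduced[j] = resp
            records.append(
                TrialRecord(
                    experiment_id=config.experiment_id,
                    condition=config.condition,
                    chain_id=chain_id,
                    generation=gen,
                    trial_index=trial,
                    stimulus_id=stimulus_ids[j],
                    presented=stimulus,
                    reproduced=resp,
                )
            )
        lineage = [reproduced[j] for j in range(len(lineage))]
    return records


def run_transmission_chain(
    config: SimConfig, rng: np.random.Generator, chain_id: int = 1,
    seeds: list[SymbolString] | None = None,
) -> ChainDataset:
    """One transmission chain: a fresh participant each generation relearns
    the 60 sequences reproduced by the previous generation."""
    if config.condition != TRANSMISSION:
        raise ValueError("config.condition must be transmission")
    if seeds is None:
        seeds = generate_seed_sequences(
            config.n_seed_sequences, config.sequence_length, config.alphabet, rng
        )
    fixed_order = np.arange(len(seeds))
    records = _run_chain(
        config, chain_id, seeds, list(range(1, len(seeds) + 1)), rng, fixed_order
    )
    return ChainDataset(records, _meta(config))


def run_individual_chain(
    config: SimConfig, rng: np.random.Generator, chain_id: int = 1,
    seed_pool: list[SymbolString] | None = None,
) -> ChainDataset:
    """One individual-condition chain: the same participant relearns its own
    30 reproductions, generation after generation (300 trials)."""
    if config.condition != INDIVIDUAL:
        raise ValueError("config.condition must be individual")
    if seed_pool is None:
        seed_pool = generate_seed_sequences(
            config.n_seed_sequences, config.sequence_length, config.alphabet, rng
        )
    pick = rng.choice(len(seed_pool), size=config.trials_per_generation, replace=False)
    pick.sort()
    seeds = [seed_pool[i] for i in pick]
    stimulus_ids = [int(i) + 1 for i in pick]  # keep the shared lineage identity
    fixed_order = np.arange(len(seeds))
    records = _run_chain(config, chain_id, seeds, stimulus_ids, rng, fixed_order)
    return ChainDataset(records, _meta(config))


def _meta(config: SimConfig) -> ChainMeta:
    return ChainMeta(
        generations=config.generations,
        trials_per_generation=config.trials_per_generation,
        alphabet=frozenset(config.alphabet),
        sequence_length=config.sequence_length,
        presentation_order=config.presentation_order,
    )


def simulate_experiment(
    n_transmission_chains: int = 10,
    n_individual_chains: int = 20,
    seed: int = 0,
    generations: int = 10,
    presentation_order: str = "fixed",
    hyperpriors: AgentHyperpriors | None = None,
    experiment_id: str = "sim",
) -> ChainDataset:
    """Both condition arms of the study design in one trial table.

    All chains of both conditions share the same 60 seed sequences (each
    individual-condition participant receives a random 30 of them), as in
    the fixed-order design.  Everything derives from ``seed``.
    """
    hyper = hyperpriors or AgentHyperpriors()
    root = np.random.default_rng(np.random.SeedSequence(seed))
    base = SimConfig(
        generations=generations,
        presentation_order=presentation_order,
        hyperpriors=hyper,
        experiment_id=experiment_id,
    )
    seeds = generate_seed_sequences(
        base.n_seed_sequences, base.sequence_length, base.alphabet, root
    )
    tconf = replace(base, condition=TRANSMISSION)
    iconf = replace(base, condition=INDIVIDUAL)
    records: list[TrialRecord] = []
    for c in range(1, n_transmission_chains + 1):
        ds = run_transmission_chain(tconf, root.spawn(1)[0], chain_id=c, seeds=seeds)
        records.extend(ds.records)
    for c in range(1, n_individual_chains + 1):
        ds = run_individual_chain(iconf, root.spawn(1)[0], chain_id=c, seed_pool=seeds)
        records.extend(ds.records)
    return ChainDataset(records, _meta(tconf))


# ---------------------------------------------------------------------------
# direct beta-regression oracle (ground truth for inference tests)


def generate_betareg_oracle(
    n_chains: int = 6,
    n_stimuli: int = 10,
    generations: int = 10,
    *,
    intercept: float = 0.5,
    beta_condition: float = 0.3,
    beta_generation: float = 0.15,
    beta_interaction: float = 0.0,
    sd_chain: float = 0.3,
    sd_stimulus: float = 0.3,
    phi: float = 30.0,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sample a modeling table directly from the regression likelihood.

    Half the chains are assigned to each condition; every chain sees every
    stimulus lineage at every generation.  Columns match the output of
    :func:`iterlearn.inference.transform_response`.
    """
    chain_eff = rng.normal(0.0, sd_chain, size=n_chains)
    stim_eff = rng.normal(0.0, sd_stimulus, size=n_stimuli)
    condition_of_chain = (np.arange(n_chains) % 2).astype(float)
    rows = []
    for c in range(n_chains):
        for s in range(n_stimuli):
            for g in range(1, generations + 1):
                cond = condition_of_chain[c]
                eta = (
                    intercept
                    + beta_condition * cond
                    + beta_generation * g
                    + beta_interaction * cond * g
                    + chain_eff[c]
                    + stim_eff[s]
                )
                mu = 1.0 / (1.0 + np.exp(-eta))
                y = rng.beta(mu * phi, (1 - mu) * phi)
                rows.append((y, cond, float(g), c, s))
    return pd.DataFrame(
        rows, columns=["y", "condition", "generation", "chain", "stimulus"]
    )
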