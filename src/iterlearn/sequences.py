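"""Domain types and I/O for transmission-chain trial data.

A trial table is a tidy table of memorize-and-reproduce trials from an
iterated-learning ("Simon Game") experiment: per trial, a presented color
sequence and the participant's reproduction, keyed by condition, chain,
generation, trial index and the seed-lineage stimulus id.  Sequences are
strings over the four-symbol alphabet ``{r, g, b, y}`` (red, green, blue,
yellow), length 12 in the study design.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "DEFAULT_ALPHABET",
    "COLOR_CODES",
    "CSV_COLUMNS",
    "TRANSMISSION",
    "INDIVIDUAL",
    "SymbolString",
    "TrialRecord",
    "ChainMeta",
    "ChainDataset",
    "ValidationIssue",
    "ValidationReport",
    "encode_sequence",
    "is_valid_symbol_string",
    "read_chain_table",
    "write_chain_table",
    "validate_dataset",
    "load_deposited",
]

#: Single-letter codes for the four stimulus colors.
COLOR_CODES = {"red": "r", "green": "g", "blue": "b", "yellow": "y"}

DEFAULT_ALPHABET = frozenset("rgby")

#: Condition coding used throughout the models: 0 = transmission
#: (fresh participant each generation), 1 = individual (same participant).
TRANSMISSION = 0
INDIVIDUAL = 1

#: Canonical column order of the on-disk CSV schema.
CSV_COLUMNS = [
    "experiment_id",
    "condition",
    "chain_id",
    "generation",
    "trial_index",
    "stimulus_id",
    "presented",
    "reproduced",
]

# Sequences are plain Python strings over the alphabet; the alias documents
# intent at API boundaries.
SymbolString = str


class SequenceError(ValueError):
    """Raised for malformed sequences or trial tables."""


def encode_sequence(colors: Sequence[str]) -> SymbolString:
    """Convert a list of color names to a symbol string.

    ``["red", "green", "blue", "yellow"]`` becomes ``"rgby"``; order and
    length are preserved.  Color names are case-insensitive.

    Raises
    ------
    SequenceError
        If any entry is not one of red/green/blue/yellow; the message names
        the offending token and its (zero-based) position.
    """
    out = []
    for i, name in enumerate(colors):
        code = COLOR_CODES.get(str(name).strip().lower())
        if code is None:
            raise SequenceError(f"unknown color name {name!r} at position {i}")
        out.append(code)
    return "".join(out)


def is_valid_symbol_string(s: str, alphabet: frozenset[str] = DEFAULT_ALPHABET) -> bool:
    return all(ch in alphabet for ch in s)


@dataclass(frozen=True)
class TrialRecord:
    """One memorize-and-reproduce trial.

    ``stimulus_id`` identifies the seed lineage the presented sequence
    descends from (constant across generations within a chain); it is the
    "stimulus sequence number" random-intercept grouping unit of the
    regression models.
    """

    experiment_id: str
    condition: int  # 0 transmission, 1 individual
    chain_id: int
    generation: int
    trial_index: int
    stimulus_id: int
    presented: SymbolString
    reproduced: SymbolString


@dataclass(frozen=True)
class ChainMeta:
    """Design parameters of a trial table."""

    generations: int = 10
    trials_per_generation: int = 60
    alphabet: frozenset[str] = DEFAULT_ALPHABET
    sequence_length: int = 12
    presentation_order: str = "fixed"  # "fixed" or "randomized"


@dataclass
class ChainDataset:
    """A tidy trial table plus its design metadata."""

    records: list[TrialRecord]
    meta: ChainMeta = field(default_factory=ChainMeta)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Return the table as a DataFrame in canonical column order."""
        return pd.DataFrame(
            [
                (
                    r.experiment_id,
                    r.condition,
                    r.chain_id,
                    r.generation,
                    r.trial_index,
                    r.stimulus_id,
                    r.presented,
                    r.reproduced,
                )
                for r in self.records
            ],
            columns=CSV_COLUMNS,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, meta: ChainMeta | None = None) -> "ChainDataset":
        missing = [c for c in CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise SequenceError(f"missing column(s): {', '.join(missing)}")
        records = []
        for row_number, row in enumerate(frame.itertuples(index=False), start=1):
            try:
                rec = TrialRecord(
                    experiment_id=str(row.experiment_id),
                    condition=int(row.condition),
                    chain_id=int(row.chain_id),
                    generation=int(row.generation),
                    trial_index=int(row.trial_index),
                    stimulus_id=int(row.stimulus_id),
                    presented=str(row.presented),
                    reproduced=str(row.reproduced),
                )
            except (TypeError, ValueError) as exc:
                raise SequenceError(f"row {row_number}: {exc}") from exc
            for col in ("presented", "reproduced"):
                s = getattr(rec, col)
                if not is_valid_symbol_string(s):
                    bad = sorted(set(s) - DEFAULT_ALPHABET)
                    raise SequenceError(
                        f"row {row_number}: {col} contains symbol(s) {bad} "
                        f"outside alphabet rgby"
                    )
            records.append(rec)
        if meta is None:
            meta = _infer_meta(records)
        return cls(records, meta)

    def append(self, other: "ChainDataset") -> "ChainDataset":
        """Concatenate two tables (metadata taken from ``self``)."""
        return ChainDataset(self.records + other.records, self.meta)


def _infer_meta(records: list[TrialRecord]) -> ChainMeta:
    if not records:
        return ChainMeta()
    return ChainMeta(
        generations=max(r.generation for r in records),
        trials_per_generation=max(r.trial_index for r in records),
        sequence_length=max(len(r.presented) for r in records),
    )


def read_chain_table(path: str | Path) -> ChainDataset:
    """Read a trial table CSV (schema in :data:`CSV_COLUMNS`).

    Round-trips with :func:`write_chain_table` byte-identically modulo line
    endings.  Malformed rows raise :class:`SequenceError` naming the row.
    """
    frame = pd.read_csv(
        path,
        dtype={"experiment_id": str, "presented": str, "reproduced": str},
        keep_default_na=False,
    )
    # empty-string sequences read back as "" rather than NaN via keep_default_na
    return ChainDataset.from_frame(frame)


def write_chain_table(dataset: ChainDataset, path: str | Path) -> None:
    """Write a trial table CSV with deterministic column order and formatting."""
    dataset.to_frame().to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class ValidationIssue:
    locator: str  # e.g. "exp1/cond0/chain3/gen2/trial15"
    rule: str  # "alphabet" | "length" | "trial_index" | "lineage"
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue]

    @property
    def ok(self) -> bool:
        return not self.issues


def _locator(r: TrialRecord) -> str:
    return (
        f"{r.experiment_id}/cond{r.condition}/chain{r.chain_id}"
        f"/gen{r.generation}/trial{r.trial_index}"
    )


def validate_dataset(dataset: ChainDataset) -> ValidationReport:
    """Check the structural invariants of a trial table.

    Reports *all* violations of: symbol alphabet, sequence length,
    trial-index completeness within each participant-generation, and the
    lineage invariant — the sequence presented at generation g > 1 must equal
    the reproduction of the same stimulus lineage at generation g - 1 in the
    same chain.  Order-independent: shuffling records does not change the
    outcome.
    """
    issues: list[ValidationIssue] = []
    meta = dataset.meta

    for r in dataset.records:
        for col in ("presented", "reproduced"):
            s = getattr(r, col)
            if not is_valid_symbol_string(s, meta.alphabet):
                issues.append(
                    ValidationIssue(
                        _locator(r),
                        "alphabet",
                        f"{col} has symbols outside {''.join(sorted(meta.alphabet))}",
                    )
                )
            if len(s) != meta.sequence_length:
                issues.append(
                    ValidationIssue(
                        _locator(r),
                        "length",
                        f"{col} has length {len(s)}, expected {meta.sequence_length}",
                    )
                )

    # trial-index completeness per participant-generation
    by_pg: dict[tuple, list[TrialRecord]] = {}
    for r in dataset.records:
        by_pg.setdefault(
            (r.experiment_id, r.condition, r.chain_id, r.generation), []
        ).append(r)
    for (exp, cond, chain, gen), recs in sorted(by_pg.items()):
        idx = sorted(r.trial_index for r in recs)
        expected = list(range(1, len(recs) + 1))
        if idx != expected:
            issues.append(
                ValidationIssue(
                    f"{exp}/cond{cond}/chain{chain}/gen{gen}",
                    "trial_index",
                    f"trial indices {idx} are not 1..{len(recs)} without gaps/duplicates",
                )
            )

    # lineage: presented at g equals reproduced at g-1 for the same stimulus
    by_lineage: dict[tuple, dict[int, TrialRecord]] = {}
    for r in dataset.records:
        key = (r.experiment_id, r.condition, r.chain_id, r.stimulus_id)
        gens = by_lineage.setdefault(key, {})
        if r.generation in gens:
            issues.append(
                ValidationIssue(
                    _locator(r),
                    "lineage",
                    f"duplicate record for stimulus {r.stimulus_id} at generation {r.generation}",
                )
            )
        else:
            gens[r.generation] = r
    for key, gens in sorted(by_lineage.items()):
        for g, r in sorted(gens.items()):
            if g <= 1:
                continue
            prev = gens.get(g - 1)
            if prev is None:
                issues.append(
                    ValidationIssue(
                        _locator(r),
                        "lineage",
                        f"no generation {g - 1} record for stimulus {r.stimulus_id}",
                    )
                )
            elif prev.reproduced != r.presented:
                issues.append(
                    ValidationIssue(
                        _locator(r),
                        "lineage",
                        f"presented at generation {g} differs from the "
                        f"generation {g - 1} reproduction of stimulus {r.stimulus_id}",
                    )
                )

    return ValidationReport(issues)


# ---------------------------------------------------------------------------
# loader for a local clone of the deposited experiment data

_COLUMN_ALIASES = {
    "experiment_id": ("experiment_id", "experiment", "exp"),
    "condition": ("condition", "cond"),
    "chain_id": ("chain_id", "chain", "chain_number"),
    "generation": ("generation", "gen"),
    "trial_index": ("trial_index", "trial", "trial_number"),
    "stimulus_id": ("stimulus_id", "stimulus", "stimulus_number", "seq_id"),
    "presented": ("presented", "stimulus_sequence", "presented_sequence", "target"),
    "reproduced": ("reproduced", "reproduced_sequence", "response", "answer"),
}


def load_deposited(path: str | Path, experiment_id: str = "exp1") -> ChainDataset:
    """Load a local clone of the study's deposited trial data.

    Maps CSV files with recognizable column names onto the canonical schema.
    Ambiguities (several candidate columns, none, or unparseable sequences)
    raise :class:`SequenceError` rather than being silently guessed.
    """
    path = Path(path)
    files = sorted(path.rglob("*.csv")) if path.is_dir() else [path]
    if not files:
        raise SequenceError(f"no CSV files under {path}")
    frames = []
    for f in files:
        raw = pd.read_csv(f, keep_default_na=False)
        lower = {re.sub(r"\W+", "_", c.strip().lower()): c for c in raw.columns}
        mapping = {}
        for canon, aliases in _COLUMN_ALIASES.items():
            hits = [lower[a] for a in aliases if a in lower]
            if len(hits) > 1:
                raise SequenceError(f"{f}: ambiguous columns {hits} for {canon!r}")
            if hits:
                mapping[canon] = hits[0]
        required = set(CSV_COLUMNS) - {"experiment_id"}
        missing = required - set(mapping)
        if missing:
            raise SequenceError(f"{f}: could not locate column(s) {sorted(missing)}")
        out = pd.DataFrame({canon: raw[src] for canon, src in mapping.items()})
        if "experiment_id" not in out.columns:
            out["experiment_id"] = experiment_id
        frames.append(out[CSV_COLUMNS])
    return ChainDataset.from_frame(pd.concat(frames, ignore_index=True))
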