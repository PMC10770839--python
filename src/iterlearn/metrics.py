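"""The four sequence measures: accuracy, compression ratio, hierarchy depth,
and chain diversity.

* ``accuracy`` — 1 minus the Levenshtein distance normalized by the longer
  string's length; 1.0 for a perfect reproduction.
* ``compression_ratio`` — compressed/uncompressed byte ratio under DEFLATE;
  smaller means more redundant, non-random structure.
* ``grammar depth`` — longest chain of nested Sequitur rules (see
  :mod:`iterlearn.sequitur`).
* ``diversity`` — within-chain similarity relative to within- plus
  across-chain similarity; values above 0.5 mean chains have diverged.

``measure_table`` evaluates all four per trial row for downstream modeling.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

from .sequences import ChainDataset, SymbolString
from .sequitur import grammar_depth, induce_grammar

__all__ = [
    "edit_distance",
    "accuracy",
    "compression_ratio",
    "sequence_depth",
    "DiversityResult",
    "diversity",
    "measure_table",
    "DEFAULT_COMPRESSION_LEVEL",
]

#: DEFLATE level pinned for reproducibility (maximum compression).
DEFAULT_COMPRESSION_LEVEL = 9


def edit_distance(a: SymbolString, b: SymbolString) -> int:
    """Unit-cost Levenshtein distance (insertions, deletions, substitutions).

    Symmetric, zero iff the strings are equal, bounded by ``max(|a|, |b|)``,
    and satisfies the triangle inequality.
    """
    if not a or not b:  # edlib requires non-empty queries
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def accuracy(presented: SymbolString, reproduced: SymbolString) -> float:
    """1 minus the edit distance normalized by the longer string's length.

    Equals 1.0 iff the reproduction matches the presented sequence exactly;
    0.0 when every position needs an edit.
    """
    m = max(len(presented), len(reproduced))
    if m == 0:
        raise ValueError("accuracy is undefined for two empty strings")
    return 1.0 - edit_distance(presented, reproduced) / m


def compression_ratio(
    texts: Sequence[SymbolString] | SymbolString,
    mode: str = "per_generation_concat",
    level: int = DEFAULT_COMPRESSION_LEVEL,
) -> float:
    """Compressed/uncompressed byte-size ratio of serialized sequences.

    ``per_generation_concat`` (default): the sequences are serialized one per
    line (LF separated, trailing LF) and compressed as one zlib stream; the
    intended unit is one participant-generation's reproductions.
    ``per_sequence_raw_stream``: a single sequence compressed as a raw
    DEFLATE stream with no container header or trailer, for sensitivity
    analysis on very short inputs.

    Deterministic for fixed input, mode and level.
    """
    if isinstance(texts, str):
        texts = [texts]
    if not texts or any(len(t) == 0 for t in texts):
        raise ValueError("compression ratio requires non-empty sequences")
    if mode == "per_generation_concat":
        payload = ("\n".join(texts) + "\n").encode("ascii")
        compressed = zlib.compress(payload, level)
    elif mode == "per_sequence_raw_stream":
        if len(texts) != 1:
            raise ValueError("per_sequence_raw_stream takes exactly one sequence")
        payload = texts[0].encode("ascii")
        comp = zlib.compressobj(level, zlib.DEFLATED, -zlib.MAX_WBITS)
        compressed = comp.compress(payload) + comp.flush()
    else:
        raise ValueError(f"unknown compression mode {mode!r}")
    return len(compressed) / len(payload)


def sequence_depth(s: SymbolString) -> int:
    """Sequitur hierarchy depth of one sequence."""
    return grammar_depth(induce_grammar(s))


@dataclass(frozen=True)
class DiversityResult:
    value: float
    within: float
    across: float


def diversity(
    dataset: ChainDataset, chain_id: int, generation: int, condition: int | None = None
) -> DiversityResult:
    """Chain divergence of one participant-generation's reproductions.

    ``within`` is the mean pairwise similarity (the accuracy measure) among
    the focal participant-generation's reproduced sequences (unordered
    pairs, no self-pairs); ``across`` is the mean similarity between those
    sequences and the reproductions of every other chain of the same
    condition at the same generation.  The statistic is
    ``within / (within + across)``: above 0.5 when a chain resembles itself
    more than it resembles its contemporaries.
    """
    recs = [r for r in dataset.records if r.generation == generation]
    if condition is not None:
        recs = [r for r in recs if r.condition == condition]
    focal = [r.reproduced for r in recs if r.chain_id == chain_id]
    others = [r.reproduced for r in recs if r.chain_id != chain_id]
    if not focal:
        raise ValueError(f"no records for chain {chain_id} at generation {generation}")
    if not others:
        raise ValueError("diversity requires at least two chains at the generation")
    within_pairs = [accuracy(a, b) for a, b in combinations(focal, 2)]
    if not within_pairs:
        raise ValueError("diversity requires >= 2 focal sequences")
    within = sum(within_pairs) / len(within_pairs)
    across = sum(accuracy(a, b) for a in focal for b in others) / (
        len(focal) * len(others)
    )
    total = within + across
    if total == 0:
        raise ValueError("diversity undefined: within + across similarity is 0")
    return DiversityResult(within / total, within, across)


def measure_table(
    dataset: ChainDataset,
    compression_mode: str = "per_generation_concat",
    compression_level: int = DEFAULT_COMPRESSION_LEVEL,
    include_diversity: bool = True,
) -> pd.DataFrame:
    """Per-trial measure rows: the trial table plus the four measures.

    Accuracy and depth are per trial.  The compression ratio is computed on
    the participant-generation's reproductions serialized one per line and
    attributed to each member row.  Diversity is likewise computed per
    participant-generation (it needs the other chains of the same condition
    and generation) and replicated across that participant's rows; it is
    left as NaN when a condition has a single chain.
    """
    frame = dataset.to_frame()
    frame["accuracy"] = [
        accuracy(r.presented, r.reproduced) for r in dataset.records
    ]
    # sequitur is deterministic per string: dedupe before inducing
    depth_of = {s: sequence_depth(s) for s in set(frame["reproduced"])}
    frame["depth"] = frame["reproduced"].map(depth_of)

    group_cols = ["experiment_id", "condition", "chain_id", "generation"]
    if compression_mode == "per_generation_concat":
        frame["compression_ratio"] = frame.groupby(group_cols, sort=False)[
            "reproduced"
        ].transform(
            lambda col: compression_ratio(list(col), mode=compression_mode, level=compression_level)
        )
    else:
        ratio_of = {
            s: compression_ratio([s], mode=compression_mode, level=compression_level)
            for s in set(frame["reproduced"])
        }
        frame["compression_ratio"] = frame["reproduced"].map(ratio_of)

    if include_diversity:
        frame["diversity"] = _diversity_column(frame)
    return frame


def _similarity_matrix(uniq: list[str]) -> "np.ndarray":
    m = np.ones((len(uniq), len(uniq)))
    for i, j in combinations(range(len(uniq)), 2):
        m[i, j] = m[j, i] = accuracy(uniq[i], uniq[j])
    return m


def _diversity_column(frame: pd.DataFrame) -> pd.Series:
    """Participant-generation diversity replicated across its rows.

    Equivalent to calling :func:`diversity` per (chain, generation) but
    evaluated on a deduplicated similarity matrix, which matters once late
    generations converge on a few repeated sequences.
    """
    out = pd.Series(float("nan"), index=frame.index)
    for (_, _, _), grp in frame.groupby(
        ["experiment_id", "condition", "generation"], sort=False
    ):
        chain_ids = grp["chain_id"].unique()
        if len(chain_ids) < 2:
            continue
        uniq = sorted(set(grp["reproduced"]))
        pos = {s: k for k, s in enumerate(uniq)}
        sim = _similarity_matrix(uniq)
        idx = grp["reproduced"].map(pos).to_numpy()
        counts = {
            c: np.bincount(idx[(grp["chain_id"] == c).to_numpy()], minlength=len(uniq))
            for c in chain_ids
        }
        total = sum(counts.values())
        for c in chain_ids:
            cf = counts[c]
            n_f = int(cf.sum())
            if n_f < 2:
                continue
            co = total - cf
            n_o = int(co.sum())
            within = (cf @ sim @ cf - n_f) / (n_f * (n_f - 1))
            across = (cf @ sim @ co) / (n_f * n_o)
            rows = grp.index[(grp["chain_id"] == c).to_numpy()]
            out.loc[rows] = within / (within + across)
    return out
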