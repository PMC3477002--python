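"""Nearest-neighbor separability scores and the configuration-grid runner.

The framework asks: under a given encoding (word length ``n``, similarity
measure ``s``), how separable are the taxonomic classes of a labeled
sequence pool at a rank ``t``?  Two scores answer it, both in [0, 1]:

*Conventional score* — the fraction of sequences whose single nearest
neighbor in the whole pool shares their taxon at level ``t``.  Sequences
that are the only representative of their class at ``t`` are excluded
(their neighbor is necessarily wrong-class, which would bias the score
downward).

*Hierarchical score* — models a tree of per-clade classifiers.  At the
domain it equals the conventional score.  Deeper, each sequence's
neighbor pool is first pruned to the sequences sharing its class one
level above; the per-level match fraction is multiplied by the
hierarchical score one level above, giving a recursive product of
per-level fractions.

A *configuration* is one point (dataset, level, n, measure, score mode)
of the score function; :func:`run_grid` evaluates a full cartesian grid
of configurations and returns a long-format table.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .kmer import FrequencyVector, encode
from .similarity import Measure
from .taxonomy import LabeledDataset, SequenceRecord, TaxonLevel, class_key

__all__ = [
    "Configuration",
    "ScoreResult",
    "EncodedPool",
    "encode_pool",
    "distance_matrix",
    "nearest_neighbor",
    "conventional_score",
    "hierarchical_score",
    "run_grid",
    "ScoreMode",
]

logger = logging.getLogger(__name__)

_MEASURE_KIND = {
    Measure.ONE_NORM: _kernels.KIND_L1,
    Measure.TWO_NORM: _kernels.KIND_L2,
    Measure.INF_NORM: _kernels.KIND_LINF,
    Measure.KL: _kernels.KIND_KL,
}

#: Score modes A = {conventional, hierarchical}.
ScoreMode = ("conventional", "hierarchical")


@dataclass(frozen=True)
class Configuration:
    """One grid cell: (dataset, taxon level, word length, measure, score mode)."""

    dataset_id: str
    level: TaxonLevel
    n: int
    measure: Measure
    score_measure: str  # "conventional" | "hierarchical"

    def __post_init__(self):
        if self.score_measure not in ScoreMode:
            raise ValueError(f"score_measure must be one of {ScoreMode}")


@dataclass(frozen=True)
class ScoreResult:
    """Outcome of one configuration.

    ``score`` is ``None`` when the configuration is undefined (no
    sequence was scorable at some contributing level, reported in
    ``undefined_level``).  For hierarchical runs ``level_factors`` holds
    the per-level match fractions, domain first; their product is the
    score.  ``m`` is the number of sequences scored at the target level.
    """

    config: Configuration
    score: float | None
    m: int
    level_factors: tuple[float | None, ...] | None = None
    undefined_level: TaxonLevel | None = None

    @property
    def defined(self) -> bool:
        return self.score is not None


class InsufficientPoolError(ValueError):
    """Nearest-neighbor search needs at least one candidate besides the query."""


@dataclass
class EncodedPool:
    """A pool's frequency vectors packed into CSR arrays for the kernels."""

    ids: list[str]
    indptr: np.ndarray
    indices: np.ndarray
    data: np.ndarray
    zero_values: np.ndarray
    n: int
    dim: int
    smoothed: bool

    @classmethod
    def from_vectors(cls, ids: Sequence[str], vectors: Sequence[FrequencyVector]) -> "EncodedPool":
        n = vectors[0].n
        indptr = np.zeros(len(vectors) + 1, dtype=np.int64)
        np.cumsum([v.indices.size for v in vectors], out=indptr[1:])
        return cls(
            ids=list(ids),
            indptr=indptr,
            indices=np.concatenate([v.indices for v in vectors]) if vectors else np.empty(0, np.int64),
            data=np.concatenate([v.values for v in vectors]),
            zero_values=np.array([v.zero_value for v in vectors]),
            n=n,
            dim=4 ** n,
            smoothed=vectors[0].smoothed,
        )

    def vector(self, i: int) -> FrequencyVector:
        sl = slice(self.indptr[i], self.indptr[i + 1])
        return FrequencyVector(
            n=self.n,
            indices=self.indices[sl],
            values=self.data[sl],
            smoothed=self.smoothed,
            zero_value=float(self.zero_values[i]),
        )


def encode_pool(pool: LabeledDataset, n: int, smoothed: bool) -> EncodedPool:
    """Encode every record of ``pool`` at word length ``n``; cached on the pool."""
    key = (n, smoothed)
    cached = pool.encoded.get(key)
    if cached is None:
        cached = EncodedPool.from_vectors(
            pool.ids(), [encode(r.sequence, n, smoothed) for r in pool]
        )
        pool.encoded[key] = cached
    return cached


def distance_matrix(pool: LabeledDataset, n: int, measure: Measure | str) -> np.ndarray:
    """All-pairs dissimilarity matrix for ``pool`` under (n, measure).

    KL cells use add-one-smoothed encodings (row = query), the norms use
    plain normalized frequencies.  The diagonal is 0; nearest-neighbor
    search always excludes the query itself.
    """
    measure = Measure.coerce(measure)
    enc = encode_pool(pool, n, smoothed=measure.needs_smoothing)
    return _kernels.pairwise_matrix(
        enc.indptr, enc.indices, enc.data, enc.zero_values, enc.dim, _MEASURE_KIND[measure]
    )


def _id_ranks(ids: Sequence[str]) -> np.ndarray:
    """rank[i] = position of ids[i] in lexicographic order (for tie-breaks)."""
    order = np.argsort(np.asarray(ids, dtype=object), kind="stable")
    ranks = np.empty(len(ids), dtype=np.int64)
    ranks[order] = np.arange(len(ids))
    return ranks


def _argmin_with_ties(row: np.ndarray, candidates: np.ndarray, id_ranks: np.ndarray) -> int:
    """Index of the minimum of ``row[candidates]``; bit-equal ties go to the
    lexicographically smallest record ID."""
    vals = row[candidates]
    best = vals.min()
    tied = candidates[vals == best]
    if tied.size == 1:
        return int(tied[0])
    return int(tied[np.argmin(id_ranks[tied])])


def _nn_indices(
    D: np.ndarray,
    ids: Sequence[str],
    records: Sequence[SequenceRecord],
    exclude_same_source: bool,
) -> np.ndarray:
    """Nearest neighbor of every row, self excluded; -1 if no candidate."""
    m = D.shape[0]
    ranks = _id_ranks(ids)
    nn = np.full(m, -1, dtype=np.int64)
    all_idx = np.arange(m)
    for i in range(m):
        mask = all_idx != i
        if exclude_same_source and records[i].source_id is not None:
            mask &= np.array([r.source_id != records[i].source_id for r in records])
        cands = all_idx[mask]
        if cands.size:
            nn[i] = _argmin_with_ties(D[i], cands, ranks)
    return nn


def nearest_neighbor(
    query: SequenceRecord,
    pool: LabeledDataset,
    n: int,
    measure: Measure | str,
    exclude_same_source: bool = False,
) -> str:
    """ID of the pool record (≠ query) closest to ``query`` under (n, measure).

    Ties at bit-equal distance go to the lexicographically smallest ID.
    """
    if len(pool) <= 1:
        raise InsufficientPoolError("nearest-neighbor search needs a pool of ≥ 2 records")
    qi = pool.ids().index(query.id)
    D = distance_matrix(pool, n, Measure.coerce(measure))
    nn = _nn_indices(D, pool.ids(), pool.records, exclude_same_source)
    if nn[qi] < 0:
        raise InsufficientPoolError("no eligible neighbor for query")
    return pool.ids()[nn[qi]]


def _conventional(
    pool: LabeledDataset,
    level: TaxonLevel,
    nn: np.ndarray,
    prefix: bool,
) -> tuple[float | None, int]:
    """Match fraction at ``level`` given precomputed nearest neighbors."""
    keys = [class_key(r, level, prefix) for r in pool.records]
    sizes = Counter(keys)
    m = 0
    hits = 0
    for i in range(len(keys)):
        if sizes[keys[i]] < 2:  # unique representative: skip
            continue
        if nn[i] < 0:
            continue
        m += 1
        if keys[nn[i]] == keys[i]:
            hits += 1
    return (hits / m if m else None), m


def conventional_score(
    pool: LabeledDataset,
    level: TaxonLevel | str | int,
    n: int,
    measure: Measure | str,
    D: np.ndarray | None = None,
    exclude_same_source: bool = False,
    prefix: bool = False,
) -> ScoreResult:
    """Fraction of sequences whose nearest neighbor shares their taxon at ``level``.

    Sequences that are the sole representative of their class at ``level``
    are not scored (do not contribute to ``m``).  Returns an undefined
    result when nothing is scorable.
    """
    level = TaxonLevel.coerce(level)
    measure = Measure.coerce(measure)
    if D is None:
        D = distance_matrix(pool, n, measure)
    nn = _nn_indices(D, pool.ids(), pool.records, exclude_same_source)
    score, m = _conventional(pool, level, nn, prefix)
    cfg = Configuration(pool.dataset_id, level, n, measure, "conventional")
    return ScoreResult(
        config=cfg,
        score=score,
        m=m,
        undefined_level=level if score is None else None,
    )


def _level_factor(
    pool: LabeledDataset,
    level: TaxonLevel,
    D: np.ndarray,
    ranks: np.ndarray,
    exclude_same_source: bool,
    prefix: bool,
) -> tuple[float | None, int]:
    """One hierarchical level above domain: prune to the class at ``level - 1``,
    then score nearest neighbors within each pruned group."""
    records = pool.records
    groups: dict = {}
    for i, r in enumerate(records):
        groups.setdefault(class_key(r, level - 1, prefix), []).append(i)

    m = 0
    hits = 0
    all_local = None
    for idx in groups.values():
        if len(idx) <= 1:  # |d'| > 1 required
            continue
        idx_arr = np.array(idx, dtype=np.int64)
        keys_t = [class_key(records[i], level, prefix) for i in idx]
        sizes = Counter(keys_t)
        sub = D[np.ix_(idx_arr, idx_arr)]
        local = np.arange(len(idx))
        for li, i in enumerate(idx):
            if sizes[keys_t[li]] < 2:  # unique representative within d'
                continue
            mask = local != li
            if exclude_same_source and records[i].source_id is not None:
                mask &= np.array(
                    [records[idx[lj]].source_id != records[i].source_id for lj in local]
                )
            cands = local[mask]
            if cands.size == 0:
                continue
            m += 1
            j = _argmin_with_ties(sub[li], cands, ranks[idx_arr])
            if keys_t[j] == keys_t[li]:
                hits += 1
    return (hits / m if m else None), m


def _hierarchical_factors(
    pool: LabeledDataset,
    level: TaxonLevel,
    D: np.ndarray,
    exclude_same_source: bool,
    prefix: bool,
) -> list[tuple[float | None, int]]:
    """Per-level (fraction, m) for levels domain..``level``; the recursion is
    pool-level, so lower levels are computed once, not once per record."""
    ranks = _id_ranks(pool.ids())
    nn = _nn_indices(D, pool.ids(), pool.records, exclude_same_source)
    factors: list[tuple[float | None, int]] = [
        _conventional(pool, TaxonLevel.DOMAIN, nn, prefix)
    ]
    for t in range(2, int(level) + 1):
        factors.append(
            _level_factor(pool, TaxonLevel(t), D, ranks, exclude_same_source, prefix)
        )
    return factors


def hierarchical_score(
    pool: LabeledDataset,
    level: TaxonLevel | str | int,
    n: int,
    measure: Measure | str,
    D: np.ndarray | None = None,
    exclude_same_source: bool = False,
    prefix: bool = False,
) -> ScoreResult:
    """Recursive product of per-level nearest-neighbor match fractions.

    At the domain this is exactly the conventional score.  Deeper, the
    neighbor pool of each sequence is pruned to the sequences sharing its
    class one level above before the nearest neighbor is sought; the
    level's match fraction multiplies the hierarchical score one level
    above.  Undefined when any contributing level scores no sequence.
    """
    level = TaxonLevel.coerce(level)
    measure = Measure.coerce(measure)
    if D is None:
        D = distance_matrix(pool, n, measure)
    factors = _hierarchical_factors(pool, level, D, exclude_same_source, prefix)
    cfg = Configuration(pool.dataset_id, level, n, measure, "hierarchical")
    return _assemble_hierarchical(cfg, factors)


def _assemble_hierarchical(
    cfg: Configuration, factors: list[tuple[float | None, int]]
) -> ScoreResult:
    fracs = tuple(f for f, _ in factors)
    m_top = factors[-1][1]
    undefined = next(
        (TaxonLevel(t + 1) for t, f in enumerate(fracs) if f is None), None
    )
    score = None
    if undefined is None:
        score = float(np.prod(fracs))
    return ScoreResult(
        config=cfg,
        score=score,
        m=m_top,
        level_factors=fracs,
        undefined_level=undefined,
    )


def run_grid(
    dataset: LabeledDataset,
    levels: Iterable[TaxonLevel | str | int],
    N_set: Iterable[int],
    S_set: Iterable[Measure | str],
    A_set: Iterable[str] = ScoreMode,
    exclude_same_source: bool = False,
    prefix: bool = False,
    progress: bool = False,
) -> pd.DataFrame:
    """Evaluate every configuration (t, n, s, a) on ``dataset``.

    Returns a long-format table with one row per cell and columns
    ``dataset level n measure score_measure score m defined
    level_factors`` (level_factors comma-joined, empty for conventional
    cells).  Undefined cells are recorded, not fatal.  Encodings are
    cached per (n, smoothing); the distance matrix for each (n, s) is
    computed once and shared by all levels and both score modes.
    """
    levels = [TaxonLevel.coerce(t) for t in levels]
    N_set = sorted(set(int(n) for n in N_set))
    S_set = [Measure.coerce(s) for s in S_set]
    A_set = list(A_set)
    if not levels or not N_set or not S_set or not A_set:
        raise ValueError("all configuration axes must be non-empty")
    for a in A_set:
        if a not in ScoreMode:
            raise ValueError(f"unknown score measure {a!r}")

    rows = []
    deepest = max(levels)
    for n in N_set:
        for s in S_set:
            if progress:
                logger.info("grid: n=%d measure=%s", n, s.value)
            D = distance_matrix(dataset, n, s)
            nn = _nn_indices(D, dataset.ids(), dataset.records, exclude_same_source)
            factors = None
            if "hierarchical" in A_set:
                factors = _hierarchical_factors(
                    dataset, deepest, D, exclude_same_source, prefix
                )
            for t in levels:
                for a in A_set:
                    cfg = Configuration(dataset.dataset_id, t, n, s, a)
                    if a == "conventional":
                        score, m = _conventional(dataset, t, nn, prefix)
                        res = ScoreResult(
                            cfg, score, m, undefined_level=t if score is None else None
                        )
                    else:
                        res = _assemble_hierarchical(cfg, factors[: int(t)])
                    rows.append(res)
        dataset.encoded.clear()  # keep memory flat across the n sweep

    return results_table(rows)


def results_table(results: Iterable[ScoreResult]) -> pd.DataFrame:
    """Long-format results table (one row per ScoreResult)."""
    rows = []
    for r in results:
        lf = ""
        if r.level_factors is not None:
            lf = ",".join("" if f is None else f"{f:.10g}" for f in r.level_factors)
        rows.append(
            {
                "dataset": r.config.dataset_id,
                "level": r.config.level.name.lower(),
                "n": r.config.n,
                "measure": r.config.measure.value,
                "score_measure": r.config.score_measure,
                "score": np.nan if r.score is None else r.score,
                "m": r.m,
                "defined": r.defined,
                "level_factors": lf,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "dataset", "level", "n", "measure", "score_measure",
            "score", "m", "defined", "level_factors",
        ],
    )
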