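"""Seven-level taxonomic lineages and the labeled sequence datasets they annotate.

A lineage is an ordered vector of seven taxon identifiers — one per rank
from domain down to species — emulating the NCBI taxid vectors used to
label microbial genomes.  Records with an incomplete lineage are dropped
at load time (dataset curation happens once, not at scoring time).

Class identity at a level compares the single slot at that level, which
is correct for globally unique identifiers such as NCBI taxids.  For
identifier schemes where names repeat across clades, the membership
helpers accept ``prefix=True`` to compare the full lineage prefix
instead.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "TaxonLevel",
    "Lineage",
    "SequenceRecord",
    "LabeledDataset",
    "class_at",
    "class_key",
    "is_unique_representative",
    "subset_same_class",
    "load_lineages",
]

logger = logging.getLogger(__name__)

#: Lineage slot count (domain .. species).
N_LEVELS = 7


class TaxonLevel(enum.IntEnum):
    """Taxonomic ranks, ordered root-to-leaf; ``DOMAIN == 1``."""

    DOMAIN = 1
    PHYLUM = 2
    CLASS = 3
    ORDER = 4
    FAMILY = 5
    GENUS = 6
    SPECIES = 7

    @classmethod
    def coerce(cls, value: "TaxonLevel | str | int") -> "TaxonLevel":
        if isinstance(value, cls):
            return value
        if isinstance(value, int):
            return cls(value)
        return cls[str(value).upper()]


#: A complete lineage: exactly seven non-empty identifiers, domain→species.
Lineage = tuple[str, ...]


def _validate_lineage(lineage: Iterable[str]) -> Lineage:
    lin = tuple(str(t) for t in lineage)
    if len(lin) != N_LEVELS or any(not t for t in lin):
        raise ValueError(f"lineage must have {N_LEVELS} non-empty slots, got {lin!r}")
    return lin


@dataclass(frozen=True)
class SequenceRecord:
    """One labeled nucleotide sequence.

    ``source_id`` records the genome a simulated fragment was sampled
    from (``None`` for primary sequences); nearest-neighbor search can
    optionally exclude same-source candidates.
    """

    id: str
    sequence: str
    lineage: Lineage
    source_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "lineage", _validate_lineage(self.lineage))


def class_at(record: SequenceRecord, level: TaxonLevel | str | int) -> str:
    """The record's taxon identifier at ``level`` (Algorithm: class(d_i) at t)."""
    return record.lineage[TaxonLevel.coerce(level) - 1]


def class_key(record: SequenceRecord, level: TaxonLevel | str | int, prefix: bool = False):
    """Hashable class identity at ``level``.

    With ``prefix=True`` the identity is the full lineage prefix down to
    ``level``, for label schemes whose identifiers are not globally unique.
    """
    t = TaxonLevel.coerce(level)
    return record.lineage[:t] if prefix else record.lineage[t - 1]


class LabeledDataset:
    """An ordered collection of labeled sequences with unique IDs.

    Also hosts the per-``(n, smoothed)`` cache of encoded frequency
    vectors, filled lazily by the scoring layer.
    """

    def __init__(self, records: Iterable[SequenceRecord], dataset_id: str = "dataset"):
        self.records: list[SequenceRecord] = list(records)
        self.dataset_id = dataset_id
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record IDs: {dupes}")
        self._by_id = {r.id: r for r in self.records}
        self.encoded: dict = {}  # (n, smoothed) -> EncodedPool, managed by scoring

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, record_id: str) -> SequenceRecord:
        return self._by_id[record_id]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def subset(self, record_ids: Iterable[str]) -> "LabeledDataset":
        wanted = set(record_ids)
        return LabeledDataset(
            (r for r in self.records if r.id in wanted), dataset_id=self.dataset_id
        )


def is_unique_representative(
    record: SequenceRecord,
    pool: LabeledDataset | list[SequenceRecord],
    level: TaxonLevel | str | int,
    prefix: bool = False,
) -> bool:
    """True iff no *other* record in ``pool`` shares the record's class at ``level``.

    Unique representatives are excluded from scoring: their nearest
    neighbor necessarily belongs to another class, which would bias the
    score downward.
    """
    key = class_key(record, level, prefix)
    for other in pool:
        if other.id != record.id and class_key(other, level, prefix) == key:
            return False
    return True


def subset_same_class(
    pool: LabeledDataset,
    record: SequenceRecord,
    level: TaxonLevel | str | int,
    prefix: bool = False,
) -> LabeledDataset:
    """Records of ``pool`` (including ``record``) sharing the record's class at ``level``."""
    key = class_key(record, level, prefix)
    return LabeledDataset(
        (r for r in pool if class_key(r, level, prefix) == key),
        dataset_id=pool.dataset_id,
    )


_COLUMNS = ["id", "domain", "phylum", "class", "order", "family", "genus", "species"]


def load_lineages(path: str | Path, warn_inconsistent_parents: bool = True) -> dict[str, Lineage]:
    """Read a lineage table: TSV with a header and columns
    ``id  domain  phylum  class  order  family  genus  species``.

    Rows with any empty slot are dropped (with a logged count), mirroring
    the curation that removes genomes with an incomplete lineage.
    Duplicate sequence IDs raise.  Optionally warns when the same
    identifier appears under two distinct parents, which usually signals
    a non-unique labeling scheme (use ``prefix`` comparisons then).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != _COLUMNS:
        raise ValueError(
            f"lineage table {path} must have columns {_COLUMNS}, found {list(df.columns)}"
        )
    if df["id"].duplicated().any():
        dupes = sorted(df.loc[df["id"].duplicated(), "id"].unique())
        raise ValueError(f"duplicate sequence IDs in lineage table: {dupes}")

    complete = (df[_COLUMNS[1:]] != "").all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d record(s) with incomplete lineage", n_dropped)
    kept = df[complete]

    lineages = {row.id: tuple(row[1:]) for row in kept.itertuples(index=False)}

    if warn_inconsistent_parents and lineages:
        parents: dict[tuple[int, str], set[str]] = {}
        for lin in lineages.values():
            for t in range(1, N_LEVELS):
                parents.setdefault((t, lin[t]), set()).add(lin[t - 1])
        clashes = [taxid for (_, taxid), ps in parents.items() if len(ps) > 1]
        if clashes:
            logger.warning(
                "taxon identifier(s) %s appear under multiple parents; "
                "consider prefix-based class comparison",
                sorted(set(clashes))[:10],
            )
    return lineages
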