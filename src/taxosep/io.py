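"""FASTA / lineage-table / results I/O.

Sequence I/O goes through Biopython; lineage tables are the TSV format
described in :mod:`taxosep.taxonomy`.  ``load_dataset`` joins the two
into a :class:`~taxosep.taxonomy.LabeledDataset`, dropping (with a log
line) sequences that have no complete lineage.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .taxonomy import LabeledDataset, SequenceRecord, load_lineages

__all__ = [
    "read_fasta",
    "write_fasta",
    "load_dataset",
    "save_dataset",
    "write_results",
    "FastaFormatError",
]

logger = logging.getLogger(__name__)


class FastaFormatError(ValueError):
    pass


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA as ``(id, sequence)`` pairs in file order.

    IDs are the first whitespace-delimited header token.  Empty files,
    duplicate IDs and sequence-less records are format errors.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate FASTA ID {rec.id!r} in {path}")
        seq = str(rec.seq)
        if not seq:
            raise FastaFormatError(f"record {rec.id!r} in {path} has no sequence")
        seen.add(rec.id)
        pairs.append((rec.id, seq))
    if not pairs:
        raise FastaFormatError(f"no FASTA records in {path}")
    return pairs


def write_fasta(path: str | Path, records) -> None:
    """Write ``(id, sequence)`` pairs or :class:`SequenceRecord` s as FASTA."""
    bio = []
    for r in records:
        rid, seq = (r.id, r.sequence) if isinstance(r, SequenceRecord) else r
        bio.append(BioSeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(bio, str(path), "fasta")


def load_dataset(
    fasta_path: str | Path, lineage_path: str | Path, dataset_id: str | None = None
) -> LabeledDataset:
    """Join a FASTA file with its lineage table into a labeled dataset.

    Sequences whose ID is absent from the (completeness-filtered)
    lineage table are dropped with a logged count — the table is the
    curation record.
    """
    pairs = read_fasta(fasta_path)
    lineages = load_lineages(lineage_path)
    records = []
    dropped = 0
    for rid, seq in pairs:
        lin = lineages.get(rid)
        if lin is None:
            dropped += 1
            continue
        records.append(SequenceRecord(id=rid, sequence=seq, lineage=lin))
    if dropped:
        logger.info("dropped %d sequence(s) without a complete lineage", dropped)
    if not records:
        raise ValueError("no sequence has a complete lineage; nothing to score")
    return LabeledDataset(
        records, dataset_id=dataset_id or Path(fasta_path).stem
    )


_LINEAGE_COLUMNS = ["id", "domain", "phylum", "class", "order", "family", "genus", "species"]


def save_dataset(
    dataset: LabeledDataset,
    fasta_path: str | Path,
    lineage_path: str | Path,
    provenance_path: str | Path | None = None,
    provenance: dict | None = None,
) -> None:
    """Write FASTA + lineage TSV (+ optional provenance JSON) for a dataset."""
    write_fasta(fasta_path, dataset.records)
    rows = [{"id": r.id, **dict(zip(_LINEAGE_COLUMNS[1:], r.lineage))} for r in dataset]
    pd.DataFrame(rows, columns=_LINEAGE_COLUMNS).to_csv(lineage_path, sep="\t", index=False)
    if provenance_path is not None:
        Path(provenance_path).write_text(json.dumps(provenance or {}, indent=2) + "\n")


def write_results(df: pd.DataFrame, path: str | Path) -> None:
    """Write the long-format results table as TSV."""
    df.to_csv(path, sep="\t", index=False)
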