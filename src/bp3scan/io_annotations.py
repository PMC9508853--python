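"""Genome, annotation and retention-table I/O.

Reads a genome FASTA plus GFF3 intron annotations into strand-correct,
transcript-oriented intron sequences, and reads per-intron intron-retention
log2-ratio tables (mutant/wild-type, splicing-sensitive microarray).

Conventions used throughout the package:

* Sequences are RNA (``A C G U N``); DNA input is normalised (``T`` -> ``U``,
  case-folded to upper).  ``N`` is preserved and never matches any motif.
* On-disk coordinates are GFF3: 1-based, inclusive.  In-memory intron-local
  positions are 1-based from the intron's 5' end.
* Minus-strand introns are reverse-complemented on read so that every
  ``IntronRecord.sequence`` reads 5'->3' in transcript orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import gffutils
import pandas as pd
from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGUN")
_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def normalize_rna(raw: str, *, context: str = "sequence") -> str:
    """Upper-case ``raw``, convert T to U and reject non-RNA characters."""
    seq = raw.upper().replace("T", "U")
    for pos, char in enumerate(seq, start=1):
        if char not in RNA_ALPHABET:
            raise FormatError(
                f"{context}: invalid character {char!r} at position {pos} "
                "(allowed: A, C, G, U/T, N)"
            )
    return seq


def reverse_complement(sequence: str) -> str:
    """Reverse complement in RNA space (U<->A, G<->C, N->N)."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A single contig in RNA alphabet."""

    contig_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise FormatError(f"contig {self.contig_id!r}: empty sequence")
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise FormatError(
                f"contig {self.contig_id!r}: invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class IntronRecord:
    """One intron with genomic coordinates and transcript-oriented sequence.

    ``start``/``end`` are 1-based inclusive genomic coordinates on
    ``contig_id``; ``sequence`` always reads 5'->3' of the transcript, so for
    ``strand == '-'`` it is the reverse complement of the plus-strand slice.
    """

    intron_id: str
    gene_id: str
    intron_index: int
    contig_id: str
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.intron_id}: end {self.end} < start {self.start}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.intron_id}: strand must be '+' or '-'")
        if self.intron_index < 1:
            raise ValueError(f"{self.intron_id}: intron_index must be >= 1")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"{self.intron_id}: sequence length {len(self.sequence)} does not "
                f"match coordinates [{self.start}, {self.end}]"
            )
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(f"{self.intron_id}: invalid residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RetentionMeasure:
    """Per-intron log2(mutant/wt) intron-retention signal.

    ``log2_ratio_30c`` is the ratio measured at 30 degrees C (the
    classification temperature); ``None`` marks a missing measurement.
    ``other_ratios`` maps further temperature labels to their ratios.
    """

    intron_id: str
    log2_ratio_30c: float | None
    other_ratios: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.intron_id:
            raise ValueError("intron_id must be non-empty")
        if self.log2_ratio_30c is not None and not math.isfinite(self.log2_ratio_30c):
            raise ValueError(f"{self.intron_id}: non-finite retention ratio")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, GenomeSequence]:
    """Read a genome FASTA into a contig_id -> GenomeSequence map."""
    path = Path(path)
    with open(path) as handle:
        first = ""
        for line in handle:
            if line.strip():
                first = line
                break
        if not first:
            raise FormatError(f"{path}: empty FASTA file")
        if not first.startswith(">"):
            raise FormatError(
                f"{path}: malformed FASTA, expected '>' header on line 1, "
                f"got {first.strip()!r}"
            )
    genome: dict[str, GenomeSequence] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise FormatError(f"{path}: duplicate contig id {record.id!r}")
        residues = normalize_rna(str(record.seq), context=f"contig {record.id!r}")
        genome[record.id] = GenomeSequence(record.id, residues)
    if not genome:
        raise FormatError(f"{path}: no FASTA records found")
    return genome


def write_fasta(genome: Mapping[str, GenomeSequence], path: str | Path,
                width: int = 70) -> None:
    """Write contigs to FASTA (RNA alphabet, fixed line width)."""
    with open(path, "w") as handle:
        for contig in genome.values():
            handle.write(f">{contig.contig_id}\n")
            for i in range(0, len(contig.residues), width):
                handle.write(contig.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _slice_intron(genome: Mapping[str, GenomeSequence], contig_id: str,
                  start: int, end: int, strand: str, label: str) -> str:
    if contig_id not in genome:
        raise FormatError(f"{label}: unknown contig {contig_id!r}")
    contig = genome[contig_id]
    if start < 1 or end > len(contig):
        raise FormatError(
            f"{label}: coordinates [{start}, {end}] outside contig "
            f"{contig_id!r} of length {len(contig)}"
        )
    plus = contig.residues[start - 1:end]
    return reverse_complement(plus) if strand == "-" else plus


def _attr(feature: gffutils.Feature, *keys: str) -> str | None:
    for key in keys:
        if key in feature.attributes:
            return feature.attributes[key][0]
    return None


def read_gff3_introns(path: str | Path,
                      genome: Mapping[str, GenomeSequence]) -> list[IntronRecord]:
    """Read intron features from GFF3, inferring them from exons if absent.

    Explicit ``intron`` features are used when present; otherwise introns are
    derived per transcript as the gaps between consecutive exons (annotation
    exports vary in whether introns are materialised).  Minus-strand introns
    are reverse-complemented and ``intron_index`` counts in transcript
    orientation (index 1 is the 5'-most intron of the transcript).
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    introns: list[IntronRecord] = []
    explicit = list(db.features_of_type("intron"))
    if explicit:
        by_parent: dict[str, list[gffutils.Feature]] = {}
        for feat in explicit:
            parent = _attr(feat, "Parent", "gene", "ID") or f"{feat.seqid}:{feat.start}"
            by_parent.setdefault(parent, []).append(feat)
        for parent, feats in by_parent.items():
            feats.sort(key=lambda f: f.start)
            if feats[0].strand == "-":
                feats = feats[::-1]
            for index, feat in enumerate(feats, start=1):
                intron_id = _attr(feat, "ID") or f"{parent}.intron{index}"
                seq = _slice_intron(genome, feat.seqid, feat.start, feat.end,
                                    feat.strand, intron_id)
                introns.append(IntronRecord(
                    intron_id=intron_id, gene_id=parent, intron_index=index,
                    contig_id=feat.seqid, start=feat.start, end=feat.end,
                    strand=feat.strand, sequence=seq,
                ))
    else:
        exons_by_tx: dict[str, list[gffutils.Feature]] = {}
        for feat in db.features_of_type("exon"):
            parent = _attr(feat, "Parent", "ID") or f"{feat.seqid}:{feat.start}"
            exons_by_tx.setdefault(parent, []).append(feat)
        for tx, exons in sorted(exons_by_tx.items()):
            exons.sort(key=lambda f: f.start)
            gaps = [
                (left.end + 1, right.start - 1, left.seqid, left.strand)
                for left, right in zip(exons, exons[1:])
                if right.start - left.end > 1
            ]
            if exons[0].strand == "-":
                gaps = gaps[::-1]
            for index, (start, end, seqid, strand) in enumerate(gaps, start=1):
                intron_id = f"{tx}.intron{index}"
                seq = _slice_intron(genome, seqid, start, end, strand, intron_id)
                introns.append(IntronRecord(
                    intron_id=intron_id, gene_id=tx, intron_index=index,
                    contig_id=seqid, start=start, end=end, strand=strand,
                    sequence=seq,
                ))
    return introns


def write_gff3_introns(introns: list[IntronRecord], path: str | Path,
                       source: str = "bp3scan") -> None:
    """Write introns as explicit GFF3 ``intron`` features."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for intron in introns:
            attrs = (
                f"ID={intron.intron_id};Parent={intron.gene_id};"
                f"intron_index={intron.intron_index}"
            )
            handle.write(
                f"{intron.contig_id}\t{source}\tintron\t{intron.start}\t"
                f"{intron.end}\t.\t{intron.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Retention table
# ---------------------------------------------------------------------------

RETENTION_RATIO_COLUMN = "log2_ratio_30C"


def read_retention_table(path: str | Path) -> list[RetentionMeasure]:
    """Read a TSV of per-intron retention ratios.

    Mandatory columns: ``intron_id`` and ``log2_ratio_30C``.  Empty/NA ratios
    are retained with the ratio flagged missing.  Additional ``log2_ratio_*``
    columns are collected as other-temperature measurements.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype={"intron_id": str})
    for column in ("intron_id", RETENTION_RATIO_COLUMN):
        if column not in frame.columns:
            raise FormatError(f"{path}: missing mandatory column {column!r}")
    duplicated = frame["intron_id"][frame["intron_id"].duplicated()]
    if not duplicated.empty:
        raise FormatError(
            f"{path}: duplicate intron_id {duplicated.iloc[0]!r}"
        )
    extra_cols = [
        c for c in frame.columns
        if c.startswith("log2_ratio_") and c != RETENTION_RATIO_COLUMN
    ]
    measures: list[RetentionMeasure] = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        record = row._asdict()
        ratio = _parse_ratio(record[RETENTION_RATIO_COLUMN], path, row_number)
        others = {}
        for col in extra_cols:
            value = _parse_ratio(record[col], path, row_number, column=col)
            if value is not None:
                others[col.removeprefix("log2_ratio_")] = value
        measures.append(RetentionMeasure(
            intron_id=str(record["intron_id"]),
            log2_ratio_30c=ratio,
            other_ratios=others,
        ))
    return measures


def _parse_ratio(value, path: Path, row_number: int,
                 column: str = RETENTION_RATIO_COLUMN) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if value in {"", "NA", "NaN", "nan"}:
            return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise FormatError(
            f"{path}: non-numeric {column} {value!r} on row {row_number}"
        ) from None


def write_retention_table(measures: list[RetentionMeasure],
                          path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write(f"intron_id\t{RETENTION_RATIO_COLUMN}\n")
        for measure in measures:
            ratio = "" if measure.log2_ratio_30c is None else repr(measure.log2_ratio_30c)
            handle.write(f"{measure.intron_id}\t{ratio}\n")
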