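"""Readers and writers for the external formats the pipeline touches.

FASTA/FASTQ go through Bio.SeqIO, GFF3 through gffutils, BED6 and TSV
tables through pandas. All sequence input is normalized to uppercase
A/C/G/T/N (U mapped to T); anything else is rejected. Gzip input is
transparent for sequence files (suffix ``.gz``).
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterable

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

from .records import ExpressionDelta, GeneRecord, ReadSetMetadata, SequenceRecord

log = logging.getLogger("tandemreads")

_NORMALIZE = str.maketrans("acgtnuU", "ACGTNTT")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _normalize_sequence(seq: str, where: str) -> str:
    out = seq.translate(_NORMALIZE)
    rec_ok = set(out) <= {"A", "C", "G", "T", "N"}
    if not rec_ok:
        bad = sorted(set(out) - {"A", "C", "G", "T", "N"})
        raise ValueError(f"{where}: invalid sequence characters {bad!r}")
    return out


def read_sequences(path: str | Path, format: str | None = None) -> list[SequenceRecord]:
    """Read FASTA or FASTQ into :class:`SequenceRecord`, in file order.

    ``format`` is inferred from the suffix when omitted. An empty file
    yields an empty list; a malformed record raises ``ValueError``.
    """
    path = Path(path)
    if format is None:
        stem = path.name[:-3] if path.suffix == ".gz" else path.name
        format = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported sequence format {format!r}")
    records: list[SequenceRecord] = []
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, format):
                seq = _normalize_sequence(str(rec.seq), f"{path.name}:{rec.id}")
                qual = None
                if format == "fastq":
                    phred = rec.letter_annotations.get("phred_quality")
                    if phred is not None:
                        qual = "".join(chr(q + 33) for q in phred)
                records.append(SequenceRecord(id=rec.id, sequence=seq, quality=qual))
        except ValueError as exc:
            raise ValueError(f"parse error in {path}: {exc}") from exc
    return records


def write_sequences(records: Iterable[SequenceRecord], path: str | Path,
                    format: str | None = None) -> None:
    """Write records as FASTA or FASTQ (constant quality 'I' if absent)."""
    path = Path(path)
    if format is None:
        format = "fastq" if path.name.endswith((".fastq", ".fq")) else "fasta"
    with open(path, "wt") as fh:
        if format == "fasta":
            for rec in records:
                fh.write(f">{rec.id}\n{rec.sequence}\n")
        elif format == "fastq":
            for rec in records:
                qual = rec.quality or "I" * len(rec.sequence)
                fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")
        else:
            raise ValueError(f"unsupported sequence format {format!r}")


def as_genome_dict(records: Iterable[SequenceRecord]) -> dict[str, str]:
    """Map seq_id -> sequence, rejecting duplicate ids."""
    genome: dict[str, str] = {}
    for rec in records:
        if rec.id in genome:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        genome[rec.id] = rec.sequence
    return genome


def genome_size_of(records: Iterable[SequenceRecord]) -> int:
    return sum(len(r) for r in records)


# ---------------------------------------------------------------- annotations

def read_gene_annotations(path: str | Path, format: str | None = None,
                          feature_type: str = "gene") -> list[GeneRecord]:
    """Read gene TSS anchors from GFF3 or BED6.

    GFF3 1-based closed coordinates are converted to the internal 0-based
    convention: TSS = start-1 for plus-strand genes, end-1 for minus-strand
    genes. BED is taken as already 0-based half-open.
    """
    path = Path(path)
    if format is None:
        format = "bed" if path.suffix.lower() == ".bed" else "gff3"
    if format == "gff3":
        genes = _read_gff3(path, feature_type)
    elif format == "bed":
        genes = _read_bed(path)
    else:
        raise ValueError(f"unsupported annotation format {format!r}")
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id!r} in {path}")
        seen.add(g.gene_id)
    return genes


def _read_gff3(path: Path, feature_type: str) -> list[GeneRecord]:
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="error", keep_order=True)
    out: list[GeneRecord] = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        if feat.strand not in ("+", "-"):
            raise ValueError(f"gene {gene_id!r}: missing or invalid strand")
        tss = feat.start - 1 if feat.strand == "+" else feat.end - 1
        out.append(GeneRecord(gene_id=gene_id, seq_id=feat.seqid,
                              tss=tss, strand=feat.strand))
    return out


def _read_bed(path: Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name", "score", "strand"],
                     dtype={"chrom": str, "name": str, "strand": str})
    out: list[GeneRecord] = []
    for row in df.itertuples(index=False):
        if row.strand not in ("+", "-"):
            raise ValueError(f"gene {row.name!r}: missing or invalid strand")
        tss = int(row.start) if row.strand == "+" else int(row.end) - 1
        out.append(GeneRecord(gene_id=str(row.name), seq_id=str(row.chrom),
                              tss=tss, strand=row.strand))
    return out


def write_gene_annotations(genes: Iterable[GeneRecord], path: str | Path,
                           gene_length: int = 1000) -> None:
    """Write genes as a minimal GFF3 (nominal fixed-length features)."""
    with open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            if g.strand == "+":
                start1, end1 = g.tss + 1, g.tss + gene_length
            else:
                start1, end1 = max(1, g.tss + 2 - gene_length), g.tss + 1
            fh.write(f"{g.seq_id}\ttandemreads\tgene\t{start1}\t{end1}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")


# ----------------------------------------------------------------- expression

def read_expression_table(path: str | Path) -> list[ExpressionDelta]:
    """Read a TSV with header columns ``gene_id`` and ``log2fc``."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "log2fc"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df.empty:
        return []
    dupes = df["gene_id"][df["gene_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicated gene_id values {dupes!r}")
    deltas = pd.to_numeric(df["log2fc"], errors="coerce")
    bad = df["gene_id"][~np.isfinite(deltas)].tolist()
    if bad:
        raise ValueError(f"{path}: non-numeric log2fc for genes {bad!r}")
    return [ExpressionDelta(gene_id=g, delta=float(d))
            for g, d in zip(df["gene_id"], deltas)]


# -------------------------------------------------------------------- reports

def write_report(table: pd.DataFrame, path: str | Path) -> None:
    """Write a rectangular report as TSV: header row, UTF-8, row order as
    given, floats rendered with 6 significant digits."""
    if table.columns.duplicated().any():
        raise ValueError("report column names must be unique")
    table.to_csv(path, sep="\t", index=False, float_format="%.6g",
                 encoding="utf-8")


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ------------------------------------------------------------------- catalogs

def write_catalog(catalog, path: str | Path) -> None:
    """Write a repeat catalog as TSV with '#key=value' metadata headers."""
    md = catalog.metadata
    with open(path, "wt") as fh:
        fh.write(f"#total_reads={md.total_reads}\n")
        fh.write(f"#read_length={md.read_length}\n")
        if md.genome_size is not None:
            fh.write(f"#genome_size={md.genome_size}\n")
        catalog.to_frame().to_csv(fh, sep="\t", index=False)


def read_catalog(path: str | Path):
    """Inverse of :func:`write_catalog`."""
    from .scan import RepeatCatalog  # deferred: avoid import cycle

    meta: dict[str, int] = {}
    with open(path, "rt") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key] = int(val)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    metadata = ReadSetMetadata(total_reads=meta["total_reads"],
                               read_length=meta["read_length"],
                               genome_size=meta.get("genome_size"))
    entries = {row.canonical_unit: (int(row.times_found), int(row.reads_with))
               for row in df.itertuples(index=False)}
    return RepeatCatalog(entries=entries, metadata=metadata)
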