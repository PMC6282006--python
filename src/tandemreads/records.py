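"""Core record types shared across the pipeline.

All coordinates are 0-based, half-open. Sequences are uppercase over the
alphabet ``{A, C, G, T, N}``; ``N`` marks masked or unknown bases and is
skipped by the scanning stages rather than dropped from the sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

VALID_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """A single read or reference sequence.

    Quality values, when present (FASTQ input), are carried along for
    round-tripping but ignored by every analysis stage.
    """

    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid characters {sorted(bad)!r} "
                "(expected A/C/G/T/N after normalization)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadSetMetadata:
    """Sequencing-run facts needed to normalize raw repeat counts.

    ``genome_size`` may be left unset when a catalog is built from reads
    alone; copy-number estimation requires it and raises if missing.
    """

    total_reads: int
    read_length: int
    genome_size: int | None = None

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.genome_size is not None and self.genome_size <= 0:
            raise ValueError("genome_size must be positive when supplied")

    def require_genome_size(self) -> int:
        if self.genome_size is None:
            raise ValueError(
                "genome_size is required for copy-number normalization; "
                "supply it directly or sum a reference FASTA"
            )
        return self.genome_size


@dataclass(frozen=True)
class GeneRecord:
    """A gene anchored by its transcription start site (TSS).

    ``tss`` is a 0-based coordinate on the forward strand of ``seq_id``;
    for a minus-strand gene it is the first transcribed base, i.e. the
    rightmost base of the feature.
    """

    gene_id: str
    seq_id: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id!r}: tss must be >= 0")


@dataclass(frozen=True)
class ExpressionDelta:
    """Per-gene log2 fold change (mutant minus wild type)."""

    gene_id: str
    delta: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta):
            raise ValueError(f"gene {self.gene_id!r}: non-finite log2 fold change")


@dataclass(frozen=True)
class MotifSpec:
    """A short DNA motif tracked around TSSs (e.g. the STRE CCCCT)."""

    motif: str
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.motif) < 3:
            raise ValueError("motif must be at least 3 bp")
        bad = set(self.motif) - set("ACGT")
        if bad:
            raise ValueError(f"motif alphabet must be A/C/G/T, got {sorted(bad)!r}")
        if not self.label:
            object.__setattr__(self, "label", self.motif)


@dataclass(frozen=True)
class WindowGrid:
    """Nested distance windows around the TSS, in transcription orientation."""

    extents: tuple[int, ...] = tuple(range(200, 2001, 200))
    directions: tuple[str, ...] = ("upstream", "downstream")

    def __post_init__(self) -> None:
        if not self.extents:
            raise ValueError("at least one extent required")
        if any(e <= 0 for e in self.extents):
            raise ValueError("extents must be positive")
        if list(self.extents) != sorted(set(self.extents)):
            raise ValueError("extents must be strictly increasing")
        for d in self.directions:
            if d not in ("upstream", "downstream"):
                raise ValueError(f"unknown direction {d!r}")
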