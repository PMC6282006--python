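"""Long-read classification and repeat/rDNA co-occurrence.

Long reads (multi-kilobase, ~10% substitution error) are classified two
ways: (i) does the read carry a tandem repeat unit, detected as exact
substring matches of any rotation of the unit on either strand, with a
minimum hit count so isolated chance matches do not flag a read; and
(ii) does the read belong to the rDNA locus, proxied by k-mer containment
— the fraction of the read's k-mers found in the rDNA reference (either
strand) — against a low threshold chosen so that ~0.9**k survival of exact
k-mers at long-read error rates still clears it. The co-occurrence
fraction, per unit, is the share of unit-carrying reads that also pass
the rDNA test; in the study system it exposes how telomere-like arrays
are interspersed with the rDNA repeats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import codes_in_set, kmer_code_of, kmer_codes, kmer_set, revcomp, rotations
from .records import SequenceRecord
from .scan import canonical_unit

DEFAULT_K = 15
DEFAULT_MIN_HITS = 3
DEFAULT_CONTAINMENT = 0.10


@dataclass(frozen=True)
class ReadClassification:
    read_id: str
    unit_hits: dict
    rdna_containment: float
    rdna_hit: bool


@dataclass(frozen=True)
class CooccurrenceResult:
    unit: str
    n_unit_reads: int
    n_both: int

    @property
    def fraction(self) -> float | None:
        if self.n_unit_reads == 0:
            return None
        return self.n_both / self.n_unit_reads


def _rotation_code_set(unit: str) -> tuple[np.ndarray, int]:
    """Sorted numeric codes of all rotations of a unit and its reverse
    complement (both strands of every phase)."""
    rep = canonical_unit(unit)
    L = len(rep)
    forms = set(rotations(rep)) | set(rotations(revcomp(rep)))
    return np.unique(np.array([kmer_code_of(f) for f in forms],
                              dtype=np.uint64)), L


def count_unit_hits(read: SequenceRecord, unit: str) -> int:
    """Exact occurrences (by start position) of any rotation of *unit* on
    either strand within the read."""
    code_set, L = _rotation_code_set(unit)
    if len(read) < L:
        return 0
    if L <= 31:
        codes, ok = kmer_codes(read.sequence, L)
        return int(codes_in_set(codes[ok], code_set).sum())
    forms = set(rotations(canonical_unit(unit))) | set(
        rotations(revcomp(canonical_unit(unit))))
    seq = read.sequence
    hits = 0
    for f in forms:
        i = seq.find(f)
        while i != -1:
            hits += 1
            i = seq.find(f, i + 1)
    return hits


def detect_unit_in_longread(read: SequenceRecord, unit: str,
                            min_hits: int = DEFAULT_MIN_HITS
                            ) -> tuple[bool, int]:
    """Flag a read as carrying the unit when rotation matches reach
    *min_hits*. Invariant under reverse-complementing the read."""
    if min_hits < 1:
        raise ValueError("min_hits must be >= 1")
    hits = count_unit_hits(read, unit)
    return hits >= min_hits, hits


def kmer_containment(read: SequenceRecord, reference: SequenceRecord,
                     k: int = DEFAULT_K) -> float:
    """Fraction of the read's k-mers present in the reference (either
    strand). N-containing k-mers are excluded from numerator and
    denominator; returns 0.0 when no k-mer is scorable."""
    if k > len(read):
        raise ValueError(f"k={k} exceeds read length {len(read)}")
    if not reference.sequence:
        raise ValueError("empty reference")
    ref_set = kmer_set(reference.sequence, k)
    codes, ok = kmer_codes(read.sequence, k)
    n_ok = int(ok.sum())
    if n_ok == 0:
        return 0.0
    return int(codes_in_set(codes[ok], ref_set).sum()) / n_ok


def classify_read(read: SequenceRecord, units: Sequence[str],
                  rdna_set: np.ndarray, k: int,
                  min_hits: int, containment_threshold: float
                  ) -> ReadClassification:
    unit_hits = {canonical_unit(u): count_unit_hits(read, u) for u in units}
    if len(read) >= k:
        codes, ok = kmer_codes(read.sequence, k)
        n_ok = int(ok.sum())
        cont = (int(codes_in_set(codes[ok], rdna_set).sum()) / n_ok
                if n_ok else 0.0)
    else:
        cont = 0.0
    return ReadClassification(read_id=read.id, unit_hits=unit_hits,
                              rdna_containment=cont,
                              rdna_hit=cont >= containment_threshold)


def cooccurrence(longreads: Sequence[SequenceRecord], units: Sequence[str],
                 rdna: SequenceRecord, *, min_hits: int = DEFAULT_MIN_HITS,
                 k: int = DEFAULT_K,
                 containment_threshold: float = DEFAULT_CONTAINMENT
                 ) -> list[CooccurrenceResult]:
    """Per-unit co-occurrence of repeat content and rDNA membership."""
    if not longreads:
        raise ValueError("empty long-read set")
    if min_hits < 1 or k < 1 or containment_threshold <= 0:
        raise ValueError("parameters must be positive")
    reps = [canonical_unit(u) for u in units]
    rdna_set = kmer_set(rdna.sequence, k)
    n_unit = {u: 0 for u in reps}
    n_both = {u: 0 for u in reps}
    for read in longreads:
        cls = classify_read(read, reps, rdna_set, k, min_hits,
                            containment_threshold)
        for u in reps:
            if cls.unit_hits[u] >= min_hits:
                n_unit[u] += 1
                if cls.rdna_hit:
                    n_both[u] += 1
    return [CooccurrenceResult(unit=u, n_unit_reads=n_unit[u], n_both=n_both[u])
            for u in reps]


def cooccurrence_table(results: Iterable[CooccurrenceResult]) -> pd.DataFrame:
    rows = [(r.unit, len(r.unit), r.n_unit_reads, r.n_both,
             np.nan if r.fraction is None else r.fraction)
            for r in results]
    return pd.DataFrame(rows, columns=["unit", "unit_length", "n_unit_reads",
                                       "n_both", "fraction"])
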