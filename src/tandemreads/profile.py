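"""Copy-number normalization and repeat-content comparison across strains.

The genomic copy number of a repeat is estimated from raw-read counts
without any reference alignment::

    copy_number = times_found * genome_size
                  ------------------------------------------------
                  total_reads * (read_length - repeat_length + 1)

The denominator counts the read offsets at which a pattern of
``repeat_length`` bases can be fully sampled, so the ratio converts "hits
per read set" into "patterns per genome". ``repeat_length`` defaults to the
full duplication window 2L (the object actually matched in reads); a mode
switch uses the bare unit length L for sensitivity analysis.

The module also groups raw repeat units into phased-rotation classes (near
equal counts across phases imply an array longer than a single
duplication), decomposes composite units into tilings of shorter units, and
compares per-strain read fractions of repeat families and rDNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp, rotations
from .records import ReadSetMetadata, SequenceRecord
from .scan import RepeatCatalog, canonical_unit


@dataclass(frozen=True)
class CopyNumberEstimate:
    unit: str
    copy_number: float
    repeat_length_used: int


def estimate_copy_number(times_found: int, metadata: ReadSetMetadata,
                         repeat_length: int) -> CopyNumberEstimate:
    """Apply the read-count normalization equation for one repeat.

    Raises if ``read_length < repeat_length`` (the per-read sampling term
    would be non-positive) or if ``genome_size`` is unknown.
    """
    if times_found < 0:
        raise ValueError("times_found must be >= 0")
    if metadata.read_length < repeat_length:
        raise ValueError(
            f"read_length {metadata.read_length} < repeat_length {repeat_length}: "
            "reads cannot sample the pattern")
    genome_size = metadata.require_genome_size()
    denom = metadata.total_reads * (metadata.read_length - repeat_length + 1)
    cn = times_found * genome_size / denom
    return CopyNumberEstimate(unit="", copy_number=cn,
                              repeat_length_used=repeat_length)


def copy_number_table(catalog: RepeatCatalog,
                      repeat_length_mode: str = "2L") -> pd.DataFrame:
    """Copy-number estimates for every catalog unit.

    ``repeat_length_mode`` is ``"2L"`` (duplication window, default) or
    ``"L"`` (bare unit). Units whose window exceeds the read length are
    skipped (they cannot be sampled and never enter the catalog anyway).
    """
    if repeat_length_mode not in ("2L", "L"):
        raise ValueError(f"unknown repeat_length_mode {repeat_length_mode!r}")
    md = catalog.metadata
    rows = []
    for unit, (tf, rw) in catalog.entries.items():
        L = len(unit)
        rl = 2 * L if repeat_length_mode == "2L" else L
        if rl > md.read_length:
            continue
        est = estimate_copy_number(tf, md, rl)
        rows.append((unit, L, tf, rw, rl, est.copy_number))
    df = pd.DataFrame(rows, columns=["canonical_unit", "unit_length",
                                     "times_found", "reads_with",
                                     "repeat_length_used", "copy_number"])
    return df.sort_values(["copy_number", "canonical_unit"],
                          ascending=[False, True], ignore_index=True)


# --------------------------------------------------------------- phasing

@dataclass
class PhasedGroup:
    """Raw rotation phases of one canonical unit observed in reads.

    Near-equal counts across two or more phases indicate reads sampling a
    tandem array longer than a single duplication, because a long array is
    entered at every offset equally often.
    """

    canonical: str
    member_counts: dict[str, int]
    array_inferred: bool

    @property
    def members(self) -> set[str]:
        return set(self.member_counts)


def phase_groups(raw_counts: Mapping[str, int],
                 similarity_threshold: float = 2.0) -> list[PhasedGroup]:
    """Partition raw (uncanonicalized) unit counts into rotation classes.

    ``array_inferred`` is set when at least two phases were observed and
    the max/min count ratio does not exceed *similarity_threshold*.
    """
    if similarity_threshold < 1:
        raise ValueError("similarity_threshold must be >= 1")
    by_canon: dict[str, dict[str, int]] = {}
    for raw, count in raw_counts.items():
        by_canon.setdefault(canonical_unit(raw), {})[raw] = int(count)
    groups = []
    for canon in sorted(by_canon):
        members = by_canon[canon]
        counts = list(members.values())
        inferred = (len(members) >= 2
                    and max(counts) <= similarity_threshold * min(counts))
        groups.append(PhasedGroup(canonical=canon, member_counts=members,
                                  array_inferred=inferred))
    return groups


# ----------------------------------------------------------- composites

@dataclass
class CompositeDecomposition:
    """An exact tiling of (a rotation of) a composite unit by shorter units."""

    unit: str
    components: tuple[str, ...]
    multiplicity: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        for c in self.components:
            counts[c] = counts.get(c, 0) + 1
        self.multiplicity = counts

    @property
    def empty(self) -> bool:
        return not self.components


def decompose_composite(unit: str, components: Iterable[str]
                        ) -> CompositeDecomposition:
    """Tile a composite unit with fixed component sequences.

    Every rotation of the unit and of its reverse complement is searched
    for an exact concatenation of component strings (components are used
    as given, not rotated). The tiling with the fewest components wins;
    ties break to the lexicographically least component sequence. Returns
    an empty decomposition when no rotation tiles.
    """
    # components at least as long as the unit can never participate
    comps = sorted(c for c in set(components) if len(c) < len(unit))
    best: tuple[int, tuple[str, ...]] | None = None
    frames = rotations(unit) + rotations(revcomp(unit))
    for frame in dict.fromkeys(frames):
        tiling = _min_tiling(frame, comps)
        if tiling is not None:
            key = (len(tiling), tiling)
            if best is None or key < best:
                best = key
    if best is None:
        return CompositeDecomposition(unit=unit, components=())
    return CompositeDecomposition(unit=unit, components=best[1])


def _min_tiling(s: str, comps: list[str]) -> tuple[str, ...] | None:
    """Fewest-components exact tiling of *s*, lexicographic tie-break."""
    n = len(s)
    # dp[i]: best (count, components) covering s[:i]
    dp: list[tuple[int, tuple[str, ...]] | None] = [None] * (n + 1)
    dp[0] = (0, ())
    for i in range(n):
        if dp[i] is None:
            continue
        count, seq = dp[i]
        for c in comps:
            j = i + len(c)
            if j <= n and s.startswith(c, i):
                cand = (count + 1, seq + (c,))
                if dp[j] is None or cand < dp[j]:
                    dp[j] = cand
    return dp[n][1] if dp[n] is not None else None


# ------------------------------------------------------- strain profiles

@dataclass
class StrainRepeatProfile:
    """Per-strain fractions of reads carrying each repeat family and rDNA."""

    strain_id: str
    unit_fractions: dict[str, float]
    rdna_fraction: float

    def __post_init__(self) -> None:
        for u, f in self.unit_fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"strain {self.strain_id}: fraction for {u} "
                                 f"outside [0,1]")
        if not 0.0 <= self.rdna_fraction <= 1.0:
            raise ValueError(f"strain {self.strain_id}: rdna fraction outside [0,1]")


def strain_profile(catalog: RepeatCatalog, rdna_read_hits: int, strain_id: str,
                   tracked_units: Sequence[str]) -> StrainRepeatProfile:
    """Read fractions for tracked canonical units and the rDNA reference."""
    md = catalog.metadata
    if md is None or md.total_reads == 0:
        raise ValueError("catalog metadata with positive total_reads required")
    if rdna_read_hits > md.total_reads:
        raise ValueError("rdna_read_hits exceeds total_reads")
    fractions = {canonical_unit(u): catalog.reads_with(canonical_unit(u)) / md.total_reads
                 for u in tracked_units}
    return StrainRepeatProfile(strain_id=strain_id, unit_fractions=fractions,
                               rdna_fraction=rdna_read_hits / md.total_reads)


def compare_strains(profiles: Sequence[StrainRepeatProfile],
                    reference_strain: str) -> pd.DataFrame:
    """Fractions and ratio-to-reference per unit (plus an rDNA row) across
    strains, with strain column order as given."""
    ids = [p.strain_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate strain ids in {ids!r}")
    if reference_strain not in ids:
        raise ValueError(f"reference strain {reference_strain!r} not among {ids!r}")
    ref = next(p for p in profiles if p.strain_id == reference_strain)
    units = sorted({u for p in profiles for u in p.unit_fractions},
                   key=lambda u: (len(u), u))
    rows = []
    for u in units + ["rDNA"]:
        row: dict[str, object] = {"unit": u}
        ref_f = ref.rdna_fraction if u == "rDNA" else ref.unit_fractions.get(u, 0.0)
        for p in profiles:
            f = p.rdna_fraction if u == "rDNA" else p.unit_fractions.get(u, 0.0)
            row[f"fraction_{p.strain_id}"] = f
            row[f"ratio_{p.strain_id}"] = f / ref_f if ref_f > 0 else np.nan
        rows.append(row)
    cols = ["unit"] + [c for p in profiles
                       for c in (f"fraction_{p.strain_id}", f"ratio_{p.strain_id}")]
    return pd.DataFrame(rows, columns=cols)


def count_rdna_hits(reads: Iterable[SequenceRecord], rdna: SequenceRecord,
                    k: int = 15, containment_threshold: float = 0.5) -> int:
    """Number of reads whose k-mer containment in the rDNA reference meets
    the threshold — an alignment-free stand-in for 'reads that align to the
    rDNA repeat'. Default threshold 0.5 suits low-error short reads."""
    from ._seq import codes_in_set, kmer_codes, kmer_set

    ref_set = kmer_set(rdna.sequence, k)
    hits = 0
    for rec in reads:
        if len(rec) < k:
            continue
        codes, ok = kmer_codes(rec.sequence, k)
        n_ok = int(ok.sum())
        if n_ok == 0:
            continue
        frac = int(codes_in_set(codes[ok], ref_set).sum()) / n_ok
        if frac >= containment_threshold:
            hits += 1
    return hits
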