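"""Exhaustive tandem-duplication scanning in raw reads.

A *tandem duplication* of unit size L at offset i in a read is an exact
equality ``read[i:i+L] == read[i+L:i+2L]`` over a window free of N. Every
unit size in a configurable range (default 1-75 bp, the largest duplication
a 150 bp read can contain) is scanned, and each hit is attributed to the
*canonical* form of its unit: the lexicographically least string among all
rotations of the unit and of its reverse complement, so that every phase of
an array and both sequencing strands collapse to one catalog entry.

Non-primitive windows (units that are themselves a whole-number power of a
shorter unit, e.g. ``ATAT``) are suppressed: a homopolymer or dimer run is
counted only at its primitive unit length, never again at every multiple.

``scan_read`` is the per-read reference path; ``build_catalog`` batches
reads into one N-separated buffer and runs the same scan vectorized, which
is what makes whole-read-set scans tractable in numpy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._seq import decode_kmer, revcomp, rotations
from .records import ReadSetMetadata, SequenceRecord

_MAX_GATHER = 8_000_000  # bound on elements per primitivity gather block


def canonical_unit(unit: str) -> str:
    """Rotation/reverse-complement-invariant representative of a unit.

    Lexicographic minimum over the 2L candidate strings (all rotations of
    the unit and all rotations of its reverse complement). Idempotent.
    """
    if not unit:
        raise ValueError("empty unit")
    if set(unit) - set("ACGT"):
        raise ValueError(f"unit {unit!r} contains non-ACGT characters")
    return min(min(rotations(unit)), min(rotations(revcomp(unit))))


def is_primitive(unit: str) -> bool:
    """True unless *unit* equals a shorter unit repeated a whole number of
    times (classic doubling trick: u is non-primitive iff u occurs in
    (u+u) at an offset strictly between 0 and len(u))."""
    if not unit:
        raise ValueError("empty unit")
    return (unit + unit).find(unit, 1) == len(unit)


@lru_cache(maxsize=128)
def _proper_divisors(n: int) -> tuple[int, ...]:
    return tuple(d for d in range(1, n) if n % d == 0)


@dataclass(frozen=True)
class TandemOccurrence:
    """One exact duplication window found in a read."""

    read_id: str
    start: int
    unit: str           # canonical representative
    unit_length: int
    run_length: int     # bases of the maximal tandem run containing the window


@dataclass
class RepeatCatalog:
    """Aggregated per-canonical-unit counts over a read set.

    ``times_found`` sums distinct duplication start positions over all
    reads (occurrence mode, consumed by the copy-number estimator);
    ``reads_with`` counts reads containing at least one occurrence
    (presence mode, consumed by read-fraction comparisons).
    """

    entries: dict[str, tuple[int, int]] = field(default_factory=dict)
    metadata: ReadSetMetadata | None = None

    def times_found(self, unit: str) -> int:
        return self.entries.get(unit, (0, 0))[0]

    def reads_with(self, unit: str) -> int:
        return self.entries.get(unit, (0, 0))[1]

    def to_frame(self) -> pd.DataFrame:
        rows = [(u, len(u), tf, rw) for u, (tf, rw) in self.entries.items()]
        df = pd.DataFrame(rows, columns=["canonical_unit", "unit_length",
                                         "times_found", "reads_with"])
        return df.sort_values(["times_found", "canonical_unit"],
                              ascending=[False, True], ignore_index=True)

    def validate(self) -> None:
        for u, (tf, rw) in self.entries.items():
            if not (0 <= rw <= tf):
                raise AssertionError(f"catalog entry {u}: reads_with > times_found")
            if self.metadata and rw > self.metadata.total_reads:
                raise AssertionError(f"catalog entry {u}: reads_with > total_reads")


# ------------------------------------------------------------- per-read scan

def _byte_view(seq: str) -> tuple[np.ndarray, np.ndarray]:
    a = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return a, a != ord("N")


def _match_starts(a: np.ndarray, valid: np.ndarray, L: int) -> tuple[np.ndarray, np.ndarray]:
    """Offsets i with a[i:i+L] == a[i+L:i+2L], window N-free.

    Returns (starts, eq) where eq[j] marks a[j] == a[j+L] with both valid.
    """
    n = a.size
    eq = (a[:-L] == a[L:]) & valid[:-L] & valid[L:]
    c = np.concatenate(([0], np.cumsum(eq, dtype=np.int64)))
    s = c[L:] - c[: n - 2 * L + 1]
    return np.flatnonzero(s == L), eq


def _primitive_mask(a: np.ndarray, starts: np.ndarray, L: int) -> np.ndarray:
    """Which matched L-windows at *starts* are primitive units."""
    if starts.size == 0 or L == 1:
        return np.ones(starts.size, dtype=bool)
    nonprim = np.zeros(starts.size, dtype=bool)
    for d in _proper_divisors(L):
        span = L - d
        block = max(1, _MAX_GATHER // max(span, 1))
        for lo in range(0, starts.size, block):
            sub = starts[lo : lo + block]
            idx = sub[:, None] + np.arange(span)
            nonprim[lo : lo + block] |= (a[idx] == a[idx + d]).all(axis=1)
    return ~nonprim


def scan_read(read: SequenceRecord, unit_range: tuple[int, int] = (1, 75)
              ) -> list[TandemOccurrence]:
    """All tandem duplications in one read, attributed to canonical units.

    Requires ``2 * unit_range[1] <= len(read)`` so every unit size in the
    range is actually scannable.
    """
    lmin, lmax = unit_range
    if lmin < 1 or lmax < lmin:
        raise ValueError(f"invalid unit range {unit_range}")
    if 2 * lmax > len(read):
        raise ValueError(
            f"read {read.id!r} of length {len(read)} cannot hold a "
            f"duplication of unit size {lmax}")
    seq = read.sequence
    a, valid = _byte_view(seq)
    out: list[TandemOccurrence] = []
    for L in range(lmin, lmax + 1):
        starts, eq = _match_starts(a, valid, L)
        if starts.size == 0:
            continue
        starts = starts[_primitive_mask(a, starts, L)]
        if starts.size == 0:
            continue
        # maximal-run lookup: runs of consecutive True in eq
        padded = np.concatenate(([False], eq, [False]))
        d = np.diff(padded.astype(np.int8))
        run_starts = np.flatnonzero(d == 1)
        run_ends = np.flatnonzero(d == -1)
        for i in starts.tolist():
            r = np.searchsorted(run_starts, i, side="right") - 1
            run_len = int(run_ends[r] - run_starts[r]) + L
            out.append(TandemOccurrence(
                read_id=read.id, start=int(i),
                unit=canonical_unit(seq[i : i + L]),
                unit_length=L, run_length=run_len))
    return out


# -------------------------------------------------------------- batched scan

class _CanonicalCache:
    """Memoized raw-window -> canonical-unit mapping, keyed by numeric code
    for L <= 31 and by string otherwise."""

    def __init__(self) -> None:
        self._by_code: dict[tuple[int, int], str] = {}
        self._by_str: dict[str, str] = {}

    def from_code(self, L: int, code: int) -> str:
        key = (L, code)
        got = self._by_code.get(key)
        if got is None:
            got = canonical_unit(decode_kmer(code, L))
            self._by_code[key] = got
        return got

    def from_str(self, raw: str) -> str:
        got = self._by_str.get(raw)
        if got is None:
            got = canonical_unit(raw)
            self._by_str[raw] = got
        return got


def _window_codes(a2: np.ndarray, starts: np.ndarray, L: int) -> np.ndarray:
    codes = np.zeros(starts.size, dtype=np.uint64)
    for j in range(L):
        codes = (codes << np.uint64(2)) | a2[starts + j].astype(np.uint64)
    return codes


def _scan_chunk(seqs: list[str], lmin: int, lmax: int, cache: _CanonicalCache,
                times: dict[str, int], reads_with: dict[str, int],
                raw_times: dict[str, int] | None = None,
                raw_only_length: int | None = None) -> None:
    from ._seq import encode

    big = "N".join(seqs)
    a, valid = _byte_view(big)
    a2, _ = encode(big)
    lens = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=len(seqs))
    read_starts = np.concatenate(([0], np.cumsum(lens + 1)))[:-1]
    n_chunk = len(seqs)
    lmax_eff = min(lmax, int(lens.max()) // 2)
    for L in range(lmin, lmax_eff + 1):
        if a.size < 2 * L:
            break
        starts, _eq = _match_starts(a, valid, L)
        if starts.size == 0:
            continue
        starts = starts[_primitive_mask(a, starts, L)]
        if starts.size == 0:
            continue
        ridx = np.searchsorted(read_starts, starts, side="right") - 1
        if L <= 31:
            codes = _window_codes(a2, starts, L)
            uniq, inverse, counts = np.unique(codes, return_inverse=True,
                                              return_counts=True)
            canon_strings = [cache.from_code(L, int(c)) for c in uniq]
        else:
            raws = [big[i : i + L] for i in starts.tolist()]
            uniq_raw, inverse, counts = np.unique(raws, return_inverse=True,
                                                  return_counts=True)
            canon_strings = [cache.from_str(r) for r in uniq_raw]
        if raw_times is not None and L == raw_only_length:
            raw_list = ([decode_kmer(int(c), L) for c in uniq] if L <= 31
                        else list(uniq_raw))
            for r, c in zip(raw_list, counts.tolist()):
                raw_times[r] = raw_times.get(r, 0) + int(c)
        # collapse raw windows that share a canonical representative
        canon_index: dict[str, int] = {}
        cid_of_uniq = np.empty(len(canon_strings), dtype=np.int64)
        for j, cs in enumerate(canon_strings):
            cid_of_uniq[j] = canon_index.setdefault(cs, len(canon_index))
        canon_list = list(canon_index)
        cid = cid_of_uniq[inverse]
        tf = np.bincount(cid, minlength=len(canon_list))
        key = cid * n_chunk + ridx
        uk = np.unique(key)
        rw = np.bincount(uk // n_chunk, minlength=len(canon_list))
        for j, cs in enumerate(canon_list):
            times[cs] = times.get(cs, 0) + int(tf[j])
            reads_with[cs] = reads_with.get(cs, 0) + int(rw[j])


def build_catalog(reads: Iterable[SequenceRecord],
                  unit_range: tuple[int, int] = (1, 75),
                  metadata: ReadSetMetadata | None = None,
                  chunk_reads: int = 50_000) -> RepeatCatalog:
    """Aggregate :func:`scan_read` semantics over a whole read set.

    Reads are processed in bounded-memory chunks; the result is invariant
    under read order and under reverse-complementing any subset of reads.
    When *metadata* is omitted it is derived from the reads themselves
    (``read_length`` = maximum observed length; ``genome_size`` unset).
    """
    lmin, lmax = unit_range
    if lmin < 1 or lmax < lmin:
        raise ValueError(f"invalid unit range {unit_range}")
    times: dict[str, int] = {}
    rw: dict[str, int] = {}
    cache = _CanonicalCache()
    total, max_len = 0, 0
    chunk: list[str] = []
    for rec in reads:
        chunk.append(rec.sequence)
        total += 1
        if len(rec.sequence) > max_len:
            max_len = len(rec.sequence)
        if len(chunk) >= chunk_reads:
            _scan_chunk(chunk, lmin, lmax, cache, times, rw)
            chunk = []
    if chunk:
        _scan_chunk(chunk, lmin, lmax, cache, times, rw)
    if metadata is None:
        if total == 0:
            raise ValueError("cannot build a catalog from zero reads without metadata")
        metadata = ReadSetMetadata(total_reads=total, read_length=max_len)
    entries = {u: (times[u], rw[u]) for u in times}
    catalog = RepeatCatalog(entries=entries, metadata=metadata)
    catalog.validate()
    return catalog


def raw_unit_counts(reads: Iterable[SequenceRecord], unit_length: int,
                    chunk_reads: int = 50_000) -> dict[str, int]:
    """Occurrence counts keyed by *raw* (uncanonicalized) unit string at one
    unit length — the input to phased-rotation grouping."""
    raw: dict[str, int] = {}
    times: dict[str, int] = {}
    rw: dict[str, int] = {}
    cache = _CanonicalCache()
    chunk: list[str] = []
    for rec in reads:
        chunk.append(rec.sequence)
        if len(chunk) >= chunk_reads:
            _scan_chunk(chunk, unit_length, unit_length, cache, times, rw,
                        raw_times=raw, raw_only_length=unit_length)
            chunk = []
    if chunk:
        _scan_chunk(chunk, unit_length, unit_length, cache, times, rw,
                    raw_times=raw, raw_only_length=unit_length)
    return raw


# ----------------------------------------------------------- genome scanning

def duplication_window_positions(sequence: str, unit: str) -> np.ndarray:
    """Genomic offsets i with ``seq[i:i+L] == seq[i+L:i+2L]`` whose primitive
    unit canonicalizes to *unit* — the exact planted-truth quantity the
    copy-number estimator targets."""
    rep = canonical_unit(unit)
    L = len(rep)
    if not is_primitive(rep):
        raise ValueError(f"unit {unit!r} is not primitive")
    a, valid = _byte_view(sequence)
    if a.size < 2 * L:
        return np.empty(0, dtype=np.int64)
    starts, _eq = _match_starts(a, valid, L)
    if starts.size == 0:
        return starts
    starts = starts[_primitive_mask(a, starts, L)]
    if starts.size == 0:
        return starts
    cache = _CanonicalCache()
    if L <= 31:
        from ._seq import encode

        a2, _ = encode(sequence)
        codes = _window_codes(a2, starts, L)
        keep = np.fromiter((cache.from_code(L, int(c)) == rep for c in codes),
                           dtype=bool, count=codes.size)
    else:
        keep = np.fromiter(
            (cache.from_str(sequence[i : i + L]) == rep for i in starts.tolist()),
            dtype=bool, count=starts.size)
    return starts[keep]


def genome_window_counts(sequence: str, units: Iterable[str]) -> dict[str, int]:
    """Duplication-window count per canonical unit across a genome."""
    return {canonical_unit(u): int(duplication_window_positions(sequence, u).size)
            for u in units}
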