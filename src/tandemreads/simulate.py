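"""Synthetic genomes, read sets and expression tables with planted truth.

The generator emulates the repeat landscape the pipeline targets: a unique
random background, tandem arrays of short units (telomere-like 10-mers,
12/16-mer derivatives and their composites), and a tandemly repeated rDNA
unit, with a configurable proportion of the tandem arrays placed
immediately adjacent to rDNA blocks (interspersion). Every output is a
pure function of its spec including the seed, and the truth sidecar
records exactly recomputable quantities: duplication-window positions
scanned directly from the emitted genome, per-array intervals, and
noiseless expression effects.

Reads use a substitution-only error model (no indels): the scanning
semantics are exact-match, so substitutions are the error mode that
matters, and exactness keeps the planted truth closed-form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import _DECODE, codes_in_set, encode, kmer_codes, kmer_set, revcomp
from .motifs import count_overlapping, window_sequence
from .records import GeneRecord, ReadSetMetadata, SequenceRecord
from .scan import canonical_unit, duplication_window_positions, is_primitive


# ------------------------------------------------------------------- genomes

@dataclass(frozen=True)
class ArraySpec:
    """One planted tandem array: *copy_count* exact copies of *unit*."""

    unit: str
    copy_count: int

    def __post_init__(self) -> None:
        if self.copy_count < 2:
            raise ValueError("an array needs at least 2 copies")
        if not is_primitive(self.unit):
            raise ValueError(f"array unit {self.unit!r} is not primitive")


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    unique_length: int
    arrays: tuple[ArraySpec, ...]
    rdna_unit: str | None = None
    rdna_copy_count: int = 0
    interleave_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.unique_length <= 0:
            raise ValueError("unique_length must be positive")
        if not 0.0 <= self.interleave_fraction <= 1.0:
            raise ValueError("interleave_fraction must lie in [0, 1]")
        if self.rdna_unit is not None and self.rdna_copy_count < 2:
            raise ValueError("rdna_copy_count must be >= 2 when rdna_unit given")
        object.__setattr__(self, "arrays", tuple(self.arrays))


@dataclass
class TruthSet:
    """Machine-readable planted truth emitted alongside a genome."""

    genome_length: int
    array_intervals: pd.DataFrame   # start, end, unit, copy_count, adjacent_rdna
    rdna_intervals: pd.DataFrame    # start, end, copy_count
    window_positions: dict[str, np.ndarray]
    gene_effects: pd.DataFrame | None = None
    read_provenance: pd.DataFrame | None = None

    def window_count(self, unit: str) -> int:
        return int(self.window_positions[canonical_unit(unit)].size)

    def expected_read_fraction(self, unit: str, read_length: int) -> float:
        rep = canonical_unit(unit)
        return expected_read_fraction(self.genome_length,
                                      self.window_positions[rep],
                                      len(rep), read_length)


def scale_spec(spec: SyntheticGenomeSpec, retention: float,
               seed: int | None = None) -> SyntheticGenomeSpec:
    """Derive a mutant-strain spec retaining a fraction of the repeat
    compartment (array and rDNA copy counts scaled, background unchanged
    when the seed is kept)."""
    if not 0.0 < retention <= 1.0:
        raise ValueError("retention must lie in (0, 1]")
    arrays = tuple(replace(a, copy_count=max(2, round(a.copy_count * retention)))
                   for a in spec.arrays)
    rdna_copies = (max(2, round(spec.rdna_copy_count * retention))
                   if spec.rdna_unit else 0)
    return replace(spec, arrays=arrays, rdna_copy_count=rdna_copies,
                   seed=spec.seed if seed is None else seed)


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return _DECODE[rng.integers(0, 4, n, dtype=np.uint8)].tobytes().decode()


def _resample_collisions(chunk: str, planted: set[str],
                         rng: np.random.Generator) -> str:
    """Resample background windows that accidentally duplicate a planted
    unit, so the truth compartment stays cleanly planted."""
    lengths = sorted({len(u) for u in planted})
    for _ in range(20):
        dirty = False
        for L in lengths:
            units = [u for u in planted if len(u) == L]
            for u in units:
                pos = duplication_window_positions(chunk, u)
                if pos.size:
                    dirty = True
                    s = list(chunk)
                    for p in pos.tolist():
                        repl = _random_bases(rng, 2 * L)
                        s[p : p + 2 * L] = repl
                    chunk = "".join(s)
        if not dirty:
            return chunk
    raise RuntimeError("could not clear background collisions")


def make_genome(spec: SyntheticGenomeSpec) -> tuple[SequenceRecord, TruthSet]:
    """Assemble a genome from the spec and scan its planted truth.

    Deterministic for a fixed seed. The stated ``interleave_fraction`` of
    arrays is placed immediately upstream of an rDNA block; remaining rDNA
    copies form one standalone block. Raises if the layout cannot honor
    the spec (e.g. too few rDNA copies to populate every adjacent block).
    """
    rng = np.random.default_rng(spec.seed)
    n_arr = len(spec.arrays)
    k = round(spec.interleave_fraction * n_arr) if spec.rdna_unit else 0
    interleaved = set(rng.permutation(n_arr)[:k].tolist()) if n_arr else set()

    rdna_block_copies: list[int] = []
    if spec.rdna_unit:
        n_blocks = k + 1
        base = spec.rdna_copy_count // n_blocks
        if base < 2:
            raise ValueError(
                f"rdna_copy_count={spec.rdna_copy_count} too small to fill "
                f"{n_blocks} blocks with >= 2 copies each")
        rdna_block_copies = [base] * k + [spec.rdna_copy_count - base * k]

    # blocks in randomized order: arrays (some fused with an rDNA block),
    # then the standalone rDNA block
    order = rng.permutation(n_arr).tolist()
    blocks: list[tuple[str, list[tuple[str, object]]]] = []
    rdna_i = 0
    for i in order:
        a = spec.arrays[i]
        parts: list[tuple[str, object]] = [("array", a)]
        seq = a.unit * a.copy_count
        if i in interleaved:
            c = rdna_block_copies[rdna_i]
            rdna_i += 1
            seq += spec.rdna_unit * c
            parts.append(("rdna", c))
        blocks.append((seq, parts))
    if spec.rdna_unit:
        c = rdna_block_copies[-1]
        blocks.append((spec.rdna_unit * c, [("rdna", c)]))

    planted = {canonical_unit(a.unit) for a in spec.arrays}
    cuts = np.sort(rng.integers(0, spec.unique_length + 1, len(blocks)))
    bounds = np.concatenate(([0], cuts, [spec.unique_length]))
    bg_lengths = np.diff(bounds)
    background = _random_bases(rng, spec.unique_length)
    chunks = []
    off = 0
    for ln in bg_lengths.tolist():
        chunk = background[off : off + ln]
        if planted and ln > 0:
            chunk = _resample_collisions(chunk, planted, rng)
        chunks.append(chunk)
        off += ln

    pieces: list[str] = []
    pos = 0
    array_rows, rdna_rows = [], []
    for j, (seq, parts) in enumerate(blocks):
        pieces.append(chunks[j])
        pos += len(chunks[j])
        cursor = pos
        adjacent = len(parts) > 1
        for kind, payload in parts:
            if kind == "array":
                a = payload
                end = cursor + len(a.unit) * a.copy_count
                array_rows.append((cursor, end, canonical_unit(a.unit), a.unit,
                                   a.copy_count, adjacent))
                cursor = end
            else:
                c = payload
                end = cursor + len(spec.rdna_unit) * c
                rdna_rows.append((cursor, end, c))
                cursor = end
        pieces.append(seq)
        pos = cursor
    pieces.append(chunks[-1])
    genome = "".join(pieces)

    truth = TruthSet(
        genome_length=len(genome),
        array_intervals=pd.DataFrame(
            array_rows, columns=["start", "end", "unit", "raw_unit",
                                 "copy_count", "adjacent_rdna"]),
        rdna_intervals=pd.DataFrame(rdna_rows,
                                    columns=["start", "end", "copy_count"]),
        window_positions={u: duplication_window_positions(genome, u)
                          for u in planted},
    )
    _assert_truth(spec, truth)
    return SequenceRecord(id=f"synthetic|seed={spec.seed}", sequence=genome), truth


def _assert_truth(spec: SyntheticGenomeSpec, truth: TruthSet) -> None:
    """Planted arrays must account for their interior duplication windows."""
    expected: dict[str, int] = {}
    for a in spec.arrays:
        L = len(a.unit)
        interior = a.copy_count * L - 2 * L + 1
        rep = canonical_unit(a.unit)
        expected[rep] = expected.get(rep, 0) + max(0, interior)
    for rep, n_interior in expected.items():
        found = truth.window_count(rep)
        if found < n_interior:
            raise AssertionError(
                f"truth scan found {found} windows for {rep}, expected >= "
                f"{n_interior} from planted arrays")


def expected_read_fraction(genome_length: int, window_positions: np.ndarray,
                           unit_length: int, read_length: int) -> float:
    """Exact probability that a uniformly placed read (either strand)
    contains at least one duplication window of the unit."""
    if window_positions.size == 0:
        return 0.0
    w = np.sort(np.asarray(window_positions, dtype=np.int64))
    lo = np.maximum(0, w - (read_length - 2 * unit_length))
    hi = np.minimum(genome_length - read_length, w)
    keep = hi >= lo
    lo, hi = lo[keep], hi[keep]
    if lo.size == 0:
        return 0.0
    prev = np.concatenate(([-1], np.maximum.accumulate(hi)[:-1]))
    contrib = np.maximum(0, hi - np.maximum(lo, prev + 1) + 1)
    return float(contrib.sum()) / (genome_length - read_length + 1)


def expected_rdna_read_fraction(genome: str, rdna_unit: str, read_length: int,
                                k: int = 15, threshold: float = 0.5) -> float:
    """Exact probability that a uniformly placed error-free read passes the
    k-mer containment test against the rDNA reference."""
    ref_set = kmer_set(rdna_unit, k)
    codes, ok = kmer_codes(genome, k)
    member = codes_in_set(codes, ref_set) & ok
    m = read_length - k + 1  # k-mers per read
    cs = np.concatenate(([0], np.cumsum(member.astype(np.int64))))
    per_read = cs[m:] - cs[:-m]
    n_starts = len(genome) - read_length + 1
    per_read = per_read[:n_starts]
    return float((per_read >= threshold * m).mean())


# --------------------------------------------------------------------- reads

def _emit_reads(g2: np.ndarray, starts: np.ndarray, lengths: np.ndarray,
                flips: np.ndarray, error_rate: float,
                rng: np.random.Generator, prefix: str
                ) -> tuple[list[SequenceRecord], pd.DataFrame]:
    reads: list[SequenceRecord] = []
    rows = []
    uniform = lengths.min() == lengths.max()
    if uniform:
        R = int(lengths[0])
        mat = g2[starts[:, None] + np.arange(R)]
        rev = mat[flips][:, ::-1]
        mat[flips] = 3 - rev
        if error_rate > 0:
            errs = rng.random(mat.shape) < error_rate
            shift = rng.integers(1, 4, size=mat.shape, dtype=np.uint8)
            mat = np.where(errs, (mat + shift) % 4, mat)
        chars = _DECODE[mat]
        for i in range(starts.size):
            rid = f"{prefix}{i}"
            reads.append(SequenceRecord(id=rid,
                                        sequence=chars[i].tobytes().decode()))
            rows.append((rid, int(starts[i]), int(starts[i]) + R,
                         "-" if flips[i] else "+"))
    else:
        for i in range(starts.size):
            ln = int(lengths[i])
            row = g2[int(starts[i]) : int(starts[i]) + ln].copy()
            if flips[i]:
                row = 3 - row[::-1]
            if error_rate > 0:
                errs = rng.random(ln) < error_rate
                shift = rng.integers(1, 4, size=ln, dtype=np.uint8)
                row = np.where(errs, (row + shift) % 4, row)
            rid = f"{prefix}{i}"
            reads.append(SequenceRecord(id=rid,
                                        sequence=_DECODE[row].tobytes().decode()))
            rows.append((rid, int(starts[i]), int(starts[i]) + ln,
                         "-" if flips[i] else "+"))
    prov = pd.DataFrame(rows, columns=["read_id", "start", "end", "strand"])
    return reads, prov


def simulate_short_reads(genome: SequenceRecord | str, n_reads: int,
                         read_length: int = 150, error_rate: float = 0.0,
                         seed: int = 0
                         ) -> tuple[list[SequenceRecord], ReadSetMetadata,
                                    pd.DataFrame]:
    """Uniformly placed fixed-length reads from either strand with i.i.d.
    substitution errors. Returns (reads, metadata, provenance)."""
    seq = genome.sequence if isinstance(genome, SequenceRecord) else genome
    if read_length > len(seq):
        raise ValueError("read_length exceeds genome length")
    rng = np.random.default_rng(seed)
    g2, _ = encode(seq)
    starts = rng.integers(0, len(seq) - read_length + 1, n_reads)
    flips = rng.random(n_reads) < 0.5
    lengths = np.full(n_reads, read_length, dtype=np.int64)
    reads, prov = _emit_reads(g2, starts, lengths, flips, error_rate, rng, "sr")
    md = ReadSetMetadata(total_reads=n_reads, read_length=read_length,
                         genome_size=len(seq))
    return reads, md, prov


def n_reads_for_coverage(genome_length: int, coverage: float,
                         read_length: int) -> int:
    return int(round(coverage * genome_length / read_length))


@dataclass(frozen=True)
class LongReadLengthModel:
    """Log-normal long-read lengths pinned to a stated median and mean,
    clamped to the observed range."""

    median: float = 2331.0
    mean: float = 3548.0
    min_length: int = 117
    max_length: int = 29910

    def __post_init__(self) -> None:
        if not (0 < self.min_length <= self.median <= self.max_length):
            raise ValueError("inconsistent length model")
        if self.mean <= self.median:
            raise ValueError("log-normal requires mean > median")

    @property
    def mu(self) -> float:
        return math.log(self.median)

    @property
    def sigma(self) -> float:
        return math.sqrt(2.0 * math.log(self.mean / self.median))


def draw_long_read_lengths(n: int, model: LongReadLengthModel,
                           rng: np.random.Generator) -> np.ndarray:
    lengths = rng.lognormal(model.mu, model.sigma, n)
    return np.clip(np.round(lengths), model.min_length,
                   model.max_length).astype(np.int64)


def simulate_long_reads(genome: SequenceRecord | str, n_reads: int,
                        length_model: LongReadLengthModel | None = None,
                        error_rate: float = 0.10, seed: int = 0
                        ) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Uniformly placed variable-length reads with substitution errors."""
    seq = genome.sequence if isinstance(genome, SequenceRecord) else genome
    model = length_model or LongReadLengthModel()
    rng = np.random.default_rng(seed)
    lengths = draw_long_read_lengths(n_reads, model, rng)
    lengths = np.minimum(lengths, len(seq))
    g2, _ = encode(seq)
    starts = rng.integers(0, len(seq) - lengths + 1)
    flips = rng.random(n_reads) < 0.5
    return _emit_reads(g2, starts, lengths, flips, error_rate, rng, "lr")


def cooccurrence_truth(genome: SequenceRecord | str, n_reads: int,
                       units: Sequence[str], rdna: SequenceRecord, *,
                       length_model: LongReadLengthModel | None = None,
                       error_rate: float = 0.10, seed: int = 0,
                       min_hits: int = 3, k: int = 15,
                       containment_threshold: float = 0.10
                       ) -> dict[str, float | None]:
    """Generator truth for the repeat/rDNA co-occurrence fraction.

    The noisy classifier with containment threshold t effectively asks an
    error-free read for ``t / (1-e)**k`` containment, because only k-mers
    with all k bases uncorrupted can match the reference. The truth is
    therefore the classification of the *error-free twin* read set (same
    seed, hence identical positions/strands/lengths) at that adjusted
    threshold — the quantity the noisy pipeline estimates.
    """
    from .longread import cooccurrence

    clean, _ = simulate_long_reads(genome, n_reads, length_model,
                                   error_rate=0.0, seed=seed)
    t_adj = containment_threshold / (1.0 - error_rate) ** k
    results = cooccurrence(clean, units, rdna, min_hits=min_hits, k=k,
                           containment_threshold=t_adj)
    return {r.unit: r.fraction for r in results}


# ---------------------------------------------------------- genes/expression

def make_genes(genome_length: int, n_genes: int, seed: int = 0,
               margin: int = 2200, seq_id: str = "chr1") -> list[GeneRecord]:
    """Random distinct TSS positions with random strands, kept *margin*
    away from contig ends so the default window grid never truncates."""
    rng = np.random.default_rng(seed)
    span = genome_length - 2 * margin
    if span < n_genes:
        raise ValueError("genome too short for requested gene count")
    pos = np.sort(rng.choice(span, size=n_genes, replace=False)) + margin
    strands = rng.integers(0, 2, n_genes)
    width = len(str(n_genes))
    return [GeneRecord(gene_id=f"g{i:0{width}d}", seq_id=seq_id,
                       tss=int(p), strand="+-"[int(s)])
            for i, (p, s) in enumerate(zip(pos, strands))]


@dataclass(frozen=True)
class MotifEffect:
    """Additive expression effect per capped motif site in a TSS window."""

    motif: str
    effect_per_site: float = -0.5
    extent: int = 1000
    direction: str = "upstream"
    cap: int = 2


def simulate_expression(genome: Mapping[str, str],
                        genes: Sequence[GeneRecord],
                        effects: Sequence[MotifEffect],
                        noise_sd: float = 0.3, seed: int = 0
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene log2 fold changes driven by planted motif-count effects.

    delta(gene) = sum over effects of effect_per_site * (capped plus count
    + capped minus count in the effect window) + N(0, noise_sd). Returns
    (expression table, truth) where truth records per-effect capped counts
    and the noiseless delta.
    """
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    for gene in genes:
        noiseless = 0.0
        counts: dict[str, int] = {}
        for eff in effects:
            seq = window_sequence(genome, gene, eff.extent, eff.direction)
            plus = min(eff.cap, count_overlapping(seq, eff.motif))
            minus = min(eff.cap, count_overlapping(seq, revcomp(eff.motif)))
            counts[f"{eff.motif}_plus"] = plus
            counts[f"{eff.motif}_minus"] = minus
            noiseless += eff.effect_per_site * (plus + minus)
        delta = noiseless + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        rows.append((gene.gene_id, delta))
        truth_rows.append({"gene_id": gene.gene_id, **counts,
                           "noiseless_delta": noiseless, "delta": delta})
    expr = pd.DataFrame(rows, columns=["gene_id", "log2fc"])
    return expr, pd.DataFrame(truth_rows)
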