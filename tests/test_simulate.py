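import numpy as np
import pandas as pd
import pytest

from tandemreads.records import GeneRecord, SequenceRecord
from tandemreads.simulate import (ArraySpec, LongReadLengthModel, MotifEffect,
                                  SyntheticGenomeSpec, _random_bases,
                                  cooccurrence_truth, draw_long_read_lengths,
                                  expected_read_fraction, make_genes,
                                  make_genome, n_reads_for_coverage,
                                  scale_spec, simulate_expression,
                                  simulate_long_reads, simulate_short_reads)
from tandemreads._seq import revcomp

from oracles import brute_force_scan

UNIT = "TTAGTCAGGG"


def spec_10mer(copies=50, unique=20_000, seed=5, **kw):
    return SyntheticGenomeSpec(unique_length=unique,
                               arrays=(ArraySpec(UNIT, copies),), seed=seed,
                               **kw)


class TestMakeGenome:
    def test_length_arithmetic(self):
        genome, truth = make_genome(spec_10mer())
        assert truth.genome_length == 20_000 + 50 * 10
        assert len(genome.sequence) == truth.genome_length

    def test_determinism(self):
        a, ta = make_genome(spec_10mer())
        b, tb = make_genome(spec_10mer())
        assert a.sequence == b.sequence
        assert ta.array_intervals.equals(tb.array_intervals)

    def test_truth_windows_match_brute_force(self):
        genome, truth = make_genome(spec_10mer(copies=20, unique=3_000))
        want = [s for s, L, u, _ in brute_force_scan(genome.sequence, 10, 10)
                if u == "AACCCTGACT"]
        assert truth.window_positions["AACCCTGACT"].tolist() == want

    def test_full_interleaving_puts_every_array_next_to_rdna(self, rng):
        rdna = _random_bases(rng, 300)
        spec = SyntheticGenomeSpec(
            unique_length=30_000,
            arrays=tuple(ArraySpec(UNIT, 30) for _ in range(5)),
            rdna_unit=rdna, rdna_copy_count=40, interleave_fraction=1.0,
            seed=9)
        genome, truth = make_genome(spec)
        assert truth.array_intervals["adjacent_rdna"].all()
        rdna_starts = set(truth.rdna_intervals["start"])
        for end in truth.array_intervals["end"]:
            assert end in rdna_starts

    def test_background_free_of_planted_duplications(self):
        genome, truth = make_genome(spec_10mer(copies=30, unique=50_000))
        arr = truth.array_intervals.iloc[0]
        pos = truth.window_positions["AACCCTGACT"]
        # every truth window sits at (or within one unit of) the array
        assert ((pos >= arr.start - 10) & (pos <= arr.end)).all()

    def test_mutant_scaling(self):
        base = spec_10mer(copies=100)
        mut = scale_spec(base, 0.2)
        assert mut.arrays[0].copy_count == 20
        g_base, _ = make_genome(base)
        g_mut, _ = make_genome(mut)
        # same background, smaller repeat compartment
        assert len(g_base.sequence) - len(g_mut.sequence) == 800

    def test_too_small_rdna_rejected(self, rng):
        with pytest.raises(ValueError, match="rdna_copy_count"):
            make_genome(SyntheticGenomeSpec(
                unique_length=10_000,
                arrays=tuple(ArraySpec(UNIT, 10) for _ in range(4)),
                rdna_unit=_random_bases(rng, 100), rdna_copy_count=4,
                interleave_fraction=1.0, seed=1))


class TestShortReads:
    def test_error_free_reads_are_genome_substrings(self):
        genome, _ = make_genome(spec_10mer())
        reads, md, prov = simulate_short_reads(genome, 500, 100, 0.0, seed=2)
        assert md.total_reads == 500 and md.read_length == 100
        for rec, row in zip(reads[:50], prov.itertuples()):
            sub = genome.sequence[row.start:row.end]
            assert rec.sequence == (sub if row.strand == "+" else revcomp(sub))

    def test_determinism(self):
        genome, _ = make_genome(spec_10mer())
        a = simulate_short_reads(genome, 100, 100, 0.05, seed=3)[0]
        b = simulate_short_reads(genome, 100, 100, 0.05, seed=3)[0]
        assert [r.sequence for r in a] == [r.sequence for r in b]

    def test_empirical_error_rate(self):
        genome, _ = make_genome(spec_10mer())
        reads, _, prov = simulate_short_reads(genome, 10_000, 100, 0.01, seed=4)
        mismatches = total = 0
        for rec, row in zip(reads, prov.itertuples()):
            sub = genome.sequence[row.start:row.end]
            if row.strand == "-":
                sub = revcomp(sub)
            mismatches += sum(a != b for a, b in zip(rec.sequence, sub))
            total += len(sub)
        assert mismatches / total == pytest.approx(0.01, rel=0.10)

    def test_coverage_identity(self):
        genome, truth = make_genome(spec_10mer(unique=30_000))
        n = n_reads_for_coverage(truth.genome_length, 10, 150)
        reads, _, prov = simulate_short_reads(genome, n, 150, 0.0, seed=5)
        diff = np.zeros(truth.genome_length + 1)
        np.add.at(diff, prov["start"], 1)
        np.add.at(diff, prov["end"], -1)
        cover = np.cumsum(diff)[:-1]
        # interior mean depth within 5% of nominal (edges undersampled)
        assert cover[150:-150].mean() == pytest.approx(10.0, rel=0.05)


class TestLongReads:
    def test_length_model_median_and_range(self, rng):
        lens = draw_long_read_lengths(10_000, LongReadLengthModel(), rng)
        assert np.median(lens) == pytest.approx(2331, rel=0.05)
        assert lens.min() >= 117 and lens.max() <= 29_910

    def test_error_free_reads_are_substrings(self):
        genome, _ = make_genome(spec_10mer(unique=60_000))
        reads, prov = simulate_long_reads(genome, 50, error_rate=0.0, seed=6)
        for rec, row in zip(reads, prov.itertuples()):
            sub = genome.sequence[row.start:row.end]
            assert rec.sequence == (sub if row.strand == "+" else revcomp(sub))

    def test_noisy_and_clean_twins_share_provenance(self):
        genome, _ = make_genome(spec_10mer(unique=60_000))
        _, pa = simulate_long_reads(genome, 200, error_rate=0.0, seed=7)
        _, pb = simulate_long_reads(genome, 200, error_rate=0.10, seed=7)
        assert pa.equals(pb)

    def test_model_requires_mean_above_median(self):
        with pytest.raises(ValueError):
            LongReadLengthModel(median=3000, mean=2000)


class TestExpression:
    def grid_genome(self, rng):
        genome = {"chr1": _random_bases(rng, 200_000)}
        genes = make_genes(200_000, 300, seed=8)
        return genome, genes

    def test_noiseless_delta_counts_sites(self, rng):
        genome, genes = self.grid_genome(rng)
        expr, truth = simulate_expression(
            genome, genes, [MotifEffect("CCCCT", -0.5)], noise_sd=0.0, seed=9)
        expected = -0.5 * (truth["CCCCT_plus"] + truth["CCCCT_minus"])
        assert np.allclose(truth["noiseless_delta"], expected)
        assert np.allclose(expr["log2fc"], truth["noiseless_delta"])

    def test_null_model_is_pure_noise(self, rng):
        genome, genes = self.grid_genome(rng)
        # strip the motif from both strands: planted effect vanishes
        seq = genome["chr1"]
        for m in ("CCCCT", "AGGGG"):
            while m in seq:
                seq = seq.replace(m, "ACTAG", 1)
        expr, truth = simulate_expression(
            {"chr1": seq}, genes, [MotifEffect("CCCCT", -0.5)],
            noise_sd=0.3, seed=10)
        assert (truth["noiseless_delta"] == 0.0).all()
        deltas = expr["log2fc"].to_numpy()
        assert abs(deltas.mean()) < 4 * 0.3 / np.sqrt(len(deltas))
        assert np.std(deltas) == pytest.approx(0.3, rel=0.2)

    def test_determinism(self, rng):
        genome, genes = self.grid_genome(rng)
        a = simulate_expression(genome, genes, [MotifEffect("CCCCT")], seed=11)
        b = simulate_expression(genome, genes, [MotifEffect("CCCCT")], seed=11)
        assert a[0].equals(b[0]) and a[1].equals(b[1])


class TestExpectedReadFraction:
    def test_matches_direct_enumeration(self):
        genome, truth = make_genome(spec_10mer(copies=20, unique=5_000))
        R = 150
        pos = truth.window_positions["AACCCTGACT"]
        n_starts = truth.genome_length - R + 1
        hit = 0
        pos_set = pos
        for p in range(n_starts):
            if ((pos_set >= p) & (pos_set + 20 <= p + R)).any():
                hit += 1
        assert truth.expected_read_fraction(UNIT, R) == \
            pytest.approx(hit / n_starts)
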