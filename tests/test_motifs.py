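import numpy as np
import pandas as pd
import pytest

from tandemreads.motifs import (build_count_matrix, count_motif_window,
                                count_overlapping, profile_expression,
                                window_sequence)
from tandemreads.records import (ExpressionDelta, GeneRecord, MotifSpec,
                                 WindowGrid)
from tandemreads.simulate import _random_bases
from tandemreads._seq import revcomp

from oracles import count_substring_ref

ACGCG = MotifSpec("ACGCG")
CCCCT = MotifSpec("CCCCT")


def plant(genome: str, pos: int, what: str) -> str:
    return genome[:pos] + what + genome[pos + len(what):]


@pytest.fixture
def blank_genome(rng):
    # neutral background guaranteed free of the tracked 5-mers
    seq = _random_bases(rng, 10_000)
    for m in ("ACGCG", "CGCGT", "CCCCT", "AGGGG"):
        while m in seq:
            seq = seq.replace(m, "ACTAG", 1)
    return {"chr1": seq}


class TestWindowSequence:
    def test_plus_strand_windows(self, blank_genome):
        gene = GeneRecord("g", "chr1", 5000, "+")
        down = window_sequence(blank_genome, gene, 200, "downstream")
        up = window_sequence(blank_genome, gene, 200, "upstream")
        assert down == blank_genome["chr1"][5000:5200]
        assert up == blank_genome["chr1"][4800:5000]

    def test_minus_strand_windows_are_mirrored(self, blank_genome):
        gene = GeneRecord("g", "chr1", 5000, "-")
        down = window_sequence(blank_genome, gene, 200, "downstream")
        up = window_sequence(blank_genome, gene, 200, "upstream")
        assert down == revcomp(blank_genome["chr1"][4801:5001])
        assert up == revcomp(blank_genome["chr1"][5001:5201])

    def test_truncated_at_contig_edge(self, blank_genome):
        gene = GeneRecord("g", "chr1", 50, "+")
        assert len(window_sequence(blank_genome, gene, 200, "upstream")) == 50

    def test_unknown_contig_rejected(self, blank_genome):
        with pytest.raises(KeyError):
            window_sequence(blank_genome, GeneRecord("g", "chrX", 0, "+"),
                            200, "downstream")


class TestCountMotifWindow:
    def test_planted_plus_motif(self, blank_genome):
        # A guards prevent the insertion junction from spelling CGCGT
        genome = {"chr1": plant(blank_genome["chr1"], 5100, "AACGCGA")}
        gene = GeneRecord("g", "chr1", 5000, "+")
        cell = count_motif_window(genome, gene, ACGCG, 200, "downstream")
        assert (cell.plus_count, cell.minus_count) == (1, 0)

    def test_planted_opposite_strand_motif(self, blank_genome):
        genome = {"chr1": plant(blank_genome["chr1"], 5100, "GCGCGTG")}
        gene = GeneRecord("g", "chr1", 5000, "+")
        cell = count_motif_window(genome, gene, ACGCG, 200, "downstream")
        assert (cell.plus_count, cell.minus_count) == (0, 1)

    def test_cap_applied(self, blank_genome):
        seq = blank_genome["chr1"]
        for pos in (5020, 5060, 5100):
            seq = plant(seq, pos, "CCCCT")
        gene = GeneRecord("g", "chr1", 5000, "+")
        cell = count_motif_window({"chr1": seq}, gene, CCCCT, 200,
                                  "downstream", cap=2)
        assert cell.plus_count == 2

    def test_overlap_counting_matches_naive_oracle(self, rng):
        # C-rich sequences exercise overlapping CCCCT starts
        for _ in range(50):
            seq = "".join("CCCT"[i] for i in rng.integers(0, 4, 60))
            assert count_overlapping(seq, "CCCCT") == \
                count_substring_ref(seq, "CCCCT")
        assert count_overlapping("CCCCCCT", "CCCCT") == 1
        assert count_overlapping("CCCCTCCCCT", "CCCCT") == 2

    def test_minus_strand_gene_registers_upstream_motif(self, blank_genome):
        # motif planted 150 bp 5' of the TSS in transcription orientation
        # of a minus-strand gene sits at larger forward coordinates
        genome = {"chr1": plant(blank_genome["chr1"], 5150, revcomp("ACGCG"))}
        gene = GeneRecord("g", "chr1", 5000, "-")
        up = count_motif_window(genome, gene, ACGCG, 200, "upstream")
        down = count_motif_window(genome, gene, ACGCG, 200, "downstream")
        assert up.plus_count == 1 and down.plus_count == 0


class TestCountMatrix:
    def test_cardinality(self, blank_genome, rng):
        genes = [GeneRecord(f"g{i}", "chr1", int(p), "+-"[int(s)])
                 for i, (p, s) in enumerate(zip(rng.integers(2000, 8000, 10),
                                                rng.integers(0, 2, 10)))]
        cells = build_count_matrix(blank_genome, genes, CCCCT, WindowGrid())
        assert len(cells) == 10 * 10 * 2

    def test_counts_nested_in_extent(self, rng):
        genome = {"chr1": _random_bases(rng, 30_000)}
        genes = [GeneRecord(f"g{i}", "chr1", int(p), "+-"[i % 2])
                 for i, p in enumerate(rng.integers(2500, 27_000, 30))]
        cells = build_count_matrix(genome, genes, CCCCT, WindowGrid(), cap=99)
        for (g, d), sub in cells.groupby(["gene_id", "direction"]):
            sub = sub.sort_values("extent")
            assert sub["plus_count"].is_monotonic_increasing
            assert sub["minus_count"].is_monotonic_increasing

    def test_strand_duality(self, rng):
        genome = {"chr1": _random_bases(rng, 30_000)}
        genes = [GeneRecord(f"g{i}", "chr1", int(p), "+-"[i % 2])
                 for i, p in enumerate(rng.integers(2500, 27_000, 20))]
        a = build_count_matrix(genome, genes, MotifSpec("ACGCG"), WindowGrid())
        b = build_count_matrix(genome, genes, MotifSpec(revcomp("ACGCG")),
                               WindowGrid())
        merged = a.merge(b, on=["gene_id", "extent", "direction"])
        assert (merged["plus_count_x"] == merged["minus_count_y"]).all()
        assert (merged["minus_count_x"] == merged["plus_count_y"]).all()

    def test_uncapped_whole_contig_equals_naive_count(self, rng):
        seq = _random_bases(rng, 4000)
        genome = {"chr1": seq}
        gene = GeneRecord("g", "chr1", 0, "+")
        grid = WindowGrid(extents=(4000,), directions=("downstream",))
        cells = build_count_matrix(genome, [gene], CCCCT, grid, cap=10**9)
        assert cells.loc[0, "plus_count"] == count_substring_ref(seq, "CCCCT")
        assert cells.loc[0, "minus_count"] == \
            count_substring_ref(seq, revcomp("CCCCT"))

    def test_duplicate_gene_ids_rejected(self, blank_genome):
        genes = [GeneRecord("g", "chr1", 5000, "+"),
                 GeneRecord("g", "chr1", 6000, "+")]
        with pytest.raises(ValueError, match="unique"):
            build_count_matrix(blank_genome, genes, CCCCT)


class TestProfileExpression:
    def cells_for(self, counts):
        rows = [(f"g{i}", 200, "downstream", c, 0) for i, c in enumerate(counts)]
        return pd.DataFrame(rows, columns=["gene_id", "extent", "direction",
                                           "plus_count", "minus_count"])

    def test_all_zero_deltas_give_zero_means(self):
        cells = self.cells_for([0, 1, 2, 1])
        deltas = [ExpressionDelta(f"g{i}", 0.0) for i in range(4)]
        prof = profile_expression(cells, deltas)
        assert (prof.loc[prof.n_genes > 0, "mean_delta"] == 0.0).all()

    def test_constructed_group_means(self):
        cells = self.cells_for([0, 0, 1, 2])
        deltas = [ExpressionDelta("g0", 0.0), ExpressionDelta("g1", 0.0),
                  ExpressionDelta("g2", -1.0), ExpressionDelta("g3", -1.0)]
        prof = profile_expression(cells, deltas).set_index(
            ["plus_count", "minus_count"])
        assert prof.loc[(0, 0), "mean_delta"].item() == 0.0
        assert prof.loc[(1, 0), "mean_delta"].item() == -1.0
        assert prof.loc[(2, 0), "mean_delta"].item() == -1.0

    def test_group_sizes_sum_to_gene_count(self):
        cells = self.cells_for([0, 1, 2, 2, 1])
        deltas = [ExpressionDelta(f"g{i}", float(i)) for i in range(5)]
        prof = profile_expression(cells, deltas)
        assert prof["n_genes"].sum() == 5

    def test_full_grid_emitted_with_empty_categories(self):
        cells = self.cells_for([0])
        prof = profile_expression(cells, [ExpressionDelta("g0", 1.0)], cap=2)
        assert len(prof) == (2 + 1) ** 2
        empty = prof[prof.n_genes == 0]
        assert empty["mean_delta"].isna().all()

    def test_disjoint_gene_sets_rejected(self):
        cells = self.cells_for([0])
        with pytest.raises(ValueError, match="no genes shared"):
            profile_expression(cells, [ExpressionDelta("other", 1.0)])
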