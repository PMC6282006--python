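#!/usr/bin/env python
"""Simulate the study system: a wild-type genome whose repeat compartment
holds a telomere-like 10-mer array, 12-mer and 12+16-mer composite arrays
interspersed with rDNA blocks; four mutant strains retaining 80/50/50/20%
of that compartment; short reads per strain; long reads from the wild
type; genes and a motif-driven expression table.

Sequence data land under scratch/ (large, regenerable); planted-truth
tables land under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tandemreads import io as trio
from tandemreads.records import SequenceRecord
from tandemreads.simulate import (ArraySpec, MotifEffect, SyntheticGenomeSpec,
                                  _random_bases, make_genes, make_genome,
                                  n_reads_for_coverage, scale_spec,
                                  simulate_expression, simulate_long_reads,
                                  simulate_short_reads)

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"

UNIT10 = "TTAGTCAGGG"
UNIT12 = "TTGACGAGGCAC"
UNIT16 = "TTGACGAGGCGCGTGC"
RETENTIONS = {"wt": 1.0, "m80": 0.8, "m50a": 0.5, "m50b": 0.5, "m20": 0.2}
SEED = 20181205 % 10_000


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    rdna_unit = _random_bases(rng, 600)
    (SCRATCH / "rdna.fasta").write_text(f">rdna\n{rdna_unit}\n")

    base = SyntheticGenomeSpec(
        unique_length=400_000,
        arrays=(ArraySpec(UNIT10, 300), ArraySpec(UNIT12, 150),
                ArraySpec(UNIT12 + UNIT16, 80)),
        rdna_unit=rdna_unit, rdna_copy_count=60,
        interleave_fraction=0.5, seed=SEED + 1)

    truth_rows = []
    for i, (name, ret) in enumerate(RETENTIONS.items()):
        spec = base if ret == 1.0 else scale_spec(base, ret)
        genome, truth = make_genome(spec)
        genome = SequenceRecord("chr1", genome.sequence)
        trio.write_sequences([genome], SCRATCH / f"genome_{name}.fasta")
        n = n_reads_for_coverage(truth.genome_length, 10, 150)
        reads, md, _ = simulate_short_reads(genome, n, 150, 0.0,
                                            seed=SEED + 10 + i)
        trio.write_sequences(reads, SCRATCH / f"reads_{name}.fastq")
        for unit in (UNIT10, UNIT12, UNIT12 + UNIT16):
            truth_rows.append({
                "strain": name, "retention": ret, "unit": unit,
                "genome_length": truth.genome_length, "n_reads": n,
                "truth_windows": truth.window_count(unit),
                "truth_read_fraction": truth.expected_read_fraction(unit, 150),
            })
        print(f"{name}: genome {truth.genome_length:,} bp, {n:,} reads "
              f"(retention {ret})")

    pd.DataFrame(truth_rows).pipe(trio.write_report,
                                  RESULTS / "planted_truth.tsv")

    # long reads from the wild type for the co-occurrence analysis
    wt_genome = trio.read_sequences(SCRATCH / "genome_wt.fasta")[0]
    longreads, _ = simulate_long_reads(wt_genome, 1000, error_rate=0.10,
                                       seed=SEED + 30)
    trio.write_sequences(longreads, SCRATCH / "longreads_wt.fasta")
    print(f"long reads: {len(longreads)} (10% substitution error)")

    # genes + expression: CCCCT sites near the TSS depress expression
    genes = make_genes(len(wt_genome.sequence), 400, seed=SEED + 40)
    trio.write_gene_annotations(genes, SCRATCH / "genes.gff3")
    expr, gene_truth = simulate_expression(
        {"chr1": wt_genome.sequence}, genes,
        [MotifEffect("CCCCT", -0.5, extent=1000, direction="upstream")],
        noise_sd=0.3, seed=SEED + 41)
    expr.pipe(trio.write_report, SCRATCH / "expression.tsv")
    gene_truth.pipe(trio.write_report, RESULTS / "gene_effect_truth.tsv")
    print(f"expression: {len(expr)} genes, planted effect -0.5 per CCCCT site")


if __name__ == "__main__":
    main()
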