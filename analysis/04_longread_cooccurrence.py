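#!/usr/bin/env python
"""Classify the noisy wild-type long reads for tandem-repeat content and
rDNA membership, and measure how often they co-occur on the same read.
With half of the planted arrays placed adjacent to rDNA blocks, a
substantial share of repeat-carrying reads should also pass the rDNA
k-mer containment test — the signature of repeats interspersed with the
rDNA locus.

Requires: analysis/01_simulate_study.py.
Writes: results/cooccurrence.tsv.
"""

import sys
from pathlib import Path

from tandemreads import io as trio
from tandemreads import pipeline
from tandemreads.records import SequenceRecord
from tandemreads.scan import canonical_unit
from tandemreads.simulate import cooccurrence_truth

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"

UNIT10 = "TTAGTCAGGG"
UNIT12 = "TTGACGAGGCAC"
UNIT16 = "TTGACGAGGCGCGTGC"
SEED = 20181205 % 10_000  # matches the read seed in 01_simulate_study


def main() -> None:
    if not (SCRATCH / "longreads_wt.fasta").exists():
        sys.exit("run analysis/01_simulate_study.py first")
    units = [UNIT10, UNIT12, UNIT12 + UNIT16]
    cfg = pipeline.CooccurConfig(
        long_reads=str(SCRATCH / "longreads_wt.fasta"), units=units,
        rdna_fasta=str(SCRATCH / "rdna.fasta"), outdir=str(RESULTS))
    table = pipeline.run_cooccur(cfg)
    print("per-unit co-occurrence of repeat content and rDNA membership:")
    print(table.round(3).to_string(index=False))

    genome = trio.read_sequences(SCRATCH / "genome_wt.fasta")[0]
    rdna = trio.read_sequences(SCRATCH / "rdna.fasta")[0]
    truth = cooccurrence_truth(genome, 1000, units, rdna,
                               error_rate=0.10, seed=SEED + 30)
    print("\ngenerator truth (error-free twins, error-adjusted threshold):")
    for u in units:
        t = truth[canonical_unit(u)]
        print(f"  {canonical_unit(u)}: "
              + ("undefined" if t is None else f"{t:.3f}"))


if __name__ == "__main__":
    main()
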