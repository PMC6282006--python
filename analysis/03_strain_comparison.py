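#!/usr/bin/env python
"""Compare repeat and rDNA read content across the five strains. Each
mutant's fraction-of-reads ratio to wild type should track its planted
repeat-compartment retention (0.8 / 0.5 / 0.5 / 0.2), for the tandem
units and the rDNA alike — the reference-genome-agnostic signature of a
shared repeat-compartment loss.

Requires: analysis/01_simulate_study.py.
Writes: results/strain_comparison.tsv (via the repeat-profile pipeline).
"""

import sys
from pathlib import Path

from tandemreads import io as trio
from tandemreads import pipeline

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"

UNIT10 = "TTAGTCAGGG"
UNIT12 = "TTGACGAGGCAC"
UNIT16 = "TTGACGAGGCGCGTGC"
STRAINS = ["wt", "m80", "m50a", "m50b", "m20"]


def main() -> None:
    if not (SCRATCH / "reads_wt.fastq").exists():
        sys.exit("run analysis/01_simulate_study.py first")
    cfg = pipeline.RepeatProfileConfig(
        strains=[pipeline.StrainInput(s, [str(SCRATCH / f"reads_{s}.fastq")])
                 for s in STRAINS],
        reference_strain="wt", outdir=str(RESULTS),
        reference_fasta=str(SCRATCH / "genome_wt.fasta"),
        rdna_fasta=str(SCRATCH / "rdna.fasta"),
        tracked_units=[UNIT10, UNIT12, UNIT12 + UNIT16])
    comp = pipeline.run_repeat_profile(cfg)
    print("fractions of reads containing each repeat family (and rDNA), "
          "with ratio to wild type:")
    print(comp.round(4).to_string(index=False))
    truth = trio.read_report(RESULTS / "planted_truth.tsv")
    wt = truth[truth.strain == "wt"].set_index("unit")["truth_read_fraction"]
    print("\nplanted truth ratios (exact, from the truth genomes):")
    for s in STRAINS[1:]:
        rows = truth[truth.strain == s].set_index("unit")
        ratios = (rows["truth_read_fraction"] / wt).round(3)
        print(f"  {s}: " + ", ".join(f"{u[:10]}…={r}" if len(u) > 10
                                     else f"{u}={r}"
                                     for u, r in ratios.items()))


if __name__ == "__main__":
    main()
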