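#!/usr/bin/env python
"""Profile mean differential expression by capped CCCCT (STRE) counts on
each strand in nested TSS windows. With a planted effect of -0.5 per
upstream site, category means at the effect window should fall by ~0.5
per additional site — the promoter-motif/expression coupling the
pipeline is built to expose.

Requires: analysis/01_simulate_study.py.
Writes: results/motif_profile.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from tandemreads import io as trio
from tandemreads import pipeline

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"


def main() -> None:
    if not (SCRATCH / "expression.tsv").exists():
        sys.exit("run analysis/01_simulate_study.py first")
    cfg = pipeline.MotifProfileConfig(
        genome_fasta=str(SCRATCH / "genome_wt.fasta"),
        genes=str(SCRATCH / "genes.gff3"),
        expression=str(SCRATCH / "expression.tsv"),
        motifs=["CCCCT", "ACGCG"], outdir=str(RESULTS))
    table = pipeline.run_motif_profile(cfg)

    at = table[(table.motif == "CCCCT") & (table.extent == 1000)
               & (table.direction == "upstream") & (table.n_genes > 0)].copy()
    at["total_sites"] = at.plus_count + at.minus_count
    by_total = at.groupby("total_sites").apply(
        lambda d: pd.Series({"n_genes": d.n_genes.sum(),
                             "mean_delta": np.average(d.mean_delta,
                                                      weights=d.n_genes)}),
        include_groups=False)
    print("CCCCT, upstream 1000 bp window: mean log2FC by total site count")
    print(by_total.round(3).to_string())
    x = by_total.index.to_numpy(dtype=float)
    y = by_total["mean_delta"].to_numpy()
    w = by_total["n_genes"].to_numpy()
    xbar = np.average(x, weights=w)
    slope = np.average((x - xbar) * y, weights=w) / \
        np.average((x - xbar) ** 2, weights=w)
    print(f"\nestimated effect per site: {slope:+.3f} (planted -0.5)")


if __name__ == "__main__":
    main()
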