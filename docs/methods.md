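# Methods

## Tandem-duplication scanning

A read contains a tandem duplication of unit size L at offset i when
`read[i:i+L] == read[i+L:i+2L]` exactly. Matching is exact by design: the
scan runs on raw short reads, and substitution errors only deflate counts
(approximately uniformly across strains at equal platform error), they do
not shift which unit is seen. Windows containing `N` are skipped whole —
no partial credit — so masked bases can never fabricate or split a unit.

Unit sizes 1–75 bp are scanned by default because a duplication needs
`2L <= read_length` and the nominal short-read length is 150 bp; the
bound is configurable for other read lengths (`scan_read` refuses a range
the read cannot hold).

Two suppression rules keep the catalog meaningful:

* **Primitivity.** A window whose unit is a whole-number power of a
  shorter unit (`ATAT`, `AAA`) is counted only at the primitive unit
  length. Without this, every homopolymer run would be recounted at every
  divisor length.
* **Canonicalization.** Each occurrence is attributed to the
  lexicographically least string among the 2L rotations of the unit and
  of its reverse complement. All phases of an array and both sequencing
  strands therefore share one catalog entry. Canonicalization is
  idempotent and total (strings are totally ordered, so no tie-break is
  ever needed).

Two counts are kept per canonical unit, because they answer different
questions: `times_found` (distinct duplication start positions summed
over reads) scales with total array length and feeds the copy-number
estimator; `reads_with` (reads containing at least one occurrence) is
the per-read presence statistic used for strain-to-strain fractions. The
implementation batches reads into one `N`-separated buffer and runs the
per-L scan vectorized; a per-read reference path exists and the suite
asserts exact agreement between the two and against an independent
double-loop oracle.

## Copy-number normalization

```
copy_number = times_found * genome_size
              / (total_reads * (read_length - repeat_length + 1))
```

The denominator counts the offsets at which one read can fully sample a
pattern of `repeat_length` bases, so the ratio converts hit totals into
genomic pattern counts. `repeat_length` defaults to the duplication
window `2L` — that is the object actually searched for, and with it the
estimator targets the genome's duplication-window count, an exactly
recomputable quantity on synthetic truth. A mode switch uses the bare
unit length `L` for sensitivity analysis (it changes only the sampling
term, i.e. a factor `(R-L+1)/(R-2L+1)`). `genome_size` has no default; it
must be supplied or summed from a reference FASTA. The estimate is exact
in expectation up to an edge factor `genome_size/(genome_size - read_length + 1)`
from reads near contig ends (~0.015% at 1 Mb), far below the sampling
noise at desk scale.

## Phased rotations and composite units

Reads sampling a long array enter it at every phase equally often, so
the raw (uncanonicalized) counts of a unit's rotations are near-equal;
a single isolated duplication shows one phase only. A rotation class is
flagged `array_inferred` when at least two phases were observed and the
max/min count ratio is at most 2. The threshold is a deliberate default
for an unquantified notion of "similar coverage": 2 tolerates binomial
noise at moderate counts while rejecting order-of-magnitude imbalance.

Composite units are decomposed by exact tiling: every rotation of the
unit *and of its reverse complement* is searched for a concatenation of
the given component strings (components are used as written, not
rotated). Both frames must be searched because canonical representatives
of the composite and of its components can sit on opposite strands. The
tiling with the fewest components wins; ties break to the
lexicographically least component sequence, making the result
deterministic. Components no shorter than the unit are simply unusable
and yield an empty decomposition rather than an error.

## rDNA membership and long-read co-occurrence

rDNA membership is decided without an aligner: the fraction of a read's
k-mers (k = 15 by default) present in the rDNA reference on either
strand, thresholded at 0.10. The arithmetic behind the defaults: at a
long-read substitution rate e, a k-mer survives intact with probability
`(1-e)^k` (~0.21 at e = 0.10), so a read drawn mostly from rDNA scores
~0.2 and clears the 0.10 threshold, while background 15-mer collisions
are negligible. For clean short reads the same statistic is used with a
0.5 threshold.

Long-read unit detection counts exact substring matches of any rotation
of the unit on either strand and flags the read at `min_hits = 3`:
chance 10-mer hits on a 10 kb random read are ~0.2 expected, so three
hits essentially never arise by chance, while a 50-copy array at 10%
error still yields ~17 intact copies.

The co-occurrence fraction per unit is `n_both / n_unit_reads` over the
classified read set. Its *generator truth* is defined operationally: the
error-free twin read set (same seed, hence identical positions, strands
and lengths) classified at the error-adjusted containment threshold
`t / (1-e)^k`. That adjustment is not a fudge: a noisy classifier at
threshold t asks an error-free read for exactly that much true
containment in expectation, so the truth is the quantity the noisy
pipeline estimates, and the recovery check then isolates binomial noise
rather than a known, deliberate bias of the proxy.

## TSS-window motif profiling

Windows extend 200–2,000 bp in 200 bp steps up- and downstream of each
TSS *in transcription orientation*: minus-strand genes are mirrored, so
"downstream" is always 3' of the TSS. An alternative convention would
count in fixed chromosome orientation for all genes; the mirrored one is
the biologically coherent choice (promoter logic is orientation-relative)
and is applied uniformly. Windows are truncated at
contig boundaries (with a logged count), and genes overlapping their
neighbors are not excluded.

Within a window, motif occurrences are counted by substring start
position (overlaps count — the naive-oracle semantics, pinned by a test)
for the motif (`plus_count`) and its reverse complement (`minus_count`)
on the oriented sequence, both capped at 2 so categories are 0/1/2+.
Genes are grouped by (extent, direction, plus, minus) and the mean log2
fold change and group size are reported on the full category grid,
empty categories included with missing means.

## The synthetic generator

The generator emulates the target genome architecture: a uniform random
unique background; tandem arrays of configurable units and copy numbers;
an rDNA unit repeated in tandem blocks; and an `interleave_fraction` of
the arrays placed immediately adjacent to an rDNA block (remaining rDNA
copies form one standalone block). Mutant strains are derived by scaling
the repeat-compartment copy counts by a retention factor while keeping
the background seed, so wild type and mutant differ only in the
compartment — the loss pattern the strain comparison is built to detect.

Truth is recomputed, not assumed: duplication-window positions come from
scanning the emitted genome (asserted at generation time to cover at
least every array's interior windows), and the expected fraction of
reads containing a unit is computed exactly from those positions by
interval union over read start offsets. Background windows that would
accidentally duplicate a planted unit are resampled, and flank-induced
junction windows are captured by the scan-based truth regardless.

Reads use a substitution-only error model (no indels). This is a
deliberate simplification: every detector in the pipeline has exact-match
semantics, for which substitutions are the operative error mode, and it
keeps all truth quantities closed-form. Short reads are fixed-length,
uniformly placed, strand-symmetric. Long-read lengths follow a
log-normal pinned to a median of 2,331 bp and mean of 3,548 bp
(`mu = ln(median)`, `sigma^2 = 2 ln(mean/median)`), clamped to
[117, 29,910] bp — the clamp moves <0.4% of draws, so the median is
preserved. Long-read error defaults to 0.10.

Expression is simulated as `delta = sum_m beta_m * (capped plus + minus
counts in the effect window) + N(0, sigma)`, default one motif (`CCCCT`)
with beta = -0.5 per site in the upstream 1,000 bp window and sigma =
0.3; the truth table records the noiseless value and per-strand counts.
Gene TSSs are placed uniformly (margin 2,200 bp from contig ends so the
default grid never truncates) with random strands; motif-count variation
comes from the random background itself (a 5-mer appears about once per
kilobase per strand, populating the 0/1/2+ categories).

What the generator does **not** emulate — and hence what passing tests
do not certify on real data: indels and homopolymer error modes,
quality-value structure, GC and coverage bias, paired-end insert
geometry, polymorphic repeat variants within an array, and biological
confounders of the expression signal (chromatin, neighboring genes,
trans effects). The recovery tests certify the estimators against the
stated sampling models, not against platform artifacts.

## Numerical and testing choices

* Exact string equality everywhere in scanning; no mismatch tolerance.
* Degenerate inputs: empty read sets need explicit metadata; zero
  tracked hits give fraction 0; a unit absent from all reads gives an
  undefined (reported missing) co-occurrence fraction; reference-strain
  fractions of 0 give missing ratios.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); no global RNG is touched. Generator
  outputs are byte-identical for a fixed spec.
* Desk-scale problem sizes used by the suite and the acceptance script,
  chosen as the smallest sizes at which binomial error bars are
  informative: 1 Mb genome at 20x for copy-number recovery; five 400 kb
  strains at 10x (20x in the acceptance report) for loss recovery;
  1,000 long reads over a 600 kb genome with twenty 120-copy arrays
  (interleave 0.6) for co-occurrence; 2,000 genes on 7 Mb for the motif
  profile. Statistical recovery checks use 3 binomial SE for fractions
  and ratios; motif category means are checked at 2 SE against planted
  values after stratifying by total site count — the axis along which
  "monotone in count" is well-defined (the 2D (plus, minus) grid carries
  no total order).

## Known limitations

* `times_found` counts duplication windows, not repeat copies; for an
  array of c copies of an L-mer it targets ~`(c-2)L` windows, so copy
  estimates are comparable across strains and units but are not direct
  copy counts. (Both counting modes are reported precisely because the
  natural-language notion of "times found" is ambiguous.)
* The k-mer containment proxy is threshold-sensitive for reads that
  straddle an rDNA boundary; percentages derived from it inherit that
  method sensitivity, as any unstated-aligner "mapped to" criterion
  would.
* Composite tiling is exact-match only; a polymorphic composite array
  decomposes only at its exact unit.
* The scanner holds per-chunk buffers (~50k reads) and the catalog in
  memory; read sets stream, genomes do not.
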