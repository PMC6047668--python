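# Methods

## Scientific setting

Histone-modifying enzyme inhibitors conjugated to pyrrole–imidazole (Py-Im)
polyamides can, in principle, redirect an epigenetic activity to genomic
regions carrying the polyamide's recognition sequence. Py/Py pairs read A/T
base pairs and Im/Py pairs read G/C, so a four-ring polyamide recognizes a
6-bp degenerate site such as WWWWWW (W = A or T) or WWCGWW. The
computational question this package addresses is: given ChIP-style coverage
for activating histone marks (H3K4me2, H3K4me3, H3K27ac) in a treated and a
control condition, which regions gained signal, what chromatin state are
they in, is the DNA sequence composition around their centers biased toward
a recognition class, and do their nearest genes respond transcriptionally?

## Pipeline

### Region calling

Coverage is held in fixed-width bins (default 25 bp). The signal of a
candidate interval is the overlap-weighted mean bin value scaled to
signal-per-million of the track's library total (RPM-like). The fold
change is

    fold = (signal_treated + c) / (signal_control + c)

with pseudocount c = 1 RPM, and a region is called activated when
`fold > 3.0` — a strict inequality, reading "more than 3-fold" literally. A
secondary 1.5-fold threshold supports sensitivity stratification. The
normalization scale and pseudocount are package choices: raw tag-count
pipelines differ, so `quantify_signal` isolates the definition behind one
function that can be swapped.

Caveat of per-million normalization: if called regions occupy a
non-negligible fraction of the genome, their own gained signal inflates the
treated library total and deflates every fold estimate. This matters only
for dense toy genomes; the synthetic scenarios used in the acceptance
script therefore keep planted peaks below ~1% of the genome, as in real
data.

### Chromatin-state classification

Each called region is assigned exactly one state:

- **PROMOTER** — H3K4me3 signal above a positivity threshold *and* center
  within 2 kb of an annotated TSS;
- **ENHANCER** — H3K4me2 above threshold with H3K4me3 at or below it;
- **OTHER** — everything else.

The TSS-proximity requirement is a deliberate addition to the pure
mark-logic definition: H3K4me3-positive distal sites exist, and a
promoter/enhancer/other partition anchored to genes is the convention the
classification mirrors. The default positivity threshold is twice the
genome-wide median bin value of the H3K4me3 track (in RPM), a robust scale
estimate that ignores the peak tail.

### K-mer catalog and ranking

Around each region center a window of 2·250 + 1 = 501 bases is extracted
("within 250 bp of the center", center base included; windows crossing a
contig edge are dropped with a warning). All overlapping k-mers (step 1)
are counted; any k-mer containing a non-ACGT letter is skipped, never
imputed. By default both strands are counted — polyamide minor-groove
binding is strand-agnostic — which makes `counts[x] == counts[revcomp(x)]`
an exact invariant; forward-only counting is available.

The catalog always spans all 4^k k-mers, zero counts included. Two
orderings coexist:

- **midranks** over descending counts, used by every statistic (ties share
  the average of their positions, so the rank sum is N(N+1)/2 exactly);
- **display order** (count descending, lexicographic tie-break), used for
  top-N listings and "best rank of a class" queries, where rank #1 is the
  most frequent k-mer.

### Degenerate classes and rank enrichment

A class is the concrete expansion of an IUPAC W/S pattern ("WWCGWW" → 16
members), a compositional rule ("five S and one W" → 384 members), or an
"or" of both (the GC-rich class "SSSSSS or five S and one W" has 448
members). WWCGWW is its own reverse complement as a pattern, so class
membership is strand-consistent.

`class_rank_ks` tests whether a class sits unusually high or low in the
ranking: the one-sample Kolmogorov–Smirnov statistic D compares the
empirical CDF of the class's normalized midranks r_i/4^k with the uniform
CDF on (0, 1]. The p-value uses the exact finite-n Kolmogorov null
(`scipy.stats.kstwo`) rather than the large-n limit: at class sizes of
16–448 the asymptotic approximation is visibly miscalibrated, and the
package's own null-calibration test (below) holds only with the exact
distribution. Reported p-values are floored at 1e-15; direction is
"upward" when the class's mean normalized rank is below the catalog's mean
(which is (N+1)/2N, not exactly 1/2), "downward" when above, "none" on
exact equality. `compare_class` applies the two-sample KS test either to
one class's ranks in two catalogs (treatment comparisons) or to two
classes' ranks within one catalog.

A known limitation of rank-based KS statistics: midranks are discrete.
When mean counts per k-mer are low, large tie groups quantize the rank
lattice and inflate D relative to the continuous null. The calibration
test therefore simulates a deep-coverage regime (1600 windows × 501 bp per
replicate, mean ≈ 200 counts per 6-mer, both strands), where the
discreteness is negligible; at shallow depth p-values from any
continuous-null KS implementation should be treated as approximate. No
background correction for CpG depletion is applied — the analysis ranks
raw appearance frequencies.

### Expression association

Each region maps to the gene with the nearest TSS (|TSS − center|
minimized; ties to the smaller coordinate, then the lexicographically
smaller id; regions on contigs without genes are excluded, not imputed).
The resulting gene set is tested with a paired two-sided Student's t-test
on d_g = log2(treated_g + 1) − log2(control_g + 1); the same genes are
measured in both conditions, which motivates pairing, and the +1 keeps
zero-FPKM genes finite. A one-sided alternative is available by flag, and
a zero-variance difference vector returns a flagged degenerate result with
p = 1. The transform is recorded in the result object.

### Conjugate mass

`monoisotopic_mz` sums per-element monoisotopic masses (C = 12 exactly,
H = 1.0078250319, N = 14.0030740052, O = 15.9949146221), subtracts one
electron mass (0.0005485799 Da) per positive charge, divides by |charge|,
and rounds half-even to 4 decimals — the convention under which the
[M+H]+ cation C60H69N14O10+ of the WWCGWW-targeting conjugate evaluates to
1145.5316.

## Synthetic data: what it emulates and what it does not

The generator produces a single-contig i.i.d. genome of controllable GC
fraction, with peak flanks (±250 bp) rewritten to a composition class:

- **AT_RICH / GC_RICH** — i.i.d. bases with P(A)+P(T) (resp. P(G)+P(C))
  equal to an intensity parameter (default 0.9);
- **WCGW_SEEDED** — a neutral background carrying non-overlapping copies of
  randomly instantiated W W C G W W hexamers at a base-coverage fraction
  set by the intensity (default 0.2), so the whole degenerate class, not
  one literal 6-mer, is enriched;
- **NEUTRAL** — untouched.

Coverage is truncated-normal baseline noise (mean = `read_depth_scale`,
CV = 0.2, clipped at zero) on 25-bp bins. Treated tracks add, per peak, a
symmetric triangle of half-width 250 bp whose apex is
2·baseline·(fold − 1); the expected window-mean treated/control ratio then
equals the planted fold exactly, which is what makes fold-recovery tests
sharp, and the apex bin makes center recovery by argmax exact (leftmost
bin on ties). Control tracks carry baseline only. Default planted fold is
4 — comfortably above the 3-fold calling threshold yet close enough that
calling is a real test — and H3K4me3 is left flat, mirroring the
biological expectation that the inhibited demethylase does not act on the
trimethyl mark. Expression tables are log-normal FPKM-like values with a
planted log2 shift (default 1.0, noise SD 0.3) for genes nearest to
planted peaks.

Everything is a pure function of its arguments including the seed, and
generated files embed the seed in a header comment.

Not emulated: read-level sampling (FASTQ), mappability and GC bias,
fragment-length effects, replicate structure, CpG depletion and isochore
structure of real genomes, diploidy. Passing tests therefore demonstrate
the correctness and calibration of the analysis logic under a clean
generative model, not robustness to alignment or library artifacts.

## Numerical and degenerate-input choices

- Fold at exactly the threshold is excluded (strict inequality).
- An all-zero track quantifies to 0 rather than dividing by a zero library
  total; a bedGraph with no records yields an empty (all-zero) track.
- Two-sample KS on identical rank samples short-circuits to D = 0, p = 1,
  direction "none".
- Top-N GC standard error uses the sample SD (ddof = 1)/√n, and is
  reported as 0 for n = 1.
- Formula parsing treats each trailing sign character as one charge unit.

## Problem sizes

Test-suite simulations use genomes of 50 kb–500 kb, 100–1600 windows, and
20–500 replicate seeds; the acceptance script plants 50 peaks in a 4 Mb
genome with 200 genes. These sizes keep every planted effect far enough
from its decision boundary that recovery is deterministic under the
default noise, while the calibration studies use enough replicates for the
uniformity tests to have real power.
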