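# epikmer

Sequence-composition analysis of histone-modification changes.

`epikmer` is for epigenomics analysts asking whether the genomic regions
that gain an activating histone mark (H3K4me2, H3K4me3, H3K27ac) between
two conditions are biased toward particular DNA sequence classes — the
question that arises when an epigenetic inhibitor is tethered to a
sequence-reading molecule such as a pyrrole–imidazole polyamide, whose
recognition sites are 6-bp degenerate words like WWWWWW or WWCGWW
(W = A/T, S = C/G). The package provides the full computational chain on
standard formats (FASTA, BED, bedGraph, TSV), plus a synthetic-data module
with planted ground truth so every stage is testable without external
data.

## What it computes

1. **Differential regions.** Candidate intervals are quantified as
   signal-per-million mean coverage and called activated when
   (s_T + c)/(s_C + c) > 3 (pseudocount c = 1; a secondary 1.5-fold
   threshold is available). Regions are classified as promoter
   (H3K4me3-positive near a TSS), enhancer (H3K4me2-positive,
   H3K4me3-negative), or other.

2. **K-mer rank enrichment** (the core). For the ±250 bp windows around
   region centers, all 4^k k-mers are counted (both strands by default)
   and ranked by frequency, rank #1 = most frequent, midranks for ties.
   A degenerate class C with normalized ranks r_i/4^k is tested against
   the uniform distribution with the one-sample Kolmogorov–Smirnov
   statistic

       D = sup_x | F̂_C(x) − x | ,

   with exact finite-n p-values floored at 1e-15; classes can also be
   compared between catalogs or against each other (two-sample KS), and
   top-N listings report mean GC% ± SE.

3. **Expression association.** Regions map to nearest-TSS genes; the gene
   set's shift d_g = log2(treated+1) − log2(control+1) is tested with a
   paired two-sided Student's t-test.

4. **Conjugate mass.** Monoisotopic, electron-corrected m/z of a molecular
   formula (e.g. the conjugate cation C60H69N14O10+ → 1145.5316), for
   checking compound identity against ESI-TOF values.

See `docs/methods.md` for models, assumptions, and limitations.

## Worked example

Simulate a treatment that activates AT-rich regions (25 peaks with 4-fold
H3K27ac gain, flanks rewritten to 90% A/T), then run the pipeline:

```python
from epikmer import (
    CompositionClass, GenomicInterval, SimConfig, simulate_dataset,
    class_rank_ks, count_kmers, expand_pattern, extract_windows,
    rank_catalog, top_summary, expression_shift_test, nearest_gene, tss_index,
)
from epikmer.regions import call_increased_regions

config = SimConfig(genome_length=2_000_000, n_genes=100, n_peaks_per_class=25,
                   peak_fold=4.0, seed=42)
data = simulate_dataset(config, composition_class=CompositionClass.AT_RICH,
                        intensity=0.9)

hw = config.flank_half_width
candidates = [GenomicInterval("chr1", p.center - hw, p.center + hw + 1)
              for p in data.peaks]
regions = call_increased_regions(
    data.coverage[("H3K27ac", "treated")],
    data.coverage[("H3K27ac", "control")],
    candidates, "H3K27ac",
)
print(f"{len(regions)} of {len(candidates)} regions above 3-fold")

windows = extract_windows(data.genome,
                          [("chr1", r.interval.center) for r in regions], 250)
catalog = rank_catalog(count_kmers(windows, k=6))
summary = top_summary(catalog, 10)
print("top 10 6-mers:", " ".join(summary.kmers))
print(f"top-10 GC% = {summary.gc_mean:.0f} ± {summary.gc_se:.0f}")

w_class = expand_pattern("WWWWWW or five W and one S", name="W-rich")
res = class_rank_ks(catalog, w_class)
print(f"W-rich class ({res.n_members} 6-mers): D={res.ks_statistic:.3f}, "
      f"p={res.p_value:.3g}, {res.direction}")

genes = set(nearest_gene(regions, tss_index(data.annotation)).values())
shift = expression_shift_test(genes, data.expression)
print(f"nearest genes (n={shift.n_genes}): mean log2 shift "
      f"{shift.mean_log2_shift:.2f}, p = {shift.p_value:.2g}")
```

Output:

```
25 of 25 regions above 3-fold
top 10 6-mers: AATTAA TTAATT AAATAA ATTAAT TTATTT AATATA TAATTA TATATT AATAAA TTTATT
top-10 GC% = 0 ± 0
W-rich class (448 6-mers): D=0.891, p=1e-15, upward
nearest genes (n=24): mean log2 shift 0.99, p = 3.4e-13
```

Every planted peak is recovered at the 3-fold threshold; all top-10 6-mers
are all-W words (0% GC), the 448-member AT-rich class is shifted to the
top of the ranking far beyond chance (p at the 1e-15 reporting floor), and
the genes nearest the activated regions show the planted ~1-log2
expression gain.

The same stages are available as a command-line tool:

```sh
epikmer simulate --config sim.yaml --outdir data/
epikmer call-regions --treated data/H3K27ac_treated.bedgraph \
    --control data/H3K27ac_control.bedgraph \
    --candidates data/peaks_truth.bed --mark H3K27ac --out regions.json
epikmer kmer-enrich --genome data/genome.fa --regions data/peaks_truth.bed \
    --k 6 --out enrich.json
epikmer expr-test --regions regions.json --annotation data/genes.bed \
    --expr data/expression.tsv --out shift.json
epikmer mass "C60H69N14O10+"
```

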