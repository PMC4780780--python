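# Methods

## Coordinates and windows

All coordinates are 0-based, half-open internally; GFF3's 1-based
inclusive convention is converted at the parsing boundary. The TSS of a
gene feature is its 5′ end (start for `+`, end for `−`), expressed as the
0-based coordinate of the first transcribed base; one window per gene, so
transcript-level TSS variation is collapsed to the gene feature. Windows
cover relative positions [−3000, +500) with position 0 = the TSS base.
Minus-strand windows are reverse-complemented so every window reads 5′→3′
in transcriptional orientation; relative position *p* maps to string index
`offset_of_tss + p`. Windows truncated at scaffold ends are retained (the
missing positions are simply absent) but `filter_full_upstream` removes
them for the headline analyses, which are restricted to genes with the
complete 3-kb upstream domain. Soft-masked (lower-case) bases are
upper-cased and counted; N bases are kept in the sequence but excluded
from every dinucleotide and mononucleotide denominator. Windows are
extracted regardless of neighboring genes — no attempt is made to clip
upstream regions that run into an adjacent gene.

## Density profiles

The motif indicator assigns a dinucleotide to the position of its **first**
base (the C of CpG); entries with an ambiguous base are missing. The
profile value at a position is the mean of the indicator over a centered
moving window (default 51 bp, uniform weights; a triangular kernel is
available as a sensitivity option), with missing entries removed from the
denominator. No edge padding: positions whose centered window is not fully
inside the sequence are absent, which costs 25 bp at each end of the
domain and nothing downstream, rather than fabricating values at
boundaries. Per-gene profiles are averaged position-wise across genes with
equal weight (each position also records its contributing-gene count and
the standard error of the mean), and normalization is applied to the
aggregate: `none`, division by the aggregated G+C fraction profile, or
`obs_over_exp` — division by the product of the aggregated windowed C and
G fractions, the classic CpG observed/expected ratio. Normalizing the
aggregate rather than each gene avoids amplifying the noise of per-gene
window denominators; zero denominators yield missing values, never
infinities.

The TSS enrichment ratio is the mean normalized density over a near-TSS
interval divided by that over a far-upstream background. The background is
[−3000, −2000), upstream of where the density ramp begins; the near-TSS
interval is fixed at [−100, 0) by this package (a narrow window hugging
the TSS on the upstream side) and is configurable.

## Null models

Randomized control gene models emulate composition, not gene structure:
3,000 upstream bases i.i.d. from the genome-wide base frequencies
(computed over all scaffolds, ambiguity codes excluded) and a 500-bp first
exon of codons sampled i.i.d. from a codon usage table. Since 500 is not
divisible by 3, 167 codons are drawn and the final base dropped. One
shared control set (default 20,000 models) is generated per configuration
and is byte-reproducible from its seed. The mirror (GpC) control is
computed by profiling the reversed motif on the forward sequences, which
is provably identical, position-reversed, to profiling CpG on reversed
sequences.

## Region statistics

Region frequencies use raw, unsmoothed dinucleotide counts — the 51-bp
moving average would leak signal across region boundaries; a region's
frequency for a gene is (CpG starts with first base in the region) /
(unambiguous dinucleotide start positions in the region). Regions are
half-open, the TSS base belongs to the exon-side region [0, +500), and a
dinucleotide belongs to the region of its first base.

Kruskal–Wallis (mid-ranks, standard tie-correction divisor, chi-square
reference with k−1 df) is Bonferroni-corrected over the four regions; the
all-identical degenerate case is defined as H = 0, p = 1. Dunn's pairwise
z uses the pooled-rank variance with tie term Σ(t³−t)/(12(N−1)) and
two-sided normal p-values; pairwise p-values are unadjusted by default
(significance letters at α are the reported summary), with
Bonferroni-over-pairs selectable. The focal-set comparison runs Wilcoxon
rank-sum per region, also Bonferroni-corrected over the four regions by
default (the family is configurable); the reported statistic is the
mid-rank sum of the focal sample, with exact enumeration when the pooled
sample is tie-free and ≤ 20 values, otherwise the tie-corrected normal
approximation with continuity correction. Kruskal–Wallis and Wilcoxon are
computed via scipy.stats; Dunn's test is implemented here and verified
against closed-form hand computations and permutation checks.

## Synthetic data generator

The generator emulates the features of real promoter data the pipeline
depends on: multi-scaffold genomes, plus/minus-strand genes embedded as
reverse complements, genome-wide base composition, a position-dependent
CpG observed/expected profile rho(x) — background level with a linear ramp
from −2000 bp to a peak at the TSS, held over the exon — class-specific
multiplicative rho offsets over stated intervals, and a flagged focal
subset with its own offset. Defaults: 5,000 genes, uniform base
composition, rho background 0.6, ramp from −2000 bp to 1.38× background,
half the genes on the minus strand, 10% of genes carrying two KEGG
classes, 1% focal.

Emission is first-order: every base is drawn from the configured base
frequencies except that P(G | previous base C at position x) =
rho(x)·f_G. The residual probability mass is rebalanced so that the C
marginal stays exactly f_C and the G marginal exactly f_G at every
position (A and T share the remainder in proportion to their
frequencies). This compensation is what makes the generator's parameter
exactly recoverable: the CpG start probability at x is f_C·rho(x)·f_G
while the mononucleotide composition is position-independent, so the
pipeline's windowed o/e estimates rho(x) without composition confounds.
The simpler alternative — redistributing the post-C deficit over all
three other bases proportionally — perturbs the stationary C and G
marginals as a function of rho and biases the recovered enrichment ratio
several percent low, which is why it was not used. Note the recovered
near-TSS/background ratio is expected slightly below the peak factor
(≈1.37 for a 1.38 peak) because the near interval [−100, 0) averages the
top of the ramp rather than sampling its endpoint.

What the generator does **not** emulate: CpG islands, isochores, repeats,
real codon structure in exons (the exon is generated by the same rho
process at peak level; codon realism lives in the null-model generator),
deamination mutation processes, or annotation error. Passing tests
therefore demonstrate correctness of the measurement and statistics
pipeline on data with known truth, not biological conclusions about real
genomes.

Genes are laid out per scaffold as `[spacer][window][spacer][window]…`
with i.i.d. spacer bases (default gap 1,000 bp) so that every embedded
window is recoverable exactly by extraction; the first base of each
window is drawn unconditionally, a negligible edge effect. `truth.json`
records every generative parameter and per-gene labels and is the single
source of expected values in tests.

## Problem sizes and numerical choices

The shipped analyses use simulation sizes chosen to give comfortable
statistical resolution at interactive runtimes: 5,000 genes for
enrichment-ratio recovery (sampling error on the ratio ≈ 1%), 2,000
randomized models for control-equivalence checks (per-position SE ≈
0.0015 on a frequency of 0.0625), and 200 replicates of 500 genes for
type-I calibration of the class comparison (95% binomial interval
0.020–0.080 around the nominal 0.05). Random number streams derive from a
single integer seed per run; all generators are numpy `default_rng`.

## Known limitations

- Overlapping genes and bidirectional promoters are profiled as-is; no
  masking of neighboring features.
- The Bonferroni family for the omnibus and focal-set tests is the four
  regions; whether to correct additionally across class pairs in Dunn's
  test is left to the `adjust` option.
- The G+C normalization divides the aggregate CpG profile by the aggregate
  G+C profile; per-gene normalization is not offered.
- `obs_over_exp` uses windowed mono fractions from the same window as the
  numerator, so it is a local o/e, not a genome-wide one.
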