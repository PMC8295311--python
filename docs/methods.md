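# Methods

This note documents the models, estimators and numerical choices behind
`accessmap`, what the synthetic-data generator does and does not emulate,
and the known limitations of each statistic.

## Study design being modelled

The package targets a two-condition developmental comparison — an
embryonic-like stage (`E21`) and a postnatal-like stage (`P11`) — with two
ATAC-seq replicates per stage and four RNA-seq replicates per stage. All
downstream logic is agnostic to the labels; they parameterize the
simulation and the summaries.

## Reproducible OCRs and accessibility scores

Peaks from the two replicates of a stage are clustered transitively by
≥1 bp overlap. A cluster supported by both replicates becomes one
reproducible OCR with the union interval and the arithmetic mean of all
contributing heights; replicate-unique clusters are discarded. The union
interval preserves the full reproducible footprint; the mean matches the
"average normalized peak height" reading of replicate aggregation. The
operation is symmetric in its arguments.

Assignment uses the peak **center** (floor of the interval midpoint) and a
strict precedence: promoter (|center − nearest TSS| ≤ 3 000 bp, symmetric
window) > genic (≥1 bp overlap with a gene span) > distal
(3 000 < |d| ≤ 100 000 bp) > unassigned. The three windows form a
partition, so region-class counts always sum to the OCR count.
Nearest-TSS ties break by smaller distance, then lexicographic gene id.
Each OCR is assigned to at most one gene; bidirectional promoters sharing
a peak are not modelled. A gene's accessibility score per region class and
stage is the plain sum of assigned OCR heights; genes without OCRs score 0.

## Negative-binomial differential test

Counts are modelled as NB with variance μ + φμ². The pieces:

* **Size factors** — median-of-ratios: per sample, the median over
  all-positive features of count / per-feature geometric mean. An input
  with no all-positive feature is rejected rather than silently patched.
* **Dispersion** — per-feature method of moments on normalized counts,
  with the sample variance pooled *within* stages (mean of the per-stage
  ddof-1 variances) so real between-stage differences do not inflate φ:
  φ = max(10⁻⁸, (s² − μ̄)/μ̄²).
* **Trend floor** — at two samples per group the per-feature MoM estimate
  carries ~2 degrees of freedom and its lower tail is essentially noise;
  using it directly makes the Wald test anti-conservative (null p < 0.05
  fraction ≈ 0.13 in 2v2 simulations). Each feature's dispersion is
  therefore floored at a binned-median mean–dispersion trend (20 quantile
  bins of the grand normalized mean). This restores the empirical size to
  ≈ 0.06 at nominal 0.05 and ≈ 0.02 at nominal 0.01 while keeping power
  for planted log2FC = 3 effects above 0.9. A *t* reference was evaluated
  instead and rejected: df small enough to fix the size destroys power.
  `estimate_dispersion` still returns the raw MoM values;
  `nb_wald_test(moderate_dispersion=False)` disables the floor.
* **Wald test** — stage means of normalized counts with a 0.5 pseudocount
  (for fold-change stability at zeros; `pseudocount=0` restores exact
  invariance of log2FC under per-sample library rescaling),
  log2FC = log2(μ̂_A/μ̂_B), delta-method SE
  √(Var(x̄_A)/μ̂_A² + Var(x̄_B)/μ̂_B²)/ln 2 with Var(x̄) = (μ̂ + φμ̂²)/n,
  two-sided normal p, Benjamini–Hochberg across features. Significance:
  |log2FC| > 1 and q < 0.01 (both configurable).

This is deliberately a simplified, self-contained test: no dispersion
shrinkage toward a fitted trend curve beyond the floor, no fold-change
shrinkage, no outlier handling, no covariates. Numeric agreement with any
external differential-expression package is not claimed.

When only normalized peak heights are available for accessibility,
per-OCR "counts" are the rounded sums of sample peak heights overlapping
each reference OCR — a documented stand-in for reads-in-peaks counting.

## Correlations

All correlations are plain Pearson with the exact t-transform p-value
(t = r√((n−2)/(1−r²))). The expression side uses log2(normalized mean + 1)
rather than a variance-stabilizing transform — transparent and adequate at
the simulated depths. Change–change correlation pairs
log2((score_A+1)/(score_B+1)) with the expression log2FC. DOR–expression
concordance reports, per gene with promoter DORs of a single direction,
whether that direction matches the sign of the expression change; genes
with DORs of both directions are tabulated separately and excluded from
the summary fraction. Replicate concordance is Pearson r between binned
signal tracks on an identical grid (default 5 kb).

## PWM scanning (Patser-style)

A count matrix becomes column probabilities with a 0.25-per-cell
pseudocount, then a log2-odds matrix against the background composition
(default uniform). The null score distribution of a background W-mer is
computed exactly by dynamic programming: per-column scores are rounded to
multiples of δ = 0.01 bits and convolved; tail probabilities follow by
suffix summation. Enumeration over all 4^W words reproduces the DP tails
exactly on the rounded grid, and the rounding displaces any word's score
by at most W·δ/2, which bounds the cutoff error by W·δ.

Scanning scores every window on both strands (windows containing N are
skipped; reverse-strand hits are reported at the leftmost forward
coordinate) and calls hits at the score cutoff implied by a per-hit
p-value α, with W·δ/2 slack so the unrounded window scores are judged
consistently with the rounded grid. Whole-genome scans are performed once
per motif and reused: a window fully inside any region scores identically
whether the region is extracted first or not, so region-level hit counts
come from sorted-position lookup.

Two α values are used: **α = 10⁻⁴** for binding-site calling (CREB target
genes), and **α = 10⁻³** for enrichment scanning. The permissive
enrichment cutoff matters statistically, not just computationally — see
the ORI section.

## ORI enrichment

ORI = (F_T·D_T)/(F_B·D_B), frequency (fraction of regions with ≥1 site,
smoothed (k+½)/(n+1)) times density (sites/kb, smoothed +½ hit). "Density"
is hits per kb; both strands are scanned. The background for each of 100
replicates is drawn from the genomic complement of all OCRs with the same
number and length multiset as the targets: a pool interval is chosen with
probability proportional to its number of valid placements (len − L + 1),
then a uniform start, which makes every placement equally likely.
Significance is a one-sample, one-sided t-test of the 100 ORI values
against 1.2, BH-corrected across motifs (default q < 0.05, with the
stricter 0.01 available).

**Known property**: the t-test measures only background-resampling noise;
the chance enrichment of the single target draw is outside its error
model. When per-region hit counts are sparse (strict cutoffs, short
regions), the ORI of a null target set fluctuates well past the 1.2
offset and the test rejects far too often (~40 % observed at α = 10⁻⁴
with 1 kb regions). With dense counts — permissive α = 10⁻³ and
promoter-DOR-sized regions (~1–2 kb), where motif frequencies reach the
tens of percent — the chance fluctuation falls below the 1.2 offset and
the null BH-rejection fraction drops to ≲0.5 %. This is why enrichment
scans use α = 10⁻³, and why ORI conclusions on very small or very clean
target sets should be treated with caution. If the sampled ORI values are
all identical, p is defined as 0 when the mean exceeds the null value and
1 otherwise.

The exact published form of the ORI statistic is not fully pinned down by
its originating description ("frequency and density"); the formula above
is isolated in `compute_ori` so it can be swapped without touching the
resampling or testing machinery.

## Binomial enrichment (HOMER-style)

k of n target regions contain ≥1 site; the background frequency f_B is
the per-region hit fraction of complement-derived regions (≥100; a zero
estimate is replaced by 0.5/(n_B+1) with a warning). p = P(X ≥ k),
X ~ Binomial(n, f_B), exact upper tail. A motif passes when fold =
f_T/f_B ≥ 2, f_T > 0.05, and BH q < 0.01. No GC matching is applied to the
background — complement regions are used directly.

## CREB target genes

Among significant DEGs with ≥1 promoter-class OCR, a gene is a target if
any of its promoter OCRs contains ≥1 binding site at α = 10⁻⁴. Restricting
to promoter OCRs is the default (configurable to all gene-associated
OCRs).

## Synthetic-data generator

What it emulates, with defaults chosen to represent the modelled study at
desk scale (1 500 genes on a 30 Mb chromosome, 4 000 peaks per sample):

* **Annotation** — non-overlapping genes with alternating strands, spans
  lognormal (median 8 kb), placed uniformly with a 5 kb margin from
  chromosome ends; 1–5 exons per gene.
* **Peaks** — one master template shared by all samples: 70 % of centers
  Laplace-distributed (scale 200 bp) around random TSSs, the rest uniform;
  widths lognormal (median 400 bp), heights lognormal (median 50). 10 % of
  genes are DOR genes (half per stage) with a guaranteed promoter peak
  whose favored-stage height is scaled by 2^L, L ~ N(3, 0.25). Replicates
  multiply every height by exp(N(0, 0.1)). Only DOR promoter peaks are
  protected from overlap; background peaks may overlap, as real calls near
  busy promoters do.
* **Expression** — per-gene baseline log2 mean ~ N(5, 1); NB counts with
  φ = 0.1 and mild per-sample depth jitter. The expression log2FC is
  ρ·(standardized accessibility log2FC) + √(1−ρ²)·ε, rescaled to the
  accessibility-change spread, so the realized truth coupling converges to
  ρ. The *baseline* is additionally coupled (same ρ) to baseline promoter
  accessibility, because within-stage accessibility–expression correlation
  cannot arise from fold-change coupling alone; the marginal baseline
  distribution stays N(5, 1).
* **Sequences** — an explicit genome realized as i.i.d. bases from the
  configured composition; PWM-sampled sites are written into the genome in
  60 % of target-stage DOR promoter peaks and 1 % of all other peaks, at
  uniform offset and strand, positions recorded. Peak sequences and
  complement background sequences are slices of the same molecule.
* **Determinism** — all randomness flows from one seed through four named
  sub-streams (annotation / peaks / expression / sequences); toggling one
  stage never perturbs the others, and identical configs give bitwise
  identical outputs.

What it does **not** emulate: read-level noise and Tn5 insertion bias, GC
and mappability structure, nucleosome positioning, multi-transcript
isoforms, trans-acting or distal (enhancer) regulation, and realistic
motif co-occurrence. Passing recovery tests on this generator therefore
demonstrates the correctness and calibration of the statistics, not their
field performance on real libraries.

The bundled CREB/ATF-like matrix (`creb_like_pwm`, consensus ATGACGTCAT,
near-deterministic columns) is a **synthetic** stand-in for a curated
CREB matrix, as are the random decoy motifs.

## Problem sizes

Defaults are desk-scale by design: the full pipeline (simulation, OCR
calling, differential testing, correlations, 8 motifs × 2 stages of ORI
with 100 resamples each, binomial enrichment, target calling) runs in
about two minutes on one CPU; the calibration studies (50 decoys × 10
seeds for the ORI null, 10 × 5 000-feature NB nulls) add a few minutes.
Larger designs scale linearly in genome size and motif count.

## Known limitations

* The within-stage correlation at default settings is attenuated relative
  to the coupling target: overlapping background peaks merge into OCRs
  with mean (not summed) heights, diluting per-gene scores. The
  change–change correlation, which the recovery checks rely on, is robust
  to this; recovery is asserted against the *realized* truth coupling over
  the same gene set.
* DOR pseudo-counts derived from rounded peak heights inherit the height
  normalization; with real reads-in-peaks counts the differential module
  can be used unchanged.
* The ORI t-test's error model excludes target-draw noise (above); its
  null calibration is honest only in the dense-count regime.
* BH adjustment and binomial tails are delegated to statsmodels/scipy;
  both are cross-checked in the test suite against independent
  from-definition oracles.
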