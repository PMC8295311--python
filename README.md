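# accessmap

Integrative analysis of developmental chromatin accessibility and gene
expression, built for two-stage, two-replicate ATAC-seq + RNA-seq designs
such as embryonic vs postnatal retinal ganglion cells (RGCs). The package
implements the full downstream path from called peaks to transcription-factor
biology:

1. **Reproducible OCR calling** — peaks from two biological replicates are
   intersected; only regions supported by both survive, with union
   coordinates and the mean of the replicate-normalized peak heights.
2. **Region-class assignment** — each open-chromatin region (OCR) is tied
   to at most one gene as *promoter* (|center − TSS| ≤ 3 kb), *genic*
   (overlapping the gene span), *distal* (3–100 kb from the nearest TSS) or
   *unassigned*, and per-gene accessibility is the sum of assigned OCR
   heights per class.
3. **Differential testing** — a self-contained negative-binomial Wald test
   (median-of-ratios size factors, method-of-moments dispersion with a
   mean-trend floor, Benjamini–Hochberg adjustment) calls differentially
   expressed genes (DEGs) and differentially open regions (DORs) at
   |log2FC| > 1 and FDR q < 0.01.
4. **Accessibility–expression integration** — Pearson correlation of
   log-scale accessibility with expression within a stage, of accessibility
   changes with expression changes between stages, and direction
   concordance of promoter DORs with expression fold changes.
5. **Motif analysis** — Patser-style PWM scanning with *exact*
   score-distribution p-values computed by dynamic programming; motif
   over-representation in stage-specific promoter DORs by (a) the ORI
   statistic (frequency × density ratio against 100 length-matched
   resamples of the non-open genomic background, one-sided t-test against
   a null of 1.2) and (b) HOMER-style cumulative-binomial enrichment with
   ≥2-fold and >5 % frequency filters; and CREB-target calling (DEGs with
   ≥1 binding site in a promoter OCR).

A first-class synthetic-data generator produces coupled gene models, peak
sets, count matrices and genome sequence with *known ground truth* —
stage-specific promoter DORs, expression fold changes correlated with
accessibility fold changes at a chosen ρ, and motif instances planted at
stage-specific frequencies — so every stage of the pipeline can be scored
for recovery.

## The statistics, briefly

For a motif *m* and a region set *S*, let F(S) be the fraction of regions
with at least one binding site and D(S) the site density per kb. The
over-representation index against a background set *B* is

    ORI = (F_T · D_T) / (F_B · D_B)

with Laplace-style smoothing (F = (k + ½)/(n + 1), D = (hits + ½)/kb). The
background is resampled 100 times from the genomic complement of all OCRs,
matching the targets' number and length distribution; significance is a
one-sample, one-sided t-test of the 100 ORI values against 1.2.

Binding sites come from the log-odds score s(w) = Σ_j log2(p_j(w_j)/q(w_j));
the p-value of a score is the exact probability that a random background
W-mer scores at least as high, computed by convolving per-column score
distributions on a 0.01-bit grid.

The NB Wald test models counts with variance μ + φμ², estimates φ per
feature by method of moments pooled within stages, floors it at a
binned-median mean–dispersion trend, and tests log2FC with a delta-method
standard error.

## Worked example

```python
from accessmap import pipeline

cfg = pipeline.RunConfig(seed=1, out_dir="demo_run")
summary = pipeline.run_pipeline(cfg)
print(summary["reproducible_ocrs"])          # {'E21': 2666, 'P11': 2666}
print(summary["degs"])                       # {'total': 270, 'up_E21': 133, 'up_P11': 137}
print(summary["promoter_dor_genes"])         # {'E21': 75, 'P11': 74}
print(summary["planted_promoter_dor_recovery"])
                                             # {'E21': 0.9867, 'P11': 0.9467}
print(summary["motifs_passing_both"])        # {'E21': ['CREB_ATF_synthetic'], 'P11': []}
print(summary["correlations"]["change_promoter"])
                                             # r = 0.426, p = 2.6e-67, n = 1500
```

Reading this output: the simulated experiment planted 150 genes with a
stage-specific promoter DOR (75 per stage); the pipeline recalls ~97 % of
them as promoter DORs with the correct stage direction. The promoter
accessibility change correlates with the expression change at r ≈ 0.43
(the generator's target coupling is ρ = 0.5; the remainder is measurement
attenuation), while the distal-class change correlation is null. Exactly
one motif — the planted CREB/ATF-like matrix — passes both the ORI and the
binomial enrichment filters, and only in its planted stage; among the 246
DEGs with a promoter OCR, 33 carry a CREB site and are flagged as CREB
target genes.

The same run is available from the shell:

```bash
accessmap run --config run.yaml       # full pipeline
accessmap simulate --config run.yaml --out data/
accessmap intersect rep1.narrowPeak rep2.narrowPeak --out ocrs.bed
accessmap scan peaks.fa --pwm creb.pwm --alpha 1e-4 --out hits.tsv
```

## Layout

```
src/accessmap/
  formats_io.py      # BED/narrowPeak/BED12/FASTA/JASPAR/TSV readers+writers
  synthetic_data.py  # coupled generator with ground truth
  peak_gene.py       # reproducible OCRs, assignment, accessibility scores
  differential.py    # NB Wald test, size factors, dispersion, BH
  correlate.py       # stage/change correlations, concordance, QC
  motif_scan.py      # log-odds scanning, exact score distributions
  enrichment.py      # ORI, binomial enrichment, CREB targets
  pipeline.py        # orchestration, config validation, run summary
  cli.py             # `accessmap` command
```
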