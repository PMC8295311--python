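"""Accessibility-expression relationships and replicate-concordance QC.

Within-stage correlation pairs log2(per-gene accessibility score + 1)
with log2(mean normalized expression + 1); change-change correlation
pairs promoter-accessibility log2 fold changes with expression log2 fold
changes; DOR-expression concordance asks whether the direction of a
gene's promoter accessibility change matches its expression change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import DifferentialResult, size_factors
from .formats_io import CountMatrix
from .peak_gene import AccessibilityScore, RegionAssignment


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    transform: str


def pearson(x, y, transform: str = "identity") -> CorrelationResult:
    """Product-moment correlation with the exact t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if len(x) < 3:
        raise InsufficientDataError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InsufficientDataError("correlation undefined for constant input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        r=float(res.statistic), p=float(res.pvalue), n=len(x),
        transform=transform,
    )


def _mean_normalized_expression(expr: CountMatrix, stage: str) -> pd.Series:
    sf = size_factors(expr)
    norm = expr.counts / sf[None, :]
    idx = expr.samples_of_stage(stage)
    return pd.Series(norm[:, idx].mean(axis=1), index=expr.feature_ids)


def _score_series(
    scores: list[AccessibilityScore], region_class: str, require_ocr: bool
) -> pd.Series:
    data = {
        s.gene_id: s.score
        for s in scores
        if s.region_class == region_class and (s.n_ocrs >= 1 or not require_ocr)
    }
    return pd.Series(data, dtype=float)


def stage_correlation(
    scores: list[AccessibilityScore],
    expr: CountMatrix,
    stage: str,
    region_class: str = "promoter",
) -> CorrelationResult:
    """r between log2(score+1) and log2(mean normalized expression+1)
    over genes with at least one OCR of the class at that stage."""
    sc = _score_series(
        [s for s in scores if s.stage == stage], region_class, require_ocr=True
    )
    ex = _mean_normalized_expression(expr, stage)
    genes = sc.index.intersection(ex.index)
    if len(genes) < 3:
        raise InsufficientDataError(
            f"only {len(genes)} genes with {region_class} OCRs at {stage}"
        )
    return pearson(
        np.log2(sc.loc[genes] + 1), np.log2(ex.loc[genes] + 1),
        transform="log2(x+1)",
    )


def change_correlation(
    scores_a: list[AccessibilityScore],
    scores_b: list[AccessibilityScore],
    diff_expr: list[DifferentialResult],
    region_class: str = "promoter",
) -> CorrelationResult:
    """r between accessibility log2((scoreA+1)/(scoreB+1)) and the
    expression log2 fold change, over genes scored in both stages."""
    sa = _score_series(scores_a, region_class, require_ocr=False)
    sb = _score_series(scores_b, region_class, require_ocr=False)
    fc = pd.Series({r.feature_id: r.log2fc for r in diff_expr})
    genes = sa.index.intersection(sb.index).intersection(fc.index)
    if len(genes) < 3:
        raise InsufficientDataError(f"only {len(genes)} genes in common")
    acc_fc = np.log2((sa.loc[genes] + 1) / (sb.loc[genes] + 1))
    return pearson(acc_fc, fc.loc[genes], transform="log2((x+1)/(y+1))")


def dor_expression_concordance(
    promoter_dors: list[DifferentialResult],
    dor_direction: dict[str, str],
    assignments: list[RegionAssignment],
    diff_expr: list[DifferentialResult],
    stage_a: str,
) -> tuple[pd.DataFrame, float]:
    """Direction agreement between promoter DORs and expression changes.

    Genes with DORs of both directions in their promoter are reported in
    the 'both' category and excluded from the summary fraction.
    """
    gene_of_peak = {
        a.peak_id: a.gene_id
        for a in assignments
        if a.region_class == "promoter" and a.gene_id is not None
    }
    gene_dirs: dict[str, set[str]] = {}
    for r in promoter_dors:
        if not r.is_significant or r.feature_id not in gene_of_peak:
            continue
        gene = gene_of_peak[r.feature_id]
        gene_dirs.setdefault(gene, set()).add(dor_direction[r.feature_id])
    expr_fc = {r.feature_id: r.log2fc for r in diff_expr}
    rows = []
    agree = total = 0
    for gene, dirs in sorted(gene_dirs.items()):
        if gene not in expr_fc:
            continue
        fc = expr_fc[gene]
        if len(dirs) > 1:
            rows.append((gene, "both", fc, None))
            continue
        dor_stage = next(iter(dirs))
        expr_stage = stage_a if fc > 0 else None if fc == 0 else "other"
        matches = (dor_stage == stage_a) == (fc > 0)
        rows.append((gene, dor_stage, fc, bool(matches)))
        total += 1
        agree += int(matches)
        del expr_stage
    table = pd.DataFrame(
        rows, columns=["gene_id", "dor_direction", "expr_log2fc", "concordant"]
    )
    fraction = agree / total if total else float("nan")
    return table, fraction


def replicate_concordance(
    track1: pd.DataFrame, track2: pd.DataFrame, resolution: int
) -> CorrelationResult:
    """Pearson r between two binned signal tracks on identical grids."""
    for t in (track1, track2):
        widths = t["end"] - t["start"]
        if not (widths == resolution).all():
            raise ValueError(f"track bins are not at {resolution} bp resolution")
    k1 = list(zip(track1["chrom"], track1["start"]))
    k2 = list(zip(track2["chrom"], track2["start"]))
    if k1 != k2:
        raise ValueError("tracks are on different bin grids")
    return pearson(
        track1["value"].to_numpy(), track2["value"].to_numpy(),
        transform="binned counts",
    )


def bin_peak_signal(
    peaks, chrom_sizes: dict[str, int], resolution: int
) -> pd.DataFrame:
    """Sum peak heights into fixed-width genome bins (bedGraph-like)."""
    frames = []
    for chrom, size in chrom_sizes.items():
        n_bins = (size + resolution - 1) // resolution
        vals = np.zeros(n_bins)
        for p in peaks:
            if p.chrom != chrom:
                continue
            b0, b1 = p.start // resolution, (p.end - 1) // resolution
            for b in range(b0, b1 + 1):
                lo = max(p.start, b * resolution)
                hi = min(p.end, (b + 1) * resolution)
                vals[b] += p.height * (hi - lo) / (p.end - p.start)
        starts = np.arange(n_bins) * resolution
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts,
            "end": np.minimum(starts + resolution, size), "value": vals,
        }))
    return pd.concat(frames, ignore_index=True)
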