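"""Motif over-representation in stage-specific promoter DORs.

Two complementary statistics:

* **ORI** (over-representation index): combines motif *frequency* (the
  fraction of regions containing >= 1 site) and *density* (sites per kb)
  in target vs background regions, ORI = (F_t * D_t) / (F_b * D_b).
  The background is resampled 100 times from the genomic complement of
  all OCRs, matching the targets' number and length distribution, and a
  one-sided one-sample t-test asks whether the mean ORI exceeds 1.2.
* **Cumulative-binomial enrichment** (HOMER-style): the number of target
  regions containing the motif against the background per-region motif
  frequency, with >= 2-fold and > 5 % frequency filters at BH q < 0.01.

Both consume precomputed genome-wide hit positions (one scan per motif),
which is equivalent to scanning each region's extracted sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .differential import DifferentialResult
from .formats_io import PeakSet
from .motif_scan import GenomeHits
from .peak_gene import RegionAssignment

logger = logging.getLogger(__name__)

Region = tuple[str, int, int]

ORI_NULL = 1.2
N_REP_DEFAULT = 100


@dataclass(frozen=True)
class HitSummary:
    n_seqs: int
    n_seqs_with_hit: int
    total_hits: int
    total_kb: float


@dataclass
class ORIResult:
    motif_id: str
    stage: str
    ori_values: np.ndarray = field(repr=False)
    ori_mean: float = 0.0
    freq_target: float = 0.0
    density_target: float = 0.0
    freq_background: float = 0.0
    density_background: float = 0.0
    t_statistic: float = float("nan")
    p_one_sided: float = 1.0
    bh_q: float = 1.0
    pct_dors_with_motif: float = 0.0


@dataclass
class BinomialEnrichmentResult:
    motif_id: str
    stage: str
    n_dors: int
    k_dors_with_motif: int
    f_target: float
    f_background: float
    fold: float
    p_binomial: float
    bh_q: float = 1.0
    passes_filters: bool = False


# ---------------------------------------------------------------------------
# Background construction
# ---------------------------------------------------------------------------


def complement_regions(
    all_ocrs: PeakSet, chrom_sizes: dict[str, int]
) -> list[Region]:
    """Set-complement of the merged OCR union within each chromosome."""
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    for p in all_ocrs:
        if p.chrom not in chrom_sizes:
            raise ValueError(f"no chromosome size for {p.chrom}")
        if p.end > chrom_sizes[p.chrom]:
            raise ValueError(
                f"OCR {p.peak_id} extends past end of {p.chrom}"
            )
        by_chrom[p.chrom].append((p.start, p.end))
    out: list[Region] = []
    for chrom, size in chrom_sizes.items():
        ivs = sorted(by_chrom[chrom])
        merged: list[tuple[int, int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        pos = 0
        for s, e in merged:
            if s > pos:
                out.append((chrom, pos, s))
            pos = max(pos, e)
        if pos < size:
            out.append((chrom, pos, size))
    return out


def sample_matched_background(
    query_regions: list[Region],
    pool: list[Region],
    rng: np.random.Generator | int,
) -> list[Region]:
    """Length-matched random regions from the pool, with replacement.

    For each query of length L, a pool interval is chosen with
    probability proportional to its number of possible placements
    (length - L + 1, among intervals of length >= L), then a uniform
    start within it — i.e. placements are uniform over all valid
    positions in the pool.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    pool_arr = np.array([(s, e) for _, s, e in pool], dtype=np.int64)
    pool_lens = pool_arr[:, 1] - pool_arr[:, 0]
    chroms = [c for c, _, _ in pool]
    # choosing a pool interval proportionally to (len - L + 1) and then a
    # uniform start makes every valid placement equally likely; cumulative
    # weights are cached per distinct query length
    cum_cache: dict[int, np.ndarray] = {}
    out: list[Region] = []
    for _, qs, qe in query_regions:
        L = qe - qs
        cum = cum_cache.get(L)
        if cum is None:
            placements = np.maximum(pool_lens - L + 1, 0)
            cum = np.cumsum(placements, dtype=np.float64)
            if cum[-1] <= 0:
                raise ValueError(
                    f"no pool interval can hold a query of length {L}"
                )
            cum_cache[L] = cum
        u = rng.random() * cum[-1]
        i = int(np.searchsorted(cum, u, side="right"))
        n_place = int(pool_lens[i] - L + 1)
        start = int(pool_arr[i, 0] + rng.integers(0, n_place))
        out.append((chroms[i], start, start + L))
    return out


# ---------------------------------------------------------------------------
# ORI
# ---------------------------------------------------------------------------


def summarize_hits(regions: list[Region], hits: GenomeHits) -> HitSummary:
    counts = hits.counts_in(regions)
    total_kb = sum(e - s for _, s, e in regions) / 1000.0
    return HitSummary(
        n_seqs=len(regions),
        n_seqs_with_hit=int((counts > 0).sum()),
        total_hits=int(counts.sum()),
        total_kb=total_kb,
    )


def compute_ori(
    target: HitSummary, background: HitSummary, smoothed: bool = True
) -> float:
    """ORI = (F_t * D_t) / (F_b * D_b), frequency x density ratio.

    The smoothed form adds half a hit per set and treats the frequency as
    a Laplace-style (k + 0.5)/(n + 1) estimate so the ratio stays finite
    for empty sets.
    """
    if target.total_kb == 0 or background.total_kb == 0:
        raise ValueError("total sequence length must be positive")

    def fd(s: HitSummary) -> tuple[float, float]:
        if smoothed:
            return (
                (s.n_seqs_with_hit + 0.5) / (s.n_seqs + 1),
                (s.total_hits + 0.5) / s.total_kb,
            )
        return s.n_seqs_with_hit / s.n_seqs, s.total_hits / s.total_kb

    ft, dt = fd(target)
    fb, db = fd(background)
    if fb == 0 or db == 0:
        raise ValueError("unsmoothed ORI undefined for hit-free background")
    return (ft * dt) / (fb * db)


def ori_test(
    target_regions: list[Region],
    pool: list[Region],
    hits: GenomeHits,
    stage: str = "",
    n_rep: int = N_REP_DEFAULT,
    null_value: float = ORI_NULL,
    seed: int = 0,
) -> ORIResult:
    """Resampled-background ORI with a one-sided t-test against 1.2.

    Each of ``n_rep`` replicates draws a fresh length-matched background
    from the complement pool and yields one ORI value against the fixed
    target summary; the one-sample t-test asks whether the mean ORI
    exceeds ``null_value``.
    """
    if n_rep < 2:
        raise ValueError("n_rep must be >= 2 for the t-test")
    target = summarize_hits(target_regions, hits)
    oris = np.empty(n_rep)
    fb_list = np.empty(n_rep)
    db_list = np.empty(n_rep)
    for rep in range(n_rep):
        bg_regions = sample_matched_background(
            target_regions, pool, rng=seed + rep + 1
        )
        bg = summarize_hits(bg_regions, hits)
        oris[rep] = compute_ori(target, bg)
        fb_list[rep] = (bg.n_seqs_with_hit + 0.5) / (bg.n_seqs + 1)
        db_list[rep] = (bg.total_hits + 0.5) / bg.total_kb
    mean = float(oris.mean())
    if oris.std(ddof=1) == 0.0:
        t_stat = float("inf") if mean > null_value else float("-inf")
        p = 0.0 if mean > null_value else 1.0
    else:
        t_stat, p = stats.ttest_1samp(oris, null_value, alternative="greater")
        t_stat, p = float(t_stat), float(p)
    return ORIResult(
        motif_id=hits.motif_id,
        stage=stage,
        ori_values=oris,
        ori_mean=mean,
        freq_target=(target.n_seqs_with_hit + 0.5) / (target.n_seqs + 1),
        density_target=(target.total_hits + 0.5) / target.total_kb,
        freq_background=float(fb_list.mean()),
        density_background=float(db_list.mean()),
        t_statistic=t_stat,
        p_one_sided=p,
        pct_dors_with_motif=100.0 * target.n_seqs_with_hit / max(1, target.n_seqs),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone-enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_ori_results(
    results: list[ORIResult], q_threshold: float = 0.05
) -> list[ORIResult]:
    """BH-adjust ORI p-values across motifs (within one stage)."""
    q = bh_adjust([r.p_one_sided for r in results])
    for r, qi in zip(results, q):
        r.bh_q = float(qi)
    del q_threshold  # significance judged by callers against r.bh_q
    return results


def ori_ratio(ori_a: ORIResult, ori_b: ORIResult) -> float:
    """log2 of the stage-A over stage-B mean ORI for one motif."""
    if ori_a.motif_id != ori_b.motif_id:
        raise ValueError("ORI ratio requires the same motif in both stages")
    if ori_a.ori_mean <= 0 or ori_b.ori_mean <= 0:
        raise ValueError("ORI ratio requires positive mean ORIs")
    return float(np.log2(ori_a.ori_mean / ori_b.ori_mean))


# ---------------------------------------------------------------------------
# HOMER-style cumulative binomial
# ---------------------------------------------------------------------------


def binomial_enrichment(
    target_regions: list[Region],
    background_regions: list[Region],
    hits: GenomeHits,
    stage: str = "",
) -> BinomialEnrichmentResult:
    """Upper-tail binomial test of the target per-region motif frequency
    against the background frequency estimate."""
    t_counts = hits.counts_in(target_regions)
    b_counts = hits.counts_in(background_regions)
    n = len(target_regions)
    k = int((t_counts > 0).sum())
    n_bg = len(background_regions)
    f_b = float((b_counts > 0).mean()) if n_bg else 0.0
    if f_b == 0.0:
        f_b = 0.5 / (n_bg + 1)
        logger.warning(
            "motif %s: background frequency 0; substituting %g",
            hits.motif_id, f_b,
        )
    f_t = k / n if n else 0.0
    p = float(stats.binom.sf(k - 1, n, f_b)) if n else 1.0
    return BinomialEnrichmentResult(
        motif_id=hits.motif_id,
        stage=stage,
        n_dors=n,
        k_dors_with_motif=k,
        f_target=f_t,
        f_background=f_b,
        fold=f_t / f_b,
        p_binomial=p,
    )


def adjust_binomial_results(
    results: list[BinomialEnrichmentResult],
    fold_min: float = 2.0,
    freq_min: float = 0.05,
    q_threshold: float = 0.01,
) -> list[BinomialEnrichmentResult]:
    """BH across motifs, then apply the fold / frequency / q filters."""
    q = bh_adjust([r.p_binomial for r in results])
    for r, qi in zip(results, q):
        r.bh_q = float(qi)
        r.passes_filters = (
            r.fold >= fold_min and r.f_target > freq_min and r.bh_q < q_threshold
        )
    return results


# ---------------------------------------------------------------------------
# CREB target genes
# ---------------------------------------------------------------------------


def creb_targets(
    diff_expr: list[DifferentialResult],
    assignments: list[RegionAssignment],
    ocr_hit_counts: dict[str, int],
    promoter_only: bool = True,
) -> tuple[pd.DataFrame, int, int]:
    """Count DEGs whose gene-associated OCRs contain >= 1 binding site.

    Among significant DEGs having at least one promoter-class OCR (or any
    gene-associated OCR when ``promoter_only`` is False), flags those
    with a motif hit in one of those OCRs. Returns (per-gene table,
    n_degs_with_ocr, n_with_motif).
    """
    classes = ("promoter",) if promoter_only else ("promoter", "genic", "distal")
    ocrs_of_gene: dict[str, list[str]] = {}
    for a in assignments:
        if a.gene_id is not None and a.region_class in classes:
            ocrs_of_gene.setdefault(a.gene_id, []).append(a.peak_id)
    rows = []
    for r in diff_expr:
        if not r.is_significant:
            continue
        ocrs = ocrs_of_gene.get(r.feature_id)
        if not ocrs:
            continue
        n_hits = sum(ocr_hit_counts.get(o, 0) for o in ocrs)
        rows.append((r.feature_id, r.log2fc, len(ocrs), n_hits, n_hits > 0))
    table = pd.DataFrame(
        rows,
        columns=["gene_id", "expr_log2fc", "n_ocrs", "n_motif_hits", "is_target"],
    )
    return table, len(table), int(table["is_target"].sum()) if len(table) else 0


def ori_results_to_frame(results: list[ORIResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "motif_id": [r.motif_id for r in results],
            "stage": [r.stage for r in results],
            "ori_mean": [r.ori_mean for r in results],
            "freq_target": [r.freq_target for r in results],
            "density_target": [r.density_target for r in results],
            "freq_background": [r.freq_background for r in results],
            "density_background": [r.density_background for r in results],
            "t": [r.t_statistic for r in results],
            "p": [r.p_one_sided for r in results],
            "q": [r.bh_q for r in results],
            "pct_dors_with_motif": [r.pct_dors_with_motif for r in results],
        }
    )


def binomial_results_to_frame(
    results: list[BinomialEnrichmentResult],
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "motif_id": [r.motif_id for r in results],
            "stage": [r.stage for r in results],
            "n_dors": [r.n_dors for r in results],
            "k_with_motif": [r.k_dors_with_motif for r in results],
            "f_target": [r.f_target for r in results],
            "f_background": [r.f_background for r in results],
            "fold": [r.fold for r in results],
            "p": [r.p_binomial for r in results],
            "q": [r.bh_q for r in results],
            "passes_filters": [r.passes_filters for r in results],
        }
    )
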