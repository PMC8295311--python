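"""Reproducible OCR calling, peak-to-gene assignment, accessibility scores.

Replicate peak sets are intersected into reproducible open-chromatin
regions (OCRs): only intervals supported by both biological replicates
survive, with the union footprint and the mean of the contributing
heights. Each OCR is then assigned to at most one gene by region class —
promoter (center within 3 kb of the nearest TSS), genic (overlapping a
gene span), distal (3-100 kb from the nearest TSS) or unassigned — and
per-gene accessibility is the sum of assigned OCR heights per class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .formats_io import CountMatrix, GeneModel, Peak, PeakSet

logger = logging.getLogger(__name__)

PROMOTER_WINDOW = 3_000
DISTAL_WINDOW = 100_000

REGION_CLASSES = ("promoter", "genic", "distal", "unassigned")


@dataclass(frozen=True)
class RegionAssignment:
    peak_id: str
    gene_id: str | None
    region_class: str
    signed_distance: int | None  # bp from peak center to TSS, upstream < 0


@dataclass(frozen=True)
class AccessibilityScore:
    gene_id: str
    region_class: str
    stage: str
    score: float
    n_ocrs: int


def reproducible_ocrs(rep1: PeakSet, rep2: PeakSet) -> PeakSet:
    """Intersect two replicate peak sets into reproducible OCRs.

    Overlapping peaks (>= 1 bp) are clustered transitively across both
    replicates; a cluster containing peaks from both replicates becomes
    one OCR spanning the union interval with the arithmetic mean of all
    contributing heights. Replicate-unique clusters are dropped.
    """
    if rep1.stage is not None and rep2.stage is not None and rep1.stage != rep2.stage:
        raise ValueError(
            f"replicates from different stages: {rep1.stage!r} vs {rep2.stage!r}"
        )
    stage = rep1.stage or rep2.stage
    tagged = [(p, 0) for p in rep1] + [(p, 1) for p in rep2]
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))

    ocrs: list[Peak] = []
    cluster: list[tuple[Peak, int]] = []

    def flush() -> None:
        if not cluster:
            return
        reps = {r for _, r in cluster}
        if reps == {0, 1}:
            start = min(p.start for p, _ in cluster)
            end = max(p.end for p, _ in cluster)
            height = float(np.mean([p.height for p, _ in cluster]))
            chrom = cluster[0][0].chrom
            ocrs.append(
                Peak(
                    chrom=chrom,
                    start=start,
                    end=end,
                    peak_id=f"{stage or 'ocr'}:{chrom}:{start}-{end}",
                    height=height,
                    sample_id=f"{stage or 'merged'}_ocr",
                )
            )
        cluster.clear()

    cur_chrom: str | None = None
    cur_end = -1
    for peak, rep in tagged:
        if peak.chrom != cur_chrom or peak.start >= cur_end:
            flush()
            cur_chrom = peak.chrom
            cur_end = peak.end
        else:
            cur_end = max(cur_end, peak.end)
        cluster.append((peak, rep))
    flush()
    return PeakSet(sample_id=f"{stage or 'merged'}_ocr", stage=stage, peaks=ocrs)


def merge_peaksets(sets: list[PeakSet], sample_id: str = "union") -> PeakSet:
    """Transitively merge overlapping peaks across sets (union intervals,
    mean heights); used to build the cross-stage OCR reference."""
    allp = sorted(
        (p for s in sets for p in s), key=lambda p: (p.chrom, p.start, p.end)
    )
    merged: list[Peak] = []
    cluster: list[Peak] = []

    def flush() -> None:
        if not cluster:
            return
        start = min(p.start for p in cluster)
        end = max(p.end for p in cluster)
        chrom = cluster[0].chrom
        merged.append(
            Peak(
                chrom=chrom,
                start=start,
                end=end,
                peak_id=f"{sample_id}:{chrom}:{start}-{end}",
                height=float(np.mean([p.height for p in cluster])),
                sample_id=sample_id,
            )
        )
        cluster.clear()

    cur_chrom, cur_end = None, -1
    for p in allp:
        if p.chrom != cur_chrom or p.start >= cur_end:
            flush()
            cur_chrom, cur_end = p.chrom, p.end
        else:
            cur_end = max(cur_end, p.end)
        cluster.append(p)
    flush()
    return PeakSet(sample_id=sample_id, stage=None, peaks=merged)


class _GeneIndex:
    """Per-chromosome sorted TSS arrays and gene-span interval trees."""

    def __init__(self, genes: list[GeneModel]):
        self.by_chrom: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
        self.span_trees: dict[str, IntervalTree] = {}
        chroms: dict[str, list[GeneModel]] = {}
        for g in genes:
            chroms.setdefault(g.chrom, []).append(g)
        for chrom, gs in chroms.items():
            # sort by (tss, gene_id) so equidistant ties resolve lexicographically
            gs_sorted = sorted(gs, key=lambda g: (g.tss, g.gene_id))
            self.by_chrom[chrom] = (
                np.array([g.tss for g in gs_sorted]),
                gs_sorted,
            )
            tree = IntervalTree()
            for g in gs:
                tree[g.span_start:g.span_end] = g
            self.span_trees[chrom] = tree

    def nearest_tss(self, chrom: str, pos: int) -> tuple[GeneModel, int] | None:
        """Nearest gene by |TSS - pos|; ties by smaller |distance| then id."""
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return None
        tss_arr, gs = entry
        i = int(np.searchsorted(tss_arr, pos))
        best: tuple[int, str, GeneModel] | None = None
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(gs):
                g = gs[j]
                d = abs(g.tss - pos)
                key = (d, g.gene_id)
                if best is None or key < (best[0], best[1]):
                    best = (d, g.gene_id, g)
        if best is None:
            return None
        return best[2], best[0]

    def overlapping_genes(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self.span_trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree[start:end]]


def _signed_distance(gene: GeneModel, center: int) -> int:
    """Distance from peak center to TSS, negative upstream of the gene."""
    d = center - gene.tss
    return d if gene.strand == "+" else -d


def assign_peaks(
    ocrs: PeakSet,
    genes: list[GeneModel],
    promoter_window: int = PROMOTER_WINDOW,
    distal_window: int = DISTAL_WINDOW,
) -> list[RegionAssignment]:
    """Assign each OCR to exactly one gene/region class.

    Precedence: promoter (|center - nearest TSS| <= promoter_window) >
    genic (>= 1 bp overlap with a gene span) > distal (promoter_window <
    |d| <= distal_window) > unassigned.
    """
    if not genes:
        logger.warning("empty gene list: all OCRs unassigned")
        return [
            RegionAssignment(p.peak_id, None, "unassigned", None) for p in ocrs
        ]
    index = _GeneIndex(genes)
    out: list[RegionAssignment] = []
    for p in ocrs:
        center = p.center
        near = index.nearest_tss(p.chrom, center)
        if near is not None:
            gene, dist = near
            if dist <= promoter_window:
                out.append(
                    RegionAssignment(
                        p.peak_id, gene.gene_id, "promoter",
                        _signed_distance(gene, center),
                    )
                )
                continue
        overlapping = index.overlapping_genes(p.chrom, p.start, p.end)
        if overlapping:
            g = min(
                overlapping,
                key=lambda g: (abs(g.tss - center), g.gene_id),
            )
            out.append(
                RegionAssignment(
                    p.peak_id, g.gene_id, "genic", _signed_distance(g, center)
                )
            )
            continue
        if near is not None and near[1] <= distal_window:
            gene, _ = near
            out.append(
                RegionAssignment(
                    p.peak_id, gene.gene_id, "distal",
                    _signed_distance(gene, center),
                )
            )
            continue
        out.append(RegionAssignment(p.peak_id, None, "unassigned", None))
    return out


def accessibility_scores(
    assignments: list[RegionAssignment],
    ocrs: PeakSet,
    stage: str,
    genes: list[GeneModel] | None = None,
) -> list[AccessibilityScore]:
    """Per (gene, region class): sum of assigned OCR heights in one stage.

    If ``genes`` is given, every (gene, class) combination is reported,
    with zero-score entries for genes lacking OCRs in a class.
    """
    height_of = {p.peak_id: p.height for p in ocrs}
    acc: dict[tuple[str, str], tuple[float, int]] = {}
    for a in assignments:
        if a.gene_id is None or a.peak_id not in height_of:
            continue
        key = (a.gene_id, a.region_class)
        score, n = acc.get(key, (0.0, 0))
        acc[key] = (score + height_of[a.peak_id], n + 1)
    if genes is not None:
        for g in genes:
            for cls in ("promoter", "genic", "distal"):
                acc.setdefault((g.gene_id, cls), (0.0, 0))
    return [
        AccessibilityScore(gene_id=gid, region_class=cls, stage=stage,
                           score=score, n_ocrs=n)
        for (gid, cls), (score, n) in sorted(acc.items())
    ]


def scores_to_frame(scores: list[AccessibilityScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in scores],
            "region_class": [s.region_class for s in scores],
            "stage": [s.stage for s in scores],
            "score": [s.score for s in scores],
            "n_ocrs": [s.n_ocrs for s in scores],
        }
    )


def tss_distance_profile(
    ocrs: PeakSet,
    genes: list[GeneModel],
    window: int = 5_000,
    binsize: int = 100,
) -> pd.DataFrame:
    """Histogram of strand-oriented OCR-center distances to the nearest TSS.

    Bins cover [-window, window); only OCRs whose nearest-TSS distance
    falls inside the window contribute.
    """
    if window % binsize != 0:
        raise ValueError("window must be a multiple of binsize")
    index = _GeneIndex(genes)
    dists = []
    for p in ocrs:
        near = index.nearest_tss(p.chrom, p.center)
        if near is None:
            continue
        gene, _ = near
        d = _signed_distance(gene, p.center)
        if -window <= d < window:
            dists.append(d)
    # bins are centered on 0 (e.g. [-50, 50) for binsize 100) so the
    # TSS-proximal mode falls into a single unambiguous bin
    edges = np.arange(-window - binsize / 2, window + binsize, binsize)
    counts, _ = np.histogram(dists, bins=edges)
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
    )


def ocr_counts(
    reference: PeakSet,
    samples: list[PeakSet],
    stage_of: dict[str, str],
    scale: float = 1.0,
) -> CountMatrix:
    """Per-reference-OCR pseudo-counts from sample peak heights.

    For each reference OCR and sample, sums the heights of sample peaks
    overlapping the OCR and rounds to an integer — the accessibility
    analogue of reads-in-peaks counting when only normalized heights are
    available.
    """
    trees: dict[str, IntervalTree] = {}
    for p in reference:
        trees.setdefault(p.chrom, IntervalTree())[p.start:p.end] = p.peak_id
    idx = {p.peak_id: i for i, p in enumerate(reference)}
    mat = np.zeros((len(reference), len(samples)))
    for j, s in enumerate(samples):
        for p in s:
            tree = trees.get(p.chrom)
            if tree is None:
                continue
            for iv in tree[p.start:p.end]:
                mat[idx[iv.data], j] += p.height
    counts = np.rint(mat * scale).astype(np.int64)
    return CountMatrix(
        feature_ids=[p.peak_id for p in reference],
        sample_ids=[s.sample_id for s in samples],
        counts=counts,
        stage_of=dict(stage_of),
    )
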