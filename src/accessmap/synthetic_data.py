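"""Coupled synthetic data with known ground truth.

Emulates a two-stage (embryonic-like vs postnatal-like), two-replicate
ATAC + RNA design on a synthetic genome: gene models placed without
overlap on one chromosome; open-chromatin peaks concentrated near TSSs
(Laplace-distributed offsets); a designated fraction of genes carrying a
stage-specific differentially open promoter peak; negative-binomial
expression counts whose stage log2 fold changes are correlated with the
promoter-accessibility log2 fold changes at a configurable coupling rho;
and peak sequences with motif instances planted at stage-specific
frequencies for enrichment testing.

All randomness flows from ``config.seed`` through named sub-streams
(annotation / peaks / expression / sequences), so regenerating one stage
never perturbs the others.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .formats_io import CountMatrix, GeneModel, Peak, PeakSet, PWMRecord
from .motif_scan import decode_sequence

_STREAMS = {"annotation": 0, "peaks": 1, "expression": 2, "sequences": 3}


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic two-stage experiment."""

    n_genes: int = 1500
    chrom_length: int = 30_000_000
    chrom_name: str = "chrS"
    n_peaks_per_sample: int = 4000
    fraction_tss_proximal: float = 0.7
    tss_scale: float = 200.0               # bp, Laplace scale around the TSS
    peak_width_log_mean: float = math.log(400.0)
    peak_width_log_sd: float = 0.25
    height_log_mean: float = math.log(50.0)
    height_log_sd: float = 0.6
    replicate_noise_sd: float = 0.1        # log-scale replicate height noise
    fraction_dor_genes: float = 0.1
    dor_log2fc_mean: float = 3.0
    dor_log2fc_sd: float = 0.25
    nb_dispersion: float = 0.1
    coupling: float = 0.5                  # target acc/expr log2FC correlation
    motif_plant_freq_target: float = 0.6
    motif_plant_freq_background: float = 0.01
    background_base_composition: tuple[float, float, float, float] = (
        0.25, 0.25, 0.25, 0.25,
    )
    seed: int = 0
    stages: tuple[str, str] = ("E21", "P11")
    n_replicates: int = 2            # ATAC replicates per stage
    n_expr_replicates: int = 4       # RNA replicates per stage
    expr_baseline_log2_mean: float = 5.0
    expr_baseline_log2_sd: float = 1.0
    expr_depth_sd: float = 0.15
    gene_span_log_mean: float = math.log(8000.0)
    gene_span_log_sd: float = 0.5
    motif_target_stage: str | None = None  # defaults to stages[0]
    couple_baseline: bool = True
    min_peak_width: int = 50
    promoter_offset_max: int = 1000        # DOR promoter peak center vs TSS

    def __post_init__(self) -> None:
        fracs = {
            "fraction_tss_proximal": self.fraction_tss_proximal,
            "fraction_dor_genes": self.fraction_dor_genes,
            "motif_plant_freq_target": self.motif_plant_freq_target,
            "motif_plant_freq_background": self.motif_plant_freq_background,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if not -1.0 <= self.coupling <= 1.0:
            raise ConfigError("coupling must lie in [-1, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        for name in ("chrom_length", "n_peaks_per_sample", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_genes < 0:
            raise ConfigError("n_genes must be non-negative")
        bg = np.asarray(self.background_base_composition, dtype=float)
        if bg.shape != (4,) or np.any(bg <= 0) or not np.isclose(bg.sum(), 1.0):
            raise ConfigError(
                "background_base_composition must be 4 positive values summing to 1"
            )
        if self.motif_target_stage is None:
            self.motif_target_stage = self.stages[0]
        if self.motif_target_stage not in self.stages:
            raise ConfigError(
                f"motif_target_stage {self.motif_target_stage!r} "
                f"not among stages {self.stages}"
            )

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery scoring."""

    dor_gene_ids: dict[str, list[str]] = field(default_factory=dict)
    acc_log2fc: dict[str, float] = field(default_factory=dict)
    expr_log2fc: dict[str, float] = field(default_factory=dict)
    dor_promoter_peak: dict[str, str] = field(default_factory=dict)
    baseline_promoter_score: dict[str, float] = field(default_factory=dict)
    stage_promoter_score: dict[str, dict[str, float]] = field(default_factory=dict)
    expr_log2_mean: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_sites: dict[str, list[tuple[int, str]]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class Genome:
    """Encoded synthetic chromosomes (uint8 codes: A=0 C=1 G=2 T=3)."""

    codes: dict[str, np.ndarray]

    @property
    def sizes(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.codes.items()}

    def sequence(self, chrom: str, start: int, end: int) -> str:
        return decode_sequence(self.codes[chrom][start:end])

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, arr in self.codes.items():
                fh.write(f">{chrom}\n")
                seq = decode_sequence(arr)
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------


def simulate_annotation(config: SimulationConfig) -> list[GeneModel]:
    """Place non-overlapping genes with alternating strands uniformly."""
    rng = config.rng("annotation")
    n = config.n_genes
    if n == 0:
        return []
    spans = np.maximum(
        200,
        np.rint(
            rng.lognormal(config.gene_span_log_mean, config.gene_span_log_sd, n)
        ).astype(int),
    )
    total = int(spans.sum())
    if total >= 0.95 * config.chrom_length:
        raise ConfigError(
            f"cannot pack {n} genes totalling {total} bp into "
            f"{config.chrom_length} bp"
        )
    # keep genes away from chromosome ends so promoter windows and
    # TSS-centered peaks never truncate
    margin = min(5000, config.chrom_length // 20)
    free = config.chrom_length - total - 2 * margin
    if free <= 0:
        raise ConfigError("chromosome too short for gene margin")
    cuts = np.sort(rng.uniform(0, free, n)).astype(int)
    starts = margin + cuts + np.concatenate([[0], np.cumsum(spans[:-1])])
    genes: list[GeneModel] = []
    for i in range(n):
        start, end = int(starts[i]), int(starts[i] + spans[i])
        strand = "+" if i % 2 == 0 else "-"
        n_exons = min(1 + rng.poisson(1.5), max(1, (end - start) // 400))
        if n_exons > 1:
            inner = np.sort(
                rng.choice(
                    np.arange(start + 1, end - 1), 2 * (n_exons - 1),
                    replace=False,
                )
            )
            bounds = [start, *inner.tolist(), end]
        else:
            bounds = [start, end]
        exons = tuple(
            (bounds[2 * k], bounds[2 * k + 1]) for k in range(len(bounds) // 2)
        )
        genes.append(
            GeneModel(f"gene{i:05d}", config.chrom_name, strand, start, end, exons)
        )
    return genes


def simulate_peaks(
    annotation: list[GeneModel], config: SimulationConfig
) -> tuple[dict[tuple[str, int], PeakSet], PeakSet, GroundTruth]:
    """Generate stage x replicate peak sets over one shared peak template.

    Returns ({(stage, replicate): PeakSet}, master template with baseline
    heights, GroundTruth). Every DOR-designated gene gets a guaranteed
    promoter peak whose height in its favored stage is scaled by
    2^L, L ~ N(dor_log2fc_mean, dor_log2fc_sd).
    """
    rng = config.rng("peaks")
    gt = GroundTruth()
    stage_a, stage_b = config.stages

    n_dor = int(round(config.fraction_dor_genes * len(annotation)))
    dor_idx = (
        rng.choice(len(annotation), n_dor, replace=False) if n_dor else
        np.array([], dtype=int)
    )
    half = n_dor // 2
    favored_of: dict[int, str] = {}
    for k, gi in enumerate(dor_idx):
        favored_of[int(gi)] = stage_a if k < half else stage_b
    gt.dor_gene_ids = {
        st: sorted(
            annotation[gi].gene_id for gi, f in favored_of.items() if f == st
        )
        for st in config.stages
    }

    tss = np.array([g.tss for g in annotation], dtype=int)

    def draw_width() -> int:
        w = int(round(rng.lognormal(config.peak_width_log_mean,
                                    config.peak_width_log_sd)))
        return max(config.min_peak_width, w)

    # --- master template: guaranteed DOR promoter peaks first. Only the
    # DOR promoter peaks are protected from overlap (so their planted fold
    # change is never diluted by a merged neighbour); background peaks may
    # overlap each other, as real peak calls near busy promoters do.
    entries: list[dict] = []  # chrom fixed; center/width/height/gene
    protected: list[tuple[int, int]] = []

    def clear_of_protected(start: int, end: int) -> bool:
        return all(end <= s or start >= e for s, e in protected)

    for gi in sorted(favored_of):
        g = annotation[gi]
        width = draw_width()
        off = int(np.rint(np.clip(rng.laplace(0, config.tss_scale),
                                  -config.promoter_offset_max,
                                  config.promoter_offset_max)))
        center = int(np.clip(g.tss + off, width // 2,
                             config.chrom_length - width // 2 - 1))
        start, end = center - width // 2, center - width // 2 + width
        entries.append({"start": start, "end": end, "gene": gi,
                        "height": rng.lognormal(config.height_log_mean,
                                                config.height_log_sd)})
        protected.append((start, end))

    n_bg = max(0, config.n_peaks_per_sample - len(entries))
    attempts = 0
    while len(entries) < config.n_peaks_per_sample and attempts < 20 * n_bg + 100:
        attempts += 1
        width = draw_width()
        if len(tss) and rng.random() < config.fraction_tss_proximal:
            g = int(rng.integers(len(tss)))
            center = int(np.rint(tss[g] + rng.laplace(0, config.tss_scale)))
        else:
            center = int(rng.uniform(0, config.chrom_length))
        center = int(np.clip(center, width // 2,
                             config.chrom_length - width // 2 - 1))
        start, end = center - width // 2, center - width // 2 + width
        if not clear_of_protected(start, end):
            continue
        entries.append({"start": start, "end": end, "gene": None,
                        "height": rng.lognormal(config.height_log_mean,
                                                config.height_log_sd)})

    entries.sort(key=lambda e: e["start"])
    peak_ids = [f"peak{i:05d}" for i in range(len(entries))]

    # ground truth: per-gene accessibility log2FC (stage A over stage B)
    for g in annotation:
        gt.acc_log2fc[g.gene_id] = 0.0
    fc_of_entry = np.zeros(len(entries))
    for i, e in enumerate(entries):
        if e["gene"] is None:
            continue
        gi = e["gene"]
        g = annotation[gi]
        L = float(rng.normal(config.dor_log2fc_mean, config.dor_log2fc_sd))
        sign = 1.0 if favored_of[gi] == stage_a else -1.0
        fc_of_entry[i] = sign * L
        gt.acc_log2fc[g.gene_id] = sign * L
        gt.dor_promoter_peak[g.gene_id] = peak_ids[i]

    # true promoter accessibility per gene (peaks within 3 kb of TSS):
    # baseline (pre-fold-change) and per-stage noise-free scores
    order = np.argsort(tss) if len(tss) else np.array([], dtype=int)
    tss_sorted = tss[order]
    base_scores = np.zeros(len(annotation))
    stage_scores = {st: np.zeros(len(annotation)) for st in config.stages}
    for i, e in enumerate(entries):
        center = (e["start"] + e["end"]) // 2
        if not len(tss_sorted):
            continue
        j = int(np.searchsorted(tss_sorted, center))
        best, bestd = None, None
        for k in (j - 1, j, j + 1):
            if 0 <= k < len(tss_sorted):
                d = abs(int(tss_sorted[k]) - center)
                if bestd is None or d < bestd:
                    best, bestd = int(order[k]), d
        if best is not None and bestd is not None and bestd <= 3000:
            base_scores[best] += e["height"]
            for st in config.stages:
                sgn = 1.0 if st == stage_a else -1.0
                stage_scores[st][best] += e["height"] * 2.0 ** max(
                    sgn * fc_of_entry[i], 0.0
                )
    for gi, g in enumerate(annotation):
        gt.baseline_promoter_score[g.gene_id] = float(base_scores[gi])
    gt.stage_promoter_score = {
        st: {g.gene_id: float(stage_scores[st][gi])
             for gi, g in enumerate(annotation)}
        for st in config.stages
    }

    # --- realize per-sample heights
    base_h = np.array([e["height"] for e in entries])
    master = PeakSet(
        sample_id="master", stage=None,
        peaks=[
            Peak(config.chrom_name, e["start"], e["end"], pid,
                 float(h), "master")
            for e, pid, h in zip(entries, peak_ids, base_h)
        ],
    )
    peaksets: dict[tuple[str, int], PeakSet] = {}
    for stage in config.stages:
        sign = 1.0 if stage == stage_a else -1.0
        stage_h = base_h * np.power(2.0, np.maximum(sign * fc_of_entry, 0.0))
        for rep in range(1, config.n_replicates + 1):
            noise = np.exp(rng.normal(0.0, config.replicate_noise_sd,
                                      len(entries)))
            sample = f"{stage}_rep{rep}"
            peaksets[(stage, rep)] = PeakSet(
                sample_id=sample, stage=stage,
                peaks=[
                    Peak(config.chrom_name, e["start"], e["end"], pid,
                         float(h), sample)
                    for e, pid, h in zip(entries, peak_ids, stage_h * noise)
                ],
            )
    return peaksets, master, gt


def simulate_expression(
    annotation: list[GeneModel],
    ground_truth: GroundTruth,
    config: SimulationConfig,
) -> CountMatrix:
    """NB expression counts whose log2FCs are coupled to accessibility.

    The per-gene expression log2FC is rho * standardized accessibility
    log2FC plus independent noise, rescaled to the accessibility-change
    spread. The baseline log2 mean is likewise coupled (at the same rho)
    to baseline promoter accessibility so that within-stage
    accessibility-expression correlation mirrors the change coupling.
    """
    rng = config.rng("expression")
    n = len(annotation)
    rho = config.coupling
    gene_ids = [g.gene_id for g in annotation]

    a = np.array([ground_truth.acc_log2fc[g] for g in gene_ids])
    sd_a = a.std()
    if sd_a > 0:
        z_a = (a - a.mean()) / sd_a
        eps = rng.normal(0.0, 1.0, n)
        l2fc = (rho * z_a + math.sqrt(1 - rho**2) * eps) * sd_a
    else:
        rng.normal(0.0, 1.0, n)  # keep stream alignment
        l2fc = np.zeros(n)

    eta = rng.normal(0.0, 1.0, n)
    if config.couple_baseline and rho != 0.0:
        s = np.log2(1.0 + np.array(
            [ground_truth.baseline_promoter_score[g] for g in gene_ids]
        ))
        sd_s = s.std()
        z_s = (s - s.mean()) / sd_s if sd_s > 0 else np.zeros(n)
        b = (config.expr_baseline_log2_mean
             + config.expr_baseline_log2_sd
             * (rho * z_s + math.sqrt(1 - rho**2) * eta))
    else:
        b = config.expr_baseline_log2_mean + config.expr_baseline_log2_sd * eta

    stage_a, stage_b = config.stages
    mu = {
        stage_a: np.power(2.0, b + l2fc / 2.0),
        stage_b: np.power(2.0, b - l2fc / 2.0),
    }
    phi = config.nb_dispersion
    nb_n = 1.0 / phi
    sample_ids, cols, stage_of = [], [], {}
    for stage in config.stages:
        for rep in range(1, config.n_expr_replicates + 1):
            depth = math.exp(rng.normal(0.0, config.expr_depth_sd))
            m = mu[stage] * depth
            cols.append(rng.negative_binomial(nb_n, nb_n / (nb_n + m)))
            sid = f"{stage}_rna{rep}"
            sample_ids.append(sid)
            stage_of[sid] = stage
    ground_truth.expr_log2fc = dict(zip(gene_ids, l2fc.astype(float)))
    ground_truth.expr_log2_mean = {
        stage_a: dict(zip(gene_ids, (b + l2fc / 2.0).astype(float))),
        stage_b: dict(zip(gene_ids, (b - l2fc / 2.0).astype(float))),
    }
    return CountMatrix(
        feature_ids=gene_ids,
        sample_ids=sample_ids,
        counts=np.column_stack(cols).astype(np.int64),
        stage_of=stage_of,
    )


def simulate_sequences(
    master: PeakSet,
    pwm: PWMRecord,
    config: SimulationConfig,
    ground_truth: GroundTruth,
) -> tuple[Genome, dict[str, str]]:
    """Realize the genome sequence and plant motif instances in peaks.

    Background bases are i.i.d. from the configured composition. Promoter
    peaks of DOR genes favoring ``motif_target_stage`` receive one
    PWM-sampled site with probability motif_plant_freq_target; every
    other peak with probability motif_plant_freq_background. Plants are
    written into the genome, so peak sequences and complement-region
    background sequences come from one coherent molecule.
    """
    rng = config.rng("sequences")
    bg = np.asarray(config.background_base_composition, dtype=float)
    codes = rng.choice(4, size=config.chrom_length, p=bg).astype(np.uint8)
    W = pwm.width
    target_peaks = {
        ground_truth.dor_promoter_peak[g]
        for g in ground_truth.dor_gene_ids.get(config.motif_target_stage, [])
        if g in ground_truth.dor_promoter_peak
    }
    ground_truth.planted_sites = {}
    for p in master:
        if p.width < W:
            if (config.motif_plant_freq_background > 0
                    or p.peak_id in target_peaks):
                import logging
                logging.getLogger(__name__).warning(
                    "peak %s shorter than motif width; skipped", p.peak_id
                )
            continue
        freq = (config.motif_plant_freq_target if p.peak_id in target_peaks
                else config.motif_plant_freq_background)
        if rng.random() >= freq:
            continue
        site = np.array(
            [rng.choice(4, p=pwm.probs[:, j]) for j in range(W)],
            dtype=np.uint8,
        )
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            site = (3 - site)[::-1]
        offset = int(rng.integers(0, p.width - W + 1))
        codes[p.start + offset:p.start + offset + W] = site
        ground_truth.planted_sites.setdefault(p.peak_id, []).append(
            (offset, strand)
        )
    genome = Genome({config.chrom_name: codes})
    peak_seqs = {
        p.peak_id: genome.sequence(p.chrom, p.start, p.end) for p in master
    }
    return genome, peak_seqs


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    annotation: list[GeneModel]
    peaksets: dict[tuple[str, int], PeakSet]
    master: PeakSet
    expression: CountMatrix
    genome: Genome | None
    peak_sequences: dict[str, str]
    ground_truth: GroundTruth


def simulate_all(
    config: SimulationConfig, pwm: PWMRecord | None = None
) -> SimulatedDataset:
    """Run annotation -> peaks -> expression -> (optional) sequences."""
    annotation = simulate_annotation(config)
    peaksets, master, gt = simulate_peaks(annotation, config)
    expression = simulate_expression(annotation, gt, config)
    genome, peak_seqs = (None, {})
    if pwm is not None:
        genome, peak_seqs = simulate_sequences(master, pwm, config, gt)
    return SimulatedDataset(
        config=config, annotation=annotation, peaksets=peaksets,
        master=master, expression=expression, genome=genome,
        peak_sequences=peak_seqs, ground_truth=gt,
    )


def creb_like_pwm(width: int = 10, strength: float = 97.0) -> PWMRecord:
    """A synthetic CREB/ATF-like test matrix (consensus ATGACGTCAT).

    Synthetic stand-in for a curated CREB/ATF matrix: near-deterministic
    counts (``strength`` for the consensus base, 1 elsewhere) over an
    extended cAMP-response-element consensus.
    """
    from .formats_io import BASE_INDEX, counts_to_pwm

    consensus = "ATGACGTCATGACGTCAT"[:width]
    counts = np.ones((4, width))
    for j, base in enumerate(consensus):
        counts[BASE_INDEX[base], j] = strength
    return counts_to_pwm("CREB_ATF_synthetic", counts, pseudocount=0.25)


def decoy_pwms(
    n: int, width: int = 10, seed: int = 7, strength: float = 97.0
) -> list[PWMRecord]:
    """Random near-deterministic decoy motifs (not planted anywhere)."""
    from .formats_io import counts_to_pwm

    rng = np.random.default_rng([seed, 99])
    out = []
    for k in range(n):
        counts = np.ones((4, width))
        cons = rng.integers(0, 4, width)
        counts[cons, np.arange(width)] = strength
        out.append(counts_to_pwm(f"decoy{k:03d}", counts, pseudocount=0.25))
    return out
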