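"""End-to-end orchestration: simulate -> intersect -> assign -> differential
-> correlate -> scan -> enrich -> targets, as one reproducible run.

Every output lands in the run directory with a header carrying the
config hash and seed; rerunning with an identical config and seed
reproduces every file byte-for-byte.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from . import correlate, differential, enrichment, motif_scan, peak_gene
from . import formats_io, synthetic_data
from .formats_io import write_narrowpeak, write_gene_models, write_counts
from .synthetic_data import SimulationConfig

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Validated thresholds and simulation settings for one pipeline run."""

    model_config = ConfigDict(extra="forbid")

    seed: int = Field(default=0, ge=0, lt=2**31)
    out_dir: str = "accessmap_run"
    simulation: dict[str, Any] = Field(default_factory=dict)
    lfc: float = Field(default=1.0, ge=0)
    fdr: float = Field(default=0.01, gt=0, lt=1)
    promoter_window: int = Field(default=3_000, gt=0)
    distal_window: int = Field(default=100_000, gt=0)
    alpha_hit: float = Field(default=1e-4, gt=0, lt=1)
    alpha_enrich: float = Field(default=1e-3, gt=0, lt=1)
    n_rep: int = Field(default=100, ge=2)
    ori_null: float = Field(default=1.2, gt=0)
    enrich_q: float = Field(default=0.05, gt=0, lt=1)
    binom_q: float = Field(default=0.01, gt=0, lt=1)
    fold_min: float = Field(default=2.0, ge=1)
    freq_min: float = Field(default=0.05, ge=0, lt=1)
    n_decoys: int = Field(default=7, ge=0)
    run_motifs: bool = True
    concordance_resolution: int = Field(default=5_000, gt=0)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(seed=self.seed, **self.simulation)


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config, with readable errors."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    known = set(RunConfig.model_fields)
    problems = []
    for key in raw:
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1, cutoff=0.4)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            problems.append(f"unknown key {key!r}{suffix}")
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))
    if "seed" not in raw:
        logger.warning("%s: no seed given; defaulting to 0", path)
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        msgs = [
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}"
            for e in exc.errors()
        ]
        raise ValueError(f"{path}: " + "; ".join(msgs)) from exc


def _write_tsv(df, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage in dependency order; returns the run summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# accessmap {__version__} seed={config.seed} config={config.config_hash()}\n"
    summary: dict[str, Any] = {
        "software": f"accessmap {__version__}",
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.model_dump(),
    }

    # --- simulate -----------------------------------------------------
    sim_cfg = config.sim_config()
    pwm = synthetic_data.creb_like_pwm() if config.run_motifs else None
    data = synthetic_data.simulate_all(sim_cfg, pwm=pwm)
    stage_a, stage_b = sim_cfg.stages
    gt = data.ground_truth

    write_gene_models(data.annotation, out / "genes.bed12")
    for (stage, rep), ps in data.peaksets.items():
        write_narrowpeak(ps, out / f"peaks_{stage}_rep{rep}.narrowPeak")
    write_counts(data.expression, out / "expression_counts.tsv")
    gt.to_json(out / "ground_truth.json")
    summary["ocrs_per_sample"] = {
        f"{st}_rep{r}": len(ps) for (st, r), ps in sorted(data.peaksets.items())
    }

    # --- reproducible OCRs -------------------------------------------
    stage_ocrs = {
        st: peak_gene.reproducible_ocrs(
            data.peaksets[(st, 1)], data.peaksets[(st, 2)]
        )
        for st in sim_cfg.stages
    }
    for st, ocrs in stage_ocrs.items():
        formats_io.write_peaks(ocrs, out / f"ocrs_{st}.bed")
    summary["reproducible_ocrs"] = {st: len(o) for st, o in stage_ocrs.items()}

    # --- cross-stage OCR reference, assignment, scores ----------------
    reference = peak_gene.merge_peaksets(list(stage_ocrs.values()), "ocr")
    assignments = peak_gene.assign_peaks(
        reference, data.annotation,
        config.promoter_window, config.distal_window,
    )
    class_counts = {c: 0 for c in peak_gene.REGION_CLASSES}
    for a in assignments:
        class_counts[a.region_class] += 1
    summary["ocr_region_classes"] = class_counts

    stage_scores = {}
    for st in sim_cfg.stages:
        st_assign = peak_gene.assign_peaks(
            stage_ocrs[st], data.annotation,
            config.promoter_window, config.distal_window,
        )
        stage_scores[st] = peak_gene.accessibility_scores(
            st_assign, stage_ocrs[st], st, genes=data.annotation
        )
        _write_tsv(
            peak_gene.scores_to_frame(stage_scores[st]),
            out / f"accessibility_scores_{st}.tsv", header,
        )
    profile = peak_gene.tss_distance_profile(reference, data.annotation)
    _write_tsv(profile, out / "tss_distance_profile.tsv", header)

    # --- differential expression --------------------------------------
    deg_results = differential.nb_wald_test(
        data.expression, config.lfc, config.fdr, stage_a, stage_b
    )
    _write_tsv(
        differential.results_to_frame(deg_results),
        out / "diffexp.tsv", header,
    )
    summary["degs"] = {
        "total": sum(r.is_significant for r in deg_results),
        f"up_{stage_a}": sum(
            r.is_significant and r.log2fc > 0 for r in deg_results
        ),
        f"up_{stage_b}": sum(
            r.is_significant and r.log2fc < 0 for r in deg_results
        ),
    }

    # --- differential accessibility (DORs) ----------------------------
    acc_counts = peak_gene.ocr_counts(
        reference,
        [data.peaksets[(st, r)] for st in sim_cfg.stages
         for r in range(1, sim_cfg.n_replicates + 1)],
        stage_of={
            f"{st}_rep{r}": st for st in sim_cfg.stages
            for r in range(1, sim_cfg.n_replicates + 1)
        },
    )
    dor_results, dor_direction = differential.call_dors(
        acc_counts, config.lfc, config.fdr, stage_a, stage_b
    )
    _write_tsv(
        differential.results_to_frame(dor_results),
        out / "diffacc.tsv", header,
    )
    assign_of = {a.peak_id: a for a in assignments}
    dor_class_counts: dict[str, dict[str, int]] = {
        st: {c: 0 for c in peak_gene.REGION_CLASSES} for st in sim_cfg.stages
    }
    promoter_dor_genes: dict[str, set[str]] = {st: set() for st in sim_cfg.stages}
    promoter_dor_regions: dict[str, list[enrichment.Region]] = {
        st: [] for st in sim_cfg.stages
    }
    peak_by_id = {p.peak_id: p for p in reference}
    for r in dor_results:
        if not r.is_significant:
            continue
        st = dor_direction[r.feature_id]
        a = assign_of[r.feature_id]
        dor_class_counts[st][a.region_class] += 1
        if a.region_class == "promoter" and a.gene_id is not None:
            promoter_dor_genes[st].add(a.gene_id)
            p = peak_by_id[r.feature_id]
            promoter_dor_regions[st].append((p.chrom, p.start, p.end))
    summary["dors"] = {
        st: int(sum(dor_class_counts[st].values())) for st in sim_cfg.stages
    }
    summary["dors_by_region_class"] = dor_class_counts
    summary["promoter_dor_genes"] = {
        st: len(promoter_dor_genes[st]) for st in sim_cfg.stages
    }

    # recovery of planted promoter-DOR genes, with correct direction
    recovery = {}
    for st in sim_cfg.stages:
        planted = set(gt.dor_gene_ids.get(st, []))
        if planted:
            recovery[st] = len(planted & promoter_dor_genes[st]) / len(planted)
    summary["planted_promoter_dor_recovery"] = recovery

    # --- correlations -------------------------------------------------
    corr: dict[str, Any] = {}
    try:
        c = correlate.stage_correlation(
            stage_scores[stage_a], data.expression, stage_a, "promoter"
        )
        corr[f"stage_{stage_a}_promoter"] = {"r": c.r, "p": c.p, "n": c.n}
    except correlate.InsufficientDataError:
        pass
    for cls in ("promoter", "distal"):
        try:
            c = correlate.change_correlation(
                stage_scores[stage_a], stage_scores[stage_b], deg_results, cls
            )
            corr[f"change_{cls}"] = {"r": c.r, "p": c.p, "n": c.n}
        except correlate.InsufficientDataError:
            pass
    chrom_sizes = {sim_cfg.chrom_name: sim_cfg.chrom_length}
    t1 = correlate.bin_peak_signal(
        data.peaksets[(stage_a, 1)], chrom_sizes, config.concordance_resolution
    )
    t2 = correlate.bin_peak_signal(
        data.peaksets[(stage_a, 2)], chrom_sizes, config.concordance_resolution
    )
    c = correlate.replicate_concordance(t1, t2, config.concordance_resolution)
    corr["replicate_concordance"] = {
        "r": c.r, "p": c.p, "n": c.n,
        "resolution": config.concordance_resolution,
    }
    prom_dors = [r for r in dor_results if r.is_significant
                 and assign_of[r.feature_id].region_class == "promoter"]
    conc_table, conc_frac = correlate.dor_expression_concordance(
        prom_dors, dor_direction, assignments, deg_results, stage_a
    )
    _write_tsv(conc_table, out / "dor_expression_concordance.tsv", header)
    corr["dor_expression_concordance_fraction"] = conc_frac
    summary["correlations"] = corr

    # --- motif scanning and enrichment --------------------------------
    if config.run_motifs and data.genome is not None:
        motifs = [synthetic_data.creb_like_pwm()] + synthetic_data.decoy_pwms(
            config.n_decoys, seed=config.seed
        )
        pool = enrichment.complement_regions(
            peak_gene.merge_peaksets(
                [data.peaksets[(st, r)] for st in sim_cfg.stages
                 for r in range(1, sim_cfg.n_replicates + 1)], "all"
            ),
            chrom_sizes,
        )
        # HOMER-style background: complement-derived regions used directly
        bg_rng = np.random.default_rng([config.seed, 17])
        template = (promoter_dor_regions[stage_a]
                    or promoter_dor_regions[stage_b])
        binom_bg = (
            enrichment.sample_matched_background(
                template * max(1, 1000 // max(1, len(template))),
                pool, bg_rng,
            )
            if template else []
        )

        ori_rows, binom_rows = [], []
        passing_both: dict[str, list[str]] = {st: [] for st in sim_cfg.stages}
        creb_hits: motif_scan.GenomeHits | None = None
        per_stage_ori: dict[str, list[enrichment.ORIResult]] = {
            st: [] for st in sim_cfg.stages
        }
        per_stage_binom: dict[str, list[enrichment.BinomialEnrichmentResult]] = {
            st: [] for st in sim_cfg.stages
        }
        for pwm_rec in motifs:
            lom = motif_scan.log_odds(pwm_rec)
            dist = motif_scan.score_distribution(lom)
            # permissive cutoff for enrichment scans (dense counts keep
            # the resampled ORI statistic well-behaved); the stricter
            # site-calling cutoff is recovered by filtering the same scan
            cutoff = motif_scan.score_cutoff(dist, config.alpha_enrich)
            hits = motif_scan.scan_genome(
                data.genome.codes, lom, cutoff, dist=dist
            )
            if pwm_rec.motif_id.startswith("CREB"):
                strict = motif_scan.score_cutoff(dist, config.alpha_hit)
                creb_hits = hits.filter_min_score(
                    strict - lom.width * dist.delta / 2
                )
            for st in sim_cfg.stages:
                targets = promoter_dor_regions[st]
                if not targets:
                    logger.warning("stage %s has no promoter DORs to test", st)
                    continue
                per_stage_ori[st].append(
                    enrichment.ori_test(
                        targets, pool, hits, stage=st,
                        n_rep=config.n_rep, null_value=config.ori_null,
                        seed=config.seed,
                    )
                )
                if binom_bg:
                    per_stage_binom[st].append(
                        enrichment.binomial_enrichment(
                            targets, binom_bg, hits, stage=st
                        )
                    )
        for st in sim_cfg.stages:
            enrichment.adjust_ori_results(per_stage_ori[st])
            enrichment.adjust_binomial_results(
                per_stage_binom[st], config.fold_min, config.freq_min,
                config.binom_q,
            )
            ori_pass = {
                r.motif_id for r in per_stage_ori[st] if r.bh_q < config.enrich_q
            }
            binom_pass = {
                r.motif_id for r in per_stage_binom[st] if r.passes_filters
            }
            passing_both[st] = sorted(ori_pass & binom_pass)
            ori_rows.extend(per_stage_ori[st])
            binom_rows.extend(per_stage_binom[st])
            summary.setdefault("motifs_passing_ori", {})[st] = sorted(ori_pass)
            summary.setdefault("motifs_passing_binomial", {})[st] = sorted(
                binom_pass
            )
        summary["motifs_passing_both"] = passing_both
        if ori_rows:
            _write_tsv(
                enrichment.ori_results_to_frame(ori_rows),
                out / "enrichment_ori.tsv", header,
            )
        if binom_rows:
            _write_tsv(
                enrichment.binomial_results_to_frame(binom_rows),
                out / "enrichment_binomial.tsv", header,
            )
        if (per_stage_ori[stage_a] and per_stage_ori[stage_b]):
            ratios = {
                ra.motif_id: enrichment.ori_ratio(ra, rb)
                for ra, rb in zip(per_stage_ori[stage_a], per_stage_ori[stage_b])
            }
            summary["ori_ratio_log2"] = ratios

        # CREB target genes among DEGs with promoter OCRs
        if creb_hits is not None:
            hit_counts = {
                p.peak_id: creb_hits.count_in(p.chrom, p.start, p.end)
                for p in reference
            }
            table, n_with_ocr, n_target = enrichment.creb_targets(
                deg_results, assignments, hit_counts
            )
            _write_tsv(table, out / "creb_targets.tsv", header)
            summary["creb_targets"] = {
                "n_degs_with_promoter_ocr": n_with_ocr,
                "n_with_motif": n_target,
            }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=_jsonable)
        fh.write("\n")
    return summary


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
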