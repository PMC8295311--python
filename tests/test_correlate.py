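"""Accessibility-expression correlation and concordance."""

import numpy as np
import pandas as pd
import pytest

from accessmap import correlate, differential, peak_gene
from accessmap import synthetic_data as sd

from conftest import pearson_oracle


class TestPearson:
    def test_exact_linearity(self):
        x = np.arange(10.0)
        res = correlate.pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_hand_computed_value(self):
        res = correlate.pearson([1, 2, 3], [1, 2, 4])
        assert res.r == pytest.approx(9 / np.sqrt(84), abs=1e-12)

    def test_matches_from_definition_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            assert correlate.pearson(x, y).r == pytest.approx(
                pearson_oracle(x, y), abs=1e-12
            )

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(2)
        res = correlate.pearson(rng.normal(size=10_000), rng.normal(size=10_000))
        assert abs(res.r) < 0.03

    def test_affine_invariance_positive_slope(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(size=30)
        base = correlate.pearson(x, y).r
        assert correlate.pearson(3.5 * x + 2, y).r == pytest.approx(base)
        assert correlate.pearson(x, 0.1 * y - 7).r == pytest.approx(base)

    def test_constant_vector_rejected(self):
        with pytest.raises(correlate.InsufficientDataError):
            correlate.pearson([1, 1, 1], [1, 2, 3])

    def test_too_few_points_rejected(self):
        with pytest.raises(correlate.InsufficientDataError):
            correlate.pearson([1, 2], [3, 4])


@pytest.fixture(scope="module")
def coupled_run():
    """Scores + DEGs from a rho=0.5-coupled simulation (fixed seed)."""
    cfg = sd.SimulationConfig(
        n_genes=1200, chrom_length=25_000_000, n_peaks_per_sample=3200, seed=21
    )
    data = sd.simulate_all(cfg)
    scores = {}
    for st in cfg.stages:
        ocrs = peak_gene.reproducible_ocrs(
            data.peaksets[(st, 1)], data.peaksets[(st, 2)]
        )
        assigns = peak_gene.assign_peaks(ocrs, data.annotation)
        scores[st] = peak_gene.accessibility_scores(
            assigns, ocrs, st, genes=data.annotation
        )
    degs = differential.nb_wald_test(data.expression)
    return cfg, data, scores, degs


class TestStageCorrelation:
    def test_recovers_realized_coupling(self, coupled_run):
        cfg, data, scores, _ = coupled_run
        res = correlate.stage_correlation(
            scores["E21"], data.expression, "E21", "promoter"
        )
        gt = data.ground_truth
        qualifying = [
            s.gene_id for s in scores["E21"]
            if s.region_class == "promoter" and s.n_ocrs >= 1
        ]
        truth_acc = np.log2(
            1 + np.array([gt.stage_promoter_score["E21"][g] for g in qualifying])
        )
        truth_expr = np.array([gt.expr_log2_mean["E21"][g] for g in qualifying])
        realized = pearson_oracle(truth_acc, truth_expr)
        assert res.r == pytest.approx(realized, abs=0.1)
        assert res.n == len(qualifying)

    def test_null_coupling_uncorrelated(self):
        cfg = sd.SimulationConfig(
            n_genes=1500, chrom_length=30_000_000, n_peaks_per_sample=3500,
            coupling=0.0, seed=22,
        )
        data = sd.simulate_all(cfg)
        ocrs = peak_gene.reproducible_ocrs(
            data.peaksets[("E21", 1)], data.peaksets[("E21", 2)]
        )
        assigns = peak_gene.assign_peaks(ocrs, data.annotation)
        scores = peak_gene.accessibility_scores(
            assigns, ocrs, "E21", genes=data.annotation
        )
        res = correlate.stage_correlation(scores, data.expression, "E21")
        assert abs(res.r) < 0.06


class TestChangeCorrelation:
    def test_recovers_realized_change_coupling(self, coupled_run):
        cfg, data, scores, degs = coupled_run
        res = correlate.change_correlation(
            scores["E21"], scores["P11"], degs, "promoter"
        )
        gt = data.ground_truth
        genes = sorted(gt.acc_log2fc)
        realized = pearson_oracle(
            [gt.acc_log2fc[g] for g in genes],
            [gt.expr_log2fc[g] for g in genes],
        )
        assert res.r == pytest.approx(realized, abs=0.1)

    def test_promoter_exceeds_distal_when_coupling_promoter_only(
        self, coupled_run
    ):
        cfg, data, scores, degs = coupled_run
        prom = correlate.change_correlation(
            scores["E21"], scores["P11"], degs, "promoter"
        )
        dist = correlate.change_correlation(
            scores["E21"], scores["P11"], degs, "distal"
        )
        assert prom.r > dist.r
        assert prom.p < 0.01

    def test_perfect_construction_gives_r_one(self):
        # accessibility change identical to expression change by construction
        from accessmap.peak_gene import AccessibilityScore
        from accessmap.differential import DifferentialResult
        rng = np.random.default_rng(5)
        sa, sb, de = [], [], []
        for i in range(20):
            a = float(rng.uniform(1, 100))
            b = float(rng.uniform(1, 100))
            sa.append(AccessibilityScore(f"g{i}", "promoter", "E", a, 1))
            sb.append(AccessibilityScore(f"g{i}", "promoter", "P", b, 1))
            de.append(DifferentialResult(
                f"g{i}", 0.0, float(np.log2((a + 1) / (b + 1))),
                0.1, 0.5, 0.5, False,
            ))
        res = correlate.change_correlation(sa, sb, de, "promoter")
        assert res.r == pytest.approx(1.0)

    def test_sign_flip_negates_r(self):
        from accessmap.peak_gene import AccessibilityScore
        from accessmap.differential import DifferentialResult
        rng = np.random.default_rng(6)
        sa, sb, de, de_neg = [], [], [], []
        for i in range(20):
            a, b = float(rng.uniform(1, 100)), float(rng.uniform(1, 100))
            fc = float(rng.normal())
            sa.append(AccessibilityScore(f"g{i}", "promoter", "E", a, 1))
            sb.append(AccessibilityScore(f"g{i}", "promoter", "P", b, 1))
            de.append(DifferentialResult(f"g{i}", 0, fc, 0.1, 0.5, 0.5, False))
            de_neg.append(DifferentialResult(f"g{i}", 0, -fc, 0.1, 0.5, 0.5, False))
        r1 = correlate.change_correlation(sa, sb, de, "promoter").r
        r2 = correlate.change_correlation(sa, sb, de_neg, "promoter").r
        assert r1 == pytest.approx(-r2)


class TestConcordance:
    def _mk(self, pairs):
        """pairs: list of (gene, dor_stage(s), expr_fc)."""
        from accessmap.differential import DifferentialResult
        from accessmap.peak_gene import RegionAssignment
        dors, direction, assigns, degs = [], {}, [], []
        pid = 0
        for gene, stages, fc in pairs:
            for st in stages:
                peak = f"p{pid}"
                pid += 1
                dors.append(DifferentialResult(
                    peak, 10, 2 if st == "E" else -2, 0.1, 1e-6, 1e-6, True
                ))
                direction[peak] = st
                assigns.append(RegionAssignment(peak, gene, "promoter", 0))
            degs.append(DifferentialResult(gene, 10, fc, 0.1, 0.5, 0.5, False))
        return dors, direction, assigns, degs

    def test_all_matching_fraction_one(self):
        dors, direction, assigns, degs = self._mk(
            [("g1", ["E"], 2.0), ("g2", ["P"], -1.5)]
        )
        _, frac = correlate.dor_expression_concordance(
            dors, direction, assigns, degs, stage_a="E"
        )
        assert frac == 1.0

    def test_both_direction_gene_excluded(self):
        dors, direction, assigns, degs = self._mk(
            [("g1", ["E", "P"], 2.0), ("g2", ["E"], 1.0)]
        )
        table, frac = correlate.dor_expression_concordance(
            dors, direction, assigns, degs, stage_a="E"
        )
        assert (table["dor_direction"] == "both").sum() == 1
        assert frac == 1.0  # only g2 counts

    def test_randomized_pairing_near_half(self):
        rng = np.random.default_rng(8)
        pairs = [
            (f"g{i}", ["E" if rng.random() < 0.5 else "P"],
             float(rng.choice([-2.0, 2.0])))
            for i in range(2000)
        ]
        dors, direction, assigns, degs = self._mk(pairs)
        _, frac = correlate.dor_expression_concordance(
            dors, direction, assigns, degs, stage_a="E"
        )
        assert frac == pytest.approx(0.5, abs=0.05)


class TestReplicateConcordance:
    def _track(self, values, res=1000):
        n = len(values)
        return pd.DataFrame({
            "chrom": "chr1",
            "start": np.arange(n) * res,
            "end": (np.arange(n) + 1) * res,
            "value": values,
        })

    def test_identical_tracks(self):
        t = self._track(np.random.default_rng(1).poisson(10, 500).astype(float))
        assert correlate.replicate_concordance(t, t, 1000).r == pytest.approx(1.0)

    def test_scale_invariance(self):
        v = np.random.default_rng(2).poisson(10, 500).astype(float)
        t1, t2 = self._track(v), self._track(3 * v)
        assert correlate.replicate_concordance(t1, t2, 1000).r == pytest.approx(1.0)

    def test_independent_tracks_near_zero(self):
        rng = np.random.default_rng(3)
        t1 = self._track(rng.poisson(10, 10_000).astype(float))
        t2 = self._track(rng.poisson(10, 10_000).astype(float))
        assert abs(correlate.replicate_concordance(t1, t2, 1000).r) < 0.05

    def test_grid_mismatch_rejected(self):
        t1 = self._track(np.ones(10))
        t2 = self._track(np.ones(11))
        with pytest.raises(ValueError):
            correlate.replicate_concordance(t1, t2, 1000)
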