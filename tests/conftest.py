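"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from accessmap import synthetic_data as sd


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """From-definition Benjamini-Hochberg step-up with monotonicity."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = running
    return q


def pearson_oracle(x, y) -> float:
    """Two-pass product-moment correlation straight from the definition."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float(
        (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
    )


def assign_oracle(peak, genes, promoter_window=3000, distal_window=100_000):
    """All-pairs brute-force region classification for one peak."""
    center = (peak.start + peak.end) // 2
    same_chrom = [g for g in genes if g.chrom == peak.chrom]
    nearest = None
    if same_chrom:
        nearest = min(same_chrom, key=lambda g: (abs(g.tss - center), g.gene_id))
    if nearest is not None and abs(nearest.tss - center) <= promoter_window:
        return ("promoter", nearest.gene_id)
    overlapping = [
        g for g in same_chrom
        if g.span_start < peak.end and peak.start < g.span_end
    ]
    if overlapping:
        g = min(overlapping, key=lambda g: (abs(g.tss - center), g.gene_id))
        return ("genic", g.gene_id)
    if nearest is not None and abs(nearest.tss - center) <= distal_window:
        return ("distal", nearest.gene_id)
    return ("unassigned", None)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact coupled dataset with motifs, shared across tests."""
    cfg = sd.SimulationConfig(
        n_genes=300,
        chrom_length=6_000_000,
        n_peaks_per_sample=800,
        seed=11,
    )
    return sd.simulate_all(cfg, pwm=sd.creb_like_pwm())
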