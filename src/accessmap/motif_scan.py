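"""Patser-style PWM scanning with exact score-distribution p-values.

A PWM is converted to a log2-odds matrix against a background base
composition; the distribution of the score of a random background W-mer
is computed exactly by dynamic programming over positions on a
discretized score grid, giving each observed window score a tail
probability P(random W-mer scores >= s). Binding sites are windows on
either strand whose score passes the cutoff implied by a per-hit
p-value threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import BASES, PWMRecord

logger = logging.getLogger(__name__)

UNIFORM_BG = np.full(4, 0.25)
DELTA_DEFAULT = 0.01  # bits; cutoff discretization error is bounded by W*delta
ALPHA_DEFAULT = 1e-4

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode_sequence(seq: str) -> np.ndarray:
    """ACGTN string -> uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_sequence(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def reverse_complement(seq: str) -> str:
    codes = encode_sequence(seq)
    rc = np.where(codes < 4, 3 - codes, 4)[::-1]
    return decode_sequence(rc.astype(np.uint8))


@dataclass(frozen=True)
class LogOddsMatrix:
    motif_id: str
    scores: np.ndarray = field(compare=False)   # 4 x W, log2(prob/background)
    background: np.ndarray = field(compare=False)

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "background", bg)
        if np.any(bg <= 0) or not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError("background must be strictly positive and sum to 1")
        if not np.all(np.isfinite(scores)):
            raise ValueError("log-odds scores must be finite")

    @property
    def width(self) -> int:
        return self.scores.shape[1]

    def reverse_complement(self) -> "LogOddsMatrix":
        return LogOddsMatrix(
            motif_id=self.motif_id,
            scores=self.scores[::-1, ::-1],
            background=self.background,
        )


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int          # 0-based leftmost base, forward coordinates
    strand: str
    score: float
    p_value: float


def log_odds(pwm: PWMRecord, background: np.ndarray | None = None) -> LogOddsMatrix:
    """scores[i][j] = log2(probs[i][j] / background[i])."""
    bg = UNIFORM_BG if background is None else np.asarray(background, dtype=float)
    if np.any(pwm.probs <= 0):
        raise ValueError(
            f"PWM {pwm.motif_id} has zero probabilities; "
            "rebuild it with a positive pseudocount"
        )
    return LogOddsMatrix(
        motif_id=pwm.motif_id,
        scores=np.log2(pwm.probs / bg[:, None]),
        background=bg,
    )


@dataclass
class ScoreDistribution:
    """Exact background distribution of W-mer log-odds scores on a δ grid."""

    delta: float
    support: np.ndarray      # sorted score values (multiples of delta)
    probs: np.ndarray        # P(score == s) under the background
    tail: np.ndarray         # P(score >= s), non-increasing

    def p_value(self, score: float | np.ndarray) -> np.ndarray:
        """Tail probability of observing ``score`` or greater."""
        s = np.atleast_1d(np.asarray(score, dtype=float))
        # half-delta slack so a score equal to a support point (up to
        # rounding) maps onto that point's tail
        idx = np.searchsorted(self.support, s - self.delta / 2, side="left")
        out = np.where(idx >= len(self.support), self.tail[-1],
                       self.tail[np.minimum(idx, len(self.support) - 1)])
        return out if np.ndim(score) else float(out[0])

    @property
    def max_score(self) -> float:
        return float(self.support[-1])


def score_distribution(
    lom: LogOddsMatrix, delta: float = DELTA_DEFAULT
) -> ScoreDistribution:
    """DP over PWM columns: convolve per-column score distributions.

    Each column contributes score[i][j] with probability background[i];
    scores are rounded to multiples of ``delta``, so any tail probability
    is exact for the rounded scores and within W*delta in score units of
    the unrounded ones.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    offsets = np.rint(lom.scores / delta).astype(np.int64)  # 4 x W
    lo = int(offsets.min(axis=0).sum())
    hi = int(offsets.max(axis=0).sum())
    # running distribution over grid [cur_lo, cur_hi]
    probs = np.array([1.0])
    cur_lo = 0
    for j in range(lom.width):
        col = offsets[:, j]
        new_lo = cur_lo + int(col.min())
        new_hi = cur_lo + len(probs) - 1 + int(col.max())
        new = np.zeros(new_hi - new_lo + 1)
        for i in range(4):
            shift = cur_lo + int(col[i]) - new_lo
            new[shift:shift + len(probs)] += lom.background[i] * probs
        probs = new
        cur_lo = new_lo
    assert cur_lo == lo and cur_lo + len(probs) - 1 == hi
    nz = probs > 0
    grid = (np.arange(lo, hi + 1)[nz]).astype(float)
    probs = probs[nz]
    tail = np.cumsum(probs[::-1])[::-1]
    tail = np.minimum(tail, 1.0)
    return ScoreDistribution(
        delta=delta, support=grid * delta, probs=probs, tail=tail
    )


def score_cutoff(dist: ScoreDistribution, alpha: float) -> float:
    """Minimal support score whose tail probability is <= alpha."""
    if not 0 < alpha < 1:
        if alpha == 1:
            return float(dist.support[0])
        raise ValueError("alpha must lie in (0, 1]")
    ok = dist.tail <= alpha
    if not ok.any():
        logger.warning(
            "motif %s: no score reaches tail probability %g "
            "(minimum attainable %g)", "?", alpha, dist.tail[-1]
        )
        return np.inf
    return float(dist.support[np.argmax(ok)])


def window_scores(codes: np.ndarray, lom: LogOddsMatrix) -> np.ndarray:
    """Score every forward-strand window; windows containing N get -inf."""
    W = lom.width
    L = len(codes)
    if L < W:
        return np.empty(0)
    # 5th row = -inf so any N in a window sinks its score; float32 keeps
    # the per-position gathers memory-bound rather than cache-thrashing
    mat = np.vstack([lom.scores, np.full((1, W), -np.inf)]).astype(np.float32)
    n_win = L - W + 1
    total = np.zeros(n_win, dtype=np.float32)
    with np.errstate(invalid="ignore"):
        for j in range(W):
            total += mat[:, j][codes[j:j + n_win]]
    return np.nan_to_num(total.astype(np.float64), nan=-np.inf)


def scan(
    seq: str,
    lom: LogOddsMatrix,
    cutoff: float,
    dist: ScoreDistribution | None = None,
    sequence_id: str = "seq",
    both_strands: bool = True,
) -> list[MotifHit]:
    """Call binding sites where the window score passes the cutoff.

    Reverse-strand hits are reported in forward coordinates of the hit's
    leftmost base. All overlapping hits are reported.
    """
    codes = encode_sequence(seq)
    W = lom.width
    if len(codes) < W:
        logger.warning(
            "sequence %s shorter than motif width %d", sequence_id, W
        )
        return []
    hits: list[MotifHit] = []
    strands = [("+", lom)]
    if both_strands:
        strands.append(("-", lom.reverse_complement()))
    # unrounded window scores are compared against the delta-grid cutoff
    # with W*delta/2 slack: per-column rounding in the DP shifts a word's
    # grid score by at most delta/2 per position
    eff_cutoff = cutoff - (W * dist.delta / 2 if dist is not None else 0.0)
    for strand, mat in strands:
        scores = window_scores(codes, mat)
        for off in np.nonzero(scores >= eff_cutoff)[0]:
            s = float(scores[off])
            p = dist.p_value(s) if dist is not None else np.nan
            hits.append(MotifHit(sequence_id, int(off), strand, s, p))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


@dataclass
class GenomeHits:
    """All above-cutoff hit positions of one motif across a genome."""

    motif_id: str
    width: int
    starts: dict[str, np.ndarray]   # chrom -> sorted leftmost-base offsets
    scores: dict[str, np.ndarray]
    strands: dict[str, np.ndarray]  # '+' / '-'

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Hits lying fully inside [start, end)."""
        pos = self.starts.get(chrom)
        if pos is None or len(pos) == 0:
            return 0
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end - self.width, side="right")
        return int(hi - lo)

    def counts_in(self, regions: list[tuple[str, int, int]]) -> np.ndarray:
        return np.array([self.count_in(*r) for r in regions], dtype=np.int64)

    def filter_min_score(self, min_score: float) -> "GenomeHits":
        """Hits at a stricter score threshold, without rescanning."""
        starts, scores, strands = {}, {}, {}
        for chrom, sc in self.scores.items():
            keep = sc >= min_score
            starts[chrom] = self.starts[chrom][keep]
            scores[chrom] = sc[keep]
            strands[chrom] = self.strands[chrom][keep]
        return GenomeHits(self.motif_id, self.width, starts, scores, strands)


def scan_genome(
    genome: dict[str, np.ndarray],
    lom: LogOddsMatrix,
    cutoff: float,
    both_strands: bool = True,
    dist: ScoreDistribution | None = None,
) -> GenomeHits:
    """Scan whole encoded chromosomes once; positions are genome offsets.

    Scanning a genome once and counting hits inside regions afterwards is
    identical to extracting and scanning each region, because a window
    fully inside a region scores the same either way.
    """
    starts: dict[str, np.ndarray] = {}
    scores: dict[str, np.ndarray] = {}
    strands: dict[str, np.ndarray] = {}
    eff_cutoff = cutoff - (
        lom.width * dist.delta / 2 if dist is not None else 0.0
    )
    mats = [("+", lom)] + ([("-", lom.reverse_complement())] if both_strands else [])
    for chrom, codes in genome.items():
        pos_all, sc_all, st_all = [], [], []
        for strand, mat in mats:
            sc = window_scores(codes, mat)
            hit = np.nonzero(sc >= eff_cutoff)[0]
            pos_all.append(hit)
            sc_all.append(sc[hit])
            st_all.append(np.full(len(hit), strand))
        pos = np.concatenate(pos_all)
        order = np.argsort(pos, kind="stable")
        starts[chrom] = pos[order]
        scores[chrom] = np.concatenate(sc_all)[order]
        strands[chrom] = np.concatenate(st_all)[order]
    return GenomeHits(lom.motif_id, lom.width, starts, scores, strands)


def hits_to_frame(hits: list[MotifHit], motif_id: str, width: int) -> pd.DataFrame:
    """BED-like hit table (seq, start, end, motif, score, strand, p)."""
    return pd.DataFrame(
        {
            "seq": [h.sequence_id for h in hits],
            "start": [h.offset for h in hits],
            "end": [h.offset + width for h in hits],
            "motif_id": motif_id,
            "score": [h.score for h in hits],
            "strand": [h.strand for h in hits],
            "p_value": [h.p_value for h in hits],
        }
    )
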