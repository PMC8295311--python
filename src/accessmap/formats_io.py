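"""Readers/writers for the standard formats the pipeline touches.

All coordinates are 0-based half-open internally (BED convention).
Domain types validate their invariants at construction time so downstream
modules can assume well-formed inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class FormatError(ValueError):
    """Raised when a file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """Raised when parsed content violates a domain-type invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene with a strand-aware TSS; the anchor for all distance logic.

    The TSS is ``span_start`` on the + strand and ``span_end - 1`` on the
    - strand. One transcript per gene (one BED12 row = one gene).
    """

    gene_id: str
    chrom: str
    strand: str
    span_start: int
    span_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}"
            )
        if not self.span_start < self.span_end:
            raise ValidationError(
                f"gene {self.gene_id}: span_start must be < span_end"
            )
        prev_end = self.span_start
        for start, end in self.exons:
            if start < self.span_start or end > self.span_end:
                raise ValidationError(
                    f"gene {self.gene_id}: exon [{start},{end}) exceeds span"
                )
            if start < prev_end:
                raise ValidationError(
                    f"gene {self.gene_id}: exons overlap or are unsorted"
                )
            if start >= end:
                raise ValidationError(f"gene {self.gene_id}: empty exon")
            prev_end = end

    @property
    def tss(self) -> int:
        return self.span_start if self.strand == "+" else self.span_end - 1


@dataclass(frozen=True)
class Peak:
    """An open-chromatin region with a normalized signal height."""

    chrom: str
    start: int
    end: int
    peak_id: str
    height: float
    sample_id: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(
                f"peak {self.peak_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.height < 0:
            raise ValidationError(f"peak {self.peak_id}: negative height")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class PeakSet:
    """All peaks called in one sample, sorted by (chrom, start)."""

    sample_id: str
    stage: str | None
    peaks: list[Peak]

    def __post_init__(self) -> None:
        for p in self.peaks:
            if p.sample_id != self.sample_id:
                raise ValidationError(
                    f"peak {p.peak_id} carries sample {p.sample_id!r}, "
                    f"set is {self.sample_id!r}"
                )
        self.peaks.sort(key=lambda p: (p.chrom, p.start, p.end))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


@dataclass
class CountMatrix:
    """Non-negative integer features x samples table with stage labels."""

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    stage_of: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValidationError("duplicated feature ids")
        missing = [s for s in self.sample_ids if s not in self.stage_of]
        if missing:
            raise ValidationError(f"samples missing from stage map: {missing}")
        stages = set(self.stage_of[s] for s in self.sample_ids)
        for stage in stages:
            if not any(self.stage_of[s] == stage for s in self.sample_ids):
                raise ValidationError(f"stage {stage} has no samples")

    @property
    def stages(self) -> list[str]:
        seen: list[str] = []
        for s in self.sample_ids:
            st = self.stage_of[s]
            if st not in seen:
                seen.append(st)
        return seen

    def samples_of_stage(self, stage: str) -> list[int]:
        return [
            i for i, s in enumerate(self.sample_ids) if self.stage_of[s] == stage
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.feature_ids, columns=self.sample_ids
        )


@dataclass(frozen=True)
class PWMRecord:
    """A position weight matrix over ACGT, column-stochastic after pseudocount."""

    motif_id: str
    probs: np.ndarray = field(compare=False)
    source_counts: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.ndim != 2 or probs.shape[0] != 4:
            raise ValidationError(
                f"PWM {self.motif_id}: probs must be 4 x W, got {probs.shape}"
            )
        colsums = probs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValidationError(
                f"PWM {self.motif_id}: columns must sum to 1 (got {colsums})"
            )
        if np.any(probs <= 0) or np.any(probs > 1):
            raise ValidationError(
                f"PWM {self.motif_id}: probabilities must lie in (0, 1]; "
                "use a positive pseudocount"
            )

    @property
    def width(self) -> int:
        return self.probs.shape[1]


# ---------------------------------------------------------------------------
# Peak I/O  (BED3/5/6 and ENCODE narrowPeak)
# ---------------------------------------------------------------------------

_BED_COLUMN_COUNTS = {3, 4, 5, 6, 10}


def read_peaks(path: str | Path, sample_id: str, stage: str | None = None) -> PeakSet:
    """Read a BED or narrowPeak file into a :class:`PeakSet`.

    Height comes from narrowPeak signalValue (column 7) when the file has 10
    columns, from the BED score (column 5) for 5/6-column BED, else 1.0.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) not in _BED_COLUMN_COUNTS:
                raise FormatError(
                    f"{path}:{lineno}: expected 3-6 or 10 columns, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start ({start}) must be < end ({end})"
                )
            peak_id = (
                fields[3] if len(fields) >= 4 and fields[3] not in ("", ".")
                else f"{sample_id}_peak{lineno}"
            )
            if len(fields) == 10:
                height = float(fields[6])  # narrowPeak signalValue
            elif len(fields) >= 5:
                height = float(fields[4])
            else:
                height = 1.0
            peaks.append(
                Peak(fields[0], start, end, peak_id, height, sample_id)
            )
    if not peaks:
        logger.warning("no peaks parsed from %s", path)
    return PeakSet(sample_id=sample_id, stage=stage, peaks=peaks)


def write_peaks(peakset: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as 5-column BED (height in the score column)."""
    with open(path, "w") as fh:
        for p in peakset:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t{p.height:g}\n"
            )


def write_narrowpeak(peakset: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peakset:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t0\t.\t"
                f"{p.height:g}\t-1\t-1\t-1\n"
            )


# ---------------------------------------------------------------------------
# Gene model I/O (BED12)
# ---------------------------------------------------------------------------


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read BED12 gene models; block structure defines exons."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"{path}:{lineno}: BED12 requires 12 columns, got {len(fields)}"
                )
            chrom = fields[0]
            start, end = int(fields[1]), int(fields[2])
            gene_id = fields[3]
            strand = fields[5]
            if strand not in ("+", "-"):
                raise FormatError(
                    f"{path}:{lineno}: strand must be + or -, got {strand!r}"
                )
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(
                    f"{path}:{lineno}: blockCount disagrees with block lists"
                )
            exons = tuple(
                (start + s, start + s + sz) for s, sz in zip(starts, sizes)
            )
            genes.append(GeneModel(gene_id, chrom, strand, start, end, exons))
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.span_start) for s, _ in g.exons)
            fh.write(
                f"{g.chrom}\t{g.span_start}\t{g.span_end}\t{g.gene_id}\t0\t"
                f"{g.strand}\t{g.span_start}\t{g.span_end}\t0\t"
                f"{len(g.exons)}\t{sizes}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# PWM I/O (JASPAR-style count matrices)
# ---------------------------------------------------------------------------


def read_pwm(path: str | Path, pseudocount: float = 0.25) -> PWMRecord:
    """Read one JASPAR-style count matrix and convert counts to probabilities.

    Accepts either bracketed JASPAR rows (``A [ 3 10 ... ]``) or bare
    whitespace-separated rows in ACGT order, optionally preceded by a
    ``>motif_id`` header.
    """
    records = read_pwms(path, pseudocount=pseudocount)
    if len(records) != 1:
        raise FormatError(f"{path}: expected exactly one motif, found {len(records)}")
    return records[0]


def read_pwms(path: str | Path, pseudocount: float = 0.25) -> list[PWMRecord]:
    """Read one or more JASPAR-style count matrices from a file."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    records: list[PWMRecord] = []
    motif_id: str | None = None
    rows: list[list[float]] = []
    default_id = Path(path).stem

    def flush() -> None:
        nonlocal rows, motif_id
        if not rows:
            return
        if len(rows) != 4:
            raise FormatError(f"{path}: expected 4 rows (A,C,G,T), got {len(rows)}")
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise FormatError(f"{path}: ragged matrix rows (widths {sorted(widths)})")
        counts = np.array(rows, dtype=float)
        if np.any(counts < 0):
            raise ValidationError(f"{path}: negative counts")
        records.append(counts_to_pwm(motif_id or default_id, counts, pseudocount))
        rows = []
        motif_id = None

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                motif_id = line[1:].split()[0]
                continue
            body = line
            if body[0] in "ACGTacgt" and (len(body) == 1 or not body[1].isdigit()):
                body = body[1:]
            body = body.replace("[", " ").replace("]", " ")
            rows.append([float(x) for x in body.split()])
    flush()
    if not records:
        raise FormatError(f"{path}: no matrix found")
    return records


def counts_to_pwm(
    motif_id: str, counts: np.ndarray, pseudocount: float = 0.25
) -> PWMRecord:
    counts = np.asarray(counts, dtype=float)
    colsums = counts.sum(axis=0)
    if pseudocount == 0 and np.any(colsums == 0):
        raise ValidationError(
            f"PWM {motif_id}: all-zero column requires a positive pseudocount"
        )
    probs = (counts + pseudocount) / (colsums + 4 * pseudocount)
    return PWMRecord(motif_id=motif_id, probs=probs, source_counts=counts)


def write_pwm(pwm: PWMRecord, path: str | Path) -> None:
    mat = pwm.source_counts if pwm.source_counts is not None else pwm.probs
    with open(path, "w") as fh:
        fh.write(f">{pwm.motif_id}\n")
        for i, base in enumerate(BASES):
            vals = " ".join(f"{v:g}" for v in mat[i])
            fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# Count-table I/O
# ---------------------------------------------------------------------------


def read_counts(path: str | Path, stage_map: Mapping[str, str]) -> CountMatrix:
    """Read a TSV count table (features x samples) and attach stage labels."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicated feature ids {dupes}")
    for col in df.columns:
        series = df[col]
        if not np.issubdtype(series.dtype, np.integer):
            bad = series[series != np.floor(series)]
            if len(bad):
                raise ValidationError(
                    f"{path}: non-integer count {bad.iloc[0]!r} at "
                    f"feature {bad.index[0]!r}, sample {col!r}"
                )
    missing = [c for c in df.columns if c not in stage_map]
    if missing:
        raise ValidationError(f"{path}: samples missing from stage map: {missing}")
    return CountMatrix(
        feature_ids=list(df.index.astype(str)),
        sample_ids=list(df.columns.astype(str)),
        counts=df.to_numpy(),
        stage_of={s: stage_map[s] for s in df.columns},
    )


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.to_frame().to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an {id: upper-cased sequence} mapping (alphabet ACGTN)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValidationError(
                f"{path}: sequence {rec.id} contains non-ACGTN characters {sorted(bad)}"
            )
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# Misc tabular / bedGraph
# ---------------------------------------------------------------------------


def write_tsv(df: pd.DataFrame, path: str | Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", index=False, **kwargs)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a 4-column bedGraph (chrom, start, end, value)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
    )
    if (df["start"] >= df["end"]).any():
        raise FormatError(f"{path}: empty or inverted interval")
    return df


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", index=False, header=False
    )
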