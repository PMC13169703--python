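"""RNA polymerase III occupancy scoring from ChIP read counts.

Occupancy at a locus is summarized as a clamped log-ratio of treatment
(RPC4-style pulldown) to control (IgG / no-antibody) read counts over the
locus extended by a fixed margin both sides:

    score = clamp(log2((treatment + p) / (control + p)), 0, cap)

with pseudocount p = 20 and cap 6 by default. Only uniquely mapping reads
are counted, since tRNA loci are highly repetitive and multi-mapping reads
would smear signal across copies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .annotations_io import TRNALocus

DEFAULT_PSEUDOCOUNT = 20.0
DEFAULT_CAP = 6.0
DEFAULT_EXTENSION = 50
DEFAULT_POL3_CUTOFF = 2.0
DEFAULT_TRNA_CUTOFF = 50.0

CLASS_ACTIVE = "active_tRNA"
CLASS_SILENT = "silent_highscoring"
CLASS_TRNA_LIKE = "transcribed_tRNA_like"
CLASS_INACTIVE = "inactive_element"


@dataclass(frozen=True)
class ReadRecord:
    """One aligned read; ``mapq_unique`` marks a uniquely mapping record."""

    chrom: str
    start: int
    end: int
    mapq_unique: bool = True

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"invalid read interval [{self.start},{self.end})")


@dataclass(frozen=True)
class PolIIIMeasurement:
    locus_id: str
    treatment_count: int
    control_count: int
    score: float


def count_reads(
    reads: Iterable[ReadRecord],
    locus: TRNALocus,
    extension: int = DEFAULT_EXTENSION,
) -> int:
    """Count uniquely mapping reads overlapping the extended locus window
    [start-extension, end+extension) by >= 1 bp, strand-agnostically."""
    if extension < 0:
        raise ValueError("extension must be >= 0")
    lo = max(0, locus.start - extension)
    hi = locus.end + extension
    n = 0
    for r in reads:
        if not r.mapq_unique:
            continue
        if r.chrom == locus.chrom and r.start < hi and r.end > lo:
            n += 1
    return n


def pol3_score(
    treatment,
    control,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    cap: float = DEFAULT_CAP,
):
    """Clamped log2 enrichment of treatment over control (vectorized).

    Accepts scalars or array-likes; returns a float for scalar inputs.
    """
    t = np.asarray(treatment, dtype=float)
    c = np.asarray(control, dtype=float)
    if np.any(t < 0) or np.any(c < 0):
        raise ValueError("read counts must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    val = np.clip(np.log2((t + pseudocount) / (c + pseudocount)), 0.0, cap)
    if val.ndim == 0:
        return float(val)
    return val


def classify_locus(
    trna_score: float,
    p3_score: float,
    t_cut: float = DEFAULT_TRNA_CUTOFF,
    p_cut: float = DEFAULT_POL3_CUTOFF,
) -> str:
    """2x2 classification by (covariance score > t_cut) x (Pol III score >= p_cut).

    The covariance-score comparison is strict (>); the occupancy comparison
    is inclusive (>=), matching how the two cutoffs are used.
    """
    high = trna_score > t_cut
    bound = p3_score >= p_cut
    if high and bound:
        return CLASS_ACTIVE
    if high:
        return CLASS_SILENT
    if bound:
        return CLASS_TRNA_LIKE
    return CLASS_INACTIVE


def score_loci(
    counts: Mapping[str, tuple[int, int]],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    cap: float = DEFAULT_CAP,
) -> dict[str, PolIIIMeasurement]:
    """Score every locus in a (treatment, control) count table."""
    out = {}
    for locus_id in sorted(counts):
        t, c = counts[locus_id]
        out[locus_id] = PolIIIMeasurement(
            locus_id=locus_id,
            treatment_count=t,
            control_count=c,
            score=pol3_score(t, c, pseudocount, cap),
        )
    return out


def dataset_concordance(
    scores_a: Mapping[str, float], scores_b: Mapping[str, float]
) -> float:
    """Pearson correlation of two score sets over their shared loci.

    Returns NaN (with a warning) if either vector has zero variance.
    """
    shared = sorted(set(scores_a) & set(scores_b))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared loci, have {len(shared)}")
    a = np.array([scores_a[k] for k in shared])
    b = np.array([scores_b[k] for k in shared])
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("zero variance in one score vector; correlation undefined")
        return float("nan")
    r, _ = stats.pearsonr(a, b)
    return float(r)


def reads_from_sam(path: str | Path) -> list[ReadRecord]:
    """Adapter from SAM-dialect alignments to :class:`ReadRecord`.

    A record is uniquely mapping when MAPQ > 0 and it carries no
    XS-equivalent ambiguity (an XS secondary-alignment score reaching the
    primary AS score).
    """
    import pysam

    reads: list[ReadRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.reference_start is None:
                continue
            end = aln.reference_end
            if end is None or end <= aln.reference_start:
                continue
            unique = aln.mapping_quality > 0
            if unique and aln.has_tag("XS") and aln.has_tag("AS"):
                unique = aln.get_tag("XS") < aln.get_tag("AS")
            reads.append(
                ReadRecord(
                    chrom=aln.reference_name,
                    start=aln.reference_start,
                    end=end,
                    mapq_unique=unique,
                )
            )
    return reads


def write_score_table(
    measurements: Mapping[str, PolIIIMeasurement],
    trna_scores: Mapping[str, float],
    t_cut: float = DEFAULT_TRNA_CUTOFF,
    p_cut: float = DEFAULT_POL3_CUTOFF,
) -> str:
    lines = ["locus_id\ttreatment\tcontrol\tscore\tclass"]
    for locus_id in sorted(measurements):
        m = measurements[locus_id]
        cls = (
            classify_locus(trna_scores[locus_id], m.score, t_cut, p_cut)
            if locus_id in trna_scores
            else "NA"
        )
        lines.append(
            f"{m.locus_id}\t{m.treatment_count}\t{m.control_count}\t{m.score:.4f}\t{cls}"
        )
    return "\n".join(lines) + "\n"
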