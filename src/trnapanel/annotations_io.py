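"""Readers and writers for the external formats used across the pipeline.

Formats covered:

* tRNAscan-SE 2.x tabular output (the dialect with ``Sequence``/``Name``/
  ``----`` header lines; 1-based inclusive coordinates, begin>end on the
  minus strand),
* BED6 intervals,
* FASTA genomes (via Biopython),
* pairwise coordinate liftover maps (9-column TSV), and
* per-locus ChIP read-count tables (locus_id, treatment, control).

All in-memory coordinates are uniformly 0-based half-open on the forward
strand; dialect conversions happen only at these parse/write boundaries.
Intron intervals are stored in *gene* coordinates, i.e. offsets along the
gene's 5'->3' (strand-oriented) direction.
"""

from __future__ import annotations

import io
from collections import namedtuple
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Default tRNAscan-SE covariance-score floor (bits); rows below are dropped.
DEFAULT_SCORE_FLOOR = 10.0
#: Default covariance-score threshold separating tRNAs from tRNA-like elements.
DEFAULT_HIGH_SCORE = 50.0


class FormatError(ValueError):
    """Raised when an external file violates its dialect."""


@dataclass(frozen=True)
class TRNALocus:
    """One annotated tRNA or tRNA-like gene.

    ``score`` is the covariance-model bit score reported by the scanner.
    ``introns`` are 0-based half-open intervals relative to the gene's 5'
    end along its own strand, strictly inside the gene body, disjoint and
    sorted. ``note`` preserves any trailing scanner columns verbatim but is
    never interpreted.
    """

    locus_id: str
    genome: str
    chrom: str
    start: int
    end: int
    strand: str
    isotype: str
    anticodon: str
    score: float
    introns: tuple[tuple[int, int], ...] = ()
    note: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"{self.locus_id}: invalid interval [{self.start},{self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_id}: bad strand {self.strand!r}")
        if self.score < 0:
            raise ValueError(f"{self.locus_id}: negative score {self.score}")
        span = self.end - self.start
        prev = 0
        for s, e in self.introns:
            if not (0 < s < e < span):
                raise ValueError(
                    f"{self.locus_id}: intron [{s},{e}) not nested in gene body"
                )
            if s < prev:
                raise ValueError(f"{self.locus_id}: introns overlap or unsorted")
            prev = e

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def node(self) -> tuple[str, str]:
        """Graph node identity: (genome, locus_id)."""
        return (self.genome, self.locus_id)


@dataclass(frozen=True)
class LiftoverRecord:
    """One projected interval from a whole-genome-alignment liftover."""

    src_genome: str
    src_chrom: str
    src_start: int
    src_end: int
    dst_genome: str
    dst_chrom: str
    dst_start: int
    dst_end: int
    dst_strand: str

    def __post_init__(self) -> None:
        for s, e in ((self.src_start, self.src_end), (self.dst_start, self.dst_end)):
            if s < 0 or s >= e:
                raise ValueError(f"invalid liftover interval [{s},{e})")
        if self.dst_strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.dst_strand!r}")


ScorePartition = namedtuple("ScorePartition", ["high", "low"])

BedRecord = namedtuple("BedRecord", ["chrom", "start", "end", "name", "score", "strand"])


# ---------------------------------------------------------------------------
# tRNAscan-SE tabular dialect
# ---------------------------------------------------------------------------

_HEADER_PREFIXES = ("Sequence", "Name", "----", "--------")


def _intron_to_gene_coords(
    ib: int, ie: int, begin: int, strand: str
) -> tuple[int, int]:
    """Convert a 1-based inclusive genomic intron to gene-relative half-open.

    ``begin`` is the 1-based genomic coordinate of the gene's 5' base (the
    larger coordinate for minus-strand rows). On the minus strand the scanner
    reports intron bounds in transcription order, so ib > ie there too.
    """
    if strand == "+":
        return (ib - begin, ie - begin + 1)
    return (begin - ib, begin - ie + 1)


def _intron_to_genomic(rel: tuple[int, int], begin: int, strand: str) -> tuple[int, int]:
    s, e = rel
    if strand == "+":
        return (begin + s, begin + e - 1)
    return (begin - s, begin - e + 1)


def parse_trnascan_table(
    text: str | TextIO,
    genome: str,
    score_floor: float = DEFAULT_SCORE_FLOOR,
) -> list[TRNALocus]:
    """Parse tRNAscan-SE 2.x tabular output into :class:`TRNALocus` records.

    Rows scoring below ``score_floor`` are dropped (the scanner's own
    minimum-score setting). Both the bare 9-column layout and variants with
    extra trailing columns (isotype-model scores, notes) are accepted; the
    extras are preserved opaquely in ``note``.
    """
    if hasattr(text, "read"):
        text = text.read()
    loci: list[TRNALocus] = []
    seen: set[str] = set()
    problems: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(_HEADER_PREFIXES):
            continue
        cols = line.split()
        if len(cols) < 9:
            problems.append(f"line {lineno}: expected >=9 columns, got {len(cols)}")
            continue
        name, num, begin_s, end_s, isotype, anticodon, ib_s, ie_s, score_s = cols[:9]
        note = "\t".join(cols[9:])
        try:
            begin, end = int(begin_s), int(end_s)
            score = float(score_s)
        except ValueError:
            problems.append(f"line {lineno}: non-numeric coordinate or score")
            continue
        if begin <= end:
            strand, start0, end0 = "+", begin - 1, end
        else:
            strand, start0, end0 = "-", end - 1, begin
        introns: list[tuple[int, int]] = []
        try:
            ibs = [int(v) for v in ib_s.split(",")]
            ies = [int(v) for v in ie_s.split(",")]
        except ValueError:
            problems.append(f"line {lineno}: non-numeric intron bound")
            continue
        for ib, ie in zip(ibs, ies):
            if ib == 0 and ie == 0:
                continue
            introns.append(_intron_to_gene_coords(ib, ie, begin, strand))
        introns.sort()
        if score < score_floor:
            continue
        locus_id = f"{name}.trna{num}"
        if locus_id in seen:
            problems.append(f"line {lineno}: duplicate locus id {locus_id}")
            continue
        seen.add(locus_id)
        try:
            loci.append(
                TRNALocus(
                    locus_id=locus_id,
                    genome=genome,
                    chrom=name,
                    start=start0,
                    end=end0,
                    strand=strand,
                    isotype=isotype,
                    anticodon=anticodon,
                    score=score,
                    introns=tuple(introns),
                    note=note,
                )
            )
        except ValueError as exc:
            problems.append(f"line {lineno}: {exc}")
    if problems:
        raise FormatError("; ".join(problems))
    return loci


def write_trnascan_table(loci: Iterable[TRNALocus]) -> str:
    """Serialize loci back to the scanner's tabular dialect (lossless)."""
    lines = []
    for loc in loci:
        name, _, num = loc.locus_id.rpartition(".trna")
        if loc.strand == "+":
            begin, end = loc.start + 1, loc.end
        else:
            begin, end = loc.end, loc.start + 1
        if loc.introns:
            pairs = [_intron_to_genomic(iv, begin, loc.strand) for iv in loc.introns]
            ib = ",".join(str(p[0]) for p in pairs)
            ie = ",".join(str(p[1]) for p in pairs)
        else:
            ib = ie = "0"
        fields = [
            name or loc.chrom,
            num or "0",
            str(begin),
            str(end),
            loc.isotype,
            loc.anticodon,
            ib,
            ie,
            format(loc.score, "g"),
        ]
        if loc.note:
            fields.append(loc.note)
        lines.append("\t".join(fields))
    return "\n".join(lines) + ("\n" if lines else "")


def classify_by_score(
    loci: Iterable[TRNALocus], threshold: float = DEFAULT_HIGH_SCORE
) -> ScorePartition:
    """Partition loci into high-scoring tRNAs (score strictly > threshold)
    and low-scoring tRNA-like elements (everything else)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    high = [l for l in loci if l.score > threshold]
    low = [l for l in loci if l.score <= threshold]
    return ScorePartition(high=high, low=low)


# ---------------------------------------------------------------------------
# Liftover map TSV
# ---------------------------------------------------------------------------


def read_liftover_map(text: str | TextIO) -> list[LiftoverRecord]:
    """Read a 9-column liftover TSV; '#' comment lines are skipped."""
    if hasattr(text, "read"):
        text = text.read()
    records: list[LiftoverRecord] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t") if "\t" in line else line.split()
        if len(cols) != 9:
            raise FormatError(f"line {lineno}: expected 9 columns, got {len(cols)}")
        try:
            rec = LiftoverRecord(
                src_genome=cols[0],
                src_chrom=cols[1],
                src_start=int(cols[2]),
                src_end=int(cols[3]),
                dst_genome=cols[4],
                dst_chrom=cols[5],
                dst_start=int(cols[6]),
                dst_end=int(cols[7]),
                dst_strand=cols[8],
            )
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
        records.append(rec)
    return records


def write_liftover_map(records: Iterable[LiftoverRecord]) -> str:
    lines = [
        "\t".join(
            [
                r.src_genome,
                r.src_chrom,
                str(r.src_start),
                str(r.src_end),
                r.dst_genome,
                r.dst_chrom,
                str(r.dst_start),
                str(r.dst_end),
                r.dst_strand,
            ]
        )
        for r in records
    ]
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------


def write_bed6(loci: Iterable[TRNALocus]) -> str:
    """Write loci as BED6; the BED score is score*10 rounded, clamped to [0,1000]."""
    lines = []
    for loc in loci:
        bed_score = min(1000, max(0, round(loc.score * 10)))
        lines.append(
            "\t".join(
                [loc.chrom, str(loc.start), str(loc.end), loc.locus_id, str(bed_score), loc.strand]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def read_bed6(text: str | TextIO) -> list[BedRecord]:
    if hasattr(text, "read"):
        text = text.read()
    out = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t") if "\t" in line else line.split()
        if len(cols) < 6:
            raise FormatError(f"line {lineno}: expected 6 BED columns")
        try:
            out.append(
                BedRecord(cols[0], int(cols[1]), int(cols[2]), cols[3], int(cols[4]), cols[5])
            )
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(source: str | Path | TextIO) -> dict[str, str]:
    """Read a FASTA file into {name: sequence}; case is preserved."""
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        handle: TextIO = open(source)
        close = True
    elif isinstance(source, str):
        handle = io.StringIO(source)
        close = False
    else:
        handle = source  # type: ignore[assignment]
        close = False
    try:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}
    finally:
        if close:
            handle.close()


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# ChIP count tables
# ---------------------------------------------------------------------------


def read_count_table(text: str | TextIO) -> dict[str, tuple[int, int]]:
    """Read (locus_id, treatment, control) TSV into a dict."""
    if hasattr(text, "read"):
        text = text.read()
    counts: dict[str, tuple[int, int]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("locus_id"):
            continue
        cols = line.split("\t") if "\t" in line else line.split()
        if len(cols) < 3:
            raise FormatError(f"line {lineno}: expected 3 columns")
        try:
            counts[cols[0]] = (int(cols[1]), int(cols[2]))
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
    return counts


def write_count_table(counts: Mapping[str, tuple[int, int]]) -> str:
    lines = ["locus_id\ttreatment\tcontrol"]
    for locus_id in sorted(counts):
        t, c = counts[locus_id]
        lines.append(f"{locus_id}\t{t}\t{c}")
    return "\n".join(lines) + "\n"
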