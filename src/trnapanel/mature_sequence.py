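"""Projection of genomic tRNA loci to their mature transcript sequences.

The mature form of a nuclear tRNA is derived from its genomic gene body by
excising introns, appending the universally added 3' CCA tail (not
genome-encoded in eukaryotic nuclear tRNAs), and prepending the
post-transcriptionally added G-1 base for histidine tRNAs. Sequences that
retain ambiguous (non-ACGT) bases after projection are rejected rather than
guessed at, since copy-number identity downstream relies on exact string
equality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, TypeVar

from Bio.Seq import reverse_complement

from .annotations_io import TRNALocus

#: Default flank (bp) taken around the gene body for ortholog projection.
DEFAULT_FLANK = 20
#: Wider flank used for flank-anchored ortholog validation alignments.
VALIDATION_FLANK = 100
#: Minimum extracted-sequence length retained for analysis (bp).
DEFAULT_MIN_LEN = 50

#: Rejection reason vocabulary used in discard logs.
REASON_AMBIGUOUS = "ambiguous"
REASON_TOO_SHORT = "too_short"
REASON_NO_SCAN_HIT = "no_scan_hit"


@dataclass(frozen=True)
class MatureSequence:
    """A projected mature tRNA sequence tied back to its source locus."""

    seq: str
    source_locus: str

    @property
    def length(self) -> int:
        return len(self.seq)

    def __post_init__(self) -> None:
        if not self.seq.endswith("CCA"):
            raise ValueError(f"{self.source_locus}: mature sequence lacks CCA tail")
        if set(self.seq) - set("ACGT"):
            raise ValueError(f"{self.source_locus}: ambiguous bases in mature sequence")


@dataclass(frozen=True)
class Rejection:
    """A locus discarded during projection, with the reason logged."""

    locus_id: str
    reason: str


def extract_genomic(
    genome: Mapping[str, str], locus: TRNALocus, flank: int = DEFAULT_FLANK
) -> str:
    """Extract the locus sequence (plus ``flank`` bp each side) on the gene's strand.

    Flanks are truncated at chromosome edges; minus-strand loci are
    reverse-complemented so the result always reads 5'->3' along the gene.
    The result is uppercased so soft-masking cannot affect downstream
    sequence-identity comparisons.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if locus.chrom not in genome:
        raise KeyError(f"chromosome {locus.chrom!r} absent from FASTA")
    chrom_seq = genome[locus.chrom]
    if locus.end > len(chrom_seq):
        raise ValueError(
            f"{locus.locus_id}: interval [{locus.start},{locus.end}) exceeds "
            f"chromosome {locus.chrom} length {len(chrom_seq)}"
        )
    lo = max(0, locus.start - flank)
    hi = min(len(chrom_seq), locus.end + flank)
    seq = chrom_seq[lo:hi].upper()
    if locus.strand == "-":
        seq = reverse_complement(seq)
    return seq


def extract_gene_body(genome: Mapping[str, str], locus: TRNALocus) -> str:
    """The strand-oriented gene body without flanks."""
    return extract_genomic(genome, locus, flank=0)


def project_mature(locus: TRNALocus, gene_seq: str) -> MatureSequence | Rejection:
    """Project a strand-oriented gene body to the mature transcript sequence.

    Introns (gene-relative coordinates) are excised, CCA is appended
    unconditionally, and His tRNAs receive the post-transcriptional G-1.
    Any remaining non-ACGT base yields a :class:`Rejection` ("ambiguous").
    """
    gene_seq = gene_seq.upper()
    span = len(gene_seq)
    for s, e in locus.introns:
        if not (0 <= s < e <= span):
            raise ValueError(
                f"{locus.locus_id}: intron [{s},{e}) outside gene body of length {span}"
            )
    pieces = []
    prev = 0
    for s, e in locus.introns:
        pieces.append(gene_seq[prev:s])
        prev = e
    pieces.append(gene_seq[prev:])
    mature = "".join(pieces) + "CCA"
    if locus.isotype == "His":
        mature = "G" + mature
    if set(mature) - set("ACGT"):
        return Rejection(locus_id=locus.locus_id, reason=REASON_AMBIGUOUS)
    return MatureSequence(seq=mature, source_locus=locus.locus_id)


_S = TypeVar("_S", str, MatureSequence)


def filter_short(seqs: Iterable[_S], min_len: int = DEFAULT_MIN_LEN) -> list[_S]:
    """Keep sequences of length >= ``min_len`` (strictly shorter are removed)."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    out = []
    for s in seqs:
        length = len(s.seq) if isinstance(s, MatureSequence) else len(s)
        if length >= min_len:
            out.append(s)
    return out
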