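"""Sequence variation within ortholog sets.

Members of an ortholog set are near-identical mature sequences; they are
stacked into a small multiple alignment (a star alignment anchored on the
longest member) whose columns serve as the positional proxy for canonical
tRNA (Sprinzl) positions. On top of the alignment this module counts
mismatches against the reference member, distinct sequence variants,
per-column variation frequencies by locus class, and anticodon/isotype
identity changes. An optional user-supplied column->Sprinzl map can relabel
columns for real data.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import Align

from .annotations_io import TRNALocus

GAP = "-"

_GLOBAL = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-2,
)


@dataclass
class FamilyAlignment:
    """Aligned mature sequences of one ortholog set, keyed by genome."""

    rows: dict[str, str]
    ref_key: str

    @property
    def ncols(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def __post_init__(self) -> None:
        lens = {len(r) for r in self.rows.values()}
        if len(lens) > 1:
            raise ValueError("alignment rows have unequal lengths")
        if self.rows and self.ref_key not in self.rows:
            raise ValueError(f"reference row {self.ref_key!r} absent")


@dataclass(frozen=True)
class IdentityChange:
    """A member whose (isotype, anticodon) differs from the reference member."""

    strain: str
    new_isotype: str
    new_anticodon: str
    ambiguous: bool = False


def _gap_runs(anchor_row: str) -> dict[int, int]:
    """Map anchor position -> length of the gap run inserted before it."""
    runs: dict[int, int] = {}
    pos = 0
    i = 0
    n = len(anchor_row)
    while i < n:
        if anchor_row[i] == GAP:
            j = i
            while j < n and anchor_row[j] == GAP:
                j += 1
            runs[pos] = runs.get(pos, 0) + (j - i)
            i = j
        else:
            pos += 1
            i += 1
    return runs


def _expand_row(anchor_row: str, seq_row: str, ins: Mapping[int, int], anchor_len: int) -> str:
    """Re-pad one pairwise-aligned row onto the merged column layout."""
    out: list[str] = []
    pos = 0
    i = 0
    n = len(anchor_row)
    while pos <= anchor_len:
        block: list[str] = []
        while i < n and anchor_row[i] == GAP:
            block.append(seq_row[i])
            i += 1
        block.extend(GAP * (ins.get(pos, 0) - len(block)))
        out.extend(block)
        if pos < anchor_len:
            out.append(seq_row[i])
            i += 1
        pos += 1
    return "".join(out)


def align_family(named_seqs: Mapping[str, str]) -> FamilyAlignment:
    """Star alignment of an ortholog set's mature sequences.

    The anchor is the longest sequence (ties: lexicographically smallest
    sequence, then key); every other member is globally aligned to the
    anchor with the same scoring as the local aligner (+1/-1/-2), and the
    pairwise alignments are merged column-wise ("once a gap, always a
    gap"). Deterministic for a given input mapping.
    """
    if not named_seqs:
        raise ValueError("align_family requires at least one sequence")
    order = sorted(named_seqs.items(), key=lambda kv: (-len(kv[1]), kv[1], kv[0]))
    anchor_key, anchor = order[0]
    anchor_len = len(anchor)
    pairwise: dict[str, tuple[str, str, dict[int, int]]] = {}
    ins: dict[int, int] = defaultdict(int)
    for key, seq in order[1:]:
        if seq == anchor:
            pairwise[key] = (anchor, seq, {})
            continue
        aln = next(iter(_GLOBAL.align(anchor, seq)))
        a_row, s_row = str(aln[0]), str(aln[1])
        runs = _gap_runs(a_row)
        pairwise[key] = (a_row, s_row, runs)
        for p, l in runs.items():
            ins[p] = max(ins[p], l)

    rows: dict[str, str] = {}
    # anchor row with merged insertions
    parts: list[str] = []
    for p in range(anchor_len + 1):
        parts.append(GAP * ins.get(p, 0))
        if p < anchor_len:
            parts.append(anchor[p])
    rows[anchor_key] = "".join(parts)
    for key, (a_row, s_row, _) in pairwise.items():
        rows[key] = _expand_row(a_row, s_row, ins, anchor_len)

    ref_key = anchor_key if anchor_key in named_seqs else next(iter(named_seqs))
    return FamilyAlignment(rows=rows, ref_key=ref_key)


def count_mismatches(aln: FamilyAlignment, ref_row: str, other_row: str) -> int:
    """Columns where the two rows differ; gap-vs-residue counts as one mismatch."""
    a = aln.rows[ref_row]
    b = aln.rows[other_row]
    return sum(1 for x, y in zip(a, b) if x != y)


def variant_count(seqs: Iterable[str]) -> int:
    """Number of distinct sequence strings among an ortholog set's members."""
    return len(set(seqs))


def position_variation_frequency(
    alignments: Sequence[FamilyAlignment],
    column: int,
    strains: Sequence[str],
) -> float:
    """Maximum per-strain variation frequency at one alignment column.

    For each strain: the fraction of ortholog sets whose member in that
    strain differs from the reference row at ``column``; the maximum over
    strains is returned. Sets lacking that strain or that column do not
    vary there.
    """
    if not alignments:
        raise ValueError("need at least one ortholog-set alignment")
    n = len(alignments)
    best = 0.0
    for strain in strains:
        diff = 0
        for aln in alignments:
            if strain == aln.ref_key:
                continue
            row = aln.rows.get(strain)
            if row is None or column >= aln.ncols:
                continue
            if row[column] != aln.rows[aln.ref_key][column]:
                diff += 1
        best = max(best, diff / n)
    return best


def variation_profile(
    alignments: Sequence[FamilyAlignment], strains: Sequence[str]
) -> list[float]:
    """Per-column maximum variation frequency across a class of sets."""
    if not alignments:
        return []
    ncols = max(a.ncols for a in alignments)
    return [
        position_variation_frequency(alignments, c, strains) for c in range(ncols)
    ]


def detect_identity_change(
    member_annotations: Mapping[str, TRNALocus], reference: str | None = None
) -> list[IdentityChange]:
    """Members whose (isotype, anticodon) differs from the reference member's.

    The reference member is the reference genome's when present, else the
    lexicographically first genome's. Members carrying an "NNN" anticodon
    are reported with ``ambiguous=True`` and are not counted as changes.
    """
    if not member_annotations:
        return []
    if reference is not None and reference in member_annotations:
        ref_key = reference
    else:
        ref_key = min(member_annotations)
    ref = member_annotations[ref_key]
    out: list[IdentityChange] = []
    for strain in sorted(member_annotations):
        if strain == ref_key:
            continue
        loc = member_annotations[strain]
        if (loc.isotype, loc.anticodon) == (ref.isotype, ref.anticodon):
            continue
        out.append(
            IdentityChange(
                strain=strain,
                new_isotype=loc.isotype,
                new_anticodon=loc.anticodon,
                ambiguous=(loc.anticodon == "NNN" or ref.anticodon == "NNN"),
            )
        )
    return out
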