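"""Gene-conversion inference between genome pairs.

A candidate conversion is an ortholog set whose locus carries one multicopy
sequence family in one genome and a *different* multicopy family in
another: a precise switch between two sequences that each exist in
multiple identical copies in both genomes is very unlikely to arise by
independent point mutation and is the signature of non-reciprocal transfer
(concerted evolution). Directionality cannot be determined from a pair
alone; an optional parsimony annotation marks the panel-minority sequence
as the likely convertee.

Point mutations cannot create false positives under this rule: a mutated
copy is single-copy in its genome by construction and fails the
multicopy-in-both requirement.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .ortholog_sets import OrthologSet

DEFAULT_MIN_COPIES = 2
DEFAULT_RECURRENCE = 10


@dataclass(frozen=True)
class ConversionEvent:
    """An ortholog set switching family identity between two genomes.

    ``seq_from`` is the sequence carried in ``genome_a``, ``seq_to`` the one
    in ``genome_b``; the direction of transfer is not implied.
    """

    genome_a: str
    genome_b: str
    set_id: str
    seq_from: str
    seq_to: str

    def __post_init__(self) -> None:
        if self.seq_from == self.seq_to:
            raise ValueError("conversion requires two distinct sequences")

    @property
    def pair(self) -> tuple[str, str]:
        """Unordered sequence-pair key."""
        return tuple(sorted((self.seq_from, self.seq_to)))  # type: ignore[return-value]


def detect_conversions(
    sets: Sequence[OrthologSet],
    mature_by_member: Mapping[tuple[str, str], str],
    counts_by_genome: Mapping[str, Mapping[str, int]],
    genome_a: str,
    genome_b: str,
    min_copies: int = DEFAULT_MIN_COPIES,
) -> list[ConversionEvent]:
    """Candidate conversions between one genome pair.

    For each ortholog set with members in both genomes whose mature
    sequences differ, an event is emitted iff *both* sequences are present
    at >= ``min_copies`` copies in *both* genomes.
    """
    ca = counts_by_genome[genome_a]
    cb = counts_by_genome[genome_b]
    events: list[ConversionEvent] = []
    for oset in sets:
        la = oset.members.get(genome_a)
        lb = oset.members.get(genome_b)
        if la is None or lb is None:
            continue
        sa = mature_by_member.get((genome_a, la))
        sb = mature_by_member.get((genome_b, lb))
        if sa is None or sb is None or sa == sb:
            continue
        if (
            ca.get(sa, 0) >= min_copies
            and cb.get(sa, 0) >= min_copies
            and ca.get(sb, 0) >= min_copies
            and cb.get(sb, 0) >= min_copies
        ):
            events.append(
                ConversionEvent(
                    genome_a=genome_a,
                    genome_b=genome_b,
                    set_id=oset.set_id,
                    seq_from=sa,
                    seq_to=sb,
                )
            )
    return events


def filter_substrings(events: Iterable[ConversionEvent]) -> list[ConversionEvent]:
    """Drop events where one sequence is a contiguous substring of the other
    (truncation artifacts rather than true family switches)."""
    return [
        e
        for e in events
        if e.seq_from not in e.seq_to and e.seq_to not in e.seq_from
    ]


def all_pairwise_conversions(
    sets: Sequence[OrthologSet],
    mature_by_member: Mapping[tuple[str, str], str],
    counts_by_genome: Mapping[str, Mapping[str, int]],
    genomes: Sequence[str],
    min_copies: int = DEFAULT_MIN_COPIES,
) -> list[ConversionEvent]:
    """Conversions over every unordered genome pair in ``genomes``."""
    events: list[ConversionEvent] = []
    ordered = sorted(genomes)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            events.extend(
                detect_conversions(
                    sets, mature_by_member, counts_by_genome, a, b, min_copies
                )
            )
    return events


def recurrence_counts(events: Iterable[ConversionEvent]) -> Counter[tuple[str, str]]:
    """Events per unordered sequence pair across all genome pairs."""
    c: Counter[tuple[str, str]] = Counter()
    for e in events:
        c[e.pair] += 1
    return c


def recurrent_pairs(
    counts: Mapping[tuple[str, str], int], threshold: int = DEFAULT_RECURRENCE
) -> dict[tuple[str, str], int]:
    """Sequence pairs converted at least ``threshold`` times."""
    return {p: n for p, n in counts.items() if n >= threshold}


def likely_converted_genomes(
    oset: OrthologSet, mature_by_member: Mapping[tuple[str, str], str]
) -> list[str]:
    """Parsimony annotation: genomes carrying the set's minority sequence.

    If one sequence dominates the set across the panel, the genomes holding
    a different (minority) sequence are the likely sites of conversion.
    Returns [] when no strict majority exists.
    """
    seq_of: dict[str, str] = {}
    for g, l in oset.members.items():
        s = mature_by_member.get((g, l))
        if s is not None:
            seq_of[g] = s
    if not seq_of:
        return []
    tally = Counter(seq_of.values())
    (top, n), *rest = tally.most_common()
    if rest and rest[0][1] == n:
        return []
    return sorted(g for g, s in seq_of.items() if s != top)


def write_events_tsv(
    events: Sequence[ConversionEvent], names: Mapping[str, str] | None = None
) -> str:
    """Events table; sequences are labelled via ``names`` when available."""

    def label(seq: str) -> str:
        return names.get(seq, seq) if names else seq

    lines = ["genome_a\tgenome_b\tset_id\tseq_from\tseq_to\tedit_distance"]
    for e in sorted(events, key=lambda e: (e.genome_a, e.genome_b, e.set_id)):
        dist = _edit_distance(e.seq_from, e.seq_to)
        lines.append(
            f"{e.genome_a}\t{e.genome_b}\t{e.set_id}\t{label(e.seq_from)}\t"
            f"{label(e.seq_to)}\t{dist}"
        )
    return "\n".join(lines) + "\n"


def write_recurrence_tsv(
    counts: Mapping[tuple[str, str], int], names: Mapping[str, str] | None = None
) -> str:
    def label(seq: str) -> str:
        return names.get(seq, seq) if names else seq

    lines = ["seq_a\tseq_b\tn_events"]
    for pair in sorted(counts, key=lambda p: (-counts[p], p)):
        lines.append(f"{label(pair[0])}\t{label(pair[1])}\t{counts[pair]}")
    return "\n".join(lines) + "\n"


def _edit_distance(a: str, b: str) -> int:
    if len(a) == len(b):
        return sum(1 for x, y in zip(a, b) if x != y)
    try:
        import edlib

        return edlib.align(a, b)["editDistance"]
    except Exception:  # pragma: no cover - edlib is present in practice
        prev = list(range(len(b) + 1))
        for i, x in enumerate(a, 1):
            cur = [i]
            for j, y in enumerate(b, 1):
                cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (x != y)))
            prev = cur
        return prev[-1]
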