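"""Copy-number analysis of mature tRNA sequences across a genome panel.

Copy identity is exact mature-sequence equality (after CCA addition and the
His G-1 rule); a config switch allows genomic-body identity instead. Absent
sequences count as zero copies, not missing data, so ranges and
single-copy-conservation statistics treat absence and multicopy uniformly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotations_io import TRNALocus
from .mature_sequence import MatureSequence

STATUS_SINGLE = "single"
STATUS_MULTI = "multi"
STATUS_ABSENT = "absent"


def count_copies(seqs: Iterable[str | MatureSequence]) -> Counter[str]:
    """Exact string-identity copy counts for one genome's sequences.

    Accepts plain strings or any record with ``seq`` (e.g.
    :class:`~trnapanel.mature_sequence.MatureSequence`).
    """
    c: Counter[str] = Counter()
    for s in seqs:
        c[getattr(s, "seq", s)] += 1
    return c


@dataclass
class CopyTable:
    """Cross-genome copy-count matrix.

    ``df`` is indexed by mature sequence string with one integer column per
    genome; ``names`` maps each sequence to a human-readable label —
    reference-genome annotation style where the sequence occurs in the
    reference, else a "novel-<genome>-<ordinal>" identifier.
    """

    df: pd.DataFrame
    names: dict[str, str] = field(default_factory=dict)

    @property
    def genomes(self) -> list[str]:
        return list(self.df.columns)

    def counts(self, genome: str) -> Counter[str]:
        col = self.df[genome]
        return Counter({seq: int(n) for seq, n in col.items() if n > 0})

    def to_tsv(self) -> str:
        lines = ["\t".join(["name", "sequence", *self.df.columns])]
        for seq in self.df.index:
            row = [self.names.get(seq, seq), seq]
            row.extend(str(int(v)) for v in self.df.loc[seq])
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


def build_copy_table(
    mature_by_genome: Mapping[str, Iterable[str | MatureSequence]],
    genomes: Sequence[str] | None = None,
    reference: str | None = None,
    reference_loci: Mapping[str, TRNALocus] | None = None,
) -> CopyTable:
    """Assemble the per-genome copy counts into one matrix.

    ``reference_loci`` maps reference locus_id -> annotation, used to label
    rows by isotype/anticodon where the sequence exists in the reference.
    Row order is deterministic: reference-first by label, then novel rows in
    first-seen order.
    """
    if genomes is None:
        genomes = list(mature_by_genome)
    counters: dict[str, Counter[str]] = {}
    source_locus: dict[str, dict[str, str]] = {}
    for g in genomes:
        seqs = list(mature_by_genome.get(g, []))
        counters[g] = count_copies(seqs)
        by_seq: dict[str, str] = {}
        for s in seqs:
            if hasattr(s, "seq") and hasattr(s, "source_locus"):
                cur = by_seq.get(s.seq)
                if cur is None or s.source_locus < cur:
                    by_seq[s.seq] = s.source_locus
        source_locus[g] = by_seq

    # stable row order: reference sequences first (by first source locus),
    # then novel sequences in genome order / first-seen order
    rows: list[str] = []
    seen: set[str] = set()
    ref_counter = counters.get(reference, Counter()) if reference else Counter()
    if reference:
        for seq in sorted(ref_counter, key=lambda s: source_locus[reference].get(s, s)):
            rows.append(seq)
            seen.add(seq)
    for g in genomes:
        for s in mature_by_genome.get(g, []):
            seq = getattr(s, "seq", s)
            if seq not in seen:
                rows.append(seq)
                seen.add(seq)

    names: dict[str, str] = {}
    novel_ord: Counter[str] = Counter()
    iso_ord: Counter[tuple[str, str]] = Counter()
    for seq in rows:
        if reference and ref_counter.get(seq, 0) > 0:
            loc = None
            if reference_loci:
                lid = source_locus[reference].get(seq)
                loc = reference_loci.get(lid) if lid else None
            if loc is not None:
                key = (loc.isotype, loc.anticodon)
                iso_ord[key] += 1
                names[seq] = f"tRNA-{loc.isotype}-{loc.anticodon}-{iso_ord[key]}"
            else:
                names[seq] = f"{reference}-{source_locus[reference].get(seq, seq[:12])}"
        else:
            first = next(
                g for g in genomes if counters[g].get(seq, 0) > 0
            )
            novel_ord[first] += 1
            names[seq] = f"novel-{first}-{novel_ord[first]}"

    df = pd.DataFrame(
        {g: [counters[g].get(seq, 0) for seq in rows] for g in genomes},
        index=rows,
        dtype=int,
    )
    return CopyTable(df=df, names=names)


def copy_number_range(
    table: CopyTable, exclude: Iterable[str] = ()
) -> pd.Series:
    """Per sequence: max - min copy count over the non-excluded genomes
    (a genome lacking the sequence contributes 0 copies)."""
    excl = set(exclude)
    cols = [g for g in table.df.columns if g not in excl]
    if not cols:
        raise ValueError("no genomes left after exclusion")
    sub = table.df[cols]
    return sub.max(axis=1) - sub.min(axis=1)


def single_copy_conservation(
    table: CopyTable, strain_set: Sequence[str]
) -> pd.Series:
    """Per sequence: in how many strains is it maintained at exactly one copy?

    A sequence that is multicopy or absent in every strain scores 0.
    """
    missing = [g for g in strain_set if g not in table.df.columns]
    if missing:
        raise ValueError(f"genomes not in table: {missing}")
    sub = table.df[list(strain_set)]
    return (sub == 1).sum(axis=1)


def cross_species_single_copy(
    table: CopyTable,
    extra_genomes: Sequence[str],
    candidates: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Single/multi/absent status of candidate sequences in extra genomes.

    ``candidates`` defaults to every row; upstream callers restrict it to
    sequences single-copy across more than a threshold number of strains.
    """
    rows = list(candidates) if candidates is not None else list(table.df.index)
    out = {}
    for g in extra_genomes:
        col = table.df[g].reindex(rows).fillna(0).astype(int)
        out[g] = col.map(
            lambda n: STATUS_ABSENT if n == 0 else (STATUS_SINGLE if n == 1 else STATUS_MULTI)
        )
    return pd.DataFrame(out, index=rows)


def strain_count_histogram(values: Iterable[int]) -> dict[int, int]:
    """Histogram helper for per-sequence strain counts (summary output)."""
    c = Counter(int(v) for v in values)
    return {k: c[k] for k in sorted(c)}
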