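"""Ortholog-set construction across a genome panel from liftover projections.

Because tRNA genes occur as many identical dispersed copies, orthology
cannot be inferred from sequence similarity alone. This module instead
builds an orthology graph from whole-genome-alignment liftover records
(coordinate projections of each annotated locus into every other genome),
then:

1. merges fragmented projections and drops short ones,
2. keeps only bidirectionally supported locus pairs,
3. validates each remaining pair by a flank-anchored local alignment —
   requiring the aligned length to reach half the shorter flanked sequence,
   which a pair of identical gene bodies sitting in unrelated flanking
   contexts cannot achieve — and
4. resolves the validated graph into cliques holding at most one locus per
   genome (ortholog sets).

Genomes in which a set has no member are classified as "missing" (no
projection reaches the genome at all) or "pseudo" (a projected region
exists but carries no scanner-detected tRNA).
"""

from __future__ import annotations

from collections import defaultdict, deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
from Bio import Align
from intervaltree import IntervalTree

from .annotations_io import LiftoverRecord, TRNALocus

Node = tuple[str, str]  # (genome, locus_id)

DEFAULT_MERGE_GAP = 10
DEFAULT_MIN_ALIGN_FRAC = 0.5

STATUS_MISSING = "missing"
STATUS_PSEUDO = "pseudo"
STATUS_CONFLICT = "conflict"


@dataclass(frozen=True)
class AlignmentResult:
    """Score and column count of an optimal local alignment."""

    score: int
    aligned_length: int


@dataclass(frozen=True)
class ProjectedInterval:
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class OrthologyGraph:
    """Candidate orthology relationships between loci of different genomes.

    ``graph`` nodes are (genome, locus_id); edges carry the set of
    projection directions (src_genome, dst_genome) that produced them.
    ``projections`` records every merged projected interval per
    (source node, destination genome), including intervals that hit no
    annotated locus — needed later to tell "missing" from "pseudo".
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    projections: dict[tuple[Node, str], list[ProjectedInterval]] = field(
        default_factory=dict
    )


@dataclass
class OrthologSet:
    """A validated group of mutually orthologous loci, <=1 per genome."""

    set_id: str
    members: dict[str, str]  # genome -> locus_id
    absences: dict[str, str] = field(default_factory=dict)  # genome -> status

    @property
    def nodes(self) -> list[Node]:
        return sorted(self.members.items())


@dataclass(frozen=True)
class EdgeRejection:
    """A candidate pair removed by flank-anchored validation."""

    node_a: Node
    node_b: Node
    score: int
    aligned_length: int
    required_length: float


# ---------------------------------------------------------------------------
# Interval machinery
# ---------------------------------------------------------------------------


def _locus_trees(
    loci_by_genome: Mapping[str, Sequence[TRNALocus]]
) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    for genome, loci in loci_by_genome.items():
        for loc in loci:
            trees[(genome, loc.chrom)].addi(loc.start, loc.end, loc)
    return dict(trees)


def _merge_intervals(
    intervals: Iterable[tuple[int, int]], merge_gap: int
) -> list[tuple[int, int]]:
    """Merge intervals whose gaps are <= merge_gap (duplicates collapse)."""
    ivs = sorted(set(intervals))
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def project_orthologs(
    records: Iterable[LiftoverRecord],
    loci_by_genome: Mapping[str, Sequence[TRNALocus]],
    min_len: int = 50,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> OrthologyGraph:
    """Turn liftover records into a candidate orthology graph.

    Destination fragments from the same (source locus, destination genome,
    chrom, strand) with gaps <= ``merge_gap`` merge into one interval;
    merged intervals shorter than ``min_len`` create no edges (but are still
    recorded as projections for absence classification). An edge joins the
    source locus to every annotated destination locus overlapping a merged
    interval by >= 1 bp.
    """
    trees = _locus_trees(loci_by_genome)
    known = set(loci_by_genome)
    # (src_node, dst_genome, dst_chrom, dst_strand) -> fragment intervals
    frags: dict[tuple[Node, str, str, str], list[tuple[int, int]]] = defaultdict(list)
    og = OrthologyGraph()
    for loci in loci_by_genome.values():
        for loc in loci:
            og.graph.add_node(loc.node)
    for rec in records:
        if rec.src_genome not in known or rec.dst_genome not in known:
            raise ValueError(
                f"liftover record references unknown genome "
                f"{rec.src_genome!r} or {rec.dst_genome!r}"
            )
        tree = trees.get((rec.src_genome, rec.src_chrom))
        if tree is None:
            continue
        hits = tree.overlap(rec.src_start, rec.src_end)
        if not hits:
            continue
        # most-overlapping source locus; ties broken by locus_id
        src = max(
            (iv.data for iv in hits),
            key=lambda l: (
                min(l.end, rec.src_end) - max(l.start, rec.src_start),
                l.locus_id,
            ),
        )
        frags[(src.node, rec.dst_genome, rec.dst_chrom, rec.dst_strand)].append(
            (rec.dst_start, rec.dst_end)
        )

    projections: dict[tuple[Node, str], list[ProjectedInterval]] = defaultdict(list)
    for (src_node, dst_genome, dst_chrom, dst_strand), ivs in frags.items():
        for s, e in _merge_intervals(ivs, merge_gap):
            proj = ProjectedInterval(dst_chrom, s, e, dst_strand)
            projections[(src_node, dst_genome)].append(proj)
            if proj.length < min_len:
                continue
            dst_tree = trees.get((dst_genome, dst_chrom))
            if dst_tree is None:
                continue
            for iv in dst_tree.overlap(s, e):
                dst: TRNALocus = iv.data
                if dst.genome == src_node[0]:
                    continue
                if og.graph.has_edge(src_node, dst.node):
                    og.graph.edges[src_node, dst.node]["directions"].add(
                        (src_node[0], dst_genome)
                    )
                else:
                    og.graph.add_edge(
                        src_node,
                        dst.node,
                        directions={(src_node[0], dst_genome)},
                        validated=None,
                    )
    og.projections = dict(projections)
    return og


def enforce_bidirectional(og: OrthologyGraph) -> OrthologyGraph:
    """Keep only edges supported by projections in both directions."""
    out = OrthologyGraph(projections=og.projections)
    out.graph.add_nodes_from(og.graph.nodes)
    for u, v, data in og.graph.edges(data=True):
        dirs = data.get("directions", set())
        if (u[0], v[0]) in dirs and (v[0], u[0]) in dirs:
            out.graph.add_edge(u, v, **data)
    return out


# ---------------------------------------------------------------------------
# Local alignment and flank validation
# ---------------------------------------------------------------------------

_LOCAL = Align.PairwiseAligner(
    mode="local",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-2,
)


def local_align(a: str, b: str) -> AlignmentResult:
    """Optimal local alignment under match +1 / mismatch -1 / gap -2.

    A non-positive optimum is treated as no alignment (score 0, length 0).
    The traceback is deterministic (the aligner's canonical first optimum).
    """
    if not a or not b:
        return AlignmentResult(0, 0)
    score = _LOCAL.score(a, b)
    if score <= 0:
        return AlignmentResult(0, 0)
    aln = next(iter(_LOCAL.align(a, b)))
    return AlignmentResult(int(score), aln.length)


def validate_edge(
    seq_a: str, seq_b: str, min_frac: float = DEFAULT_MIN_ALIGN_FRAC
) -> bool:
    """Flank-anchored validation: does the local alignment of the two
    flanked sequences span at least ``min_frac`` of the shorter one?

    Identical gene bodies embedded in unrelated flanks align only over the
    body and fail; true orthologs share flanking sequence and pass.
    """
    if not seq_a or not seq_b:
        return False
    res = local_align(seq_a, seq_b)
    return res.aligned_length >= min_frac * min(len(seq_a), len(seq_b))


def validate_graph(
    og: OrthologyGraph,
    flanked_seqs: Mapping[Node, str],
    min_frac: float = DEFAULT_MIN_ALIGN_FRAC,
) -> tuple[OrthologyGraph, list[EdgeRejection]]:
    """Apply :func:`validate_edge` to every edge; failing edges are removed
    and logged. ``flanked_seqs`` maps nodes to their gene+flank sequences."""
    out = OrthologyGraph(projections=og.projections)
    out.graph.add_nodes_from(og.graph.nodes)
    rejections: list[EdgeRejection] = []
    for u, v, data in og.graph.edges(data=True):
        a = flanked_seqs.get(u, "")
        b = flanked_seqs.get(v, "")
        res = local_align(a, b) if a and b else AlignmentResult(0, 0)
        required = min_frac * min(len(a), len(b)) if a and b else float("inf")
        if a and b and res.aligned_length >= required:
            out.graph.add_edge(u, v, **{**data, "validated": True})
        else:
            ua, vb = sorted([u, v])
            rejections.append(
                EdgeRejection(ua, vb, res.score, res.aligned_length, required)
            )
    return out, rejections


# ---------------------------------------------------------------------------
# Set assembly
# ---------------------------------------------------------------------------


def _is_valid_set(graph: nx.Graph, nodes: set[Node]) -> bool:
    genomes = [g for g, _ in nodes]
    if len(genomes) != len(set(genomes)):
        return False
    nodelist = list(nodes)
    for i, u in enumerate(nodelist):
        for v in nodelist[i + 1 :]:
            if not graph.has_edge(u, v):
                return False
    return True


def assemble_sets(
    og: OrthologyGraph, reference: str | None = None
) -> list[OrthologSet]:
    """Resolve the validated graph into ortholog sets.

    Connected components that are cliques with at most one locus per genome
    become sets directly. Other components are resolved by iteratively
    removing the lowest-degree node (ties: lexicographic locus_id, then
    genome) until the clique/one-per-genome property holds; removed nodes
    re-enter as their own candidate components. Singleton nodes become
    single-member sets.
    """
    G = og.graph
    sets: list[OrthologSet] = []
    queue = deque(sorted(G.subgraph(c).nodes) for c in nx.connected_components(G))
    while queue:
        comp = set(queue.popleft())
        if not comp:
            continue
        sub = G.subgraph(comp)
        nodes = set(comp)
        removed: set[Node] = set()
        while nodes and not _is_valid_set(sub, nodes):
            degree = {
                n: sum(1 for m in nodes if m != n and sub.has_edge(n, m))
                for n in nodes
            }
            victim = min(nodes, key=lambda n: (degree[n], n[1], n[0]))
            nodes.remove(victim)
            removed.add(victim)
        if nodes:
            sets.append(_make_set(nodes, reference))
        if removed:
            rsub = G.subgraph(removed)
            for c in nx.connected_components(rsub):
                queue.append(sorted(c))
    # deterministic ordering of output
    sets.sort(key=lambda s: s.set_id)
    return sets


def _make_set(nodes: set[Node], reference: str | None) -> OrthologSet:
    members = {g: l for g, l in nodes}
    if reference is not None and reference in members:
        set_id = f"{reference}|{members[reference]}"
    else:
        g, l = min(nodes)
        set_id = f"{g}|{l}"
    return OrthologSet(set_id=set_id, members=members)


def classify_absence(
    oset: OrthologSet,
    genome: str,
    og: OrthologyGraph,
    annotated_loci: Sequence[TRNALocus],
) -> str:
    """Classify why ``genome`` has no member in ``oset``.

    "missing": no member's projection reaches the genome at all.
    "pseudo": a projected region exists but overlaps no annotated (scanner
    score >= floor) locus there.
    "conflict": a projection overlaps an annotated locus that nonetheless is
    not in the set — flagged for QC rather than silently re-labelled.
    """
    if genome in oset.members:
        raise ValueError(f"{genome} is a member of set {oset.set_id}")
    intervals: list[ProjectedInterval] = []
    for g, l in oset.members.items():
        intervals.extend(og.projections.get(((g, l), genome), []))
    if not intervals:
        return STATUS_MISSING
    for iv in intervals:
        for loc in annotated_loci:
            if loc.chrom == iv.chrom and loc.start < iv.end and loc.end > iv.start:
                return STATUS_CONFLICT
    return STATUS_PSEUDO


def classify_all_absences(
    sets: Sequence[OrthologSet],
    genomes: Sequence[str],
    og: OrthologyGraph,
    loci_by_genome: Mapping[str, Sequence[TRNALocus]],
) -> None:
    """Fill ``absences`` in place for every set and panel genome."""
    for oset in sets:
        for genome in genomes:
            if genome not in oset.members:
                oset.absences[genome] = classify_absence(
                    oset, genome, og, loci_by_genome.get(genome, [])
                )


def write_ortholog_sets_tsv(
    sets: Sequence[OrthologSet], genomes: Sequence[str]
) -> str:
    """Ortholog-set table: one row per set, one column per genome holding the
    member locus_id, or "missing"/"pseudo"/"conflict", or "NA"."""
    header = ["set_id", *genomes]
    lines = ["\t".join(header)]
    for oset in sets:
        row = [oset.set_id]
        for g in genomes:
            if g in oset.members:
                row.append(oset.members[g])
            else:
                row.append(oset.absences.get(g, "NA"))
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
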