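"""Statistical comparisons and pipeline orchestration.

Runs the full analysis end to end — annotation ingestion, mature-sequence
projection, ortholog-set construction, copy-number statistics, Pol III
scoring, per-position variation, and gene-conversion inference — and
writes the result tables, a summary JSON and a discard-accounting log.
Also provides the exact/asymptotic Mann-Whitney U test used to compare
Pol III occupancy between conservation classes.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from . import annotations_io as aio
from . import conversion as conv
from . import copy_number as cn
from . import mature_sequence as ms
from . import ortholog_sets as orth
from . import pol3
from . import variation as var
from .synthetic_data import SimulatedPanel


@dataclass
class PipelineConfig:
    """All thresholds in one place; numeric defaults are the published ones."""

    score_floor: float = 10.0          # scanner minimum score (bits)
    high_score_cutoff: float = 50.0    # tRNA vs tRNA-like (strict >)
    pol3_cutoff: float = 2.0           # occupancy class boundary (>=)
    pseudocount: float = 20.0
    score_cap: float = 6.0
    read_extension: int = 50           # bp each side for read counting
    ortholog_flank: int = 20           # bp flank for liftover projection
    validation_flank: int = 100        # bp flank for edge validation
    min_length: int = 50               # bp; shorter projections dropped
    merge_gap: int = 10                # bp; projection fragments merged
    min_align_frac: float = 0.5        # of the shorter flanked sequence
    multicopy_threshold: int = 2
    recurrence_threshold: int = 10
    single_copy_conservation_threshold: int = 16
    copy_identity: str = "mature"      # or "genomic": gene-body identity
    reference: str = "mm_ref"
    outgroup: tuple[str, ...] = ("outgroup",)
    seed: int = 0

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        kwargs = {k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(cls)}}
        if "outgroup" in kwargs and not isinstance(kwargs["outgroup"], tuple):
            og = kwargs["outgroup"]
            kwargs["outgroup"] = (og,) if isinstance(og, str) else tuple(og)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outgroup"] = list(self.outgroup)
        return d


@dataclass(frozen=True)
class _IdentitySeq:
    """A bare (sequence, source locus) record for copy-identity grouping."""

    seq: str
    source_locus: str


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    pvalue: float
    method: str  # "exact" or "normal"


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], exact_limit: int = 16
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    U is the statistic for ``x`` computed from midrank sums. The p-value is
    exact (full enumeration of labelings of the pooled sample) when
    n_x + n_y <= ``exact_limit``, else a normal approximation with tie and
    continuity corrections. Two-sided p doubles the smaller tail, capped
    at 1.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)

    if n1 + n2 <= exact_limit:
        n = n1 + n2
        base = n1 * (n1 + 1) / 2
        le = ge = total = 0
        eps = 1e-9
        for combo in itertools.combinations(range(n), n1):
            u = float(sum(ranks[i] for i in combo) - base)
            total += 1
            if u <= u_obs + eps:
                le += 1
            if u >= u_obs - eps:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
        return MannWhitneyResult(U=u_obs, pvalue=p, method="exact")

    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_counts = np.array(list(Counter(pooled.tolist()).values()), dtype=float)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return MannWhitneyResult(U=u_obs, pvalue=1.0, method="normal")
    sigma = math.sqrt(sigma2)
    diff = u_obs - mu
    cc = 0.5 if diff > 0 else (-0.5 if diff < 0 else 0.0)
    z = (diff - cc) / sigma
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return MannWhitneyResult(U=u_obs, pvalue=float(p), method="normal")


# ---------------------------------------------------------------------------
# Input loading
# ---------------------------------------------------------------------------


@dataclass
class PanelInputs:
    """Everything the analysis consumes, already parsed."""

    genomes: list[str]
    reference: str
    outgroup: tuple[str, ...]
    fastas: dict[str, dict[str, str]]
    loci_by_genome: dict[str, list[aio.TRNALocus]]
    liftover_records: list[aio.LiftoverRecord]
    chip_counts: list[dict[str, tuple[int, int]]]


def load_inputs(input_dir: str | Path, config: PipelineConfig) -> PanelInputs:
    """Load a panel from a directory carrying a manifest.json."""
    input_dir = Path(input_dir)
    manifest = json.loads((input_dir / "manifest.json").read_text())
    genomes = sorted(manifest["genomes"])
    fastas: dict[str, dict[str, str]] = {}
    loci: dict[str, list[aio.TRNALocus]] = {}
    for g in genomes:
        files = manifest["genomes"][g]
        fastas[g] = aio.read_fasta(input_dir / files["fasta"])
        loci[g] = aio.parse_trnascan_table(
            (input_dir / files["trnascan"]).read_text(), g, config.score_floor
        )
    records = aio.read_liftover_map((input_dir / manifest["liftover"]).read_text())
    chip = [
        aio.read_count_table((input_dir / name).read_text())
        for name in manifest.get("chip_counts", [])
    ]
    return PanelInputs(
        genomes=genomes,
        reference=manifest.get("reference", config.reference),
        outgroup=tuple(
            manifest.get("outgroup", config.outgroup)
            if isinstance(manifest.get("outgroup", config.outgroup), (list, tuple))
            else [manifest["outgroup"]]
        ),
        fastas=fastas,
        loci_by_genome=loci,
        liftover_records=records,
        chip_counts=chip,
    )


def inputs_from_panel(panel: SimulatedPanel, config: PipelineConfig) -> PanelInputs:
    """Adapter from an in-memory simulated panel (no file round trip)."""
    loci = {
        g: aio.parse_trnascan_table(panel.trnascan_tables[g], g, config.score_floor)
        for g in panel.genomes
    }
    return PanelInputs(
        genomes=list(panel.genomes),
        reference=panel.reference,
        outgroup=(panel.outgroup,),
        fastas=panel.fastas,
        loci_by_genome=loci,
        liftover_records=list(panel.liftover_records),
        chip_counts=[dict(c) for c in panel.chip_counts],
    )


# ---------------------------------------------------------------------------
# Analysis
# ---------------------------------------------------------------------------


@dataclass
class AnalysisResult:
    config: PipelineConfig
    inputs: PanelInputs
    mature_by_genome: dict[str, list[ms.MatureSequence]]
    mature_by_member: dict[tuple[str, str], str]
    rejections: list[ms.Rejection]
    graph: orth.OrthologyGraph
    edge_rejections: list[orth.EdgeRejection]
    sets: list[orth.OrthologSet]
    copy_table: cn.CopyTable
    measurements: dict[str, pol3.PolIIIMeasurement]
    concordance: float | None
    alignments: dict[str, var.FamilyAlignment]
    conversion_events: list[conv.ConversionEvent]
    recurrence: Counter
    summary: dict
    log_lines: list[str] = field(default_factory=list)


def analyze(inputs: PanelInputs, config: PipelineConfig) -> AnalysisResult:
    """Run every stage of the comparative analysis on parsed inputs."""
    log: list[str] = []
    strains = [g for g in inputs.genomes if g not in inputs.outgroup]
    n_loci = sum(len(v) for v in inputs.loci_by_genome.values())
    log.append(f"loci parsed (score >= {config.score_floor:g}): {n_loci}")

    # --- score classes -----------------------------------------------------
    high_by_genome = {}
    for g, loci in inputs.loci_by_genome.items():
        part = aio.classify_by_score(loci, config.high_score_cutoff)
        high_by_genome[g] = {l.locus_id for l in part.high}
    n_high = sum(len(v) for v in high_by_genome.values())

    # --- mature projection -------------------------------------------------
    mature_by_genome: dict[str, list[ms.MatureSequence]] = {}
    mature_by_member: dict[tuple[str, str], str] = {}
    rejections: list[ms.Rejection] = []
    loci_index: dict[tuple[str, str], aio.TRNALocus] = {}
    for g in inputs.genomes:
        out: list[ms.MatureSequence] = []
        for loc in inputs.loci_by_genome[g]:
            loci_index[(g, loc.locus_id)] = loc
            flanked = ms.extract_genomic(inputs.fastas[g], loc, config.ortholog_flank)
            if len(flanked) < config.min_length:
                rejections.append(ms.Rejection(loc.locus_id, ms.REASON_TOO_SHORT))
                continue
            body = ms.extract_gene_body(inputs.fastas[g], loc)
            res = ms.project_mature(loc, body)
            if isinstance(res, ms.Rejection):
                rejections.append(res)
                continue
            out.append(res)
            mature_by_member[(g, loc.locus_id)] = res.seq
        mature_by_genome[g] = out
    log.append(f"mature sequences: {sum(len(v) for v in mature_by_genome.values())}")
    log.append(f"projection rejections: {len(rejections)}")

    # --- ortholog sets -----------------------------------------------------
    graph0 = orth.project_orthologs(
        inputs.liftover_records,
        inputs.loci_by_genome,
        min_len=config.min_length,
        merge_gap=config.merge_gap,
    )
    n_edges0 = graph0.graph.number_of_edges()
    graph1 = orth.enforce_bidirectional(graph0)
    n_edges1 = graph1.graph.number_of_edges()
    flanked_seqs = {
        (g, loc.locus_id): ms.extract_genomic(
            inputs.fastas[g], loc, config.validation_flank
        )
        for g, loci in inputs.loci_by_genome.items()
        for loc in loci
    }
    graph2, edge_rejections = orth.validate_graph(
        graph1, flanked_seqs, config.min_align_frac
    )
    log.append(
        f"orthology edges: projected {n_edges0}, bidirectional {n_edges1}, "
        f"validated {graph2.graph.number_of_edges()} "
        f"(removed one-way {n_edges0 - n_edges1}, "
        f"failed validation {len(edge_rejections)})"
    )
    sets = orth.assemble_sets(graph2, reference=inputs.reference)
    orth.classify_all_absences(sets, inputs.genomes, graph2, inputs.loci_by_genome)
    absence_tally = Counter(st for s in sets for st in s.absences.values())
    log.append(
        f"ortholog sets: {len(sets)}; absences "
        + ", ".join(f"{k}={absence_tally.get(k, 0)}" for k in ("missing", "pseudo", "conflict"))
    )

    # --- copy number -------------------------------------------------------
    ref_loci = {l.locus_id: l for l in inputs.loci_by_genome.get(inputs.reference, [])}
    if config.copy_identity == "genomic":
        # copy identity by genomic gene body instead of mature transcript
        identity_seqs: Mapping = {
            g: [
                _IdentitySeq(
                    seq=ms.extract_gene_body(inputs.fastas[g], loc),
                    source_locus=loc.locus_id,
                )
                for loc in inputs.loci_by_genome[g]
                if not set(ms.extract_gene_body(inputs.fastas[g], loc)) - set("ACGT")
            ]
            for g in inputs.genomes
        }
    else:
        identity_seqs = mature_by_genome
    copy_table = cn.build_copy_table(
        identity_seqs,
        genomes=inputs.genomes,
        reference=inputs.reference,
        reference_loci=ref_loci,
    )
    ranges = cn.copy_number_range(copy_table, exclude=inputs.outgroup)
    conservation = cn.single_copy_conservation(copy_table, strains)
    n_conserved = int(
        (conservation >= config.single_copy_conservation_threshold).sum()
    )
    cross = cn.cross_species_single_copy(
        copy_table,
        [g for g in inputs.outgroup if g in copy_table.df.columns],
        candidates=[
            s
            for s in copy_table.df.index
            if conservation[s] >= config.single_copy_conservation_threshold
        ],
    )

    # --- Pol III -----------------------------------------------------------
    measurements: dict[str, pol3.PolIIIMeasurement] = {}
    concordance = None
    if inputs.chip_counts:
        measurements = pol3.score_loci(
            inputs.chip_counts[0], config.pseudocount, config.score_cap
        )
        if len(inputs.chip_counts) > 1:
            rep = pol3.score_loci(
                inputs.chip_counts[1], config.pseudocount, config.score_cap
            )
            concordance = pol3.dataset_concordance(
                {k: m.score for k, m in measurements.items()},
                {k: m.score for k, m in rep.items()},
            )
    ref_scores = {l.locus_id: l.score for l in inputs.loci_by_genome.get(inputs.reference, [])}
    class_of_ref_locus: dict[str, str] = {}
    for lid, m in measurements.items():
        if lid in ref_scores:
            class_of_ref_locus[lid] = pol3.classify_locus(
                ref_scores[lid], m.score, config.high_score_cutoff, config.pol3_cutoff
            )
    class_tally = Counter(class_of_ref_locus.values())

    # --- variation ---------------------------------------------------------
    alignments: dict[str, var.FamilyAlignment] = {}
    mismatch_by_strain: dict[str, Counter] = defaultdict(Counter)
    variant_counts: dict[str, int] = {}
    for oset in sets:
        seqs = {
            g: mature_by_member[(g, lid)]
            for g, lid in oset.members.items()
            if (g, lid) in mature_by_member
        }
        if not seqs:
            continue
        aln = var.align_family(seqs)
        if inputs.reference in aln.rows:
            aln.ref_key = inputs.reference
        alignments[oset.set_id] = aln
        variant_counts[oset.set_id] = var.variant_count(seqs.values())
        for g in aln.rows:
            if g != aln.ref_key:
                mismatch_by_strain[g][var.count_mismatches(aln, aln.ref_key, g)] += 1
    class_alignments: dict[str, list[var.FamilyAlignment]] = defaultdict(list)
    for oset in sets:
        ref_member = oset.members.get(inputs.reference)
        if ref_member is None or oset.set_id not in alignments:
            continue
        cls = class_of_ref_locus.get(ref_member)
        if cls:
            class_alignments[cls].append(alignments[oset.set_id])
    profiles = {
        cls: var.variation_profile(alns, strains)
        for cls, alns in sorted(class_alignments.items())
    }
    identity_changes = []
    for oset in sets:
        anns = {
            g: loci_index[(g, lid)]
            for g, lid in oset.members.items()
            if (g, lid) in loci_index and g in strains
        }
        for change in var.detect_identity_change(anns, inputs.reference):
            identity_changes.append((oset.set_id, change))
    n_identity_changes = sum(1 for _, c in identity_changes if not c.ambiguous)

    # --- conversion --------------------------------------------------------
    counts_by_genome = {g: copy_table.counts(g) for g in inputs.genomes}
    raw_events = conv.all_pairwise_conversions(
        sets,
        mature_by_member,
        counts_by_genome,
        strains,
        config.multicopy_threshold,
    )
    events = conv.filter_substrings(raw_events)
    log.append(
        f"conversion events: {len(raw_events)} raw, "
        f"{len(raw_events) - len(events)} removed by substring filter"
    )
    recurrence = conv.recurrence_counts(events)
    recurrent = conv.recurrent_pairs(recurrence, config.recurrence_threshold)

    # --- statistics --------------------------------------------------------
    mw: MannWhitneyResult | None = None
    ref_mature = {s.source_locus: s.seq for s in mature_by_genome.get(inputs.reference, [])}
    hi_all, lo_cons = [], []
    for lid, m in measurements.items():
        seq = ref_mature.get(lid)
        if seq is None or seq not in conservation.index:
            continue
        c = int(conservation[seq])
        if c == len(strains):
            hi_all.append(m.score)
        elif c < config.single_copy_conservation_threshold:
            lo_cons.append(m.score)
    if hi_all and lo_cons:
        mw = mann_whitney_u(hi_all, lo_cons)

    # record audit: every parsed locus is analyzed or discarded with reason
    n_rejected = len(rejections)
    n_analyzed = sum(len(v) for v in mature_by_genome.values())
    assert n_analyzed + n_rejected == n_loci, "record accounting mismatch"

    strain_counts = Counter(
        sum(1 for g in s.members if g in strains) for s in sets
    )
    summary = {
        "n_loci": n_loci,
        "n_high": n_high,
        "n_low": n_loci - n_high,
        "n_mature": n_analyzed,
        "n_rejections": n_rejected,
        "n_sets": len(sets),
        "n_missing": absence_tally.get("missing", 0),
        "n_pseudo": absence_tally.get("pseudo", 0),
        "n_conflict": absence_tally.get("conflict", 0),
        "n_unique_sequences": int(len(copy_table.df)),
        "max_copy_range": int(ranges.max()) if len(ranges) else 0,
        "n_single_copy_conserved": n_conserved,
        "cross_species_status": {
            g: dict(Counter(cross[g])) for g in cross.columns
        },
        "pol3_classes": {k: class_tally.get(k, 0) for k in sorted(class_tally)},
        "replicate_concordance_r": None if concordance is None else round(concordance, 4),
        "max_variant_count": max(variant_counts.values(), default=0),
        "n_identity_changes": n_identity_changes,
        "n_conversion_events": len(events),
        "n_recurrent_pairs": len(recurrent),
        "strain_count_histogram": {str(k): strain_counts[k] for k in sorted(strain_counts)},
        "mannwhitney": None
        if mw is None
        else {"U": mw.U, "p": mw.pvalue, "method": mw.method,
              "n_x": len(hi_all), "n_y": len(lo_cons)},
    }
    log.append("summary: " + json.dumps(summary, sort_keys=True))

    result = AnalysisResult(
        config=config,
        inputs=inputs,
        mature_by_genome=mature_by_genome,
        mature_by_member=mature_by_member,
        rejections=rejections,
        graph=graph2,
        edge_rejections=edge_rejections,
        sets=sets,
        copy_table=copy_table,
        measurements=measurements,
        concordance=concordance,
        alignments=alignments,
        conversion_events=events,
        recurrence=recurrence,
        summary=summary,
        log_lines=log,
    )
    result.summary["profiles"] = {
        cls: [round(v, 4) for v in prof] for cls, prof in profiles.items()
    }
    return result


# ---------------------------------------------------------------------------
# Output bundle
# ---------------------------------------------------------------------------


def write_outputs(result: AnalysisResult, outdir: str | Path) -> Path:
    """Write the TSV bundle, summary.json and pipeline.log (all deterministic)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = result.inputs
    (outdir / "ortholog_sets.tsv").write_text(
        orth.write_ortholog_sets_tsv(result.sets, inputs.genomes)
    )
    (outdir / "copy_table.tsv").write_text(result.copy_table.to_tsv())
    ref_scores = {
        l.locus_id: l.score for l in inputs.loci_by_genome.get(inputs.reference, [])
    }
    (outdir / "pol3_scores.tsv").write_text(
        pol3.write_score_table(
            result.measurements,
            ref_scores,
            result.config.high_score_cutoff,
            result.config.pol3_cutoff,
        )
    )
    names = result.copy_table.names
    (outdir / "conversion_events.tsv").write_text(
        conv.write_events_tsv(result.conversion_events, names)
    )
    (outdir / "conversion_recurrence.tsv").write_text(
        conv.write_recurrence_tsv(result.recurrence, names)
    )
    rej = ["locus_id\treason"]
    rej += [f"{r.locus_id}\t{r.reason}" for r in sorted(result.rejections, key=lambda r: r.locus_id)]
    (outdir / "rejections.tsv").write_text("\n".join(rej) + "\n")
    edge_rej = ["node_a\tnode_b\tscore\taligned_length\trequired_length"]
    for e in sorted(result.edge_rejections, key=lambda e: (e.node_a, e.node_b)):
        edge_rej.append(
            f"{e.node_a[0]}|{e.node_a[1]}\t{e.node_b[0]}|{e.node_b[1]}\t"
            f"{e.score}\t{e.aligned_length}\t{e.required_length:.1f}"
        )
    (outdir / "edge_rejections.tsv").write_text("\n".join(edge_rej) + "\n")
    (outdir / "summary.json").write_text(
        json.dumps(result.summary, indent=1, sort_keys=True) + "\n"
    )
    (outdir / "pipeline.log").write_text("\n".join(result.log_lines) + "\n")
    return outdir / "summary.json"


def run_pipeline(
    config: PipelineConfig, input_dir: str | Path, outdir: str | Path
) -> AnalysisResult:
    """Load a panel directory, analyze it, and write the report bundle."""
    inputs = load_inputs(input_dir, config)
    result = analyze(inputs, config)
    write_outputs(result, outdir)
    return result
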