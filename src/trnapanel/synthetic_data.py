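"""Seeded synthetic strain panels with known ground truth.

The generator emulates the statistical structure of a panel of closely
related mouse-strain assemblies plus a distant outgroup, as seen through
the eyes of this pipeline's inputs:

* ancestral tRNA families of realistic length (70-90 bp) present in one or
  several identical copies, each copy planted at a unique flanking context
  on a toy chromosome;
* a fixed strain-tree topology (a clade of close laboratory strains, one
  divergent strain, one outgroup) down which copies evolve by per-branch
  point substitutions, rare whole-locus deletions (-> "missing"), rare
  pseudogenizations (the scanner no longer detects the locus -> "pseudo"),
  and gene conversions (a locus body overwritten by another family's
  sequence, flanks preserved);
* abundant low-scoring tRNA-like (SINE-like) families alongside
  high-scoring tRNAs, with covariance scores assigned by truth class;
* liftover maps derived from the true coordinate correspondence, with
  optional fragmentation noise, planted one-way records, and planted
  paralog-trap records (identical bodies, unrelated flanks) to exercise
  the bidirectionality and flank-validation safeguards;
* negative-binomial ChIP read counts separating active from silent loci.

Every draw comes from one seeded generator, so a fixed seed reproduces all
outputs bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .annotations_io import (
    LiftoverRecord,
    TRNALocus,
    write_bed6,
    write_count_table,
    write_fasta,
    write_liftover_map,
    write_trnascan_table,
)

_BASES = "ACGT"
_ISOTYPES = [
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "Ile", "Leu",
    "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
]  # His handled separately via his_fraction


@dataclass
class PanelConfig:
    """Generator parameters; defaults are the study conditions.

    ``n_strains`` counts the close strains plus one divergent strain (the
    reference is among the close strains); an outgroup genome is always
    added on top. Rates are per locus per unit branch length.
    """

    n_strains: int = 17
    n_families: int = 24
    copy_number_probs: tuple[tuple[int, float], ...] = (
        (1, 0.50),
        (2, 0.20),
        (3, 0.15),
        (4, 0.10),
        (6, 0.05),
    )
    fraction_trna_like: float = 0.3
    substitution_rate: float = 0.08
    deletion_rate: float = 0.004
    pseudogenization_rate: float = 0.004
    conversion_rate: float = 0.004
    his_fraction: float = 0.05
    intron_fraction: float = 0.08
    active_fraction: float = 0.8
    trna_like_active_fraction: float = 0.1
    chip_mean_active: float = 640.0
    chip_mean_silent: float = 20.0
    chip_dispersion: float = 5.0
    n_chip_replicates: int = 2
    flank_len: int = 120
    spacer_len: int = 60
    fragmentation_rate: float = 0.2
    oneway_noise_rate: float = 0.05
    paralog_trap_rate: float = 0.05
    n_forced_conversions: int = 0
    substring_family_pairs: int = 0
    force_delete_strain: str | None = None
    max_chrom_len: int = 5_000_000
    reference: str = "mm_ref"
    outgroup: str = "outgroup"
    seed: int = 0

    def strain_names(self) -> list[str]:
        close = [self.reference] + [
            f"strain{i:02d}" for i in range(1, self.n_strains - 1)
        ]
        return close + (["divergent"] if self.n_strains > 1 else [])

    def genome_names(self) -> list[str]:
        return self.strain_names() + [self.outgroup]


@dataclass
class FamilyTruth:
    family_id: str
    body: str  # ancestral 5'->3' gene body, intron included
    intron: tuple[int, int] | None
    isotype: str
    anticodon_offset: int
    score: float
    trna_like: bool
    active: bool
    n_copies: int


@dataclass
class LocusTruth:
    copy_id: str
    status: str  # "present" | "pseudo" | "absent"
    locus_id: str | None
    chrom: str | None
    start: int | None
    end: int | None
    strand: str
    body: str | None
    family_id: str | None
    isotype: str | None
    anticodon: str | None
    score: float | None
    mature: str | None
    active: bool


@dataclass
class PlantedConversion:
    copy_id: str
    from_family: str
    to_family: str
    genomes: tuple[str, ...]


@dataclass
class PanelTruth:
    families: dict[str, FamilyTruth]
    copy_family: dict[str, str]  # copy_id -> ancestral family
    copy_strand: dict[str, str]
    per_genome: dict[str, dict[str, LocusTruth]]
    copy_matrix: pd.DataFrame
    ortholog_pairs: set[tuple[tuple[str, str], tuple[str, str]]]
    conversions: list[PlantedConversion]
    oneway_edges: list[tuple[tuple[str, str], tuple[str, str]]]
    trap_edges: list[tuple[tuple[str, str], tuple[str, str]]]
    substring_pairs: list[tuple[str, str]]
    locus_index: dict[tuple[str, str], str]  # (genome, locus_id) -> copy_id

    def annotated(self, genome: str) -> dict[str, LocusTruth]:
        return {
            c: lt
            for c, lt in self.per_genome[genome].items()
            if lt.status == "present"
        }


@dataclass
class SimulatedPanel:
    config: PanelConfig
    genomes: list[str]
    reference: str
    outgroup: str
    fastas: dict[str, dict[str, str]]
    trnascan_tables: dict[str, str]
    beds: dict[str, str]
    liftover_records: list[LiftoverRecord]
    chip_counts: list[dict[str, tuple[int, int]]]
    truth: PanelTruth

    def write(self, outdir: str | Path) -> Path:
        """Emit all files plus a manifest.json; returns the manifest path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest: dict = {
            "reference": self.reference,
            "outgroup": self.outgroup,
            "seed": self.config.seed,
            "genomes": {},
            "liftover": "liftover.tsv",
            "chip_counts": [],
            "config": _config_dict(self.config),
        }
        for g in self.genomes:
            files = {
                "fasta": f"{g}.fa",
                "trnascan": f"{g}.trnascan.tsv",
                "bed": f"{g}.bed",
            }
            write_fasta(self.fastas[g], outdir / files["fasta"])
            (outdir / files["trnascan"]).write_text(self.trnascan_tables[g])
            (outdir / files["bed"]).write_text(self.beds[g])
            manifest["genomes"][g] = files
        (outdir / "liftover.tsv").write_text(
            write_liftover_map(self.liftover_records)
        )
        for i, counts in enumerate(self.chip_counts, start=1):
            name = f"chip_rep{i}.tsv"
            (outdir / name).write_text(write_count_table(counts))
            manifest["chip_counts"].append(name)
        path = outdir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
        return path


def _config_dict(config: PanelConfig) -> dict:
    d = dataclasses.asdict(config)
    d["copy_number_probs"] = [list(p) for p in config.copy_number_probs]
    return d


# ---------------------------------------------------------------------------
# Strain tree
# ---------------------------------------------------------------------------


def build_tree(config: PanelConfig):
    """Fixed (name, branch_length, children) topology: outgroup vs a mouse
    ancestor that splits into one divergent strain and two clades of close
    laboratory strains. Branch lengths are in arbitrary rate units."""
    strains = config.strain_names()
    close = [s for s in strains if s != "divergent"]
    half = (len(close) + 1) // 2
    clades = []
    for name, members in (("cladeA", close[:half]), ("cladeB", close[half:])):
        if members:
            clades.append((name, 0.3, [(m, 0.2, []) for m in members]))
    lab = ("lab_anc", 0.5, clades)
    mouse_children = []
    if "divergent" in strains:
        mouse_children.append(("divergent", 3.0, []))
    mouse_children.append(lab)
    mouse = ("mouse_anc", 1.0, mouse_children)
    return ("root", 0.0, [(config.outgroup, 6.0, []), mouse])


def _leaves(node) -> list[str]:
    name, _, children = node
    if not children:
        return [name]
    out: list[str] = []
    for c in children:
        out.extend(_leaves(c))
    return out


# ---------------------------------------------------------------------------
# Family / copy creation
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _mutate(rng: np.random.Generator, body: str) -> str:
    pos = int(rng.integers(0, len(body)))
    alternatives = [b for b in _BASES if b != body[pos]]
    new = alternatives[int(rng.integers(0, 3))]
    return body[:pos] + new + body[pos + 1 :]


@dataclass
class _Template:
    """Annotation-bearing sequence template a copy currently carries."""

    family_id: str
    intron: tuple[int, int] | None
    isotype: str
    anticodon_offset: int
    score: float
    trna_like: bool
    active: bool


@dataclass
class _CopyState:
    present: bool
    pseudo: bool
    body: str
    template: _Template


def _make_families(config: PanelConfig, rng: np.random.Generator):
    families: dict[str, FamilyTruth] = {}
    ancestral_templates: dict[str, tuple[str, _Template]] = {}
    substring_pairs: list[tuple[str, str]] = []

    values = [v for v, _ in config.copy_number_probs]
    probs = np.array([p for _, p in config.copy_number_probs], dtype=float)
    probs = probs / probs.sum()

    def new_family(fid: str, body: str, n_copies: int, force_plain: bool = False):
        trna_like = (not force_plain) and rng.random() < config.fraction_trna_like
        if force_plain:
            isotype = _ISOTYPES[int(rng.integers(0, len(_ISOTYPES)))]
        else:
            isotype = (
                "His"
                if rng.random() < config.his_fraction
                else _ISOTYPES[int(rng.integers(0, len(_ISOTYPES)))]
            )
        ac_off = 33 if len(body) >= 36 else max(0, (len(body) - 3) // 2)
        intron = None
        if not force_plain and rng.random() < config.intron_fraction and len(body) >= 45:
            ilen = int(rng.integers(12, 21))
            ip = 38
            intron_seq = _random_seq(rng, ilen)
            body = body[:ip] + intron_seq + body[ip:]
            intron = (ip, ip + ilen)
        score = (
            round(float(rng.uniform(10, 45)), 1)
            if trna_like
            else round(float(rng.uniform(55, 90)), 1)
        )
        active = rng.random() < (
            config.trna_like_active_fraction if trna_like else config.active_fraction
        )
        families[fid] = FamilyTruth(
            family_id=fid,
            body=body,
            intron=intron,
            isotype=isotype,
            anticodon_offset=ac_off,
            score=score,
            trna_like=trna_like,
            active=active,
            n_copies=n_copies,
        )
        ancestral_templates[fid] = (
            body,
            _Template(fid, intron, isotype, ac_off, score, trna_like, active),
        )

    idx = 0
    for _ in range(config.substring_family_pairs):
        short = _random_seq(rng, int(rng.integers(70, 80)))
        prefix = _random_seq(rng, int(rng.integers(8, 16)))
        fid_a, fid_b = f"fam{idx:03d}", f"fam{idx + 1:03d}"
        new_family(fid_a, short, 3, force_plain=True)
        new_family(fid_b, prefix + short, 3, force_plain=True)
        substring_pairs.append((fid_a, fid_b))
        idx += 2
    while idx < config.n_families:
        body = _random_seq(rng, int(rng.integers(70, 91)))
        if any(body == f.body for f in families.values()):
            continue
        n_copies = int(values[int(rng.choice(len(values), p=probs))])
        new_family(f"fam{idx:03d}", body, n_copies)
        idx += 1

    copies: list[str] = []
    copy_family: dict[str, str] = {}
    copy_strand: dict[str, str] = {}
    flanks: dict[str, tuple[str, str, str]] = {}  # spacer, left, right
    for fid in sorted(families):
        fam = families[fid]
        for k in range(fam.n_copies):
            cid = f"{fid}.c{k}"
            copies.append(cid)
            copy_family[cid] = fid
            copy_strand[cid] = "+" if rng.random() < 0.5 else "-"
            flanks[cid] = (
                _random_seq(rng, config.spacer_len),
                _random_seq(rng, config.flank_len),
                _random_seq(rng, config.flank_len),
            )
    return families, ancestral_templates, substring_pairs, copies, copy_family, copy_strand, flanks


# ---------------------------------------------------------------------------
# Evolution down the tree
# ---------------------------------------------------------------------------


def _evolve(
    config: PanelConfig,
    rng: np.random.Generator,
    tree,
    copies: Sequence[str],
    ancestral_templates: Mapping[str, tuple[str, _Template]],
    copy_family: Mapping[str, str],
) -> tuple[dict[str, dict[str, _CopyState]], list[PlantedConversion]]:
    fam_ids = sorted(ancestral_templates)
    root_state = {
        cid: _CopyState(
            present=True,
            pseudo=False,
            body=ancestral_templates[copy_family[cid]][0],
            template=ancestral_templates[copy_family[cid]][1],
        )
        for cid in copies
    }
    leaf_states: dict[str, dict[str, _CopyState]] = {}
    conversions: list[PlantedConversion] = []

    def walk(node, state: dict[str, _CopyState]):
        name, _, children = node
        if not children:
            leaf_states[name] = state
            return
        for child in children:
            cname, length, _ = child
            child_state = {
                cid: _CopyState(s.present, s.pseudo, s.body, s.template)
                for cid, s in state.items()
            }
            for cid in copies:
                s = child_state[cid]
                if not s.present:
                    continue
                if cname == config.force_delete_strain:
                    s.present = False
                    continue
                if rng.random() < min(1.0, config.deletion_rate * length):
                    s.present = False
                    continue
                if (not s.pseudo) and rng.random() < min(
                    1.0, config.pseudogenization_rate * length
                ):
                    s.pseudo = True
                if rng.random() < min(1.0, config.conversion_rate * length):
                    donors = [f for f in fam_ids if f != s.template.family_id]
                    if donors:
                        donor = donors[int(rng.integers(0, len(donors)))]
                        body, tmpl = ancestral_templates[donor]
                        old = s.template.family_id
                        s.body, s.template = body, tmpl
                        conversions.append(
                            PlantedConversion(
                                copy_id=cid,
                                from_family=old,
                                to_family=donor,
                                genomes=tuple(_leaves(child)),
                            )
                        )
                n_sub = int(rng.poisson(config.substitution_rate * length))
                for _ in range(n_sub):
                    s.body = _mutate(rng, s.body)
            walk(child, child_state)

    walk(tree, root_state)
    return leaf_states, conversions


def _force_conversions(
    config: PanelConfig,
    rng: np.random.Generator,
    leaf_states: dict[str, dict[str, _CopyState]],
    families: Mapping[str, FamilyTruth],
    ancestral_templates: Mapping[str, tuple[str, _Template]],
    substring_pairs: Sequence[tuple[str, str]],
) -> list[PlantedConversion]:
    """Deterministically plant guaranteed-detectable conversion events on
    single leaves (sources with >=3 copies so both families stay multicopy),
    plus one event per planted substring family pair."""
    strains = [g for g in leaf_states if g != config.outgroup]
    planted: list[PlantedConversion] = []

    def apply(cid: str, donor: str, leaf: str) -> bool:
        state = leaf_states[leaf].get(cid)
        if state is None or not state.present or state.pseudo:
            return False
        old = state.template.family_id
        if old == donor:
            return False
        body, tmpl = ancestral_templates[donor]
        state.body, state.template = body, tmpl
        planted.append(
            PlantedConversion(
                copy_id=cid, from_family=old, to_family=donor, genomes=(leaf,)
            )
        )
        return True

    for fid_a, fid_b in substring_pairs:
        leaf = strains[int(rng.integers(0, len(strains)))]
        apply(f"{fid_a}.c0", fid_b, leaf)

    eligible_src = sorted(
        f for f, fam in families.items() if fam.n_copies >= 3
    )
    eligible_dst = sorted(
        f for f, fam in families.items() if fam.n_copies >= 2
    )
    n_done = 0
    attempts = 0
    while n_done < config.n_forced_conversions and attempts < 50 * max(
        1, config.n_forced_conversions
    ):
        attempts += 1
        if not eligible_src or len(eligible_dst) < 2:
            break
        src = eligible_src[int(rng.integers(0, len(eligible_src)))]
        donor = eligible_dst[int(rng.integers(0, len(eligible_dst)))]
        if donor == src:
            continue
        leaf = strains[int(rng.integers(0, len(strains)))]
        cid = f"{src}.c{int(rng.integers(0, families[src].n_copies))}"
        if apply(cid, donor, leaf):
            n_done += 1
    return planted


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------


def _mature_of(body: str, tmpl: _Template) -> str:
    if tmpl.intron is not None:
        s, e = tmpl.intron
        seq = body[:s] + body[e:]
    else:
        seq = body
    seq = seq + "CCA"
    if tmpl.isotype == "His":
        seq = "G" + seq
    return seq


def _anticodon_of(body: str, tmpl: _Template) -> str:
    if tmpl.intron is not None:
        s, e = tmpl.intron
        seq = body[:s] + body[e:]
    else:
        seq = body
    off = tmpl.anticodon_offset
    if off + 3 > len(seq):
        return "NNN"
    return seq[off : off + 3]


def _build_genome(
    config: PanelConfig,
    genome: str,
    copies: Sequence[str],
    states: Mapping[str, _CopyState],
    copy_strand: Mapping[str, str],
    flanks: Mapping[str, tuple[str, str, str]],
    tail: str,
) -> tuple[dict[str, str], list[TRNALocus], dict[str, LocusTruth]]:
    chrom = "chr1"
    parts: list[str] = []
    offset = 0
    loci: list[TRNALocus] = []
    truth: dict[str, LocusTruth] = {}
    n_annotated = 0
    for cid in copies:
        s = states[cid]
        strand = copy_strand[cid]
        if not s.present:
            truth[cid] = LocusTruth(
                copy_id=cid, status="absent", locus_id=None, chrom=None,
                start=None, end=None, strand=strand, body=None, family_id=None,
                isotype=None, anticodon=None, score=None, mature=None,
                active=False,
            )
            continue
        spacer, left, right = flanks[cid]
        oriented = s.body if strand == "+" else reverse_complement(s.body)
        start = offset + len(spacer) + len(left)
        end = start + len(oriented)
        parts.extend([spacer, left, oriented, right])
        offset = end + len(right)
        tmpl = s.template
        if s.pseudo:
            truth[cid] = LocusTruth(
                copy_id=cid, status="pseudo", locus_id=None, chrom=chrom,
                start=start, end=end, strand=strand, body=s.body,
                family_id=tmpl.family_id, isotype=tmpl.isotype,
                anticodon=None, score=None, mature=None, active=False,
            )
            continue
        n_annotated += 1
        locus_id = f"{chrom}.trna{n_annotated}"
        anticodon = _anticodon_of(s.body, tmpl)
        introns = (tmpl.intron,) if tmpl.intron is not None else ()
        locus = TRNALocus(
            locus_id=locus_id,
            genome=genome,
            chrom=chrom,
            start=start,
            end=end,
            strand=strand,
            isotype=tmpl.isotype,
            anticodon=anticodon,
            score=tmpl.score,
            introns=introns,
        )
        loci.append(locus)
        truth[cid] = LocusTruth(
            copy_id=cid, status="present", locus_id=locus_id, chrom=chrom,
            start=start, end=end, strand=strand, body=s.body,
            family_id=tmpl.family_id, isotype=tmpl.isotype,
            anticodon=anticodon, score=tmpl.score,
            mature=_mature_of(s.body, tmpl), active=tmpl.active,
        )
    parts.append(tail)
    chrom_seq = "".join(parts)
    if len(chrom_seq) > config.max_chrom_len:
        raise ValueError(
            f"panel does not fit: chromosome length {len(chrom_seq)} exceeds "
            f"max_chrom_len={config.max_chrom_len}"
        )
    return {chrom: chrom_seq}, loci, truth


def _liftover(
    config: PanelConfig,
    rng: np.random.Generator,
    genomes: Sequence[str],
    copies: Sequence[str],
    per_genome: Mapping[str, dict[str, LocusTruth]],
) -> list[LiftoverRecord]:
    flank = 20
    records: list[LiftoverRecord] = []
    for a in genomes:
        for b in genomes:
            if a == b:
                continue
            for cid in copies:
                la = per_genome[a][cid]
                lb = per_genome[b][cid]
                if la.status != "present":  # sources must be annotated
                    continue
                if lb.status == "absent":  # nothing to project onto
                    continue
                ss, se = la.start - flank, la.end + flank
                ds, de = lb.start - flank, lb.end + flank
                L = min(se - ss, de - ds)
                if (
                    rng.random() < config.fragmentation_rate
                    and L > 70
                ):
                    m = int(rng.integers(30, L - 30))
                    g = int(rng.integers(1, 11))
                    if m + g < L - 10:
                        records.append(
                            LiftoverRecord(a, la.chrom, ss, ss + m, b, lb.chrom, ds, ds + m, lb.strand)
                        )
                        records.append(
                            LiftoverRecord(a, la.chrom, ss + m + g, se, b, lb.chrom, ds + m + g, de, lb.strand)
                        )
                        continue
                records.append(
                    LiftoverRecord(a, la.chrom, ss, se, b, lb.chrom, ds, de, lb.strand)
                )
    return records


def _plant_noise(
    config: PanelConfig,
    rng: np.random.Generator,
    genomes: Sequence[str],
    copies: Sequence[str],
    copy_family: Mapping[str, str],
    families: Mapping[str, FamilyTruth],
    per_genome: Mapping[str, dict[str, LocusTruth]],
    records: list[LiftoverRecord],
):
    """Append planted one-way and paralog-trap liftover records.

    Copies are chosen so they are annotated in both genomes of the pair —
    the noise then cannot perturb missing/pseudo classification, only the
    graph structure the safeguards are meant to clean up.
    """
    flank = 20
    oneway: list[tuple[tuple[str, str], tuple[str, str]]] = []
    traps: list[tuple[tuple[str, str], tuple[str, str]]] = []

    def annotated_in_both(a: str, b: str) -> list[str]:
        return [
            cid
            for cid in copies
            if per_genome[a][cid].status == "present"
            and per_genome[b][cid].status == "present"
        ]

    for i, a in enumerate(genomes):
        for b in genomes[i + 1 :]:
            both = annotated_in_both(a, b)
            if rng.random() < config.oneway_noise_rate and len(both) >= 2:
                k1 = int(rng.integers(0, len(both)))
                k2 = int(rng.integers(0, len(both) - 1))
                if k2 >= k1:
                    k2 += 1
                ca, cb = both[k1], both[k2]
                la, lb = per_genome[a][ca], per_genome[b][cb]
                records.append(
                    LiftoverRecord(
                        a, la.chrom, la.start - flank, la.end + flank,
                        b, lb.chrom, lb.start - flank, lb.end + flank, lb.strand,
                    )
                )
                oneway.append(((a, la.locus_id), (b, lb.locus_id)))
            if rng.random() < config.paralog_trap_rate:
                multi = sorted(
                    {
                        copy_family[cid]
                        for cid in both
                        if families[copy_family[cid]].n_copies >= 2
                    }
                )
                pair = None
                for fid in multi:
                    sibs = [c for c in both if copy_family[c] == fid]
                    if len(sibs) >= 2:
                        pair = (sibs[0], sibs[1])
                        break
                if pair is None:
                    continue
                ci, cj = pair
                la, lb = per_genome[a][ci], per_genome[b][cj]
                records.append(
                    LiftoverRecord(
                        a, la.chrom, la.start - flank, la.end + flank,
                        b, lb.chrom, lb.start - flank, lb.end + flank, lb.strand,
                    )
                )
                records.append(
                    LiftoverRecord(
                        b, lb.chrom, lb.start - flank, lb.end + flank,
                        a, la.chrom, la.start - flank, la.end + flank, la.strand,
                    )
                )
                traps.append(((a, la.locus_id), (b, lb.locus_id)))
    return oneway, traps


def _negbin(
    rng: np.random.Generator, mean: float, dispersion: float, size: int
) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size, dtype=int)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_chip_counts(
    truth: PanelTruth,
    config: PanelConfig,
    rng: np.random.Generator,
    genome: str | None = None,
) -> dict[str, tuple[int, int]]:
    """Negative-binomial treatment/control counts for one pulldown replicate
    over the annotated loci of ``genome`` (default: the reference)."""
    genome = genome or config.reference
    ann = truth.annotated(genome)
    cids = sorted(ann)
    n = len(cids)
    active = np.array([ann[c].active for c in cids])
    control = _negbin(rng, config.chip_mean_silent, config.chip_dispersion, n)
    t_active = _negbin(rng, config.chip_mean_active, config.chip_dispersion, n)
    t_silent = _negbin(rng, config.chip_mean_silent, config.chip_dispersion, n)
    treatment = np.where(active, t_active, t_silent)
    return {
        ann[c].locus_id: (int(t), int(ctrl))
        for c, t, ctrl in zip(cids, treatment, control)
    }


def simulate_panel(config: PanelConfig | None = None, seed: int | None = None) -> SimulatedPanel:
    """Generate a complete seeded panel: genomes, annotations, liftover maps,
    ChIP counts, and the ground truth needed to score the pipeline."""
    config = config or PanelConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    genomes = config.genome_names()

    (
        families,
        ancestral_templates,
        substring_fids,
        copies,
        copy_family,
        copy_strand,
        flanks,
    ) = _make_families(config, rng)

    est = sum(
        config.spacer_len + 2 * config.flank_len + len(families[copy_family[c]].body)
        for c in copies
    ) + config.spacer_len
    if est > config.max_chrom_len:
        raise ValueError(
            f"panel does not fit: estimated chromosome length {est} exceeds "
            f"max_chrom_len={config.max_chrom_len}"
        )

    tree = build_tree(config)
    leaf_states, conversions = _evolve(
        config, rng, tree, copies, ancestral_templates, copy_family
    )
    conversions += _force_conversions(
        config, rng, leaf_states, families, ancestral_templates, substring_fids
    )

    tail = _random_seq(rng, config.spacer_len)
    fastas: dict[str, dict[str, str]] = {}
    tables: dict[str, str] = {}
    beds: dict[str, str] = {}
    per_genome: dict[str, dict[str, LocusTruth]] = {}
    for g in genomes:
        fasta, loci, truth_g = _build_genome(
            config, g, copies, leaf_states[g], copy_strand, flanks, tail
        )
        fastas[g] = fasta
        tables[g] = write_trnascan_table(loci)
        beds[g] = write_bed6(loci)
        per_genome[g] = truth_g

    records = _liftover(config, rng, genomes, copies, per_genome)
    oneway, traps = _plant_noise(
        config, rng, genomes, copies, copy_family, families, per_genome, records
    )

    # truth summaries
    seq_counts = {
        g: Counter(
            lt.mature for lt in per_genome[g].values() if lt.status == "present"
        )
        for g in genomes
    }
    all_seqs = sorted({s for c in seq_counts.values() for s in c})
    copy_matrix = pd.DataFrame(
        {g: [seq_counts[g].get(s, 0) for s in all_seqs] for g in genomes},
        index=all_seqs,
        dtype=int,
    )
    pairs: set[tuple[tuple[str, str], tuple[str, str]]] = set()
    locus_index: dict[tuple[str, str], str] = {}
    for cid in copies:
        present = [
            (g, per_genome[g][cid].locus_id)
            for g in genomes
            if per_genome[g][cid].status == "present"
        ]
        for g, lid in present:
            locus_index[(g, lid)] = cid
        for i, na in enumerate(present):
            for nb in present[i + 1 :]:
                pairs.add(tuple(sorted((na, nb))))  # type: ignore[arg-type]

    substring_pairs = []
    for fid_a, fid_b in substring_fids:
        _, ta = ancestral_templates[fid_a]
        _, tb = ancestral_templates[fid_b]
        substring_pairs.append(
            (
                _mature_of(ancestral_templates[fid_a][0], ta),
                _mature_of(ancestral_templates[fid_b][0], tb),
            )
        )

    truth = PanelTruth(
        families=families,
        copy_family=copy_family,
        copy_strand=copy_strand,
        per_genome=per_genome,
        copy_matrix=copy_matrix,
        ortholog_pairs=pairs,
        conversions=conversions,
        oneway_edges=oneway,
        trap_edges=traps,
        substring_pairs=substring_pairs,
        locus_index=locus_index,
    )

    chip = [
        simulate_chip_counts(truth, config, rng)
        for _ in range(config.n_chip_replicates)
    ]

    return SimulatedPanel(
        config=config,
        genomes=genomes,
        reference=config.reference,
        outgroup=config.outgroup,
        fastas=fastas,
        trnascan_tables=tables,
        beds=beds,
        liftover_records=records,
        chip_counts=chip,
        truth=truth,
    )


def expected_conversion_events(
    truth: PanelTruth, strains: Sequence[str], min_copies: int = 2
) -> set[tuple[str, str, str]]:
    """Conversion events derivable from the ground truth alone.

    Returns (genome_a, genome_b, copy_id) triples (a < b) for every copy
    annotated in both genomes with differing mature sequences where both
    sequences are multicopy in both genomes and neither is a substring of
    the other — the detection rule applied to the generator's own state,
    independent of the pipeline.
    """
    out: set[tuple[str, str, str]] = set()
    ordered = sorted(strains)
    for cid in truth.copy_family:
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                la = truth.per_genome[a].get(cid)
                lb = truth.per_genome[b].get(cid)
                if (
                    la is None
                    or lb is None
                    or la.status != "present"
                    or lb.status != "present"
                ):
                    continue
                sa, sb = la.mature, lb.mature
                if sa == sb:
                    continue
                if sa in sb or sb in sa:
                    continue
                ca = truth.copy_matrix[a]
                cb = truth.copy_matrix[b]
                if (
                    ca.get(sa, 0) >= min_copies
                    and cb.get(sa, 0) >= min_copies
                    and ca.get(sb, 0) >= min_copies
                    and cb.get(sb, 0) >= min_copies
                ):
                    out.add((a, b, cid))
    return out
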