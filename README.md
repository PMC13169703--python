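# trnapanel

Comparative analysis of tRNA genes and tRNA-like elements across a panel
of closely related genome assemblies (e.g. laboratory mouse strains plus a
rat-like outgroup).

tRNA genes are a large multigene family whose members often exist as many
*identical* dispersed copies, so orthology cannot be inferred from sequence
similarity the way it is for protein-coding genes. This package implements
a liftover-based comparative pipeline for such families:

* **Ortholog sets.** Coordinate projections of every annotated locus into
  every other genome (a 9-column liftover TSV standing in for
  whole-genome-alignment liftover output) are merged, required to be
  bidirectional, validated by a flank-anchored local alignment — the
  aligned length must reach half the shorter flanked sequence, so identical
  gene bodies sitting in unrelated flanking contexts cannot pass — and
  resolved into cliques with at most one locus per genome. Genomes without
  a member are classified *missing* (no projection at all) or *pseudo* (a
  projected region with no scanner-detected gene).
* **Copy number.** Loci are projected to mature transcript sequences
  (introns excised, 3' CCA appended, G-1 prepended for His), and exact
  sequence identity defines copy families; the cross-genome copy matrix
  yields copy-number ranges and single-copy conservation counts.
* **Pol III occupancy.** Per-locus ChIP read counts give the occupancy
  score `clamp(log2((t + 20)/(c + 20)), 0, 6)` over loci extended ±50 bp,
  and a 2×2 grid over (covariance score > 50) × (Pol III score ≥ 2)
  separates active tRNAs, silent high-scoring tRNAs, transcribed tRNA-like
  elements and inactive elements.
* **Variation.** Ortholog-set members are stacked into a star alignment;
  mismatch counts, distinct-variant counts, per-column maximum variation
  frequencies by occupancy class, and anticodon identity changes are
  computed on its columns.
* **Gene conversion.** An ortholog whose locus carries one multicopy
  sequence family in one genome and a *different* multicopy family in
  another (both families at ≥2 copies in both genomes, neither a substring
  of the other) is a conversion candidate; recurrence counts find sequence
  pairs converted many times independently.

A seeded synthetic strain-panel generator emulates all the inputs with
full ground truth (planted substitutions, deletions, pseudogenizations,
conversions, noise liftover records, negative-binomial ChIP counts), so
every stage is testable end to end without any genome downloads.

## Worked example

```python
from trnapanel import PanelConfig, PipelineConfig, simulate_panel, analyze
from trnapanel.stats_report import inputs_from_panel

panel = simulate_panel(PanelConfig(seed=1))          # 17 strains + outgroup
cfg = PipelineConfig()
res = analyze(inputs_from_panel(panel, cfg), cfg)
print(res.summary["n_loci"], res.summary["n_sets"],
      res.summary["n_missing"], res.summary["n_pseudo"],
      res.summary["n_conversion_events"],
      res.summary["replicate_concordance_r"])
```

prints

```
933 53 1 20 16 0.9333
```

i.e. 933 annotated loci across the 18 genomes resolve into 53 ortholog
sets; one absent ortholog is a true deletion ("missing") and 20 are
pseudogenized loci ("pseudo"); 16 multicopy-to-multicopy switches are
flagged as gene-conversion candidates; and the two simulated ChIP
replicates agree at Pearson r = 0.93. On this panel the recovered copy
matrix equals the generator's planted matrix cell for cell, and 100% of
the 7,888 planted ortholog pairs land in the same set.

The same run from the shell:

```bash
trnapanel simulate --seed 1 --outdir panel/
trnapanel run-all --input panel/ --outdir out/
trnapanel report --outdir out/
```

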