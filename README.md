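# mirna-cnv

Population-scale burden analysis of copy-number variants (CNVs) that
overlap microRNA genes.

CNVs — genomic segments larger than ~1 kb whose copy number deviates from
the diploid reference — frequently capture miRNA genes, changing the
dosage of post-transcriptional regulators and, through them, of whole
target pathways. Given per-individual CNV call tables from array-based
callers, a miRNA gene annotation (GFF3 or BED) and a pedigree-style
cohort manifest, this package computes the downstream population
analysis:

- **Annotation** — QC filtering (strictly >1 kb and >5 probes), optional
  validation against a reference CNV set at ≥50% reciprocal overlap, and
  intersection with miRNA genes (≥1 bp overlap; a call that hits at least
  one gene is a *miRNA-CNV*). Gene hits are tallied both with
  multiplicity and as distinct ("singleton") identifiers.
- **Burden** — per-population carrier counts and percentages,
  duplication/deletion splits over events and over gene hits, mean
  miRNA-CNVs and mean gene hits per carrier, copy-number state spectra
  over states {0,1,2,3,4} with fraction-weighted mean state, sex bias of
  gene hits, and chromosome-wise distributions.
- **Trio inheritance** — proband calls are classified *inherited* (a
  parental call matches both breakpoints), *unknown* (exactly one
  breakpoint precisely matches, the other extended), *de novo* (no
  parental overlap at all), or *ambiguous* (overlap without an endpoint
  match), with parental origin and per-population rates.
- **Hotspots** — recurrent regions detected as maximal cliques of the
  overlap graph (edges at ≥40% reciprocal overlap, Bron–Kerbosch with
  pivoting), 99%-overlap *families* of near-identical breakpoints inside
  each region, and hotspot / intermediate / unique event labels.
- **Frequencies** — breakpoint-identical miRNA-CNVs grouped across
  individuals, with per-population carrier frequencies
  `100 · carriers_p / miRNA-carriers_p` and a pooled global frequency —
  carrier frequencies, not diploid allele frequencies.
- **Simulation** — a seeded generator producing cohorts with planted
  hotspot loci, duplication/deletion mixtures and labelled trio events,
  so every stage is testable against ground truth without array data.

## Worked example

Classify trio inheritance on a simulated cohort
(`examples/03_trio_inheritance.py`):

```python
from mirna_cnv import simulate as sim, trio

cfg = sim.SimConfig(populations=[sim.PopulationSpec("YRI", 20, 10)],
                    n_trios_per_population=10, seed=3)
individuals, calls, _, truth = sim.generate_cohort(cfg)
results = trio.classify_cohort(calls, individuals, tol_bp=0)
rates = trio.inheritance_rates(results, individuals)
```

prints, via the example script:

```
planted proband events: 199; labels recovered: 199 (=100%)
YRI rates over 199 classified calls: inherited 14.6%, de novo 55.8%, unknown 29.6%
maternal share of inherited: 55.2%
```

Every planted label is recovered because the classes are defined by exact
breakpoint arithmetic; the rate percentages sum to 100 over the classes,
and the maternal share fluctuates binomially around the 50% planting
ratio. The other scripts in `examples/` walk through annotation and
burden summaries, hotspot cliques and the cross-population frequency
table; `mirna-cnv demo --seed 7 -o demo/` runs the whole pipeline on a
synthetic cohort and writes a truth-recovery report, and
`mirna-cnv run --config pipeline.yaml` runs it on real input files.

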