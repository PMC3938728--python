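# Methods

## Coordinate and size conventions

All intervals are 1-based and fully closed; the size of a call is
`end − start + 1`. Published breakpoint tables for this kind of array
data print 1-based positions, and the closed-interval size is the only
convention consistent with them. BED input/output (0-based half-open) is
converted at the boundary and the conversion is its own inverse.
Chromosome names are normalized by stripping a leading `chr` and
uppercasing X/Y, so mixed-source inputs collate.

## QC and annotation

The QC rule keeps a call iff size > 1000 bp **and** probe support > 5 —
both strict inequalities, matching the ">1 kb, >5 probes" defaults of
the array genotyping software this pipeline sits downstream of. Calls
with unknown probe count (stored as 0) fail the probe test unless
`require_probes=False` exempts them, because the QC rule presumes probe
counts exist.

A call is a miRNA-CNV when it overlaps an annotated miRNA gene by at
least 1 bp (configurable via `min_gene_overlap_bp`). No minimum overlap
fraction is imposed: partial-gene duplications and deletions alter
dosage just as whole-gene events do, so they count. Strand is ignored.

CNV type is assigned against sex-aware expected ploidy: 2 on autosomes;
on X, 1 for males and 2 for females; on Y, 1 for males and 0 for
females (unknown sex falls back to 2 on X and 1 on Y). A CN state above
expectation is a duplication, below is a deletion, at it is "none" —
this is what lets a CN=2 event on a male X count as a duplication.

"Singleton genes" are the distinct gene identifiers among all hits,
versus "gene hits" counted with multiplicity. The distinction matters
because recurrent regions (e.g. a 22q11-type locus) hit the same gene in
many individuals: totals ballooned by one locus, singletons not.

Reference validation uses reciprocal overlap — `min(shared/len_a,
shared/len_b)` — at a ≥0.5 threshold, with losses and gains matched
separately when the reference is typed. Reciprocal overlap is symmetric
and bounded by the shorter/longer length ratio; both properties are
tested.

## Burden summaries

Per-population summaries report **both** a mean miRNA-CNVs per carrier
and a mean gene hits per carrier, explicitly labelled, because summary
tables in this literature conflate the two. Duplication/deletion
percentages are likewise computed both over event counts and over gene
occurrences — the two diverge whenever gene density differs between
duplicated and deleted regions — and both are emitted. Percentages use
the convention `100·part/whole` with NaN (reported NA) on empty
denominators, never 0. CN-state spectra are fractions over miRNA-CNVs;
the mean state is the fraction-weighted mean, in [0, 4]. Sex-bias
percentages exclude unknown-sex individuals from the denominator and
count their hits in a separate column; populations sampled from a single
sex are flagged rather than silently reported as 100/0.

## Trio classification

Classes are evaluated per proband call in strict priority order:
inherited (some same-chromosome parental call matches both endpoints
within `tol_bp`), then unknown (some parental call matches exactly one
endpoint), then de novo (no parental call shares ≥1 bp), else ambiguous
(overlap without endpoint match). The priority order prevents double
classification when different parental calls match differently. The
ambiguous class exists because the three traditional clusters do not
cover overlap-without-endpoint-match; `collapse_ambiguous` folds it into
either neighbour to reproduce three-cluster conventions. `tol_bp`
defaults to 0 ("precisely inherited"); a tolerance accommodates noisy
callers. De novo scope is parental calls only, not the whole cohort.
Classification is invariant to parental list order: candidates are
ranked on sorted coordinates.

## Hotspot detection

Two events are connected when their reciprocal overlap is ≥ the merge
fraction (default 0.40). Reciprocal is the conservative reading of a
"shared base-pair overlap" criterion and matches the 50% validation
convention used elsewhere in the pipeline; a `single` mode (larger of
the two one-sided fractions) is available for comparison. A merged
region is a maximal clique of size ≥2 — with fractional-overlap edges
the graph is not guaranteed to be an interval graph, so a general
algorithm (Bron–Kerbosch with pivoting, via networkx) is used, anchored
in tests by an exhaustive bitmask subset-enumeration oracle on graphs of
≤15 nodes. A call may belong to several maximal cliques; all are
reported. For the partition-based event labels each call is assigned to
its largest containing region (ties to the earlier region id): unique if
none, hotspot if that region spans ≥ `min_events` distinct individuals
(default 5 — a config choice, as no published cutoff exists),
intermediate otherwise. Families are maximal cliques within a region at
the family fraction (default 0.99, near-identical breakpoints); the
family threshold must dominate the merge threshold. Raising the merge
fraction can only shrink regions (edge set shrinks), which is tested as
a monotonicity property.

## Frequency tables

Breakpoint groups at `tol_bp=0` are exact-equality classes of (chrom,
start, end); with a positive tolerance grouping is single-linkage and
order-independent (inputs are canonically sorted first). An individual
counts at most once per group. The per-population denominator is the
number of individuals in that population carrying ≥1 miRNA-CNV — not
the number assessed: reconstructing published frequency cells
(e.g. 1/25 = 4%, 1/14 = 7.14%, 2/31 = 6.45%) identifies the carrier
count as the denominator in every verifiable cell. The global frequency
pools reconstructed carriers over the summed per-population
denominators; by construction it equals the carrier-weighted pooling of
per-population frequencies, which is asserted as an identity in tests.
Zero-denominator populations report NA, never 0. Reported frequencies
are rounded to 2 decimals; unrounded values stay on the objects.

## Synthetic cohort generator

The generator emulates the structure of a multi-population array-CNV
cohort, not probe-level intensities or caller noise. Defaults are the
study conditions the pipeline targets:

- `dup_fraction = 0.876` — duplications' share of miRNA-CNVs;
- CN state conditional on type: deletions from {0: 0.6, 1: 0.4},
  duplications from {3: 0.94, 4: 0.06}, consistent with CN=3 dominating
  duplications (≈58–80%) and CN=4 staying rare (≈3–5%); CN=2 events are
  only produced on male X when `sex_chrom_events` is enabled;
- sizes: duplications 10–400 kb, deletions 10–700 kb — deletions carry
  the size burden even though duplications dominate counts;
- `background_rate = 2.3` events/individual (≈4007 miRNA-CNVs over 1715
  individuals), with `frac_mirna_targeted = 0.85` of background events
  positioned over a random miRNA gene (the remainder land uniformly and
  are mostly non-miRNA calls);
- trio planting rates 2.9 / 11.1 / 5.0 inherited / de novo / unknown
  events per proband — the published trio-cluster counts (175/668/298)
  over the ~60 trio probands they came from;
- default genome: chromosomes 3, 5, 15, 16, 22 at approximately real
  lengths — the chromosomes where the recurrent miRNA loci of interest
  live, plus one quiet autosome; one hotspot locus at a 22q11-like
  position carried by 30% of each population.

One miRNA gene is always placed inside each hotspot locus, so hotspot
calls are miRNA-CNVs by construction; hotspot carrier counts are exact
(`round(fraction × population size)`), not sampled. Planted trio events
are guaranteed to satisfy their class definitions by rejection sampling
(a de novo event is re-drawn until disjoint from every parental call;
an unknown event until it matches exactly one parental endpoint), so a
correct classifier must recover 100% of labels — recovery failures
indicate classifier bugs, not generator noise. Probands carry only
planted events, making the truth table exhaustive for them. All
randomness flows through one `numpy` generator seeded from the config,
so identical configurations regenerate identical cohorts.

What passing on synthetic data does *not* show: robustness to caller
breakpoint jitter (planted breakpoints are exact), probe-level
artefacts, population stratification of background events, or linkage
between neighbouring loci — real cohorts have all of these.

## Numerical and reporting choices

Annotated output is sorted by (chrom, start, end, individual id);
regions, groups and tables have deterministic orderings; TSV output is
byte-identical across reruns, and the pipeline writes a run manifest
(input SHA-256, version, seed, config) sufficient to reproduce any
output. Problem sizes in the test-suite simulations (hundreds of
individuals, thousands of events, 60-trio cohorts, 200 random clique
instances of ≤15 nodes) were chosen so that every invariant is exercised
at scales where binomial error bands are tight while the whole suite
runs in seconds.
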