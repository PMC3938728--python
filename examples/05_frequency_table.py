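"""Cross-population carrier frequencies of recurrent breakpoints.

Breakpoint-identical miRNA-CNVs are grouped across individuals; each
group's frequency in a population is carriers divided by that
population's miRNA-CNV carrier count, and the global frequency pools
carriers over the summed denominators. This is a carrier frequency, not
a diploid allele frequency.
"""

from mirna_cnv import annotate, frequency
from mirna_cnv import simulate as sim

cfg = sim.SimConfig(seed=11)  # four populations with a shared 22q hotspot
individuals, calls, genes, _ = sim.generate_cohort(cfg)
annotated = annotate.annotate_mirna(
    calls, genes, sex_of={i.individual_id: i.sex for i in individuals})

groups = frequency.group_breakpoints(annotated, individuals, tol_bp=0)
denoms = frequency.mirna_carrier_counts(annotated, individuals)
groups = frequency.compute_frequencies(groups, denoms)

print("miRNA-CNV carriers per population:", denoms)
top = groups[0]  # sorted by populations shared, then global frequency
print(f"\nmost shared breakpoint: chr{top.chrom}:{top.start}-{top.end} "
      f"({','.join(top.genes)})")
for pop, f in top.freq_by_population.items():
    print(f"  {pop:8s} {top.carriers_by_population.get(pop, 0):3d} carriers "
          f"-> {f:6.2f}%")
print(f"  global   {top.n_carriers:3d} carriers -> {top.global_freq:6.2f}%")
# The planted hotspot appears in every population at ~30% of carriers;
# private background breakpoints sit in the 1-population tier below it.
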