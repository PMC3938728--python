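"""Per-population burden statistics for miRNA-CNVs.

Computes the carrier counts, duplication/deletion splits (both over event
counts and over gene occurrences — the two diverge and both are reported),
per-carrier means, CN-state spectra, sex bias of gene hits, and
chromosome-wise distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .model import AnnotatedCall, Individual

CN_STATES = (0, 1, 2, 3, 4)


def pct(part: float, whole: float) -> float:
    """Percentage ``100*part/whole``; NaN when the denominator is zero."""
    return 100.0 * part / whole if whole else math.nan


def mean_per_carrier(total: float, n_carriers: int) -> float:
    """Mean count per carrying individual; NaN with no carriers.

    E.g. 6542 gene hits over 1438 carriers -> 4.5 genes per carrier.
    """
    return total / n_carriers if n_carriers else math.nan


@dataclass(frozen=True)
class PopulationSummary:
    population: str
    n_assessed: int
    n_carriers: int
    pct_carriers: float
    n_mirna_cnvs: int
    pct_dup: float
    pct_del: float
    gene_hits_dup_pct: float
    gene_hits_del_pct: float
    mean_cnvs_per_carrier: float
    mean_genes_per_carrier: float
    mean_size_dup: float
    mean_size_del: float
    n_gene_hits: int
    n_singleton_genes: int
    cn_state_fractions: Mapping[int, float]
    mean_cn_state: float
    pct_genes_male: float
    pct_genes_female: float


def _frames(
    annotated: Sequence[AnnotatedCall],
    individuals: Sequence[Individual],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten annotated calls into a call frame and a gene-hit frame."""
    pop = {i.individual_id: i.population for i in individuals}
    sex = {i.individual_id: i.sex for i in individuals}
    call_rows, hit_rows = [], []
    for ac in annotated:
        c = ac.call
        row = {
            "call_id": c.call_id,
            "individual_id": c.individual_id,
            "population": pop.get(c.individual_id, "unknown"),
            "sex": sex.get(c.individual_id, "unknown"),
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "size": c.size,
            "cn_state": c.cn_state,
            "cnv_type": ac.cnv_type,
            "is_mirna": ac.is_mirna_cnv,
            "n_genes": len(ac.genes),
        }
        call_rows.append(row)
        for g in ac.genes:
            hit_rows.append({**row, "gene_id": g})
    cols = ["call_id", "individual_id", "population", "sex", "chrom", "start",
            "end", "size", "cn_state", "cnv_type", "is_mirna", "n_genes"]
    calls_df = pd.DataFrame(call_rows, columns=cols)
    hits_df = pd.DataFrame(hit_rows, columns=cols + ["gene_id"])
    return calls_df, hits_df


def summarize_population(
    annotated: Sequence[AnnotatedCall],
    individuals: Sequence[Individual],
    population: str,
) -> PopulationSummary:
    """Burden summary for one population.

    ``mean_genes_per_carrier`` = total gene hits in the population divided
    by the number of individuals carrying at least one miRNA-CNV;
    percentages of duplication/deletion are over miRNA-CNV event counts,
    and separately over gene occurrences. Empty populations report zero
    counts and NaN means.
    """
    known = {i.population for i in individuals}
    if population not in known:
        raise KeyError(f"unknown population label {population!r}")
    calls_df, hits_df = _frames(annotated, individuals)
    n_assessed = sum(1 for i in individuals if i.population == population)
    mc = calls_df[(calls_df.population == population) & calls_df.is_mirna]
    mh = hits_df[hits_df.population == population]
    n_carriers = mc.individual_id.nunique()
    n_cnvs = len(mc)
    n_dup = int((mc.cnv_type == "duplication").sum())
    n_del = int((mc.cnv_type == "deletion").sum())
    hits_dup = int((mh.cnv_type == "duplication").sum())
    hits_del = int((mh.cnv_type == "deletion").sum())
    typed = n_dup + n_del
    typed_hits = hits_dup + hits_del
    frac = cn_state_fractions(mc.cn_state.tolist())
    sexed = mh[mh.sex.isin(["male", "female"])]
    n_sexed = len(sexed)
    return PopulationSummary(
        population=population,
        n_assessed=n_assessed,
        n_carriers=n_carriers,
        pct_carriers=pct(n_carriers, n_assessed),
        n_mirna_cnvs=n_cnvs,
        pct_dup=pct(n_dup, typed),
        pct_del=pct(n_del, typed),
        gene_hits_dup_pct=pct(hits_dup, typed_hits),
        gene_hits_del_pct=pct(hits_del, typed_hits),
        mean_cnvs_per_carrier=mean_per_carrier(n_cnvs, n_carriers),
        mean_genes_per_carrier=mean_per_carrier(len(mh), n_carriers),
        mean_size_dup=float(mc[mc.cnv_type == "duplication"]["size"].mean()),
        mean_size_del=float(mc[mc.cnv_type == "deletion"]["size"].mean()),
        n_gene_hits=len(mh),
        n_singleton_genes=mh.gene_id.nunique(),
        cn_state_fractions=frac,
        mean_cn_state=mean_cn_state(frac),
        pct_genes_male=pct(int((sexed.sex == "male").sum()), n_sexed),
        pct_genes_female=pct(int((sexed.sex == "female").sum()), n_sexed),
    )


def summarize_all(
    annotated: Sequence[AnnotatedCall],
    individuals: Sequence[Individual],
) -> pd.DataFrame:
    """One summary row per population, in sorted label order."""
    pops = sorted({i.population for i in individuals})
    rows = []
    for p in pops:
        s = summarize_population(annotated, individuals, p)
        row = {k: v for k, v in vars(s).items() if k != "cn_state_fractions"}
        for st in CN_STATES:
            row[f"cn{st}_pct"] = s.cn_state_fractions[st]
        rows.append(row)
    return pd.DataFrame(rows)


def cn_state_fractions(states: Sequence[int]) -> dict[int, float]:
    """Percentage of events at each CN state; NaN-free, sums to 100 if any."""
    n = len(states)
    return {s: pct(sum(1 for x in states if x == s), n) if n else 0.0 for s in CN_STATES}


def mean_cn_state(fractions: Mapping[int, float]) -> float:
    """Fraction-weighted mean CN state, in [0, 4]."""
    if all(math.isnan(v) for v in fractions.values()):
        return math.nan
    return sum(s * f for s, f in fractions.items() if not math.isnan(f)) / 100.0


def cn_state_spectrum(
    annotated: Sequence[AnnotatedCall],
    individuals: Sequence[Individual],
) -> pd.DataFrame:
    """Per-population CN-state fractions (%) and mean CN state."""
    calls_df, _ = _frames(annotated, individuals)
    mc = calls_df[calls_df.is_mirna]
    rows = []
    for p in sorted({i.population for i in individuals}):
        states = mc[mc.population == p].cn_state.tolist()
        frac = cn_state_fractions(states)
        rows.append({"population": p, "n_mirna_cnvs": len(states),
                     **{f"cn{s}_pct": frac[s] for s in CN_STATES},
                     "mean_cn_state": mean_cn_state(frac) if states else math.nan})
    return pd.DataFrame(rows)


def sex_bias(
    annotated: Sequence[AnnotatedCall],
    individuals: Sequence[Individual],
) -> pd.DataFrame:
    """Per-population % of miRNA gene hits carried by males vs females.

    Individuals of unknown sex are excluded from the percentages and
    reported in a separate count column. Populations with no samples of
    one sex are flagged (``single_sex_only``).
    """
    _, hits_df = _frames(annotated, individuals)
    sexes_present: dict[str, set[str]] = {}
    for i in individuals:
        sexes_present.setdefault(i.population, set()).add(i.sex)
    rows = []
    for p in sorted({i.population for i in individuals}):
        h = hits_df[hits_df.population == p]
        male = int((h.sex == "male").sum())
        female = int((h.sex == "female").sum())
        unknown = int((h.sex == "unknown").sum())
        known = male + female
        present = sexes_present.get(p, set()) & {"male", "female"}
        rows.append({
            "population": p,
            "gene_hits_male": male,
            "gene_hits_female": female,
            "gene_hits_unknown_sex": unknown,
            "pct_genes_male": pct(male, known),
            "pct_genes_female": pct(female, known),
            "single_sex_only": len(present) == 1,
        })
    return pd.DataFrame(rows)


def chromosome_distribution(
    annotated: Sequence[AnnotatedCall],
    individuals: Sequence[Individual],
) -> pd.DataFrame:
    """Per-population, per-chromosome shares of the miRNA-CNV burden.

    Four percentage columns — event counts, summed event size, gene hits,
    singleton (distinct) genes — each summing to 100 within a population.
    """
    calls_df, hits_df = _frames(annotated, individuals)
    mc = calls_df[calls_df.is_mirna]
    rows = []
    for p in sorted({i.population for i in individuals}):
        pc = mc[mc.population == p]
        ph = hits_df[hits_df.population == p]
        tot_n, tot_sz, tot_hits = len(pc), pc["size"].sum(), len(ph)
        tot_single = ph.gene_id.nunique()
        for chrom in sorted(set(pc.chrom) | set(ph.chrom)):
            cc = pc[pc.chrom == chrom]
            ch = ph[ph.chrom == chrom]
            rows.append({
                "population": p,
                "chrom": chrom,
                "n_mirna_cnvs": len(cc),
                "pct_count": pct(len(cc), tot_n),
                "pct_size": pct(cc["size"].sum(), tot_sz),
                "pct_gene_hits": pct(len(ch), tot_hits),
                "pct_singleton_genes": pct(ch.gene_id.nunique(), tot_single),
            })
    return pd.DataFrame(rows, columns=["population", "chrom", "n_mirna_cnvs",
                                       "pct_count", "pct_size", "pct_gene_hits",
                                       "pct_singleton_genes"])
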