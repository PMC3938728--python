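"""Recurrent-breakpoint grouping and carrier-frequency tables.

miRNA-CNVs with identical breakpoints (same chromosome, start and end;
optionally within a tolerance, merged by single linkage) are grouped
across individuals. Each group's frequency in a population is the share
of that population's miRNA-CNV *carriers* who carry the breakpoint — a
carrier frequency, not a diploid allele frequency — and the global
frequency pools carriers over the summed per-population denominators:

    freq_p  = 100 * carriers_p / n_mirna_carriers_p
    global  = 100 * sum_p carriers_p / sum_p n_mirna_carriers_p
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import pandas as pd

from .model import AnnotatedCall, ConfigError, Individual


@dataclass(frozen=True)
class RecurrentBreakpoint:
    """A breakpoint-identical miRNA-CNV group with per-population counts."""

    chrom: str
    start: int
    end: int
    genes: tuple[str, ...]
    carrier_ids: tuple[str, ...]
    carriers_by_population: Mapping[str, int]
    freq_by_population: Mapping[str, float] = field(default_factory=dict)
    global_freq: float = math.nan

    @property
    def n_populations(self) -> int:
        return sum(1 for n in self.carriers_by_population.values() if n > 0)

    @property
    def n_carriers(self) -> int:
        return len(self.carrier_ids)


class _DSU:
    def __init__(self, n: int):
        self.p = list(range(n))

    def find(self, i: int) -> int:
        while self.p[i] != i:
            self.p[i] = self.p[self.p[i]]
            i = self.p[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.p[max(ra, rb)] = min(ra, rb)


def group_breakpoints(
    annotated: Sequence[AnnotatedCall],
    individuals: Sequence[Individual],
    tol_bp: int = 0,
) -> list[RecurrentBreakpoint]:
    """Group miRNA-CNV calls sharing both breakpoints across individuals.

    With ``tol_bp=0`` grouping is exact equality of (chrom, start, end);
    with a positive tolerance, calls whose starts and ends each differ by
    at most ``tol_bp`` are merged by single linkage (order-independent).
    Each individual is counted at most once per group, however many
    duplicate rows it contributes. Groups are returned sorted by
    (chrom, start, end); frequencies are left for
    :func:`compute_frequencies`.
    """
    if tol_bp < 0:
        raise ConfigError("tol_bp must be >= 0")
    pop_of = {i.individual_id: i.population for i in individuals}
    mirna = sorted(
        (ac for ac in annotated if ac.is_mirna_cnv),
        key=lambda a: (a.call.chrom, a.call.start, a.call.end, a.call_id),
    )
    if not mirna:
        return []
    dsu = _DSU(len(mirna))
    by_chrom: dict[str, list[int]] = {}
    for i, ac in enumerate(mirna):
        by_chrom.setdefault(ac.call.chrom, []).append(i)
    for idxs in by_chrom.values():
        for pos, i in enumerate(idxs):
            a = mirna[i].call
            for j in idxs[pos + 1:]:
                b = mirna[j].call
                if b.start - a.start > tol_bp:
                    break
                if abs(a.end - b.end) <= tol_bp:
                    dsu.union(i, j)
    clusters: dict[int, list[int]] = {}
    for i in range(len(mirna)):
        clusters.setdefault(dsu.find(i), []).append(i)
    groups = []
    for root in sorted(clusters):
        members = [mirna[i] for i in clusters[root]]
        rep = members[0].call
        carriers = sorted({m.individual_id for m in members})
        by_pop: dict[str, int] = {}
        for ind in carriers:
            p = pop_of.get(ind, "unknown")
            by_pop[p] = by_pop.get(p, 0) + 1
        genes = tuple(sorted({g for m in members for g in m.genes}))
        groups.append(RecurrentBreakpoint(
            chrom=rep.chrom, start=rep.start, end=rep.end,
            genes=genes, carrier_ids=tuple(carriers),
            carriers_by_population=dict(sorted(by_pop.items())),
        ))
    groups.sort(key=lambda g: (g.chrom, g.start, g.end))
    return groups


def mirna_carrier_counts(
    annotated: Sequence[AnnotatedCall],
    individuals: Sequence[Individual],
) -> dict[str, int]:
    """Per-population number of individuals carrying >= 1 miRNA-CNV."""
    pop_of = {i.individual_id: i.population for i in individuals}
    carriers: dict[str, set[str]] = {i.population: set() for i in individuals}
    for ac in annotated:
        if ac.is_mirna_cnv:
            p = pop_of.get(ac.individual_id, "unknown")
            carriers.setdefault(p, set()).add(ac.individual_id)
    return {p: len(s) for p, s in sorted(carriers.items())}


def global_frequency(
    carriers_by_population: Mapping[str, int],
    denominators: Mapping[str, int],
) -> float:
    """Pooled carrier frequency (%) over the summed population denominators."""
    total_den = sum(denominators.values())
    total_car = sum(carriers_by_population.get(p, 0) for p in denominators)
    return 100.0 * total_car / total_den if total_den else math.nan


def compute_frequencies(
    groups: Sequence[RecurrentBreakpoint],
    denominators: Mapping[str, int],
) -> list[RecurrentBreakpoint]:
    """Fill per-population and global carrier frequencies into the groups.

    ``denominators`` maps population -> number of miRNA-CNV carriers (the
    frequency denominator). Populations with a zero denominator get NaN
    (reported NA), never 0. Groups are re-sorted by descending
    (n_populations, global_freq) for reporting.
    """
    out = []
    for g in groups:
        freqs = {}
        for p, den in denominators.items():
            car = g.carriers_by_population.get(p, 0)
            freqs[p] = 100.0 * car / den if den else math.nan
        out.append(replace(
            g,
            freq_by_population=freqs,
            global_freq=global_frequency(g.carriers_by_population, denominators),
        ))
    out.sort(key=lambda g: (-g.n_populations, -(g.global_freq if not math.isnan(g.global_freq) else -1),
                            g.chrom, g.start, g.end))
    return out


def frequency_table(
    groups: Sequence[RecurrentBreakpoint],
    populations: Optional[Sequence[str]] = None,
    decimals: int = 2,
) -> pd.DataFrame:
    """Wide table: one row per breakpoint group, one column per population.

    Frequencies are rounded to ``decimals`` for reporting (the unrounded
    values stay on the group objects); absent carriers show as 0 only if
    the population was assessed, NaN denominators as NA.
    """
    if populations is None:
        populations = sorted({p for g in groups for p in g.freq_by_population})
    rows = []
    for g in groups:
        row = {
            "chrom": g.chrom, "start": g.start, "end": g.end,
            "genes": ",".join(g.genes), "n_populations": g.n_populations,
            "n_carriers": g.n_carriers,
        }
        for p in populations:
            v = g.freq_by_population.get(p, math.nan)
            row[p] = round(v, decimals) if not math.isnan(v) else math.nan
        row["global_freq"] = round(g.global_freq, decimals) if not math.isnan(g.global_freq) else math.nan
        rows.append(row)
    cols = ["chrom", "start", "end", "genes", "n_populations", "n_carriers",
            *populations, "global_freq"]
    return pd.DataFrame(rows, columns=cols)


def shared_population_tiers(groups: Sequence[RecurrentBreakpoint]) -> pd.DataFrame:
    """Tiered report grouping breakpoints by how many populations share them.

    One row per group, ordered by descending tier (number of carrying
    populations) then global frequency — the layout of a cross-population
    recurrence table.
    """
    ordered = sorted(groups, key=lambda g: (-g.n_populations,
                                            -(g.global_freq if not math.isnan(g.global_freq) else -1),
                                            g.chrom, g.start, g.end))
    rows = [{
        "tier": f"{g.n_populations} population{'s' if g.n_populations != 1 else ''}",
        "n_populations": g.n_populations,
        "chrom": g.chrom, "start": g.start, "end": g.end,
        "genes": ",".join(g.genes),
        "n_carriers": g.n_carriers,
        "global_freq": round(g.global_freq, 2) if not math.isnan(g.global_freq) else math.nan,
    } for g in ordered]
    return pd.DataFrame(rows, columns=["tier", "n_populations", "chrom", "start",
                                       "end", "genes", "n_carriers", "global_freq"])
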