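"""Trio inheritance classification of proband CNV calls.

A proband call is compared against every parental call on the same
chromosome and assigned exactly one class, in priority order:

1. inherited — some parental call matches BOTH endpoints (within tol_bp);
2. unknown — some parental call matches exactly one endpoint, the other
   being extended or contracted (the study's "one breakpoint precisely
   inherited" cluster);
3. de_novo — no parental call shares even a single base;
4. ambiguous — a parental call overlaps but matches neither endpoint.

The fourth class covers a configuration the three-cluster scheme leaves
undefined; ``collapse_ambiguous`` folds it into "unknown" or "de_novo" to
reproduce either convention. Matching is exact (tol_bp=0) by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .model import CnvCall, ConfigError, Individual

CLASSES = ("inherited", "de_novo", "unknown", "ambiguous")


@dataclass(frozen=True, slots=True)
class InheritanceCall:
    proband_id: str
    proband_call_id: str
    label: str  # inherited | de_novo | unknown | ambiguous
    origin: str  # mother | father | both_possible | none
    matched_parent_call_id: Optional[str] = None
    matched_endpoints: str = "none"  # both | start_only | end_only | none


def _endpoint_match(a: CnvCall, b: CnvCall, tol: int) -> tuple[bool, bool]:
    return abs(a.start - b.start) <= tol, abs(a.end - b.end) <= tol


def classify_trio(
    proband: Sequence[CnvCall],
    father: Sequence[CnvCall],
    mother: Sequence[CnvCall],
    tol_bp: int = 0,
    collapse_ambiguous: Optional[str] = None,
) -> list[InheritanceCall]:
    """Classify every proband call against the two parental call sets.

    Results are independent of the order of the parental lists: candidate
    matches are ranked on sorted coordinates, not input position. With
    several both-endpoint matches from different parents the origin is
    ``both_possible``.
    """
    if tol_bp < 0:
        raise ConfigError("tol_bp must be >= 0")
    if collapse_ambiguous not in (None, "unknown", "de_novo"):
        raise ConfigError("collapse_ambiguous must be None, 'unknown' or 'de_novo'")
    parental = sorted(
        [(c, "father") for c in father] + [(c, "mother") for c in mother],
        key=lambda t: (t[0].chrom, t[0].start, t[0].end, t[1], t[0].call_id),
    )
    out = []
    for pc in proband:
        same_chrom = [(c, role) for c, role in parental if c.chrom == pc.chrom]
        both = [(c, role) for c, role in same_chrom
                if all(_endpoint_match(pc, c, tol_bp))]
        if both:
            roles = {role for _, role in both}
            out.append(InheritanceCall(
                proband_id=pc.individual_id,
                proband_call_id=pc.call_id,
                label="inherited",
                origin="both_possible" if len(roles) == 2 else roles.pop(),
                matched_parent_call_id=both[0][0].call_id,
                matched_endpoints="both",
            ))
            continue
        one = []
        for c, role in same_chrom:
            s, e = _endpoint_match(pc, c, tol_bp)
            if s != e:
                one.append((c, role, "start_only" if s else "end_only"))
        if one:
            roles = {role for _, role, _ in one}
            out.append(InheritanceCall(
                proband_id=pc.individual_id,
                proband_call_id=pc.call_id,
                label="unknown",
                origin="both_possible" if len(roles) == 2 else roles.pop(),
                matched_parent_call_id=one[0][0].call_id,
                matched_endpoints=one[0][2],
            ))
            continue
        overlapping = any(
            min(pc.end, c.end) >= max(pc.start, c.start) for c, _ in same_chrom
        )
        if not overlapping:
            out.append(InheritanceCall(
                proband_id=pc.individual_id,
                proband_call_id=pc.call_id,
                label="de_novo",
                origin="none",
            ))
        else:
            label = collapse_ambiguous or "ambiguous"
            out.append(InheritanceCall(
                proband_id=pc.individual_id,
                proband_call_id=pc.call_id,
                label=label,
                origin="none",
            ))
    return out


def classify_cohort(
    calls: Sequence[CnvCall],
    individuals: Sequence[Individual],
    tol_bp: int = 0,
    collapse_ambiguous: Optional[str] = None,
) -> list[InheritanceCall]:
    """Run :func:`classify_trio` for every complete trio in the cohort.

    A trio is any individual whose father and mother ids both resolve to
    cohort members. Probands are processed in sorted id order.
    """
    by_ind: dict[str, list[CnvCall]] = {}
    for c in calls:
        by_ind.setdefault(c.individual_id, []).append(c)
    known = {i.individual_id for i in individuals}
    out = []
    for ind in sorted(individuals, key=lambda i: i.individual_id):
        if not ind.has_both_parents:
            continue
        if ind.father_id not in known or ind.mother_id not in known:
            continue
        out.extend(classify_trio(
            by_ind.get(ind.individual_id, []),
            by_ind.get(ind.father_id, []),
            by_ind.get(ind.mother_id, []),
            tol_bp=tol_bp,
            collapse_ambiguous=collapse_ambiguous,
        ))
    return out


def inheritance_rates(
    inh_calls: Sequence[InheritanceCall],
    individuals: Sequence[Individual],
    mirna_call_ids: Optional[set[str]] = None,
) -> pd.DataFrame:
    """Per-population class percentages and parental-origin split.

    Percentages are over classified proband calls of the population
    (restricted to miRNA-CNVs when ``mirna_call_ids`` is given) and sum to
    100. The origin columns split the inherited calls by matching parent.
    """
    pop = {i.individual_id: i.population for i in individuals}
    rows = []
    selected = [
        ic for ic in inh_calls
        if mirna_call_ids is None or ic.proband_call_id in mirna_call_ids
    ]
    pops = sorted({pop.get(ic.proband_id, "unknown") for ic in selected})
    for p in pops:
        sub = [ic for ic in selected if pop.get(ic.proband_id, "unknown") == p]
        n = len(sub)
        counts = {cl: sum(1 for ic in sub if ic.label == cl) for cl in CLASSES}
        inherited = [ic for ic in sub if ic.label == "inherited"]
        n_inh = len(inherited)
        rows.append({
            "population": p,
            "n_classified": n,
            **{f"n_{cl}": counts[cl] for cl in CLASSES},
            **{f"pct_{cl}": 100.0 * counts[cl] / n if n else float("nan")
               for cl in CLASSES},
            "pct_maternal": (100.0 * sum(1 for ic in inherited if ic.origin == "mother") / n_inh
                             if n_inh else float("nan")),
            "pct_paternal": (100.0 * sum(1 for ic in inherited if ic.origin == "father") / n_inh
                             if n_inh else float("nan")),
            "pct_origin_both_possible": (100.0 * sum(1 for ic in inherited if ic.origin == "both_possible") / n_inh
                                         if n_inh else float("nan")),
        })
    return pd.DataFrame(rows)


def inheritance_table(inh_calls: Sequence[InheritanceCall]) -> pd.DataFrame:
    """Flat TSV-ready table of per-call classifications."""
    return pd.DataFrame(
        [vars(ic) if not hasattr(ic, "__slots__") else
         {k: getattr(ic, k) for k in ic.__slots__} for ic in inh_calls],
        columns=["proband_id", "proband_call_id", "label", "origin",
                 "matched_parent_call_id", "matched_endpoints"],
    )
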