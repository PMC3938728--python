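"""Recurrent CNV region detection via overlap-graph maximal cliques.

CNV events are nodes of an undirected graph with an edge wherever two
same-chromosome events share at least the merge overlap fraction (default
40%, reciprocal). A merged region is a maximal clique of size >= 2 — a set
of events each overlapping all others — and a family is a maximal clique
within a region at the stricter family threshold (default 99%,
near-identical breakpoints). Events are then labelled hotspot,
intermediate or unique from the size of their largest region.

Maximal cliques are enumerated with the Bron-Kerbosch pivoting algorithm
(networkx); with fractional-overlap edges the graph need not be an
interval graph, so a general algorithm is required.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .annotate import reciprocal_overlap
from .model import CnvCall, ConfigError


def build_overlap_graph(
    calls: Sequence[CnvCall],
    min_fraction: float = 0.40,
    overlap_mode: str = "reciprocal",
) -> nx.Graph:
    """Overlap graph: nodes are call_ids, edges where overlap >= threshold.

    ``overlap_mode='reciprocal'`` requires min(shared/len_a, shared/len_b)
    >= ``min_fraction``; ``'single'`` requires only the larger of the two
    fractions to reach it. Edges never join different chromosomes; the
    graph is undirected with no self-loops. Node attributes carry the
    event coordinates for downstream region spans.
    """
    if not 0 < min_fraction <= 1:
        raise ConfigError(f"min_fraction must be in (0, 1], got {min_fraction}")
    if overlap_mode not in ("reciprocal", "single"):
        raise ConfigError(f"unknown overlap_mode {overlap_mode!r}")
    g = nx.Graph()
    for c in calls:
        g.add_node(c.call_id, chrom=c.chrom, start=c.start, end=c.end,
                   individual_id=c.individual_id, cn_state=c.cn_state)
    by_chrom: dict[str, list[CnvCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom_calls in by_chrom.values():
        # sweep on sorted starts: only pairs that can overlap are compared
        chrom_calls.sort(key=lambda c: (c.start, c.end, c.call_id))
        for i, a in enumerate(chrom_calls):
            for b in chrom_calls[i + 1:]:
                if b.start > a.end:
                    break
                frac = reciprocal_overlap(a, b)
                if overlap_mode == "single" and frac > 0:
                    shared = min(a.end, b.end) - max(a.start, b.start) + 1
                    frac = max(shared / a.size, shared / b.size)
                if frac >= min_fraction:
                    g.add_edge(a.call_id, b.call_id)
    return g


@dataclass(frozen=True)
class MergedRegion:
    """A maximal set of mutually overlapping CNV events and its span."""

    region_id: str
    chrom: str
    span_start: int
    span_end: int
    member_call_ids: tuple[str, ...]
    n_individuals: int
    n_populations: int
    families: tuple[tuple[str, ...], ...] = ()


def find_merged_regions(
    graph: nx.Graph,
    population_of: Optional[Mapping[str, str]] = None,
) -> list[MergedRegion]:
    """Enumerate maximal cliques of size >= 2 as merged regions.

    A call may be a member of several maximal cliques (overlapping
    regions are all reported); singleton nodes are not regions — they
    surface as 'unique' in :func:`classify_events`. Output order is
    deterministic: by (chrom, span start, span end, members).
    """
    population_of = population_of or {}
    raw = [tuple(sorted(c)) for c in nx.find_cliques(graph) if len(c) >= 2]
    decorated = []
    for members in raw:
        chrom = graph.nodes[members[0]]["chrom"]
        start = min(graph.nodes[m]["start"] for m in members)
        end = max(graph.nodes[m]["end"] for m in members)
        inds = {graph.nodes[m]["individual_id"] for m in members}
        pops = {population_of[i] for i in inds if i in population_of}
        decorated.append((chrom, start, end, members, len(inds), len(pops)))
    decorated.sort()
    return [
        MergedRegion(
            region_id=f"MR{i:05d}",
            chrom=chrom, span_start=start, span_end=end,
            member_call_ids=members,
            n_individuals=n_inds, n_populations=n_pops,
        )
        for i, (chrom, start, end, members, n_inds, n_pops) in enumerate(decorated, 1)
    ]


def find_families(
    region: MergedRegion,
    calls_by_id: Mapping[str, CnvCall],
    family_fraction: float = 0.99,
    merge_fraction: float = 0.40,
) -> list[tuple[str, ...]]:
    """Maximal cliques of size >= 2 within a region at the family threshold.

    Families group near-identical breakpoints (default 99% reciprocal
    overlap). The family threshold must not be below the merge threshold.
    """
    if family_fraction < merge_fraction:
        raise ConfigError(
            f"family_fraction {family_fraction} < merge_fraction {merge_fraction}")
    members = [calls_by_id[m] for m in region.member_call_ids]
    sub = build_overlap_graph(members, min_fraction=family_fraction)
    return sorted(tuple(sorted(c)) for c in nx.find_cliques(sub) if len(c) >= 2)


def attach_families(
    regions: Sequence[MergedRegion],
    calls: Sequence[CnvCall],
    family_fraction: float = 0.99,
    merge_fraction: float = 0.40,
) -> list[MergedRegion]:
    by_id = {c.call_id: c for c in calls}
    return [
        MergedRegion(
            region_id=r.region_id, chrom=r.chrom,
            span_start=r.span_start, span_end=r.span_end,
            member_call_ids=r.member_call_ids,
            n_individuals=r.n_individuals, n_populations=r.n_populations,
            families=tuple(find_families(r, by_id, family_fraction, merge_fraction)),
        )
        for r in regions
    ]


def classify_events(
    regions: Sequence[MergedRegion],
    calls: Sequence[CnvCall],
    min_events: int = 5,
) -> dict[str, str]:
    """Label every call hotspot, intermediate or unique.

    unique: member of no size->=2 merged region; hotspot: its largest
    containing region spans at least ``min_events`` distinct individuals;
    intermediate: otherwise. Each call is judged by its largest region
    (most individuals, ties to the earlier region id), so the three labels
    partition the calls.
    """
    if min_events < 1:
        raise ConfigError("min_events must be >= 1")
    best: dict[str, MergedRegion] = {}
    for r in regions:
        for m in r.member_call_ids:
            cur = best.get(m)
            if cur is None or r.n_individuals > cur.n_individuals or (
                    r.n_individuals == cur.n_individuals
                    and r.region_id < cur.region_id):
                best[m] = r
    labels = {}
    for c in calls:
        r = best.get(c.call_id)
        if r is None:
            labels[c.call_id] = "unique"
        elif r.n_individuals >= min_events:
            labels[c.call_id] = "hotspot"
        else:
            labels[c.call_id] = "intermediate"
    return labels


def regions_table(regions: Sequence[MergedRegion]) -> pd.DataFrame:
    rows = [{
        "region_id": r.region_id,
        "chrom": r.chrom,
        "span_start": r.span_start,
        "span_end": r.span_end,
        "n_members": len(r.member_call_ids),
        "n_individuals": r.n_individuals,
        "n_populations": r.n_populations,
        "n_families": len(r.families),
        "member_call_ids": ",".join(r.member_call_ids),
    } for r in regions]
    return pd.DataFrame(rows, columns=["region_id", "chrom", "span_start", "span_end",
                                       "n_members", "n_individuals", "n_populations",
                                       "n_families", "member_call_ids"])


def families_table(regions: Sequence[MergedRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        for j, fam in enumerate(r.families, 1):
            rows.append({"region_id": r.region_id, "family_id": f"{r.region_id}.F{j}",
                         "n_members": len(fam), "member_call_ids": ",".join(fam)})
    return pd.DataFrame(rows, columns=["region_id", "family_id", "n_members",
                                       "member_call_ids"])


def write_graphml(graph: nx.Graph, path) -> None:
    """Export the overlap graph for external graph tools (Gephi-loadable)."""
    nx.write_graphml(graph, path)
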