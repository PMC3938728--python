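"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from mirna_cnv import simulate as sim
from mirna_cnv.model import CnvCall, GeneFeature, Individual


def brute_force_maximal_cliques(n: int, edges: set[tuple[int, int]]) -> set[frozenset[int]]:
    """Exhaustive maximal-clique enumeration over all vertex subsets.

    Independent oracle for clique detection: checks every one of the 2^n
    subsets for the clique property with bitmask adjacency, then keeps
    those extendable by no outside vertex. Feasible for n <= 15.
    """
    adj = np.zeros(n, dtype=np.int64)
    for a, b in edges:
        adj[a] |= 1 << b
        adj[b] |= 1 << a
    masks = np.arange(1, 1 << n, dtype=np.int64)
    is_clique = np.ones(len(masks), dtype=bool)
    for v in range(n):
        has_v = (masks >> v) & 1 == 1
        rest = masks & ~np.int64(1 << v)
        ok = (rest & ~adj[v]) == 0
        is_clique &= ~has_v | ok
    cliques = masks[is_clique]
    maximal = []
    for m in cliques:
        extendable = False
        for w in range(n):
            if (m >> w) & 1 == 0 and (m & ~adj[w]) == 0:
                extendable = True
                break
        if not extendable:
            maximal.append(frozenset(v for v in range(n) if (m >> v) & 1))
    return set(maximal)


def brute_force_gene_hits(calls, genes, min_overlap_bp: int = 1):
    """All-pairs O(n*m) interval intersection oracle."""
    out = {}
    for c in calls:
        hit = set()
        for g in genes:
            if g.chrom != c.chrom:
                continue
            shared = min(c.end, g.end) - max(c.start, g.start) + 1
            if shared >= min_overlap_bp:
                hit.add(g.gene_id)
        out[c.call_id] = frozenset(hit)
    return out


@pytest.fixture(scope="session")
def clique_oracle():
    return brute_force_maximal_cliques


@pytest.fixture(scope="session")
def gene_hit_oracle():
    return brute_force_gene_hits


@pytest.fixture(scope="session")
def small_cohort():
    """A modest deterministic synthetic cohort with trios and a hotspot."""
    cfg = sim.SimConfig(
        populations=[
            sim.PopulationSpec("POP_A", 40, 20),
            sim.PopulationSpec("POP_B", 30, 15),
        ],
        n_trios_per_population=4,
        n_mirna_genes=25,
        seed=11,
    )
    individuals, calls, genes, truth = sim.generate_cohort(cfg)
    return cfg, individuals, calls, genes, truth


@pytest.fixture()
def toy_genes():
    return [
        GeneFeature("MIR650", "22", 23_100_000, 23_100_099, "+"),
        GeneFeature("MIR1233", "15", 34_700_000, 34_700_120, "-"),
    ]


def make_call(individual="I1", chrom="22", start=100, end=200, cn=3,
              probes=20, call_id="x1") -> CnvCall:
    return CnvCall(individual, chrom, start, end, cn, probes, call_id)
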