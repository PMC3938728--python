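"""QC filtering, reference validation and miRNA gene annotation of CNV calls.

A call is a miRNA-CNV when it overlaps at least one annotated miRNA gene
by at least one base (no minimum fraction — partial-gene duplications and
deletions change dosage just as whole-gene events do). Reference
validation follows the standard reciprocal-overlap convention: a call is
validated when some reference interval shares at least 50% of both
intervals' lengths, losses and gains matched separately when the reference
carries a type.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .model import (
    AnnotatedCall,
    CnvCall,
    ConfigError,
    GeneFeature,
    expected_ploidy,
)


def qc_filter(
    calls: Sequence[CnvCall],
    min_size_bp: int = 1000,
    min_probes: int = 5,
    require_probes: bool = True,
) -> tuple[list[CnvCall], list[CnvCall]]:
    """Split calls into (kept, dropped) by the array-QC rule.

    A call is kept iff its size is strictly greater than ``min_size_bp``
    AND it is supported by strictly more than ``min_probes`` probes —
    both inequalities strict, mirroring the caller's ">1 Kb and >5 probes"
    defaults. Calls with unknown probe count (``n_probes == 0``) fail the
    probe test unless ``require_probes`` is False, in which case they are
    exempt from it.
    """
    if min_size_bp < 0 or min_probes < 0:
        raise ConfigError("QC thresholds must be non-negative")
    kept, dropped = [], []
    for c in calls:
        ok_size = c.size > min_size_bp
        if c.n_probes == 0 and not require_probes:
            ok_probes = True
        else:
            ok_probes = c.n_probes > min_probes
        (kept if ok_size and ok_probes else dropped).append(c)
    return kept, dropped


def overlap_bp(a, b) -> int:
    """Shared bases between two closed intervals on the same chromosome."""
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def reciprocal_overlap(a, b) -> float:
    """Reciprocal overlap fraction of two intervals, in [0, 1].

    min(shared/len(a), shared/len(b)); 0 when disjoint or on different
    chromosomes. Symmetric by construction. ``a`` and ``b`` are any
    objects with ``chrom``, ``start``, ``end`` (calls, genes, reference
    records).
    """
    if a.start > a.end or b.start > b.end or a.start < 1 or b.start < 1:
        raise ValueError("invalid interval")
    if a.chrom != b.chrom:
        return 0.0
    shared = overlap_bp(a, b)
    if shared == 0:
        return 0.0
    len_a = a.end - a.start + 1
    len_b = b.end - b.start + 1
    return min(shared / len_a, shared / len_b)


@dataclass(frozen=True, slots=True)
class ReferenceInterval:
    """A reference CNV region; ``kind`` is 'gain', 'loss' or None (untyped)."""

    chrom: str
    start: int
    end: int
    kind: Optional[str] = None


def _call_kind(call: CnvCall) -> Optional[str]:
    # Sex-unaware typing is adequate for loss/gain matching pre-annotation.
    if call.cn_state < 2:
        return "loss"
    if call.cn_state > 2:
        return "gain"
    return None


def validate_against_reference(
    calls: Sequence[CnvCall],
    reference: Sequence[ReferenceInterval],
    threshold: float = 0.5,
) -> dict[str, bool]:
    """Flag each call (by call_id) as validated against a reference set.

    A call is validated iff some reference interval has reciprocal overlap
    >= ``threshold`` with it. Typed reference intervals ('gain'/'loss')
    only match calls of the same type; untyped intervals match any call.
    """
    by_chrom: dict[str, list[ReferenceInterval]] = {}
    trees: dict[str, IntervalTree] = {}
    for i, ref in enumerate(reference):
        trees.setdefault(ref.chrom, IntervalTree()).addi(ref.start, ref.end + 1, ref)
    flags: dict[str, bool] = {}
    for call in calls:
        ok = False
        tree = trees.get(call.chrom)
        if tree is not None:
            kind = _call_kind(call)
            for iv in tree.overlap(call.start, call.end + 1):
                ref = iv.data
                if ref.kind is not None and kind is not None and ref.kind != kind:
                    continue
                if reciprocal_overlap(call, ref) >= threshold:
                    ok = True
                    break
        flags[call.call_id] = ok
    return flags


def annotate_mirna(
    calls: Sequence[CnvCall],
    genes: Sequence[GeneFeature],
    sex_of: Optional[Mapping[str, str]] = None,
    min_gene_overlap_bp: int = 1,
    validated: Optional[Mapping[str, bool]] = None,
) -> list[AnnotatedCall]:
    """Intersect calls with miRNA genes and assign CNV types.

    A gene is listed for a call when they share at least
    ``min_gene_overlap_bp`` bases (default 1; strand ignored). ``cnv_type``
    compares the CN state with the sex-aware expected ploidy of the
    chromosome (``sex_of`` maps individual_id to sex; unknown individuals
    are treated as sex 'unknown'). Output is sorted by (chrom, start, end,
    individual_id) for determinism.
    """
    if min_gene_overlap_bp < 1:
        raise ConfigError("min_gene_overlap_bp must be >= 1")
    sex_of = sex_of or {}
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)
    out = []
    for call in calls:
        hit_genes = []
        tree = trees.get(call.chrom)
        if tree is not None:
            for iv in tree.overlap(call.start, call.end + 1):
                if overlap_bp(call, iv.data) >= min_gene_overlap_bp:
                    hit_genes.append(iv.data.gene_id)
        sex = sex_of.get(call.individual_id, "unknown")
        exp = expected_ploidy(call.chrom, sex)
        if call.cn_state > exp:
            cnv_type = "duplication"
        elif call.cn_state < exp:
            cnv_type = "deletion"
        else:
            cnv_type = "none"
        out.append(AnnotatedCall(
            call=call,
            genes=tuple(sorted(set(hit_genes))),
            cnv_type=cnv_type,
            qc_pass=True,
            reference_validated=None if validated is None else validated.get(call.call_id, False),
        ))
    out.sort(key=lambda a: (a.call.chrom, a.call.start, a.call.end, a.call.individual_id))
    return out


@dataclass(frozen=True)
class GeneAccounting:
    """Gene-level tallies over all miRNA-CNVs.

    ``total_gene_hits`` counts gene occurrences with multiplicity across
    calls; ``singleton_genes`` is the set of distinct gene identifiers hit
    at least once (each counted once, however often its locus recurs).
    """

    total_gene_hits: int
    singleton_genes: frozenset[str]
    per_individual_gene_counts: Mapping[str, int]


def gene_accounting(annotated: Iterable[AnnotatedCall]) -> GeneAccounting:
    total = 0
    singles: set[str] = set()
    per_ind: dict[str, int] = {}
    for ac in annotated:
        n = len(ac.genes)
        if n == 0:
            continue
        total += n
        singles.update(ac.genes)
        per_ind[ac.individual_id] = per_ind.get(ac.individual_id, 0) + n
    return GeneAccounting(total, frozenset(singles), per_ind)
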