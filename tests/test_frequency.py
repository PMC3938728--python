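"""Breakpoint grouping and per-population carrier frequencies."""

import math

import pytest

from mirna_cnv import annotate as ann
from mirna_cnv import frequency as fq
from mirna_cnv import simulate as sim
from mirna_cnv.model import CnvCall, ConfigError, GeneFeature, Individual

GENES = [GeneFeature("MIR650", "22", 23_100_000, 23_100_099)]


def _ann(ind, start, end, cid, chrom="22"):
    call = CnvCall(ind, chrom, start, end, 3, 20, cid)
    return ann.annotate_mirna([call], GENES)[0]


def _inds(*pairs):
    return [Individual(i, p, "male") for i, p in pairs]


class TestGrouping:
    def test_identical_breakpoints_grouped(self):
        inds = _inds(("A", "YRI"), ("B", "YRI"))
        annotated = [_ann("A", 23_040_138, 23_255_556, "c1"),
                     _ann("B", 23_040_138, 23_255_556, "c2")]
        (g,) = fq.group_breakpoints(annotated, inds)
        assert g.n_carriers == 2 and g.carriers_by_population == {"YRI": 2}
        assert g.genes == ("MIR650",)

    def test_duplicate_rows_count_individual_once(self):
        inds = _inds(("A", "YRI"))
        annotated = [_ann("A", 23_040_138, 23_255_556, "c1"),
                     _ann("A", 23_040_138, 23_255_556, "c2")]
        (g,) = fq.group_breakpoints(annotated, inds)
        assert g.n_carriers == 1

    def test_one_bp_difference_splits_at_tol_zero(self):
        inds = _inds(("A", "YRI"), ("B", "YRI"))
        annotated = [_ann("A", 23_040_138, 23_255_556, "c1"),
                     _ann("B", 23_040_139, 23_255_556, "c2")]
        assert len(fq.group_breakpoints(annotated, inds, tol_bp=0)) == 2
        assert len(fq.group_breakpoints(annotated, inds, tol_bp=1)) == 1

    def test_single_linkage_is_order_independent(self):
        inds = _inds(("A", "P"), ("B", "P"), ("C", "P"))
        annotated = [_ann("A", 23_099_990, 23_255_556, "c1"),
                     _ann("B", 23_099_995, 23_255_556, "c2"),
                     _ann("C", 23_100_000, 23_255_556, "c3")]
        g1 = fq.group_breakpoints(annotated, inds, tol_bp=5)
        g2 = fq.group_breakpoints(list(reversed(annotated)), inds, tol_bp=5)
        assert [g.carrier_ids for g in g1] == [g.carrier_ids for g in g2]
        assert len(g1) == 1  # chain linked transitively

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ConfigError):
            fq.group_breakpoints([], [], tol_bp=-1)


class TestFrequencies:
    def test_carrier_denominator_convention(self):
        # 1 carrier among 25 population carriers -> 4.0%
        inds = _inds(("A", "YRI"))
        annotated = [_ann("A", 23_040_138, 23_255_556, "c1")]
        groups = fq.group_breakpoints(annotated, inds)
        (g,) = fq.compute_frequencies(groups, {"YRI": 25})
        assert g.freq_by_population["YRI"] == pytest.approx(4.0)

    def test_tibet_cell(self):
        # 2 carriers among 31 -> 6.45% (2 d.p.)
        inds = _inds(("A", "Tibet"), ("B", "Tibet"))
        annotated = [_ann("A", 23_040_138, 23_255_556, "c1"),
                     _ann("B", 23_040_138, 23_255_556, "c2")]
        (g,) = fq.compute_frequencies(
            fq.group_breakpoints(annotated, inds), {"Tibet": 31})
        assert round(g.freq_by_population["Tibet"], 2) == 6.45

    def test_zero_denominator_is_na_not_zero(self):
        inds = _inds(("A", "YRI"))
        annotated = [_ann("A", 23_040_138, 23_255_556, "c1")]
        (g,) = fq.compute_frequencies(
            fq.group_breakpoints(annotated, inds), {"YRI": 25, "EMPTY": 0})
        assert math.isnan(g.freq_by_population["EMPTY"])

    def test_global_frequency_pools_carriers(self):
        carriers = {"YRI": 1, "AJ1": 15, "AJ2": 2, "China": 2, "Tibet": 2,
                    "India": 1, "JPT": 1, "Australia": 1, "Taiwan": 4}
        denoms = {"YRI": 25, "CEU": 44, "AJ1": 441, "AJ2": 468, "CHB": 14,
                  "China": 93, "Tibet": 31, "India": 30, "JPT": 20,
                  "Australia": 51, "NewWorld": 36, "Taiwan": 181}
        got = fq.global_frequency(carriers, denoms)
        assert got == pytest.approx(100.0 * 29 / 1434)
        assert round(got, 2) == 2.02

    def test_global_equals_carrier_weighted_pooling(self, small_cohort):
        """Identity: pooling per-population freqs by their denominators
        reproduces the global frequency exactly."""
        _, individuals, calls, genes, _ = small_cohort
        annotated = ann.annotate_mirna(calls, genes)
        denoms = fq.mirna_carrier_counts(annotated, individuals)
        groups = fq.compute_frequencies(
            fq.group_breakpoints(annotated, individuals), denoms)
        total_den = sum(denoms.values())
        for g in groups[:50]:
            pooled = sum((g.freq_by_population[p] / 100) * denoms[p]
                         for p in denoms if denoms[p])
            assert g.global_freq == pytest.approx(100 * pooled / total_den)

    def test_no_double_counting_within_population(self, small_cohort):
        _, individuals, calls, genes, _ = small_cohort
        annotated = ann.annotate_mirna(calls, genes)
        denoms = fq.mirna_carrier_counts(annotated, individuals)
        for g in fq.group_breakpoints(annotated, individuals):
            for p, n in g.carriers_by_population.items():
                assert n <= denoms.get(p, 0)


class TestTiers:
    def test_tier_assignment(self):
        inds = _inds(*[(f"I{k}", f"P{k}") for k in range(9)], ("Z", "P0"))
        annotated = [_ann(f"I{k}", 23_040_138, 23_255_556, f"c{k}") for k in range(9)]
        annotated.append(_ann("Z", 23_000_000, 23_200_000, "cz"))
        denoms = {f"P{k}": 5 for k in range(9)}
        groups = fq.compute_frequencies(
            fq.group_breakpoints(annotated, inds), denoms)
        tiers = fq.shared_population_tiers(groups)
        assert tiers.iloc[0].tier == "9 populations"
        assert tiers.iloc[1].tier == "1 population"

    def test_planted_hotspot_spans_configured_populations(self):
        pops = [sim.PopulationSpec(f"P{k}", 20, 10) for k in range(7)]
        cfg = sim.SimConfig(
            populations=pops, background_rate=0.0, n_mirna_genes=5,
            hotspot_loci=[sim.HotspotLocus("22", 23_000_000, 23_200_000, 0.25)],
            seed=13,
        )
        individuals, calls, genes, _ = sim.generate_cohort(cfg)
        annotated = ann.annotate_mirna(calls, genes)
        denoms = fq.mirna_carrier_counts(annotated, individuals)
        groups = fq.compute_frequencies(
            fq.group_breakpoints(annotated, individuals), denoms)
        (g,) = groups
        assert g.n_populations == 7
        assert fq.shared_population_tiers(groups).iloc[0].tier == "7 populations"


def test_frequency_table_shape():
    inds = _inds(("A", "YRI"), ("B", "CEU"))
    annotated = [_ann("A", 23_040_138, 23_255_556, "c1"),
                 _ann("B", 23_040_138, 23_255_556, "c2")]
    groups = fq.compute_frequencies(
        fq.group_breakpoints(annotated, inds), {"YRI": 25, "CEU": 44})
    df = fq.frequency_table(groups, ["YRI", "CEU"])
    assert list(df.columns) == ["chrom", "start", "end", "genes", "n_populations",
                                "n_carriers", "YRI", "CEU", "global_freq"]
    assert df.iloc[0].YRI == 4.0 and df.iloc[0].CEU == pytest.approx(2.27)
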