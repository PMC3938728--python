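"""QC filtering, reciprocal overlap, reference validation and annotation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirna_cnv import annotate as ann
from mirna_cnv.model import CnvCall, ConfigError, GeneFeature

from conftest import make_call


class TestQcFilter:
    def test_strict_boundaries(self):
        # >1 kb and >5 probes are strict: exactly-at-threshold calls drop
        at_size = make_call(start=1, end=1000, probes=10, call_id="a")  # size 1000
        above = make_call(start=1, end=1001, probes=6, call_id="b")  # size 1001
        at_probes = make_call(start=1, end=5000, probes=5, call_id="c")
        kept, dropped = ann.qc_filter([at_size, above, at_probes])
        assert [c.call_id for c in kept] == ["b"]
        assert [c.call_id for c in dropped] == ["a", "c"]

    def test_empty_input(self):
        assert ann.qc_filter([]) == ([], [])

    def test_unknown_probe_count_exemption(self):
        c = make_call(start=1, end=5000, probes=0)
        assert ann.qc_filter([c])[0] == []
        assert ann.qc_filter([c], require_probes=False)[0] == [c]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ConfigError):
            ann.qc_filter([], min_size_bp=-1)

    def test_partition(self, small_cohort):
        _, _, calls, _, _ = small_cohort
        kept, dropped = ann.qc_filter(calls)
        assert len(kept) + len(dropped) == len(calls)


class TestReciprocalOverlap:
    def test_identity_is_one(self):
        a = make_call(start=10, end=100)
        assert ann.reciprocal_overlap(a, a) == 1.0

    def test_half_overlap(self):
        a = make_call(start=1, end=100, call_id="a")
        b = make_call(start=51, end=150, call_id="b")
        assert ann.reciprocal_overlap(a, b) == pytest.approx(0.5)

    def test_disjoint_and_cross_chromosome(self):
        a = make_call(start=1, end=100)
        b = make_call(start=200, end=300, call_id="b")
        c = make_call(chrom="15", start=1, end=100, call_id="c")
        assert ann.reciprocal_overlap(a, b) == 0.0
        assert ann.reciprocal_overlap(a, c) == 0.0

    @settings(max_examples=200, deadline=None)
    @given(st.integers(1, 500), st.integers(0, 500),
           st.integers(1, 500), st.integers(0, 500))
    def test_symmetric_and_bounded(self, s1, l1, s2, l2):
        a = make_call(start=s1, end=s1 + l1, call_id="a")
        b = make_call(start=s2, end=s2 + l2, call_id="b")
        f_ab = ann.reciprocal_overlap(a, b)
        f_ba = ann.reciprocal_overlap(b, a)
        assert f_ab == f_ba
        shorter = min(a.size, b.size)
        longer = max(a.size, b.size)
        assert 0.0 <= f_ab <= shorter / longer + 1e-12


class TestReferenceValidation:
    def test_identical_interval_validates(self):
        c = make_call(start=100, end=200)
        ref = [ann.ReferenceInterval("22", 100, 200)]
        assert ann.validate_against_reference([c], ref) == {"x1": True}

    def test_forty_nine_percent_fails(self):
        c = make_call(start=1, end=100)
        ref = [ann.ReferenceInterval("22", 1, 49)]  # min(0.49, 1.0) < 0.5
        assert ann.validate_against_reference([c], ref) == {"x1": False}

    def test_empty_reference_validates_nothing(self):
        c = make_call()
        assert ann.validate_against_reference([c], []) == {"x1": False}

    def test_gains_and_losses_matched_separately(self):
        gain = make_call(start=100, end=200, cn=3, call_id="g")
        loss = make_call(start=100, end=200, cn=1, call_id="l")
        ref = [ann.ReferenceInterval("22", 100, 200, kind="gain")]
        flags = ann.validate_against_reference([gain, loss], ref)
        assert flags == {"g": True, "l": False}


class TestAnnotateMirna:
    def test_spanning_call_lists_gene(self, toy_genes):
        c = make_call(start=23_000_000, end=23_200_000)
        (ac,) = ann.annotate_mirna([c], toy_genes)
        assert ac.genes == ("MIR650",) and ac.is_mirna_cnv

    def test_single_base_overlap_counts(self, toy_genes):
        c = make_call(start=23_099_000, end=23_100_000)  # last base touches gene
        (ac,) = ann.annotate_mirna([c], toy_genes)
        assert ac.genes == ("MIR650",)
        c2 = make_call(start=23_099_000, end=23_099_999, call_id="x2")
        (ac2,) = ann.annotate_mirna([c2], toy_genes)
        assert ac2.genes == ()

    @pytest.mark.parametrize("chrom,sex,cn,expected", [
        ("22", "male", 3, "duplication"),
        ("22", "female", 1, "deletion"),
        ("22", "male", 2, "none"),
        ("X", "male", 2, "duplication"),  # expected ploidy 1 on male X
        ("X", "female", 2, "none"),
        ("X", "male", 0, "deletion"),
        ("Y", "male", 1, "none"),
    ])
    def test_sex_aware_cnv_type(self, chrom, sex, cn, expected):
        c = make_call(chrom=chrom, cn=cn)
        (ac,) = ann.annotate_mirna([c], [], sex_of={"I1": sex})
        assert ac.cnv_type == expected

    def test_matches_brute_force_oracle(self, gene_hit_oracle):
        rng = np.random.default_rng(42)
        for _ in range(20):
            chroms = ["1", "2", "X"]
            genes = [
                GeneFeature(f"G{i}", str(rng.choice(chroms)),
                            int(s := rng.integers(1, 10_000)), int(s + rng.integers(0, 200)))
                for i in range(50)
            ]
            calls = [
                CnvCall(f"I{i % 7}", str(rng.choice(chroms)),
                        int(s := rng.integers(1, 10_000)), int(s + rng.integers(0, 2_000)),
                        int(rng.choice([0, 1, 3, 4])), 10, f"c{i}")
                for i in range(200)
            ]
            annotated = ann.annotate_mirna(calls, genes)
            got = {a.call_id: frozenset(a.genes) for a in annotated}
            assert got == gene_hit_oracle(calls, genes)

    def test_mirna_partition(self, small_cohort):
        _, individuals, calls, genes, _ = small_cohort
        annotated = ann.annotate_mirna(calls, genes)
        n_mirna = sum(a.is_mirna_cnv for a in annotated)
        n_plain = sum(not a.is_mirna_cnv for a in annotated)
        assert n_mirna + n_plain == len(calls)


class TestGeneAccounting:
    def test_multiplicity_vs_distinct(self, toy_genes):
        calls = [make_call(start=23_000_000, end=23_200_000, call_id=f"c{i}")
                 for i in range(3)]
        acc = ann.gene_accounting(ann.annotate_mirna(calls, toy_genes))
        assert acc.total_gene_hits == 3
        assert acc.singleton_genes == {"MIR650"}

    def test_empty(self):
        acc = ann.gene_accounting([])
        assert acc.total_gene_hits == 0 and acc.singleton_genes == frozenset()

    def test_per_individual_counts_sum_to_total(self, small_cohort):
        _, _, calls, genes, _ = small_cohort
        acc = ann.gene_accounting(ann.annotate_mirna(calls, genes))
        assert sum(acc.per_individual_gene_counts.values()) == acc.total_gene_hits
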