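"""Mutation matrices, exact tests (with exact-rational oracles), burden,
and UV classification."""

import math
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genoconcord.io_formats import CoverageTrack, MutationRecord, VariantClass
from genoconcord.mutation_stats import (
    ContingencyTable22,
    build_mutation_matrix,
    coverage_breadth,
    differential_mutation_test,
    exclusivity_midp,
    fisher_exact_two_sided,
    mutation_burden,
    table_from_matrix,
    test_exclusivity_pairs as pair_exclusivity_test,
    uv_signature,
)

# ---------------------------------------------------------------------------
# independent exact-rational oracles (enumeration over all fixed-margin
# tables; integer combinatorics only)
# ---------------------------------------------------------------------------


def oracle_midp(table: ContingencyTable22) -> Fraction:
    N, K, n, b = table.n, table.m1, table.m2, table.both
    den = comb(N, n)
    total = Fraction(0)
    for k in range(max(0, n + K - N), min(K, n) + 1):
        pk = Fraction(comb(K, k) * comb(N - K, n - k), den)
        if k < b:
            total += pk
        elif k == b:
            total += pk / 2
    return total


def oracle_fisher_two_sided(a: int, b: int, c: int, d: int) -> Fraction:
    # same inclusion convention as the implementation: tables with
    # probability <= observed * (1 + 1e-7) contribute
    row1, col1 = a + b, a + c
    N = a + b + c + d
    den = comb(N, col1)
    num_obs = comb(row1, a) * comb(N - row1, col1 - a)
    total = 0
    for k in range(max(0, col1 - (N - row1)), min(row1, col1) + 1):
        num_k = comb(row1, k) * comb(N - row1, col1 - k)
        if num_k * 10_000_000 <= num_obs * 10_000_001:
            total += num_k
    return Fraction(total, den)


def rel_close(x: float, y: float, digits: int = 10) -> bool:
    if y == 0:
        return x == 0
    return abs(x - y) / abs(y) < 10 ** (-digits)


# ---------------------------------------------------------------------------
# exclusivity mid-p
# ---------------------------------------------------------------------------


class TestExclusivityMidp:
    @pytest.mark.parametrize(
        "table,printed_raw",
        [
            ((12, 5, 34, 2), 0.0156621),  # strongly co-covered driver pair, n=53
            ((98, 110, 196, 8), 8.8857e-32),
        ],
    )
    def test_against_exact_enumeration(self, table, printed_raw):
        t = ContingencyTable22(*table)
        p = exclusivity_midp(t)
        assert rel_close(p, float(oracle_midp(t)), digits=10)
        assert p == pytest.approx(printed_raw, rel=1e-4)

    def test_zero_margin_gives_exactly_half(self):
        # gene2 never mutated: B is forced to 0, so p = 0.5 * P(B=0) = 0.5
        assert exclusivity_midp(ContingencyTable22(10, 0, 5, 0)) == pytest.approx(0.5)

    def test_co_occurring_pair_near_one(self):
        # both counts far above the independence expectation
        p = exclusivity_midp(ContingencyTable22(50, 2, 2, 46))
        assert p > 0.999

    def test_symmetric_in_gene_labels(self):
        t1 = ContingencyTable22(30, 10, 20, 3)
        t2 = ContingencyTable22(30, 20, 10, 3)  # genes swapped
        assert exclusivity_midp(t1) == pytest.approx(exclusivity_midp(t2), rel=1e-14)

    @given(
        neither=st.integers(0, 25),
        g2=st.integers(0, 25),
        g1=st.integers(0, 25),
        both=st.integers(0, 10),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_oracle_on_random_tables(self, neither, g2, g1, both):
        if neither + g2 + g1 + both == 0:
            return
        t = ContingencyTable22(neither, g2, g1, both)
        assert rel_close(exclusivity_midp(t), float(oracle_midp(t)), digits=10)


class TestFisherTwoSided:
    @pytest.mark.parametrize(
        "table,multiplier,printed",
        [((41, 12, 0, 412), 1192, 2.82e-45), ((52, 1, 29, 383), 1192, 1.46e-43)],
    )
    def test_extreme_tables_against_oracle(self, table, multiplier, printed):
        p = fisher_exact_two_sided(*table)
        assert rel_close(p, float(oracle_fisher_two_sided(*table)), digits=10)
        assert p * multiplier == pytest.approx(printed, rel=5e-3)

    def test_equal_proportions_give_one(self):
        assert fisher_exact_two_sided(5, 45, 41, 369) == pytest.approx(1.0)

    def test_matches_scipy_at_moderate_scale(self):
        from scipy.stats import fisher_exact

        for table in [(8, 2, 1, 9), (3, 17, 12, 8), (0, 10, 10, 0)]:
            a, b, c, d = table
            ours = fisher_exact_two_sided(a, b, c, d)
            ref = fisher_exact([[a, b], [c, d]]).pvalue
            assert ours == pytest.approx(ref, rel=1e-9)

    @given(
        a=st.integers(0, 20), b=st.integers(0, 20),
        c=st.integers(0, 20), d=st.integers(0, 20),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_oracle_on_random_tables(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = fisher_exact_two_sided(a, b, c, d)
        assert rel_close(p, float(oracle_fisher_two_sided(a, b, c, d)), digits=10)
        assert 0 < p <= 1


# ---------------------------------------------------------------------------
# mutation matrix and cohort-level tests
# ---------------------------------------------------------------------------


def record(sample, gene, synonymous=False, vclass=VariantClass.SNP):
    ref, alt = ("C", "T") if vclass is VariantClass.SNP else ("AT", "A")
    return MutationRecord(
        sample_id=sample, gene=gene, chrom="1", pos=100, ref_allele=ref,
        alt_allele=alt, variant_class=vclass, is_synonymous=synonymous,
        vaf=0.5, depth=50, flank5="C", flank3="T",
    )


class TestMutationMatrix:
    def test_presence_is_idempotent(self):
        m = build_mutation_matrix(
            [record("S1", "BRAF"), record("S1", "BRAF")], ["BRAF"], ["S1", "S2"]
        )
        assert m.loc["BRAF", "S1"] and not m.loc["BRAF", "S2"]

    def test_synonymous_never_sets_a_bit(self):
        m = build_mutation_matrix(
            [record("S1", "BRAF", synonymous=True)], ["BRAF"], ["S1"]
        )
        assert not m.loc["BRAF", "S1"]

    def test_empty_records_all_false(self):
        m = build_mutation_matrix([], ["BRAF", "NRAS"], ["S1"])
        assert not m.to_numpy().any()

    def test_duplicate_samples_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_mutation_matrix([], ["BRAF"], ["S1", "S1"])


class TestDifferentialMutation:
    def make_matrices(self, k_a, n_a, k_b, n_b, gene="G"):
        a = pd.DataFrame(
            [[j < k_a for j in range(n_a)]], index=[gene],
            columns=[f"A{j}" for j in range(n_a)],
        )
        b = pd.DataFrame(
            [[j < k_b for j in range(n_b)]], index=[gene],
            columns=[f"B{j}" for j in range(n_b)],
        )
        return a, b

    def test_reproduces_extreme_differential_gene(self):
        # 41/53 vs 0/412 with universe multiplier 1192
        a, b = self.make_matrices(41, 53, 0, 412)
        res = differential_mutation_test(a, b, min_mutated=5, multiplier=1192)
        assert len(res) == 1
        assert res[0].p_adjusted == pytest.approx(2.82e-45, rel=5e-3)

    def test_min_mutated_excludes_rare_genes(self):
        a, b = self.make_matrices(3, 10, 1, 10)
        assert differential_mutation_test(a, b, min_mutated=5) == []
        assert len(differential_mutation_test(a, b, min_mutated=4)) == 1

    def test_adjusted_is_capped_min_of_one(self):
        a, b = self.make_matrices(5, 50, 41, 410)
        res = differential_mutation_test(a, b, min_mutated=5, multiplier=100)
        assert res[0].p_raw == pytest.approx(1.0)
        assert res[0].p_adjusted == 1.0

    def test_low_multiplier_warns(self):
        a, b = self.make_matrices(10, 20, 1, 20)
        with pytest.warns(UserWarning, match="multiplier"):
            differential_mutation_test(a, b, min_mutated=5, multiplier=0)


class TestExclusivityPairs:
    def make_matrix(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(8)]
        samples = [f"S{j}" for j in range(60)]
        return pd.DataFrame(
            rng.random((8, 60)) < 0.3, index=genes, columns=samples
        )

    def test_eight_genes_give_28_pairs(self):
        res = pair_exclusivity_test(self.make_matrix(), [f"G{i}" for i in range(8)])
        assert len(res) == 28
        assert all(r.multiplier == 28 for r in res)

    def test_table_construction_from_matrix(self):
        m = pd.DataFrame(
            [[True, True, False, False], [True, False, True, False]],
            index=["G1", "G2"], columns=["S1", "S2", "S3", "S4"],
        )
        t = table_from_matrix(m, "G1", "G2")
        assert (t.neither, t.gene2_only, t.gene1_only, t.both) == (1, 1, 1, 1)

    def test_absent_gene_named_in_error(self):
        with pytest.raises(KeyError, match="NOPE"):
            pair_exclusivity_test(self.make_matrix(), ["G1", "NOPE"])

    def test_planted_exclusive_pair_detected(self):
        # margins ~200 and ~120 of 400 with both = 8: far below independence
        n, m1, m2, both = 400, 200, 120, 8
        g1 = [True] * m1 + [False] * (n - m1)
        g2 = (
            [True] * both + [False] * (m1 - both)
            + [True] * (m2 - both) + [False] * (n - m1 - m2 + both)
        )
        m = pd.DataFrame(
            [g1, g2], index=["A", "B"], columns=[f"S{j}" for j in range(n)]
        )
        res = pair_exclusivity_test(m, ["A", "B"], multiplier=28)
        assert res[0].p_adjusted < 0.05


# ---------------------------------------------------------------------------
# burden and UV
# ---------------------------------------------------------------------------


class TestBurden:
    def test_per_mb_and_log2(self):
        records = [record("S1", f"G{i}") for i in range(30)]
        b = mutation_burden(records, breadth_bp=30_000_000, sample_id="S1")
        assert b.per_mb == pytest.approx(1.0)
        assert b.log2_per_mb == pytest.approx(0.0)
        b2 = mutation_burden(records * 2, breadth_bp=30_000_000)
        assert b2.log2_per_mb == pytest.approx(1.0)

    def test_synonymous_included(self):
        records = [record("S1", "G1"), record("S1", "G2", synonymous=True)]
        assert mutation_burden(records, 1_000_000).n_mutations == 2

    def test_vaf_filter_applies(self):
        low = MutationRecord(
            "S1", "G1", "1", 5, "C", "T", VariantClass.SNP, False,
            vaf=0.09, depth=100,
        )
        assert mutation_burden([low, record("S1", "G2")], 1_000_000).n_mutations == 1

    def test_zero_breadth_errors(self):
        with pytest.raises(ValueError):
            mutation_burden([], 0)

    def test_scaling_invariance(self):
        records = [record("S1", f"G{i}") for i in range(12)]
        b1 = mutation_burden(records, 2_000_000)
        b3 = mutation_burden(records * 3, 6_000_000)
        assert b1.per_mb == pytest.approx(b3.per_mb)

    def test_empty_track_breadth_zero(self):
        track = CoverageTrack("S1", "intervals", intervals=[])
        assert coverage_breadth(track) == 0


def sub(ref, alt, f5, f3, vclass=VariantClass.SNP):
    return MutationRecord(
        "S1", "G1", "1", 10, ref, alt, vclass, False, vaf=0.5, depth=50,
        flank5=f5, flank3=f3,
    )


class TestUVSignature:
    def test_sixty_percent_branch(self):
        records = [sub("C", "T", "C", "A") for _ in range(7)] + [
            sub("A", "C", "G", "G") for _ in range(3)
        ]
        u = uv_signature(records)
        assert u.n_substitutions == 10
        assert u.frac_ct_dipyrimidine == pytest.approx(0.7)
        assert u.is_uv

    def test_cc_tt_branch(self):
        records = (
            [sub("CC", "TT", "A", "A", VariantClass.DNP) for _ in range(5)]
            + [sub("C", "T", "T", "A") for _ in range(10)]
            + [sub("T", "G", "A", "A") for _ in range(85)]
        )
        u = uv_signature(records)
        assert u.frac_cc_tt == pytest.approx(0.05)
        assert u.frac_ct_dipyrimidine == pytest.approx(0.10)
        assert u.is_uv

    def test_non_uv_spectrum_negative(self):
        records = [sub("A", "G", "C", "C") for _ in range(20)]
        u = uv_signature(records)
        assert u.frac_ct_dipyrimidine == 0.0
        assert u.frac_cc_tt == 0.0
        assert not u.is_uv

    def test_strand_normalization_g_to_a(self):
        # G>A on the plus strand is C>T on the pyrimidine strand; the 3'
        # flank complements to the 5' side
        plus = sub("G", "A", "T", "G")  # complement: C>T with flank5 C
        u = uv_signature([plus])
        assert u.frac_ct_dipyrimidine == 1.0

    def test_unknown_context_counted_separately(self):
        records = [sub("C", "T", None, None), sub("C", "T", "T", "A")]
        u = uv_signature(records)
        assert u.n_substitutions == 1
        assert u.n_context_unknown == 1

    def test_indels_excluded_everywhere(self):
        records = [sub("AT", "A", None, None, VariantClass.DEL)]
        u = uv_signature(records)
        assert u.n_substitutions == 0 and not u.is_uv

    def test_five_prime_only_mode(self):
        r = sub("C", "T", "A", "T")  # pyrimidine only on the 3' side
        assert uv_signature([r], either_flank=True).frac_ct_dipyrimidine == 1.0
        assert uv_signature([r], either_flank=False).frac_ct_dipyrimidine == 0.0
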