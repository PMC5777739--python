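"""Segment projection, FGA, and copy-number correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genoconcord.copy_number import (
    correlation_to_mean_profile,
    fga,
    pairwise_gene_cn_correlation,
    project_segments_to_genes,
)
from genoconcord.io_formats import GeneModel, SegmentProfile


def profile(segments, sample_id="S1"):
    return SegmentProfile(sample_id, segments)


class TestProjection:
    def test_gene_inside_one_segment_carries_its_value(self):
        model = GeneModel([("G1", "1", 100, 200)])
        p = profile([("1", 1, 1000, 0.7)])
        cn = project_segments_to_genes([p], model)
        assert cn.loc["G1", "S1"] == pytest.approx(0.7)

    def test_boundary_spanning_gene_overlap_weighted(self):
        # gene 100..299 (200 bp): 50 bp in a 0.0 segment, 150 bp in a 0.4 one
        model = GeneModel([("G1", "1", 100, 299)])
        p = profile([("1", 1, 149, 0.0), ("1", 150, 1000, 0.4)])
        cn = project_segments_to_genes([p], model)
        assert cn.loc["G1", "S1"] == pytest.approx((50 * 0.0 + 150 * 0.4) / 200)

    def test_drop_xy(self):
        model = GeneModel([("GA", "1", 100, 200), ("GX", "X", 100, 200)])
        p = profile([("1", 1, 1000, 0.5), ("X", 1, 1000, 0.5)])
        cn = project_segments_to_genes([p], model, drop_xy=True)
        assert list(cn.index) == ["GA"]
        cn_keep = project_segments_to_genes([p], model, drop_xy=False)
        assert list(cn_keep.index) == ["GA", "GX"]

    def test_no_overlap_is_missing(self):
        model = GeneModel([("G1", "1", 5000, 6000)])
        p = profile([("1", 1, 1000, 0.5)])
        cn = project_segments_to_genes([p], model)
        assert np.isnan(cn.loc["G1", "S1"])


class TestFga:
    def test_all_below_threshold(self):
        r = fga(profile([("1", 1, 1000, 0.1), ("2", 1, 1000, -0.15)]), 0.2)
        assert r.fga == 0.0

    def test_all_above_threshold(self):
        r = fga(profile([("1", 1, 1000, 0.5), ("2", 1, 1000, -0.9)]), 0.2)
        assert r.fga == 1.0

    def test_length_weighting(self):
        # 3 Mb at |mean| 0.5 and 1 Mb at |mean| 0.1, T = 0.2 -> 0.75
        r = fga(
            profile([("1", 1, 3_000_000, 0.5), ("1", 3_000_001, 4_000_000, 0.1)]),
            0.2,
        )
        assert r.fga == pytest.approx(3_000_000 / 4_000_000)

    def test_strict_inequality_at_threshold(self):
        p = profile([("1", 1, 1000, 0.2)])
        assert fga(p, 0.2).fga == 0.0
        assert fga(p, 0.2, inclusive=True).fga == 1.0

    def test_sex_chromosomes_excluded(self):
        r = fga(profile([("1", 1, 1000, 0.0), ("X", 1, 10_000, 5.0)]), 0.2)
        assert r.fga == 0.0
        assert r.total_length == 1000

    def test_empty_profile_errors(self):
        with pytest.raises(ValueError):
            fga(profile([]), 0.2)

    @given(
        means=st.lists(
            st.floats(-2, 2, allow_nan=False), min_size=1, max_size=8
        ),
        split=st.integers(1, 999),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_segment_subdivision(self, means, split):
        segs = [
            ("1", i * 1000 + 1, (i + 1) * 1000, m) for i, m in enumerate(means)
        ]
        whole = fga(profile(segs), 0.2).fga
        first = segs[0]
        subdivided = [
            ("1", first[1], first[1] + split - 1, first[3]),
            ("1", first[1] + split, first[2], first[3]),
        ] + segs[1:]
        assert fga(profile(subdivided), 0.2).fga == pytest.approx(whole, abs=1e-12)


def grid_model(n_genes=5):
    return GeneModel([(f"G{i}", "1", i * 1000 + 1, i * 1000 + 500) for i in range(n_genes)])


def matrix_from(values, genes, samples):
    return pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=samples)


class TestPairwiseCorrelation:
    genes = [f"G{i}" for i in range(5)]

    def test_identical_profiles_r_one(self):
        a = matrix_from([[1], [2], [3], [4], [5]], self.genes, ["A"])
        r, n = pairwise_gene_cn_correlation(a, a.rename(columns={"A": "B"}))
        assert r.loc["A", "B"] == pytest.approx(1.0)
        assert n.loc["A", "B"] == 5

    def test_negated_profile_r_minus_one(self):
        a = matrix_from([[1], [2], [3], [4], [5]], self.genes, ["A"])
        b = -a.rename(columns={"A": "B"})
        r, _ = pairwise_gene_cn_correlation(a, b)
        assert r.loc["A", "B"] == pytest.approx(-1.0)

    def test_known_five_gene_value(self):
        # hand covariance: r = 6 / sqrt(10 * 6); scipy as independent check
        from scipy.stats import pearsonr

        a = matrix_from([[1], [2], [3], [4], [5]], self.genes, ["A"])
        b = matrix_from([[2], [4], [5], [4], [5]], self.genes, ["B"])
        r, _ = pairwise_gene_cn_correlation(a, b)
        expected = 6 / np.sqrt(60)
        assert r.loc["A", "B"] == pytest.approx(expected, rel=1e-12)
        assert r.loc["A", "B"] == pytest.approx(
            pearsonr(a["A"], b["B"]).statistic, rel=1e-12
        )

    def test_too_few_genes_is_missing_with_count(self):
        a = matrix_from([[1], [2], [np.nan], [np.nan], [np.nan]], self.genes, ["A"])
        b = matrix_from([[2], [4], [5], [4], [5]], self.genes, ["B"])
        r, n = pairwise_gene_cn_correlation(a, b)
        assert np.isnan(r.loc["A", "B"])
        assert n.loc["A", "B"] == 2

    def test_zero_variance_is_missing(self):
        a = matrix_from([[1], [1], [1], [1], [1]], self.genes, ["A"])
        b = matrix_from([[2], [4], [5], [4], [5]], self.genes, ["B"])
        r, _ = pairwise_gene_cn_correlation(a, b)
        assert np.isnan(r.loc["A", "B"])

    def test_gene_subset_restriction(self):
        a = matrix_from([[1], [2], [3], [4], [5]], self.genes, ["A"])
        b = matrix_from([[1], [2], [3], [-4], [-5]], self.genes, ["B"])
        r_all, _ = pairwise_gene_cn_correlation(a, b)
        r_sub, n_sub = pairwise_gene_cn_correlation(
            a, b, gene_subset=["G0", "G1", "G2"]
        )
        assert r_sub.loc["A", "B"] == pytest.approx(1.0)
        assert n_sub.loc["A", "B"] == 3
        assert r_all.loc["A", "B"] < 1.0

    def test_sample_reordering_invariance(self):
        rng = np.random.default_rng(11)
        a = matrix_from(rng.normal(size=(5, 3)), self.genes, ["A1", "A2", "A3"])
        b = matrix_from(rng.normal(size=(5, 2)), self.genes, ["B1", "B2"])
        r1, _ = pairwise_gene_cn_correlation(a, b)
        r2, _ = pairwise_gene_cn_correlation(a[["A3", "A1", "A2"]], b)
        assert r2.loc["A1", "B1"] == pytest.approx(r1.loc["A1", "B1"])


class TestMeanProfileCorrelation:
    genes = [f"G{i}" for i in range(5)]

    def test_single_sample_b_equals_pairwise(self):
        rng = np.random.default_rng(5)
        a = matrix_from(rng.normal(size=(5, 2)), self.genes, ["A1", "A2"])
        b = matrix_from(rng.normal(size=(5, 1)), self.genes, ["B1"])
        pair, _ = pairwise_gene_cn_correlation(a, b)
        mean = correlation_to_mean_profile(a, b).set_index("sample_id")
        for s in ("A1", "A2"):
            assert mean.loc[s, "r"] == pytest.approx(pair.loc[s, "B1"])

    def test_identical_b_samples(self):
        rng = np.random.default_rng(6)
        col = rng.normal(size=5)
        a = matrix_from(rng.normal(size=(5, 1)), self.genes, ["A1"])
        b = matrix_from(np.column_stack([col, col, col]), self.genes, ["B1", "B2", "B3"])
        pair, _ = pairwise_gene_cn_correlation(a, b)
        mean = correlation_to_mean_profile(a, b).set_index("sample_id")
        assert mean.loc["A1", "r"] == pytest.approx(pair.loc["A1", "B1"])

    def test_mean_profile_beats_mean_pairwise_on_shared_signal(self, default_cohort):
        # averaging tumors cancels independent noise, so a cell line sharing
        # the planted focal events correlates better with the tumor mean
        from genoconcord.copy_number import project_segments_to_genes

        model = default_cohort.gene_model
        t_cn = project_segments_to_genes(default_cohort.tumor_segments, model)
        c_cn = project_segments_to_genes(default_cohort.cell_line_segments, model)
        pair, _ = pairwise_gene_cn_correlation(c_cn, t_cn)
        mean = correlation_to_mean_profile(c_cn, t_cn).set_index("sample_id")
        assert mean["r"].mean() > pair.mean(axis=1).mean()


def test_shared_event_fraction_drives_concordance():
    """Mean pairwise r rises monotonically with the planted shared-event
    fraction at a fixed seed."""
    from genoconcord.synthetic import (
        SyntheticCohortConfig,
        focal_events_with_shared_fraction,
        simulate_cohort,
    )

    from dataclasses import replace

    means = []
    for q in (0.0, 0.25, 0.5, 0.75, 1.0):
        base = SyntheticCohortConfig(
            seed=421, n_tumors=12, n_cell_lines=6, background_cn_sd=0.1,
            background_mut_rate=1.0, generate_coverage=False,
        )
        cfg = replace(base, focal_events=focal_events_with_shared_fraction(base, q))
        cohort = simulate_cohort(cfg)
        t_cn = project_segments_to_genes(cohort.tumor_segments, cohort.gene_model)
        c_cn = project_segments_to_genes(cohort.cell_line_segments, cohort.gene_model)
        r, _ = pairwise_gene_cn_correlation(c_cn, t_cn)
        means.append(float(np.nanmean(r.to_numpy())))
    assert all(a < b for a, b in zip(means, means[1:]))
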