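"""Synthetic-data generator: ground-truth construction and sampling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gadnet
from gadnet import gad7
from gadnet.synth import (
    DagTruth,
    LikertConfig,
    apply_inclusion_filter,
    build_ggm_truth,
    dag_latent_covariance,
    default_config,
    default_thresholds,
    sample_likert_from_dag,
    sample_likert_from_ggm,
)


class TestBuildGgmTruth:
    def test_no_edges_gives_identity_precision(self):
        t = build_ggm_truth(3, [])
        assert np.allclose(t.precision, np.eye(3))
        assert np.allclose(t.partial_corr, 0.0)

    def test_reference_structure_reproduced_exactly(self, published_net):
        t = gadnet.reference_ggm_truth()
        assert np.max(np.abs(t.partial_corr - published_net.weights)) < 1e-6

    def test_single_edge_matches_inversion_oracle(self):
        t = build_ggm_truth(3, [(0, 1, 0.5)])
        # oracle: invert precision by hand and standardize
        K = t.precision
        w01 = -K[0, 1] / np.sqrt(K[0, 0] * K[1, 1])
        assert w01 == pytest.approx(0.5, abs=1e-9)
        assert t.partial_corr[0, 2] == 0.0

    def test_precision_is_positive_definite(self):
        t = build_ggm_truth(4, [(0, 1, 0.6), (1, 2, 0.6), (2, 3, 0.6)])
        assert np.linalg.eigvalsh(t.precision).min() >= 0.05 - 1e-8
        assert np.allclose(t.partial_corr[0, 1], 0.6, atol=1e-8)

    def test_infeasible_weights_fail_with_magnitude(self):
        with pytest.raises(ValueError, match="0.9"):
            build_ggm_truth(3, [(0, 1, 0.9), (1, 2, 0.9), (0, 2, 0.9)])


class TestSampleFromGgm:
    def test_quartile_thresholds_give_uniform_levels(self):
        t = build_ggm_truth(3, [])
        th = np.tile(stats.norm.ppf([0.25, 0.5, 0.75]), (3, 1))
        cfg = LikertConfig(n=100_000, thresholds=th, inclusion_min_total=None)
        d = sample_likert_from_ggm(t, cfg, seed=0)
        freqs = d.apply(lambda c: c.value_counts(normalize=True)).to_numpy()
        assert np.max(np.abs(freqs - 0.25)) < 0.01

    def test_empty_after_filter_keeps_labels(self):
        t = build_ggm_truth(7, [])
        th = np.tile([2.0, 2.5, 3.0], (7, 1))  # level 0 nearly certain
        cfg = LikertConfig(n=50, thresholds=th, inclusion_min_total=21)
        d = sample_likert_from_ggm(t, cfg, seed=0)
        assert len(d) == 0
        assert list(d.columns) == list(gad7.ITEM_LABELS)

    def test_seed_determinism(self, reference_truth):
        cfg = default_config(n=500)
        a = sample_likert_from_ggm(reference_truth, cfg, seed=9)
        b = sample_likert_from_ggm(reference_truth, cfg, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_unfiltered_means_match_published_descriptives(self, reference_truth):
        cfg = default_config(n=20_000, inclusion_min_total=None)
        d = sample_likert_from_ggm(reference_truth, cfg, seed=3)
        for item, mean in gad7.ITEM_MEANS.items():
            assert d[item].mean() == pytest.approx(mean, abs=0.1)

    def test_sample_spearman_matches_population_oracle(self, reference_truth, cohort_5000):
        """Sample Spearman vs numerically integrated population value.

        The population Spearman of two discretized latent-normal items is
        the Pearson correlation of their midrank scores under the exact
        cell probabilities (bivariate-normal rectangle masses).
        """
        cov = reference_truth.covariance()
        th = default_thresholds()
        sample = gadnet.spearman_matrix(cohort_5000).values
        for i, j in [(0, 1), (3, 4), (0, 6), (2, 5)]:
            pop = _population_spearman(cov[i, j], th[i], th[j])
            assert sample[i, j] == pytest.approx(pop, abs=0.05)


def _population_spearman(rho, th_x, th_y):
    from scipy.stats import multivariate_normal

    edges_x = np.concatenate([[-np.inf], th_x, [np.inf]])
    edges_y = np.concatenate([[-np.inf], th_y, [np.inf]])
    bvn = multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])

    def boxp(a0, a1, b0, b1):
        def F(x, y):
            if np.isinf(x) and x < 0 or np.isinf(y) and y < 0:
                return 0.0
            return bvn.cdf([min(x, 40), min(y, 40)])

        return F(a1, b1) - F(a0, b1) - F(a1, b0) + F(a0, b0)

    P = np.array(
        [
            [boxp(edges_x[a], edges_x[a + 1], edges_y[b], edges_y[b + 1]) for b in range(4)]
            for a in range(4)
        ]
    )
    px, py = P.sum(axis=1), P.sum(axis=0)
    # midrank score of level k: F(k-1) + p_k/2
    mx = np.cumsum(px) - px / 2
    my = np.cumsum(py) - py / 2
    ex, ey = px @ mx, py @ my
    cov_xy = sum(P[a, b] * (mx[a] - ex) * (my[b] - ey) for a in range(4) for b in range(4))
    vx = px @ (mx - ex) ** 2
    vy = py @ (my - ey) ** 2
    return cov_xy / np.sqrt(vx * vy)


class TestSampleFromDag:
    def test_zero_coefficient_gives_independence(self):
        t = DagTruth(p=2, arcs=[(0, 1)], coefficients=[0.0], seed=0)
        cfg = default_config(n=4000, inclusion_min_total=None)
        cfg = LikertConfig(n=4000, thresholds=default_thresholds()[:2], inclusion_min_total=None)
        d = sample_likert_from_dag(t, cfg, seed=0)
        r = stats.spearmanr(d.iloc[:, 0], d.iloc[:, 1]).statistic
        assert abs(r) < 0.05

    def test_chain_latent_correlation_matches_path_tracing(self):
        t = DagTruth(p=3, arcs=[(0, 1), (1, 2)], coefficients=[0.8, 0.8], seed=0)
        cov = dag_latent_covariance(t)
        # path tracing: cov(A,C) = 0.64; var(C) = 0.64*1.64 + 1
        assert cov[0, 2] == pytest.approx(0.64, abs=1e-12)
        r_ac = cov[0, 2] / np.sqrt(cov[0, 0] * cov[2, 2])
        assert r_ac == pytest.approx(0.64 / np.sqrt(0.8**2 * 1.64 + 1), abs=1e-12)
        # discretized data keeps the ordering of associations
        cfg = LikertConfig(n=6000, thresholds=default_thresholds()[:3], inclusion_min_total=None)
        d = sample_likert_from_dag(t, cfg, seed=4)
        r_ab = stats.spearmanr(d.iloc[:, 0], d.iloc[:, 1]).statistic
        r_ac_s = stats.spearmanr(d.iloc[:, 0], d.iloc[:, 2]).statistic
        assert r_ab > r_ac_s > 0.3

    def test_cycle_raises_naming_an_arc(self):
        with pytest.raises(ValueError, match="cycle"):
            DagTruth(p=3, arcs=[(0, 1), (1, 2), (2, 0)], coefficients=[0.5] * 3)

    def test_seed_determinism(self):
        t = DagTruth(p=3, arcs=[(0, 1)], coefficients=[0.7], seed=0)
        cfg = LikertConfig(n=300, thresholds=default_thresholds()[:3], inclusion_min_total=None)
        a = sample_likert_from_dag(t, cfg, seed=5)
        b = sample_likert_from_dag(t, cfg, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestInclusionFilter:
    def test_boundary_is_inclusive(self):
        d = pd.DataFrame({"a": [3, 4, 4], "b": [4, 4, 5]})
        # totals 7, 8, 9 with min_total 8 keep exactly two rows
        d7 = pd.DataFrame(np.column_stack([d, np.zeros((3, 5), int)]),
                          columns=list("abcdefg"))
        kept = apply_inclusion_filter(d7, 8)
        assert len(kept) == 2
        assert kept.iloc[0].sum() == 8

    def test_zero_threshold_is_identity(self):
        d = pd.DataFrame(np.random.default_rng(0).integers(0, 4, (20, 7)))
        pd.testing.assert_frame_equal(apply_inclusion_filter(d, 0), d)

    def test_retained_fraction_matches_convolution_oracle(self):
        rng = np.random.default_rng(1)
        d = pd.DataFrame(rng.integers(0, 4, (10_000, 7)))
        kept = apply_inclusion_filter(d, 8)
        # exact distribution of the total of 7 iid uniform{0..3} items
        dist = np.array([1.0])
        for _ in range(7):
            dist = np.convolve(dist, np.full(4, 0.25))
        p_keep = dist[8:].sum()
        se = np.sqrt(p_keep * (1 - p_keep) / 10_000)
        assert len(kept) / 10_000 == pytest.approx(p_keep, abs=4 * se)

    def test_monotone_in_threshold(self):
        d = pd.DataFrame(np.random.default_rng(2).integers(0, 4, (500, 7)))
        counts = [len(apply_inclusion_filter(d, m)) for m in range(0, 22, 3)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
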