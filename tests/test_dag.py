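"""BIC scoring, hill-climb search and bootstrap model averaging."""

import math

import numpy as np
import pandas as pd
import pytest

import gadnet
from gadnet.dag import (
    DagEnsemble,
    DagModel,
    GaussianBicScorer,
    average_dag,
    bic_score,
    bootstrap_dags,
    hill_climb,
    optimal_cutoff,
)
from gadnet.synth import DagTruth, LikertConfig, default_thresholds, sample_likert_from_dag


def _gauss(rng, n):
    return rng.normal(size=n)


class TestBicScore:
    def test_empty_dag_matches_closed_form(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(500, 3))
        dag = DagModel(labels=["a", "b", "c"], arcs=[], score=0.0)
        got = bic_score(X, dag)
        Xc = X - X.mean(axis=0)
        expect = 0.0
        for j in range(3):
            s2 = (Xc[:, j] ** 2).mean()
            expect += -0.5 * 500 * (math.log(2 * math.pi * s2) + 1) - 0.5 * 2 * math.log(500)
        assert got == pytest.approx(expect, rel=1e-12)

    def test_true_parent_arc_increases_score(self):
        rng = np.random.default_rng(1)
        x = _gauss(rng, 1000)
        y = 0.8 * x + _gauss(rng, 1000)
        X = np.column_stack([x, y])
        empty = bic_score(X, DagModel(labels=["x", "y"], arcs=[], score=0.0))
        with_arc = bic_score(X, DagModel(labels=["x", "y"], arcs=[("x", "y")], score=0.0))
        assert with_arc > empty

    def test_null_arc_cost_is_half_log_n(self):
        rng = np.random.default_rng(2)
        n = 2000
        deltas = []
        for _ in range(60):
            X = rng.normal(size=(n, 2))
            empty = bic_score(X, DagModel(labels=["x", "y"], arcs=[], score=0.0))
            full = bic_score(X, DagModel(labels=["x", "y"], arcs=[("x", "y")], score=0.0))
            deltas.append(full - empty)
        # E[delta] = E[chi2_1]/2 - log(n)/2 = 0.5 - log(n)/2
        assert np.mean(deltas) == pytest.approx(0.5 - 0.5 * math.log(n), abs=0.5)

    def test_cyclic_input_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            DagModel(labels=["a", "b"], arcs=[("a", "b"), ("b", "a")], score=0.0)


class TestHillClimb:
    def test_single_arc_recovered(self):
        rng = np.random.default_rng(3)
        x = _gauss(rng, 2000)
        y = 0.8 * x + _gauss(rng, 2000)
        z = _gauss(rng, 2000)
        m = hill_climb(np.column_stack([x, y, z]), restarts=5, perturbations=20, seed=0)
        assert m.skeleton() == {frozenset({"V1", "V2"})}

    def test_independent_columns_stay_mostly_empty(self):
        # a spurious arc enters when a pair's chi-square deviance exceeds
        # log n; with 10 pairs at n=1000 that leaves P(empty) ~ 0.92
        rng = np.random.default_rng(4)
        empty = 0
        for s in range(20):
            X = rng.normal(size=(1000, 5))
            m = hill_climb(X, restarts=3, perturbations=15, seed=s)
            empty += len(m.arcs) == 0
        assert empty >= 16

    def test_chain_skeleton_recovered_on_continuous_data(self):
        truth = DagTruth(p=7, arcs=[(i, i + 1) for i in range(6)], coefficients=[0.5] * 6)
        from gadnet.synth import dag_latent_covariance

        cov = dag_latent_covariance(truth)
        want = {frozenset({f"V{i+1}", f"V{i+2}"}) for i in range(6)}
        hits = 0
        for s in range(5):
            rng = np.random.default_rng(60 + s)
            X = rng.multivariate_normal(np.zeros(7), cov, size=5000)
            m = hill_climb(X, restarts=10, perturbations=40, seed=s)
            hits += m.skeleton() == want
        assert hits >= 4

    def test_score_beats_empty_model_and_is_deterministic(self):
        rng = np.random.default_rng(5)
        x = _gauss(rng, 800)
        X = np.column_stack([x, 0.7 * x + _gauss(rng, 800), _gauss(rng, 800)])
        m1 = hill_climb(X, restarts=5, perturbations=20, seed=9)
        m2 = hill_climb(X, restarts=5, perturbations=20, seed=9)
        assert m1.arcs == m2.arcs and m1.score == m2.score
        assert m1.score > bic_score(X, DagModel(labels=m1.labels, arcs=[], score=0.0))

    def test_deletion_strengths_negative_for_supportive_arcs(self):
        rng = np.random.default_rng(6)
        x = _gauss(rng, 2000)
        y = 0.8 * x + _gauss(rng, 2000)
        m = hill_climb(np.column_stack([x, y]), restarts=2, perturbations=10, seed=0)
        assert all(v < 0 for v in m.strength.values())


class TestBootstrapAveraging:
    def test_ensemble_deterministic(self):
        rng = np.random.default_rng(7)
        x = _gauss(rng, 400)
        X = np.column_stack([x, 0.8 * x + _gauss(rng, 400), _gauss(rng, 400)])
        a = bootstrap_dags(X, B=100, seed=1, restarts=2, perturbations=10)
        b = bootstrap_dags(X, B=100, seed=1, restarts=2, perturbations=10)
        assert a.presence == b.presence and a.forward == b.forward

    def test_true_pair_frequency_high_and_directions_sum_to_one(self):
        rng = np.random.default_rng(8)
        x = _gauss(rng, 800)
        X = np.column_stack([x, 0.8 * x + _gauss(rng, 800), _gauss(rng, 800)])
        ens = bootstrap_dags(X, B=100, seed=2, restarts=3, perturbations=15)
        freqs = ens.frequencies()
        assert freqs.get((0, 1), 0.0) >= 0.9
        for pair in ens.presence:
            f, r = ens.direction_split(pair)
            assert f + r == pytest.approx(1.0)

    def test_end_to_end_single_arc_recovery(self):
        rng = np.random.default_rng(9)
        x = _gauss(rng, 800)
        X = np.column_stack([x, 0.8 * x + _gauss(rng, 800), _gauss(rng, 800)])
        ens = bootstrap_dags(X, B=100, seed=3, restarts=3, perturbations=15)
        avg = average_dag(ens, X)
        assert {frozenset(a) for a in avg.arcs} == {frozenset({"V1", "V2"})}
        (arc,) = avg.arcs
        assert avg.direction_probability[arc] > 0.5


class TestOptimalCutoff:
    def test_two_cluster_frequencies_separated(self):
        t = optimal_cutoff([0.05, 0.06, 0.95, 0.97])
        kept = [f for f in [0.05, 0.06, 0.95, 0.97] if f > t]
        assert kept == [0.95, 0.97]

    def test_all_equal_returns_that_value(self):
        assert optimal_cutoff([0.7, 0.7, 0.7]) == pytest.approx(0.7)

    def test_zero_one_split(self):
        t = optimal_cutoff([0.0, 1.0])
        assert 0.0 <= t < 1.0
        assert [f for f in (0.0, 1.0) if f > t] == [1.0]

    def test_noise_heavy_ensemble_keeps_only_signal(self):
        freqs = [0.1, 0.15, 0.2, 0.12, 0.08, 0.3, 0.25, 0.95, 0.98, 1.0]
        t = optimal_cutoff(freqs)
        assert 0.3 <= t < 0.95


class TestAverageDag:
    def _ensemble(self, presence, forward, labels=("a", "b", "c")):
        return DagEnsemble(B=200, labels=list(labels), presence=presence, forward=forward, seed=0)

    def test_majority_direction_and_probability(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(300, 3))
        ens = self._ensemble({(0, 1): 200, (1, 2): 10}, {(0, 1): 130, (1, 2): 5})
        avg = average_dag(ens, X)
        assert avg.arcs == [("a", "b")]
        assert avg.direction_probability[("a", "b")] == pytest.approx(0.65)
        assert avg.direction_uncertain == set()

    def test_exact_tie_is_flagged_direction_uncertain(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(300, 3))
        ens = self._ensemble({(0, 1): 200, (1, 2): 10}, {(0, 1): 100, (1, 2): 5})
        avg = average_dag(ens, X)
        (arc,) = avg.arcs
        assert avg.direction_probability[arc] == pytest.approx(0.5)
        assert arc in avg.direction_uncertain

    def test_cycle_from_majority_orientation_resolved(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(300, 3))
        # all three pairs kept; majority directions form a->b->c->a
        ens = self._ensemble(
            {(0, 1): 200, (1, 2): 180, (0, 2): 160},
            {(0, 1): 150, (1, 2): 140, (0, 2): 20},
        )
        avg = average_dag(ens, X)
        # weakest link (a-c, frequency 0.8) is dropped to break the cycle
        assert {frozenset(a) for a in avg.arcs} == {frozenset({"a", "b"}), frozenset({"b", "c"})}

    def test_output_is_acyclic_and_exports(self, tmp_path):
        rng = np.random.default_rng(13)
        x = _gauss(rng, 500)
        X = np.column_stack([x, 0.8 * x + _gauss(rng, 500), 0.6 * x + _gauss(rng, 500)])
        ens = bootstrap_dags(X, B=100, seed=4, restarts=3, perturbations=15)
        avg = average_dag(ens, X)  # DagModel.__post_init__ verifies acyclicity
        avg.to_csv(tmp_path / "dag.csv")
        avg.to_dot(tmp_path / "dag.dot")
        df = pd.read_csv(tmp_path / "dag.csv")
        assert list(df.columns)[:4] == ["from", "to", "strength_bic", "direction_probability"]
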