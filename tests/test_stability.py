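"""Consistency/relevance filtering and correlation-graph clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from splitclust import (
    AnalysisConfig,
    Cohort,
    CorrelationMatrixPair,
    StabilityReport,
    SyntheticConfig,
    Variable,
    VariableSchema,
    classify_consistency,
    correlation_matrices,
    filter_pairs,
    find_clusters,
    generate_cohort,
    stratified_analysis,
)
from splitclust.stability import masked_heatmap_frame

from conftest import make_cohort, spawned_seeds


def tiny_schema(markers=("A", "B", "C", "D")):
    vs = [Variable(m, "biomarker", "continuous") for m in markers]
    vs += [
        Variable("CVS", "group_label", "binary"),
        Variable("set", "set_label", "ordinal", levels=("training", "validation")),
    ]
    return VariableSchema(tuple(vs), correlation_variables=tuple(markers))


def pair_matrix(variables, r_train, r_val, r_combined):
    """Build a CorrelationMatrixPair from dense symmetric matrices."""
    return CorrelationMatrixPair(
        tuple(variables),
        np.asarray(r_train, float),
        np.asarray(r_val, float),
        np.asarray(r_combined, float),
    )


def two_var_matrices(rt, rv, rc):
    def m(r):
        return np.array([[1.0, r], [r, 1.0]])

    return pair_matrix(("A", "B"), m(rt), m(rv), m(rc))


def report_from_edges(edges):
    """Minimal retained-pair report for cluster tests."""
    rows = [
        {"var_i": a, "var_j": b, "r_train": 0.5, "r_val": 0.5,
         "r_combined": 0.5, "consistent": True, "relevant": True,
         "retained": True}
        for a, b in edges
    ]
    return StabilityReport(pd.DataFrame(
        rows, columns=["var_i", "var_j", "r_train", "r_val", "r_combined",
                       "consistent", "relevant", "retained"]
    ), 0.25, 0.25)


def components_oracle(edges, vertices=None):
    """Brute-force union-find connected components."""
    parent = {}

    def find(u):
        parent.setdefault(u, u)
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for a, b in edges:
        parent[find(a)] = find(b)
    comps = {}
    for v in vertices or list(parent):
        comps.setdefault(find(v), set()).add(v)
    return [frozenset(c) for c in comps.values()]


class TestCorrelationMatrices:
    def test_diagonal_and_antithetic_pair(self, schema):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        df = pd.DataFrame({"A": x, "B": -x, "C": rng.normal(size=40),
                           "D": rng.normal(size=40),
                           "CVS": 1, "set": ["training"] * 25 + ["validation"] * 15})
        mats = correlation_matrices(make_cohort(df, tiny_schema()))
        for m in (mats.r_train, mats.r_val, mats.r_combined):
            np.testing.assert_allclose(np.diag(m), 1.0)
            assert m[0, 1] == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        n = 10_000
        df = pd.DataFrame({
            "A": rng.normal(size=n), "B": rng.normal(size=n),
            "C": rng.normal(size=n), "D": rng.normal(size=n),
            "CVS": 1,
            "set": ["training"] * (2 * n // 3) + ["validation"] * (n - 2 * n // 3),
        })
        mats = correlation_matrices(make_cohort(df, tiny_schema()))
        off = mats.r_combined[np.triu_indices(4, k=1)]
        assert np.all(np.abs(off) < 0.05)

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"A": 1.0, "B": np.arange(10.0), "C": np.arange(10.0),
                           "D": np.arange(10.0), "CVS": 1,
                           "set": ["training"] * 6 + ["validation"] * 4})
        with pytest.raises(ValueError, match="zero variance"):
            correlation_matrices(make_cohort(df, tiny_schema()))

    def test_tiny_set_rejected(self):
        df = pd.DataFrame({"A": np.arange(6.0), "B": np.arange(6.0) ** 2,
                           "C": np.arange(6.0) ** 3, "D": np.arange(6.0) % 3,
                           "CVS": 1,
                           "set": ["training"] * 4 + ["validation"] * 2})
        with pytest.raises(ValueError, match="fewer than 3"):
            correlation_matrices(make_cohort(df, tiny_schema()))

    def test_spearman_option(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        df = pd.DataFrame({"A": x, "B": np.exp(x), "C": rng.normal(size=30),
                           "D": rng.normal(size=30), "CVS": 0,
                           "set": ["training"] * 20 + ["validation"] * 10})
        mats = correlation_matrices(make_cohort(df, tiny_schema()), kind="spearman")
        assert mats.r_combined[0, 1] == pytest.approx(1.0)


class TestClassifyConsistency:
    @pytest.mark.parametrize(
        "rt,rv,delta,expected",
        [
            (0.30, 0.10, 0.25, True),
            (0.30, -0.05, 0.25, False),  # opposite sign
            (0.60, 0.30, 0.25, False),  # difference 0.30 > 0.25
            (0.00, 0.10, 0.25, True),  # exact zero never opposite-signed
            (0.00, -0.10, 0.25, True),
            (-0.30, -0.10, 0.25, True),
            (0.25, 0.50, 0.25, True),  # boundary difference retained
        ],
    )
    def test_rule(self, rt, rv, delta, expected):
        assert classify_consistency(rt, rv, delta) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_consistency(1.2, 0.0, 0.25)

    @settings(derandomize=True, max_examples=200)
    @given(
        rt=st.floats(-1, 1), rv=st.floats(-1, 1),
        delta=st.floats(0.01, 1.9), wider=st.floats(0.0, 0.1),
    )
    def test_monotone_in_delta_and_symmetric(self, rt, rv, delta, wider):
        if classify_consistency(rt, rv, delta):
            assert classify_consistency(rt, rv, delta + wider)
        assert classify_consistency(rt, rv, delta) == classify_consistency(
            rv, rt, delta
        )


class TestFilterPairs:
    def test_planted_pairs_exactly_retained(self):
        # three pairs at r ~ 0.7, all other couplings null, n = 2000/set
        rng = np.random.default_rng(3)
        n = 4000
        markers = ["A", "B", "C", "D", "E", "F"]
        z = rng.normal(size=(n, 6))
        for i, j in ((0, 1), (2, 3), (4, 5)):
            z[:, j] = 0.7 * z[:, i] + np.sqrt(1 - 0.7**2) * z[:, j]
        df = pd.DataFrame(z, columns=markers)
        df["CVS"] = 1
        df["set"] = ["training"] * (n // 2) + ["validation"] * (n // 2)
        cohort = make_cohort(df, tiny_schema(tuple(markers)))
        report = filter_pairs(correlation_matrices(cohort), AnalysisConfig())
        retained = {frozenset(p) for p in report.retained_pairs()}
        assert retained == {
            frozenset("AB"), frozenset("CD"), frozenset("EF"),
        }

    def test_tiny_tau_keeps_every_consistent_pair(self):
        cfg = AnalysisConfig(tau_magnitude=1e-9)
        report = filter_pairs(two_var_matrices(0.1, 0.05, 0.08), cfg)
        assert (report.table["relevant"] == True).all()  # noqa: E712
        assert report.n_retained == report.n_consistent

    def test_boundary_magnitude_retained(self):
        # |r_combined| = tau exactly counts as relevant (">= 0.25")
        report = filter_pairs(two_var_matrices(0.3, 0.2, 0.25), AnalysisConfig())
        assert report.table.iloc[0]["retained"]

    def test_relevance_on_training_option(self):
        cfg = AnalysisConfig(relevance_on="train")
        report = filter_pairs(two_var_matrices(0.3, 0.2, 0.1), cfg)
        assert report.table.iloc[0]["retained"]

    @pytest.mark.parametrize("n_vars", [4, 12])
    def test_pair_count(self, n_vars):
        names = [f"v{i}" for i in range(n_vars)]
        eye = np.eye(n_vars)
        report = filter_pairs(
            pair_matrix(names, eye, eye, eye), AnalysisConfig()
        )
        assert report.n_pairs == n_vars * (n_vars - 1) // 2

    def test_retained_set_shrinks_with_stricter_thresholds(self, transformed):
        mats = correlation_matrices(transformed)
        loose = filter_pairs(mats, AnalysisConfig(delta_consistency=0.3))
        base = filter_pairs(mats, AnalysisConfig())
        strict_tau = filter_pairs(mats, AnalysisConfig(tau_magnitude=0.4))
        strict_delta = filter_pairs(mats, AnalysisConfig(delta_consistency=0.15))
        as_sets = lambda r: {frozenset(p) for p in r.retained_pairs()}
        assert as_sets(base) <= as_sets(loose)  # delta 0.3 superset
        assert as_sets(strict_tau) <= as_sets(base)
        assert as_sets(strict_delta) <= as_sets(base)


class TestFindClusters:
    def test_triangle_forms_single_cluster(self):
        report = report_from_edges([("A", "B"), ("B", "C"), ("A", "C")])
        out = find_clusters(report, 3)
        assert out.clusters == [frozenset("ABC")]
        assert out.residual_pairs == []

    def test_single_edge_is_residual(self):
        out = find_clusters(report_from_edges([("E", "F")]), 3)
        assert out.clusters == []
        assert out.residual_pairs == [("E", "F")]

    def test_mixed_components(self):
        out = find_clusters(
            report_from_edges([("A", "B"), ("B", "C"), ("D", "E")]), 3
        )
        assert out.clusters == [frozenset("ABC")]
        assert out.residual_pairs == [("D", "E")]

    def test_chain_counts_via_connectivity_not_cliques(self):
        # a path A-B-C is a cluster under the component rule
        out = find_clusters(report_from_edges([("A", "B"), ("B", "C")]), 3)
        assert out.clusters == [frozenset("ABC")]

    def test_clique_method_requires_mutual_edges(self):
        edges = [("A", "B"), ("B", "C")]
        assert find_clusters(report_from_edges(edges), 3, "cliques").clusters == []
        edges += [("A", "C")]
        assert find_clusters(report_from_edges(edges), 3, "cliques").clusters == [
            frozenset("ABC")
        ]

    def test_invariant_to_edge_order_and_relabeling(self):
        rng = np.random.default_rng(4)
        letters = list("ABCDEFGHIJKL")
        for _ in range(50):
            k = rng.integers(1, 12)
            edges = set()
            while len(edges) < k:
                a, b = rng.choice(12, size=2, replace=False)
                edges.add((letters[min(a, b)], letters[max(a, b)]))
            edges = list(edges)
            out1 = find_clusters(report_from_edges(edges), 3)
            rng.shuffle(edges)
            out2 = find_clusters(report_from_edges(edges), 3)
            assert sorted(map(sorted, out1.clusters)) == sorted(
                map(sorted, out2.clusters)
            )
            oracle = [
                c for c in components_oracle(edges) if len(c) >= 3
            ]
            assert set(out1.clusters) == set(oracle)


class TestStratifiedAnalysis:
    def test_duplicated_strata_yield_identical_reports(self, schema):
        base = generate_cohort(SyntheticConfig(rng_seed=11))
        cvs_rows = base.data[base.data["CVS"] == 1].copy()
        mirror = cvs_rows.copy()
        mirror["CVS"] = 0
        mirror[schema.id_column] = mirror[schema.id_column] + "m"
        dup = Cohort(pd.concat([cvs_rows, mirror], ignore_index=True), schema)
        results = stratified_analysis(dup, AnalysisConfig())
        pd.testing.assert_frame_equal(results[0][0].table, results[1][0].table)
        assert results[0][1].clusters == results[1][1].clusters

    def test_null_retained_count_matches_permutation_oracle(self):
        # no planted structure: the average number of retained pairs over
        # fresh cohorts must match a set-label permutation null
        cfg = AnalysisConfig()
        n_rep = 60
        fresh = []
        for seed in spawned_seeds(21, n_rep):
            c = generate_cohort(SyntheticConfig(blocks=(), rng_seed=seed))
            sub = c.strata()[1]
            fresh.append(
                filter_pairs(correlation_matrices(sub), cfg).n_retained
            )
        base = generate_cohort(SyntheticConfig(blocks=(), rng_seed=777)).strata()[1]
        rng = np.random.default_rng(5)
        permuted = []
        for _ in range(n_rep):
            df = base.data.copy()
            df["set"] = rng.permutation(df["set"].to_numpy())
            sub = Cohort(df, base.schema)
            permuted.append(
                filter_pairs(correlation_matrices(sub), cfg).n_retained
            )
        se = np.hypot(np.std(fresh, ddof=1), np.std(permuted, ddof=1)) / np.sqrt(
            n_rep
        )
        assert abs(np.mean(fresh) - np.mean(permuted)) < 3 * se

    def test_empty_stratum_cell_rejected(self, schema):
        base = generate_cohort(SyntheticConfig(rng_seed=12))
        df = base.data.copy()
        df.loc[df["CVS"] == 1, "set"] = "training"
        with pytest.raises(ValueError, match="fewer than 3"):
            stratified_analysis(Cohort(df, schema), AnalysisConfig())


class TestHeatmapExport:
    def test_non_retained_cells_masked(self):
        report = filter_pairs(two_var_matrices(0.9, 0.1, 0.6), AnalysisConfig())
        frame = masked_heatmap_frame(report)
        assert np.isnan(frame.loc["A", "B"])  # inconsistent pair masked
        retained = filter_pairs(two_var_matrices(0.6, 0.55, 0.6), AnalysisConfig())
        frame2 = masked_heatmap_frame(retained)
        assert frame2.loc["A", "B"] == pytest.approx(0.6)
        assert frame2.loc["A", "A"] == 1.0
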