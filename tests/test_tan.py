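"""Tree-augmented naive Bayes: CMI, Chow-Liu tree, classification, chi-square."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mps2screen import (
    TANModel,
    build_tan,
    chi_square_independence,
    conditional_mutual_information,
    fit_nbc,
    posterior_frame,
    tan_classify,
    tan_posterior,
    tan_posterior_frame,
)

from conftest import make_training


def ts_from_columns(cols: dict, y):
    return make_training(pd.DataFrame(cols), y).restrict(list(cols))


class TestCMI:
    def test_independent_within_class_is_zero(self):
        # exact product proportions within each class: 4 copies of every
        # (xi, xj) cell per class
        xi, xj, y = [], [], []
        for c in (0, 1):
            for a in (0, 1):
                for b in (0, 1):
                    for _ in range(4):
                        xi.append(a)
                        xj.append(b)
                        y.append(c)
        assert conditional_mutual_information(xi, xj, y, alpha=0.0) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_copied_feature_equals_conditional_entropy(self):
        # I(X; X | Y) = H(X | Y); compare against the entropy formula
        rng = np.random.default_rng(4)
        y = np.array([0] * 50 + [1] * 50)
        x = np.where(y == 0, rng.random(100) < 0.3, rng.random(100) < 0.7).astype(int)
        cmi = conditional_mutual_information(x, x, y, alpha=0.0)
        h = 0.0
        for c in (0, 1):
            p = x[y == c].mean()
            w = (y == c).mean()
            for q in (p, 1 - p):
                if q > 0:
                    h -= w * q * math.log(q)
        assert cmi == pytest.approx(h, abs=1e-12)

    def test_nonnegative(self, rng):
        for _ in range(20):
            xi = rng.integers(0, 2, 30)
            xj = rng.integers(0, 2, 30)
            y = rng.integers(0, 2, 30)
            assert conditional_mutual_information(xi, xj, y) >= 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            conditional_mutual_information([0, 1], [0], [0, 1])


class TestChowLiuTree:
    def test_copied_feature_edge_selected(self, rng):
        y = rng.integers(0, 2, 400)
        x1 = rng.integers(0, 2, 400)
        ts = ts_from_columns(
            {"Hearing": x1, "Otitis": x1, "Joint": rng.integers(0, 2, 400)}, y
        )
        model = build_tan(ts, alpha=1.0)
        assert ("Hearing", "Otitis") in model.edges or (
            "Otitis",
            "Hearing",
        ) in model.edges

    def test_edge_count(self, study_design_training):
        model = build_tan(study_design_training, alpha=1.0)
        assert len(model.edges) == len(model.feature_names) - 1

    def test_tree_is_spanning_and_acyclic(self, study_design_training):
        model = build_tan(study_design_training, alpha=1.0)
        g = nx.Graph(model.edges)
        g.add_nodes_from(model.feature_names)
        assert nx.is_tree(g)

    @pytest.mark.parametrize("n_features", [3, 4, 5])
    def test_optimal_vs_brute_force(self, rng, n_features):
        # exhaustive spanning-tree enumeration: the Chow-Liu tree's total CMI
        # must equal the maximum over all spanning trees
        names = ["Hearing", "Otitis", "Joint", "Apnea", "COPD"][:n_features]
        y = rng.integers(0, 2, 120)
        cols = {f: rng.integers(0, 2, 120) for f in names}
        cols[names[1]] = (cols[names[0]] ^ (rng.random(120) < 0.2)).astype(int)
        ts = ts_from_columns(cols, y)
        model = build_tan(ts, alpha=1.0)
        weight = model.edge_weights

        def w(u, v):
            return weight[(u, v)] if (u, v) in weight else weight[(v, u)]

        got = sum(w(*e) for e in model.edges)
        all_edges = list(itertools.combinations(names, 2))
        best = -np.inf
        for subset in itertools.combinations(all_edges, n_features - 1):
            g = nx.Graph(subset)
            g.add_nodes_from(names)
            if nx.is_tree(g):
                best = max(best, sum(w(*e) for e in subset))
        assert got == pytest.approx(best, abs=1e-12)

    def test_deterministic_structure(self, rng):
        y = rng.integers(0, 2, 100)
        cols = {f: rng.integers(0, 2, 100) for f in ("Hearing", "Otitis", "Joint")}
        ts = ts_from_columns(cols, y)
        a = build_tan(ts, alpha=1.0)
        b = build_tan(ts, alpha=1.0)
        assert a.parent == b.parent
        assert a.root == sorted(a.feature_names)[0]


class TestTANClassification:
    def hand_model(self):
        # 3 features: b depends on a; c is root-independent
        return TANModel(
            feature_names=("a", "b", "c"),
            parent={"a": None, "b": "a", "c": "a"},
            class_prior=np.array([0.6, 0.4]),
            cpt={
                "a": np.array([[0.2, 0.7]]),
                "b": np.array([[0.1, 0.5], [0.8, 0.9]]),
                "c": np.array([[0.3, 0.4], [0.6, 0.2]]),
            },
            alpha=0.0,
        )

    def joint_enumeration(self, model, x):
        def p_rec(vec, y):
            p = model.class_prior[y]
            idx = {f: i for i, f in enumerate(model.feature_names)}
            for f in model.feature_names:
                pa = model.parent[f]
                pv = 0 if pa is None else vec[idx[pa]]
                p1 = model.cpt[f][pv, y]
                p *= p1 if vec[idx[f]] == 1 else 1 - p1
            return p
        num = [p_rec(tuple(x), y) for y in (0, 1)]
        return np.array(num) / sum(num)

    def test_matches_enumeration_oracle(self):
        model = self.hand_model()
        for vec in itertools.product((0, 1), repeat=3):
            expected = self.joint_enumeration(model, vec)
            got = tan_posterior(model, np.array(vec))
            assert got.probs == pytest.approx(expected, abs=1e-12)
            assert got.map_class == int(expected[1] > expected[0])

    def test_uninformative_cpts_return_prior(self):
        model = TANModel(
            feature_names=("a", "b"),
            parent={"a": None, "b": "a"},
            class_prior=np.array([0.3, 0.7]),
            cpt={"a": np.full((1, 2), 0.5), "b": np.full((2, 2), 0.5)},
            alpha=0.0,
        )
        for vec in itertools.product((0, 1), repeat=2):
            assert tan_posterior(model, np.array(vec)).probs == pytest.approx(
                [0.3, 0.7]
            )

    def test_tie_breaks_to_negative(self):
        model = TANModel(
            feature_names=("a",),
            parent={"a": None},
            class_prior=np.array([0.5, 0.5]),
            cpt={"a": np.full((1, 2), 0.5)},
            alpha=0.0,
        )
        assert tan_classify(model, np.array([1])) == 0

    def test_posteriors_normalized_and_label_symmetric(self, rng):
        y = rng.integers(0, 2, 200)
        cols = {f: rng.integers(0, 2, 200) for f in ("Hearing", "Otitis", "Joint")}
        ts = ts_from_columns(cols, y)
        m1 = build_tan(ts, alpha=1.0)
        p1 = tan_posterior_frame(m1, ts.X)
        assert p1[["p_negative", "p_positive"]].sum(axis=1).to_numpy() == pytest.approx(
            np.ones(200), abs=1e-12
        )
        ts_swapped = ts_from_columns(cols, 1 - y)
        p2 = tan_posterior_frame(build_tan(ts_swapped, alpha=1.0), ts.X)
        assert p1["p_positive"].to_numpy() == pytest.approx(
            p2["p_negative"].to_numpy(), abs=1e-12
        )

    def test_close_to_nbc_when_independent_given_class(self):
        # generated with class-conditionally independent features, TAN and
        # NBC posteriors must agree closely at large n
        rng = np.random.default_rng(10)
        n = 10_000
        y = rng.integers(0, 2, n)
        probs = {"Hearing": (0.2, 0.8), "Otitis": (0.4, 0.6), "Joint": (0.1, 0.3)}
        cols = {
            f: (rng.random(n) < np.where(y == 1, p1, p0)).astype(int)
            for f, (p0, p1) in probs.items()
        }
        ts = ts_from_columns(cols, y)
        tan = build_tan(ts, alpha=1.0)
        nbc = fit_nbc(ts, alpha=1.0)
        pt = tan_posterior_frame(tan, ts.X)["p_positive"].to_numpy()
        pn = posterior_frame(nbc, ts.X)["p_positive"].to_numpy()
        assert np.abs(pt - pn).max() < 0.02

    def test_json_round_trip(self, tmp_path, rng):
        y = rng.integers(0, 2, 60)
        cols = {f: rng.integers(0, 2, 60) for f in ("Hearing", "Otitis")}
        model = build_tan(ts_from_columns(cols, y), alpha=1.0)
        path = tmp_path / "tan.json"
        model.to_json(path)
        back = TANModel.from_json(path)
        assert back.parent == model.parent
        for f in model.feature_names:
            assert (back.cpt[f] == model.cpt[f]).all()

    def test_dot_export_mentions_edges(self, rng):
        y = rng.integers(0, 2, 60)
        cols = {f: rng.integers(0, 2, 60) for f in ("Hearing", "Otitis")}
        model = build_tan(ts_from_columns(cols, y), alpha=1.0)
        dot = model.to_dot()
        assert "digraph" in dot and '"Hearing"' in dot


class TestChiSquare:
    def test_perfect_association_equals_n(self):
        y = np.array([0] * 50 + [1] * 50)
        res = chi_square_independence(y, y)
        assert res.statistic == pytest.approx(100.0)
        assert res.dof == 1
        assert res.p_value < 1e-20

    def test_exact_independence(self):
        x = np.array([1, 1, 0, 0] * 25)
        y = np.array([1, 0, 1, 0] * 25)
        res = chi_square_independence(x, y)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_scipy(self, rng):
        x = rng.integers(0, 2, 300)
        y = rng.integers(0, 2, 300)
        table = np.array(
            [
                [((x == 0) & (y == 0)).sum(), ((x == 0) & (y == 1)).sum()],
                [((x == 1) & (y == 0)).sum(), ((x == 1) & (y == 1)).sum()],
            ]
        )
        ref = stats.chi2_contingency(table, correction=False)
        res = chi_square_independence(x, y)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_marginal_undefined(self):
        res = chi_square_independence(np.zeros(10, dtype=int),
                                      np.array([0, 1] * 5))
        assert math.isnan(res.statistic) and math.isnan(res.p_value)

    def test_statistic_nonnegative(self, rng):
        for _ in range(20):
            x = rng.integers(0, 2, 40)
            y = rng.integers(0, 2, 40)
            res = chi_square_independence(x, y)
            assert math.isnan(res.statistic) or res.statistic >= 0
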