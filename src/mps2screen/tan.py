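"""Tree-augmented naive Bayes (TAN) comparator and independence tests.

The naive Bayes classifier assumes the symptom features are conditionally
independent given the disease class.  A TAN relaxes that assumption minimally:
besides the class parent, each feature may have exactly one other feature as a
parent, and those feature-feature arcs form a tree.  The tree is learned by
the Chow-Liu/Friedman construction — a maximum-weight spanning tree over the
pairwise class-conditional mutual information

    I(X_i; X_j | Y) = sum p(x_i, x_j, y) log[ p(x_i, x_j | y) /
                                              (p(x_i | y) p(x_j | y)) ],

with deterministic tie-breaking (lexicographic feature-name order) and the
root fixed at the alphabetically first feature, so that repeated runs build
the same model.  Conditional probability tables P(x_i | parent(x_i), y) are
estimated with the same additive smoothing as the NBC; classification is by
the MAP rule in log space with ties to the negative class.

Also provided: the Pearson chi-square test (no continuity correction, 1 df)
of independence between each binary feature and the binary target.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .index import TrainingSet
from .nbc import Posterior, _normalize


def conditional_mutual_information(xi, xj, y, alpha: float = 0.0) -> float:
    """Empirical I(X_i; X_j | Y) in nats for binary variables.

    ``alpha`` adds a pseudo-count to each of the 8 cells of the joint
    (x_i, x_j, y) table before normalizing (the same shrinkage used for the
    CPTs).  With alpha = 0, zero-probability cells contribute 0.
    """
    xi = np.asarray(xi, dtype=np.int8)
    xj = np.asarray(xj, dtype=np.int8)
    y = np.asarray(y, dtype=np.int8)
    if not (xi.shape == xj.shape == y.shape):
        raise ValueError("xi, xj, y must have equal length")
    counts = np.zeros((2, 2, 2), dtype=float)
    for a in (0, 1):
        for b in (0, 1):
            for c in (0, 1):
                counts[a, b, c] = ((xi == a) & (xj == b) & (y == c)).sum()
    counts += alpha
    total = counts.sum()
    if total == 0:
        raise ValueError("empty input")
    p = counts / total
    p_y = p.sum(axis=(0, 1))  # (2,)
    p_iy = p.sum(axis=1)  # (2, 2) over x_i, y
    p_jy = p.sum(axis=0)  # (2, 2) over x_j, y
    cmi = 0.0
    for a in (0, 1):
        for b in (0, 1):
            for c in (0, 1):
                if p[a, b, c] > 0 and p_y[c] > 0:
                    cmi += p[a, b, c] * math.log(
                        p[a, b, c] * p_y[c] / (p_iy[a, c] * p_jy[b, c])
                    )
    return max(cmi, 0.0)


@dataclass
class IndependenceTestResult:
    statistic: float
    dof: int
    p_value: float


def chi_square_independence(x, y) -> IndependenceTestResult:
    """Pearson chi-square test of a 2x2 feature-target table, 1 df.

    No continuity correction.  A zero row or column marginal makes the
    statistic undefined; it is reported as NaN rather than 0.
    """
    x = np.asarray(x, dtype=np.int8)
    y = np.asarray(y, dtype=np.int8)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    n11 = float(((x == 1) & (y == 1)).sum())
    n10 = float(((x == 1) & (y == 0)).sum())
    n01 = float(((x == 0) & (y == 1)).sum())
    n00 = float(((x == 0) & (y == 0)).sum())
    n = n11 + n10 + n01 + n00
    if n == 0:
        raise ValueError("empty table")
    r1, r0 = n11 + n10, n01 + n00
    c1, c0 = n11 + n01, n10 + n00
    if min(r1, r0, c1, c0) == 0:
        return IndependenceTestResult(math.nan, 1, math.nan)
    stat = n * (n11 * n00 - n10 * n01) ** 2 / (r1 * r0 * c1 * c0)
    return IndependenceTestResult(stat, 1, float(stats.chi2.sf(stat, 1)))


# -- Chow-Liu tree ------------------------------------------------------------


def _max_spanning_tree(names: list[str], weight: dict) -> list[tuple[str, str]]:
    """Kruskal maximum spanning tree; ties broken by sorted edge names."""
    edges = sorted(
        ((u, v) for i, u in enumerate(names) for v in names[i + 1 :]),
        key=lambda e: (-weight[e], e),
    )
    parent = {f: f for f in names}

    def find(f: str) -> str:
        while parent[f] != f:
            parent[f] = parent[parent[f]]
            f = parent[f]
        return f

    tree = []
    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            tree.append((u, v))
    return tree


@dataclass
class TANModel:
    """Tree-structured feature dependencies plus the class parent.

    ``parent[f]`` is the feature parent of f (None for the root); every
    feature additionally has the class as a parent.  ``cpt[f]`` has shape
    (n_parent_states, 2) holding P(x_f = 1 | parent value, y): one row for
    the root, two otherwise.
    """

    feature_names: tuple[str, ...]
    parent: dict[str, str | None]
    class_prior: np.ndarray
    cpt: dict[str, np.ndarray]
    alpha: float
    edge_weights: dict[tuple[str, str], float] | None = None

    @property
    def root(self) -> str:
        return next(f for f in self.feature_names if self.parent[f] is None)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [(p, f) for f, p in self.parent.items() if p is not None]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "feature_names": list(self.feature_names),
            "parent": self.parent,
            "class_prior": self.class_prior.tolist(),
            "cpt": {f: t.tolist() for f, t in self.cpt.items()},
            "alpha": self.alpha,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TANModel":
        text = str(source)
        try:
            if Path(source).exists():
                text = Path(source).read_text()
        except OSError:
            pass
        payload = json.loads(text)
        return cls(
            feature_names=tuple(payload["feature_names"]),
            parent=dict(payload["parent"]),
            class_prior=np.array(payload["class_prior"], dtype=float),
            cpt={f: np.array(t, dtype=float) for f, t in payload["cpt"].items()},
            alpha=float(payload["alpha"]),
        )

    def to_dot(self) -> str:
        """Graphviz DOT rendering of the network (class node -> features)."""
        lines = ["digraph TAN {", '  "MPSII" [shape=doublecircle];']
        for f in self.feature_names:
            lines.append(f'  "MPSII" -> "{f}";')
        for p, f in self.edges:
            lines.append(f'  "{p}" -> "{f}";')
        lines.append("}")
        return "\n".join(lines)


def build_tan(train: TrainingSet, alpha: float = 1.0) -> TANModel:
    """Learn a TAN: Chow-Liu tree on conditional mutual information + CPTs.

    With a single feature the model degenerates to a plain NBC (no tree
    edges).  CMI is estimated with the same smoothing alpha as the CPTs.
    """
    X, y = train.X, train.y
    names = list(X.columns)
    if len(names) < 1:
        raise ValueError("at least one feature required")
    if y.min() == y.max():
        raise ValueError("training data must contain both classes")
    Xv = X.to_numpy(dtype=np.int8)
    col = {f: Xv[:, i] for i, f in enumerate(names)}

    weight = {
        (u, v): conditional_mutual_information(col[u], col[v], y, alpha=alpha)
        for i, u in enumerate(names)
        for v in names[i + 1 :]
    }
    tree_edges = _max_spanning_tree(names, weight) if len(names) > 1 else []

    # orient edges away from the alphabetically first feature
    root = sorted(names)[0]
    adj: dict[str, list[str]] = {f: [] for f in names}
    for u, v in tree_edges:
        adj[u].append(v)
        adj[v].append(u)
    parent: dict[str, str | None] = {root: None}
    queue = [root]
    while queue:
        node = queue.pop(0)
        for nb in sorted(adj[node]):
            if nb not in parent:
                parent[nb] = node
                queue.append(nb)

    n_y = np.array([(y == 0).sum(), (y == 1).sum()], dtype=float)
    prior = n_y / n_y.sum()
    cpt: dict[str, np.ndarray] = {}
    for f in names:
        p = parent[f]
        if p is None:
            table = np.empty((1, 2))
            for c in (0, 1):
                sel = y == c
                table[0, c] = (col[f][sel].sum() + alpha) / (sel.sum() + 2 * alpha)
        else:
            table = np.empty((2, 2))
            for pv in (0, 1):
                for c in (0, 1):
                    sel = (col[p] == pv) & (y == c)
                    table[pv, c] = (col[f][sel].sum() + alpha) / (
                        sel.sum() + 2 * alpha
                    )
        cpt[f] = table
    return TANModel(tuple(names), parent, prior, cpt, alpha, edge_weights=weight)


def _record_matrix(model: TANModel, X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        missing = [f for f in model.feature_names if f not in X.columns]
        if missing:
            raise ValueError(f"record is missing features {missing!r}")
        return X[list(model.feature_names)].to_numpy(dtype=np.int8)
    arr = np.atleast_2d(np.asarray(X, dtype=np.int8))
    if arr.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} features, got {arr.shape[1]}"
        )
    return arr


def tan_log_scores(model: TANModel, X) -> np.ndarray:
    """(n, 2) log P(y) + sum_f log P(x_f | pa(x_f), y) in log space."""
    Xv = _record_matrix(model, X)
    idx = {f: i for i, f in enumerate(model.feature_names)}
    with np.errstate(divide="ignore"):
        scores = np.tile(np.log(model.class_prior), (Xv.shape[0], 1))
        for f in model.feature_names:
            x = Xv[:, idx[f]]
            p = model.parent[f]
            pv = np.zeros_like(x) if p is None else Xv[:, idx[p]]
            for c in (0, 1):
                p1 = model.cpt[f][pv, c]
                scores[:, c] += np.where(x == 1, np.log(p1), np.log(1.0 - p1))
    return scores


def tan_posterior(model: TANModel, record) -> Posterior:
    """Normalized TAN posterior for one record; MAP ties go to class 0."""
    if isinstance(record, (dict, pd.Series)):
        vec = np.array(
            [record[f] for f in model.feature_names], dtype=np.int8
        )[None, :]
    else:
        vec = np.atleast_2d(np.asarray(record, dtype=np.int8))
    scores = tan_log_scores(model, vec)
    probs = _normalize(scores)[0]
    return Posterior(probs, int(scores[0, 1] > scores[0, 0]))


def tan_classify(model: TANModel, record) -> int:
    return tan_posterior(model, record).map_class


def tan_posterior_frame(model: TANModel, X) -> pd.DataFrame:
    """Vectorized TAN posteriors, same layout as nbc.posterior_frame."""
    scores = tan_log_scores(model, X)
    probs = _normalize(scores)
    return pd.DataFrame(
        {
            "p_negative": probs[:, 0],
            "p_positive": probs[:, 1],
            "map_class": (scores[:, 1] > scores[:, 0]).astype(np.int8),
        },
        index=X.index if isinstance(X, pd.DataFrame) else None,
    )
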