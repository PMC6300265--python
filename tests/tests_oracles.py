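"""Independent brute-force oracles shared by the test suite.

These compute posteriors from exhaustive joint-distribution tables, never
through the log-space code paths they are used to check.
"""

import itertools

import numpy as np

from mps2screen import NaiveBayesModel, TANModel


def random_nbc_model(rng, n_features: int) -> NaiveBayesModel:
    prior1 = rng.uniform(0.2, 0.8)
    return NaiveBayesModel(
        tuple(f"f{i}" for i in range(n_features)),
        np.array([1 - prior1, prior1]),
        rng.uniform(0.05, 0.95, size=(n_features, 2)),
        alpha=0.0,
    )


def enumeration_posterior_nbc(model: NaiveBayesModel, x: np.ndarray) -> np.ndarray:
    joint = {}
    for vec in itertools.product((0, 1), repeat=len(model.feature_names)):
        for y in (0, 1):
            p = model.class_prior[y]
            for i, v in enumerate(vec):
                q = model.feature_prob[i, y]
                p *= q if v else 1 - q
            joint[(vec, y)] = p
    key = tuple(int(v) for v in x)
    px = joint[(key, 0)] + joint[(key, 1)]
    return np.array([joint[(key, 0)] / px, joint[(key, 1)] / px])


def random_tan_model(rng, n_features: int) -> TANModel:
    names = tuple(f"f{i}" for i in range(n_features))
    parent = {names[0]: None}
    for i in range(1, n_features):
        parent[names[i]] = names[rng.integers(0, i)]
    prior1 = rng.uniform(0.2, 0.8)
    cpt = {}
    for f in names:
        shape = (1, 2) if parent[f] is None else (2, 2)
        cpt[f] = rng.uniform(0.05, 0.95, size=shape)
    return TANModel(names, parent, np.array([1 - prior1, prior1]), cpt, 0.0)


def enumeration_posterior_tan(model: TANModel, x: np.ndarray) -> np.ndarray:
    idx = {f: i for i, f in enumerate(model.feature_names)}

    def joint(vec, y):
        p = model.class_prior[y]
        for f in model.feature_names:
            pa = model.parent[f]
            pv = 0 if pa is None else vec[idx[pa]]
            p1 = model.cpt[f][pv, y]
            p *= p1 if vec[idx[f]] else 1 - p1
        return p

    key = tuple(int(v) for v in x)
    p0, p1 = joint(key, 0), joint(key, 1)
    return np.array([p0 / (p0 + p1), p1 / (p0 + p1)])
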