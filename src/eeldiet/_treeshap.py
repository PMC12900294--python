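"""Exact Shapley attributions for tree ensembles over few features.

With only the five proximate-composition features, Shapley values can be
computed exactly by enumerating all 2^d coalitions.  The value of a
coalition S for a sample x is the tree-conditional expectation E[f(x) | x_S]
obtained by descending each tree: known features follow their split,
unknown features average the children weighted by training coverage
(the path-dependent convention).  Attributions then follow directly from
the Shapley formula and inherit its efficiency axiom: per-sample
attributions plus the base value equal the model prediction exactly.
"""

from __future__ import annotations

from math import factorial

import numpy as np


def _tree_expectation(tree, X: np.ndarray, known: np.ndarray) -> np.ndarray:
    """E[f(x) | x_known] per row of X for one fitted sklearn tree."""
    left = tree.children_left
    right = tree.children_right
    feat = tree.feature
    thr = tree.threshold
    value = tree.value.reshape(-1)
    wn = tree.weighted_n_node_samples

    def rec(node: int) -> np.ndarray:
        if left[node] == -1:  # leaf
            return np.full(X.shape[0], value[node])
        f = feat[node]
        vl, vr = rec(left[node]), rec(right[node])
        if known[f]:
            return np.where(X[:, f] <= thr[node], vl, vr)
        w = wn[left[node]] / wn[node]
        return w * vl + (1.0 - w) * vr

    return rec(0)


def _coalition_values(model, X: np.ndarray) -> np.ndarray:
    """v[mask, i] = ensemble conditional expectation for coalition ``mask``."""
    d = X.shape[1]
    if d > 15:
        raise ValueError("exact enumeration is limited to <= 15 features")
    v = np.zeros((1 << d, X.shape[0]))
    for mask in range(1 << d):
        known = np.array([(mask >> j) & 1 for j in range(d)], dtype=bool)
        acc = np.zeros(X.shape[0])
        for est in model.estimators_:
            acc += _tree_expectation(est.tree_, X, known)
        v[mask] = acc / len(model.estimators_)
    return v


def tree_shap_values(model, X) -> tuple[np.ndarray, float]:
    """Exact Shapley attributions for a fitted RandomForestRegressor.

    Returns ``(phi, base)`` where ``phi`` has shape (n_samples, n_features)
    and ``base + phi.sum(axis=1)`` equals ``model.predict(X)`` exactly
    (efficiency axiom).
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    v = _coalition_values(model, X)
    phi = np.zeros((n, d))
    fact = [factorial(i) for i in range(d + 1)]
    denom = fact[d]
    for mask in range(1 << d):
        s = bin(mask).count("1")
        for j in range(d):
            if (mask >> j) & 1:
                continue
            w = fact[s] * fact[d - s - 1] / denom
            phi[:, j] += w * (v[mask | (1 << j)] - v[mask])
    base = float(v[0].mean())
    # v[0] is constant across samples (no feature known); use per-sample value
    return phi, base


def shap_dependence_table(
    X: np.ndarray,
    phi: np.ndarray,
    feature_idx: int,
    n_bins: int = 10,
    n_boot: int = 200,
    ci: float = 0.95,
    seed: int = 0,
) -> "np.ndarray":
    """Binned dependence: per feature-value bin, mean attribution + bootstrap CI.

    Returns a structured record array with fields bin_center, n, mean_phi,
    ci_low, ci_high.  Empty bins are omitted.
    """
    x = np.asarray(X, dtype=float)[:, feature_idx]
    f = np.asarray(phi, dtype=float)[:, feature_idx]
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    which = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)
    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci) / 2
    rows = []
    for b in range(n_bins):
        vals = f[which == b]
        if len(vals) == 0:
            continue
        boots = np.array([
            rng.choice(vals, size=len(vals), replace=True).mean()
            for _ in range(n_boot)
        ])
        rows.append((
            0.5 * (edges[b] + edges[b + 1]),
            len(vals),
            float(vals.mean()),
            float(np.quantile(boots, alpha)),
            float(np.quantile(boots, 1 - alpha)),
        ))
    return np.array(
        rows,
        dtype=[("bin_center", float), ("n", int), ("mean_phi", float),
               ("ci_low", float), ("ci_high", float)],
    )
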