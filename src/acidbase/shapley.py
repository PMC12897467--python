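"""Exact Shapley attributions for sklearn tree ensembles.

Computes the path-dependent conditional expectation v(S) of a regression
tree — descend the tree, following the sample's value for features in S and
averaging children by their training cover otherwise — for *every* feature
subset S, then combines them with exact Shapley weights. With the small
feature sets used here (at most a handful of predictors per acid-base
framework) the 2^M enumeration is exact and cheap, so no sampling or
polynomial-time approximation is needed. The inner loops are numba-compiled.

Satisfies the usual Shapley properties by construction, in particular
efficiency: contributions plus the base value sum to the model prediction.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["tree_ensemble_shap", "mean_abs_shap"]

MAX_FEATURES = 16


@njit(cache=True)
def _shapley_kernel(cl, cr, feat, thr, val, cover, offsets, X, weights, popcnt, M):
    nsamp = X.shape[0]
    ntrees = offsets.shape[0] - 1
    nsub = 1 << M
    phi = np.zeros((nsamp, M))
    base = np.zeros(nsamp)
    for t in range(ntrees):
        a = offsets[t]
        nn = offsets[t + 1] - a
        v = np.empty((nn, nsub))
        for si in range(nsamp):
            for node in range(nn - 1, -1, -1):
                g = a + node
                left = cl[g]
                if left < 0:
                    leaf = val[g]
                    for s in range(nsub):
                        v[node, s] = leaf
                else:
                    right = cr[g]
                    f = feat[g]
                    wl = cover[a + left]
                    wr = cover[a + right]
                    wt = wl + wr
                    child = left if X[si, f] <= thr[g] else right
                    bit = 1 << f
                    for s in range(nsub):
                        if s & bit:
                            v[node, s] = v[child, s]
                        else:
                            v[node, s] = (wl * v[left, s] + wr * v[right, s]) / wt
            base[si] += v[0, 0]
            for i in range(M):
                bit = 1 << i
                acc = 0.0
                for s in range(nsub):
                    if s & bit == 0:
                        acc += weights[popcnt[s]] * (v[0, s | bit] - v[0, s])
                phi[si, i] += acc
    return phi / ntrees, base / ntrees


def _pack_trees(estimators):
    cl, cr, feat, thr, val, cover, offsets = [], [], [], [], [], [], [0]
    for est in estimators:
        t = est.tree_
        cl.append(t.children_left)
        cr.append(t.children_right)
        feat.append(t.feature)
        thr.append(t.threshold)
        val.append(t.value[:, 0, 0])
        cover.append(t.weighted_n_node_samples)
        offsets.append(offsets[-1] + t.node_count)
    cat = lambda parts, dt: np.ascontiguousarray(np.concatenate(parts).astype(dt))
    return (
        cat(cl, np.int64), cat(cr, np.int64), cat(feat, np.int64),
        cat(thr, np.float64), cat(val, np.float64), cat(cover, np.float64),
        np.asarray(offsets, dtype=np.int64),
    )


def tree_ensemble_shap(model, X) -> tuple[np.ndarray, np.ndarray]:
    """Exact Shapley values for a fitted sklearn tree model on rows of ``X``.

    ``model`` is a ``DecisionTreeRegressor`` or an averaging ensemble of them
    (``RandomForestRegressor``). Returns ``(phi, base)`` where ``phi`` is
    (n_samples, n_features) and ``base`` the per-sample expected prediction
    (identical across samples for a fixed model); ``phi.sum(1) + base``
    equals the model prediction.
    """
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    M = X.shape[1]
    if M > MAX_FEATURES:
        raise ValueError(f"exact enumeration limited to {MAX_FEATURES} features, got {M}")
    estimators = getattr(model, "estimators_", None) or [model]
    packed = _pack_trees(estimators)
    weights = np.array(
        [_subset_weight(k, M) for k in range(M)], dtype=np.float64
    )
    popcnt = np.array([bin(s).count("1") for s in range(1 << M)], dtype=np.int64)
    phi, base = _shapley_kernel(*packed, X, weights, popcnt, M)
    return phi, base


def _subset_weight(k: int, M: int) -> float:
    # |S|! (M - |S| - 1)! / M!
    import math

    return math.factorial(k) * math.factorial(M - k - 1) / math.factorial(M)


def mean_abs_shap(model, X) -> np.ndarray:
    """Mean absolute Shapley value per feature over the rows of ``X``."""
    phi, _ = tree_ensemble_shap(model, X)
    return np.abs(phi).mean(axis=0)
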