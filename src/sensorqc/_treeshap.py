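"""Exact path-dependent SHAP values for sklearn tree ensembles.

Implements the polynomial-time TreeSHAP recursion (tracking the proportion
of feature-subset permutations that flow down each tree path) iteratively
with an explicit stack, so it can be JIT-compiled with numba.  Attributions
satisfy local additivity exactly: for every observation the per-feature
contributions plus the tree's base value equal the tree's output.

Only the positive-class probability output of binary classifiers is
attributed, which is the convention used by the device-type audit.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - decided once at import
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco


__all__ = ["forest_shap_values", "forest_expected_value"]


@njit(cache=False)
def _shap_one_tree(cl, cr, feat, thr, val, wgt, x, phi, maxd):  # noqa: C901
    """Accumulate SHAP values of one tree for one sample into ``phi``."""
    plen = maxd + 2
    # path buffers, one row per recursion depth
    fi = np.empty((plen, plen), dtype=np.int64)
    zf = np.empty((plen, plen), dtype=np.float64)
    of = np.empty((plen, plen), dtype=np.float64)
    pw = np.empty((plen, plen), dtype=np.float64)
    ulen = np.empty(plen, dtype=np.int64)

    cap = cl.shape[0] + 2
    st_node = np.empty(cap, dtype=np.int64)
    st_pd = np.empty(cap, dtype=np.int64)
    st_pz = np.empty(cap, dtype=np.float64)
    st_po = np.empty(cap, dtype=np.float64)
    st_pi = np.empty(cap, dtype=np.int64)
    top = 0
    st_node[0], st_pd[0], st_pz[0], st_po[0], st_pi[0] = 0, -1, 1.0, 1.0, -1
    top = 1

    while top > 0:
        top -= 1
        node = st_node[top]
        pd = st_pd[top]
        pz = st_pz[top]
        po = st_po[top]
        pi = st_pi[top]
        d = pd + 1
        l = 0 if pd < 0 else ulen[pd] + 1
        for i in range(l):
            fi[d, i] = fi[pd, i]
            zf[d, i] = zf[pd, i]
            of[d, i] = of[pd, i]
            pw[d, i] = pw[pd, i]
        # EXTEND path with (pi, pz, po)
        fi[d, l] = pi
        zf[d, l] = pz
        of[d, l] = po
        pw[d, l] = 1.0 if l == 0 else 0.0
        for i in range(l - 1, -1, -1):
            pw[d, i + 1] += po * pw[d, i] * (i + 1.0) / (l + 1.0)
            pw[d, i] = pz * pw[d, i] * (l - i) / (l + 1.0)
        u = l

        if cl[node] < 0:  # leaf
            for i in range(1, u + 1):
                # UNWOUND path sum for entry i
                one = of[d, i]
                zero = zf[d, i]
                nxt = pw[d, u]
                total = 0.0
                for j in range(u - 1, -1, -1):
                    if one != 0.0:
                        tmp = nxt * (u + 1.0) / ((j + 1.0) * one)
                        total += tmp
                        nxt = pw[d, j] - tmp * zero * (u - j) / (u + 1.0)
                    else:
                        total += pw[d, j] / (zero * (u - j) / (u + 1.0))
                phi[fi[d, i]] += total * (of[d, i] - zf[d, i]) * val[node]
        else:
            split = feat[node]
            if x[split] <= thr[node]:
                hot, cold = cl[node], cr[node]
            else:
                hot, cold = cr[node], cl[node]
            iz = 1.0
            io = 1.0
            k = -1
            for i in range(u + 1):
                if fi[d, i] == split:
                    k = i
                    break
            if k >= 0:
                iz = zf[d, k]
                io = of[d, k]
                # UNWIND entry k from the path
                one = of[d, k]
                zero = zf[d, k]
                nxt = pw[d, u]
                for j in range(u - 1, -1, -1):
                    if one != 0.0:
                        tmp = pw[d, j]
                        pw[d, j] = nxt * (u + 1.0) / ((j + 1.0) * one)
                        nxt = tmp - pw[d, j] * zero * (u - j) / (u + 1.0)
                    else:
                        pw[d, j] = pw[d, j] * (u + 1.0) / (zero * (u - j))
                for j in range(k, u):
                    fi[d, j] = fi[d, j + 1]
                    zf[d, j] = zf[d, j + 1]
                    of[d, j] = of[d, j + 1]
                u -= 1
            ulen[d] = u
            w = wgt[node]
            st_node[top] = cold
            st_pd[top] = d
            st_pz[top] = iz * wgt[cold] / w
            st_po[top] = 0.0
            st_pi[top] = split
            top += 1
            st_node[top] = hot
            st_pd[top] = d
            st_pz[top] = iz * wgt[hot] / w
            st_po[top] = io
            st_pi[top] = split
            top += 1


@njit(cache=False)
def _shap_tree_all(cl, cr, feat, thr, val, wgt, X, out, maxd):
    for s in range(X.shape[0]):
        _shap_one_tree(cl, cr, feat, thr, val, wgt, X[s], out[s], maxd)


def _tree_arrays(estimator):
    t = estimator.tree_
    val = t.value.reshape(t.node_count, -1)
    if val.shape[1] > 1:  # classifier: positive-class probability per node
        val = val[:, 1] / val.sum(axis=1)
    else:
        val = val[:, 0]
    return (
        t.children_left.astype(np.int64),
        t.children_right.astype(np.int64),
        t.feature.astype(np.int64),
        t.threshold.astype(np.float64),
        np.ascontiguousarray(val, dtype=np.float64),
        t.weighted_n_node_samples.astype(np.float64),
        int(t.max_depth),
    )


def forest_shap_values(model, X: np.ndarray) -> np.ndarray:
    """SHAP values of the positive-class probability for each row of ``X``.

    ``model`` must be a fitted sklearn tree ensemble (e.g. a random forest
    classifier); returns an (n_samples, n_features) matrix whose row sums
    plus :func:`forest_expected_value` equal ``predict_proba[:, 1]``.
    """
    if not hasattr(model, "estimators_"):
        raise TypeError("SHAP attribution requires a fitted tree ensemble")
    X = np.ascontiguousarray(X, dtype=np.float64)
    phi = np.zeros((X.shape[0], X.shape[1]), dtype=np.float64)
    for est in model.estimators_:
        cl, cr, feat, thr, val, wgt, maxd = _tree_arrays(est)
        tree_phi = np.zeros_like(phi)
        _shap_tree_all(cl, cr, feat, thr, val, wgt, X, tree_phi, maxd)
        phi += tree_phi
    return phi / len(model.estimators_)


def forest_expected_value(model) -> float:
    """Base value: the ensemble-average, training-weighted leaf output."""
    total = 0.0
    for est in model.estimators_:
        cl, _, _, _, val, wgt, _ = _tree_arrays(est)
        leaves = cl < 0
        total += float(np.sum(val[leaves] * wgt[leaves]) / wgt[0])
    return total / len(model.estimators_)
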