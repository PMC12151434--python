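"""Path-dependent tree Shapley values in double precision.

Implements the polynomial-time tree-traversal algorithm that keeps track of
the proportion of feature subsets flowing down each path ("EXTEND"/"UNWIND"
bookkeeping over the unique path).  Attributions satisfy local accuracy
exactly in float64:

    sum_j phi_j(x) = f(x) - E[f]

where f(x) is the double-precision evaluation of the tree ensemble and
E[f] the cover-weighted mean of its leaves.  Works for any forest flattened
to (children_left, children_right, feature, threshold, value, cover) arrays;
splits may route on ``x < t`` (gradient boosting convention) or ``x <= t``
(CART convention).

The per-tree kernel is JIT-compiled with numba when available and runs as
plain Python otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FlatTree", "tree_shap", "forest_expected_value", "forest_predict"]


@dataclass
class FlatTree:
    children_left: np.ndarray   # int64, -1 for leaves
    children_right: np.ndarray
    feature: np.ndarray         # int64, -1 for leaves
    threshold: np.ndarray       # float64
    value: np.ndarray           # float64 leaf contribution (0 on internals ok)
    cover: np.ndarray           # float64 node sample weight


def _extend(fd, fz, fo, fw, l, pz, po, pi):
    fd[l] = pi
    fz[l] = pz
    fo[l] = po
    fw[l] = 1.0 if l == 0 else 0.0
    for i in range(l - 1, -1, -1):
        fw[i + 1] += po * fw[i] * (i + 1.0) / (l + 1.0)
        fw[i] = pz * fw[i] * (l - i) / (l + 1.0)


def _unwind(fd, fz, fo, fw, l, i):
    one = fo[i]
    zero = fz[i]
    n = fw[l]
    if one != 0.0:
        for j in range(l - 1, -1, -1):
            t = fw[j]
            fw[j] = n * (l + 1.0) / ((j + 1.0) * one)
            n = t - fw[j] * zero * (l - j) / (l + 1.0)
    else:
        for j in range(l - 1, -1, -1):
            fw[j] = fw[j] * (l + 1.0) / (zero * (l - j))
    for j in range(i, l):
        fd[j] = fd[j + 1]
        fz[j] = fz[j + 1]
        fo[j] = fo[j + 1]


def _unwound_sum(fz, fo, fw, l, i):
    one = fo[i]
    zero = fz[i]
    total = 0.0
    nop = fw[l]
    if one != 0.0:
        for j in range(l - 1, -1, -1):
            tmp = nop / ((j + 1.0) * one)
            total += tmp
            nop = fw[j] - tmp * zero * (l - j)
    else:
        for j in range(l - 1, -1, -1):
            total += fw[j] / (zero * (l - j))
    return total * (l + 1.0)


def _recurse(cl, cr, feat, thr, val, cov, x, phi, strict, node,
             fd, fz, fo, fw, l, pz, po, pi):
    fd = fd.copy()
    fz = fz.copy()
    fo = fo.copy()
    fw = fw.copy()
    _extend(fd, fz, fo, fw, l, pz, po, pi)
    if cl[node] < 0:  # leaf
        leaf = val[node]
        for i in range(1, l + 1):
            w = _unwound_sum(fz, fo, fw, l, i)
            phi[fd[i]] += w * (fo[i] - fz[i]) * leaf
        return
    f = feat[node]
    goes_left = (x[f] < thr[node]) if strict else (x[f] <= thr[node])
    hot = cl[node] if goes_left else cr[node]
    cold = cr[node] if goes_left else cl[node]
    iz = 1.0
    io = 1.0
    k = -1
    for i in range(l + 1):
        if fd[i] == f:
            k = i
            break
    if k >= 0:
        iz = fz[k]
        io = fo[k]
        _unwind(fd, fz, fo, fw, l, k)
        l -= 1
    hz = cov[hot] / cov[node]
    cz = cov[cold] / cov[node]
    _recurse(cl, cr, feat, thr, val, cov, x, phi, strict, hot,
             fd, fz, fo, fw, l + 1, iz * hz, io, f)
    _recurse(cl, cr, feat, thr, val, cov, x, phi, strict, cold,
             fd, fz, fo, fw, l + 1, iz * cz, 0.0, f)


def _tree_shap_one(cl, cr, feat, thr, val, cov, x, phi, strict, max_depth):
    size = max_depth + 2
    fd = np.full(size, -1, dtype=np.int64)
    fz = np.zeros(size)
    fo = np.zeros(size)
    fw = np.zeros(size)
    _recurse(cl, cr, feat, thr, val, cov, x, phi, strict, 0,
             fd, fz, fo, fw, 0, 1.0, 1.0, -1)


def _depth(tree: FlatTree) -> int:
    depth = np.zeros(len(tree.children_left), dtype=np.int64)
    out = 0
    for node in range(len(depth)):
        for child in (tree.children_left[node], tree.children_right[node]):
            if child >= 0:
                depth[child] = depth[node] + 1
                out = max(out, int(depth[child]))
    return out


try:  # compile the per-tree kernel when numba is present
    from numba import njit

    _extend = njit(cache=False)(_extend)
    _unwind = njit(cache=False)(_unwind)
    _unwound_sum = njit(cache=False)(_unwound_sum)
    _recurse = njit(cache=False)(_recurse)
    _tree_shap_one = njit(cache=False)(_tree_shap_one)
except Exception:  # pragma: no cover - numba simply speeds things up
    pass


def tree_shap(trees: list[FlatTree], X: np.ndarray, strict_less: bool) -> np.ndarray:
    """Per-row, per-feature attributions for a flattened forest.

    ``strict_less=True`` routes ``x < t`` left (gradient-boosting trees);
    ``False`` routes ``x <= t`` left (CART/sklearn trees).
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    n, p = X.shape
    phi = np.zeros((n, p))
    for tree in trees:
        md = _depth(tree)
        cl = np.ascontiguousarray(tree.children_left, dtype=np.int64)
        cr = np.ascontiguousarray(tree.children_right, dtype=np.int64)
        ft = np.ascontiguousarray(tree.feature, dtype=np.int64)
        th = np.ascontiguousarray(tree.threshold, dtype=np.float64)
        vl = np.ascontiguousarray(tree.value, dtype=np.float64)
        cv = np.ascontiguousarray(tree.cover, dtype=np.float64)
        for r in range(n):
            _tree_shap_one(cl, cr, ft, th, vl, cv, X[r], phi[r], strict_less, md)
    return phi


def forest_expected_value(trees: list[FlatTree]) -> float:
    """Cover-weighted mean of leaf values, summed over trees."""
    total = 0.0
    for tree in trees:
        leaves = tree.children_left < 0
        total += float(np.sum(tree.value[leaves] * tree.cover[leaves]) / tree.cover[0])
    return total


def forest_predict(trees: list[FlatTree], X: np.ndarray, strict_less: bool) -> np.ndarray:
    """Double-precision ensemble evaluation (sum of reached leaf values)."""
    X = np.asarray(X, dtype=np.float64)
    out = np.zeros(len(X))
    for tree in trees:
        for r in range(len(X)):
            node = 0
            while tree.children_left[node] >= 0:
                f = tree.feature[node]
                left = (X[r, f] < tree.threshold[node]) if strict_less \
                    else (X[r, f] <= tree.threshold[node])
                node = tree.children_left[node] if left else tree.children_right[node]
            out[r] += tree.value[node]
    return out
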