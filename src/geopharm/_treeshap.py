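"""Exact path-dependent TreeSHAP for XGBoost regression ensembles.

Float64 implementation of the polynomial-time tree-traversal Shapley
algorithm (the TreeExplainer algorithm class): attributions are exact, and
because predictions and the expected value are recomputed here in float64
from the same parsed trees, the local-accuracy identity

    base_value + sum_j phi_j = prediction

holds to ~1e-12 rather than the float32 rounding a mixed-precision route
would give.  Conditional expectations off the decision path use the
training cover (hessian sums) recorded in the model, i.e. the
path-dependent feature perturbation.

Cross-checks live in the test suite: xgboost's native ``pred_contribs``
and a brute-force Shapley enumeration over per-subset expected values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

try:  # numba accelerates the per-(row, tree) recursion ~100x
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap if not (args and callable(args[0])) else args[0]


@dataclass
class ParsedTrees:
    """Flat array representation of a boosted ensemble.

    Node arrays are concatenated over trees; ``tree_start[t]`` indexes the
    root of tree ``t``.  ``value`` holds leaf values (0 for internal
    nodes); ``cover`` the per-node hessian sums.
    """

    tree_start: np.ndarray      # (T+1,) offsets into node arrays
    children_left: np.ndarray   # (N,) absolute node index, -1 at leaves
    children_right: np.ndarray
    children_default: np.ndarray
    feature: np.ndarray         # (N,) split feature index, -1 at leaves
    threshold: np.ndarray       # (N,)
    value: np.ndarray           # (N,)
    cover: np.ndarray           # (N,)
    base_score: float
    max_depth: int
    feature_names: list[str]


def parse_booster(booster) -> ParsedTrees:
    """Parse an XGBoost booster's JSON dump into flat node arrays."""
    dump = booster.get_dump(dump_format="json", with_stats=True)
    names = booster.feature_names
    feat_index = ({n: i for i, n in enumerate(names)} if names is not None
                  else None)

    cl, cr, cd, ft, th, vl, cv = [], [], [], [], [], [], []
    tree_start = [0]
    max_depth = 0

    def walk(node, depth):
        nonlocal max_depth
        max_depth = max(max_depth, depth)
        idx = len(cl)
        cl.append(-1); cr.append(-1); cd.append(-1)
        if "leaf" in node:
            ft.append(-1); th.append(0.0)
            vl.append(float(node["leaf"])); cv.append(float(node["cover"]))
            return idx
        name = node["split"]
        if feat_index is not None:
            fi = feat_index[name]
        else:
            fi = int(name.lstrip("f"))
        ft.append(fi); th.append(float(node["split_condition"]))
        vl.append(0.0); cv.append(float(node["cover"]))
        kids = {c["nodeid"]: c for c in node["children"]}
        left = walk(kids[node["yes"]], depth + 1)
        right = walk(kids[node["no"]], depth + 1)
        cl[idx], cr[idx] = left, right
        cd[idx] = left if node["missing"] == node["yes"] else right
        return idx

    for tree_json in dump:
        walk(json.loads(tree_json), 0)
        tree_start.append(len(cl))

    config = json.loads(booster.save_config())
    base_score = float(
        config["learner"]["learner_model_param"]["base_score"])

    return ParsedTrees(
        tree_start=np.asarray(tree_start, dtype=np.int64),
        children_left=np.asarray(cl, dtype=np.int64),
        children_right=np.asarray(cr, dtype=np.int64),
        children_default=np.asarray(cd, dtype=np.int64),
        feature=np.asarray(ft, dtype=np.int64),
        # float32: xgboost stores split conditions and compares features
        # in single precision, and boundary ties must resolve identically
        threshold=np.asarray(th, dtype=np.float32),
        value=np.asarray(vl, dtype=np.float64),
        cover=np.asarray(cv, dtype=np.float64),
        base_score=base_score,
        max_depth=int(max_depth),
        feature_names=list(names) if names is not None else [],
    )


@njit(cache=False)
def _extend(fi, zf, of, pw, unique_depth, pz, po, pidx):
    fi[unique_depth] = pidx
    zf[unique_depth] = pz
    of[unique_depth] = po
    pw[unique_depth] = 1.0 if unique_depth == 0 else 0.0
    for i in range(unique_depth - 1, -1, -1):
        pw[i + 1] += po * pw[i] * (i + 1.0) / (unique_depth + 1.0)
        pw[i] = pz * pw[i] * (unique_depth - i) / (unique_depth + 1.0)


@njit(cache=False)
def _unwind(fi, zf, of, pw, unique_depth, path_index):
    po = of[path_index]
    pz = zf[path_index]
    nxt = pw[unique_depth]
    for i in range(unique_depth - 1, -1, -1):
        if po != 0.0:
            tmp = pw[i]
            pw[i] = nxt * (unique_depth + 1.0) / ((i + 1.0) * po)
            nxt = tmp - pw[i] * pz * (unique_depth - i) / (unique_depth + 1.0)
        else:
            pw[i] = pw[i] * (unique_depth + 1.0) / (pz * (unique_depth - i))
    for i in range(path_index, unique_depth):
        fi[i] = fi[i + 1]
        zf[i] = zf[i + 1]
        of[i] = of[i + 1]


@njit(cache=False)
def _unwound_sum(zf, of, pw, unique_depth, path_index):
    po = of[path_index]
    pz = zf[path_index]
    nxt = pw[unique_depth]
    total = 0.0
    for i in range(unique_depth - 1, -1, -1):
        if po != 0.0:
            tmp = nxt * (unique_depth + 1.0) / ((i + 1.0) * po)
            total += tmp
            nxt = pw[i] - tmp * pz * (unique_depth - i) / (unique_depth + 1.0)
        else:
            total += pw[i] / (pz * (unique_depth - i) / (unique_depth + 1.0))
    return total


@njit(cache=False)
def _recurse(cl, cr, cd, ft, th, vl, cv, x, phi,
             node, unique_depth, pfi, pzf, pof, ppw, pz, po, pidx):
    # child keeps its path in the tail of the parent's flat storage
    fi = pfi[unique_depth + 1:]
    zf = pzf[unique_depth + 1:]
    of = pof[unique_depth + 1:]
    pw = ppw[unique_depth + 1:]
    for i in range(unique_depth):
        fi[i] = pfi[i]
        zf[i] = pzf[i]
        of[i] = pof[i]
        pw[i] = ppw[i]
    _extend(fi, zf, of, pw, unique_depth, pz, po, pidx)

    if cl[node] < 0:  # leaf
        for i in range(1, unique_depth + 1):
            w = _unwound_sum(zf, of, pw, unique_depth, i)
            phi[fi[i]] += w * (of[i] - zf[i]) * vl[node]
        return

    split = ft[node]
    xv = x[split]
    if np.isnan(xv):
        hot = cd[node]
    elif xv < th[node]:
        hot = cl[node]
    else:
        hot = cr[node]
    cold = cr[node] if hot == cl[node] else cl[node]

    iz = 1.0
    io = 1.0
    path_index = 0
    ud = unique_depth
    for i in range(1, ud + 1):
        if fi[i] == split:
            path_index = i
            break
    if path_index > 0:
        iz = zf[path_index]
        io = of[path_index]
        _unwind(fi, zf, of, pw, ud, path_index)
        ud -= 1

    _recurse(cl, cr, cd, ft, th, vl, cv, x, phi, hot, ud + 1,
             fi, zf, of, pw, iz * cv[hot] / cv[node], io, split)
    _recurse(cl, cr, cd, ft, th, vl, cv, x, phi, cold, ud + 1,
             fi, zf, of, pw, iz * cv[cold] / cv[node], 0.0, split)


@njit(cache=False)
def _shap_all(tree_start, cl, cr, cd, ft, th, vl, cv, X, maxd):
    n, p = X.shape
    phi = np.zeros((n, p))
    s = (maxd + 2) * (maxd + 3)  # flat triangular path storage, with slack
    for row in range(n):
        x = X[row]
        for t in range(len(tree_start) - 1):
            root = tree_start[t]
            fi = np.empty(s, dtype=np.int64)
            zf = np.empty(s)
            of = np.empty(s)
            pw = np.empty(s)
            _recurse(cl, cr, cd, ft, th, vl, cv, x, phi[row],
                     root, 0, fi, zf, of, pw, 1.0, 1.0, -1)
    return phi


@njit(cache=False)
def _predict_all(tree_start, cl, cr, cd, ft, th, vl, X, base_score):
    n = X.shape[0]
    out = np.full(n, base_score)
    for row in range(n):
        for t in range(len(tree_start) - 1):
            node = tree_start[t]
            while cl[node] >= 0:
                xv = X[row, ft[node]]
                if np.isnan(xv):
                    node = cd[node]
                elif xv < th[node]:
                    node = cl[node]
                else:
                    node = cr[node]
            out[row] += vl[node]
    return out


@njit(cache=False)
def _expected_value(tree_start, cl, cr, vl, cv):
    total = 0.0
    for t in range(len(tree_start) - 1):
        root = tree_start[t]
        end = tree_start[t + 1]
        for node in range(root, end):
            if cl[node] < 0:
                total += vl[node] * cv[node] / cv[root]
    return total


def shap_values(trees: ParsedTrees, X: np.ndarray
                ) -> tuple[np.ndarray, float, np.ndarray]:
    """Exact attributions for every row of ``X``.

    Returns ``(phi, base_value, predictions)`` in float64; for every row,
    ``base_value + phi.sum() == prediction`` to float64 round-off.
    """
    # decisions are taken in float32 to mirror xgboost's traversal
    X = np.ascontiguousarray(X, dtype=np.float32)
    phi = _shap_all(trees.tree_start, trees.children_left,
                    trees.children_right, trees.children_default,
                    trees.feature, trees.threshold, trees.value,
                    trees.cover, X, trees.max_depth)
    base = trees.base_score + _expected_value(
        trees.tree_start, trees.children_left, trees.children_right,
        trees.value, trees.cover)
    preds = _predict_all(trees.tree_start, trees.children_left,
                         trees.children_right, trees.children_default,
                         trees.feature, trees.threshold, trees.value,
                         X, trees.base_score)
    return phi, float(base), preds


def expected_value_subset(trees: ParsedTrees, x: np.ndarray,
                          subset: frozenset | set) -> float:
    """Brute-force conditional expectation E[f(x) | x_S] under the
    path-dependent (cover-weighted) perturbation — the oracle primitive for
    enumerating Shapley values on tiny models."""

    def rec(node):
        if trees.children_left[node] < 0:
            return trees.value[node]
        f = trees.feature[node]
        if f in subset:
            xv = x[f]
            if np.isnan(xv):
                return rec(trees.children_default[node])
            nxt = (trees.children_left[node] if xv < trees.threshold[node]
                   else trees.children_right[node])
            return rec(nxt)
        l, r = trees.children_left[node], trees.children_right[node]
        wl = trees.cover[l] / trees.cover[node]
        wr = trees.cover[r] / trees.cover[node]
        return wl * rec(l) + wr * rec(r)

    return trees.base_score + sum(
        rec(trees.tree_start[t]) for t in range(len(trees.tree_start) - 1))


def brute_force_shap(trees: ParsedTrees, x: np.ndarray) -> np.ndarray:
    """Exact Shapley values by subset enumeration over the features the
    ensemble actually uses (exponential; tiny models only)."""
    from itertools import combinations
    from math import factorial

    p = int(max(trees.feature.max() + 1, len(x)))
    used = sorted({int(f) for f in trees.feature if f >= 0})
    phi = np.zeros(p)
    m = len(used)
    for j in used:
        others = [f for f in used if f != j]
        for k in range(m):
            for combo in combinations(others, k):
                s = frozenset(combo)
                weight = factorial(k) * factorial(m - k - 1) / factorial(m)
                gain = (expected_value_subset(trees, x, s | {j})
                        - expected_value_subset(trees, x, s))
                phi[j] += weight * gain
    return phi
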