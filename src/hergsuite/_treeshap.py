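"""Exact interventional Shapley values for tree ensembles.

For a tree model f and a background sample z, the coalition value of a
feature subset S is f evaluated on the hybrid point that takes features in
S from the query x and the rest from z.  Shapley values of this game can be
computed exactly by enumerating root-to-leaf paths: at every node where x
and z would take different branches the path forks, and a reached leaf's
value is shared among the unique "x-side" features (positively) and
"z-side" features (negatively) with the closed-form weights

    +v * (k-1)! m! / (k+m)!   for each of the k x-side features
    -v * k! (m-1)! / (k+m)!   for each of the m z-side features.

Averaging over a background set gives attributions that satisfy exact
additivity:  base + sum(phi) == f(x),  base = mean_z f(z).

Supported models: sklearn decision trees, random forests, classic and
histogram gradient boosting (classifier raw output = probability for
forests, raw decision score for boosting).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.special import gammaln
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    HistGradientBoostingClassifier,
    HistGradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor


@dataclass
class TreeArrays:
    """One decision tree in flat-array form.

    ``value[i]`` is the (already scaled) contribution of leaf i to the
    ensemble's raw output; internal-node entries are unused.  The split
    rule is: go left iff x[feature[i]] <= threshold[i].
    """

    left: np.ndarray
    right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    value: np.ndarray

    def leaf_value(self, x: np.ndarray) -> float:
        node = 0
        while self.left[node] >= 0:
            node = (
                self.left[node]
                if x[self.feature[node]] <= self.threshold[node]
                else self.right[node]
            )
        return float(self.value[node])


def _from_sklearn_tree(tree, scale: float, class_index: int | None,
                       normalize: bool) -> TreeArrays:
    t = tree.tree_
    value = t.value[:, 0, :]
    if class_index is not None:
        if normalize:  # classification tree stores per-class counts/fractions
            totals = value.sum(axis=1)
            totals[totals == 0] = 1.0
            v = value[:, class_index] / totals
        else:
            v = value[:, class_index]
    else:
        v = value[:, 0]
    return TreeArrays(
        left=t.children_left.copy(),
        right=t.children_right.copy(),
        feature=t.feature.copy(),
        threshold=t.threshold.copy(),
        value=v * scale,
    )


def _from_hist_predictor(predictor, scale: float) -> TreeArrays:
    nodes = predictor.nodes
    n = len(nodes)
    left = np.full(n, -1, dtype=np.int64)
    right = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        if not nodes[i]["is_leaf"]:
            left[i] = nodes[i]["left"]
            right[i] = nodes[i]["right"]
    return TreeArrays(
        left=left,
        right=right,
        feature=nodes["feature_idx"].astype(np.int64),
        threshold=nodes["num_threshold"].astype(float),
        value=nodes["value"].astype(float) * scale,
    )


def extract_trees(model, class_index: int = -1) -> tuple[list[TreeArrays], float]:
    """Flatten a supported sklearn tree model into (trees, constant offset).

    The model's raw output is offset + sum of per-tree leaf values.
    ``class_index`` selects the explained class for classifiers (ignored
    for regressors); -1 means the last (for binary tasks: positive) class.
    """
    if isinstance(model, (DecisionTreeRegressor,)):
        return [_from_sklearn_tree(model, 1.0, None, False)], 0.0
    if isinstance(model, DecisionTreeClassifier):
        ci = class_index % len(model.classes_)
        return [_from_sklearn_tree(model, 1.0, ci, True)], 0.0
    if isinstance(model, RandomForestRegressor):
        n = len(model.estimators_)
        return [_from_sklearn_tree(e, 1.0 / n, None, False) for e in model.estimators_], 0.0
    if isinstance(model, RandomForestClassifier):
        n = len(model.estimators_)
        ci = class_index % len(model.classes_)
        return [_from_sklearn_tree(e, 1.0 / n, ci, True) for e in model.estimators_], 0.0
    if isinstance(model, GradientBoostingRegressor):
        lr = model.learning_rate
        trees = [_from_sklearn_tree(e, lr, None, False) for e in model.estimators_[:, 0]]
        return trees, _probe_offset(model, trees)
    if isinstance(model, GradientBoostingClassifier):
        lr = model.learning_rate
        col = 0 if model.estimators_.shape[1] == 1 else class_index % model.estimators_.shape[1]
        trees = [_from_sklearn_tree(e, lr, None, False) for e in model.estimators_[:, col]]
        return trees, _probe_offset(model, trees, class_index)
    if isinstance(model, (HistGradientBoostingRegressor, HistGradientBoostingClassifier)):
        preds = model._predictors
        n_out = len(preds[0])
        col = 0 if n_out == 1 else class_index % n_out
        trees = [_from_hist_predictor(it[col], 1.0) for it in preds]
        return trees, _probe_offset(model, trees, class_index)
    raise TypeError(f"unsupported model type {type(model).__name__}")


def raw_output(model, X: np.ndarray, class_index: int = -1) -> np.ndarray:
    """The scalar the attributions decompose: probability for forests and
    single trees, raw decision score for boosting, prediction for
    regressors."""
    X = np.asarray(X, dtype=float)
    if isinstance(model, (RandomForestClassifier, DecisionTreeClassifier)):
        ci = class_index % len(model.classes_)
        return model.predict_proba(X)[:, ci]
    if isinstance(model, GradientBoostingClassifier):
        raw = model.decision_function(X)
        if raw.ndim == 1:
            return raw
        return raw[:, class_index % raw.shape[1]]
    if isinstance(model, HistGradientBoostingClassifier):
        raw = model._raw_predict(X)
        if raw.ndim == 2 and raw.shape[1] > 1:
            return raw[:, class_index % raw.shape[1]]
        return raw.ravel()
    return model.predict(X)


def _probe_offset(model, trees: list[TreeArrays], class_index: int = -1) -> float:
    """Constant raw-output offset (boosting init), found with one probe point."""
    n_features = getattr(model, "n_features_in_")
    x0 = np.zeros((1, n_features))
    raw = float(raw_output(model, x0, class_index)[0])
    return raw - sum(t.leaf_value(x0[0]) for t in trees)


# ---------------------------------------------------------------------------
# the Shapley recursion


def _tree_shap_xz(tree: TreeArrays, x: np.ndarray, z: np.ndarray,
                  phi: np.ndarray) -> None:
    """Accumulate exact Shapley values of f(x_S, z_~S) for one tree into phi."""

    def recurse(node: int, x_feats: dict, z_feats: dict) -> None:
        while tree.left[node] >= 0:
            f = int(tree.feature[node])
            thr = tree.threshold[node]
            x_child = tree.left[node] if x[f] <= thr else tree.right[node]
            z_child = tree.left[node] if z[f] <= thr else tree.right[node]
            if x_child == z_child:
                node = x_child
                continue
            if f in x_feats:
                node = x_child
                continue
            if f in z_feats:
                node = z_child
                continue
            # genuine fork: feature f may come from x or from z
            recurse(x_child, {**x_feats, f: None}, z_feats)
            recurse(z_child, x_feats, {**z_feats, f: None})
            return
        v = float(tree.value[node])
        k, m = len(x_feats), len(z_feats)
        if k:
            w = v / (k * comb(k + m, m))        # v * (k-1)! m! / (k+m)!
            for f in x_feats:
                phi[f] += w
        if m:
            w = v / (m * comb(k + m, k))        # v * k! (m-1)! / (k+m)!
            for f in z_feats:
                phi[f] -= w

    recurse(0, {}, {})


def tree_shap(model, X, background, class_index: int = -1
              ) -> tuple[np.ndarray, float]:
    """Exact interventional Shapley values for a tree model.

    Returns ``(phi, base)`` with ``phi`` of shape (n_samples, n_features)
    and ``base = mean_z raw(z)``; for every row,
    ``base + phi.sum() == raw(x)`` exactly (up to float round-off).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(background, dtype=float))
    trees, offset = extract_trees(model, class_index)
    base = offset + float(
        np.mean([sum(t.leaf_value(z) for t in trees) for z in Z])
    )
    phi = np.zeros((X.shape[0], X.shape[1]))
    for i, x in enumerate(X):
        acc = np.zeros(X.shape[1])
        for z in Z:
            for t in trees:
                _tree_shap_xz(t, x, z, acc)
        phi[i] = acc / Z.shape[0]
    return phi, base


# ---------------------------------------------------------------------------
# kernel approximation for non-tree models


def kernel_shap(predict_fn, X, background, n_coalitions: int = 2048,
                seed: int = 0) -> tuple[np.ndarray, float]:
    """Seeded kernel-regression Shapley approximation for black-box models.

    ``predict_fn`` maps a sample matrix to a scalar output vector.  Each
    query is explained by a weighted linear regression over random feature
    coalitions (hybrids of query and background rows), with the efficiency
    constraint sum(phi) = f(x) - base enforced exactly.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(background, dtype=float))
    n, d = X.shape
    rng = np.random.RandomState(seed)
    base = float(np.mean(predict_fn(Z)))

    # coalition sizes weighted by the Shapley kernel (M-1)/(C(M,s) s (M-s))
    sizes = np.arange(1, d)
    size_w = (d - 1) / (sizes * (d - sizes))
    size_w = size_w / size_w.sum()

    phi = np.zeros((n, d))
    for i, x in enumerate(X):
        masks = np.zeros((n_coalitions, d), dtype=bool)
        for row in range(n_coalitions):
            s = rng.choice(sizes, p=size_w)
            masks[row, rng.choice(d, size=s, replace=False)] = True
        # evaluate v(S) averaged over the background
        vals = np.zeros(n_coalitions)
        for z in Z:
            hybrids = np.where(masks, x, z)
            vals += predict_fn(hybrids)
        vals /= Z.shape[0]
        fx = float(np.mean(predict_fn(x.reshape(1, -1))))
        # weighted least squares with the constraint phi.sum() == fx - base:
        # substitute phi_d = (fx - base) - sum(phi_1..d-1)
        # Shapley kernel weights in log space (C(d, s) overflows for wide
        # fingerprints); only relative weights matter for the regression
        s_count = masks.sum(axis=1).astype(float)
        log_comb = (gammaln(d + 1) - gammaln(s_count + 1)
                    - gammaln(d - s_count + 1))
        log_w = -log_comb - np.log(s_count) - np.log(d - s_count)
        w = np.exp(log_w - log_w.max())
        A = masks[:, :-1].astype(float) - masks[:, -1:].astype(float)
        b = vals - base - masks[:, -1] * (fx - base)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(A * sw[:, None], b * sw, rcond=None)
        phi[i, :-1] = coef
        phi[i, -1] = (fx - base) - coef.sum()
    return phi, base
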