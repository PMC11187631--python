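"""Independent brute-force oracles the implementation is checked against.

Everything here is written from first principles (confusion-matrix
formulas, O(n^2) pair enumeration, 2^d Shapley enumeration) and never
calls the package's own code paths.
"""

import itertools
import math

import numpy as np


def confusion_metrics(y_true, y_pred, positive):
    """Binary metrics straight from TP/FP/TN/FN."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    se = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * precision * se / (precision + se) if precision + se else 0.0
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return {"se": se, "sp": sp, "bacc": (se + sp) / 2,
            "precision": precision, "f1": f1, "mcc": mcc}


def regression_metrics(y_true, y_pred):
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    res = y_true - y_pred
    mse = float(np.mean(res ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    return {"mse": mse, "rmse": math.sqrt(mse),
            "mae": float(np.mean(np.abs(res))),
            "r2": 1.0 - float(np.sum(res ** 2)) / ss_tot}


def tanimoto(a, b):
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    union = np.logical_or(a, b).sum()
    return float(np.logical_and(a, b).sum() / union) if union else 0.0


def pairwise_tanimoto_mean(A, B, exclude_self=False):
    vals = []
    for i, a in enumerate(A):
        for j, b in enumerate(B):
            if exclude_self and i == j:
                continue
            vals.append(tanimoto(a, b))
    return float(np.mean(vals))


def nn_distances(X, k):
    """Leave-self-out mean Euclidean k-NN distance per row, O(n^2)."""
    X = np.asarray(X, float)
    out = []
    for i in range(len(X)):
        d = np.sort([np.linalg.norm(X[i] - X[j]) for j in range(len(X)) if j != i])
        out.append(float(np.mean(d[:k])))
    return np.array(out)


def brute_shapley(value_fn, d):
    """Exact Shapley values of a set function over d players (2^d calls)."""
    phi = np.zeros(d)
    for j in range(d):
        others = [k for k in range(d) if k != j]
        for r in range(d):
            for S in itertools.combinations(others, r):
                w = (math.factorial(len(S)) * math.factorial(d - len(S) - 1)
                     / math.factorial(d))
                phi[j] += w * (value_fn(frozenset(S) | {j}) - value_fn(frozenset(S)))
    return phi


def interventional_value_fn(predict, x, Z):
    """v(S) = mean_z predict(x_S combined with z_~S)."""
    Z = np.asarray(Z, float)

    def v(S):
        idx = list(S)
        H = Z.copy()
        H[:, idx] = x[idx]
        return float(np.mean(predict(H)))

    return v


def cohens_kappa(a, b):
    a, b = np.asarray(a), np.asarray(b)
    classes = np.unique(np.concatenate([a, b]))
    p_o = float(np.mean(a == b))
    p_e = sum(float(np.mean(a == c)) * float(np.mean(b == c)) for c in classes)
    return (p_o - p_e) / (1 - p_e)
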