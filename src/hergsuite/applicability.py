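"""Applicability domain: distance-to-training-set cutoff.

A query is inside the domain when its mean Euclidean distance to its k
nearest training fingerprints does not exceed

    D_c = mean + z * sd

of the training set's own leave-self-out k-nearest-neighbor distances
(k = 1, z = 0.5 by default, the convention of the distance-based AD
literature).  Predictions outside the domain are flagged as unreliable,
never suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .featurize import FingerprintMatrix


@dataclass
class ADModel:
    reference: np.ndarray          # training fingerprints (n x bits)
    k: int = 1
    z: float = 0.5
    cutoff: float = 0.0            # D_c
    _nn: NearestNeighbors = field(default=None, repr=False)

    def _index(self) -> NearestNeighbors:
        if self._nn is None:
            self._nn = NearestNeighbors(n_neighbors=self.k, metric="euclidean")
            self._nn.fit(self.reference)
        return self._nn


def fit_ad(train: FingerprintMatrix | np.ndarray, k: int = 1, z: float = 0.5) -> ADModel:
    """Fit the domain cutoff from the training set.

    Each training compound's distance is the mean Euclidean distance to its
    k nearest *other* training compounds (leave-self-out); D_c is the mean
    plus z standard deviations (population SD) of those distances.
    """
    X = train.bits if isinstance(train, FingerprintMatrix) else np.asarray(train)
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("AD estimation needs at least 2 training compounds")
    if k < 1 or k > X.shape[0] - 1:
        raise ValueError("k must be in [1, n_train - 1]")
    nn = NearestNeighbors(n_neighbors=k + 1, metric="euclidean").fit(X)
    dist, _ = nn.kneighbors(X)
    # first column is the self-match (distance 0, possibly tied with exact
    # duplicates — either way dropping one zero-distance column is exact)
    loo = dist[:, 1:].mean(axis=1)
    cutoff = float(loo.mean() + z * loo.std())
    model = ADModel(reference=X, k=k, z=z, cutoff=cutoff)
    model._index()
    return model


def in_domain(ad: ADModel, query: np.ndarray) -> tuple[bool, float]:
    """Flag one query fingerprint: (inside_domain, mean k-NN distance)."""
    q = np.asarray(query, dtype=float).reshape(1, -1)
    if q.shape[1] != ad.reference.shape[1]:
        raise ValueError(
            f"query has {q.shape[1]} bits, reference has {ad.reference.shape[1]}"
        )
    dist, _ = ad._index().kneighbors(q, n_neighbors=ad.k)
    d = float(dist.mean())
    return d <= ad.cutoff, d


def in_domain_many(ad: ADModel, queries: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`in_domain` over a query matrix."""
    Q = np.asarray(queries, dtype=float)
    if Q.shape[1] != ad.reference.shape[1]:
        raise ValueError("bit-length mismatch")
    dist, _ = ad._index().kneighbors(Q, n_neighbors=ad.k)
    d = dist.mean(axis=1)
    return d <= ad.cutoff, d
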