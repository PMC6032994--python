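"""Fuzzy k-nearest-neighbor classification.

A fuzzy k-NN model stores graded class memberships for every training
pattern instead of crisp labels.  Training memberships follow the
constrained (Keller-style) scheme: a pattern receives a base membership of
0.51 in its own class and the remaining 0.49 is shared among classes in
proportion to the class makeup of its ``k_init`` nearest training
neighbors.  Prediction averages the neighbor membership rows with
inverse-distance weights ``w_j = ||x - x_j||^(-2/(m-1))``; the fuzzy
strength ``m > 1`` controls how sharply near neighbors dominate (large
``m`` flattens the weights toward a plain average).  The crisp decision is
the class of highest predicted membership, ties broken toward the lowest
class id.

Distances are Euclidean throughout.  Because the weights are ratios of
powers of distances, predictions are invariant to any uniform positive
rescaling of the feature space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import ContractError

__all__ = [
    "FknnModel",
    "assign_training_memberships",
    "fit",
    "predict_memberships",
    "classify",
]

ZERO_DISTANCE = 1e-12
_OWN_CLASS_BASE = 0.51


@dataclass(frozen=True)
class FknnModel:
    """Fitted fuzzy k-NN model.

    Attributes
    ----------
    features : ndarray, shape (n, d)
        Training feature matrix.
    labels : ndarray, shape (n,)
        Integer class indices into ``classes_``.
    classes_ : ndarray, shape (C,)
        Sorted original class labels.
    memberships : ndarray, shape (n, C)
        Constrained training membership matrix; rows sum to 1.
    k : int
        Prediction neighborhood size (``1 <= k <= n - 1``).
    m : float
        Fuzzy strength (``> 1``).
    k_init : int
        Neighborhood size used when the memberships were assigned.
    """

    features: np.ndarray
    labels: np.ndarray
    classes_: np.ndarray
    memberships: np.ndarray
    k: int
    m: float
    k_init: int

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    def to_text(self) -> str:
        """Serialize to a plain-text (JSON) descriptor."""
        return json.dumps(
            {
                "k": int(self.k),
                "m": float(self.m),
                "k_init": int(self.k_init),
                "classes": self.classes_.tolist(),
                "features": self.features.tolist(),
                "labels": self.labels.tolist(),
                "memberships": self.memberships.tolist(),
            }
        )

    @classmethod
    def from_text(cls, text: str) -> "FknnModel":
        d = json.loads(text)
        return cls(
            features=np.asarray(d["features"], dtype=float),
            labels=np.asarray(d["labels"], dtype=int),
            classes_=np.asarray(d["classes"]),
            memberships=np.asarray(d["memberships"], dtype=float),
            k=int(d["k"]),
            m=float(d["m"]),
            k_init=int(d["k_init"]),
        )


def _validate_xy(features, labels):
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ContractError("features must be a 2-D array")
    if y.shape != (X.shape[0],):
        raise ContractError("labels must be 1-D and match the sample count")
    return X, y


def assign_training_memberships(features, labels, k_init: int) -> np.ndarray:
    """Constrained membership matrix for the training set.

    For each training pattern its ``k_init`` nearest *other* training points
    are found (Euclidean distance, the pattern itself excluded).  With
    ``n_j`` neighbors in class ``j`` out of ``K = k_init``:

    * own class:   ``0.51 + (n_j / K) * 0.49``
    * other class: ``(n_j / K) * 0.49``

    Every row therefore sums to exactly 1.
    """
    X, y = _validate_xy(features, labels)
    n = X.shape[0]
    classes, yi = np.unique(y, return_inverse=True)
    C = classes.size
    if C < 2:
        raise ContractError("at least two classes are required")
    if not (1 <= k_init <= n - 1):
        raise ContractError(f"k_init must be in [1, {n - 1}], got {k_init}")

    D = cdist(X, X)
    np.fill_diagonal(D, np.inf)
    # stable sort keeps ties at the k-th distance deterministic (lowest index)
    order = np.argsort(D, axis=1, kind="stable")[:, :k_init]
    neighbor_classes = yi[order]  # (n, k_init)

    counts = np.zeros((n, C))
    for c in range(C):
        counts[:, c] = (neighbor_classes == c).sum(axis=1)
    U = counts / k_init * (1.0 - _OWN_CLASS_BASE)
    U[np.arange(n), yi] += _OWN_CLASS_BASE
    return U


def fit(features, labels, k: int, m: float, k_init: int | None = None) -> FknnModel:
    """Build a fuzzy k-NN model from crisp-labelled training data.

    ``k_init`` defaults to the prediction neighborhood ``k``.
    """
    X, y = _validate_xy(features, labels)
    n = X.shape[0]
    if not (1 <= k <= n - 1):
        raise ContractError(f"k must be in [1, {n - 1}], got {k}")
    if not m > 1:
        raise ContractError(f"fuzzy strength m must exceed 1, got {m}")
    if k_init is None:
        k_init = k
    classes, yi = np.unique(y, return_inverse=True)
    U = assign_training_memberships(X, y, k_init)
    return FknnModel(
        features=X,
        labels=yi,
        classes_=classes,
        memberships=U,
        k=int(k),
        m=float(m),
        k_init=int(k_init),
    )


def predict_memberships(model: FknnModel, queries) -> np.ndarray:
    """Per-class membership vectors for query points.

    Weighted average of the ``k`` nearest training membership rows with
    weights ``||x - x_j||^(-2/(m-1))``.  If any neighbor lies within
    ``1e-12`` of the query, the average of the zero-distance rows is
    returned (the continuous limit of the weighting rule).  Rows sum to 1.
    """
    Q = np.asarray(queries, dtype=float)
    single = Q.ndim == 1
    Q = np.atleast_2d(Q)
    if Q.shape[1] != model.features.shape[1]:
        raise ContractError("query dimension does not match training features")

    D = cdist(Q, model.features)
    order = np.argsort(D, axis=1, kind="stable")[:, : model.k]
    rows = np.arange(Q.shape[0])[:, None]
    dk = D[rows, order]  # (q, k)
    Uk = model.memberships[order]  # (q, k, C)

    out = np.empty((Q.shape[0], model.classes_.size))
    zero = dk < ZERO_DISTANCE
    has_zero = zero.any(axis=1)
    exponent = 2.0 / (model.m - 1.0)
    safe = np.where(zero, 1.0, dk)
    # normalize by the per-row nearest distance before exponentiating:
    # weights become (d_min/d_j)^(2/(m-1)) in (0, 1], immune to overflow
    # and manifestly scale-invariant
    ref = safe.min(axis=1, keepdims=True)
    w = (ref / safe) ** exponent
    wn = w / w.sum(axis=1, keepdims=True)
    out[:] = np.einsum("qk,qkc->qc", wn, Uk)
    if has_zero.any():
        for q in np.nonzero(has_zero)[0]:
            out[q] = Uk[q][zero[q]].mean(axis=0)
    return out[0] if single else out


def classify(model: FknnModel, queries) -> np.ndarray:
    """Crisp class prediction: argmax membership, ties to lowest class id."""
    U = np.atleast_2d(predict_memberships(model, queries))
    idx = U.argmax(axis=1)  # argmax returns the first (lowest-id) maximum
    labels = model.classes_[idx]
    return labels[0] if np.asarray(queries).ndim == 1 else labels
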