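"""Borderline-SMOTE oversampling of minority phenotype classes.

Implements the borderline-1 variant: only minority samples near the decision
boundary (the "danger" set — at least half of their m nearest neighbours in
the whole training set belong to other classes, but not all) seed synthetic
points, each drawn on the segment between the seed and one of its k nearest
same-class neighbours.  Every minority class is brought up to the majority
class count.  Applied strictly inside training partitions; validation rows
must never pass through here.
"""

from __future__ import annotations

import warnings
from collections import Counter

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .exceptions import ResamplingError


def class_counts(labels) -> dict[int, int]:
    """Frequency of each label value."""
    return dict(Counter(int(v) for v in np.asarray(labels).ravel()))


def _danger_mask(
    X: np.ndarray, y: np.ndarray, class_idx: np.ndarray, m_neighbors: int
) -> np.ndarray:
    """Borderline danger set: m/2 ≤ (foreign neighbours) < m."""
    m = min(m_neighbors, len(X) - 1)
    nn = NearestNeighbors(n_neighbors=m + 1).fit(X)
    _, idx = nn.kneighbors(X[class_idx])
    neigh_labels = y[idx[:, 1:]]  # drop self
    cls = y[class_idx[0]]
    n_foreign = (neigh_labels != cls).sum(axis=1)
    return (n_foreign * 2 >= m) & (n_foreign < m)


def borderline_smote(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    m_neighbors: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample minority classes to the majority count.

    Returns ``(X_resampled, y_resampled)`` with all original rows first,
    preserved verbatim, followed by the synthetic rows.  Each synthetic row is
    ``x + u * (x_nn - x)`` with ``u ~ U(0, 1)``, ``x`` a danger-set member of
    the minority class and ``x_nn`` one of its ``k_neighbors`` same-class
    nearest neighbours.  If a class's danger set is empty, all its members
    seed interpolation instead (plain SMOTE fallback) so the balance contract
    still holds.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ResamplingError(f"feature/label shape mismatch: {X.shape} vs {y.shape}")
    counts = class_counts(y)
    if len(counts) < 2:
        raise ResamplingError("resampling needs at least 2 distinct classes")
    majority = max(counts.values())
    rng = np.random.default_rng(seed)

    new_rows: list[np.ndarray] = []
    new_labels: list[int] = []
    for cls in sorted(counts):
        deficit = majority - counts[cls]
        if deficit == 0:
            continue
        if counts[cls] < 2:
            raise ResamplingError(
                f"class {cls} has a single sample; SMOTE cannot interpolate. "
                "Collect more data for this class or merge it."
            )
        cls_idx = np.flatnonzero(y == cls)
        Xc = X[cls_idx]
        if np.allclose(Xc, Xc[0]):
            raise ResamplingError(
                f"class {cls} has all-identical feature rows; interpolation is degenerate"
            )
        danger = _danger_mask(X, y, cls_idx, m_neighbors)
        if not danger.any():
            warnings.warn(
                f"class {cls}: empty danger set, falling back to plain SMOTE",
                stacklevel=2,
            )
            seeds = Xc
        else:
            seeds = Xc[danger]
        k = min(k_neighbors, len(Xc) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        _, neigh = nn.kneighbors(seeds)
        for _ in range(deficit):
            i = int(rng.integers(len(seeds)))
            j = int(rng.integers(1, k + 1))  # skip self at column 0
            x = seeds[i]
            x_nn = Xc[neigh[i, j]]
            u = rng.random()
            new_rows.append(x + u * (x_nn - x))
            new_labels.append(cls)

    if not new_rows:
        return X.copy(), y.copy()
    Xr = np.vstack([X, np.vstack(new_rows)])
    yr = np.concatenate([y, np.asarray(new_labels, dtype=int)])
    return Xr, yr
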