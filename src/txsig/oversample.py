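"""Minority-class oversamplers: RandomOverSampler, Borderline-SMOTE, SVM-SMOTE.

Implemented natively (no imbalanced-learn dependency). All three equalize the
class counts by appending rows for the minority class only; the original rows
are preserved verbatim at the front of the returned arrays. SMOTE-family
synthetic rows are convex combinations of two minority samples:

    x_new = x_seed + u * (x_neighbour - x_seed),   u ~ Uniform[0, 1)

Borderline-SMOTE (borderline-1) seeds only from "danger" minority points —
those whose m-neighbourhood is at least half majority but not entirely
majority. SVM-SMOTE seeds from the minority support vectors of an SVC fit on
the fold; the interpolation branch is used for every seed so the convexity
guarantee holds.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .datatypes import ValidationError

__all__ = ["OVERSAMPLERS", "oversample_training_fold"]

OVERSAMPLERS = ("BorderlineSMOTE", "SVMSMOTE", "RandomOverSampler")

_warned: set[str] = set()


def _warn_once(message: str) -> None:
    if message not in _warned:
        _warned.add(message)
        warnings.warn(message, stacklevel=3)


def _classes_and_minority(y: np.ndarray) -> tuple[np.ndarray, object, object]:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValidationError(f"oversampling requires exactly two classes, got {len(classes)}")
    order = np.argsort(counts, kind="stable")
    return classes, classes[order[0]], classes[order[1]]


def _effective_k(requested: int, n_min: int, what: str) -> int:
    if n_min < 2:
        raise ValidationError(f"minority class too small for {what} (need >= 2 samples)")
    k = min(requested, n_min - 1)
    if k < requested:
        _warn_once(
            f"{what}: neighbour count reduced from {requested} to {k} "
            f"(minority class has {n_min} samples)"
        )
    return k


def _interpolate(seeds: np.ndarray, seed_pool: np.ndarray, nn_idx: np.ndarray,
                 n_new: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n_new convex combinations seed -> one of its minority neighbours."""
    pick_seed = rng.integers(0, len(seeds), size=n_new)
    pick_nb = rng.integers(0, nn_idx.shape[1], size=n_new)
    gaps = rng.random(n_new)
    base = seeds[pick_seed]
    nb = seed_pool[nn_idx[pick_seed, pick_nb]]
    return base + gaps[:, None] * (nb - base)


def oversample_training_fold(X, y, method: str, seed: int,
                             k_neighbors: int = 5, m_neighbors: int = 10):
    """Equalize class counts on a training fold.

    Parameters
    ----------
    X : array (n_samples, n_features)
    y : array (n_samples,) with exactly two classes
    method : one of ``RandomOverSampler``, ``BorderlineSMOTE``, ``SVMSMOTE``
    seed : RNG seed; identical inputs + seed give identical output

    Returns
    -------
    (X_res, y_res) with the original rows first, synthetic/duplicated minority
    rows appended, and equal class counts.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ValidationError("X must be 2-D with one label per row")
    if method not in OVERSAMPLERS:
        raise ValidationError(f"unknown oversampler {method!r}; known: {OVERSAMPLERS}")
    classes, minority, majority = _classes_and_minority(y)
    n_min = int((y == minority).sum())
    n_maj = int((y == majority).sum())
    n_new = n_maj - n_min
    if n_new == 0:
        return X.copy(), y.copy()

    rng = np.random.default_rng(seed)
    X_min = X[y == minority]

    if method == "RandomOverSampler":
        if n_min < 2:
            raise ValidationError("minority class too small (need >= 2 samples)")
        picks = rng.integers(0, n_min, size=n_new)
        X_new = X_min[picks]
    elif method == "BorderlineSMOTE":
        k = _effective_k(k_neighbors, n_min, "BorderlineSMOTE")
        m = min(m_neighbors, len(X) - 1)
        nn_all = NearestNeighbors(n_neighbors=m + 1).fit(X)
        _, idx_all = nn_all.kneighbors(X_min)
        danger = []
        for i in range(n_min):
            neigh = idx_all[i][idx_all[i] != np.flatnonzero(y == minority)[i]][:m]
            maj_count = int((y[neigh] == majority).sum())
            if m / 2.0 <= maj_count < m:
                danger.append(i)
        if not danger:
            _warn_once(
                "BorderlineSMOTE: no danger points found; falling back to all "
                "minority points as seeds"
            )
            danger = list(range(n_min))
        seeds = X_min[danger]
        nn_min = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
        _, idx_min = nn_min.kneighbors(seeds)
        nn_idx = np.array([row[row != d][:k] for row, d in zip(idx_min, danger)])
        X_new = _interpolate(seeds, X_min, nn_idx, n_new, rng)
    else:  # SVMSMOTE
        k = _effective_k(k_neighbors, n_min, "SVMSMOTE")
        svc = SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed).fit(X, y)
        sv_idx = svc.support_[np.isin(svc.support_, np.flatnonzero(y == minority))]
        if len(sv_idx) == 0:  # degenerate fit; fall back to all minority points
            seeds = X_min
            seed_pos = list(range(n_min))
        else:
            minority_positions = {g: i for i, g in enumerate(np.flatnonzero(y == minority))}
            seed_pos = [minority_positions[g] for g in sv_idx]
            seeds = X_min[seed_pos]
        nn_min = NearestNeighbors(n_neighbors=min(k + 1, n_min)).fit(X_min)
        _, idx_min = nn_min.kneighbors(seeds)
        nn_idx = np.array([row[row != p][:min(k, n_min - 1)]
                           for row, p in zip(idx_min, seed_pos)])
        X_new = _interpolate(seeds, X_min, nn_idx, n_new, rng)

    X_res = np.vstack([X, X_new])
    y_res = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_res, y_res
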