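"""Feature selection building blocks for the generalizability search.

Correlation pruning (Spearman), univariate and neighbor-margin feature
ranking (F-test; ReliefF / SURF / MultiSURF-style weights), and a greedy
maximum-relevance-minimum-redundancy selector with F-statistic relevance
and absolute Pearson correlation redundancy.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats
from sklearn.feature_selection import f_classif
from sklearn.metrics import pairwise_distances

log = logging.getLogger(__name__)

RANK_METHODS = ("f_test", "relief", "surf", "multisurf", "mrmr")


def spearman_matrix(X: np.ndarray) -> np.ndarray:
    """|Spearman rho| between all columns; constant columns get rho = 0."""
    X = np.asarray(X, dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 0, X)
    sd = ranks.std(axis=0)
    const = sd == 0
    if const.any():
        log.warning("%d constant feature(s): treated as rho=0", const.sum())
    safe = ranks.copy()
    safe[:, const] = np.random.default_rng(0).normal(size=(X.shape[0], const.sum()))
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(safe, rowvar=False)
    rho = np.abs(np.atleast_2d(rho))
    rho[const, :] = 0.0
    rho[:, const] = 0.0
    np.fill_diagonal(rho, 1.0)
    return rho


def spearman_prune(
    X: np.ndarray,
    names: list[str],
    threshold: float,
    fixed: list[str] | None = None,
    rho: np.ndarray | None = None,
) -> list[str]:
    """Greedy scan in column order; drop a feature iff |rho| >= threshold
    with an already-kept one.  Fixed features are never dropped."""
    if not (0.8 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0.8, 1]")
    if X.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    fixed = set(fixed or [])
    rho = spearman_matrix(X) if rho is None else rho
    kept_idx: list[int] = []
    kept: list[str] = []
    for j, name in enumerate(names):
        if name in fixed:
            kept_idx.append(j)
            kept.append(name)
            continue
        if any(rho[j, i] >= threshold - 1e-12 for i in kept_idx):
            continue
        kept_idx.append(j)
        kept.append(name)
    return kept


def f_test_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    F, _ = f_classif(X, y)
    return np.nan_to_num(F, nan=0.0)


def _relief_family_scores(
    X: np.ndarray, y: np.ndarray, variant: str, n_neighbors: int = 10
) -> np.ndarray:
    """Neighbor-margin weights.

    ``relief``: ReliefF with the k nearest hits and misses per instance;
    ``surf``: all neighbors within the global mean pairwise distance;
    ``multisurf``: per-instance threshold mean_i - std_i/2.  Feature
    differences are range-normalized; updates averaged over instances and
    neighbors.  Fully deterministic (all instances used, ties by index).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    rng_span = np.ptp(X, axis=0)
    rng_span[rng_span == 0] = 1.0
    Xn = X / rng_span
    D = pairwise_distances(Xn, metric="cityblock")
    np.fill_diagonal(D, np.inf)
    W = np.zeros(p)
    if variant == "surf":
        thresh = np.full(n, D[np.isfinite(D)].mean())
    elif variant == "multisurf":
        finite = np.where(np.isfinite(D), D, np.nan)
        mu = np.nanmean(finite, axis=1)
        sd = np.nanstd(finite, axis=1)
        thresh = mu - sd / 2.0
    else:
        thresh = None

    for i in range(n):
        same = y == y[i]
        same[i] = False
        diff = ~same
        diff[i] = False
        if variant == "relief":
            hits = np.argsort(D[i] + np.where(same, 0, np.inf))[:n_neighbors]
            hits = hits[same[hits]]
            misses = np.argsort(D[i] + np.where(diff, 0, np.inf))[:n_neighbors]
            misses = misses[diff[misses]]
        else:
            near = D[i] < thresh[i]
            hits = np.nonzero(near & same)[0]
            misses = np.nonzero(near & diff)[0]
        if len(hits):
            W -= np.abs(Xn[hits] - Xn[i]).mean(axis=0)
        if len(misses):
            W += np.abs(Xn[misses] - Xn[i]).mean(axis=0)
    return W / n


def rank_features(
    X: np.ndarray, y: np.ndarray, names: list[str], method: str
) -> list[tuple[str, float]]:
    """Rank features by the requested method, descending score.

    Ties are broken by column order.  ``mrmr`` ranking is the greedy
    selection order itself (scores = negated pick order).
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    if method == "f_test":
        scores = f_test_scores(X, y)
    elif method in ("relief", "surf", "multisurf"):
        scores = _relief_family_scores(X, y, method)
    elif method == "mrmr":
        order = mrmr_select(X, y, names, k=len(names))
        pos = {n: i for i, n in enumerate(order)}
        scores = np.array([-pos[n] for n in names], dtype=float)
    else:
        raise ValueError(f"unknown method {method!r}")
    idx = sorted(range(len(names)), key=lambda j: (-scores[j], j))
    return [(names[j], float(scores[j])) for j in idx]


def mrmr_select(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str],
    k: int,
    relevance: np.ndarray | None = None,
    corr: np.ndarray | None = None,
) -> list[str]:
    """Greedy mRMR: maximize relevance(j; y) - mean_{s in S} |pearson r(j, s)|.

    Relevance is the F statistic expressed on the correlation scale via
    the exact two-class identity ``r^2 = F / (F + n - 2)`` (point-biserial
    correlation), so that the redundancy penalty — a mean absolute Pearson
    correlation in [0, 1] — is commensurable and an exact duplicate of an
    already-selected feature can never win.  The mapping is monotone in F,
    so the first pick equals the F-test top-1.  Deterministic, ties by
    column order.  ``relevance`` (raw F) and ``corr`` may be passed
    pre-computed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(names):
        raise ValueError(f"k={k} exceeds {len(names)} available features")
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    X = np.asarray(X, dtype=float)
    F = f_test_scores(X, y) if relevance is None else np.asarray(relevance)
    dof = max(1, len(y) - 2)
    rel = np.sqrt(F / (F + dof))
    if corr is None:
        sd = X.std(axis=0)
        safe = X + (sd == 0) * np.random.default_rng(0).normal(
            size=X.shape
        ) * 1e-9
        corr = np.abs(np.corrcoef(safe, rowvar=False))
        corr = np.nan_to_num(np.atleast_2d(corr), nan=0.0)
    selected: list[int] = []
    remaining = list(range(len(names)))
    while len(selected) < k:
        if not selected:
            scores = rel[remaining]
        else:
            red = corr[np.ix_(remaining, selected)].mean(axis=1)
            scores = rel[remaining] - red
        best = remaining[int(np.argmax(scores))]  # argmax takes first max: column-order ties
        selected.append(best)
        remaining.remove(best)
    return [names[j] for j in selected]
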