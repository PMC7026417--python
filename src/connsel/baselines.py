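"""Comparison feature selectors: Lasso, ElasticNet, Fisher score, trace ratio.

These are the four classical selectors the ensemble method is benchmarked
against, plus an optional two-sample Kolmogorov–Smirnov filter. Each returns
a :class:`BaselineSelection`; downstream classification of a baseline
selection goes through the same standardize → linear-SVM → nested-tuning
harness as the ensemble selector (see :mod:`connsel.evaluation`), so method
comparisons differ only in how features are chosen.

Conventions: Fisher scores use population (divide-by-n) per-class variances;
ties in any score are broken by ascending feature index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNetCV, LassoCV

__all__ = [
    "BaselineSelection",
    "lasso_select",
    "elasticnet_select",
    "fisher_score_select",
    "trace_ratio_select",
    "ks_select",
    "BASELINE_METHODS",
]

BASELINE_METHODS = ("lasso", "elasticnet", "fisher_score", "trace_ratio", "ks")


@dataclass
class BaselineSelection:
    method: str
    indices: np.ndarray
    scores: np.ndarray


def _standardize(X: np.ndarray) -> np.ndarray:
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _encode01(y: Sequence) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.tolist()}")
    return (y == classes[1]).astype(float)


def _top_k(scores: np.ndarray, k: int) -> np.ndarray:
    """Top-k indices by score, ties broken by ascending index."""
    order = np.lexsort((np.arange(scores.size), -scores))
    return np.sort(order[:k])


def lasso_select(
    X: np.ndarray,
    y: Sequence,
    penalty: float | None = None,
    cv: int = 3,
    seed: int = 0,
    n_alphas: int = 30,
) -> BaselineSelection:
    """Features with nonzero Lasso coefficients (labels regressed as 0/1).

    ``penalty=None`` tunes alpha by inner ``cv``-fold CV along the standard
    regularization path; a fixed ``penalty`` skips tuning. An all-zero
    solution returns an empty selection with a warning.
    """
    return _l1_path_select(X, y, penalty, cv, seed, n_alphas, l1_ratio=1.0, method="lasso")


def elasticnet_select(
    X: np.ndarray,
    y: Sequence,
    penalty: float | None = None,
    mix: float = 0.5,
    cv: int = 3,
    seed: int = 0,
    n_alphas: int = 30,
) -> BaselineSelection:
    """ElasticNet (L1+L2) selection; ``mix`` is the L1 ratio (1 → Lasso)."""
    return _l1_path_select(X, y, penalty, cv, seed, n_alphas, l1_ratio=mix, method="elasticnet")


def _l1_path_select(X, y, penalty, cv, seed, n_alphas, l1_ratio, method) -> BaselineSelection:
    X = _standardize(np.asarray(X, dtype=float))
    y01 = _encode01(y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if penalty is None:
            if l1_ratio == 1.0:
                model = LassoCV(alphas=n_alphas, cv=cv, random_state=seed, max_iter=5000)
            else:
                model = ElasticNetCV(
                    l1_ratio=l1_ratio, alphas=n_alphas, cv=cv, random_state=seed, max_iter=5000
                )
            model.fit(X, y01)
            coef = model.coef_
        else:
            from sklearn.linear_model import ElasticNet, Lasso

            if l1_ratio == 1.0:
                model = Lasso(alpha=penalty, max_iter=5000)
            else:
                model = ElasticNet(alpha=penalty, l1_ratio=l1_ratio, max_iter=5000)
            model.fit(X, y01)
            coef = model.coef_
    indices = np.flatnonzero(coef != 0.0)
    if indices.size == 0:
        warnings.warn(f"{method}: all coefficients zero; empty selection", stacklevel=3)
    return BaselineSelection(method, indices, np.asarray(coef, dtype=float))


def _scatter_terms(X: np.ndarray, y01: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature between-class and within-class scatter (population variances)."""
    mu = X.mean(axis=0)
    between = np.zeros(X.shape[1])
    within = np.zeros(X.shape[1])
    for c in (0.0, 1.0):
        Xc = X[y01 == c]
        nc = Xc.shape[0]
        between += nc * (Xc.mean(axis=0) - mu) ** 2
        within += nc * Xc.var(axis=0)  # population convention
    return between, within


def fisher_score_select(X: np.ndarray, y: Sequence, k: int) -> BaselineSelection:
    """Top-k features by Fisher score: between-class over within-class scatter.

    score_j = Σ_c n_c(μ_cj − μ_j)² / Σ_c n_c σ²_cj with population variances.
    Zero within-class variance with nonzero between gives an +inf sentinel
    (ranked first, with a warning).
    """
    X = np.asarray(X, dtype=float)
    y01 = _encode01(y)
    if k < 1:
        raise ValueError("k must be >= 1")
    between, within = _scatter_terms(X, y01)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = between / within
    degenerate = (within == 0) & (between > 0)
    if degenerate.any():
        warnings.warn(
            f"fisher_score: zero within-class variance for feature(s) "
            f"{np.flatnonzero(degenerate).tolist()}; using +inf sentinel",
            stacklevel=2,
        )
        scores[degenerate] = np.inf
    scores[(within == 0) & (between == 0)] = 0.0
    return BaselineSelection("fisher_score", _top_k(scores, k), scores)


def trace_ratio_select(
    X: np.ndarray,
    y: Sequence,
    k: int,
    max_iter: int = 100,
    tol: float = 1e-12,
) -> BaselineSelection:
    """Trace-ratio selection: maximize tr(S_b|S) / tr(S_w|S) over k-subsets.

    Uses the standard iterative score-and-threshold algorithm: given the
    current ratio λ, re-score features as b_j − λ·w_j, keep the top k, and
    update λ until it stabilizes. Deterministic; converges monotonically.
    Features with zero within-class scatter contribute their between-class
    scatter at zero cost and are handled by the same scoring.
    """
    X = np.asarray(X, dtype=float)
    y01 = _encode01(y)
    if k < 1:
        raise ValueError("k must be >= 1")
    between, within = _scatter_terms(X, y01)
    lam = 0.0
    subset = _top_k(between - lam * within, k)
    for _ in range(max_iter):
        denom = within[subset].sum()
        new_lam = np.inf if denom == 0 else between[subset].sum() / denom
        if not np.isfinite(new_lam):
            break
        if abs(new_lam - lam) <= tol:
            lam = new_lam
            break
        lam = new_lam
        subset = _top_k(between - lam * within, k)
    else:
        warnings.warn("trace_ratio: did not converge; returning last iterate", stacklevel=2)
    scores = between - lam * within
    return BaselineSelection("trace_ratio", subset, scores)


def ks_select(X: np.ndarray, y: Sequence, k: int) -> BaselineSelection:
    """Top-k features by two-sample Kolmogorov–Smirnov statistic between classes."""
    X = np.asarray(X, dtype=float)
    y01 = _encode01(y)
    if k < 1:
        raise ValueError("k must be >= 1")
    a, b = X[y01 == 0], X[y01 == 1]
    scores = np.array(
        [stats.ks_2samp(a[:, j], b[:, j], method="asymp").statistic for j in range(X.shape[1])]
    )
    return BaselineSelection("ks", _top_k(scores, k), scores)
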