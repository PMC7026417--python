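"""Ensemble relative-importance feature selection with SVM-FoBa refinement.

The selector (FS_RIEL) attacks the small-n / large-E regime of connectome
classification in three stages:

1. **Relative-importance ranking.** Five heterogeneous tree ensembles —
   extreme gradient boosting, extremely randomized trees, random forest,
   AdaBoost, and gradient boosting — are fit on the training data and each
   contributes its normalized per-feature importance vector.
2. **Top-fraction pooling.** Each ranker nominates its top 2% of features;
   the union of the five nominations (no repetition, provenance kept) forms
   the feature pool.
3. **SVM-FoBa refinement.** An adaptive forward-backward greedy search over
   the pool, scored by 3-fold cross-validated accuracy of a linear SVM:
   forward steps add the best-improving feature until the improvement drops
   below ``eta``; after each forward step, backward steps drop any feature
   whose removal costs less than ``nu`` times the last forward gain.

Prediction uses an unweighted majority vote of the same five learner
families refit on the refined subspace (five voters, so binary votes never
tie). SVM regularization is tuned by stratified nested 3-fold
cross-validation over a small grid.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from ._seeds import derive_seed

__all__ = [
    "LEARNER_IDS",
    "ImportanceRanking",
    "FeaturePool",
    "FoBaConfig",
    "FoBaResult",
    "FSRIELConfig",
    "FSRIELModel",
    "rank_importance",
    "select_top_fraction",
    "pool_union",
    "foba_select",
    "exhaustive_subset_search",
    "nested_tune",
    "fit_ensemble",
    "fsriel_fit",
    "EnsembleClassifier",
]

LEARNER_IDS = (
    "xgboost_like_gbt",
    "extra_trees",
    "random_forest",
    "adaboost",
    "gradient_boosting",
)

#: Default SVM regularization grid for nested tuning.
DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0)


def _encode_labels(y: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Map labels to 0/1 with classes sorted; require exactly two classes."""
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.tolist()}")
    return (y == classes[1]).astype(int), classes


def _make_learner(learner_id: str, seed: int):
    """Instantiate one of the five base learner families with fixed small defaults."""
    if learner_id == "xgboost_like_gbt":
        return XGBClassifier(
            n_estimators=100,
            max_depth=3,
            learning_rate=0.3,
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
            verbosity=0,
            eval_metric="logloss",
        )
    if learner_id == "extra_trees":
        return ExtraTreesClassifier(
            n_estimators=100, max_features="sqrt", n_jobs=1, random_state=seed
        )
    if learner_id == "random_forest":
        return RandomForestClassifier(
            n_estimators=100, max_features="sqrt", n_jobs=1, random_state=seed
        )
    if learner_id == "adaboost":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=50,
            random_state=seed,
        )
    if learner_id == "gradient_boosting":
        return GradientBoostingClassifier(
            n_estimators=100, max_depth=3, max_features="sqrt", random_state=seed
        )
    raise ValueError(f"unknown learner_id {learner_id!r}; expected one of {LEARNER_IDS}")


@dataclass
class ImportanceRanking:
    """Normalized relative importances from one base learner."""

    learner_id: str
    importances: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.importances, dtype=float)
        if np.any(v < 0):
            raise ValueError("importances must be nonnegative")
        self.importances = v


def rank_importance(X: np.ndarray, y: Sequence, learner_id: str, seed: int = 0) -> ImportanceRanking:
    """Fit one base learner and return its normalized feature importances.

    All-zero raw importances (a learner that never split) degrade to a uniform
    vector with a warning. Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y01, _ = _encode_labels(y)
    learner = _make_learner(learner_id, seed)
    learner.fit(X, y01)
    imp = np.asarray(learner.feature_importances_, dtype=float)
    imp = np.clip(imp, 0.0, None)
    total = imp.sum()
    if total <= 0:
        warnings.warn(
            f"{learner_id}: all-zero raw importances; falling back to uniform",
            stacklevel=2,
        )
        imp = np.full(X.shape[1], 1.0 / X.shape[1])
    else:
        imp = imp / total
    return ImportanceRanking(learner_id, imp)


def select_top_fraction(ranking: ImportanceRanking, fraction: float = 0.02) -> np.ndarray:
    """Indices of the top-``fraction`` features, k = max(1, floor(fraction·E)).

    Ties in importance are broken by ascending feature index.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    imp = ranking.importances
    e = imp.size
    k = max(1, int(np.floor(fraction * e)))
    # lexsort: primary key last → sort by -importance, ties by ascending index
    order = np.lexsort((np.arange(e), -imp))
    return np.sort(order[:k])


@dataclass
class FeaturePool:
    """Union of per-learner top-fraction selections, with provenance."""

    indices: np.ndarray
    provenance: dict[int, set[str]]

    def __len__(self) -> int:
        return self.indices.size


def pool_union(selections: dict[str, np.ndarray] | Sequence[np.ndarray]) -> FeaturePool:
    """Union of selections without repetition; provenance records the nominators."""
    if not isinstance(selections, dict):
        selections = {f"learner_{i}": s for i, s in enumerate(selections)}
    prov: dict[int, set[str]] = {}
    for learner_id, idx in selections.items():
        for j in np.asarray(idx, dtype=int):
            prov.setdefault(int(j), set()).add(learner_id)
    indices = np.array(sorted(prov), dtype=int)
    return FeaturePool(indices, prov)


# ---------------------------------------------------------------------------
# SVM-FoBa
# ---------------------------------------------------------------------------


@dataclass
class FoBaConfig:
    """Constants of the adaptive forward-backward search.

    ``objective`` — what the cross-validated linear SVM is scored by:
    ``"hinge"`` (default) maximizes the negative mean validation hinge loss,
    ``"accuracy"`` the mean validation accuracy. The hinge objective is the
    greedy search's natural currency: accuracy is a step function that
    saturates as soon as some small subset separates the sample, starving
    the search of gradient and stopping it before the remaining informative
    features are collected; the validation hinge loss keeps decreasing while
    added features genuinely widen the margin, yet cannot be driven below
    its floor of zero by irrelevant features.

    ``eta`` — minimum objective gain for a forward step; ``nu`` — a backward
    step may drop a feature whose removal costs less than ``nu`` × (last
    forward gain); ``max_features`` caps the subset size; ``cv`` is the
    number of internal stratified folds and ``cv_repeats`` the number of
    independent fold splits the objective is averaged over; ``C`` is the
    linear-SVM regularization used inside the objective.
    """

    eta: float = 0.005
    nu: float = 0.5
    max_features: int = 20
    cv: int = 3
    cv_repeats: int = 1
    C: float = 1.0
    objective: str = "hinge"
    seed: int = 0


@dataclass
class FoBaResult:
    """Outcome of the greedy search: selected subset and full step trace."""

    selected: list[int]
    trace: list[tuple[str, int, float]] = field(default_factory=list)
    objective: float = float("nan")


def _svm_cv_objective(
    X: np.ndarray, y01: np.ndarray, cfg: FoBaConfig
) -> Callable[[Sequence[int]], float]:
    """Cross-validated linear-SVM score of a column subset (to be maximized).

    ``cfg.objective == "hinge"`` returns minus the mean validation hinge loss
    (empty subset: the zero-margin model, loss 1); ``"accuracy"`` returns the
    mean validation accuracy (empty subset: majority-class rate). Columns are
    standardized once on the data handed to the search (training-fold data
    only in any cross-validated context); fold splits are frozen per call so
    every candidate subset is scored on identical splits.
    """
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    folds = []
    for rep in range(cfg.cv_repeats):
        skf = StratifiedKFold(
            n_splits=cfg.cv, shuffle=True, random_state=derive_seed(cfg.seed, "obj", rep)
        )
        folds.extend(skf.split(Xs, y01))
    majority = max(np.mean(y01), 1.0 - np.mean(y01))
    sign = np.where(y01 == 1, 1.0, -1.0)
    if cfg.objective not in ("hinge", "accuracy"):
        raise ValueError(f"unknown FoBa objective {cfg.objective!r}")
    use_hinge = cfg.objective == "hinge"

    def objective(cols: Sequence[int]) -> float:
        cols = list(cols)
        if not cols:
            return -1.0 if use_hinge else float(majority)
        score = 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for tr, te in folds:
                svc = LinearSVC(C=cfg.C, dual=False)
                svc.fit(Xs[np.ix_(tr, cols)], y01[tr])
                if use_hinge:
                    margins = sign[te] * svc.decision_function(Xs[np.ix_(te, cols)])
                    score -= np.mean(np.maximum(0.0, 1.0 - margins))
                else:
                    score += svc.score(Xs[np.ix_(te, cols)], y01[te])
        return score / len(folds)

    return objective


def foba_select(
    X: np.ndarray,
    y: Sequence,
    pool: FeaturePool | Sequence[int],
    config: FoBaConfig | None = None,
) -> FoBaResult:
    """Adaptive forward-backward greedy subset search over a feature pool.

    Forward: add the candidate with the largest objective gain, while the gain
    is at least ``eta`` (ties broken by ascending feature index). Backward
    (after each accepted forward step): repeatedly drop the feature whose
    removal loses least, while that loss is below ``nu`` × last forward gain.
    Constant columns in the pool are skipped with a warning. The final
    selection may be empty only if no single feature improves on the
    majority-class baseline by ``eta``.
    """
    cfg = config or FoBaConfig()
    X = np.asarray(X, dtype=float)
    y01, _ = _encode_labels(y)
    pool_idx = pool.indices if isinstance(pool, FeaturePool) else np.asarray(sorted(pool), dtype=int)
    if pool_idx.size == 0:
        raise ValueError("empty feature pool")
    const = pool_idx[X[:, pool_idx].std(axis=0) == 0]
    if const.size:
        warnings.warn(f"skipping constant feature column(s) {const.tolist()}", stacklevel=2)
        pool_idx = np.setdiff1d(pool_idx, const)
        if pool_idx.size == 0:
            raise ValueError("feature pool contains only constant columns")

    objective = _svm_cv_objective(X, y01, cfg)
    selected: list[int] = []
    trace: list[tuple[str, int, float]] = []
    current = objective([])
    last_gain = np.inf
    max_outer = 2 * cfg.max_features + 10  # churn guard; objective ↑ per cycle

    for _ in range(max_outer):
        if len(selected) >= cfg.max_features:
            break
        # forward step
        candidates = [f for f in pool_idx if f not in selected]
        if not candidates:
            break
        best_f, best_obj = -1, -np.inf
        for f in candidates:  # ascending index → ties keep the first (lowest)
            obj = objective(selected + [f])
            if obj > best_obj:
                best_f, best_obj = f, obj
        gain = best_obj - current
        if gain < cfg.eta:
            break
        selected.append(int(best_f))
        current = best_obj
        last_gain = gain
        trace.append(("forward", int(best_f), current))
        # backward sweep
        while len(selected) > 1:
            best_d, best_dobj = -1, -np.inf
            for f in selected:
                obj = objective([g for g in selected if g != f])
                if obj > best_dobj:
                    best_d, best_dobj = f, obj
            loss = current - best_dobj
            if loss < cfg.nu * last_gain:
                selected.remove(best_d)
                current = best_dobj
                trace.append(("backward", int(best_d), current))
            else:
                break

    return FoBaResult(selected, trace, objective=current)


def exhaustive_subset_search(
    X: np.ndarray,
    y: Sequence,
    pool: FeaturePool | Sequence[int],
    config: FoBaConfig | None = None,
    max_pool: int = 12,
) -> tuple[list[int], float]:
    """Brute-force best subset under the same CV-SVM objective as FoBa.

    Enumerates all non-empty subsets of the pool (pool size capped at
    ``max_pool``); reference oracle for validating the greedy search. Ties
    are broken toward smaller subsets, then lexicographically.
    """
    cfg = config or FoBaConfig()
    X = np.asarray(X, dtype=float)
    y01, _ = _encode_labels(y)
    pool_idx = list(pool.indices if isinstance(pool, FeaturePool) else sorted(pool))
    if len(pool_idx) > max_pool:
        raise ValueError(f"pool too large for exhaustive search ({len(pool_idx)} > {max_pool})")
    objective = _svm_cv_objective(X, y01, cfg)
    best_set, best_obj = [], objective([])
    for r in range(1, len(pool_idx) + 1):
        for combo in itertools.combinations(pool_idx, r):
            obj = objective(combo)
            if obj > best_obj + 1e-12:
                best_set, best_obj = list(combo), obj
    return best_set, best_obj


# ---------------------------------------------------------------------------
# Nested tuning and the voting ensemble
# ---------------------------------------------------------------------------


def nested_tune(
    X: np.ndarray,
    y: Sequence,
    grid: Sequence[float] = DEFAULT_C_GRID,
    inner_k: int = 3,
    seed: int = 0,
) -> float:
    """Pick the SVM regularization C maximizing stratified inner-CV accuracy.

    Ties return the first grid point in grid order.
    """
    X = np.asarray(X, dtype=float)
    y01, _ = _encode_labels(y)
    counts = np.bincount(y01)
    if counts.min() < inner_k:
        raise ValueError(
            f"too few samples per class ({counts.tolist()}) for {inner_k} stratified folds"
        )
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    skf = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
    folds = list(skf.split(Xs, y01))
    best_c, best_acc = grid[0], -np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for c in grid:
            acc = np.mean(
                [
                    LinearSVC(C=c, dual=False).fit(Xs[tr], y01[tr]).score(Xs[te], y01[te])
                    for tr, te in folds
                ]
            )
            if acc > best_acc + 1e-12:
                best_c, best_acc = c, acc
    return float(best_c)


@dataclass
class EnsembleClassifier:
    """Majority vote of the five base learner families on a fixed subspace."""

    members: dict[str, object]
    classes: np.ndarray

    def predict(self, X_sub: np.ndarray) -> np.ndarray:
        """Predict labels from features already restricted to the subspace."""
        X_sub = np.asarray(X_sub, dtype=float)
        votes = np.zeros(X_sub.shape[0], dtype=int)
        for member in self.members.values():
            votes += np.asarray(member.predict(X_sub), dtype=int)
        return self.classes[(votes * 2 > len(self.members)).astype(int)]


def fit_ensemble(X_sub: np.ndarray, y: Sequence, seed: int = 0) -> EnsembleClassifier:
    """Fit the five voters on the refined subspace (identical for all five)."""
    X_sub = np.asarray(X_sub, dtype=float)
    if X_sub.ndim != 2 or X_sub.shape[1] == 0:
        raise ValueError("empty feature subspace; select at least one feature before fitting")
    y01, classes = _encode_labels(y)
    members = {
        lid: _make_learner(lid, derive_seed(seed, "ensemble", lid)).fit(X_sub, y01)
        for lid in LEARNER_IDS
    }
    return EnsembleClassifier(members, classes)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


@dataclass
class FSRIELConfig:
    fraction: float = 0.02
    inner_k: int = 3
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    foba: FoBaConfig = field(default_factory=FoBaConfig)
    seed: int = 0


@dataclass
class FSRIELModel:
    """Fitted selector + voting ensemble, with provenance for inspection."""

    ensemble: EnsembleClassifier
    pool: FeaturePool
    foba: FoBaResult
    selected: list[int]
    feature_ids: list[str] | None
    config: FSRIELConfig
    tuned_C: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict labels for rows of the full feature matrix."""
        X = np.asarray(X, dtype=float)
        return self.ensemble.predict(X[:, self.selected])

    def selected_feature_ids(self) -> list[str]:
        if self.feature_ids is None:
            return [str(i) for i in self.selected]
        return [self.feature_ids[i] for i in self.selected]


def fsriel_fit(
    X: np.ndarray,
    y: Sequence,
    config: FSRIELConfig | None = None,
    feature_ids: Sequence[str] | None = None,
) -> FSRIELModel:
    """Run the full pipeline: rank → top-2% → pool → SVM-FoBa → voting ensemble.

    Every stochastic stage is seeded from ``config.seed`` via the documented
    seed-derivation scheme, so identical data + seed give identical output.
    If FoBa selects nothing, the single feature with the largest summed
    importance over the pool is used instead (with a loud warning).
    """
    cfg = config or FSRIELConfig()
    X = np.asarray(X, dtype=float)
    y01, _ = _encode_labels(y)
    if X.shape[0] < 6:
        raise ValueError("need at least 6 subjects for nested 3-fold tuning")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")

    rankings = {
        lid: rank_importance(X, y01, lid, seed=derive_seed(cfg.seed, "rank", lid))
        for lid in LEARNER_IDS
    }
    selections = {
        lid: select_top_fraction(r, cfg.fraction) for lid, r in rankings.items()
    }
    pool = pool_union(selections)

    tuned_c = nested_tune(
        X[:, pool.indices], y01, grid=cfg.c_grid, inner_k=cfg.inner_k,
        seed=derive_seed(cfg.seed, "tune"),
    )
    foba_cfg = FoBaConfig(
        eta=cfg.foba.eta,
        nu=cfg.foba.nu,
        max_features=cfg.foba.max_features,
        cv=cfg.foba.cv,
        cv_repeats=cfg.foba.cv_repeats,
        C=tuned_c,
        objective=cfg.foba.objective,
        seed=derive_seed(cfg.seed, "foba"),
    )
    foba = foba_select(X, y01, pool, foba_cfg)
    selected = list(foba.selected)
    if not selected:
        summed = np.zeros(X.shape[1])
        for r in rankings.values():
            summed += r.importances
        fallback = int(pool.indices[np.argmax(summed[pool.indices])])
        warnings.warn(
            "FoBa selected no features (no single feature beat the empty-model "
            f"baseline by eta); falling back to the top pooled feature {fallback}",
            stacklevel=2,
        )
        selected = [fallback]

    ensemble = fit_ensemble(X[:, selected], y, seed=derive_seed(cfg.seed, "fit"))
    return FSRIELModel(
        ensemble=ensemble,
        pool=pool,
        foba=foba,
        selected=selected,
        feature_ids=list(feature_ids) if feature_ids is not None else None,
        config=cfg,
        tuned_C=tuned_c,
    )
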