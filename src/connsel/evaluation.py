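"""Repeated cross-validated evaluation, stability analysis and transfer.

Within-cohort performance is estimated by repeated stratified k-fold
cross-validation (5-fold for the small cohort, 10-fold for the large one,
each repeated 10 times by default). The entire selection + tuning + fitting
pipeline runs inside each training fold only — test subjects never influence
feature selection — and per-loop predictions, metrics and selected features
are recorded.

Feature stability counts, for every feature, the number of (repeat, fold)
loops in which it was selected; features reaching a frequency threshold
(default 10) form the "stable set" that is carried into network-level
summaries, symptom association and cross-cohort transfer. Methods are
compared by a paired test (Wilcoxon signed-rank by default) over loop-level
accuracies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import LinearSVC

from ._seeds import derive_seed
from .baselines import (
    elasticnet_select,
    fisher_score_select,
    ks_select,
    lasso_select,
    trace_ratio_select,
)
from .fsriel import FSRIELConfig, FSRIELModel, fsriel_fit, nested_tune

__all__ = [
    "CVScheme",
    "LoopRecord",
    "CVResult",
    "PerformanceSummary",
    "run_within_cohort",
    "compute_metrics",
    "summarize_cv",
    "feature_frequency",
    "compare_methods",
    "cross_cohort_predict",
    "EVALUATION_METHODS",
]

EVALUATION_METHODS = ("fsriel", "lasso", "elasticnet", "fisher_score", "trace_ratio", "ks")


@dataclass
class CVScheme:
    """Repeated (stratified) k-fold scheme."""

    k: int = 5
    repeats: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    @property
    def n_loops(self) -> int:
        return self.k * self.repeats


@dataclass
class LoopRecord:
    repeat: int
    fold: int
    test_index: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    selected: list[int]


@dataclass
class CVResult:
    method: str
    scheme: CVScheme
    loops: list[LoopRecord]
    feature_ids: list[str] | None = None
    positive_class: object = None

    @property
    def n_loops(self) -> int:
        return len(self.loops)

    def loop_accuracies(self) -> np.ndarray:
        return np.array([np.mean(lp.y_pred == lp.y_true) for lp in self.loops])


@dataclass
class PerformanceSummary:
    accuracy: float
    sensitivity: float
    specificity: float
    accuracy_sd: float = float("nan")
    sensitivity_sd: float = float("nan")
    specificity_sd: float = float("nan")
    mean_dimensionality: float = float("nan")
    n_loops: int = 1

    def as_dict(self) -> dict[str, float | None]:
        """JSON-safe summary; undefined dispersions (single loop) become null."""
        raw = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy_sd": self.accuracy_sd,
            "sensitivity_sd": self.sensitivity_sd,
            "specificity_sd": self.specificity_sd,
            "mean_dimensionality": self.mean_dimensionality,
            "n_loops": self.n_loops,
        }
        return {k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in raw.items()}


def compute_metrics(y_pred: Sequence, y_true: Sequence, positive_class) -> dict[str, float]:
    """Accuracy, sensitivity (recall on cases), specificity (recall on controls).

    A fold with no positives (or no negatives) leaves the corresponding rate
    NaN with a warning; NaNs are excluded from cross-loop means.
    """
    y_pred, y_true = np.asarray(y_pred), np.asarray(y_true)
    if y_pred.shape != y_true.shape:
        raise ValueError("prediction/label length mismatch")
    pos = y_true == positive_class
    acc = float(np.mean(y_pred == y_true))
    if pos.sum() == 0:
        warnings.warn("no positive-class samples; sensitivity undefined", stacklevel=2)
        sens = float("nan")
    else:
        sens = float(np.mean(y_pred[pos] == y_true[pos]))
    if (~pos).sum() == 0:
        warnings.warn("no negative-class samples; specificity undefined", stacklevel=2)
        spec = float("nan")
    else:
        spec = float(np.mean(y_pred[~pos] == y_true[~pos]))
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec}


def _tuned_svm_predict(
    X_tr: np.ndarray, y_tr: np.ndarray, X_te: np.ndarray, inner_k: int, seed: int
) -> np.ndarray:
    """Standardize on train, tune C by inner CV, fit linear SVM, predict test."""
    mu, sd = X_tr.mean(axis=0), X_tr.std(axis=0)
    sd[sd == 0] = 1.0
    c = nested_tune(X_tr, y_tr, inner_k=inner_k, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        svc = LinearSVC(C=c, dual=False).fit((X_tr - mu) / sd, y_tr)
        return svc.predict((X_te - mu) / sd)


def _baseline_fit_predict(
    method: str,
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_te: np.ndarray,
    seed: int,
    k: int | None,
) -> tuple[np.ndarray, list[int]]:
    if k is None:
        k = max(1, int(np.floor(0.02 * X_tr.shape[1])))
    if method == "lasso":
        sel = lasso_select(X_tr, y_tr, seed=seed)
    elif method == "elasticnet":
        sel = elasticnet_select(X_tr, y_tr, seed=seed)
    elif method == "fisher_score":
        sel = fisher_score_select(X_tr, y_tr, k)
    elif method == "trace_ratio":
        sel = trace_ratio_select(X_tr, y_tr, k)
    elif method == "ks":
        sel = ks_select(X_tr, y_tr, k)
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {EVALUATION_METHODS}")
    idx = list(map(int, sel.indices))
    if not idx:
        # empty penalized solution: fall back to the single best Fisher feature
        idx = list(map(int, fisher_score_select(X_tr, y_tr, 1).indices))
        warnings.warn(f"{method}: empty selection; falling back to top Fisher feature", stacklevel=2)
    pred = _tuned_svm_predict(X_tr[:, idx], y_tr, X_te[:, idx], inner_k=3, seed=seed)
    return pred, idx


def _fold_iter(scheme: CVScheme, y: np.ndarray, repeat: int):
    seed = derive_seed(scheme.seed, "folds", repeat)
    if scheme.stratified:
        splitter = StratifiedKFold(n_splits=scheme.k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=scheme.k, shuffle=True, random_state=seed)
    return splitter.split(np.zeros_like(y), y)


def run_within_cohort(
    X: np.ndarray,
    y: Sequence,
    method: str,
    scheme: CVScheme,
    feature_ids: Sequence[str] | None = None,
    positive_class=None,
    fsriel_config: FSRIELConfig | None = None,
    baseline_k: int | None = None,
    progress: Callable[[int, int], None] | None = None,
) -> CVResult:
    """Repeated stratified k-fold evaluation of one selection method.

    Selection, hyperparameter tuning and fitting all happen inside the
    training portion of each loop; only predictions touch the test fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.tolist()}")
    if positive_class is None:
        positive_class = classes[1]
    if np.bincount((y == classes[1]).astype(int)).min() < scheme.k and scheme.stratified:
        raise ValueError("minority class smaller than number of folds")

    loops: list[LoopRecord] = []
    total = scheme.n_loops
    done = 0
    for repeat in range(scheme.repeats):
        for fold, (tr, te) in enumerate(_fold_iter(scheme, y, repeat)):
            if np.unique(y[tr]).size < 2 or np.unique(y[te]).size < 2:
                raise ValueError(f"fold {repeat}/{fold} lacks both classes")
            loop_seed = derive_seed(scheme.seed, "loop", repeat, fold)
            if method == "fsriel":
                base = fsriel_config or FSRIELConfig()
                cfg = FSRIELConfig(
                    fraction=base.fraction,
                    inner_k=base.inner_k,
                    c_grid=base.c_grid,
                    foba=base.foba,
                    seed=loop_seed,
                )
                model = fsriel_fit(X[tr], y[tr], cfg)
                pred = model.predict(X[te])
                selected = list(model.selected)
            else:
                pred, selected = _baseline_fit_predict(
                    method, X[tr], y[tr], X[te], seed=loop_seed, k=baseline_k
                )
            loops.append(LoopRecord(repeat, fold, te, y[te].copy(), np.asarray(pred), selected))
            done += 1
            if progress is not None:
                progress(done, total)
    return CVResult(method, scheme, loops, list(feature_ids) if feature_ids else None, positive_class)


def summarize_cv(cv: CVResult) -> PerformanceSummary:
    """Per-loop metrics averaged over all k × repeats loops (NaN-safe)."""
    rows = [compute_metrics(lp.y_pred, lp.y_true, cv.positive_class) for lp in cv.loops]
    acc = np.array([r["accuracy"] for r in rows])
    sens = np.array([r["sensitivity"] for r in rows])
    spec = np.array([r["specificity"] for r in rows])
    dims = np.array([len(lp.selected) for lp in cv.loops], dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return PerformanceSummary(
            accuracy=float(np.nanmean(acc)),
            sensitivity=float(np.nanmean(sens)),
            specificity=float(np.nanmean(spec)),
            accuracy_sd=float(np.nanstd(acc)),
            sensitivity_sd=float(np.nanstd(sens)),
            specificity_sd=float(np.nanstd(spec)),
            mean_dimensionality=float(dims.mean()),
            n_loops=len(cv.loops),
        )


@dataclass
class StabilityTable:
    counts: pd.Series  # feature index (or id) -> selection count
    threshold: int
    stable: list[int] = field(default_factory=list)


def feature_frequency(cv: CVResult, threshold: int = 10) -> StabilityTable:
    """Selection frequency of every feature over all loops; stable = count ≥ threshold."""
    counter: dict[int, int] = {}
    for lp in cv.loops:
        for f in lp.selected:
            counter[f] = counter.get(f, 0) + 1
    counts = pd.Series(counter, dtype=int).sort_values(ascending=False)
    stable = sorted(int(f) for f, c in counter.items() if c >= threshold)
    return StabilityTable(counts=counts, threshold=threshold, stable=stable)


def compare_methods(
    acc_a: Sequence[float],
    acc_b: Sequence[float],
    test: str = "wilcoxon",
) -> tuple[float, float]:
    """Paired two-sided test over matched loop-level accuracies → (stat, p).

    All-zero differences (methods identical on every loop) return p = 1.
    ``test`` ∈ {"wilcoxon", "ttest", "ks"}; KS is unpaired and provided only
    for completeness.
    """
    a, b = np.asarray(acc_a, dtype=float), np.asarray(acc_b, dtype=float)
    if test == "ks":
        res = stats.ks_2samp(a, b)
        return float(res.statistic), float(res.pvalue)
    if a.shape != b.shape:
        raise ValueError("paired tests need matched loop structures")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    if test == "wilcoxon":
        res = stats.wilcoxon(a, b, zero_method="wilcox")
        return float(res.statistic), float(res.pvalue)
    if test == "ttest":
        res = stats.ttest_rel(a, b)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def cross_cohort_predict(
    model: FSRIELModel,
    X_target: np.ndarray,
    y_target: Sequence,
    target_feature_ids: Sequence[str] | None = None,
    positive_class=None,
    refit: bool = False,
    seed: int = 0,
) -> PerformanceSummary:
    """Apply a source-cohort model unchanged to every subject of another cohort.

    The source model's selected features are mapped into the target feature
    universe by feature id (falling back to positional indices when neither
    side carries ids); a missing id raises with the full list. With
    ``refit=True`` only the *features* transfer: a fresh tuned linear SVM is
    trained on the target cohort restricted to those features and scored by
    resubstitution (the alternative reading of feature transfer).
    """
    X_target = np.asarray(X_target, dtype=float)
    y_target = np.asarray(y_target)
    classes = np.unique(y_target)
    if positive_class is None:
        positive_class = classes[1]

    if model.feature_ids is not None and target_feature_ids is not None:
        colmap = {fid: i for i, fid in enumerate(target_feature_ids)}
        wanted = model.selected_feature_ids()
        missing = [fid for fid in wanted if fid not in colmap]
        if missing:
            raise ValueError(f"target cohort lacks feature id(s): {missing}")
        cols = [colmap[fid] for fid in wanted]
    else:
        cols = list(model.selected)
        if max(cols, default=-1) >= X_target.shape[1]:
            raise ValueError("selected feature indices exceed target feature universe")

    if refit:
        y01 = (y_target == classes[1]).astype(int)
        pred01 = _tuned_svm_predict(
            X_target[:, cols], y01, X_target[:, cols], inner_k=3, seed=seed
        )
        pred = classes[pred01.astype(int)]
    else:
        pred = model.ensemble.predict(X_target[:, cols])
    m = compute_metrics(pred, y_target, positive_class)
    return PerformanceSummary(
        accuracy=m["accuracy"],
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        mean_dimensionality=float(len(cols)),
        n_loops=1,
    )
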