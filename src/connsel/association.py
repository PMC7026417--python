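"""Symptom association of selected connectivity features.

Links the stable discriminative edges back to clinical symptom severity:
per-subject connectivity summaries (by default the mean Fisher-z over the
stable edges within a network pair) are Pearson-correlated with symptom
scores, either within a diagnostic subgroup or across all subjects while
controlling for group via partial correlation (residualizing both variables
on the group indicator; the t-based p-value then uses n − 3 degrees of
freedom). Missing scores are dropped pairwise. No multiple-testing
correction is applied by default (five subscales, reported uncorrected); a
Benjamini–Hochberg helper is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import EdgeIndexMap

__all__ = [
    "AssociationResult",
    "correlate",
    "partial_correlate",
    "network_pair_fc_summary",
    "associate_pairs",
    "bh_adjust",
]


@dataclass
class AssociationResult:
    x_name: str
    y_name: str
    subgroup: str
    n: int
    r: float
    p: float


def _clean_pairs(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    x_name: str = "x",
    y_name: str = "y",
    subgroup: str = "all",
) -> AssociationResult:
    """Pearson r with two-sided p from the t distribution (n − 2 df)."""
    x, y = _clean_pairs(x, y)
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return AssociationResult(x_name, y_name, subgroup, n, float(r), float(p))


def partial_correlate(
    x: Sequence[float],
    y: Sequence[float],
    control: Sequence[float],
    x_name: str = "x",
    y_name: str = "y",
    subgroup: str = "all, group-controlled",
) -> AssociationResult:
    """Partial Pearson correlation controlling for one covariate.

    x and y are each regressed (with intercept) on the control; the residuals
    are correlated and the two-sided p uses t with n − 3 df. A constant
    control carries no information, so the plain correlation is returned
    (with its n − 2 df p-value) and a warning raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(control, dtype=float)
    if not (x.shape == y.shape == c.shape):
        raise ValueError("x, y and control must have equal length")
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(c)
    x, y, c = x[ok], y[ok], c[ok]
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 complete triples, got {n}")
    if np.std(c) == 0:
        warnings.warn("constant control covariate; returning plain correlation", stacklevel=2)
        return correlate(x, y, x_name, y_name, subgroup)
    design = np.column_stack([np.ones(n), c])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    # variables that are pure functions of the control leave only rounding
    # noise behind; treat that as zero residual variation
    if np.std(rx) <= 1e-10 * max(np.std(x), 1.0) or np.std(ry) <= 1e-10 * max(np.std(y), 1.0):
        raise ValueError(
            "no residual variation after removing the control; partial correlation undefined"
        )
    r = float(np.dot(rx, ry) / (np.linalg.norm(rx) * np.linalg.norm(ry)))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return AssociationResult(x_name, y_name, subgroup, n, r, p)


def network_pair_fc_summary(
    X: np.ndarray,
    emap: EdgeIndexMap,
    stable_edges: Sequence[int],
    pair: tuple[str, str],
    mode: str = "mean",
) -> np.ndarray:
    """Per-subject FC summary over the stable edges of one network pair.

    ``mode="mean"`` (default) averages the Fisher-z values of the stable
    edges whose endpoints lie in the given network pair; ``mode="per_edge"``
    returns the (n_subjects × n_edges) slice instead.
    """
    X = np.asarray(X, dtype=float)
    stable = np.asarray(sorted(set(map(int, stable_edges))), dtype=int)
    in_pair = emap.edges_for_pair(*pair)
    edges = np.intersect1d(stable, in_pair)
    if edges.size == 0:
        raise ValueError(f"no stable edges in network pair {pair}")
    if mode == "per_edge":
        return X[:, edges]
    if mode != "mean":
        raise ValueError("mode must be 'mean' or 'per_edge'")
    return X[:, edges].mean(axis=1)


def associate_pairs(
    X: np.ndarray,
    emap: EdgeIndexMap,
    stable_edges: Sequence[int],
    pheno: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    score_columns: Sequence[str],
    group_column: str = "group",
    case_label: str = "case",
    adjust: bool = False,
) -> pd.DataFrame:
    """Correlate network-pair FC summaries with symptom scores.

    For every (network pair, score) combination three rows are produced:
    within cases, within controls, and across all subjects controlling for
    group. Rows where a subgroup lacks enough complete pairs are skipped.
    Optional Benjamini–Hochberg adjustment adds a ``p_adj`` column.
    """
    group = pheno[group_column].to_numpy()
    is_case = group == case_label
    rows = []
    for pair in pairs:
        try:
            fc = network_pair_fc_summary(X, emap, stable_edges, pair)
        except ValueError:
            continue
        pair_name = f"{pair[0]}|{pair[1]}"
        for col in score_columns:
            score = pheno[col].to_numpy(dtype=float)
            for label, mask in (("case", is_case), ("control", ~is_case)):
                try:
                    res = correlate(fc[mask], score[mask], pair_name, col, subgroup=label)
                except ValueError:
                    continue
                rows.append(res)
            try:
                res = partial_correlate(fc, score, is_case.astype(float), pair_name, col)
                rows.append(res)
            except ValueError:
                pass
    out = pd.DataFrame([vars(r) for r in rows])
    if adjust and len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out
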