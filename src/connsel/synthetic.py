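"""Two-cohort synthetic connectome generator with planted discriminative edges.

Emulates the statistical structure the classification pipeline assumes: two
cohorts ("child"-like and "adult"-like) of case/control subjects whose
Fisher-z edge vectors are a network-blocked background plus group effects on
a known edge set plus independent Gaussian edge noise. Three planted edge
sets drive the group difference:

* **shared** edges (default within DMN and between DMN and vATN) are shifted
  by ``delta_shared`` in cases of *both* cohorts,
* **child-only** edges (default between SMN and dATN) shift only child cases,
* **adult-only** edges (default between DMN and LN) shift only adult cases.

Symptom scores are coupled to the planted-edge strength
(``score = beta · mean planted-edge z + group offset + noise``) for all
subjects, so score–connectivity correlations exist in controls as well.

A time-series mode embeds the same per-subject structure into a correlation
matrix (repaired to the nearest positive-semidefinite correlation matrix if
needed) and samples T multivariate-normal timepoints per subject, exercising
the connectome module end-to-end. The generator is fully deterministic given
its seed; ground truth sufficient to score any selector's recovery is
returned and written alongside fixtures.
"""

from __future__ import annotations

import json
import shutil
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .connectome import (
    EdgeIndexMap,
    build_edge_index_map,
    compute_connectivity,
    devectorize,
    read_atlas,
    read_edge_table,
    synthetic_atlas,
    vectorize_upper_triangle,
    write_atlas,
    write_edge_table,
    RegionTimeSeries,
)

__all__ = ["SyntheticSpec", "CohortData", "generate_cohort_pair", "write_fixture", "read_fixture"]

#: Network pairs the planted edge sets are drawn from, mirroring the finding
#: structure the generator emulates (shared: within-DMN and DMN–vATN;
#: child-specific: SMN–dATN; adult-specific: DMN–LN).
SHARED_PAIRS = (("DMN", "DMN"), ("DMN", "vATN"))
CHILD_PAIRS = (("SMN", "dATN"),)
ADULT_PAIRS = (("DMN", "LN"),)


@dataclass
class SyntheticSpec:
    """Full parameterization of the two-cohort generator.

    Defaults define the package's standard test-scale study: P = 50 regions
    (seven networks of 7 plus one unassigned region), 60 cases + 60 controls
    per cohort, 10 shared / 5 child-only / 5 adult-only planted edges with
    effect size 1.0 on the Fisher-z scale over a background of within-network
    z ≈ atanh(0.3) and between-network z ≈ atanh(0.05), with edge noise
    σ = 0.5. ``*_edges`` accept either a count (edges drawn deterministically
    from the canonical network pairs above) or an explicit list of edge
    indices.
    """

    network_sizes: dict[str, int] | None = None
    n_case: int = 60
    n_control: int = 60
    T: int = 120
    shared_edges: int | Sequence[int] = 10
    child_only_edges: int | Sequence[int] = 5
    adult_only_edges: int | Sequence[int] = 5
    delta_shared: float = 1.0
    delta_specific: float = 1.0
    rho_in: float = 0.3
    rho_out: float = 0.05
    sigma: float = 0.5
    beta: float = 5.0
    score_group_offset: float = 8.0
    score_noise: float = 2.0
    score_baseline: float = 18.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("delta_shared", "delta_specific", "sigma", "beta"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("cohorts must be non-empty")


@dataclass
class CohortData:
    """One synthetic cohort: edge features, labels, phenotype, bookkeeping."""

    cohort: str
    X: np.ndarray
    y: np.ndarray
    subject_ids: list[str]
    feature_ids: list[str]
    atlas: pd.DataFrame
    pheno: pd.DataFrame
    emap: EdgeIndexMap = field(repr=False, default=None)


def _draw_edges(
    emap: EdgeIndexMap,
    spec_edges: int | Sequence[int],
    pairs: Sequence[tuple[str, str]],
    rng: np.random.Generator,
    taken: set[int],
) -> list[int]:
    if not isinstance(spec_edges, int):
        chosen = [int(e) for e in spec_edges]
    else:
        candidates = np.concatenate([emap.edges_for_pair(*p) for p in pairs])
        candidates = np.array([c for c in np.unique(candidates) if c not in taken])
        if candidates.size < spec_edges:
            raise ValueError(
                f"not enough free edges in pairs {pairs} to plant {spec_edges}"
            )
        chosen = sorted(rng.choice(candidates, size=spec_edges, replace=False).tolist())
    overlap = taken.intersection(chosen)
    if overlap:
        raise ValueError(f"planted edge lists overlap on {sorted(overlap)}")
    taken.update(chosen)
    return list(map(int, chosen))


def _background_z(emap: EdgeIndexMap, rho_in: float, rho_out: float) -> np.ndarray:
    z_in, z_out = np.arctanh(rho_in), np.arctanh(rho_out)
    return np.where(emap.is_intra, z_in, z_out)


def _nearest_psd_correlation(R: np.ndarray, min_eig: float = 1e-6) -> tuple[np.ndarray, float]:
    """Clip eigenvalues up to ``min_eig`` and renormalize to unit diagonal."""
    w, v = np.linalg.eigh((R + R.T) / 2.0)
    shrink = float(max(0.0, min_eig - w.min()))
    w = np.clip(w, min_eig, None)
    R2 = (v * w) @ v.T
    d = np.sqrt(np.diag(R2))
    R2 = R2 / np.outer(d, d)
    np.fill_diagonal(R2, 1.0)
    return R2, shrink


def _simulate_cohort(
    cohort: str,
    emap: EdgeIndexMap,
    atlas: pd.DataFrame,
    planted: np.ndarray,  # per-edge effect added to cases
    score_edges: dict[str, list[int]],  # score column -> coupled edge list
    spec: SyntheticSpec,
    seed: int,
    mode: str,
) -> CohortData:
    rng = np.random.default_rng(seed)
    n = spec.n_case + spec.n_control
    e = emap.n_edges
    y = np.array(["case"] * spec.n_case + ["control"] * spec.n_control)
    z_bg = _background_z(emap, spec.rho_in, spec.rho_out)

    if mode == "edges":
        X = z_bg[None, :] + rng.normal(0.0, spec.sigma, size=(n, e))
        X[: spec.n_case] += planted[None, :]
    elif mode == "timeseries":
        X = np.empty((n, e))
        shrunk = 0
        for s in range(n):
            z = z_bg + (planted if s < spec.n_case else 0.0)
            R = np.tanh(devectorize(z, emap.n_regions))
            np.fill_diagonal(R, 1.0)
            R_psd, shrink = _nearest_psd_correlation(R)
            shrunk += shrink > 0
            L = np.linalg.cholesky(R_psd + 1e-10 * np.eye(emap.n_regions))
            ts = rng.standard_normal((spec.T, emap.n_regions)) @ L.T
            cm = compute_connectivity(
                RegionTimeSeries(f"{cohort}_{s:03d}", ts), apply_fisher=True
            )
            X[s] = vectorize_upper_triangle(cm)
        if shrunk:
            warnings.warn(
                f"{cohort}: repaired {shrunk} non-PSD correlation target(s) "
                "by eigenvalue clipping",
                stacklevel=3,
            )
    else:
        raise ValueError("mode must be 'edges' or 'timeseries'")

    subject_ids = [f"{cohort}_{s:03d}" for s in range(n)]
    pheno = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "cohort": cohort,
            "group": y,
        }
    )
    is_case = (y == "case").astype(float)
    for col, edges in score_edges.items():
        signal = X[:, edges].mean(axis=1) if edges else np.zeros(n)
        pheno[col] = (
            spec.score_baseline
            + spec.beta * signal
            + spec.score_group_offset * is_case
            + rng.normal(0.0, spec.score_noise, size=n)
        )
    return CohortData(
        cohort=cohort,
        X=X,
        y=y,
        subject_ids=subject_ids,
        feature_ids=emap.edge_ids(),
        atlas=atlas,
        pheno=pheno,
        emap=emap,
    )


def generate_cohort_pair(
    spec: SyntheticSpec, mode: str = "edges"
) -> tuple[CohortData, CohortData, dict]:
    """Generate the child-like and adult-like cohorts plus ground truth.

    Ground truth lists the planted edge indices and ids per category together
    with the effect sizes and seed — sufficient to compute recovery
    precision/recall of any selector with no other information.
    """
    atlas = synthetic_atlas(spec.network_sizes)
    emap = build_edge_index_map(atlas)
    rng = np.random.default_rng(derive_seed(spec.seed, "plant"))
    taken: set[int] = set()
    shared = _draw_edges(emap, spec.shared_edges, SHARED_PAIRS, rng, taken)
    child_only = _draw_edges(emap, spec.child_only_edges, CHILD_PAIRS, rng, taken)
    adult_only = _draw_edges(emap, spec.adult_only_edges, ADULT_PAIRS, rng, taken)

    e = emap.n_edges
    child_effect = np.zeros(e)
    child_effect[shared] = spec.delta_shared
    child_effect[child_only] = spec.delta_specific
    adult_effect = np.zeros(e)
    adult_effect[shared] = spec.delta_shared
    adult_effect[adult_only] = spec.delta_specific

    child = _simulate_cohort(
        "child",
        emap,
        atlas,
        child_effect,
        {"adhd_rs_total": shared, "hyperactivity_index": child_only},
        spec,
        derive_seed(spec.seed, "cohort", "child"),
        mode,
    )
    adult = _simulate_cohort(
        "adult",
        emap,
        atlas,
        adult_effect,
        {"adhd_rs_total": shared, "hyperactivity_index": adult_only},
        spec,
        derive_seed(spec.seed, "cohort", "adult"),
        mode,
    )
    ids = emap.edge_ids()
    truth = {
        "seed": spec.seed,
        "mode": mode,
        "n_regions": emap.n_regions,
        "n_edges": e,
        "delta_shared": spec.delta_shared,
        "delta_specific": spec.delta_specific,
        "sigma": spec.sigma,
        "shared_edges": shared,
        "child_only_edges": child_only,
        "adult_only_edges": adult_only,
        "shared_edge_ids": [ids[i] for i in shared],
        "child_only_edge_ids": [ids[i] for i in child_only],
        "adult_only_edge_ids": [ids[i] for i in adult_only],
    }
    return child, adult, truth


def write_fixture(
    dataset: CohortData,
    out_dir: str | Path,
    truth: dict | None = None,
    force: bool = False,
) -> Path:
    """Write a cohort as plain-text fixture files (edges/pheno/atlas TSV + truth JSON)."""
    out = Path(out_dir)
    if out.exists():
        if not force:
            raise FileExistsError(f"{out} exists; pass force=True to overwrite")
        shutil.rmtree(out)
    out.mkdir(parents=True)
    if dataset.X.shape[0] == 0:
        raise ValueError("empty cohort")
    write_edge_table(dataset.X, dataset.subject_ids, dataset.feature_ids, out / "edges.tsv")
    dataset.pheno.to_csv(out / "pheno.tsv", sep="\t", index=False, float_format="%.10g")
    write_atlas(dataset.atlas, out / "atlas.tsv")
    if truth is not None:
        (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return out


def read_fixture(fixture_dir: str | Path) -> CohortData:
    """Read back a fixture written by :func:`write_fixture`."""
    d = Path(fixture_dir)
    X, subject_ids, feature_ids = read_edge_table(d / "edges.tsv")
    pheno = pd.read_csv(d / "pheno.tsv", sep="\t")
    atlas = read_atlas(d / "atlas.tsv")
    emap = build_edge_index_map(atlas)
    y = pheno.set_index("subject_id").loc[subject_ids, "group"].to_numpy()
    cohort = str(pheno["cohort"].iloc[0]) if "cohort" in pheno else d.name
    return CohortData(
        cohort=cohort,
        X=X,
        y=y,
        subject_ids=subject_ids,
        feature_ids=feature_ids,
        atlas=atlas,
        pheno=pheno,
        emap=emap,
    )
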