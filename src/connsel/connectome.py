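"""Functional-connectivity edge features from parcel time series.

Each subject contributes a T (timepoints) × P (regions) matrix of regional
mean BOLD time series. Pairwise Pearson correlations between region time
courses give a symmetric P × P connectivity matrix; the Fisher z-transform
``z = atanh(r)`` stabilizes the variance of the correlations. The strictly
upper triangle of the z-matrix — E = P(P−1)/2 "edges" — is the feature
vector used by every downstream selector and classifier.

Edges are additionally labeled by the functional-network membership of their
two endpoint regions (the canonical seven cortical networks: visual,
somatomotor, dorsal/ventral attention, limbic, frontoparietal, default mode),
so that selected edges can be summarized as intra- vs inter-network
connectivity. Subcortical and cerebellar regions have no network assignment
in that scheme and are labeled UNASSIGNED; their edges remain ordinary
features but fall into UNASSIGNED network pairs in summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NETWORKS",
    "UNASSIGNED",
    "RegionTimeSeries",
    "ConnectivityMatrix",
    "EdgeIndexMap",
    "compute_connectivity",
    "fisher_z",
    "vectorize_upper_triangle",
    "devectorize",
    "build_edge_index_map",
    "network_pair_summary",
    "default_atlas",
    "synthetic_atlas",
    "read_atlas",
    "write_atlas",
    "read_time_series",
    "read_edge_table",
    "write_edge_table",
]

#: Canonical seven-network labels, in a fixed display order.
NETWORKS: tuple[str, ...] = ("VN", "SMN", "dATN", "vATN", "LN", "FPN", "DMN")
UNASSIGNED = "UNASSIGNED"
_ALL_LABELS = NETWORKS + (UNASSIGNED,)
_NET_ORDER = {name: i for i, name in enumerate(_ALL_LABELS)}

ANATOMICAL_CLASSES = ("cortical", "subcortical", "cerebellar")

#: Default symmetry tolerance (absolute) for connectivity matrices.
SYMMETRY_ATOL = 1e-8
#: Correlations are clipped to [-1+eps, 1-eps] before atanh.
FISHER_CLIP_EPS = 1e-7


@dataclass
class RegionTimeSeries:
    """Regional mean time series for one subject (T timepoints × P regions)."""

    subject_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (T × P) array")
        t, p = self.values.shape
        if t < 3:
            raise ValueError(
                f"subject {self.subject_id!r}: need at least 3 timepoints, got {t}"
            )
        if p < 2:
            raise ValueError(f"subject {self.subject_id!r}: need at least 2 regions")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"subject {self.subject_id!r}: non-finite values in time series")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric region × region connectivity matrix for one subject.

    ``scale`` is ``"pearson_r"`` (unit diagonal, entries in [−1, 1]) or
    ``"fisher_z"`` (zero diagonal; off-diagonals are atanh of clipped r).
    """

    subject_id: str
    values: np.ndarray
    scale: str = "fisher_z"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if self.scale not in ("pearson_r", "fisher_z"):
            raise ValueError(f"unknown scale {self.scale!r}")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def compute_connectivity(
    ts: RegionTimeSeries,
    apply_fisher: bool = True,
    clip_eps: float = FISHER_CLIP_EPS,
) -> ConnectivityMatrix:
    """Pearson-correlate all region pairs, optionally Fisher z-transform.

    Raises
    ------
    ValueError
        If any region column has zero variance (the offending region index,
        1-based, is named in the message) or if fewer than 3 timepoints.
    """
    x = ts.values
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0.0)
    if dead.size:
        raise ValueError(
            f"subject {ts.subject_id!r}: zero-variance region column(s) "
            f"{[int(i) + 1 for i in dead]} (1-based)"
        )
    r = np.corrcoef(x, rowvar=False)
    r = (r + r.T) / 2.0  # exact symmetry against rounding
    r = np.clip(r, -1.0, 1.0)
    if not apply_fisher:
        np.fill_diagonal(r, 1.0)
        return ConnectivityMatrix(ts.subject_id, r, scale="pearson_r")
    return fisher_z(ConnectivityMatrix(ts.subject_id, r, scale="pearson_r"), clip_eps)


def fisher_z(cm: ConnectivityMatrix, clip_eps: float = FISHER_CLIP_EPS) -> ConnectivityMatrix:
    """Fisher z-transform a Pearson matrix: atanh of off-diagonals, zero diagonal.

    |r| = 1 diverges under atanh, so entries are clipped to ``[-1+eps, 1-eps]``
    first; clipping is reported as a warning because it signals degenerate
    (e.g., duplicated-region) input.
    """
    if cm.scale != "pearson_r":
        raise ValueError("fisher_z expects a pearson_r-scale matrix")
    r = cm.values.copy()
    np.fill_diagonal(r, 0.0)
    hi = 1.0 - clip_eps
    n_clip = int(np.count_nonzero(np.abs(r) > hi))
    if n_clip:
        warnings.warn(
            f"subject {cm.subject_id!r}: clipped {n_clip} off-diagonal correlation(s) "
            f"with |r| > {hi} before Fisher transform",
            stacklevel=2,
        )
    z = np.arctanh(np.clip(r, -hi, hi))
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(cm.subject_id, z, scale="fisher_z")


def _as_matrix(cm: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    return cm.values if isinstance(cm, ConnectivityMatrix) else np.asarray(cm, dtype=float)


def vectorize_upper_triangle(
    cm: ConnectivityMatrix | np.ndarray, atol: float = SYMMETRY_ATOL
) -> np.ndarray:
    """Extract the strictly-upper-triangle edges in canonical order.

    Canonical order is row-major over pairs (i, j) with i < j: i ascending,
    then j ascending — the order produced by ``numpy.triu_indices``. The
    result has length E = P(P−1)/2.
    """
    m = _as_matrix(cm)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(m, m.T, atol=atol, rtol=0.0):
        raise ValueError(f"matrix is asymmetric beyond atol={atol}")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu].copy()


def devectorize(edges: np.ndarray, n_regions: int) -> np.ndarray:
    """Inverse of :func:`vectorize_upper_triangle` (zero diagonal)."""
    edges = np.asarray(edges, dtype=float)
    expected = n_regions * (n_regions - 1) // 2
    if edges.shape != (expected,):
        raise ValueError(f"expected {expected} edges for P={n_regions}, got {edges.shape}")
    m = np.zeros((n_regions, n_regions))
    iu = np.triu_indices(n_regions, k=1)
    m[iu] = edges
    return m + m.T


# ---------------------------------------------------------------------------
# Atlas and edge-index bookkeeping
# ---------------------------------------------------------------------------

_ATLAS_COLUMNS = ["index", "name", "anatomical_class", "network"]


def _validate_atlas(atlas: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _ATLAS_COLUMNS if c not in atlas.columns]
    if missing:
        raise ValueError(f"atlas table missing column(s) {missing}")
    atlas = atlas.reset_index(drop=True)
    idx = atlas["index"].to_numpy()
    if not np.array_equal(idx, np.arange(1, len(atlas) + 1)):
        raise ValueError("atlas region indices must be contiguous 1..P and sorted")
    bad_class = set(atlas["anatomical_class"]) - set(ANATOMICAL_CLASSES)
    if bad_class:
        raise ValueError(f"unknown anatomical class(es) {sorted(bad_class)}")
    bad_net = set(atlas["network"]) - set(_ALL_LABELS)
    if bad_net:
        raise ValueError(f"unknown network label(s) {sorted(bad_net)}")
    return atlas


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order a network pair by the fixed display order (VN … DMN, UNASSIGNED)."""
    return (a, b) if _NET_ORDER[a] <= _NET_ORDER[b] else (b, a)


@dataclass
class EdgeIndexMap:
    """Bijection edge index ↔ region pair ↔ network-pair label.

    Edge e connects regions ``region_i[e] < region_j[e]`` (0-based internal
    indices; atlas files are 1-based). ``network_pair[e]`` is the unordered
    pair of endpoint network labels, canonically ordered, and ``is_intra[e]``
    flags same-network edges.
    """

    atlas: pd.DataFrame
    region_i: np.ndarray = field(repr=False)
    region_j: np.ndarray = field(repr=False)
    network_pair: list[tuple[str, str]] = field(repr=False)
    is_intra: np.ndarray = field(repr=False)

    @property
    def n_regions(self) -> int:
        return len(self.atlas)

    @property
    def n_edges(self) -> int:
        return len(self.region_i)

    def __len__(self) -> int:
        return self.n_edges

    def edge_ids(self) -> list[str]:
        """Stable string identifiers ``e<i>-<j>`` with 1-based atlas indices."""
        return [
            f"e{int(i) + 1}-{int(j) + 1}" for i, j in zip(self.region_i, self.region_j)
        ]

    def pair_label(self, e: int) -> str:
        a, b = self.network_pair[e]
        return f"{a}|{b}"

    def edges_for_pair(self, a: str, b: str) -> np.ndarray:
        """Edge indices whose endpoints lie in networks {a, b} (unordered)."""
        want = canonical_pair(a, b)
        return np.flatnonzero([p == want for p in self.network_pair])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "edge_index": np.arange(self.n_edges),
                "edge_id": self.edge_ids(),
                "region_i": self.region_i + 1,
                "region_j": self.region_j + 1,
                "network_i": [p[0] for p in self.network_pair],
                "network_j": [p[1] for p in self.network_pair],
                "is_intra": self.is_intra,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_edge_index_map(atlas: pd.DataFrame) -> EdgeIndexMap:
    """Label every edge of a P-region atlas with its network pair."""
    atlas = _validate_atlas(atlas)
    p = len(atlas)
    nets = atlas["network"].to_numpy()
    iu, ju = np.triu_indices(p, k=1)
    pairs = [canonical_pair(nets[i], nets[j]) for i, j in zip(iu, ju)]
    intra = np.array([nets[i] == nets[j] for i, j in zip(iu, ju)], dtype=bool)
    return EdgeIndexMap(atlas, iu, ju, pairs, intra)


def network_pair_summary(
    edges: np.ndarray,
    emap: EdgeIndexMap,
    subset: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Per-network-pair count and mean edge value over a subset of edges.

    With ``subset=None`` all edges are summarized. An empty subset yields an
    empty table. Counts always sum to ``len(subset)``.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.shape != (emap.n_edges,):
        raise ValueError(f"edge vector length {edges.shape} != E={emap.n_edges}")
    idx = np.arange(emap.n_edges) if subset is None else np.asarray(sorted(set(subset)), dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= emap.n_edges):
        raise ValueError("subset contains out-of-range edge indices")
    rows: dict[tuple[str, str], list[float]] = {}
    for e in idx:
        rows.setdefault(emap.network_pair[e], []).append(edges[e])
    table = pd.DataFrame(
        [
            {
                "network_pair": f"{a}|{b}",
                "is_intra": a == b,
                "count": len(v),
                "mean": float(np.mean(v)),
            }
            for (a, b), v in sorted(rows.items(), key=lambda kv: (_NET_ORDER[kv[0][0]], _NET_ORDER[kv[0][1]]))
        ],
        columns=["network_pair", "is_intra", "count", "mean"],
    )
    return table


# Default whole-brain atlas bookkeeping: 273 regions = 210 cortical + 36
# subcortical + 27 cerebellar, with the 210 cortical regions split across the
# seven canonical networks. The per-network cortical counts below are this
# package's fixed convention (the parcellation's own network assignment is an
# atlas-file concern); subcortical and cerebellar regions are UNASSIGNED.
_DEFAULT_CORTICAL_SIZES = {
    "VN": 30,
    "SMN": 30,
    "dATN": 26,
    "vATN": 26,
    "LN": 26,
    "FPN": 34,
    "DMN": 38,
}  # sums to 210


def default_atlas() -> pd.DataFrame:
    """Default 273-region lookup table (210 cortical, 36 subcortical, 27 cerebellar)."""
    rows = []
    idx = 1
    for net, size in _DEFAULT_CORTICAL_SIZES.items():
        for k in range(size):
            rows.append((idx, f"CTX_{net}_{k + 1:02d}", "cortical", net))
            idx += 1
    for k in range(36):
        rows.append((idx, f"SUBCTX_{k + 1:02d}", "subcortical", UNASSIGNED))
        idx += 1
    for k in range(27):
        rows.append((idx, f"CBM_{k + 1:02d}", "cerebellar", UNASSIGNED))
        idx += 1
    return pd.DataFrame(rows, columns=_ATLAS_COLUMNS)


def synthetic_atlas(network_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Small test-scale atlas: given per-network region counts (default 7×7+1).

    UNASSIGNED regions are labeled subcortical; all others cortical.
    """
    if network_sizes is None:
        network_sizes = {net: 7 for net in NETWORKS}
        network_sizes[UNASSIGNED] = 1
    rows = []
    idx = 1
    for net, size in network_sizes.items():
        if net not in _ALL_LABELS:
            raise ValueError(f"unknown network label {net!r}")
        for k in range(size):
            cls = "subcortical" if net == UNASSIGNED else "cortical"
            prefix = "SUBCTX" if net == UNASSIGNED else f"CTX_{net}"
            rows.append((idx, f"{prefix}_{k + 1:02d}", cls, net))
            idx += 1
    return pd.DataFrame(rows, columns=_ATLAS_COLUMNS)


# ---------------------------------------------------------------------------
# Plain-text I/O
# ---------------------------------------------------------------------------


def read_atlas(path: str | Path) -> pd.DataFrame:
    atlas = pd.read_csv(path, sep="\t")
    return _validate_atlas(atlas)


def write_atlas(atlas: pd.DataFrame, path: str | Path) -> None:
    _validate_atlas(atlas).to_csv(path, sep="\t", index=False)


def read_time_series(path: str | Path, subject_id: str | None = None) -> RegionTimeSeries:
    """Read one subject's T × P time-series table (TSV/CSV, optional header).

    A header row of region names is detected by non-numeric first-row cells.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    first = pd.read_csv(path, sep=sep, header=None, nrows=1)
    has_header = first.iloc[0].map(lambda v: isinstance(v, str)).any()
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
    return RegionTimeSeries(subject_id or path.stem, df.to_numpy(dtype=float))


def write_edge_table(
    X: np.ndarray,
    subject_ids: Sequence[str],
    feature_ids: Sequence[str],
    path: str | Path,
) -> None:
    """Write a cohort edge table (subjects × E) as TSV with a subject_id column."""
    df = pd.DataFrame(np.asarray(X, dtype=float), columns=list(feature_ids))
    df.insert(0, "subject_id", list(subject_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_edge_table(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a cohort edge table; returns (X, subject_ids, feature_ids)."""
    df = pd.read_csv(path, sep="\t")
    if "subject_id" not in df.columns:
        raise ValueError(f"edge table {path} lacks a subject_id column")
    sids = df["subject_id"].astype(str).tolist()
    feats = [c for c in df.columns if c != "subject_id"]
    return df[feats].to_numpy(dtype=float), sids, feats
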