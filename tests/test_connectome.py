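import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from connsel.connectome import (
    ConnectivityMatrix,
    RegionTimeSeries,
    build_edge_index_map,
    compute_connectivity,
    default_atlas,
    devectorize,
    fisher_z,
    network_pair_summary,
    read_edge_table,
    read_time_series,
    synthetic_atlas,
    vectorize_upper_triangle,
    write_edge_table,
)


def brute_force_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Independent double-loop Pearson r from the definition."""
    mx, my = sum(x) / len(x), sum(y) / len(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = sum((a - mx) ** 2 for a in x) ** 0.5
    dy = sum((b - my) ** 2 for b in y) ** 0.5
    return num / (dx * dy)


class TestComputeConnectivity:
    def test_matches_brute_force_oracle(self):
        """Full r matrix for three known columns equals the definitional formula."""
        cols = np.array([[0, 1, 5], [1, 1, 2], [2, 2, 4], [3, 4, 1], [4, 5, 0]], dtype=float)
        cm = compute_connectivity(RegionTimeSeries("s", cols), apply_fisher=False)
        for i in range(3):
            for j in range(3):
                expect = 1.0 if i == j else brute_force_pearson(cols[:, i], cols[:, j])
                assert cm.values[i, j] == pytest.approx(expect, abs=1e-12)
        z = fisher_z(cm)
        assert z.values[0, 1] == pytest.approx(np.arctanh(cm.values[0, 1]), abs=1e-12)
        assert np.all(np.diag(z.values) == 0.0)

    def test_random_inputs_match_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((10, 8))
        cm = compute_connectivity(RegionTimeSeries("s", x), apply_fisher=False)
        for i in range(8):
            for j in range(i + 1, 8):
                assert cm.values[i, j] == pytest.approx(
                    brute_force_pearson(x[:, i], x[:, j]), abs=1e-10
                )
        assert np.array_equal(cm.values, cm.values.T)

    def test_perfect_and_anti_correlation_clip(self):
        x = np.array([[0.0, 0.0, 5.0], [1.0, 1.0, 2.0], [2.0, 2.0, 4.0], [3.0, 3.0, 1.0]])
        x[:, 1] = 2 * x[:, 0] + 1  # identical up to affine => r = 1
        with pytest.warns(UserWarning, match="clipped"):
            cm = compute_connectivity(RegionTimeSeries("s", x), apply_fisher=True)
        assert cm.values[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))
        y = np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]])
        with pytest.warns(UserWarning, match="clipped"):
            cm2 = compute_connectivity(RegionTimeSeries("s", y), apply_fisher=True)
        assert cm2.values[0, 1] == pytest.approx(-np.arctanh(1 - 1e-7))

    def test_zero_variance_column_names_region(self):
        x = np.ones((5, 3))
        x[:, 0] = np.arange(5)
        with pytest.raises(ValueError, match=r"\[2, 3\]"):
            compute_connectivity(RegionTimeSeries("s", x))

    def test_too_few_timepoints(self):
        with pytest.raises(ValueError, match="3 timepoints"):
            RegionTimeSeries("s", np.ones((2, 4)))

    def test_fisher_transform_odd_and_increasing(self):
        r = np.linspace(-0.999, 0.999, 41)
        z = np.arctanh(r)
        assert np.allclose(z, -z[::-1], atol=1e-12)  # odd
        assert np.all(np.diff(z) > 0)  # strictly increasing


class TestVectorize:
    @pytest.mark.parametrize("p,expected", [(2, 1), (3, 3), (10, 45), (273, 37128)])
    def test_edge_count(self, p, expected):
        m = np.zeros((p, p))
        assert vectorize_upper_triangle(m).shape == (expected,)

    @given(st.integers(min_value=2, max_value=12), st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_round_trip_identity(self, p, seed):
        rng = np.random.default_rng(seed)
        m = rng.standard_normal((p, p))
        m = m + m.T
        np.fill_diagonal(m, 0.0)
        assert np.array_equal(devectorize(vectorize_upper_triangle(m), p), m)

    def test_canonical_order_is_row_major(self):
        m = devectorize(np.arange(1.0, 7.0), 4)
        # (0,1)=1, (0,2)=2, (0,3)=3, (1,2)=4, (1,3)=5, (2,3)=6
        assert m[0, 1] == 1 and m[0, 3] == 3 and m[1, 2] == 4 and m[2, 3] == 6

    def test_asymmetry_rejected(self):
        m = np.zeros((3, 3))
        m[0, 1] = 1e-4
        with pytest.raises(ValueError, match="asymmetric"):
            vectorize_upper_triangle(m)


class TestEdgeIndexMap:
    def test_toy_atlas_enumeration(self, toy_atlas):
        emap = build_edge_index_map(toy_atlas)
        labels = [emap.pair_label(e) for e in range(len(emap))]
        # regions: DMN, DMN, SMN, UNASSIGNED -> 6 edges
        assert sorted(labels) == sorted(
            ["DMN|DMN", "SMN|DMN", "SMN|DMN", "DMN|UNASSIGNED", "DMN|UNASSIGNED", "SMN|UNASSIGNED"]
        )
        assert emap.is_intra.tolist() == [True, False, False, False, False, False]

    def test_counts_sum_to_E_and_single_network_all_intra(self):
        atlas = synthetic_atlas({"DMN": 6})
        emap = build_edge_index_map(atlas)
        assert len(emap) == 15
        assert emap.is_intra.all()
        table = network_pair_summary(np.ones(15), emap)
        assert table["count"].sum() == 15

    def test_pair_label_order_invariant(self, small_emap):
        a = small_emap.edges_for_pair("DMN", "vATN")
        b = small_emap.edges_for_pair("vATN", "DMN")
        assert np.array_equal(a, b) and a.size > 0


class TestNetworkPairSummary:
    def test_constant_edges_all_means_equal(self, toy_atlas):
        emap = build_edge_index_map(toy_atlas)
        t = network_pair_summary(np.full(6, 2.5), emap)
        assert np.allclose(t["mean"], 2.5)
        assert t["count"].sum() == 6

    def test_hand_enumeration(self, toy_atlas):
        emap = build_edge_index_map(toy_atlas)
        vals = np.arange(1.0, 7.0)  # edges (0,1)..(2,3)
        t = network_pair_summary(vals, emap).set_index("network_pair")
        # {DMN,DMN} = edge(0,1)=1; {SMN,DMN} = edges(0,2)=2,(1,2)=4 -> mean 3
        assert t.loc["DMN|DMN", "mean"] == 1.0
        assert t.loc["SMN|DMN", "mean"] == 3.0 and t.loc["SMN|DMN", "count"] == 2
        # {DMN,UNASSIGNED} = edges(0,3)=3,(1,3)=5 -> mean 4; {SMN,UNASSIGNED}=(2,3)=6
        assert t.loc["DMN|UNASSIGNED", "mean"] == 4.0
        assert t.loc["SMN|UNASSIGNED", "mean"] == 6.0

    def test_single_edge_and_empty_subset(self, toy_atlas):
        emap = build_edge_index_map(toy_atlas)
        one = network_pair_summary(np.arange(6.0), emap, subset=[3])
        assert len(one) == 1 and one["count"].iloc[0] == 1 and one["mean"].iloc[0] == 3.0
        assert network_pair_summary(np.arange(6.0), emap, subset=[]).empty


class TestDefaultAtlas:
    def test_region_totals(self):
        atlas = default_atlas()
        assert len(atlas) == 273
        counts = atlas["anatomical_class"].value_counts()
        assert counts["cortical"] == 210
        assert counts["subcortical"] == 36
        assert counts["cerebellar"] == 27
        assert (atlas.loc[atlas["anatomical_class"] != "cortical", "network"] == "UNASSIGNED").all()
        assert set(atlas.loc[atlas["anatomical_class"] == "cortical", "network"]) == {
            "VN", "SMN", "dATN", "vATN", "LN", "FPN", "DMN"
        }


class TestIO:
    def test_edge_table_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((4, 6))
        sids = [f"s{i}" for i in range(4)]
        fids = [f"e{i}" for i in range(6)]
        write_edge_table(X, sids, fids, tmp_path / "edges.tsv")
        X2, sids2, fids2 = read_edge_table(tmp_path / "edges.tsv")
        assert sids2 == sids and fids2 == fids
        assert np.allclose(X2, X, atol=1e-9)

    def test_time_series_header_detection(self, tmp_path):
        df = pd.DataFrame({"r1": [1.0, 2, 3, 2], "r2": [0.5, 1, 0, 2]})
        df.to_csv(tmp_path / "sub1.tsv", sep="\t", index=False)
        ts = read_time_series(tmp_path / "sub1.tsv")
        assert ts.subject_id == "sub1" and ts.values.shape == (4, 2)
        df.to_csv(tmp_path / "sub2.csv", index=False, header=False)
        ts2 = read_time_series(tmp_path / "sub2.csv")
        assert ts2.values.shape == (4, 2)
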