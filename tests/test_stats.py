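import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import caslquant as cq
from caslquant.io import QuantMap
from caslquant.stats import (
    ROIAtlas,
    aggregate_if_measurements,
    bh_fdr,
    extract_roi_means,
    mad_outlier_filter,
    region_stat_table,
    two_sample_test,
    voxelwise_group_map,
)


def brute_force_bh(p, q):
    """Independent step-up scan: largest k with p_(k) <= k q / m."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    if k_star:
        reject[order[:k_star]] = True
    # adjusted values: running minimum of m p_(j) / j from the top
    adj = np.empty(m)
    running = 1.0
    for j in range(m, 0, -1):
        running = min(running, m * p[order[j - 1]] / j)
        adj[order[j - 1]] = running
    return adj, reject


class TestExtractROIMeans:
    def _atlas(self, geometry):
        labels = np.zeros(geometry.shape, dtype=np.int32)
        labels[:16] = 1
        labels[16:] = 2
        return ROIAtlas(labels=labels, regions={1: ("CPu", 0.26), 2: ("Thal", -1.82)})

    def test_uniform_map(self, geometry):
        atlas = self._atlas(geometry)
        qm = QuantMap(data=np.full(geometry.shape, 7.5), geometry=geometry)
        out = extract_roi_means(qm, atlas)
        np.testing.assert_allclose(out["mean"], 7.5)

    def test_two_region_values(self, geometry):
        atlas = self._atlas(geometry)
        data = np.where(atlas.labels == 1, 10.0, 20.0)
        out = extract_roi_means(QuantMap(data=data, geometry=geometry), atlas)
        assert out.set_index("region")["mean"].to_dict() == {"CPu": 10.0, "Thal": 20.0}

    def test_masked_voxels_excluded_from_mean(self, geometry):
        atlas = self._atlas(geometry)
        rng = np.random.default_rng(0)
        data = rng.random(geometry.shape)
        mask = rng.random(geometry.shape) > 0.3
        out = extract_roi_means(QuantMap(data=data, geometry=geometry, mask=mask), atlas)
        sel = (atlas.labels == 1) & mask
        assert out.loc[out.region == "CPu", "mean"].item() == pytest.approx(data[sel].mean())
        assert out.loc[out.region == "CPu", "n_voxels"].item() == int(sel.sum())

    def test_empty_region_flagged_missing(self, geometry):
        atlas = self._atlas(geometry)
        qm = QuantMap(
            data=np.zeros(geometry.shape),
            geometry=geometry,
            mask=(atlas.labels != 1),
        )
        out = extract_roi_means(qm, atlas)
        row = out[out.region == "CPu"].iloc[0]
        assert row["missing"] and np.isnan(row["mean"])


class TestTwoSampleTest:
    def test_identical_groups(self):
        t, p = two_sample_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_shift_detected_with_fixed_sign(self):
        a = np.array([1.0, 2.0, 3.0])
        t, p = two_sample_test(a, a + 10.0)
        assert p < 0.01
        assert t < 0  # first group smaller
        # closed-form pooled t for equal n and equal variance
        sp2 = a.var(ddof=1)
        expected = -10.0 / np.sqrt(sp2 * (2 / 3))
        assert t == pytest.approx(expected)

    def test_swapping_groups_flips_sign(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 7.0]
        t1, p1 = two_sample_test(a, b)
        t2, p2 = two_sample_test(b, a)
        assert t1 == -t2 and p1 == p2

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            two_sample_test([1.0], [1.0, 2.0])


class TestBHFDR:
    def test_single_p_value(self):
        q_adj, reject = bh_fdr([0.04], q=0.05)
        assert reject[0] and q_adj[0] == pytest.approx(0.04)

    def test_uniform_ladder_all_rejected(self):
        p = [0.01, 0.02, 0.03, 0.04, 0.05]
        q_adj, reject = bh_fdr(p, q=0.05)
        assert reject.all()
        b_adj, b_rej = brute_force_bh(p, 0.05)
        np.testing.assert_allclose(q_adj, b_adj)
        np.testing.assert_array_equal(reject, b_rej)

    def test_all_ones_none_rejected(self):
        _, reject = bh_fdr([1.0, 1.0, 1.0])
        assert not reject.any()

    def test_empty_input(self):
        q_adj, reject = bh_fdr([])
        assert q_adj.size == 0 and reject.size == 0

    @pytest.mark.parametrize("m", range(1, 9))
    def test_matches_brute_force_on_random_vectors(self, m):
        rng = np.random.default_rng(m)
        for _ in range(25):
            p = rng.random(m)
            q = rng.choice([0.01, 0.05, 0.1])
            q_adj, reject = bh_fdr(p, q=q)
            b_adj, b_rej = brute_force_bh(p, q)
            np.testing.assert_allclose(q_adj, b_adj, atol=1e-12)
            np.testing.assert_array_equal(reject, b_rej)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_property_matches_brute_force(self, p):
        q_adj, reject = bh_fdr(p, q=0.05)
        b_adj, b_rej = brute_force_bh(p, 0.05)
        np.testing.assert_allclose(q_adj, b_adj, atol=1e-12)
        np.testing.assert_array_equal(reject, b_rej)


class TestVoxelwiseGroupMap:
    SHAPE = (24, 24, 5)

    def test_null_simulations_rarely_survive(self):
        mask = np.ones(self.SHAPE, bool)
        n_with_clusters = 0
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            A = rng.standard_normal(self.SHAPE + (10,))
            B = rng.standard_normal(self.SHAPE + (10,))
            _, table = voxelwise_group_map(A, B, mask)
            n_with_clusters += int(len(table) > 0)
        assert n_with_clusters <= 2  # <= 10% of 20 runs

    def test_planted_27_voxel_effect_survives(self):
        rng = np.random.default_rng(7)
        mask = np.ones(self.SHAPE, bool)
        A = rng.standard_normal(self.SHAPE + (10,))
        B = rng.standard_normal(self.SHAPE + (10,))
        B[5:8, 5:8, 1:4, :] += 10.0
        t_map, table = voxelwise_group_map(A, B, mask)
        assert len(table) == 1
        assert table.iloc[0]["size"] == 27
        assert t_map[6, 6, 2] != 0.0

    def test_planted_5_voxel_effect_removed_by_extent_filter(self):
        rng = np.random.default_rng(8)
        mask = np.ones(self.SHAPE, bool)
        A = rng.standard_normal(self.SHAPE + (10,))
        B = rng.standard_normal(self.SHAPE + (10,))
        B[5:10, 5, 1, :] += 10.0
        _, table = voxelwise_group_map(A, B, mask, cluster_k=10)
        assert len(table) == 0

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError, match="geometr"):
            voxelwise_group_map(
                np.zeros((4, 4, 2, 3)), np.zeros((5, 4, 2, 3)), np.ones((4, 4, 2), bool)
            )


class TestMADFilter:
    def test_degenerate_mad_keeps_only_median_values(self):
        keep = mad_outlier_filter([1, 1, 1, 1, 100])
        np.testing.assert_array_equal(keep, [True, True, True, True, False])

    def test_hand_computed_limits(self):
        # median 3, MAD 1, limits [0, 6]
        keep = mad_outlier_filter([1, 2, 3, 4, 5])
        assert keep.all()
        # {1,2,3,4,5,100}: median 3.5, MAD 1.5, limits [-1, 8]
        keep = mad_outlier_filter([1, 2, 3, 4, 5, 100])
        np.testing.assert_array_equal(keep, [True] * 5 + [False])

    def test_single_value_kept(self):
        assert mad_outlier_filter([3.0]).all()

    @given(
        st.lists(st.integers(min_value=-1000, max_value=1000), min_size=2, max_size=20),
        st.integers(min_value=-100, max_value=100),
        st.integers(min_value=1, max_value=50),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_translation_and_scale_equivariance(self, values, shift, scale):
        # integer inputs keep the interval bounds exact in float arithmetic
        x = np.array(values, dtype=float)
        base = mad_outlier_filter(x)
        np.testing.assert_array_equal(mad_outlier_filter(scale * x + shift), base)
        np.testing.assert_array_equal(mad_outlier_filter(-scale * x + shift), base)


class TestAggregateIF:
    @staticmethod
    def _records(rows):
        return pd.DataFrame(rows, columns=["animal", "region", "image", "value"])

    def test_outlier_excluded_from_animal_mean(self):
        rows = [("a1", "CPu", i, v) for i, v in enumerate([10.0, 11.0, 9.0, 10.0, 100.0])]
        out = aggregate_if_measurements(self._records(rows))
        assert len(out) == 1
        assert out.iloc[0]["value"] == pytest.approx(np.mean([10.0, 11.0, 9.0, 10.0]))
        assert out.iloc[0]["n_images"] == 4

    def test_fewer_than_three_retained_drops_animal_region(self):
        rows = [("a1", "CPu", 0, 10.0), ("a1", "CPu", 1, 10.5), ("a1", "CPu", 2, 100.0),
                ("a1", "Thal", 0, 5.0), ("a1", "Thal", 1, 5.2), ("a1", "Thal", 2, 5.1)]
        out = aggregate_if_measurements(self._records(rows))
        assert set(out["region"]) == {"Thal"}  # CPu dropped: 2 retained < 3

    def test_no_outliers_equals_groupby_mean(self):
        rng = np.random.default_rng(0)
        rows = []
        for animal in ("a1", "a2"):
            for region in ("CPu", "Thal"):
                base = rng.uniform(5, 15)
                for i in range(4):
                    rows.append((animal, region, i, base + 0.1 * i))
        df = self._records(rows)
        out = aggregate_if_measurements(df).set_index(["animal", "region"])["value"]
        expected = df.groupby(["animal", "region"])["value"].mean()
        pd.testing.assert_series_equal(out.sort_index(), expected.sort_index(), check_names=False)


class TestRegionStatTable:
    def test_q_at_least_p_and_group_columns(self):
        rng = np.random.default_rng(1)
        rows = []
        for region in ("CPu", "Thal", "RspCtx"):
            shift = 5.0 if region == "CPu" else 0.0
            for g, off in (("wt", 0.0), ("het", shift)):
                for i in range(6):
                    rows.append({"region": region, "bregma_level": 0.26,
                                 "genotype": g, "value": rng.normal(100 + off, 1.0)})
        table = region_stat_table(pd.DataFrame(rows), groups=("wt", "het"))
        assert (table["q_adjusted"] >= table["p"] - 1e-15).all()
        assert table.loc[table.region == "CPu", "significant"].item()
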