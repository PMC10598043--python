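import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import skbio.stats.distance as sksd
from nichegrad.compare import (anosim, bray_curtis, environment_distance,
                               kruskal_stress, mantel, nmds,
                               nmds_distance_correlation, spatial_distance)
from nichegrad.model import (DistanceMatrix, OtuTable, SampleMetadata)


def dm(points, ids=None):
    points = np.asarray(points, float)
    ids = ids or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(points)), ids=ids)


class TestBrayCurtis:
    def test_disjoint_samples_distance_one(self):
        t = OtuTable(pd.DataFrame([[1, 0], [0, 1]], index=["a", "b"],
                                  columns=["x", "y"]))
        assert bray_curtis(t).data[0, 1] == pytest.approx(1.0)

    def test_identical_samples_distance_zero(self):
        t = OtuTable(pd.DataFrame([[2, 3], [2, 3]], index=["a", "b"],
                                  columns=["x", "y"]))
        assert bray_curtis(t).data[0, 1] == pytest.approx(0.0)

    def test_hand_value(self):
        t = OtuTable(pd.DataFrame([[2, 2], [1, 3]], index=["a", "b"],
                                  columns=["x", "y"]))
        assert bray_curtis(t, on_counts=True).data[0, 1] == pytest.approx(0.25)

    def test_values_in_unit_interval(self, topsoil):
        sub, _, _ = topsoil
        d = bray_curtis(sub)
        assert (d.data >= 0).all() and (d.data <= 1 + 1e-12).all()

    def test_zero_sum_sample_rejected(self):
        t = OtuTable(pd.DataFrame([[1, 1], [0, 0]], index=["a", "b"],
                                  columns=["x", "y"]))
        with pytest.raises(ValueError, match="zero"):
            bray_curtis(t)


class TestSpatialDistance:
    def _meta(self, rows):
        frame = pd.DataFrame(
            rows,
            columns=["longitude_deg", "latitude_deg", "elevation_m"],
            index=[f"s{i}" for i in range(len(rows))],
        )
        frame["stand_type"] = "S"
        frame["soil_layer"] = "topsoil"
        return SampleMetadata(frame)

    def test_identical_coordinates_zero(self):
        meta = self._meta([[117.0, 36.0, 500.0], [117.0, 36.0, 500.0]])
        assert spatial_distance(meta).data[0, 1] == 0.0

    def test_pure_elevation_difference(self):
        meta = self._meta([[117.0, 36.0, 500.0], [117.0, 36.0, 600.0]])
        assert spatial_distance(meta).data[0, 1] == pytest.approx(100.0)

    def test_longitude_projection_scale(self):
        meta = self._meta([[117.00, 36.43, 500.0], [117.01, 36.43, 500.0]])
        expect = 111_320 * math.cos(math.radians(36.43)) * 0.01
        assert spatial_distance(meta).data[0, 1] == pytest.approx(expect, rel=1e-6)

    def test_missing_coordinates_named(self):
        frame = pd.DataFrame({
            "stand_type": ["S", "S"], "soil_layer": ["topsoil"] * 2,
            "longitude_deg": [117.0, np.nan],
            "latitude_deg": [36.0, 36.0], "elevation_m": [1.0, 2.0],
        }, index=["ok", "bad"])
        with pytest.raises(ValueError, match="bad"):
            spatial_distance(SampleMetadata(frame))


class TestEnvironmentDistance:
    def _meta(self, **cols):
        n = len(next(iter(cols.values())))
        frame = pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])
        frame["stand_type"] = "S"
        frame["soil_layer"] = "topsoil"
        return SampleMetadata(frame)

    def test_identical_covariates_all_zero(self):
        meta = self._meta(soil_pH=[5.0, 5.0, 5.0], soil_P=[1.0, 1.0, 1.0])
        d = environment_distance(meta, "soil_vars")
        np.testing.assert_allclose(d.data, 0.0)

    def test_single_variable_standardized_spacing(self):
        meta = self._meta(soil_pH=[0.0, 1.0, 2.0])
        d = environment_distance(meta, "soil_vars")
        off = np.array([d.data[0, 1], d.data[0, 2], d.data[1, 2]])
        np.testing.assert_allclose(off / off[0], [1.0, 2.0, 1.0], atol=1e-12)

    def test_affine_rescaling_invariance(self):
        meta1 = self._meta(soil_pH=[4.2, 5.6, 4.9], soil_P=[0.5, 2.0, 1.1])
        meta2 = self._meta(soil_pH=[42.0, 56.0, 49.0],
                           soil_P=[500.0, 2000.0, 1100.0])
        d1 = environment_distance(meta1, "soil_vars")
        d2 = environment_distance(meta2, "soil_vars")
        np.testing.assert_allclose(d1.data, d2.data, atol=1e-9)

    def test_absent_group_skipped_with_warning(self, caplog):
        meta = self._meta(soil_pH=[5.0, 4.0])
        assert environment_distance(meta, "tree_importance") is None

    def test_importance_values_use_bray_curtis(self):
        meta = self._meta(tree_a=[1.0, 0.0], tree_b=[0.0, 1.0])
        d = environment_distance(meta, "tree_importance")
        assert d.data[0, 1] == pytest.approx(1.0)


class TestNmds:
    def test_unit_square_embeds_perfectly(self):
        d = dm([[0, 0], [1, 0], [1, 1], [0, 1]])
        res = nmds(d, k=2, seed=0)
        assert res.stress < 1e-3
        np.testing.assert_allclose(
            res.coordinates.mean(axis=0), 0.0, atol=1e-9
        )

    def test_equilateral_triangle_embeds_perfectly(self):
        d = dm([[0, 0], [1, 0], [0.5, math.sqrt(3) / 2]])
        assert nmds(d, k=2, seed=0).stress < 1e-3

    def test_embedding_preserves_distance_ranks(self, topsoil):
        sub, _, _ = topsoil
        d = bray_curtis(sub)
        res = nmds(d, k=2, seed=0)
        assert nmds_distance_correlation(d, res) > 0.9

    def test_full_rank_embedding_no_worse_than_planar(self):
        rng = np.random.default_rng(0)
        d = dm(rng.normal(size=(10, 6)))
        s2 = nmds(d, k=2, seed=1).stress
        s9 = nmds(d, k=9, seed=1).stress
        assert s9 <= s2 + 1e-9

    def test_k_must_be_less_than_n(self):
        d = dm([[0, 0], [1, 1], [2, 0]])
        with pytest.raises(ValueError):
            nmds(d, k=3)


class TestAnosim:
    def test_perfect_separation_r_is_one(self):
        pts = np.array([[0.0, 0], [0.1, 0], [0, 0.1], [5, 5], [5.1, 5], [5, 5.1]])
        res = anosim(dm(pts), ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_matches_skbio_statistic(self):
        rng = np.random.default_rng(5)
        d = dm(rng.normal(size=(14, 3)))
        groups = ["a"] * 5 + ["b"] * 5 + ["c"] * 4
        mine = anosim(d, groups, n_perm=99, seed=0)
        ref = sksd.anosim(sksd.DistanceMatrix(d.data, ids=list(d.ids)),
                          grouping=groups, permutations=0)
        assert mine.statistic == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_exact_enumeration_oracle_two_by_two(self):
        """4 samples, 2 groups of 2: only 3 distinct partitions exist; the
        permutation p must converge to the enumeration p."""
        pts = np.array([[0.0, 0], [0.2, 0], [3, 0], [3.3, 0]])
        d = dm(pts)
        labels = np.array(["a", "a", "b", "b"])
        res = anosim(d, labels, n_perm=4999, seed=0)

        # enumeration over all 3 distinct pairings
        from itertools import combinations

        ranks_stat = []
        items = [0, 1, 2, 3]
        for pair in combinations(items, 2):
            lab = np.array(["b"] * 4, dtype=object)
            lab[list(pair)] = "a"
            if pair[0] != 0:
                continue  # partitions are unordered; fix sample 0 in group a
            r = anosim(d, lab, n_perm=1, seed=0).statistic
            ranks_stat.append(r)
        observed = ranks_stat[0]
        exact_p = (1 + sum(s >= observed - 1e-12 for s in ranks_stat)) / (1 + len(ranks_stat))
        # label permutations hit each distinct partition equally often;
        # the permutation p estimates the same tail probability
        assert res.p_value == pytest.approx(
            sum(s >= observed - 1e-12 for s in ranks_stat) / len(ranks_stat),
            abs=0.05,
        )
        assert exact_p <= 0.5

    def test_r_bounded_and_near_zero_under_random_labels(self):
        rng = np.random.default_rng(8)
        d = dm(rng.normal(size=(16, 4)))
        stats_ = []
        for rep in range(50):
            labels = rng.permutation(["a"] * 8 + ["b"] * 8)
            stats_.append(anosim(d, labels, n_perm=1, seed=rep).statistic)
        stats_ = np.array(stats_)
        assert (np.abs(stats_) <= 1).all()
        assert abs(stats_.mean()) < 0.1

    def test_singleton_group_rejected(self):
        d = dm([[0, 0], [1, 0], [2, 0]])
        with pytest.raises(ValueError, match="singleton"):
            anosim(d, ["a", "a", "b"])


class TestMantel:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(2)
        d = dm(rng.normal(size=(8, 3)))
        res = mantel(d, d, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_constant_matrix_rejected_as_degenerate(self):
        d1 = dm(np.random.default_rng(0).normal(size=(5, 2)))
        const = DistanceMatrix(np.ones((5, 5)) - np.eye(5), ids=list(d1.ids))
        with pytest.raises(ValueError, match="degenerate"):
            mantel(d1, const)

    def test_matches_skbio_statistic(self):
        rng = np.random.default_rng(4)
        d1 = dm(rng.normal(size=(10, 3)))
        d2 = dm(rng.normal(size=(10, 3)), ids=list(d1.ids))
        mine = mantel(d1, d2, n_perm=99, seed=0)
        r, _, _ = sksd.mantel(
            sksd.DistanceMatrix(d1.data, ids=list(d1.ids)),
            sksd.DistanceMatrix(d2.data, ids=list(d2.ids)),
            permutations=0,
        )
        assert mine.statistic == pytest.approx(r, abs=1e-12)

    def test_invariant_to_joint_sample_reordering(self):
        rng = np.random.default_rng(6)
        pts1, pts2 = rng.normal(size=(9, 3)), rng.normal(size=(9, 3))
        ids = [f"s{i}" for i in range(9)]
        r0 = mantel(dm(pts1, ids), dm(pts2, ids), n_perm=9, seed=0).statistic
        perm = rng.permutation(9)
        ids_p = [ids[i] for i in perm]
        r1 = mantel(dm(pts1[perm], ids_p), dm(pts2[perm], ids_p),
                    n_perm=9, seed=0).statistic
        assert r0 == pytest.approx(r1, abs=1e-12)

    def test_mismatched_ids_rejected(self):
        d1 = dm([[0, 0], [1, 0], [2, 0]], ids=["a", "b", "c"])
        d2 = dm([[0, 0], [1, 0], [2, 0]], ids=["a", "c", "b"])
        with pytest.raises(ValueError, match="same sample ids"):
            mantel(d1, d2)


def test_pvalue_convention_never_zero():
    from nichegrad.compare import permutation_pvalue

    assert permutation_pvalue(10.0, np.zeros(999)) == pytest.approx(1 / 1000)
    assert permutation_pvalue(-10.0, np.zeros(999)) == 1.0
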