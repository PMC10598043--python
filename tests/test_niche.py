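import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nichegrad.model import OtuTable
from nichegrad.niche import (aggregate_states, classify_niche,
                             classify_niche_table, levins_breadth,
                             null_breadth_distribution, rarefy_to_min_depth)


def table_from(counts, sample_prefix="s", otu_prefix="o"):
    counts = np.atleast_2d(np.asarray(counts))
    return OtuTable(pd.DataFrame(
        counts,
        index=[f"{sample_prefix}{i}" for i in range(counts.shape[0])],
        columns=[f"{otu_prefix}{j}" for j in range(counts.shape[1])],
    ))


class TestLevinsBreadth:
    @pytest.mark.parametrize("p, expected", [
        ((0.25, 0.25, 0.25, 0.25), 4.0),
        ((1, 0, 0, 0), 1.0),
        ((0.5, 0.5, 0, 0), 2.0),
    ])
    def test_hand_values(self, p, expected):
        assert levins_breadth(p) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            levins_breadth([0, 0, 0])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 100), min_size=1, max_size=12))
    def test_bounds_and_permutation_invariance(self, counts):
        if sum(counts) == 0:
            counts[0] = 1
        b = levins_breadth(counts)
        r = len(counts)
        assert 1.0 - 1e-12 <= b <= r + 1e-12
        rng = np.random.default_rng(0)
        assert levins_breadth(rng.permutation(counts)) == pytest.approx(b)

    def test_equals_r_iff_uniform(self):
        assert levins_breadth([7, 7, 7]) == pytest.approx(3.0)
        assert levins_breadth([7, 7, 8]) < 3.0


class TestNullDistribution:
    def test_single_read_null_is_always_one(self):
        t = table_from([[1], [0], [0]])
        for method in ("replacement_multinomial", "quasiswap"):
            null = null_breadth_distribution(t, "o0", n_perm=50, method=method,
                                             seed=1)
            np.testing.assert_allclose(null, 1.0)

    def test_huge_total_concentrates_at_r(self):
        # single OTU, equal state depths: law-of-large-numbers limit B -> r
        t = table_from(np.full((20, 1), 50_000))
        null = null_breadth_distribution(t, "o0", n_perm=200, seed=2)
        assert np.all(np.abs(null - 20.0) < 0.01)

    def test_matches_independent_multinomial_oracle(self):
        counts = np.zeros((20, 2), dtype=int)
        counts[:, 0] = 10  # 200 reads over 20 equal-depth states
        counts[:, 1] = 490
        t = table_from(counts)
        null = null_breadth_distribution(t, "o0", n_perm=1000, seed=9)
        # oracle: same seed policy, independent arithmetic
        rng = np.random.default_rng(9)
        depths = counts.sum(axis=1)
        draws = rng.multinomial(200, depths / depths.sum(), size=1000)
        oracle = np.array([1.0 / ((row / 200) ** 2).sum() for row in draws])
        np.testing.assert_allclose(np.quantile(null, [0.05, 0.5, 0.95]),
                                   np.quantile(oracle, [0.05, 0.5, 0.95]),
                                   atol=1e-9)

    def test_unknown_method_rejected(self):
        t = table_from([[5], [5]])
        with pytest.raises(ValueError, match="method"):
            null_breadth_distribution(t, "o0", method="shuffle")

    def test_quasiswap_preserves_margins(self):
        rng = np.random.default_rng(3)
        t = table_from(rng.integers(0, 30, (5, 4)) + 1)
        from scipy import stats

        counts = t.counts.to_numpy().T
        rt = stats.random_table(counts.sum(axis=1), counts.sum(axis=0))
        tab = rt.rvs(random_state=rng)
        np.testing.assert_array_equal(tab.sum(axis=1), counts.sum(axis=1))
        np.testing.assert_array_equal(tab.sum(axis=0), counts.sum(axis=0))


class TestClassifyNiche:
    def test_above_every_null_value_is_generalized(self):
        assert classify_niche(5.0, np.linspace(1, 4, 100)) == "generalized"

    def test_tie_with_degenerate_null_is_neutral(self):
        assert classify_niche(2.0, np.full(100, 2.0)) == "neutral"

    def test_below_every_null_value_is_specialized(self):
        assert classify_niche(1.0, np.linspace(2, 4, 100)) == "specialized"

    def test_uniform_high_count_otu_with_equal_depths_is_generalized(self):
        """Constructed exactly-even profile exceeds the noisy null's q95."""
        n_states = 10
        counts = np.full((n_states, 2), 1000)
        t = table_from(counts)
        res = classify_niche_table(t, n_perm=500, seed=4)
        assert res.assignments.loc["o0", "B_obs"] == pytest.approx(n_states)
        assert res.assignments.loc["o0", "niche_class"] == "generalized"

    def test_concentrated_otu_is_specialized(self):
        counts = np.zeros((10, 2), dtype=int)
        counts[0, 0] = 1000
        counts[:, 1] = 500
        res = classify_niche_table(table_from(counts), n_perm=500, seed=4)
        assert res.assignments.loc["o0", "niche_class"] == "specialized"

    def test_table_classification_matches_per_otu_calls(self):
        """Whole-table batching agrees with the one-OTU entry point on
        decisively classified fixtures (labels independent of null noise)."""
        counts = np.zeros((8, 3), dtype=int)
        counts[:, 0] = 500          # exactly even -> generalized
        counts[0, 1] = 2000         # one state -> specialized
        counts[:, 2] = [1, 0, 0, 0, 2, 1, 0, 0]
        t = table_from(counts)
        res = classify_niche_table(t, n_perm=400, seed=5)
        for otu in ("o0", "o1"):
            obs = levins_breadth(t.counts[otu].to_numpy())
            null = null_breadth_distribution(t, otu, n_perm=400, seed=99)
            assert res.assignments.loc[otu, "niche_class"] == classify_niche(obs, null)

    def test_three_classes_partition_all_classified_otus(self, topsoil):
        sub, _, _ = topsoil
        res = classify_niche_table(sub, n_perm=100, seed=0)
        counts = res.niche_class.value_counts()
        assert counts.sum() == len(res.otu_ids)
        assert set(counts.index) <= {"generalized", "neutral", "specialized"}

    def test_planted_specialists_recovered(self, topsoil):
        sub, _, truth = topsoil
        res = classify_niche_table(sub, n_perm=300, seed=1)
        j = res.assignments.join(truth)
        spec = j[j["archetype"] == "specialist"]
        assert (spec["niche_class"] == "specialized").mean() >= 0.95


class TestAggregateStates:
    def test_sample_states_identity(self, tiny_table):
        out = aggregate_states(tiny_table, state_definition="sample")
        pd.testing.assert_frame_equal(out.counts, tiny_table.counts)

    def test_stand_type_aggregation_preserves_totals(self, topsoil):
        sub, meta, _ = topsoil
        out = aggregate_states(sub, meta, state_definition="stand_type")
        assert out.n_samples == 4
        np.testing.assert_array_equal(
            out.counts.sum(axis=0).to_numpy(),
            sub.counts.sum(axis=0).to_numpy(),
        )

    def test_missing_stand_label_rejected(self, tiny_table):
        from nichegrad.model import SampleMetadata

        meta = SampleMetadata(pd.DataFrame(
            {"stand_type": ["S"], "soil_layer": ["topsoil"]}, index=["s1"]
        ))
        with pytest.raises(ValueError, match="missing"):
            aggregate_states(tiny_table, meta, state_definition="stand_type")


def test_rarefaction_equalizes_depths(topsoil):
    sub, _, _ = topsoil
    rare = rarefy_to_min_depth(sub, seed=0)
    depths = rare.sample_depths()
    assert depths.nunique() == 1
    assert depths.iloc[0] == sub.sample_depths().min()
    assert (rare.counts.to_numpy() <= sub.counts.to_numpy()).all()
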