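"""Alpha-diversity estimators: worked values, skbio cross-checks, limits."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio.diversity import alpha as skalpha

from digesta.community_diversity import (
    chao1,
    coverage_percent,
    diversity_indices,
    pool_replicates,
    rarefaction_curve,
    shannon,
    simpson,
    subsample,
    subsample_table,
    summarize_table,
)
from digesta.synthetic_data import CommunitySimSpec, simulate_otu_table

count_vectors = st.lists(st.integers(0, 50), min_size=2, max_size=30).filter(
    lambda v: sum(v) > 0
)


class TestChao1:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([5, 3, 1, 1, 2], 5.5),  # F1=2, F2=1
            ([1, 1], 3.0),  # F2=0 handled by the +1 correction
            ([5, 3, 2], 3.0),  # no singletons: Chao1 == S_obs
        ],
    )
    def test_worked_examples(self, counts, expected):
        assert chao1(counts) == pytest.approx(expected)

    @settings(deadline=None, max_examples=80)
    @given(counts=count_vectors)
    def test_at_least_richness_and_matches_skbio(self, counts):
        arr = np.array(counts)
        got = chao1(arr)
        assert got >= np.count_nonzero(arr)
        assert got == pytest.approx(skalpha.chao1(arr, bias_corrected=True))

    def test_classic_variant(self):
        # S_obs=5, F1=2, F2=2: classic form S + F1^2/(2 F2)
        assert chao1([1, 1, 2, 2, 5], bias_corrected=False) == pytest.approx(6.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            chao1([])


class TestShannonSimpson:
    @pytest.mark.parametrize(
        "counts,h,d",
        [
            ([1, 1, 1, 1], 2.0, 0.75),
            ([1, 1, 2], 1.5, 0.625),
            ([7], 0.0, 0.0),
        ],
    )
    def test_worked_examples(self, counts, h, d):
        assert shannon(counts) == pytest.approx(h)
        assert simpson(counts) == pytest.approx(d)

    @settings(deadline=None, max_examples=80)
    @given(counts=count_vectors)
    def test_permutation_invariant_and_matches_skbio(self, counts):
        arr = np.array(counts)
        perm = np.random.default_rng(0).permutation(arr)
        assert shannon(arr) == pytest.approx(shannon(perm))
        assert simpson(arr) == pytest.approx(simpson(perm))
        nz = arr[arr > 0]
        assert shannon(arr) == pytest.approx(skalpha.shannon(nz, base=2))
        assert simpson(arr) == pytest.approx(skalpha.simpson(nz))

    @settings(deadline=None, max_examples=60)
    @given(counts=count_vectors)
    def test_uniform_distribution_maximises_both(self, counts):
        arr = np.array(counts)
        k = len(arr)
        uniform = np.ones(k, dtype=int)
        assert shannon(arr) <= shannon(uniform) + 1e-9
        assert simpson(arr) <= simpson(uniform) + 1e-9

    def test_natural_log_flag(self):
        assert shannon([1, 1], base=math.e) == pytest.approx(math.log(2))


class TestCoverage:
    @pytest.mark.parametrize(
        "s_obs,chao,expected", [(52, 58, 89.7), (135, 209, 64.6), (100, 100, 100.0)]
    )
    def test_worked_examples(self, s_obs, chao, expected):
        assert coverage_percent(s_obs, chao) == expected

    def test_rejects_inverted_inputs(self):
        with pytest.raises(ValueError):
            coverage_percent(10, 5)


class TestSubsample:
    def test_total_conserved(self):
        counts = np.random.default_rng(0).integers(0, 100, 40)
        counts[0] += 3000
        out = subsample(counts, 2500, seed=1)
        assert out.sum() == 2500
        assert np.all(out <= counts)

    def test_depth_equal_total_returns_input(self):
        counts = np.array([5, 3, 2])
        assert np.array_equal(subsample(counts, 10, seed=0), counts)

    def test_single_otu(self):
        assert np.array_equal(subsample([4000], 2500, seed=0), [2500])

    def test_insufficient_reads_rejected_with_label(self):
        with pytest.raises(ValueError, match="CD99"):
            subsample([10, 10], 2500, label="CD99")

    def test_expected_counts_proportional(self):
        """Exchangeability: mean per-OTU count approaches depth * p_i."""
        counts = np.array([600, 300, 100])
        rng = np.random.default_rng(42)
        draws = np.array([subsample(counts, 100, rng) for _ in range(1000)])
        expected = 100 * counts / counts.sum()
        # hypergeometric sd per OTU < 5; 3 sigma of the mean over 1000 draws
        assert np.all(np.abs(draws.mean(axis=0) - expected) < 3 * 5 / np.sqrt(1000) + 0.2)


class TestPoolingAndTables:
    def test_pooling_is_elementwise_sum(self):
        assert np.array_equal(pool_replicates([[1, 2], [3, 4], [0, 1]]), [4, 7])

    def test_summarize_table_shape_and_columns(self):
        res = simulate_otu_table(CommunitySimSpec(n_samples=3, richness=50, depth=3000, seed=8))
        out = summarize_table(res.counts, depth=2500, seed=0)
        assert list(out.columns) == ["s_obs", "chao1", "shannon", "simpson", "coverage_percent"]
        assert len(out) == 3
        assert (out["chao1"] >= out["s_obs"]).all()

    def test_subsample_table_columns_sum_to_depth(self):
        res = simulate_otu_table(CommunitySimSpec(n_samples=4, depth=3000, seed=3))
        rarefied = subsample_table(res.counts, 2500, seed=1)
        assert (rarefied.sum(axis=0) == 2500).all()


class TestRarefaction:
    def test_depth_one_gives_one_otu(self):
        curve = rarefaction_curve([10, 10, 10], [1], reps=20, seed=0)
        assert curve["mean_richness"].iloc[0] == 1.0

    def test_full_depth_gives_s_obs(self):
        counts = [10, 5, 0, 3]
        curve = rarefaction_curve(counts, [18], reps=5, seed=0)
        assert curve["mean_richness"].iloc[0] == 3.0

    def test_means_non_decreasing_in_depth(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 200, 80)
        curve = rarefaction_curve(counts, [10, 50, 200, 1000, int(counts.sum())], reps=20, seed=2)
        assert np.all(np.diff(curve["mean_richness"]) >= -0.5)  # Monte-Carlo slack

    def test_uniform_community_approaches_richness(self):
        curve = rarefaction_curve([100] * 20, [1500], reps=10, seed=0)
        assert curve["mean_richness"].iloc[0] > 19.5

    def test_zero_reps_rejected(self):
        with pytest.raises(ValueError):
            rarefaction_curve([5, 5], [5], reps=0)


class TestPlugInConvergence:
    def test_even_community_indices_at_survey_depth(self):
        """sigma = 0: plug-in Shannon -> log2 K, Simpson -> 1 - 1/K."""
        k = 16
        spec = CommunitySimSpec(n_samples=5, richness=k, lognormal_sigma=0.0, depth=2500, seed=6)
        res = simulate_otu_table(spec)
        for col in res.counts:
            assert shannon(res.counts[col]) == pytest.approx(math.log2(k), abs=0.02)
            assert simpson(res.counts[col]) == pytest.approx(1 - 1 / k, abs=0.005)

    def test_panel_consistency(self):
        d = diversity_indices([5, 3, 1, 1, 2])
        assert d.s_obs == 5
        assert d.chao1 == 5.5
        assert d.coverage_percent == coverage_percent(5, 5.5)
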