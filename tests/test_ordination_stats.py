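"""UniFrac, PCoA, CCA and the permutation test against independent oracles."""

import io
import itertools
import shutil
import subprocess
import textwrap
from math import comb

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode
from skbio.diversity.beta import unweighted_unifrac, weighted_unifrac
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as skbio_pcoa

from digesta.ordination_stats import (
    cca,
    major_feature_filter,
    pcoa,
    permutation_group_test,
    unifrac,
    unifrac_matrix,
)

STAR = "(T1:1,T2:1,T3:1,T4:1);"


class TestUnifrac:
    def test_identical_communities_distance_zero(self):
        c = {"T1": 3, "T2": 5}
        assert unifrac(STAR, c, c) == 0.0
        assert unifrac(STAR, c, c, weighted=True) == 0.0

    def test_disjoint_star_communities_distance_one(self):
        assert unifrac(STAR, {"T1": 1, "T2": 1}, {"T3": 1, "T4": 1}) == 1.0
        assert unifrac(STAR, {"T1": 1, "T2": 1}, {"T3": 1, "T4": 1}, weighted=True) == 1.0

    def test_partially_shared_star_two_thirds(self):
        # unique branches T1 and T3 over observed branches T1, T2, T3
        got = unifrac(STAR, {"T1": 1, "T2": 1}, {"T2": 1, "T3": 1})
        assert got == pytest.approx(2 / 3)

    def test_missing_taxon_rejected_with_id(self):
        with pytest.raises(ValueError, match="T9"):
            unifrac(STAR, {"T1": 1, "T9": 1}, {"T2": 1})

    def test_agrees_with_skbio_on_random_trees(self, random_rooted_newick):
        rng = np.random.default_rng(17)
        names = [f"T{k}" for k in range(8)]
        for _ in range(15):
            nwk = random_rooted_newick(names, rng)
            ca = rng.integers(0, 20, 8)
            cb = rng.integers(0, 20, 8)
            if ca.sum() == 0 or cb.sum() == 0:
                continue
            a, b = dict(zip(names, ca)), dict(zip(names, cb))
            sk_u = unweighted_unifrac(ca, cb, taxa=names, tree=TreeNode.read(io.StringIO(nwk)))
            sk_w = weighted_unifrac(
                ca, cb, taxa=names, tree=TreeNode.read(io.StringIO(nwk)), normalized=True
            )
            assert unifrac(nwk, a, b) == pytest.approx(sk_u, abs=1e-10)
            assert unifrac(nwk, a, b, weighted=True) == pytest.approx(sk_w, abs=1e-10)

    def test_unweighted_is_a_metric_on_random_instances(self, random_rooted_newick):
        rng = np.random.default_rng(23)
        names = [f"T{k}" for k in range(6)]
        nwk = random_rooted_newick(names, rng)
        comms = [dict(zip(names, rng.integers(0, 5, 6) + (rng.random(6) < 0.5))) for _ in range(5)]
        comms = [c for c in comms if sum(c.values()) > 0]
        d = {}
        for i, j in itertools.combinations(range(len(comms)), 2):
            d[i, j] = d[j, i] = unifrac(nwk, comms[i], comms[j])
        for i, j, k in itertools.permutations(range(len(comms)), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_matrix_shape_and_symmetry(self):
        table = pd.DataFrame(
            {"s1": [1, 1, 0, 0], "s2": [0, 1, 1, 0], "s3": [0, 0, 1, 1]},
            index=["T1", "T2", "T3", "T4"],
        )
        m = unifrac_matrix(STAR, table)
        assert np.allclose(m, m.T) and np.allclose(np.diag(m), 0)
        assert m.loc["s1", "s2"] == pytest.approx(2 / 3)


class TestPcoa:
    def test_two_samples_closed_form(self):
        res = pcoa(np.array([[0.0, 3.0], [3.0, 0.0]]))
        assert sorted(res.coordinates["PC1"]) == pytest.approx([-1.5, 1.5])
        assert res.eigenvalues[0] == pytest.approx(4.5)  # d^2 / 2

    def test_all_zero_distances(self):
        res = pcoa(np.zeros((4, 4)))
        assert np.allclose(res.eigenvalues, 0.0)
        assert res.coordinates.shape[1] == 0

    def test_isometry_on_planar_points(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(7, 2))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = pcoa(d)
        emb = res.coordinates.to_numpy()
        d_emb = np.sqrt(((emb[:, None, :] - emb[None, :, :]) ** 2).sum(-1))
        assert np.allclose(d_emb, d, atol=1e-9)

    def test_eigenvalues_match_skbio(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        sk = skbio_pcoa(DistanceMatrix(d, ids=[f"s{i}" for i in range(6)]))
        ours = pcoa(d)
        assert np.allclose(sorted(ours.eigenvalues[:5])[::-1], sorted(sk.eigvals[:5])[::-1], atol=1e-9)

    def test_asymmetric_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            pcoa(d)


class TestCca:
    def test_two_by_two_closed_form(self):
        y = pd.DataFrame([[10, 0], [0, 10]], index=["s1", "s2"], columns=["f1", "f2"])
        x = pd.DataFrame({"grp": [0.0, 1.0]}, index=y.index)
        res = cca(y, x)
        assert res.total_inertia == pytest.approx(1.0)
        assert len(res.eigenvalues) == 1
        assert res.eigenvalues[0] == pytest.approx(1.0)
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_full_rank_constraints_explain_everything(self):
        rng = np.random.default_rng(4)
        y = pd.DataFrame(rng.integers(1, 20, (5, 4)).astype(float))
        x = pd.DataFrame(np.eye(5)[:, :4])  # one-hot identities span all contrasts
        res = cca(y, x)
        assert res.constrained_inertia == pytest.approx(res.total_inertia, rel=1e-9)
        assert res.residual_eigenvalues.size == 0

    def test_constraint_orthogonal_to_variation_explains_nothing(self):
        # two pairs of identical community rows: a constraint that only
        # separates within pairs carries no community signal
        y = pd.DataFrame(
            [[5, 1, 2], [5, 1, 2], [1, 6, 3], [1, 6, 3]], columns=["f1", "f2", "f3"]
        )
        x = pd.DataFrame({"within": [0.0, 1.0, 0.0, 1.0]})
        res = cca(y, x)
        assert res.constrained_inertia == pytest.approx(0.0, abs=1e-12)

    def test_eigenvalues_bounded_and_ordered(self):
        rng = np.random.default_rng(5)
        y = pd.DataFrame(rng.integers(0, 30, (8, 6)).astype(float) + 1)
        x = pd.DataFrame(rng.normal(size=(8, 3)))
        res = cca(y, x)
        assert np.all(res.eigenvalues >= 0) and np.all(res.eigenvalues <= 1)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert res.constrained_inertia <= res.total_inertia + 1e-12

    def test_constant_constraint_rejected(self):
        y = pd.DataFrame([[1, 2], [3, 4]], dtype=float)
        with pytest.raises(ValueError):
            cca(y, pd.DataFrame({"c": [1.0, 1.0]}))

    def test_collinear_constraints_rejected(self):
        y = pd.DataFrame(np.arange(1, 13, dtype=float).reshape(4, 3))
        x = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(ValueError):
            cca(y, x)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
    def test_matches_vegan(self, tmp_path):
        """Dual route: the ter Braak algorithm vs the vegan package in R."""
        rng = np.random.default_rng(7)
        y = pd.DataFrame(
            rng.integers(1, 30, size=(6, 5)).astype(float),
            index=[f"s{i}" for i in range(6)],
            columns=[f"f{j}" for j in range(5)],
        )
        x = pd.DataFrame({"x1": rng.normal(size=6), "x2": rng.normal(size=6)}, index=y.index)
        y.to_csv(tmp_path / "Y.tsv", sep="\t")
        x.to_csv(tmp_path / "X.tsv", sep="\t")
        script = textwrap.dedent(
            """
            suppressMessages(library(vegan))
            Y <- read.table("Y.tsv", header=TRUE, row.names=1, sep="\\t")
            X <- read.table("X.tsv", header=TRUE, row.names=1, sep="\\t")
            m <- cca(Y ~ x1 + x2, data=X)
            cat(m$tot.chi, m$CCA$eig, m$CA$eig, sep="\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], cwd=tmp_path, capture_output=True, text=True, check=True
        )
        vals = [float(v) for v in out.stdout.split()]
        res = cca(y, x)
        ours = [res.total_inertia, *res.eigenvalues, *res.residual_eigenvalues]
        assert np.allclose(ours, vals, atol=1e-6)


class TestMajorFeatureFilter:
    def test_inclusive_threshold(self):
        y = pd.DataFrame({"a": [20.0], "b": [19.0], "c": [961.0]})
        kept = major_feature_filter(y, 0.02)
        assert list(kept.columns) == ["a", "c"]  # 2.0 % kept, 1.9 % dropped

    def test_nothing_retained_rejected(self):
        y = pd.DataFrame(np.ones((1, 100)))
        with pytest.raises(ValueError):
            major_feature_filter(y, 0.5)

    def test_threshold_bounds(self):
        y = pd.DataFrame({"a": [1.0]})
        for bad in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                major_feature_filter(y, bad)


class TestPermutationGroupTest:
    def test_identical_groups_large_p(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        res = permutation_group_test(vals, vals, 999, seed=0)
        assert res.p_value >= 0.5

    def test_add_one_floor_at_999(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 10)
        b = rng.normal(50, 1, 10)
        res = permutation_group_test(a, b, 999, seed=2)
        assert res.p_value == pytest.approx(0.001)

    def test_small_separated_groups_tie_probability(self):
        """{0,0,0} vs {10,10,10}: only relabellings reproducing the exact
        split tie the observed statistic; their chance is 2/C(6,3)."""
        res = permutation_group_test([0.0, 0.0, 0.0], [10.0, 10.0, 10.0], 999, seed=3)
        tie_prob = 2 / comb(6, 3)
        se = np.sqrt(tie_prob * (1 - tie_prob) / 999)
        assert res.p_value == pytest.approx(tie_prob, abs=5 * se + 2 / 1000)

    def test_degenerate_equal_constant_groups(self):
        res = permutation_group_test([5.0, 5.0], [5.0, 5.0], 99, seed=0)
        assert res.degenerate and res.p_value == 1.0

    def test_seeded_reproducibility(self):
        a, b = [1.0, 2.0, 5.0], [2.0, 4.0, 9.0]
        r1 = permutation_group_test(a, b, 499, seed=7)
        r2 = permutation_group_test(a, b, 499, seed=7)
        assert r1 == r2

    def test_null_p_values_superuniform(self):
        """Under exchangeability P(p <= 0.05) must not exceed 0.05
        (binomial tolerance over simulated null datasets)."""
        rng = np.random.default_rng(11)
        hits = 0
        n_sets = 400
        for _ in range(n_sets):
            a = rng.normal(0, 1, 6)
            b = rng.normal(0, 1, 6)
            if permutation_group_test(a, b, 199, rng).p_value <= 0.05:
                hits += 1
        bound = 0.05 * n_sets + 4 * np.sqrt(n_sets * 0.05 * 0.95)
        assert hits <= bound
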