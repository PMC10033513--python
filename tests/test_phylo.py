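"""Comparative statistics: ancestral-state oracles, pGLS/OLS equivalences,
permutation tests, phylogenetic PCA and Spearman correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.optimize import minimize

from hullcom.phylo import (
    PhyloError,
    Phylogeny,
    allometry_classify,
    ancestral_states_bm,
    pgls,
    phylo_anova,
    phylo_pca,
    phylomorphospace,
    read_newick,
    spearman,
)
from hullcom.simulate import simulate_traits, simulate_tree

STAR4 = "(A:1.0,B:1.0,C:1.0,D:1.0);"


# ---------------------------------------------------------------------------
# Newick round-trips
# ---------------------------------------------------------------------------


class TestNewick:
    def test_cherry(self):
        t = read_newick("(A:1,B:1);")
        assert t.n_tips == 2
        assert t.is_ultrametric()
        assert t.depth[t.tip_indices].max() == pytest.approx(1.0)

    def test_nested_ultrametric(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        assert t.is_ultrametric()
        assert t.n_internal == 2

    def test_roundtrip_50_tips(self):
        t = simulate_tree(50, seed=9)
        t2 = read_newick(t.to_newick())
        assert t2.tip_labels == t.tip_labels
        C1 = t.vcv().to_numpy()
        C2 = t2.vcv(t.tip_labels).to_numpy()
        assert np.allclose(C1, C2, atol=1e-8)

    def test_parse_error(self):
        with pytest.raises(PhyloError):
            read_newick("((A:1,B:1;")

    def test_vcv_shared_path_lengths(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        C = t.vcv(["A", "B", "C"]).to_numpy()
        assert C[0, 0] == pytest.approx(2.0)
        assert C[0, 1] == pytest.approx(1.0)   # A,B share the basal branch
        assert C[0, 2] == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# Ancestral states
# ---------------------------------------------------------------------------


class TestAncestralStates:
    def test_star_tree_root_is_mean(self):
        t = read_newick("(A:1,B:1,C:1);")
        a = ancestral_states_bm(t, pd.Series({"A": 1.0, "B": 2.0, "C": 3.0}))
        assert a["estimate"].iloc[0] == pytest.approx(2.0, abs=1e-10)

    def test_two_taxon_inverse_branch_length_weighting(self):
        t = read_newick("(A:1,B:3);")
        a = ancestral_states_bm(t, pd.Series({"A": 0.0, "B": 4.0}))
        # root = (x1/t1 + x2/t2) / (1/t1 + 1/t2) = (0 + 4/3)/(1 + 1/3) = 1
        assert a["estimate"].iloc[0] == pytest.approx(1.0, abs=1e-10)

    def test_equal_tips_give_constant_reconstruction(self):
        t = simulate_tree(8, seed=2)
        a = ancestral_states_bm(t, pd.Series(5.0, index=t.tip_labels))
        assert np.allclose(a["estimate"], 5.0, atol=1e-9)
        assert np.allclose(a["variance"], 0.0, atol=1e-12)

    def test_root_within_tip_range(self):
        t = simulate_tree(12, seed=5)
        x = simulate_traits(t, {"z": 1.0}, seed=3)["z"]
        a = ancestral_states_bm(t, x)
        root = a["estimate"].loc["nd0"]
        assert x.min() - 1e-9 <= root <= x.max() + 1e-9

    def test_ci_is_estimate_plus_minus_196_sd(self):
        t = simulate_tree(10, seed=1)
        x = simulate_traits(t, {"z": 1.0}, seed=1)["z"]
        a = ancestral_states_bm(t, x)
        assert np.allclose(
            a["ci_high"], a["estimate"] + 1.96 * np.sqrt(a["variance"]), atol=1e-12
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_likelihood_maximisation(self, seed):
        """Node estimates equal the minimiser of the BM deviance over all
        internal states on 5-taxon trees (numerical-optimisation oracle)."""
        tree = simulate_tree(5, seed=seed)
        x = simulate_traits(tree, {"z": 1.0}, seed=seed + 10)["z"]
        est = ancestral_states_bm(tree, x)["estimate"]

        tip_vals = {lab: x[lab] for lab in tree.tip_labels}
        internal = list(tree.internal_indices)
        pos = {node: i for i, node in enumerate(internal)}

        def deviance(theta):
            def val(i):
                if tree.is_tip[i]:
                    return tip_vals[tree.node_ids[i]]
                return theta[pos[i]]

            ss = 0.0
            for i in range(1, len(tree.node_ids)):
                p = tree.parent[i]
                ss += (val(i) - val(p)) ** 2 / tree.edge_length[i]
            return ss

        res = minimize(deviance, np.full(len(internal), x.mean()), method="BFGS",
                       options={"gtol": 1e-12})
        brute = {tree.node_ids[node]: res.x[pos[node]] for node in internal}
        for node_id, val in brute.items():
            assert est[node_id] == pytest.approx(val, abs=1e-4)


# ---------------------------------------------------------------------------
# pGLS
# ---------------------------------------------------------------------------


class TestPGLS:
    def test_star_tree_equals_ols(self):
        rng = np.random.default_rng(0)
        labels = list("ABCDEFGHIJ")
        t = read_newick("(" + ",".join(f"{l}:1" for l in labels) + ");")
        x = pd.Series(rng.normal(size=10), index=labels, name="x")
        y = pd.Series(2.0 + 0.5 * x + rng.normal(scale=0.1, size=10), index=labels)
        fit = pgls(y, x, t)
        X = np.column_stack([np.ones(10), x.to_numpy()])
        beta, res_ss, *_ = np.linalg.lstsq(X, y.to_numpy(), rcond=None)
        resid = y.to_numpy() - X @ beta
        s2 = resid @ resid / (10 - 2)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        assert np.allclose(fit.coef.to_numpy(), beta, atol=1e-8)
        assert np.allclose(fit.se.to_numpy(), se, atol=1e-8)

    def test_aicc_formula(self):
        t = simulate_tree(20, seed=3)
        y = simulate_traits(t, {"z": 1.0}, seed=4)["z"]
        fit = pgls(y, pd.DataFrame(index=t.tip_labels), t)
        n, k = fit.n, fit.k
        assert k == 2  # intercept + BM rate
        expected = -2 * fit.loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert fit.aicc == pytest.approx(expected, rel=1e-12)
        # frozen arithmetic case: logLik=-10, k=2, n=20 -> 20 + 4 + 12/17
        assert 20 + 4 + 12 / 17 == pytest.approx(24.70588, abs=1e-4)

    def test_rank_deficient_design_named(self):
        t = simulate_tree(10, seed=0)
        x = pd.Series(np.arange(10.0), index=t.tip_labels, name="x")
        X = pd.DataFrame({"x": x, "x2": 2 * x})
        y = simulate_traits(t, {"z": 1.0}, seed=1)["z"]
        with pytest.raises(PhyloError, match="x2"):
            pgls(y, X, t)

    def test_lambda_zero_matches_star_gls(self):
        """With lambda -> 0 the correlation collapses to a diagonal, so a
        clearly non-phylogenetic signal should push lambda low and the
        coefficients toward OLS weighted by tip depths."""
        t = simulate_tree(25, seed=8)
        rng = np.random.default_rng(5)
        x = pd.Series(rng.normal(size=25), index=t.tip_labels, name="x")
        y = pd.Series(1.0 + 0.8 * x.to_numpy() + rng.normal(scale=0.05, size=25),
                      index=t.tip_labels)
        fit = pgls(y, x, t, correlation="lambda")
        assert fit.lam < 0.3
        assert fit.coef["x"] == pytest.approx(0.8, abs=0.05)

    def test_bm_rate_recovery(self):
        """sigma^2 estimated from intercept-only pGLS residuals on data
        simulated with sigma^2 = 1 is unbiased within Monte-Carlo error."""
        t = simulate_tree(20, seed=13)
        vals = []
        for rep in range(200):
            y = simulate_traits(t, {"z": 1.0}, seed=1000 + rep)["z"]
            fit = pgls(y, pd.DataFrame(index=t.tip_labels), t)
            vals.append(fit.sigma2 * fit.n / (fit.n - 1))  # small-n bias undone
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 1.0) <= 3 * se


@pytest.mark.parametrize(
    "ci,expected",
    [((0.20, 0.30), "negative"), ((0.30, 0.36), "isometric"),
     ((0.35, 0.40), "positive")],
)
def test_allometry_classification(ci, expected):
    fit = pgls.__new__(pgls.__class__) if False else None
    from hullcom.phylo import PGLSFit

    lo, hi = ci
    mid = 0.5 * (lo + hi)
    fake = PGLSFit(
        coef=pd.Series({"intercept": 0.0, "slope": mid}),
        se=pd.Series({"intercept": 0.0, "slope": 1.0}),
        ci_low=pd.Series({"intercept": 0.0, "slope": lo}),
        ci_high=pd.Series({"intercept": 0.0, "slope": hi}),
        sigma2=1.0, loglik=0.0, aicc=0.0, n=10, k=3, correlation="BM",
    )
    assert allometry_classify(fake, 1 / 3)["classification"] == expected


# ---------------------------------------------------------------------------
# Permutation ANOVA
# ---------------------------------------------------------------------------


class TestPhyloAnova:
    def make_star(self, n):
        labels = [f"t{i}" for i in range(n)]
        return labels, read_newick("(" + ",".join(f"{l}:1" for l in labels) + ");")

    def test_constant_trait_gives_p_one(self):
        labels, t = self.make_star(10)
        trait = pd.Series(3.0, index=labels)
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=labels)
        res = phylo_anova(trait, groups, t, n_perm=99, seed=1)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_extreme_separation_attains_minimum_p(self):
        labels, t = self.make_star(12)
        rng = np.random.default_rng(0)
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=labels)
        trait = pd.Series(
            (groups == "b").to_numpy() * 100.0 + rng.normal(scale=1e-6, size=12),
            index=labels,
        )
        res = phylo_anova(trait, groups, t, n_perm=199, seed=2)
        assert res.p_value == pytest.approx(1.0 / 200.0)

    def test_star_tree_matches_plain_permutation_anova(self):
        """On a star tree the procedure reduces to an ordinary residual-
        permutation ANOVA; check F and p against an inline re-derivation
        using the identical permutation stream."""
        labels, t = self.make_star(14)
        rng = np.random.default_rng(7)
        y = pd.Series(rng.normal(size=14), index=labels)
        groups = pd.Series(["a"] * 7 + ["b"] * 7, index=labels)
        n_perm, seed = 199, 11
        res = phylo_anova(y, groups, t, n_perm=n_perm, seed=seed)

        yv = y.to_numpy()
        g = (groups == "b").to_numpy(dtype=float)
        n = len(yv)

        def f_of(v):
            rss_r = np.sum((v - v.mean()) ** 2)
            fit = np.column_stack([np.ones(n), g])
            beta, *_ = np.linalg.lstsq(fit, v, rcond=None)
            rss_f = np.sum((v - fit @ beta) ** 2)
            return ((rss_r - rss_f) / 1) / (rss_f / (n - 2))

        F = f_of(yv)
        assert res.statistic == pytest.approx(F, abs=1e-8)
        rng2 = np.random.default_rng(seed)
        resid = yv - yv.mean()
        perms = np.argsort(rng2.random((n_perm, n)), axis=1)
        count = sum(
            1 for p in perms if f_of(yv.mean() + resid[p]) >= F - 1e-12 * max(F, 1)
        )
        assert res.p_value == pytest.approx((1 + count) / (1 + n_perm))

    def test_affine_invariance(self):
        t = simulate_tree(16, seed=4)
        y = simulate_traits(t, {"z": 1.0}, seed=5)["z"]
        groups = pd.Series(
            ["a", "b"] * 8, index=t.tip_labels
        )
        r1 = phylo_anova(y, groups, t, n_perm=199, seed=3)
        r2 = phylo_anova(7.5 * y - 1000.0, groups, t, n_perm=199, seed=3)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-9)

    def test_seed_reproducibility(self):
        t = simulate_tree(10, seed=6)
        y = simulate_traits(t, {"z": 1.0}, seed=7)["z"]
        groups = pd.Series(["a", "b"] * 5, index=t.tip_labels)
        a = phylo_anova(y, groups, t, n_perm=199, seed=42)
        b = phylo_anova(y, groups, t, n_perm=199, seed=42)
        assert a.p_value == b.p_value and a.statistic == b.statistic

    def test_ancova_slopes_null_when_slopes_equal(self):
        """Groups sharing a common slope but different intercepts should
        not trigger the slopes (interaction) test."""
        labels, t = self.make_star(20)
        groups = pd.Series(["a"] * 10 + ["b"] * 10, index=labels)
        rejections = 0
        for rep in range(20):
            rng = np.random.default_rng(900 + rep)
            x = pd.Series(rng.normal(size=20), index=labels)
            y = 2.0 * x + (groups == "b") * 5.0 + pd.Series(
                rng.normal(scale=0.5, size=20), index=labels
            )
            res = phylo_anova(y, groups, t, covariate=x, test="slopes",
                             n_perm=199, seed=rep)
            rejections += res.p_value <= 0.05
        # slopes are equal by construction: rejections stay near the 5% rate
        assert rejections <= 4

    def test_group_missing_from_tree_matched_data_errors(self):
        labels, t = self.make_star(6)
        y = pd.Series(np.arange(6.0), index=labels)
        groups = pd.Series(["a"] * 5 + ["b"], index=labels)
        with pytest.raises(PhyloError, match="< 2 taxa"):
            phylo_anova(y, groups, t, n_perm=99, seed=0)


# ---------------------------------------------------------------------------
# Phylogenetic PCA
# ---------------------------------------------------------------------------


class TestPhyloPCA:
    def test_single_trait_scores_are_centred_values(self):
        t = simulate_tree(10, seed=2)
        x = simulate_traits(t, {"z": 1.0}, seed=2)
        res = phylo_pca(x, t)
        assert len(res.eigenvalues) == 1
        assert res.percent_variance[0] == pytest.approx(100.0)
        centred = x["z"] - res.phylo_mean["z"]
        assert np.allclose(np.abs(res.scores["PC1"]), np.abs(centred), atol=1e-9)

    def test_eigenvalue_sum_equals_trace(self):
        t = simulate_tree(15, seed=3)
        X = simulate_traits(t, {"a": 1.0, "b": 0.5, "c": 2.0}, seed=4)
        res = phylo_pca(X, t)
        labels = list(X.index)
        C = t.vcv(labels).to_numpy()
        Xc = X.to_numpy() - res.phylo_mean.to_numpy()
        R = Xc.T @ np.linalg.solve(C, Xc) / (len(labels) - 1)
        assert res.eigenvalues.sum() == pytest.approx(np.trace(R), rel=1e-9)
        assert res.percent_variance.sum() == pytest.approx(100.0)

    def test_loadings_orthonormal(self):
        t = simulate_tree(12, seed=5)
        X = simulate_traits(t, {"a": 1.0, "b": 1.0}, seed=6)
        V = phylo_pca(X, t).loadings.to_numpy()
        assert np.allclose(V.T @ V, np.eye(2), atol=1e-9)

    def test_star_tree_equals_ordinary_pca(self):
        labels = [f"s{i}" for i in range(12)]
        t = read_newick("(" + ",".join(f"{l}:1" for l in labels) + ");")
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(12, 3)), index=labels,
                         columns=["a", "b", "c"])
        res = phylo_pca(X, t)
        Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / 11)
        order = np.argsort(evals)[::-1]
        assert np.allclose(res.eigenvalues, evals[order], atol=1e-8)
        for j in range(3):
            v = evecs[:, order[j]]
            w = res.loadings.to_numpy()[:, j]
            assert np.allclose(np.abs(v), np.abs(w), atol=1e-8)

    def test_equal_rate_independent_traits_have_similar_eigenvalues(self):
        t = simulate_tree(25, seed=7)
        ratios = []
        for rep in range(60):
            X = simulate_traits(t, {"a": 1.0, "b": 1.0}, seed=300 + rep)
            ev = phylo_pca(X, t).eigenvalues
            ratios.append(ev[0] / ev.sum())
        # two independent equal-rate traits: no preferred axis, so the
        # leading eigenvalue share stays near its sampling expectation
        assert 0.5 < np.mean(ratios) < 0.9

    def test_node_projection_shape(self):
        t = simulate_tree(8, seed=8)
        X = simulate_traits(t, {"a": 1.0, "b": 1.0}, seed=9)
        res = phylo_pca(X, t, project_nodes=True)
        assert res.node_scores.shape == (t.n_internal, 2)


# ---------------------------------------------------------------------------
# Phylomorphospace
# ---------------------------------------------------------------------------


class TestPhylomorphospace:
    def test_two_taxa_equal_branches_node_at_midpoint(self):
        t = read_newick("(A:1,B:1);")
        X = pd.DataFrame({"u": [0.0, 2.0], "v": [1.0, 3.0]}, index=["A", "B"])
        pm = phylomorphospace(t, X, "u", "v")
        assert pm["nodes"]["x"].iloc[0] == pytest.approx(1.0)
        assert pm["nodes"]["y"].iloc[0] == pytest.approx(2.0)

    def test_star_root_at_centroid(self):
        labels = list("ABCD")
        t = read_newick("(" + ",".join(f"{l}:1" for l in labels) + ");")
        X = pd.DataFrame(
            {"u": [0, 1, 2, 9.0], "v": [5, 5, 8, 2.0]}, index=labels
        )
        pm = phylomorphospace(t, X, "u", "v")
        assert pm["nodes"]["x"].iloc[0] == pytest.approx(3.0)
        assert pm["nodes"]["y"].iloc[0] == pytest.approx(5.0)

    def test_edge_count_is_nodes_plus_tips_minus_one(self):
        t = simulate_tree(20, seed=10)
        X = simulate_traits(t, {"u": 1.0, "v": 1.0}, seed=11)
        pm = phylomorphospace(t, X, "u", "v")
        assert len(pm["edges"]) == t.n_tips + t.n_internal - 1

    def test_node_cis_attached(self):
        t = simulate_tree(6, seed=12)
        X = simulate_traits(t, {"u": 1.0, "v": 1.0}, seed=13)
        pm = phylomorphospace(t, X, "u", "v")
        assert {"x_ci_low", "x_ci_high", "y_ci_low", "y_ci_high"} <= set(
            pm["nodes"].columns
        )


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------


class TestSpearman:
    def test_monotone_transform_gives_rho_one(self):
        x = np.arange(1.0, 11.0)
        rho, p = spearman(x, x**2)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_reversal_gives_minus_one(self):
        x = np.arange(1.0, 11.0)
        rho, _ = spearman(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_ties_match_bruteforce_rank_assignment(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 3.0, 3.0, 4.0])
        y = np.array([5.0, 4.0, 4.0, 2.0, 2.0, 1.0, 0.0])

        def brute_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            while i < len(v):
                j = i
                while j < len(v) and v[order[j]] == v[order[i]]:
                    j += 1
                ranks[order[i:j]] = np.mean(np.arange(i, j)) + 1
                i = j
            return ranks

        rho, p = spearman(x, y)
        rx, ry = brute_ranks(x), brute_ranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected, rel=1e-12)
        rho_sp, p_sp = sps.spearmanr(x, y)
        assert rho == pytest.approx(rho_sp, rel=1e-12)
        assert p == pytest.approx(p_sp, rel=1e-9)

    def test_exact_permutation_small_n(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        rho, p = spearman(x, y, method="exact")
        # all 120 permutations enumerated: p is a multiple of 1/120
        assert (p * 120) == pytest.approx(round(p * 120))
        assert 0 < p < 1

    def test_all_tied_is_undefined(self):
        with pytest.raises(ValueError, match="rank variance"):
            spearman(np.ones(5), np.arange(5.0))
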