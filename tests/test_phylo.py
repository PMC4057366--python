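"""Comparative statistics against independent oracles: hand computations,
brute-force enumeration, direct MVN densities and grid searches."""

import itertools
import math

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lanterneye.phylo import (
    _LambdaGLS,
    _MkPruner,
    fit_lambda_continuous,
    fit_lambda_discrete,
    grafen_transform,
    is_ultrametric,
    lambda_transform,
    pgls_fit,
    phylo_covariance,
    resolve_polytomies,
    run_pgls_table,
    run_signal_table,
    tip_labels,
)
from lanterneye.treesim import simulate_lambda_bm, simulate_tree


def newick(s):
    t = dendropy.Tree.get(data=s, schema="newick")
    t.is_rooted = True
    return t


# ---------------------------------------------------------------------------
# tree preparation


class TestGrafen:
    def test_three_tip_hand_computation(self, three_tip_grafen):
        # ((A,B),C), rho = 2.5: internal height (1/2)^2.5 = 0.17678
        V, labels = phylo_covariance(three_tip_grafen)
        i, j = labels.index("A"), labels.index("B")
        k = labels.index("C")
        assert V[i, i] == pytest.approx(1.0, abs=1e-12)
        # internal node sits 0.5^2.5 = 0.17678 above the tips, so A and B
        # share a root-to-MRCA path of 1 - 0.17678 = 0.82322
        assert V[i, j] == pytest.approx(1.0 - 0.5**2.5, abs=1e-9)
        assert V[i, j] == pytest.approx(0.82322, abs=1e-5)
        assert V[i, k] == 0.0

    def test_rho_one_balanced_four_tips(self):
        t = grafen_transform(newick("((A:1,B:1):1,(C:1,D:1):1);"), rho=1.0)
        V, labels = phylo_covariance(t)
        offdiag = sorted({round(V[i, j], 9) for i in range(4) for j in range(4) if i != j})
        # cherry nodes sit 1/3 above the tips, so sisters share depth 2/3;
        # tips across the root share nothing
        assert offdiag == [0.0, pytest.approx(2 / 3)]

    def test_output_ultrametric_unit_height(self):
        for seed in range(3):
            t = grafen_transform(simulate_tree(20, seed=seed, polytomy_fraction=0.3))
            assert is_ultrametric(t, rel_tol=1e-12)
            V, _ = phylo_covariance(t)
            assert np.allclose(np.diag(V), 1.0, atol=1e-12)

    def test_rejects_unrooted(self):
        t = newick("((A:1,B:1):1,C:2);")
        t.is_rooted = False
        with pytest.raises(ValueError):
            grafen_transform(t)


class TestPolytomyResolution:
    def test_binary_tree_unchanged(self):
        t = newick("((A:1,B:1):1,C:2);")
        out = resolve_polytomies(t, n_resolutions=3, seed=0)
        assert len(out) == 3
        for r in out:
            assert {l.taxon.label for l in r.leaf_node_iter()} == {"A", "B", "C"}
            assert all(len(n.child_nodes()) == 2 for n in r.preorder_internal_node_iter())

    def test_trifurcation_resolutions_near_uniform(self):
        t = newick("(A:1,B:1,C:1);")
        out = resolve_polytomies(t, n_resolutions=300, branch_length=1e-6, seed=1)
        # identify which pair got joined in each resolution
        freq = {"AB": 0, "AC": 0, "BC": 0}
        for r in out:
            for node in r.preorder_internal_node_iter():
                kids = node.child_nodes()
                labs = sorted(
                    c.taxon.label for c in kids if c.is_leaf() and c.taxon is not None
                )
                if len(labs) == 2 and node.parent_node is not None:
                    freq["".join(labs)] += 1
        counts = np.array(list(freq.values()))
        assert counts.sum() == 300
        # multinomial(300, 1/3): 4 sd band
        assert np.all(np.abs(counts - 100) < 4 * math.sqrt(300 * (1 / 3) * (2 / 3)))

    def test_new_branches_are_tiny_and_binary(self):
        t = newick("(A:1,B:1,C:1,D:1,E:1);")
        for r in resolve_polytomies(t, n_resolutions=10, branch_length=1e-6, seed=2):
            assert all(len(n.child_nodes()) == 2 for n in r.preorder_internal_node_iter())
            inner = [
                n.edge.length
                for n in r.preorder_internal_node_iter()
                if n.parent_node is not None
            ]
            assert all(bl == pytest.approx(1e-6) for bl in inner)


class TestLambdaTransform:
    def test_identity_at_one(self, tree64):
        V, _ = phylo_covariance(tree64)
        assert np.array_equal(lambda_transform(V, 1.0), V)

    def test_diagonal_at_zero(self, tree64):
        V, _ = phylo_covariance(tree64)
        C = lambda_transform(V, 0.0)
        assert np.array_equal(C, np.diag(np.diag(V)))

    def test_three_tip_half(self, three_tip_grafen):
        V, labels = phylo_covariance(three_tip_grafen)
        C = lambda_transform(V, 0.5)
        i, j = labels.index("A"), labels.index("B")
        assert C[i, j] == pytest.approx(0.5 * 0.82322, abs=1e-5)

    def test_psd_across_lambda(self, tree64):
        V, _ = phylo_covariance(tree64)
        for lam in (0.0, 0.3, 0.7, 1.0):
            w = np.linalg.eigvalsh(lambda_transform(V, lam))
            assert w.min() > -1e-9

    def test_rejects_out_of_range(self, tree64):
        V, _ = phylo_covariance(tree64)
        with pytest.raises(ValueError):
            lambda_transform(V, 1.5)


# ---------------------------------------------------------------------------
# continuous lambda


class TestContinuousLambda:
    def test_profile_likelihood_matches_direct_mvn(self):
        # oracle: scipy MVN density with the profiled mean/scale plugged in
        tree = grafen_transform(simulate_tree(5, seed=3))
        V, labels = phylo_covariance(tree)
        y = simulate_lambda_bm(tree, 0.7, sigma2=2.0, root_state=1.0, seed=4).loc[
            labels
        ].to_numpy()
        model = _LambdaGLS(V)
        X = np.ones((5, 1))
        for lam in (0.0, 0.4, 1.0):
            ll, beta, sigma2, _ = model.gls(lam, y, X)
            C = sigma2 * lambda_transform(V, lam)
            direct = stats.multivariate_normal(mean=np.full(5, beta[0]), cov=C).logpdf(y)
            assert ll == pytest.approx(direct, abs=1e-8)

    def test_optimizer_agrees_with_grid_search(self, tree64):
        V, labels = phylo_covariance(tree64)
        model = _LambdaGLS(V)
        X = np.ones((64, 1))
        for seed, lam_true in [(5, 0.5), (6, 0.9), (7, 0.2)]:
            y = simulate_lambda_bm(tree64, lam_true, seed=seed).loc[labels].to_numpy()
            lam_hat, _ = model.fit(y, X)
            grid = np.arange(0.0, 1.0 + 1e-9, 1e-3)
            lls = [model.loglik(l, y, X) for l in grid]
            lam_grid = grid[int(np.argmax(lls))]
            assert abs(lam_hat - lam_grid) <= 2e-3

    def test_optimizer_dominates_grid(self, tree64):
        V, labels = phylo_covariance(tree64)
        model = _LambdaGLS(V)
        X = np.ones((64, 1))
        y = simulate_lambda_bm(tree64, 0.6, seed=8).loc[labels].to_numpy()
        lam_hat, ll_hat = model.fit(y, X)
        for l in np.linspace(0, 1, 101):
            assert ll_hat >= model.loglik(l, y, X) - 1e-7

    def test_recovery_at_boundaries(self, tree128):
        # median lambda-hat >= 0.9 under lambda = 1, <= 0.1 under lambda = 0
        reps = 60
        y1 = simulate_lambda_bm(tree128, 1.0, seed=9, n_replicates=reps)
        y0 = simulate_lambda_bm(tree128, 0.0, seed=10, n_replicates=reps)
        hats1 = [fit_lambda_continuous(tree128, y1[i]).lambda_hat for i in range(reps)]
        hats0 = [fit_lambda_continuous(tree128, y0[i]).lambda_hat for i in range(reps)]
        assert np.median(hats1) >= 0.9
        assert np.median(hats0) <= 0.1

    def test_constant_trait_rejected(self, tree64):
        y = pd.Series(1.0, index=tip_labels(tree64))
        with pytest.raises(ValueError):
            fit_lambda_continuous(tree64, y)

    def test_loglik_at_hat_dominates_boundaries(self, tree64):
        y = simulate_lambda_bm(tree64, 0.5, seed=11)
        fit = fit_lambda_continuous(tree64, y)
        assert fit.loglik >= fit.loglik_lambda0 - 1e-9
        assert fit.loglik >= fit.loglik_lambda1 - 1e-9
        assert 0 <= fit.p_vs_0 <= 1 and 0 <= fit.p_vs_1 <= 1


# ---------------------------------------------------------------------------
# discrete lambda


def mk2_transition(q, t):
    same = 0.5 * (1 + math.exp(-2 * q * t))
    diff = 0.5 * (1 - math.exp(-2 * q * t))
    return np.array([[same, diff], [diff, same]])


def enumeration_loglik(pruner, q, lam, states):
    """Brute-force sum over all internal-node state assignments."""
    bl = pruner.branch_lengths(lam)
    n_nodes = len(pruner.is_leaf)
    internal = [i for i in range(n_nodes) if not pruner.is_leaf[i]]
    parents = {}
    for i in range(n_nodes):
        for c in pruner.children[i]:
            parents[c] = i
    total = 0.0
    for assign in itertools.product((0, 1), repeat=len(internal)):
        state = {i: s for i, s in zip(internal, assign)}
        for i in range(n_nodes):
            if pruner.is_leaf[i]:
                state[i] = states[pruner.labels[i]]
        prob = 0.5  # uniform root prior
        for i in range(n_nodes):
            if i == pruner.root:
                continue
            P = mk2_transition(q, bl[i])
            prob *= P[state[parents[i]], state[i]]
        total += prob
    return math.log(total)


class TestDiscreteLambda:
    def test_two_tip_closed_form(self):
        # tips in different states across two branches of length t:
        # L = P_same(t) P_diff(t) under the uniform root prior
        t = newick("(A:1,B:1);")
        pruner = _MkPruner(t)
        states = {"A": 0, "B": 1}
        for q in (0.3, 1.0, 2.5):
            expected = math.log(
                0.5 * (1 + math.exp(-2 * q)) * 0.5 * (1 - math.exp(-2 * q))
            )
            assert pruner.loglik(q, 1.0, states) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("n_tips", [4, 5])
    @pytest.mark.parametrize("lam", [0.0, 0.5, 1.0])
    def test_pruning_equals_enumeration(self, n_tips, lam):
        tree = grafen_transform(simulate_tree(n_tips, seed=n_tips))
        pruner = _MkPruner(tree)
        labels = tip_labels(tree)
        rng = np.random.default_rng(n_tips)
        states = {l: int(s) for l, s in zip(labels, rng.integers(0, 2, n_tips))}
        if len(set(states.values())) < 2:
            states[labels[0]] = 1 - states[labels[0]]
        for q in (0.2, 1.0, 5.0):
            a = pruner.loglik(q, lam, states)
            b = enumeration_loglik(pruner, q, lam, states)
            assert a == pytest.approx(b, rel=1e-10, abs=1e-10)

    def test_clade_constant_trait_gives_high_lambda(self):
        # trait perfectly split between the two deepest clades
        tree = grafen_transform(newick("((A:1,B:1,C:1):1,(D:1,E:1,F:1):1);"))
        trait = pd.Series([1, 1, 1, 0, 0, 0], index=["A", "B", "C", "D", "E", "F"])
        fit = fit_lambda_discrete(tree, trait)
        assert fit.lambda_hat >= 0.9

    def test_invariant_trait_rejected(self, tree64):
        trait = pd.Series(1, index=tip_labels(tree64))
        with pytest.raises(ValueError):
            fit_lambda_discrete(tree64, trait)


# ---------------------------------------------------------------------------
# PGLS


class TestPGLS:
    def test_lambda_zero_equals_ols(self, tree64):
        labels = tip_labels(tree64)
        rng = np.random.default_rng(13)
        n = len(labels)
        x1, x2 = rng.standard_normal((2, n))
        y = 1.0 + 0.5 * x1 - 0.25 * x2 + rng.standard_normal(n)
        V, _ = phylo_covariance(tree64)
        model = _LambdaGLS(V)
        X = np.column_stack([np.ones(n), x1, x2])
        _, beta_gls, _, _ = model.gls(0.0, y, X)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(beta_gls, beta_ols, atol=1e-10)

    def test_three_taxon_hand_gls(self, three_tip_grafen):
        # beta-hat = (X' V^-1 X)^-1 X' V^-1 y with V inverted directly
        V, labels = phylo_covariance(three_tip_grafen)
        y = np.array([0.3, -0.1, 0.8])
        x = np.array([1.0, 2.0, -0.5])
        X = np.column_stack([np.ones(3), x])
        Vinv = np.linalg.inv(V)
        beta_hand = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
        model = _LambdaGLS(V)
        _, beta, _, _ = model.gls(1.0, y, X)
        assert np.allclose(beta, beta_hand, atol=1e-10)

    def test_recovers_simulated_slopes(self, tree64):
        from lanterneye.treesim import PredictorSpec, simulate_regression_dataset

        specs = [
            PredictorSpec("sl", "continuous", lam=0.0),
            PredictorSpec("depth", "ordinal", lam=0.8),
        ]
        betas = np.array([0.3, 0.07])
        hats = []
        for seed in range(30):
            ds = simulate_regression_dataset(
                tree64, betas, 0.0, specs, seed=seed, sigma2_res=0.05**2
            )
            fit = pgls_fit(ds.tree, ds.traits, "response", ["sl", "depth"])
            hats.append(fit.params.loc[["sl", "depth"], "beta"].to_numpy())
        hats = np.array(hats)
        mc_se = hats.std(axis=0, ddof=1) / math.sqrt(len(hats))
        assert np.all(np.abs(hats.mean(axis=0) - betas) <= 2 * mc_se)

    def test_complete_case_drops_missing_species(self, tree64):
        labels = tip_labels(tree64)
        rng = np.random.default_rng(14)
        df = pd.DataFrame(
            {
                "species": labels,
                "x": rng.standard_normal(len(labels)),
                "y": rng.standard_normal(len(labels)),
            }
        )
        df.loc[:4, "x"] = np.nan
        fit = pgls_fit(tree64, df, "y", ["x"])
        assert fit.n == len(labels) - 5

    def test_rank_deficiency_names_columns(self, tree64):
        labels = tip_labels(tree64)
        rng = np.random.default_rng(15)
        x = rng.standard_normal(len(labels))
        df = pd.DataFrame(
            {"species": labels, "x": x, "x2": 2 * x, "y": rng.standard_normal(len(labels))}
        )
        with pytest.raises(ValueError, match="x2"):
            pgls_fit(tree64, df, "y", ["x", "x2"])

    def test_missing_column_rejected(self, tree64):
        df = pd.DataFrame({"species": tip_labels(tree64), "y": 0.0})
        with pytest.raises(ValueError, match="nope"):
            pgls_fit(tree64, df, "y", ["nope"])


# ---------------------------------------------------------------------------
# report tables


class TestReportTables:
    def test_identical_trees_identical_rows(self, tree64):
        y = simulate_lambda_bm(tree64, 0.6, seed=16)
        traits = pd.DataFrame({"species": y.index, "trait": y.to_numpy()})
        table = run_signal_table([tree64, tree64], traits)
        a = table[table.tree == 0].drop(columns="tree").reset_index(drop=True)
        b = table[table.tree == 1].drop(columns="tree").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_no_signal_trait_lambda_near_zero(self, tree64):
        rng = np.random.default_rng(17)
        traits = pd.DataFrame(
            {"species": tip_labels(tree64), "sl": rng.standard_normal(64)}
        )
        table = run_signal_table([tree64], traits)
        assert table.loc[0, "lambda_hat"] <= 0.15

    def test_clade_binary_trait_lambda_one(self):
        tree = grafen_transform(newick("((A:1,B:1,C:1,D:1):1,(E:1,F:1,G:1,H:1):1);"))
        traits = pd.DataFrame(
            {"species": list("ABCDEFGH"), "organ": [1, 1, 1, 1, 0, 0, 0, 0]}
        )
        table = run_signal_table([tree], traits)
        assert table.loc[0, "kind"] == "discrete"
        assert table.loc[0, "lambda_hat"] >= 0.9

    def test_errors_are_per_trait_not_fatal(self, tree64):
        traits = pd.DataFrame(
            {
                "species": tip_labels(tree64),
                "constant": 1.0,
                "ok": simulate_lambda_bm(tree64, 0.5, seed=18).to_numpy(),
            }
        )
        table = run_signal_table([tree64], traits)
        bad = table[table.trait == "constant"].iloc[0]
        good = table[table.trait == "ok"].iloc[0]
        assert bad["error"] != "" and np.isnan(bad["lambda_hat"])
        assert good["error"] == "" and np.isfinite(good["lambda_hat"])

    def test_pgls_table_swapping_trees_keeps_significance_pattern(self):
        from lanterneye.treesim import PredictorSpec, simulate_regression_dataset

        tree_a = grafen_transform(simulate_tree(53, seed=19))
        tree_b = grafen_transform(simulate_tree(53, seed=20))
        # same tip labels, different topologies: mirror the two-phylogeny protocol
        specs = [
            PredictorSpec("sl", "continuous", lam=0.0),
            PredictorSpec("night_depth", "ordinal", lam=0.5),
        ]
        ds = simulate_regression_dataset(
            tree_a, [0.0, 0.4], 0.0, specs, seed=21, sigma2_res=0.05**2
        )
        table = run_pgls_table([tree_a, tree_b], ds.traits, {"response": ["sl", "night_depth"]})
        sig = table.pivot(index="predictor", columns="tree", values="significant")
        assert (sig[0] == sig[1]).all()
        assert sig.loc["night_depth"].all()
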