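"""Phylogenetic comparative statistics.

Tree preparation (random polytomy resolution, Grafen's branch-length
transform), Pagel's lambda for continuous and binary traits with
likelihood-ratio tests, and PGLS multiple regression with residual lambda
estimated by maximum likelihood.

Model notes
-----------
For a continuous trait y on a tree with Brownian covariance V (entries =
shared root-to-node path lengths), Pagel's lambda multiplies the
off-diagonal of V:

    V(lambda)_ij = lambda * V_ij  (i != j),   V(lambda)_ii = V_ii

and y ~ MVN(mu 1, sigma^2 V(lambda)).  mu and sigma^2 have closed-form GLS
profiles, so the likelihood is maximised over lambda in [0, 1] alone.  On an
ultrametric tree (all tip heights h) V(lambda) = lambda V + (1-lambda) h I
shares V's eigenvectors, making each likelihood evaluation O(n^2) after one
eigendecomposition.

For a binary trait, the same lambda transform is applied to the tree's
branch lengths (internal branches scaled by lambda, terminal branches
stretched to preserve tip heights) and the likelihood of a symmetric 2-state
Markov model with rate q is computed by Felsenstein's pruning algorithm with
a uniform root prior; (q, lambda) are maximised jointly.

LRTs against lambda = 0 and lambda = 1 use chi-square with df = 1 even at
the boundary (the convention of the comparative literature this package
mirrors; boundary asymptotics are formally nonstandard).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "LambdaFit",
    "PGLSFit",
    "tip_labels",
    "phylo_covariance",
    "is_ultrametric",
    "grafen_transform",
    "resolve_polytomies",
    "lambda_transform",
    "fit_lambda_continuous",
    "fit_lambda_discrete",
    "pgls_fit",
    "run_signal_table",
    "run_pgls_table",
]

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# tree utilities


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _node_depths(tree: dendropy.Tree) -> dict:
    """Distance from root for every node (root edge ignored)."""
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            bl = node.edge.length if node.edge.length is not None else 0.0
            depths[node] = depths[node.parent_node] + bl
    return depths


def phylo_covariance(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance matrix of the tips.

    V_ii is the root-to-tip path length; V_ij the root-to-MRCA path length.
    """
    depths = _node_depths(tree)
    leaves = list(tree.leaf_node_iter())
    labels = [l.taxon.label for l in leaves]
    index = {leaf: i for i, leaf in enumerate(leaves)}
    n = len(leaves)
    V = np.zeros((n, n))
    tipsets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[node] = [index[node]]
            V[index[node], index[node]] = depths[node]
        else:
            children = node.child_nodes()
            sets = [tipsets.pop(c) for c in children]
            d = depths[node]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    for i in sets[a]:
                        V[i, sets[b]] = d
                        V[np.asarray(sets[b]), i] = d
            merged = [i for s in sets for i in s]
            tipsets[node] = merged
    return V, labels


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    depths = _node_depths(tree)
    tip_d = np.array([depths[l] for l in tree.leaf_node_iter()])
    h = tip_d.max()
    if h == 0:
        return False
    return bool(np.all(np.abs(tip_d - h) <= rel_tol * h))


def grafen_transform(tree: dendropy.Tree, rho: float = 2.5) -> dendropy.Tree:
    """Grafen's branch-length transform: heights from descendant-tip counts.

    Each node gets height ((n_descendant_tips - 1) / (n_total_tips - 1))^rho
    (tips at 0, root at 1) and branch lengths become parent height minus
    child height.  The result is ultrametric with unit root-to-tip distance,
    giving arbitrary topologies statistically usable branch lengths.
    """
    if not tree.is_rooted:
        raise ValueError("Grafen transform requires a rooted tree")
    out = tree.clone(depth=1)
    counts: dict = {}
    for node in out.postorder_node_iter():
        if node.is_leaf():
            counts[node] = 1
        else:
            counts[node] = sum(counts[c] for c in node.child_nodes())
    n_total = counts[out.seed_node]
    if n_total < 2:
        raise ValueError("tree must have at least two tips")
    heights = {
        node: ((c - 1) / (n_total - 1)) ** rho if c > 1 else 0.0
        for node, c in counts.items()
    }
    for node in out.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = heights[node.parent_node] - heights[node]
    out.seed_node.edge.length = None
    return out


def resolve_polytomies(
    tree: dendropy.Tree,
    n_resolutions: int = 100,
    branch_length: float = 1e-6,
    seed: int | np.random.Generator = 0,
) -> list[dendropy.Tree]:
    """Randomly resolve polytomies into binary trees.

    Each multifurcation is resolved by repeatedly joining two of its
    children, chosen uniformly at random, under a new internal node whose
    subtending branch has the given (infinitesimal) length; the procedure
    mirrors generating many alternative phylogenies from an
    incompletely-resolved consensus.  A binary input is returned unchanged
    (as copies).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out: list[dendropy.Tree] = []
    for _ in range(n_resolutions):
        t = tree.clone(depth=1)
        for node in list(t.preorder_internal_node_iter()):
            children = node.child_nodes()
            while len(children) > 2:
                i, j = sorted(rng.choice(len(children), size=2, replace=False))
                a, b = children[i], children[j]
                node.remove_child(a)
                node.remove_child(b)
                joint = t.node_factory()
                joint.add_child(a)
                joint.add_child(b)
                node.add_child(joint)
                joint.edge.length = branch_length
                children = node.child_nodes()
        out.append(t)
    return out


def collapse_random_edges(
    tree: dendropy.Tree, fraction: float, seed: int | np.random.Generator = 0
) -> dendropy.Tree:
    """Collapse a random fraction of internal (non-root) edges to polytomies.

    The collapsed edge's length is added to its children's edges, so tip
    heights (and ultrametricity) are preserved.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    t = tree.clone(depth=1)
    internal = [
        n
        for n in t.preorder_internal_node_iter()
        if n.parent_node is not None
    ]
    k = int(round(fraction * len(internal)))
    if k == 0:
        return t
    chosen = rng.choice(len(internal), size=k, replace=False)
    for idx in chosen:
        node = internal[idx]
        parent = node.parent_node
        bl = node.edge.length or 0.0
        for child in list(node.child_nodes()):
            node.remove_child(child)
            child.edge.length = (child.edge.length or 0.0) + bl
            parent.add_child(child)
        parent.remove_child(node)
    return t


def lambda_transform(V: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda transform of a phylogenetic covariance matrix."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must lie in [0, 1]")
    C = lam * np.asarray(V, dtype=float)
    np.fill_diagonal(C, np.diag(V))
    return C


# ---------------------------------------------------------------------------
# continuous-trait likelihood machinery


class _LambdaGLS:
    """Profile GLS likelihood over lambda for y = X b + e, e ~ N(0, s^2 V(lam)).

    On ultrametric trees V(lam) = lam V + (1 - lam) h I is diagonalised once;
    otherwise each evaluation refactorises.
    """

    def __init__(self, V: np.ndarray):
        self.V = np.asarray(V, dtype=float)
        self.n = self.V.shape[0]
        d = np.diag(self.V)
        self.h = float(d[0])
        self.ultrametric = bool(np.allclose(d, self.h, rtol=1e-8, atol=1e-12))
        if self.ultrametric:
            self.evals, self.evecs = np.linalg.eigh(self.V)

    def _whiten(self, lam: float, y: np.ndarray, X: np.ndarray):
        """Return (logdet C, yt, Xt) with C^{-1} = W' W applied implicitly."""
        if self.ultrametric:
            ev = lam * self.evals + (1.0 - lam) * self.h
            ev = np.maximum(ev, 1e-12)
            U = self.evecs
            sq = np.sqrt(ev)
            yt = (U.T @ y) / sq
            Xt = (U.T @ X) / sq[:, None]
            return float(np.log(ev).sum()), yt, Xt
        C = lambda_transform(self.V, lam)
        L = np.linalg.cholesky(C + 1e-12 * np.eye(self.n))
        yt = np.linalg.solve(L, y)
        Xt = np.linalg.solve(L, X)
        return float(2.0 * np.log(np.diag(L)).sum()), yt, Xt

    def gls(self, lam: float, y: np.ndarray, X: np.ndarray):
        """ML profile: returns (loglik, beta, sigma2_ml, XtCiX_inv)."""
        logdet, yt, Xt = self._whiten(lam, y, X)
        XtX = Xt.T @ Xt
        beta = np.linalg.solve(XtX, Xt.T @ yt)
        r = yt - Xt @ beta
        rss = float(r @ r)
        sigma2 = max(rss / self.n, 1e-300)
        ll = -0.5 * (self.n * (_LOG2PI + math.log(sigma2) + 1.0) + logdet)
        return ll, beta, sigma2, np.linalg.inv(XtX)

    def loglik(self, lam: float, y: np.ndarray, X: np.ndarray) -> float:
        return self.gls(lam, y, X)[0]

    def fit(self, y: np.ndarray, X: np.ndarray, tol: float = 1e-6):
        """Maximise over lambda in [0, 1]: coarse grid then bounded refine."""
        grid = np.linspace(0.0, 1.0, 41)
        lls = np.array([self.loglik(l, y, X) for l in grid])
        i = int(np.argmax(lls))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        if hi > lo:
            res = optimize.minimize_scalar(
                lambda l: -self.loglik(l, y, X),
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": tol},
            )
            cand = [(float(res.x), -float(res.fun))]
        else:
            cand = []
        cand += [(float(grid[i]), float(lls[i])), (0.0, float(lls[0])), (1.0, float(lls[-1]))]
        lam_hat, ll_hat = max(cand, key=lambda c: c[1])
        return lam_hat, ll_hat


@dataclass(frozen=True)
class LambdaFit:
    """Pagel's lambda estimate with boundary likelihood-ratio tests."""

    lambda_hat: float
    loglik: float
    loglik_lambda0: float
    loglik_lambda1: float
    p_vs_0: float
    p_vs_1: float
    sigma2_hat: float | None = None
    mu_hat: float | None = None
    rate_hat: float | None = None
    kind: str = "continuous"


def _lrt_p(ll_hat: float, ll_null: float) -> float:
    stat = max(2.0 * (ll_hat - ll_null), 0.0)
    return float(stats.chi2.sf(stat, df=1))


def _align_trait(tree: dendropy.Tree, trait: pd.Series | np.ndarray) -> np.ndarray:
    labels = tip_labels(tree)
    if isinstance(trait, pd.Series):
        missing = [l for l in labels if l not in trait.index]
        if missing:
            raise ValueError(f"trait missing values for tips: {missing[:5]}")
        return trait.loc[labels].to_numpy(dtype=float)
    arr = np.asarray(trait, dtype=float)
    if arr.shape[0] != len(labels):
        raise ValueError("trait length does not match number of tips")
    return arr


def fit_lambda_continuous(
    tree: dendropy.Tree, trait: pd.Series | np.ndarray, tol: float = 1e-6
) -> LambdaFit:
    """ML Pagel's lambda for a continuous trait (single-mean BM model)."""
    y = _align_trait(tree, trait)
    if y.shape[0] < 4:
        raise ValueError("need at least 4 tips to estimate lambda")
    if np.ptp(y) == 0:
        raise ValueError("trait is constant: lambda is unidentifiable")
    V, _ = phylo_covariance(tree)
    model = _LambdaGLS(V)
    X = np.ones((y.shape[0], 1))
    lam_hat, ll_hat = model.fit(y, X, tol=tol)
    ll_hat, beta, sigma2, _ = model.gls(lam_hat, y, X)
    ll0 = model.loglik(0.0, y, X)
    ll1 = model.loglik(1.0, y, X)
    return LambdaFit(
        lambda_hat=lam_hat,
        loglik=ll_hat,
        loglik_lambda0=ll0,
        loglik_lambda1=ll1,
        p_vs_0=_lrt_p(ll_hat, ll0),
        p_vs_1=_lrt_p(ll_hat, ll1),
        sigma2_hat=float(sigma2),
        mu_hat=float(beta[0]),
        kind="continuous",
    )


# ---------------------------------------------------------------------------
# discrete-trait (2-state Mk) likelihood


class _MkPruner:
    """Pruning-algorithm likelihood of a symmetric 2-state model on the
    lambda-transformed tree (requires an ultrametric input tree)."""

    def __init__(self, tree: dendropy.Tree):
        if not is_ultrametric(tree, rel_tol=1e-3):
            raise ValueError(
                "discrete lambda fit requires a (near-)ultrametric tree; "
                "apply grafen_transform first"
            )
        depths = _node_depths(tree)
        self.h = max(depths[l] for l in tree.leaf_node_iter())
        nodes = list(tree.postorder_node_iter())
        self.node_index = {node: i for i, node in enumerate(nodes)}
        self.is_leaf = np.array([n.is_leaf() for n in nodes])
        self.labels = [n.taxon.label if n.is_leaf() else None for n in nodes]
        self.parent_depth = np.array(
            [depths[n.parent_node] if n.parent_node is not None else 0.0 for n in nodes]
        )
        self.raw_bl = np.array(
            [(n.edge.length or 0.0) if n.parent_node is not None else 0.0 for n in nodes]
        )
        self.children = [
            [self.node_index[c] for c in n.child_nodes()] for n in nodes
        ]
        self.root = len(nodes) - 1

    def branch_lengths(self, lam: float) -> np.ndarray:
        """Internal branches scale by lambda; terminal branches stretch so tip
        heights stay at h (the tree form of the lambda transform)."""
        bl = np.where(self.is_leaf, self.h - lam * self.parent_depth, lam * self.raw_bl)
        return np.maximum(bl, 0.0)

    def loglik(self, q: float, lam: float, states: dict[str, int]) -> float:
        bl = self.branch_lengths(lam)
        e = np.exp(-2.0 * q * bl)
        p_same = 0.5 * (1.0 + e)
        p_diff = 0.5 * (1.0 - e)
        L = np.zeros((len(self.is_leaf), 2))
        for i in range(len(self.is_leaf)):
            if self.is_leaf[i]:
                L[i, states[self.labels[i]]] = 1.0
            else:
                part = np.ones(2)
                for c in self.children[i]:
                    down0 = p_same[c] * L[c, 0] + p_diff[c] * L[c, 1]
                    down1 = p_diff[c] * L[c, 0] + p_same[c] * L[c, 1]
                    part *= np.array([down0, down1])
                L[i] = part
        lik = 0.5 * (L[self.root, 0] + L[self.root, 1])
        return math.log(max(lik, 1e-300))


def fit_lambda_discrete(
    tree: dendropy.Tree, trait: pd.Series | np.ndarray, tol: float = 1e-6
) -> LambdaFit:
    """Joint ML of (rate q, lambda) for a binary trait under symmetric Mk
    with a uniform root prior, likelihood by the pruning algorithm."""
    labels = tip_labels(tree)
    if isinstance(trait, pd.Series):
        vals = trait.loc[labels]
    else:
        vals = pd.Series(np.asarray(trait), index=labels)
    arr = vals.to_numpy()
    uniq = set(np.unique(arr).tolist())
    if not uniq <= {0, 1, 0.0, 1.0}:
        raise ValueError("binary trait must take values in {0, 1}")
    if len(uniq) < 2:
        raise ValueError("trait is invariant: lambda/rate unidentifiable")
    states = {l: int(v) for l, v in vals.items()}
    pruner = _MkPruner(tree)

    def fit_q(lam: float) -> tuple[float, float]:
        res = optimize.minimize_scalar(
            lambda lq: -pruner.loglik(math.exp(lq), lam, states),
            bounds=(math.log(1e-4 / pruner.h), math.log(1e4 / pruner.h)),
            method="bounded",
            options={"xatol": 1e-8},
        )
        return math.exp(res.x), -float(res.fun)

    def profile(lam: float) -> float:
        return fit_q(lam)[1]

    grid = np.linspace(0.0, 1.0, 21)
    lls = np.array([profile(l) for l in grid])
    i = int(np.argmax(lls))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda l: -profile(l), bounds=(lo, hi), method="bounded", options={"xatol": tol}
    )
    cand = [(float(res.x), -float(res.fun)), (0.0, float(lls[0])), (1.0, float(lls[-1]))]
    lam_hat, ll_hat = max(cand, key=lambda c: c[1])
    q_hat, _ = fit_q(lam_hat)
    _, ll0 = fit_q(0.0)
    _, ll1 = fit_q(1.0)
    return LambdaFit(
        lambda_hat=lam_hat,
        loglik=ll_hat,
        loglik_lambda0=ll0,
        loglik_lambda1=ll1,
        p_vs_0=_lrt_p(ll_hat, ll0),
        p_vs_1=_lrt_p(ll_hat, ll1),
        rate_hat=q_hat,
        kind="discrete",
    )


# ---------------------------------------------------------------------------
# PGLS


@dataclass
class PGLSFit:
    """PGLS regression result: per-term slopes with t-tests, residual lambda
    with boundary LRTs."""

    params: pd.DataFrame  # index: term; columns beta, se, t, p
    lambda_hat: float
    p_lambda_vs_0: float
    p_lambda_vs_1: float
    loglik: float
    sigma2: float
    n: int
    df_resid: int

    def summary(self) -> str:
        lines = [
            f"PGLS fit: n = {self.n}, residual df = {self.df_resid}",
            f"lambda = {self.lambda_hat:.3f} "
            f"(P vs 0 = {self.p_lambda_vs_0:.3g}, P vs 1 = {self.p_lambda_vs_1:.3g})",
            self.params.to_string(float_format=lambda v: f"{v: .4f}"),
        ]
        return "\n".join(lines)


def pgls_fit(
    tree: dendropy.Tree,
    data: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    species_col: str = "species",
    tol: float = 1e-6,
) -> PGLSFit:
    """PGLS multiple regression with ML residual lambda.

    ``data`` holds one row per species; rows with missing values in the
    response or any predictor are dropped (complete-case), and the tree is
    pruned to the remaining species.
    """
    cols = [response, *predictors]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"data is missing columns: {missing}")
    df = data.set_index(species_col) if species_col in data.columns else data
    df = df[cols].dropna()
    labels_all = tip_labels(tree)
    keep = [l for l in labels_all if l in df.index]
    if len(keep) < len(labels_all) or len(keep) < len(df):
        tree = tree.clone(depth=1)
        tree.retain_taxa_with_labels(keep)
    labels = tip_labels(tree)
    df = df.loc[labels]
    y = df[response].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df))] + [df[p].to_numpy(dtype=float) for p in predictors])
    terms = ["(Intercept)", *predictors]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        bad = [terms[j] for j in range(X.shape[1]) if abs(R[j, j]) < 1e-8 * abs(R[0, 0])]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    n, p = X.shape
    if n - p <= 0:
        raise ValueError("no residual degrees of freedom")

    V, _ = phylo_covariance(tree)
    model = _LambdaGLS(V)
    lam_hat, ll_hat = model.fit(y, X, tol=tol)
    ll_hat, beta, sigma2_ml, XtCiX_inv = model.gls(lam_hat, y, X)
    ll0 = model.loglik(0.0, y, X)
    ll1 = model.loglik(1.0, y, X)
    sigma2 = sigma2_ml * n / (n - p)  # unbiased scale for the t tests
    se = np.sqrt(np.diag(sigma2 * XtCiX_inv))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - p)
    params = pd.DataFrame({"beta": beta, "se": se, "t": tvals, "p": pvals}, index=terms)
    return PGLSFit(
        params=params,
        lambda_hat=lam_hat,
        p_lambda_vs_0=_lrt_p(ll_hat, ll0),
        p_lambda_vs_1=_lrt_p(ll_hat, ll1),
        loglik=ll_hat,
        sigma2=float(sigma2),
        n=n,
        df_resid=n - p,
    )


# ---------------------------------------------------------------------------
# report tables


def _is_binary(col: pd.Series) -> bool:
    vals = set(col.dropna().unique().tolist())
    return vals <= {0, 1, 0.0, 1.0} and len(vals) == 2


def run_signal_table(
    trees: Sequence[dendropy.Tree],
    traits: pd.DataFrame,
    species_col: str = "species",
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pagel's lambda (with LRTs vs 0 and 1) for every trait on every tree.

    Binary 0/1 columns use the discrete Mk fit; everything else the
    continuous fit.  Per-trait failures are recorded, not fatal.  The
    returned tidy table carries one row per (tree, trait); consistency
    across trees is read off the lambda range per trait.
    """
    df = traits.set_index(species_col) if species_col in traits.columns else traits
    cols = list(columns) if columns is not None else list(df.columns)
    rows = []
    for ti, tree in enumerate(trees):
        for col in cols:
            series = df[col].dropna()
            sub = tree
            labels_all = tip_labels(tree)
            keep = [l for l in labels_all if l in series.index]
            if len(keep) < len(labels_all):
                sub = tree.clone(depth=1)
                sub.retain_taxa_with_labels(keep)
            row = {"tree": ti, "trait": col}
            try:
                if _is_binary(series):
                    fit = fit_lambda_discrete(sub, series)
                else:
                    fit = fit_lambda_continuous(sub, series)
                row.update(
                    lambda_hat=fit.lambda_hat,
                    p_vs_0=fit.p_vs_0,
                    p_vs_1=fit.p_vs_1,
                    loglik=fit.loglik,
                    kind=fit.kind,
                    error="",
                )
            except (ValueError, np.linalg.LinAlgError) as exc:
                row.update(
                    lambda_hat=np.nan, p_vs_0=np.nan, p_vs_1=np.nan,
                    loglik=np.nan, kind="", error=str(exc),
                )
            rows.append(row)
    return pd.DataFrame(rows)


def signal_consistency(signal_table: pd.DataFrame) -> pd.DataFrame:
    """Range of lambda estimates per trait across trees (consistency check)."""
    g = signal_table.dropna(subset=["lambda_hat"]).groupby("trait")["lambda_hat"]
    return g.agg(lambda_min="min", lambda_max="max", lambda_median="median").reset_index()


def run_pgls_table(
    trees: Sequence[dendropy.Tree],
    traits: pd.DataFrame,
    models: dict[str, Sequence[str]],
    species_col: str = "species",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """PGLS fits for each (response -> predictors) model on each tree.

    Emits one row per tree x model x predictor with beta, t, P, the model's
    residual lambda and its boundary-test P-values, and a significance flag.
    """
    rows = []
    for ti, tree in enumerate(trees):
        for response, predictors in models.items():
            fit = pgls_fit(tree, traits, response, list(predictors), species_col=species_col)
            for term, rec in fit.params.iterrows():
                if term == "(Intercept)":
                    continue
                rows.append(
                    {
                        "tree": ti,
                        "response": response,
                        "predictor": term,
                        "beta": rec["beta"],
                        "t": rec["t"],
                        "p": rec["p"],
                        "significant": rec["p"] < alpha,
                        "lambda": fit.lambda_hat,
                        "p_lambda_vs_0": fit.p_lambda_vs_0,
                        "p_lambda_vs_1": fit.p_lambda_vs_1,
                        "n": fit.n,
                    }
                )
    return pd.DataFrame(rows)
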