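"""Simulated phylogenies and trait evolution for recovery testing.

Pure-birth trees (optionally degraded with random polytomies, as in
genus-level consensus phylogenies), continuous traits evolving under
lambda-scaled Brownian motion, phylogenetically clustered binary and
ordinal ecological covariates, and full regression datasets with known
slopes — everything downstream comparative statistics need to be tested
against a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import dendropy
import numpy as np
import pandas as pd

from .phylo import (
    collapse_random_edges,
    grafen_transform,
    is_ultrametric,
    lambda_transform,
    phylo_covariance,
    tip_labels,
)

__all__ = [
    "simulate_tree",
    "simulate_lambda_bm",
    "PredictorSpec",
    "SimulatedComparativeDataset",
    "simulate_regression_dataset",
]


def simulate_tree(
    n_tips: int,
    seed: int | np.random.Generator = 0,
    polytomy_fraction: float = 0.0,
) -> dendropy.Tree:
    """Pure-birth (Yule) tree with unit speciation rate.

    All tips end at the same time, so the tree is ultrametric.  If
    ``polytomy_fraction`` > 0, that fraction of internal (non-root) edges is
    collapsed at random into polytomies, with the collapsed length pushed
    into the children so tip heights are preserved.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    if not (0 <= polytomy_fraction < 1):
        raise ValueError("polytomy_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    taxa = dendropy.TaxonNamespace([f"s{i + 1}" for i in range(n_tips)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    birth = {tree.seed_node: 0.0}
    active = [tree.seed_node]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        parent.edge.length = (
            t - birth[parent] if parent.parent_node is not None else None
        )
        for _ in range(2):
            child = tree.node_factory()
            parent.add_child(child)
            birth[child] = t
            active.append(child)
    t += rng.exponential(1.0 / n_tips)  # let terminal branches run on
    order = rng.permutation(n_tips)
    for k, node in enumerate(active):
        node.edge.length = t - birth[node]
        node.taxon = taxa[int(order[k])]
    # root's children may still carry provisional lengths if root never split
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            node.edge.length = 0.0
    if polytomy_fraction > 0:
        tree = collapse_random_edges(tree, polytomy_fraction, rng)
    return tree


def simulate_lambda_bm(
    tree: dendropy.Tree,
    lam: float,
    sigma2: float = 1.0,
    root_state: float = 0.0,
    seed: int | np.random.Generator = 0,
    n_replicates: int | None = None,
) -> pd.Series | pd.DataFrame:
    """Tip values of a lambda-scaled Brownian motion on an ultrametric tree.

    Draws from MVN(root_state, sigma2 * V(lambda)) where V is the tree's
    Brownian covariance with off-diagonals multiplied by lambda.  With
    ``n_replicates`` set, returns a (tips x replicates) DataFrame drawn with
    one Cholesky factorisation.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must be in [0, 1]")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if not is_ultrametric(tree, rel_tol=1e-6):
        raise ValueError("tree must be ultrametric (apply grafen_transform first)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    V, labels = phylo_covariance(tree)
    C = sigma2 * lambda_transform(V, lam)
    L = np.linalg.cholesky(C + 1e-12 * np.trace(C) / len(labels) * np.eye(len(labels)))
    if n_replicates is None:
        vals = root_state + L @ rng.standard_normal(len(labels))
        return pd.Series(vals, index=labels, name="trait")
    Z = rng.standard_normal((len(labels), n_replicates))
    return pd.DataFrame(root_state + L @ Z, index=labels)


@dataclass(frozen=True)
class PredictorSpec:
    """One synthetic predictor.

    kind 'continuous': a lambda-BM trait (unit variance scale ``sigma2``);
    'binary': a latent lambda-BM thresholded at the (1 - prevalence)
    quantile, so high-lambda latents give phylogenetically clustered
    presence/absence patterns (e.g. luminous organs); 'ordinal': the latent
    cut into three ordered levels {1, 2, 3} at the given cumulative
    proportions (depth-at-night style categories).
    """

    name: str
    kind: Literal["continuous", "binary", "ordinal"] = "continuous"
    lam: float = 1.0
    sigma2: float = 1.0
    prevalence: float = 0.5
    level_props: tuple[float, float] = (1 / 3, 2 / 3)


@dataclass
class SimulatedComparativeDataset:
    """Tree + trait table with the generating parameters retained."""

    tree: dendropy.Tree
    traits: pd.DataFrame  # species key column + predictors + response
    true_lambda: float
    true_sigma2: float
    true_betas: np.ndarray
    seed: int | None
    predictor_names: list[str] = field(default_factory=list)


def _threshold(latent: np.ndarray, q: float) -> np.ndarray:
    cut = np.quantile(latent, q)
    return (latent > cut).astype(int)


def simulate_regression_dataset(
    tree: dendropy.Tree,
    betas: Sequence[float],
    lambda_res: float,
    predictor_spec: Sequence[PredictorSpec],
    seed: int | np.random.Generator = 0,
    sigma2_res: float = 1.0,
    intercept: float = 0.0,
) -> SimulatedComparativeDataset:
    """Simulate a species trait table with a known regression structure.

    response = intercept + sum_i beta_i x_i + eps,
    eps ~ MVN(0, sigma2_res * V(lambda_res)).

    Predictors are generated per their :class:`PredictorSpec`.  The tree must
    be ultrametric (Grafen-transform first if needed).
    """
    betas = np.asarray(betas, dtype=float)
    if betas.shape[0] != len(predictor_spec):
        raise ValueError(
            f"got {betas.shape[0]} betas for {len(predictor_spec)} predictors"
        )
    if not is_ultrametric(tree, rel_tol=1e-6):
        raise ValueError("tree must be ultrametric (apply grafen_transform first)")
    base_seed = seed if isinstance(seed, (int, np.integer)) else None
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    labels = tip_labels(tree)
    n = len(labels)
    cols: dict[str, np.ndarray] = {}
    for spec in predictor_spec:
        latent = simulate_lambda_bm(tree, spec.lam, spec.sigma2, 0.0, rng).to_numpy()
        if spec.kind == "continuous":
            cols[spec.name] = latent
        elif spec.kind == "binary":
            cols[spec.name] = _threshold(latent, 1.0 - spec.prevalence)
        elif spec.kind == "ordinal":
            q1, q2 = np.quantile(latent, spec.level_props)
            cols[spec.name] = 1 + (latent > q1).astype(int) + (latent > q2).astype(int)
        else:
            raise ValueError(f"unknown predictor kind {spec.kind!r}")
    X = np.column_stack([cols[s.name] for s in predictor_spec]) if predictor_spec else np.zeros((n, 0))
    eps = simulate_lambda_bm(tree, lambda_res, sigma2_res, 0.0, rng).to_numpy()
    response = intercept + X @ betas + eps
    traits = pd.DataFrame({"species": labels, **cols, "response": response})
    return SimulatedComparativeDataset(
        tree=tree,
        traits=traits,
        true_lambda=lambda_res,
        true_sigma2=sigma2_res,
        true_betas=betas,
        seed=int(base_seed) if base_seed is not None else None,
        predictor_names=[s.name for s in predictor_spec],
    )
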