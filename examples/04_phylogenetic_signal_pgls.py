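"""Phylogenetic signal and PGLS on a simulated comparative dataset.

Simulates a 53-species pure-birth tree with genus-level polytomies,
resolves the polytomies randomly (1e-6 branches), Grafen-transforms the
branch lengths (rho = 2.5), and builds a trait table in which a
phylogenetically clustered binary organ trait carries full Brownian signal
while the response depends only on an ordinal night-depth category
(beta = 0.07) with signal-free residuals.  Pagel's lambda should be ~1 for
the organ trait and ~0 for the response residual structure; PGLS should
recover the night-depth slope.
"""

from lanterneye import grafen_transform, pgls_fit, resolve_polytomies, run_signal_table
from lanterneye.treesim import PredictorSpec, simulate_regression_dataset, simulate_tree

raw = simulate_tree(53, seed=8, polytomy_fraction=0.3)
resolved = resolve_polytomies(raw, n_resolutions=100, branch_length=1e-6, seed=9)
tree = grafen_transform(resolved[0], rho=2.5)  # one of the random resolutions

specs = [
    PredictorSpec("standard_length", "continuous", lam=0.0),
    PredictorSpec("dnvn_organs", "binary", lam=1.0, prevalence=0.5),
    PredictorSpec("night_depth", "ordinal", lam=0.8),
]
ds = simulate_regression_dataset(
    tree,
    betas=[0.0, 0.0, 0.07],
    lambda_res=0.0,
    predictor_spec=specs,
    seed=10,
    sigma2_res=0.05**2,
)

signal = run_signal_table([tree], ds.traits,
                          columns=["standard_length", "dnvn_organs", "night_depth"])
print("Pagel's lambda per trait (one resolved tree):")
print(signal[["trait", "lambda_hat", "p_vs_0", "p_vs_1", "kind"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print()

fit = pgls_fit(ds.tree, ds.traits, "response",
               ["standard_length", "dnvn_organs", "night_depth"])
print(fit.summary())
print()
print(f"true night-depth slope = 0.07; estimated "
      f"{fit.params.loc['night_depth', 'beta']:.3f} "
      f"(P = {fit.params.loc['night_depth', 'p']:.3g})")
print("note: the organ slope is truly zero; when its t-test comes out")
print("nominally significant on a single draw, that is a type-I error —")
print("over many simulated datasets its rejection rate stays near 5%.")
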