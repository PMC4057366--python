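# lanterneye

Tools for the quantitative visual ecology of deep-sea fishes: estimate
photoreceptor numbers from retinal wholemounts by optical-fractionator
stereology, map rod-density topography by Gaussian kernel smoothing,
compute optical sensitivity to downwelling light and bioluminescent
flashes, and run phylogenetic comparative statistics (Pagel's λ, PGLS)
on species trait tables. A synthetic-data module generates wholemounts,
phylogenies and trait tables with known ground truth, so the whole chain
is testable without microscope or specimen.

Written for researchers working on retinal topography and eye design in
fishes (lanternfishes being the motivating group), and for anyone needing
a tested, seed-reproducible reference implementation of this analysis
chain.

## The core quantities

**Optical fractionator.** With per-site counts Q_i from frames on a
systematic grid,

    N = ΣQ · (1/ssf)(1/asf)(1/tsf),    asf = frame area / grid-cell area,

with ssf = tsf = 1 for a flattened single-layer wholemount. Precision is
the Schaeffer coefficient of error CE = √(s²/n)/q̄, acceptable below 0.1.

**Topographic maps.** Site densities d_i are smoothed onto a raster by a
normalised Gaussian kernel with bandwidth σ equal to the grid step, masked
to the wholemount outline.

**Optical sensitivity.** Per photoreceptor, with F = 1.275 fixed by
Matthiessen's ratio (f = 2.55 × lens radius):

    S = (π/4)² (d/F)² (1 − e^{−kl})              [µm² sr, extended source]
    N = E (A²/16r²) e^{−αr} (1 − e^{−kl})        [photons, point source]

k = 0.035 µm⁻¹, E = 10¹⁰ photons, r = 1 m, α = 0.05 m⁻¹.

**Comparative statistics.** Pagel's λ scales the off-diagonal of the
Brownian covariance V; λ is fit by ML for continuous traits (profiled GLS)
and binary traits (2-state Mk by pruning), with LRTs against λ = 0 and 1
(df = 1). PGLS estimates β = (X′V(λ)⁻¹X)⁻¹X′V(λ)⁻¹y with ML λ on the
residuals. Trees are prepared by random polytomy resolution (10⁻⁶
branches) and Grafen's transform (ρ = 2.5).

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

`examples/01_wholemount_stereology.py` builds a retina with an arch-shaped
acute zone (background 400×10³, peak 800×10³ rods·mm⁻²), samples ~200
sites with a 10×10 µm frame on a 320×320 µm grid, and applies the
fractionator:

```
true total rods          : 12,255,517
fractionator estimate    : 12,064,768  (196 sites)
relative error           : -1.56%
mean density             : 601 x10^3 rods/mm^2
peak site density        : 1020 x10^3 rods/mm^2
Schaeffer CE             : 0.018  (acceptable below 0.1)
```

The estimate lands within 2% of the known truth with a CE an order of
magnitude inside the 0.1 rule; the raw site-level peak overshoots the true
field maximum (800×10³) because single-frame Poisson noise inflates a
maximum — the smoothed map peak from `examples/02_topographic_map.py` is
the stabler summary. The other examples cover topographic mapping of a
ring specialisation, the S/N sensitivity trade-off between a wide-rod
small eye and a thin-rod big eye, and λ/PGLS recovery of a night-depth
effect (β = 0.07) on a 53-species simulated phylogeny.

A thin CLI chains the stages on synthetic inputs:

```bash
lanterneye --seed 1 --out run1 all     # simulate → stereology → map → signal → pgls
```

## Layout

- `src/lanterneye/retina.py` — synthetic wholemounts and systematic sampling
- `src/lanterneye/stereology.py` — fractionator estimator and Schaeffer CE
- `src/lanterneye/topography.py` — kernel-smoothed density maps
- `src/lanterneye/optics.py` — sensitivity equations and conversions
- `src/lanterneye/phylo.py` — trees, Pagel's λ, PGLS, report tables
- `src/lanterneye/treesim.py` — simulated phylogenies and trait evolution
- `src/lanterneye/cli.py`, `config.py`, `io.py` — pipeline plumbing
- `examples/` — one narrative script per capability
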