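# npcroute

Single-molecule analysis of how transmembrane proteins cross the nuclear
pore complex (NPC).

Nuclear envelope transmembrane proteins (NETs) reach the inner nuclear
membrane by passing the NPC, either squeezing along the **peripheral
channels** (~41 nm from the pore axis) or — if a transport receptor can grab
them — detouring through the **central channel** (~25 nm radius).  High-speed
2D single-molecule localization microscopy records the projected (x, y)
positions of single tagged molecules inside the pore; because the pore is
rotationally symmetric, the 3D radial position of a transport route can be
recovered from those projections.  This package implements that analysis for
researchers working with SPEED-style localization data (or anyone who wants
to study the estimator itself on simulated ground truth):

* **Radial inversion** ("onion peeling"): the x-histogram of the projection
  satisfies the triangular system `A_j = 2 Σ_{i≥j} ρ_i s_ij`, where `s_ij`
  is the quarter-plane area of ring *i* within strip *j* (closed form via
  `∫√(R²−x²)dx = ½[x√(R²−x²) + R² asin(x/R)]`).  Back-substitution from the
  outermost ring recovers the radial density `ρ(r)`; a variance-weighted
  Gaussian fit of `ρ(r)` gives the route's peak radius and FWHM.
* **Route-precision Monte Carlo**: repeat simulate → invert → fit to measure
  how reproducibly a route radius is pinned down for a given number of
  localizations and single-molecule precision.
* **Localization model**: the moving-emitter precision
  `σ = √(F[16(s²+a²/12)/9N + 8πb²(s²+a²/12)²/a²N²])` with motion-blurred PSF
  `s = √(s₀² + D·Δt/3)`, Gaussian spot fitting on rendered frames, and the
  standard quality filters (>2000 photons, 0.5–1.0 px width).
* **Kinetics**: diffusion coefficients by MSD fitting (long tracks) and the
  jump-distance maximum-likelihood estimator (short tracks); INM:ONM
  population ratios from the axial histogram; FRAP recovery half-times; and
  the translocation-rate model
  `a₁F_mi = A(a₂F_mo) + B(a₁F_mi)`, `A/B = a₂F_mo·D_o / a₁F_mi·D_i`,
  `R = N_T·a₂·A / (a₃·2τ½·n_NPC)`.
* **Dual-channel co-tracking**: greedy one-to-one pairing of two-color
  localizations and the quadrature error budget `√(G_p²+R_p²+A_p²)`.
* **Eligibility classifier**: whether a NET's strong NLS (score ≥ 0.86) and
  a ≥65-residue intrinsically disordered run (0.45 nm/residue, enough to
  span the ~20 nm NPC scaffold) are arranged NLS → ID run → transmembrane
  anchor within one extraluminal domain.
* **Synthetic data**: seeded generators for ring routes, Brownian tracks,
  membrane populations, dual-channel pairs and PSF image stacks, all
  retaining ground truth — every stage is testable without any download.

## Worked example

```python
from npcroute import (estimate_route, invert_projection, route_precision_mc,
                      transport_rate, TransportRateInputs)
from npcroute.geometry import RouteModel
from npcroute.synthetic import simulate_route_localizations

# a peripheral-channel route observed with 10 nm localization error
table = simulate_route_localizations([RouteModel(mean_radius=41.0)],
                                     n=1000, noise=10.0, seed=7)
density = invert_projection(table, bin_width=2.0, n_bins=45)
route = estimate_route(density, loc_precision=10.0)
print(f"peak radius: {route.peak_radius:.1f} nm, FWHM: {route.fwhm:.1f} nm")

mc = route_precision_mc(41.0, n_locs=500, loc_precision=10.0, n_reps=100, seed=7)
print(f"route precision: {mc.precision:.2f} nm")

res = transport_rate(TransportRateInputs(
    a1=3, a2=1, a3=4, F_mi=0.2, F_mo=1.0, D_i=1.9, D_o=2.6,
    N_T=150_000, n_NPC=2000, tau_half=0.795))
print(f"A = {res.A:.3f}, R = {res.R:.2f} molecules/min/NPC")
```

prints

```
peak radius: 41.6 nm, FWHM: 22.3 nm
route precision: 1.64 nm
A = 0.475, R = 5.60 molecules/min/NPC
```

The fitted peak lands within the route precision of the generating 41 nm
radius; with 500 localizations at 10 nm single-molecule precision the route
itself is localized to better than 2 nm.  `A` is the fraction of
fluorescence recovery arriving from the outer membrane, and `R` the
resulting per-pore translocation rate for a wild-type-like parameter set
(150,000 copies, 2000 pores, 0.795 min recovery half-time).

The same stages are available from the shell:

```sh
npcroute simulate --radius 41 --n 1000 --noise 10 --seed 7 locs.csv
npcroute transform locs.csv density.csv
npcroute route-precision --radius 40 --n-locs 500 --loc-precision 10
```

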