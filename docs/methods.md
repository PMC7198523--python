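# Methods

## Coordinate system and geometry

All positions are in nanometres in a pore-centered frame: `x` transverse,
`y` along the nucleocytoplasmic axis (outer nuclear membrane at +20 nm,
inner at −20 nm), `z` the unobserved depth axis.  The NPC is treated as
rotationally symmetric about the y axis with a ~25 nm central-channel
radius, peripheral channels at ~41 nm radial distance, the nuclear envelope
lumen reaching ~68 nm, and a ~20 nm-thick scaffold between central and
peripheral channels.  These defaults live in `NPCGeometry` and match
cryo-EM consensus values; nothing downstream hard-codes them.

## Localization model

A moving fluorescent emitter localized by Gaussian fitting has precision

σ = √( F · [ 16(s² + a²/12)/(9N) + 8π b² (s² + a²/12)² / (a² N²) ] ),
s = √(s₀² + D·Δt/3),

with excess-noise factor `F` (2 for EM-CCDs), collected photons `N`,
effective pixel size `a` (nm), background sd `b` (photons/pixel), in-focus
PSF sd `s₀` (nm), diffusion coefficient `D` (µm²/s, converted internally at
10⁶ nm²/µm²) and frame time `Δt` (s).  At the experimental operating point
(`N`=2000, `a`=240, `b`=2, `s₀`=150, `D`=1, `Δt`=0.4 ms) σ ≈ 7.0 nm, and σ
stays below 10 nm over the full stated ranges (s₀ 100–200 nm, D 1–3 µm²/s);
the worst corner is 9.06 nm.

`fit_spot` fits an erf-integrated symmetric Gaussian plus constant offset by
unweighted least squares — integrating the PSF over pixel areas rather than
sampling at pixel centers makes the fit model identical to the renderer's
forward model, so noiseless spots are recovered exactly and the photon
parameter is the integrated signal directly.  The quality filter keeps rows
with photons strictly above 2000 and PSF width inside the closed interval
[0.5, 1.0] px; the filter is applied per localization row.

The renderer (`render_spot_stack`) adds per-pixel Gaussian fluctuations with
variance `F` times the pixel mean — the Gaussian limit of photon counting on
an excess-noise detector — plus `N(0, b)` background.  With this noise the
empirical scatter of fitted centroids matches the σ formula to a few
percent.  Not modelled: EMCCD gain registers, read-out quantization,
astigmatic 3D PSFs, photobleaching.

## Centering

The pore center is estimated from a marker image (2D Gaussian fit) when
available, then refined on the localization histograms (default 5 nm bins).
The x histogram of a ring-shaped route may be unimodal or a mirrored pair of
peaks, so both a single Gaussian and a mirrored two-Gaussian model sharing a
symmetry axis are fitted and the lower residual sum of squares wins; the y
histogram gets a single Gaussian.  The reported uncertainty is the
quadrature of the two center parameter errors.

## 2D→3D radial inversion (onion peeling)

For a rotationally symmetric density the x histogram of the (x, y)
projection equals the x histogram of the (x, z) cross-section.  Binning the
cross-section into concentric rings of width Δ and strips of the same width
gives

A_j = 2 · Σ_{i≥j} ρ_i · s_ij,

where `s_ij` is the quarter-plane (x ≥ 0, z > 0) intersection area of ring
*i* with strip *j*, computed in closed form from
Q(R, x₁, x₂) = ½[x√(R²−x²) + R²·asin(x/R)] evaluated at the strip edges,
clipped to x ≤ R.  `A` is the folded |x| histogram inside a configurable
axial window (default y ∈ [−40, 40] nm), and the triangular system is solved
by back-substitution from the outermost ring inward.  Under this convention
ρ is the density of the z-folded half plane (counts/nm²); peak positions and
widths are unaffected by the overall scale.

Design choices:

* **Bin width** defaults to 2 nm, small enough to resolve the ~12 nm FWHM
  peripheral channels; results are stable under halving/doubling (tested).
* **Negative densities** — noise-driven — are clipped to zero with a logged
  count (default); `negativity="none"` keeps them and `"nnls"` replaces
  back-substitution with nonnegative least squares.  Plain back-substitution
  is exact for any density that is uniform within each ring; a density
  concentrated at a sub-bin feature (e.g. an exact-radius ring) violates
  that assumption and produces alternating-sign ringing, which the NNLS mode
  suppresses.
* **Folding**: the factor 2 presumes left/right symmetry after centering.
  `fold=False` inverts the two half planes separately (their difference is
  an asymmetry diagnostic) and averages them.

## Route peak estimation

Onion peeling amplifies Poisson counting noise strongly toward the
innermost rings (the inner bins are reached after the longest chain of
subtractions, and their ring/strip areas are smallest).  At realistic sample
sizes (500–1000 localizations) the recovered ρ therefore has spurious
central spikes whose amplitude rivals the true route peak, and a naive fit
around the global maximum is unusable.  `estimate_route` instead:

1. propagates the counting uncertainty through the solver,
   Cov(ρ) = M⁻¹ diag(A) M⁻ᵀ with M = 2 Sᵀ, and uses the per-bin sds as
   weights in a weighted least-squares Gaussian fit of ρ against the ring
   bin centers;
2. starts the fit from each local maximum of a 1-2-1-smoothed profile (top
   three by height and top three by signal-to-noise; ties broken toward the
   larger radius) and keeps the start with the smallest weighted residual;
3. reports the fitted mean as the peak radius and 2√(2 ln 2)·sd as the FWHM.

`window_bins` optionally restricts the fit to a window around the peak; the
default uses the full profile, which is what makes the fit stable at small
sample sizes.

**Noise correction.**  A ring of radius R observed with isotropic
localization error σ has radial density ∝ exp(−(r²+R²)/2σ²)·I₀(rR/σ²),
whose maximum sits at r = R·I₁(rR/σ²)/I₀(rR/σ²) — about 1.3 nm inside R at
R = 40, σ = 10.  When the caller supplies `loc_precision`, the fitted peak
is mapped back to the generating radius by inverting this relation
(Brent root find; falls back to the uncorrected value if the relation
cannot be bracketed, which happens only when the peak is comparable to the
noise scale).  With the correction the Monte-Carlo mean peak is within 1 nm
of the generating radius across 20–70 nm at n = 500, σ = 10 nm.

**Route precision.**  `route_precision_mc` repeats simulate → invert → fit
`n_reps` times (default 100, per-rep seeds spawned from one seed) and
reports the sd of the fitted peaks.  At the standard study conditions —
500 localizations, 10 nm precision, 40 nm route — the precision is ~1.6 nm,
under the 2 nm working bound; at 100 localizations it degrades to ~9 nm.

## Diffusion, membrane ratios, FRAP, translocation rate

* **Diffusion.**  Tracks longer than 6 frames go to a weighted linear fit of
  MSD(lag) = 4·D·lag·Δt + c over lags 1–4 (free intercept absorbs
  localization error; weights follow the number of displacement pairs per
  lag).  Tracks of 2–6 frames go to the jump-distance estimator: 2D Brownian
  jumps are Rayleigh, and the maximum-likelihood D is Σδ²/(4·n·Δt), unbiased
  to <2% at 10⁴ jumps (tested).  `combined` averages the two.  The MSD
  stderr is taken from the between-track spread of per-track estimates
  because MSD values at different lags reuse the same displacements and the
  regression covariance understates the error.
* **Membrane ratio.**  Two-Gaussian fit to the y histogram initialized at
  ±20 nm; each membrane's population is the count inside its peak's FWHM
  window, and the ratio is INM:ONM.  Peaks whose separation does not exceed
  the sum of their half-FWHMs raise an error rather than returning a
  meaningless ratio.
* **FRAP.**  I(t) = I₀ + (I∞−I₀)(1−e^(−kt)); τ½ = ln 2/k in the units of the
  time axis; mobile fraction (I∞−I₀)/(I_pre−I₀).  Non-recovering curves
  (k ≤ 0) are rejected.
* **Translocation rate.**  With u = a₂F_mo and v = a₁F_mi the recovery
  partition equations have the closed form A = uvD_o/(u²D_o + v²D_i),
  B = v²D_i/(u²D_o + v²D_i); both defining equations are re-checked to
  10⁻¹⁰ after the solve.  R = N_T·a₂·A/(a₃·2τ½·n_NPC): the per-pore
  normalization divides by the pore count because the rate is reported as
  molecules·min⁻¹·NPC⁻¹.  The diffusion-corrected concentration ratio and
  τ½ are inputs, not recomputed — the upstream correction belongs to the
  smFRAP method itself, and recovery half-times are experiment-specific.
  The ONM mobile fraction defaults to 1 in examples (ONM pools exchange
  freely with the ER); the INM mobile fraction is 1 minus the INM
  immobilized fraction.
* **Ratio correction.**  `correct_ratio` scales a mobile-pool ratio back to
  total pools, final = ratio·F_mo/F_mi, with rounding to two significant
  figures deferred to reporting.

## Dual-channel co-tracking

Channels are paired per frame (optionally across a small frame gap) by
greedy nearest-neighbor in ascending distance under a separation cap
(default 60 nm, covering the 25↔44 nm two-terminus geometry plus noise);
each localization is used at most once.  The co-tracking error is the
quadrature sum √(G_p² + R_p² + A_p²) of the two channel precisions and the
registration error — 19.85 nm (<20 nm) at the stated 12/15/5 nm budget.
Reported separations are projected 2D distances; no 3D inference is
attempted on pairs.

## Eligibility classifier

A NET can use the central channel if, within one extraluminal domain, a
strong NLS (score ≥ 0.86) is followed by an intrinsically disordered run
long enough to span the ~20 nm scaffold — ≥65 residues at 0.45 nm/residue
extended backbone length — ending at the transmembrane anchor (mirrored for
N-terminal anchors).  Disorder calls come from a meta-predictor track and
are vetoed wherever a secondary-structure predictor calls structure; the
default vetoes on *either* predictor (strictest reading), with an
`"all"`-predictors mode available.  ID runs are maximal runs of qualifying
residues; `max_gap` (default 0) optionally tolerates short interruptions.
Categories are exclusive: `Both` requires NLS, ID run and arrangement; a
record with both features but a failing arrangement is reported `NLS-only`
(the receptor site remains functional; a mis-placed ID run cannot aid
central-channel transit).  All predictor tracks are inputs — NLS, disorder
and secondary-structure prediction are out of scope.

## Synthetic data: what it does and does not emulate

The generators reproduce the statistical structure the estimators assume:
cylindrically symmetric ring routes (uniform azimuth, truncated-normal
radial spread, uniform axial extent, default ±40 nm), isotropic Gaussian
localization error (from a fixed sd or the σ formula), Brownian tracks with
per-axis steps N(0, √(2DΔt)), two-membrane axial mixtures, azimuth-sharing
dual-channel pairs with a fixed-direction registration offset, and
erf-integrated PSF frames with excess-noise shot noise.  They do **not**
emulate sample drift, out-of-focus light, multi-emitter overlap, dark
states/photobleaching, anisotropic or depth-dependent PSFs, or non-Brownian
motion — so passing tests demonstrate estimator correctness under the
stated model, not robustness to every artifact of real recordings.  All
generators take explicit seeds and retain ground truth columns.

## Problem sizes and tolerances

Monte-Carlo tests use 100 repetitions (matching the standard
route-precision protocol) at 500 localizations; distributional checks use
10⁴–10⁶ samples where a closed form is available.  Inversion round trips
are exact to solver tolerance (triangular system, no regularization);
equation residuals in the rate model are enforced at 10⁻¹⁰; stochastic
recoveries are asserted at 3 standard errors or the explicitly stated
bounds (2 nm route precision, 2% estimator bias, 10% ratio recovery).
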