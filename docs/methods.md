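# Methods

This note documents the models, estimators and numerical choices behind
`cortexflow`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Particle simulation

Membrane particles move in a 2D plane (the membrane seen in near-TIRF
projection). Per frame of interval Δt each particle takes an isotropic
Gaussian step of per-axis variance 2·D_i·Δt plus a deterministic advective
offset v·Δt. The per-particle diffusivity D_i is drawn once per particle;
with a nonzero coefficient of variation `cv_D` it is log-normal with the
requested mean and CV — the log-normal is chosen because it guarantees
positive diffusivities at any CV, which a normal distribution cannot.
With `cv_D = 0` all particles share D.

Membrane turnover keeps the particle number per frame exactly constant:
each particle carries an exponential lifetime (rate `k_off`), and on
dissociation its slot is immediately taken by a new particle id at a
uniform-random position — an implicit association flux equal to the
dissociation flux. A particle visible in a frame whose lifetime ends
before the next frame is replaced starting at that next frame, so
occupancy is exactly `n_particles` in every frame and tracks are
contiguous. Particles are not reflected at the nominal field edge; the
renderer instead grows the image to the largest excursion plus a 6-pixel
margin, so no spot is ever clipped.

Rendering places a symmetric Gaussian of width `psf_sigma` (default
1.3 px, a typical high-NA PSF at ~0.1 µm/px sampling) and amplitude
`spot_amplitude` at each subpixel position on a Gaussian-noise background.
Defaults (100 particles, Δt = 0.1 s, 0.1 µm/px, background 100 ± 5
counts, spots 200 counts) give an SNR regime in which the tracking stage
recovers ground truth comfortably; they are package choices validated
through estimator-recovery tests, not measured camera statistics. The
renderer deliberately omits EMCCD gain statistics, Poisson shot noise and
photobleaching: tests validate estimator logic, not camera physics, so
passing tests bound estimator bias under clean conditions only.

The cortex channel is emulated by a fixed Gaussian-smoothed speckle
texture advected frame-to-frame by a prescribed flow field (backward warp,
bicubic interpolation, fresh additive noise per frame). It reproduces the
texture-following property PIV needs, not the appearance or turnover of a
real actomyosin cortex (real cortical texture remodels; the synthetic one
only moves).

## Spot detection and linking

Detection follows the Crocker–Grier scheme: a bandpass (Gaussian smoothing
at 1 px minus a boxcar background at the feature size), local maxima above
a user threshold, then iterative intensity-weighted centroid refinement
within the feature window (≤ 10 iterations, 10⁻³ px convergence).
Detections closer than the minimum separation merge to the brighter one.
The intensity threshold is a required user parameter — appropriate values
depend on imaging conditions and must be chosen per dataset.

Linking minimises the total squared displacement per frame pair over
candidate pairs within the per-frame displacement limit, solved exactly
with the Hungarian algorithm on an augmented cost matrix in which leaving
a particle unmatched costs the squared displacement limit. Exact distance
ties resolve deterministically through the fixed candidate ordering
(lower particle id first). With `memory = 0` an unmatched particle
terminates its track; gap closing is not implemented beyond the parameter.
Tracks shorter than `min_track_length` (default 11 frames) are discarded.

## PIV

The cortex stack is bleach-normalised (each frame rescaled to the first
frame's mean — a deliberate, simple stand-in for whatever bleach model the
data warrant), optionally rolling-time-averaged (default 2 frames), and
high-pass filtered (default size 10 px). Two interrogation passes (64 then
32 px windows) estimate displacements from the FFT cross-correlation peak;
the second pass offsets the search window by the rounded first-pass
estimate. Two bias corrections matter for accuracy: windows are zero-padded
to twice their size so the correlation is linear rather than circular, and
the correlation is divided by the per-lag overlap count, removing the
triangular taper that otherwise pulls broad peaks toward zero lag. The
peak is refined per axis with a 3-point Gaussian fit (falling back to a
parabolic fit when the triplet is not positive). These simplifications
replace full window deformation, which only matters under strong shear;
recovery on rigid and mildly sheared synthetic flows is accurate to
well under 0.05 px/frame.

Post-filters run in a fixed order: the velocity limit (default
0.3 px/frame) first, then the per-frame 5-SD filter; rejected vectors are
replaced by linear interpolation from valid neighbours (nearest-neighbour
at the hull edge) and flagged in the validity mask. The filter pass is
idempotent. The final field has a vector every 16 px; lookups use bicubic
spatial interpolation and nearest-frame temporal lookup (the rolling
average has already smoothed time). Queries up to one inter-frame spacing
beyond the sampled times clamp to the nearest frame, because PIV
timestamps sit at frame-pair midpoints while trajectories start at frame
times.

Note the default 2-frame rolling average assumes sub-pixel per-frame
motion (as in real data); at multi-pixel per-frame displacements it mixes
correlation peaks and should be disabled.

## Advection statistics

Each in-track displacement of lag τ (default 5 frames for advection, 2
for diffusion) is rotated into the frame of the local flow vector sampled
at the step's start. The pooled Δx (parallel) and Δy (perpendicular)
distributions are Gaussian; υₓ = ⟨Δx⟩/τ, υ_y = ⟨Δy⟩/τ, and
cc = υₓ/ν̄ with ν̄ the mean local flow speed over exactly the steps being
fitted (chosen so the normalisation weights match the sample entering the
fit). Steps where the local flow speed is below 0.01 µm/s are flagged and
excluded from coupling fits — the flow direction is undefined there. With
ν̄ = 0 the cc is reported as missing, never as 0.

The primary Gaussian fit is the unbinned maximum-likelihood one (sample
mean/SD); a binned least-squares histogram fit is computed alongside as a
cross-check. The two estimate the same parameter and agree to well within
one standard error on Gaussian data; they are not identical estimators,
so equality is asserted at the one-standard-error level, not to machine
precision.

Diffusivity uses ⟨d²⟩ = 4·D_ss·τ in 2D, or ⟨Δy²⟩ = 2·D_ss·τ
(perpendicular-only) whenever a flow is active, so drift cannot inflate
the estimate. Displacements from overlapping windows within one track are
correlated; pooled estimates remain unbiased but their naive standard
errors understate uncertainty — benchmarks in this package therefore use
one displacement per particle where independence matters.

Detection power is computed exactly as a drift-detection experiment: per
replicate, n displacements with drift v·τ in x and none in y
(variance 2Dτ per axis), compared by an unpaired two-tailed t test.
Two summaries are available: the per-replicate detection boundary
(majority of replicates individually significant), which sits near
D ≈ 0.3 µm²/s at n = 1000, τ = 0.5 s, v = 0.1 µm/s; and the
pooled-replicate limit (10 replicates combined into one test), which
extends detectability several-fold beyond that.

## Polarity PDE

Single species on x ∈ [0, L], L = 60 µm, x measured from the anterior
pole:

    ∂A/∂t = D ∂²A/∂x² + ∂(vA)/∂x + k_on·A_cyt − k_off·A
    A_cyt  = ρ_A − ψ·Ā

with ρ_A = 1.56 µm⁻³, ψ = 0.174 µm⁻¹ and k_on = k_off by default. The
+∂x(vA) sign convention means positive v carries membrane mass toward
x = 0 (the anterior). The flow profile

    v(x) = ((60−x)/74)·exp(−(60−x)²/391) − (x/1000)·exp(−x²/100)

vanishes at both poles and peaks at ≈ 0.115 µm/s near x = 46 µm, matching
observed cortical flow speeds (~0.1 µm/s). Flow is active for t_flow
(default 500 s, the establishment phase), then set identically to zero for
t_post (default 1500 s). The initial condition is the uniform equilibrium
A* = k_on·ρ_A/(k_off + k_on·ψ) (= ρ_A/(1+ψ) = 1.3288 when k_on = k_off).

Discretisation is a conservative finite volume on 400 cells
(Δx = 0.15 µm): total face flux F = −D·∂A/∂x − v·A with second-order
central interpolation of the face concentration, automatically re-solved
with first-order upwinding if negativity beyond 10⁻⁸·ρ_A ever appears
(it does not at the parameter ranges exercised here; upwinding changes the
reference peak ASI by < 5% and is kept strictly as a fallback). Boundary
faces carry zero flux — natural and exactly mass-conserving since
v ≈ 0 at both poles; the cytoplasmic pool is algebraic, so
ψ·Ā + A_cyt = ρ_A holds to machine precision. Doubling the grid changes
the reference peak ASI by < 0.1%.

Time integration is adaptive (rtol 10⁻⁸, atol 10⁻¹⁰): explicit
Runge–Kutta (RK45) by default, switching automatically to LSODA when the
diffusive stability limit would force more than ~5·10⁴ explicit steps
(large D and long horizons in phase-diagram sweeps); the two agree to
solver tolerance where both run.

**Metric conventions.** Pole means are taken over the anterior- and
posterior-most 30% of the domain. Two ASI conventions circulate; this
package defaults to ASI = (A−P)/(2(A+P)), whose maximum of 0.5 at a fully
cleared posterior matches the scale on which the model's reference
predictions (~0.25 for PAR-2-like parameters) and near-maximal
experimental values (~0.5) are quoted; the (A−P)/(A+P) variant is
available via `convention="full"`. Depletion defaults to 1 − P/⟨I⟩
(1 = complete posterior clearance); the raw ratio P/⟨I⟩ is available via
`convention="ratio"`. Peak values are read at t = t_flow (growth during
flow is monotone, so this equals the max over time; both are recorded).
The decay half-time t½ is the first post-flow crossing of half the
end-of-flow value, linearly interpolated between saved outputs (1 s
apart); an exponential-decay fit (t½ = τ·ln 2) is reported as a
cross-check and agrees within ~10–25% — the decay is not exactly
exponential, which is why the first-crossing definition is primary. A
metric that never halves within the simulated window reports t½ = inf.

**Two-state extension.** Two membrane fields share one cytoplasmic pool;
the binding flux k_on·A_cyt splits `fraction_fast` : (1 − fraction_fast)
between a fast state (k_off,fast, default 1 s⁻¹) and a slow state
(k_off,slow), keeping the total binding rate at the single-species
reference. At a uniform steady state the membrane shares follow the
occupancy weights f/k_off — e.g. slow binders making up 1% of binding
events at k_off,slow = 10⁻³ s⁻¹ hold 91% of the membrane pool — and the
response to flow is dominated by the slow species.

## Membrane quantification

Cross-sections of straightened membrane images (rolling-averaged 20 px
along the membrane) are fitted to a Gaussian (membrane) plus an
error-function step (cytoplasm):

    I(d) = a·exp(−(d−c)²/2w²) + p·(1 − erf((d−c)/√2·w))/2

with the centre c and width w shared between components — the sharing is a
stabilising choice (the exact linkage is not dictated by the physics) and
is recorded in the fit output; the convention places the cytoplasm on the
low-d side. Membrane concentration = Gaussian amplitude a; cytoplasmic
concentration = plateau p. Non-convergent positions are flagged and
interpolated from neighbours. Segregation metrics reuse the PDE-side
conventions, so image-side and model-side ASI are directly comparable
(round-trip agreement < 3% on synthetic profiles). Straightening itself
(from raw embryo images) is out of scope; inputs are straightened
matrices.

FRAP curves are normalised by the control region, then by the pre-bleach
mean, and fitted to I(t) = I₀ + P·(1 − e^(−t/τ)) with τ = 1/k_off; the
free post-bleach baseline I₀ absorbs incomplete bleaching. The 95% CI on
τ comes from the fit covariance (asymptotic normality; coverage ≥ 90% on
synthetic noisy curves). Curves recovering by less than 2% of the
pre-bleach level are flagged degenerate rather than fitted.

## Pipeline and reproducibility

One global seed fans out to per-stage substreams via `SeedSequence`
(stage-indexed spawn keys, all derived seeds < 2³¹), so editing one
stage's workload never perturbs another's randomness. Every run report
embeds the fully resolved configuration, per-stage seeds and package
version. Identical seeds give byte-identical trajectory tables and
reports.

## Problem sizes

Benchmarks use sizes chosen to make sampling error small relative to the
assertions while keeping the suite quick on one CPU: the PDE reference
runs on 400 cells over 2000 s (seconds per solve); coupling-coefficient
recovery uses 1,000 independent displacements (one lag-5 step per
particle) × 20 replicate simulations per diffusivity; detection power uses
1,000 displacements per replicate with 10-replicate pooling over 20
experiments; FRAP coverage uses 200 noisy repeats.

## Known limitations

- The simulator's advection is a uniform deterministic drift per step; it
  does not model spatially varying flow within one particle's step.
- PIV omits linear window deformation; strong shear within a 32-px window
  biases vectors.
- The PDE is single-compartment 1D with no feedback, by design — it
  isolates the roles of D and k_off and cannot capture
  mutual-antagonism-stabilised polarity.
- The FRAP model is one-component; mixed fast/slow recoveries will fit an
  intermediate τ.
- Synthetic fixtures validate estimator correctness under the stated
  noise models, not performance on real embryo imagery (autofluorescence,
  embryo motion, heterogeneous backgrounds are absent).
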