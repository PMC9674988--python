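# Methods

This note documents the models, estimators and conventions implemented in
`permawh`, the choices made where the design was genuinely open, and what
the bundled synthetic systems do and do not establish about real membranes.

## Units, temperature and thermodynamics

The simulation core works in kJ mol⁻¹ (energy), nm (length) and ps (time);
masses are reduced units with a default of 1.  Temperature defaults to
305.15 K (skin temperature), giving kT = 2.5372 kJ mol⁻¹ and
β = 0.39414 mol kJ⁻¹.  Conversion to the reporting unit cm h⁻¹ happens only
at the permeability boundary (1 nm ps⁻¹ = 3.6×10⁸ cm h⁻¹).

## Toy landscapes

A landscape lives on z ∈ [0, L] (default L = 5.21 nm, a lamellar
half-period) with reflective walls by default (the half-system picture with
mirror symmetry about the bilayer center); periodic boundaries are available
by configuration.  The fully coupled permeant–environment interaction is a
sum of Gaussian barriers (positive) and wells (negative) on top of a
constant solvent plateau, plus optional orientation (θ) terms:

* a **global orientation barrier** `theta_barrier · sin²θ` — in a gel-like
  environment reorientation is hindered everywhere, not just in one spot;
* **orientation traps**: inside a Gaussian envelope along z, a well
  `−depth · (1 + cos(θ − phase))/2` binds a particular orientation; traps in
  different regions may favour opposite orientations.

The default membrane echoes a lamellar skin-barrier PMF qualitatively: the
main packing barrier (25 kJ mol⁻¹ at z = 2.1 nm), a head-group barrier
(15 kJ mol⁻¹ at 3.2 nm), a trapping well (−10 kJ mol⁻¹ at 0.8 nm) and a
solvent plateau (−5 kJ mol⁻¹ beyond ≈4.4 nm).  These are *shape* choices,
not fitted values.

### Alchemical coupling

A single scalar λ ∈ [0, 1] scales all permeant–environment terms
simultaneously (21 equidistant states by default; index 0 fully coupled,
the last fully decoupled).  Barrier-type (repulsive) terms P are coupled
through an energy-space soft-core transformation derived exactly from a
Beutler-style inverse-12th-power model pair term,

    S(P, λ) = (1 − λ) P / (1 + α λ √(P/ε_sc))²,

with α = 0.5 and ε_sc = ε₀ (σ₀/σ)⁶ (ε₀ = 2.5 kJ mol⁻¹, σ₀ = 0.3 nm): larger
soft-core σ lowers the cap (1−λ)ε_sc/(αλ)², as in the distance-space
transformation.  Attractive/well/plateau terms scale linearly with (1 − λ).
Because every coupled term carries the factor (1 − λ), the decoupled end
state is *exactly* constant in z and θ — the vacuum reference that makes
the PMF directly calibratable against the solvation free energy.  The λ
dependence between the end states is a property of this model, not a claim
about any particular force field.

### Quadrature oracles

`reference_pmf` integrates the Boltzmann factor over θ at each z (periodic
trapezoid, resolution doubled until converged to 10⁻⁸ kT; non-convergence
raises with a tolerance report).  With `umbrella_k` set it instead returns
the free energy of the harmonically restrained reference states, i.e. what
an umbrella-based sampler estimates; the z-integration is truncated to
[0, L] so the outermost reference points are treated with the same
reflective-wall statistics the sampler sees.  `reference_solvation` is the
partition-function ratio of the coupled and decoupled states at a
solvent-plateau position.

## Dynamics

BAOAB velocity-Langevin integration with exact Ornstein–Uhlenbeck velocity
updates; dt = 0.003 ps and a thermostat time constant τ_t = 2 ps (friction
γ = 1/τ_t = 0.5 ps⁻¹) by default.  Fluctuation–dissipation holds for any γ,
so the same integrator serves the underdamped default and the overdamped
(τ_t = 0.02 ps) settings used when a position-local diffusion coefficient
must exist analytically (D = kT/(mγ) on a flat landscape).  Reflection at
the walls flips the velocity; θ wraps periodically.

## The AWH sampler

Each walker carries continuous (z, θ) coordinates plus a reference point
(z-bin, λ-index).  Between Monte-Carlo moves the walker follows Langevin
dynamics on the Hamiltonian of its current λ state plus the harmonic
umbrella k/2 (z − z_ref)² (k = 25,000 kJ mol⁻¹ nm⁻² by default; the toys
use softer umbrellas, see "Problem sizes").  Every `mc_interval` (10) steps
the reference point is resampled by an exact Gibbs move over all λ states
and the z-bins within 4σ_umbrella of the walker (σ_umbrella = √(kT/k)),
with weight

    w(m) ∝ ρ(m) · exp(β f(m)) · exp(−β [k/2 (z − z_m)² + U(z, θ, λ_m)]),

where ρ is the target distribution and f the shared free-energy estimate.
An accepted λ move switches the walker's Hamiltonian instantaneously
(expanded-ensemble convention).  The normalized weight vector itself (not
just the selected point) is accumulated as the sample — a Rao-Blackwellised
assignment equivalent to the Gaussian-umbrella-kernel point weighting.

### Update rule

Every `samples_per_update` (10) Gibbs samples per walker, the pooled weights
ΔW update the shared estimate:

    f(m) ← f(m) − kT · ln[ (N ρ(m) + ΔW(m)) / (N ρ(m) + n ρ(m)) ],

with n = ΣΔW and N the reference weight-histogram size.  The expected
update vanishes when the sampled marginal equals ρ; its magnitude scales as
1/N.  After every update f is re-anchored so its minimum over the target
support is zero.

### Histogram size, covering and stages

The initial histogram size is set indirectly from an error estimate:

    N₀ = (kT / ε₀)² · τ_cross / Δt_sample,

with ε₀ the initial error (default 10 kJ mol⁻¹), Δt_sample the Gibbs
sampling interval, and τ_cross the slower of the expected crossing times
L²/(2 D_z) and 1/D_λ implied by the input diffusion constants.  Larger
initial error or faster input diffusion ⇒ smaller N₀ ⇒ larger first
updates.  The input diffusion constants only set N₀; they never enter the
estimated diffusion profile.  (With the production value
D_λ = 10⁻³ ps⁻¹ the implied λ-crossing time is 1 ns, which the run metadata
reports.)

In the **initial stage**, a covering event multiplies N by 3 and the stage
ends when the covering-grown N overtakes the accumulated sample count; a
run that never covers stays in the initial stage indefinitely (this is
exactly how a 1D run on a slowly relaxing system fails).  Covering requires
the union of *qualifying* walkers to have visited every target-supported
grid point, where a walker qualifies only if it individually traversed all
supported λ states (flag, on by default) and spanned a spatial diameter of
at least 0.8 nm since the last covering; covering resets the per-walker
extents.  In the **final stage** N grows by the sample count per update, so
late errors damp as (new samples)/N.

### Targets and symmetrization

The spatial target is uniform; the λ target puts extra weight on the end
states, most on the fully interacting one (defaults 4:1:…:1:2; the gel
comparison uses 6:1:…:1:2).  With `symmetrize` on, the accumulated weights
are mirror-averaged about the grid center before each update — with
reflective boundaries the mirrored configuration is equally probable on a
symmetric landscape, which is the boundary-weight convention adopted here;
the symmetrized estimate is exactly even.  Profile-level symmetrization
averages mirror-paired free energies and is idempotent.

### Walkers, seeds and determinism

All walkers share one bias ("communicating") and are advanced in lockstep
by a compiled kernel.  Every walker owns a counter-based RNG stream keyed
by its own seed, so walker i's noise is independent of how many walkers
run; identical seeds give bit-identical results.  There is no hidden global
RNG.

## Friction metric and diffusion profiles

The local friction is the integrated autocovariance of the umbrella pull
force conditioned on the grid point,

    g(z) = β² ∫₀^∞ ⟨δF(t) δF(0)⟩_z dt,   D(z) = 1/g(z),

estimated by blocked sums over `n_blocks` (128) contiguous time blocks with
no windowing: per bin, Σ_b S_b²/(2 Σ_b T_b), where S_b sums (F − ⟨F⟩_z) dt
over the block.  On a flat landscape this recovers the free Langevin value
D = kT/(mγ) (the convention fixing the β factors), and for an
Ornstein–Uhlenbeck force it recovers σ²τ_c.  Two sample-assignment variants
are provided:

* **Reference-bin assignment** (`accumulate_friction`, the per-series
  default): each sample belongs wholly to its current reference bin.
  Accurate when reference hops are rare compared with the force correlation
  time; frequent hopping chops the series and biases D upward.
* **Gibbs-weighted assignment** (`friction_from_run`, used by the
  pipeline): every sample contributes to nearby points with its normalized
  Gibbs weight share ω, accumulated in-run as blocked sums of ωF dt, ω dt
  and ω² dt.  For a Gaussian umbrella kernel in the quasi-static diffusion
  limit the correct normalization of the blocked variance is the
  squared-weight occupancy Σω² dt (it reduces to the plain occupancy for
  hard 0/1 assignment); with the plain occupancy the estimator would be
  biased by the geometry factor Δz/(2σ√π).

Friction is accumulated from the whole run including the initial stage (an
exclusion flag exists), restricted by default to the fully coupled λ state.
The friction data stay per-walker — the bias is shared but the friction is
not — so one multi-walker run yields a cross-walker standard error; walker
profiles are combined by an occupancy-weighted mean on the friction scale.
Unsampled bins stay missing (NaN), never zero-filled.  A centered rolling
median (0.2 nm production default; 0.5 nm on the coarse toy grids) removes
single-bin spikes; the outermost reflective-wall bins systematically
overestimate D (boundary-shortened correlations) and are handled by the
median filter and by excluding two edge bins from recovery statistics, the
same role the PMF edge-spike trimming plays.

## Permeability pipeline

Sign conventions: the solvation free energy is *coupled minus vacuum*
(negative in a good solvent), ΔG_solv = f(λ=0) − f(λ=last) on the solvent
plateau.  A vacuum-referenced PMF (f(z, λ=0) minus the mean of the flat
decoupled slice) is calibrated by subtracting ΔG_solv, making the profile
≈0 wherever the environment equals the reference solvent.  An additive
constant then shifts the profile so it is never below zero, and the two
outermost points on each side may be replaced by their inner neighbours'
values (edge-spike removal).  The resistance integral is a composite
trapezoid on the PMF grid (Simpson by flag), with the diffusion profile
interpolated linearly when grids differ beyond 10⁻⁹ nm (with a warning);
missing D inside the range is an error.

Layer scaling: R_total = N·R with N = 12(±0.4) × 2.5(±0.5) = 30(±6.08…);
the delta-method SE of the product is √((2.5·0.4)² + (12·0.5)²) and
rounding to "±6" happens only at reporting.  log₁₀K_P obeys
log₁₀K_P(N) − log₁₀K_P(1) = −log₁₀N exactly; assuming ~80 layers instead of
1 subtracts log₁₀80 ≈ 1.9.  Uncertainty on log₁₀K_P combines the
layer-count term N_SE/(N ln 10) with an optional profile term, either by
first-order propagation assuming independent bins or by Monte-Carlo
resampling of the profiles within their SE — whether set-to-set spread or
within-set statistics should enter the reported uncertainty is a modelling
choice, so both are provided and labelled.  Averaging PMFs over independent
simulation sets gives per-bin means and SEs; a single set yields no SE
(a shared bias does not give a reliable error estimate from one set) and
triggers a warning.

## What the synthetic systems do and do not show

The toys emulate the *structure* of the problem: a multi-well periodic
free-energy profile with solvent plateaus, an alchemical axis whose
decoupled end is environment-independent, slow orthogonal degrees of
freedom that gate sampling while coupled, and reflective half-system
geometry.  They deliberately do not emulate: molecular detail (atoms,
force fields, electrostatics), realistic diffusion coefficients
(~10⁻⁵ nm² ps⁻¹ in a gel vs ~10⁻¹–10⁰ here — which is why the toy
configurations set the AWH input diffusion to the toy's honest scale),
anisotropic or z-dependent intrinsic friction, or lateral pathways.
Passing tests therefore establish the correctness of the estimators and
the qualitative sampling phenomena (alchemical shortcut, covering failure
modes, edge artifacts), not quantitative skin permeabilities.

Two deliberate toy calibrations, fixed once:

* **Gel toy** (2D-vs-1D comparison): global orientation barrier
  12 kJ mol⁻¹ — measured flip interval ≈500 ps at full coupling versus a
  spatial crossing time of tens of ps, and instant at decoupling — with
  opposite-phase orientation wells at 0.8 nm (−10) and 3.0 nm (−8), so a
  sampler stuck in either orientation mis-estimates part of the profile.
* **Slow-mode toy** (diffusion-vs-length trend): two *overlapping*
  opposite-phase traps keep the region between them populated in both
  orientation states while the local mean force flips sign slowly; longer
  runs (longer autocorrelation blocks) therefore capture more of the slow
  force component and the estimated D falls monotonically.  In the gel toy
  proper this trend is weak, because the Gibbs moves let walkers leave
  orientation-unfavourable bins quickly — the slow mode expresses itself in
  occupancy rather than in the bin-conditioned force.

## Problem sizes and statistical design

Desk-scale runs are sized so each check is decisive yet the whole suite
runs in about a minute on one CPU:

* two-state recovery: 16 bins, 2 walkers × 2×10⁵ steps (0.3 kJ mol⁻¹
  tolerance);
* membrane 2D recovery: 24 × 7 grid, 2 walkers × 1.2×10⁶ steps
  (0.5 kJ mol⁻¹);
* flat-landscape diffusion recovery: overdamped (γ = 50 ps⁻¹), 2 walkers ×
  6×10⁵ steps, interior occupancy-weighted mean within 25%;
* solvation: 8–16 walkers × 0.6–1.2×10⁵ steps against the Gaussian-integral
  closed form (0.3 kJ mol⁻¹);
* end-to-end permeability: compact one-barrier membrane, 2 walkers ×
  1.5×10⁶ steps, within 0.3 log₁₀ units of the analytic K_P;
* 2D-vs-1D comparison: 31 paired seeds at 8×10⁵ total steps each.  The
  sign test needs ≥21/31 wins for α = 0.05; with the measured ~0.8 per-seed
  win probability this gives the test high power while staying a strict
  test of the phenomenon.

Umbrella force constants for the toys (200–400 kJ mol⁻¹ nm⁻²) are chosen so
σ_umbrella is comparable to the bin spacing — the Gibbs window then spans a
few bins and the reference point diffuses efficiently; the production value
of 25,000 kJ mol⁻¹ nm⁻² remains the configuration default and sets the
pull-force arithmetic (a 0.01 nm displacement gives 250 kJ mol⁻¹ nm⁻¹).

## Known limitations

* The AWH error decays only as (new samples)/N after an unlucky initial
  stage, so occasional seeds show slowly-fading residual errors; medians
  over seeds are the stable statistics.
* The friction metric in the underdamped regime is intrinsically noisy
  (oscillatory cancellation in the force autocovariance); quantitative
  diffusion checks run overdamped.
* Reference-bin force assignment biases D upward when the umbrella
  reference hops faster than the force decorrelates; the Gibbs-weighted
  variant should be preferred whenever the run-integrated sums are
  available.
* The convolved-force (non-MC) AWH variant, adaptive target updating and
  replica exchange are out of scope, as are memory-kernel corrections to
  the diffusion estimate (a slow Markovian process is assumed).
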