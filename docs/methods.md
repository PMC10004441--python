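# Methods

This note records the model assumptions, estimator choices, numerical
conventions and known limitations of `pmmkinetics`, in the order the
pipeline runs.  All internal units are nm, ps, kcal/mol, e, amu and M;
rate constants cross to SI seconds only at reporting boundaries
(1 ps⁻¹ = 10¹² s⁻¹).  Physical constants are centralized in
`pmmkinetics.constants`: Coulomb constant f = 33.2063 kcal·nm·mol⁻¹·e⁻²,
k_B = 0.0019872041 kcal·mol⁻¹·K⁻¹, N_A = 6.02214076×10²³ mol⁻¹, and the
exact identity 1 kJ/mol = 1 amu·nm²·ps⁻² used for speed conversions.

## Electrostatic embedding

The quantum centre (QC) — the reactive fragment treated quantum
mechanically — is rigid at each reaction-coordinate point ξ and carries an
unperturbed energy e₀(ξ), ESP-fitted atomic charges and a permanent
dipole.  The environment enters as a finite list of point charges per
frame.  Two perturbation levels:

* **Charge level (default):** U = e₀ + Σₐ qₐ φ(rₐ).  First order, exact
  for the monopole coupling of fixed charges; it is the natural level when
  only ground-state charges are available.
* **Matrix level:** the perturbed Hamiltonian
  H̃ᵢⱼ = εᵢδᵢⱼ + q_T φ δᵢⱼ − E⃗·μ⃗ᵢⱼ on a small unperturbed electronic
  basis with a (transition-)dipole matrix, evaluated at the QC expansion
  origin; the perturbed ground energy is the lowest eigenvalue.  With one
  basis state this reduces exactly to the first-order dipole expression.

Both levels neglect short-range repulsion/penetration and multipoles
beyond those listed; neither applies periodic (Ewald) electrostatics —
truncation of the charge list is the caller's responsibility.  Sources
closer than 0.05 nm (configurable) to any target point raise a
degenerate-geometry error rather than being clamped, because a clamped
Coulomb sum silently corrupts the energy scale of the exponential
averages downstream.

## Free-energy profile

The Landau free energy difference between a window's reference point
ξ_ref and a nearby grid point ξ is the exponential average
ΔA = −k_B T ln⟨e^{−βΔU}⟩ over the ξ_ref ensemble, computed through a
log-sum-exp (invariant under constant shifts of ΔU, immune to overflow).
Each average also reports its effective sample size
ESS = (Σw)²/Σw²; points with ESS < 10 (configurable) are flagged in the
log, since the estimator is reliable only where the two ensembles overlap.

**Window geometry and chaining.**  Each window's grid spans to both
neighbouring reference points.  The forward pass estimates the sub-range
[ξ_ref,n, ξ_ref,n+1] in the ξ_ref,n ensemble, the backward pass estimates
the same sub-range in the ξ_ref,n+1 ensemble, and offsets are chained at
the shared reference grid points (nearest-shared-point chaining — exact,
interpolation-free, and directly testable).  This double coverage is what
makes the forward and backward profiles genuinely independent estimates;
their pointwise mean (after aligning each to ΔA(ξ_R) = 0) is the final
profile.  Averaging is done pointwise in ΔA, not in exponential space: the
two direction estimates are approximately unbiased in ΔA, and the
arithmetic mean preserves that while halving the variance.

The assembled profile is re-zeroed at its minimum ξ_R; the transition
state ξ_TS is the argmax beyond ξ_R, ties breaking to the smallest ξ; a
monotone profile raises a no-barrier error.  ξ_m, the lower edge of the
reactant well, defaults to the first grid point.  Default window count is
5 and default temperature 300 K.

## Rate constants

**Barrier crossing.**  K_R = e^{−βΔA‡}·⟨v⟩ / (2 Q_R) with
Q_R = ∫_{ξ_m}^{ξ_TS} e^{−βΔA} dξ by trapezoidal quadrature on the profile
grid (no refinement by default, for bit-reproducibility).  The transition
state is treated as a thin slab of width δ with constant density and
constant traversing speed; δ cancels between the slab partition function
and the flux rate, and `transition_rate_KR_via_delta` exposes the
cancellation so tests can assert it instead of trusting it.  The factor
1/2 counts the outward-moving half of the transition-state population.

**Traversing speed.**  The equilibrium mean of |dξ/dt| is taken as the
1-D Maxwell–Boltzmann mean speed √(2k_BT/(πμ)) with a user-supplied
effective mass μ along the coordinate (default 17 amu, the mass scale of
the light attacking fragment; 0.3056 nm/ps at 300 K).  For users with
actual coordinate trajectories, `traversing_speed_from_trajectory`
estimates ⟨|Δξ/Δt|⟩ directly.  The closed form is an idealization: the
true equilibrium speed along a curvilinear coordinate depends on the
metric of the underlying atomic motion.

**Association.**  k_A = 4π(D₁+D₂) r₀ N_A converted to ps⁻¹M⁻¹
(numerically 4π·D_sum·r₀·0.60221…).  Plain diffusion-limited theory: no
interaction potential, no electrodynamic or ionic-strength correction —
adequate when the encounter radius is defined operationally from the
distance distribution, as here.  Diffusion coefficients come either from
user values or from the Einstein relation, D = slope/6 of a least-squares
line through the mean-square displacement over the 10–50 % span of the
track (skipping the ballistic start and the poorly averaged tail; the
intercept is free).  Defaults when no data are given: D = 5.27×10⁻³ nm²/ps
for the hydroxide nucleophile (the experimental value) and 1.0×10⁻³ nm²/ps
for a typical small organic anion.

**Complex kinetics.**  Survival uses the first-passage convention: a
trajectory survives at t while its distance has never exceeded the cutoff
(1.2 nm for the overall complex, 0.6 nm for the reactive complex, both
configurable).  An instantaneous-occupancy variant sits behind
`mode="occupancy"`; with negligible re-entry the two agree, and the
first-passage form is the default because it maps directly onto a clean
escape rate.  The first-order rate is the weighted least-squares slope of
ln S(t) over S ∈ [0.05, 1) — the floor avoids log-of-few-counts noise —
with binomial weights n·S/(1−S); replicate simulations show this fit
matches the censored-exponential maximum-likelihood estimator in both
mean and spread.  Confidence intervals are percentile bootstrap over
trajectories (default 1000 resamples, seeded).

**Complex radius.**  Outside the complex the pair is free and its radial
density grows as r² (shell volume), so r₀ is detected by scanning
candidate bin edges downward from the top of the histogram (0.02 nm bins
by default), fitting c·r² to the normalized density above each candidate,
and stopping where the bin below shows relative excess beyond the
tolerance (default 5 %) plus a 3σ noise allowance estimated from the
scatter of the nearest tail-bin residuals.  Operating on normalized
densities with a scatter-based (not count-based) allowance keeps the
detection invariant to count scaling.  A final goodness-of-fit guard
(mass-weighted relative RMS of the tail fit above the detected radius,
cap 0.15) rejects distributions with no quadratic free region (all-bound
inputs); legitimate tails in our validation runs sit at RMS ≤ 0.10 while
a uniform bound blob sits near 0.25.

**Scheme closure.**  χ_eq is the fraction of complex frames
(r ≤ r₀) lying in the non-reactive shell (r_reactive < r ≤ r₀); the
complex-frames denominator is the convention under which
χ_eq = k1/(k1+k−1) closes consistently with the fitted rates.  Then
k−1 = k1(1−χ_eq)/χ_eq and k2 = k_D/χ_eq (pre-equilibrium within the
complex), and the overall constant is the full steady-state expression
k_H = K_R·k_A·k−1/((k2+k−1)(k1+K_R) − k1·k−1), with the K_R ≪ k1
approximation k_A·k−1·K_R/(k1·k2) reported alongside.  The full form is
derived from the steady state of both complex species and is the one the
compact approximate form follows from; it also satisfies k_H < k_A for
every positive rate tuple, which the tests assert on 10⁴ random tuples.

**ODE validation.**  `scheme_ode_validate` integrates the four-species
scheme (LSODA, rtol 10⁻¹⁰) at fixed hydroxide concentration and fits a
single exponential to the free-substrate decay after an equilibration
transient (first 20 % of the horizon).  The steady-state algebra assumes
the complexed population stays small next to free substrate, which holds
in the dilute regime k_A·[OH⁻] ≪ k2; the default validation
concentration 10⁻³ M sits in that regime, where the fitted rate matches
k_H·[OH⁻] to better than 2 %.  Total substrate material is conserved to
10⁻⁹ relative as a solver sanity check.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of its spec and seed, and ships the
analytic law the estimators are tested against.

* **Windows.**  ΔU samples are independent Gaussians per grid point (a
  symmetric two-Gaussian mixture is available as a non-Gaussian stress
  case), with spread growing as 10 kcal·mol⁻¹·nm⁻¹ × |ξ−ξ_ref| — about
  1.2 kcal/mol at a window edge, matching the few-kcal/mol near-Gaussian
  fluctuation widths such perturbed-energy distributions show in
  practice.  `WindowGeneratorSpec.from_profile` back-computes the means as
  m = ΔA* + βσ²/2 (plus the mixture correction ln cosh(βd)/β when used)
  so the generating distributions' exact stitched profile equals the
  target profile; the default target has a harmonic reactant well
  (500 kcal·mol⁻¹·nm⁻²), a smooth sin² rise to an interior transition
  state, and a slight drop beyond it.  What is *not* emulated: frame-wise
  correlation within an ensemble, cross-point correlation of U(ξ) along
  the coordinate, and anharmonic/heavy-tailed fluctuations — so recovery
  here demonstrates estimator correctness, not robustness to correlated
  MD noise.
* **Escape ensembles.**  Crossing times are drawn directly from the
  exponential law (default 70 trajectories × 500 ps at 1 ps, rate
  0.0056 ps⁻¹, cutoff 1.2 nm); distances are uniform inside the bound
  range before crossing and beyond the cutoff after.  The first recorded
  crossing is the first grid time at or after the continuous crossing
  time, which leaves the survival curve unbiased at grid times.  This
  tests the survival/fit machinery, not barrier-escape physics; a step
  larger than the mean escape time logs a discretization warning.
* **Pair equilibrium.**  Overdamped radial Brownian dynamics
  dr = D(βF(r) + 2/r)dt + √(2D dt)η in a smooth (tanh, width 0.02 nm)
  square well, with reflecting boundaries; the stationary density is
  r² e^{−βW(r)} exactly, giving the quadratic free tail and a bound
  population whose fraction follows from the partition integral.  A step
  whose drift per step exceeds half the smoothing width logs a stiffness
  warning.  Radial-only dynamics: no hydrodynamic interaction, no angular
  degrees of freedom.
* **MSD tracks.**  Free 3-D Gaussian increments with variance 2DΔt per
  axis; ensemble-mean slope 6D.

## Problem sizes

The shipped test suite and the acceptance script run entirely from
synthetic data at the study's standard sizes where those are the point —
5 windows × 20000 frames for barrier recovery, 70 × 500 ps ensembles for
escape rates (≈13 % single-ensemble sampling spread; the bootstrap CI
quantifies it per run), 100-replicate coverage checks — and at smaller
sizes (150–5000 frames, 10⁵–10⁶ Brownian steps) for distributional and
property tests, chosen to keep statistical power without waste.

## Known limitations

* The charge-level and matrix-level embeddings bracket, but do not
  implement, higher-order perturbed-matrix corrections (short-range
  terms, larger electronic bases).
* Quantum vibrational contributions are assumed independent of the
  reaction coordinate and therefore cancel from ΔA differences.
* No umbrella-sampling/WHAM/MBAR alternative estimators; bootstrap over
  frames is available as an option for profile error bars but is not the
  default.
* The Maxwell–Boltzmann traversing speed and the effective mass are a
  modelling choice wherever trajectory data for ⟨|dξ/dt|⟩ are absent.
* Computing pair distances from raw MD coordinate trajectories is out of
  scope; the pipeline consumes distance time series.
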