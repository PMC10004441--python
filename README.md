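# pmmkinetics

Rate constants of slow bimolecular reactions in solution — such as the
hydroxide-promoted hydrolysis of phosphodiesters, whose uncatalysed
half-life runs to millions of years — cannot be measured directly at room
temperature and are equally out of reach for brute-force reactive
simulation.  `pmmkinetics` implements the hybrid statistical-mechanical
route around that problem: quantum-chemical properties of a small reactive
core are combined with classical simulation data through electrostatic
embedding, a windowed free-energy profile along the reaction coordinate,
transition-state flux theory, and diffusion/encounter-complex kinetics, to
yield the overall bimolecular rate constant.

It is aimed at computational chemists who have (or can emulate) the
stage inputs — reaction-profile energies and charges, environment charge
snapshots, pair-distance trajectories, mean-square-displacement tracks —
and want a tested, reproducible pipeline from those inputs to rate
constants with uncertainties.

## The model

The pipeline estimates every constant of the association/reaction scheme

```
S + OH⁻  ⇌(kA/k2)  C_NR  ⇌(k−1/k1)  C_R  →(K_R)  P
```

where C_NR and C_R are the non-reactive and reactive encounter complexes
(pair distances within r₀ ≈ 1.2 nm and ≈ 0.6 nm respectively):

1. **Perturbed energies.**  The quantum centre's ground-state energy at
   each reaction-coordinate point ξ is perturbed by the classical
   environment's point charges, U(ξ) = e₀(ξ) + Σₐ qₐ φ(rₐ) (charge-level
   embedding; a perturbed-matrix form with transition dipoles is also
   provided).

2. **Free-energy profile.**  Within each sampling window, exponential
   averaging over the reference ensemble gives
   ΔA = −k_B T ln ⟨e^{−β ΔU}⟩ with ΔU = U(ξ) − U(ξ_ref); window estimates
   are chained at shared reference points, reconstructed in both
   directions, and averaged.  The reactant minimum ξ_R, the transition
   state ξ_TS and the barrier ΔA‡ are located on the assembled profile.

3. **Barrier-crossing rate.**
   K_R = e^{−β ΔA‡} · ⟨v⟩ / (2 ∫_{ξ_m}^{ξ_TS} e^{−β ΔA(ξ)} dξ), with ⟨v⟩
   the mean traversing speed (1-D Maxwell–Boltzmann by default).

4. **Association and complex kinetics.**  k_A = 4π(D₁+D₂) r₀ N_A
   (Smoluchowski); the dissociation constants k_D and k1 from first-order
   fits of first-passage survival curves; r₀ from the onset of the purely
   quadratic (free-pair) tail of the distance distribution; the
   equilibrium non-reactive fraction χ_eq = k1/(k1+k−1) closing the scheme
   via k−1 = k1(1−χ_eq)/χ_eq and k2 = k_D/χ_eq.

5. **Overall rate.**
   k_H = K_R·k_A·k−1 / ((k2+k−1)(k1+K_R) − k1·k−1) ≅ k_A·k−1·K_R/(k1·k2),
   validated against direct numerical integration of the scheme.

A synthetic-data module generates every input with known ground truth
(Gaussian window fluctuations with an exact stitched profile, exponential
first-passage ensembles, radial Brownian dynamics with an analytic
stationary law, free 3-D diffusion tracks), so each estimator can be
tested against its own oracle.

## Worked example

```python
from pmmkinetics import ReactionKineticsModel

model = ReactionKineticsModel.from_synthetic(seed=1)   # all-synthetic inputs
results = model.fit()
print(results.summary())
```

prints

```
Bimolecular reaction kinetics — fitted rate constants
==========================================================
temperature: 300.0 K
mean traversing speed <v>: 0.3056 nm/ps (mu = 17 amu)
free-energy barrier:  38.75 kcal/mol (xi_R = 0.100 nm, xi_TS = 0.450 nm)
----------------------------------------------------------
constant             value  unit
kA                 0.05694  ps^-1 M^-1
kD                0.006448  ps^-1  (95% CI 0.004971–0.008117)
k1                 0.02623  ps^-1  (95% CI 0.02033–0.03301)
k_minus1          0.003645  ps^-1
k2                0.007344  ps^-1
chi_eq               0.878  1
KR               1.318e-16  s^-1
kH                1.42e-16  s^-1 M^-1
kH_approx         1.42e-16  s^-1 M^-1
r0                     1.2  nm
D_substrate          0.001  nm^2 ps^-1
D_nucleophile       0.00527  nm^2 ps^-1
```

The synthetic model was generated with a 38.8 kcal/mol barrier, an
overall-complex escape rate of 0.0056 ps⁻¹ and a reactive-complex exit
rate of 0.030 ps⁻¹; the fit recovers the barrier to 0.05 kcal/mol and both
escape rates within their bootstrap confidence intervals (the 70-trajectory
ensembles carry ≈ 13 % sampling spread).  `kH` here follows from the
*synthetic* barrier-crossing rate, so its absolute scale reflects the
synthetic well shape and speed model, not any particular real reaction.
`results.plot_profile()` and `results.plot_survival()` show the averaged
profile and the survival curves.

The same pipeline runs from the shell:

```sh
pmmkinetics all --config demo.yaml --out out/        # writes out/rates.json
pmmkinetics free-energy --config demo.yaml           # profile + barrier only
pmmkinetics synth --config demo.yaml                 # write synthetic inputs
```

with a YAML/JSON configuration (schema-validated; unknown keys rejected)
selecting file inputs or synthetic generation per stage.

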