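# Methods

## Model

For an enzyme converting one substrate into products 1 and 2 in parallel,
write each pathway's maximal velocity as Vmax,i = k_cat,i·[ES_i]_max with an
Arrhenius form k_cat,i = A_i·exp(−E_a,i/RT). Under a steady-state
approximation (substrate in excess; binding/unbinding or pose
interconversion fast relative to product formation) the ratio of reactive
enzyme–substrate pose populations is Boltzmann-distributed in the binding
free-energy difference, [ES_1]/[ES_2] = exp(−ΔΔG_bind/RT). Dividing the two
Arrhenius expressions gives

    ln(Vmax,1/Vmax,2) = ln(A1/A2) − Δ/(R·T),    Δ = ΔΔG_bind + ΔEa.

Everything the two pathways share — reductase coupling, oxygen binding,
membrane-fluidity transitions, partial thermal denaturation — multiplies
both Vmax values equally and cancels in the ratio. That is why the ratio
plot is linear over a wide temperature range while single-pathway
ln Vmax plots are not, and it is the property the synthetic generator makes
testable (see below).

A plot against x = 1000/T puts the slope in kelvin: Δ[kJ/mol] = −slope·R
with R = 8.3145 J·mol⁻¹·K⁻¹. The intercept ln(A1/A2) is the relative
collision efficiency: the entropic ease of reaching the transition state
from the bound pose.

Two complements close the thermodynamic cycle:

* **Curtin–Hammett**: at a single temperature the product ratio reflects
  only the overall transition-state free-energy difference,
  ΔΔG_overall = −RT·ln(Vmax,1/Vmax,2). The package evaluates this with
  T = 300 K using the Vmax pair measured at the temperature nearest 300 K
  (the nearest measured point in the shipped data is 298.6 K; at the
  printed precision the two conventions agree, and the measured temperature
  actually used is always returned alongside).
* **Decomposition**: with an externally supplied activation-energy
  difference ΔEa (quantum-chemical reactivity predictions; stored with a
  provenance string, never computed here), ΔΔG_bind = Δ − ΔEa, and
  TΔΔS‡ = Δ − ΔΔG_overall. The entropy identity rests on equating the
  enthalpic part of ΔΔG‡ with the electronic ΔEa; the code treats it as
  exact and records the approximation in the output metadata. All
  differences are pathway-1 minus pathway-2; swapping the pair negates
  every quantity.

## Fitting choices

* **Michaelis–Menten** (v = Vmax·S/(KM+S)): bounded trust-region least
  squares with the analytic Jacobian; start values Vmax₀ = max observed
  velocity, KM₀ = concentration whose velocity is nearest Vmax₀/2;
  positivity enforced by bounds; convergence at relative tolerance 1e-12 or
  500 function evaluations, with a converged flag that excludes failed
  groups downstream. Standard errors from the Gauss–Newton approximation to
  the Hessian scaled by residual variance — the asymptotic SEs that
  commercial kinetics software reports. Replicates are pooled into one
  regression (preserves degrees of freedom) rather than averaged first.
  At least four distinct concentrations are required per group.
* **Ratio series**: formed from fitted Vmax values per temperature, never
  from raw velocities. Each point's SE propagates the two Vmax SEs to first
  order, y_SE = sqrt((SE₁/V₁)² + (SE₂/V₂)²) (verified against Monte-Carlo
  propagation in the tests). Temperatures present for only one pair member
  are dropped with a logged warning, never silently.
* **Line fits**: unweighted ordinary least squares by default — this is
  what reproduces the published slope/intercept tables from the shipped
  parameter table; inverse-variance weighting by y_SE is available behind a
  flag. Temperatures enter as given in kelvin with no rounding of 1000/T.
  Two-point series are fitted exactly but flagged non-inferential with
  undefined SEs. The classic single-pathway fit (ln Vmax vs 1000/T) is kept
  purely as a linearity diagnostic.

## Pose criteria

A trajectory frame is a catalytically active pose for a site of metabolism
(SOM) when, for aromatic hydroxylation, the C_SOM–O_ferryl distance is
< 0.35 nm and the C_SOM–H_SOM–O_ferryl angle does *not* fall in the
hydrogen-interposition exclusion written as [140°, 220°]; for aliphatic
hydrogen abstraction, the H_SOM–O_ferryl distance is < 0.35 nm and the
H_SOM–O_ferryl–Fe angle lies within [110°, 130°].

Numerical conventions: three-point angles are computed in [0°, 180°], so
the [180°, 220°] half of the aromatic exclusion reflects onto [140°, 180°]
and the exclusion reduces to angle ≥ 140° — a geometric inevitability, not
a reinterpretation. Distances are strictly below the cutoff (as the
criteria are printed); angle windows are closed. Internal unit is
nanometres; ångström input requires an explicit declaration (×0.1), and a
missing unit is an error — magnitudes are never used to guess. Frames
missing a required atom abort the run rather than being skipped, which
would bias the reported fractions. Multiple SOMs can be scored on the same
trajectory; per-trajectory fractions are reported separately, never pooled
silently. No Fe-involving constraint is applied for aromatic SOMs. The
classifier scores exactly the frames it is given (no equilibration
trimming). Binary MD formats are out of scope; the documented hook is to
convert to the delimited frame/role table or multi-frame XYZ with a
role-index mapping.

## Synthetic data

The kinetics generator draws velocities from
Vmax_i(T) = envelope(T)·A_i·exp(−G_i/RT) through the Michaelis–Menten
curve, with multiplicative Gaussian noise (CV-parameterized, truncated at
−99% so velocities stay nonnegative — matching the roughly proportional SEs
of real kinetic fits). Defaults mirror the reference study conditions:
eight temperatures from 277.0 to 317.6 K, seven substrate concentrations
from 10 to 750 µM, pooled triplicates, 5% noise, and a bell-shaped shared
envelope peaking near 298 K (chosen to emulate the observed rise-and-fall
of absolute activity; the curvature of single-pathway plots is modeled by
this envelope rather than mechanistically, since the factors behind it
cancel in ratios regardless of their form). The default pathway pair
encodes intercept 3.0 and Δ = 8.1 kJ/mol, the composite observed for the
aliphatic/aromatic mefenamic-acid pair.

The pose generator places atoms to satisfy or violate each criterion with a
margin of at least 3× the coordinate jitter (0.05 nm in distance, ≥ 20° in
angle), jitters them, and applies a random rigid rotation and translation
per frame. Active frames are assigned by exact count (round(p·n) via a
seeded shuffle) so the constructed fraction equals the target exactly.
Because the aliphatic angle window is only ±10° wide and 0.005 nm of
coordinate jitter translates to ≈3° of angular noise, a rare jitter draw
could cross a boundary; such draws are rejected and redrawn, making the
construction labels an exact oracle by guarantee rather than with high
probability. Inactive frames alternate between distance violations and
angle violations.

What the generators do not emulate: correlated noise across substrate
concentrations, KM drift with temperature (KM is constant per pathway by
default), pose autocorrelation along a trajectory, and any mechanistic
rate network for the catalytic cycle. Passing the round-trip and coverage
tests therefore shows the estimators are correct under the stated noise
model, not that real assay noise is that well-behaved.

## Problem sizes

The statistical tests run at the study's own scale: 8 temperatures × 7
concentrations per fit, 200 replicate simulated experiments for the
confidence-interval coverage check, and 1000-frame trajectories for the
classifier oracle. The whole suite completes in well under a minute on one
CPU.

## Known limitations

* The ± values in the shipped parameter table are treated as standard
  errors of the per-temperature fits (the convention of the software that
  produced them); if they were SDs, the weighted-fit option and the
  propagated y_SEs would change, though the default unweighted line fits
  would not.
* Whether published intercept uncertainties used plain OLS formulas or
  software defaults with covariance handling is unknowable from the
  printed values; OLS formulas are used.
* ΔEa inputs are taken at face value; disagreement between reactivity
  predictors (e.g., dispersion-corrected DFT vs faster heuristics) flows
  straight into ΔΔG_bind.
* No substrate-inhibition or Hill-type kinetics, no segmented Arrhenius
  fitting for membrane-transition breakpoints (the ratio method exists
  precisely to avoid needing one), and no absolute Ea, ΔG‡ or rate
  constants.
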