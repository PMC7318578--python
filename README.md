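# p450select

Thermodynamic dissection of regio- and stereoselectivity in multi-product
enzyme catalysis, built for cytochrome P450s but applicable to any enzyme
that converts one substrate into several products in parallel.

## The problem

Classic Arrhenius analysis — fit ln k_cat against 1/T, read the activation
energy off the slope — fails for P450s: the measured Vmax of each pathway is
confounded by redox-partner coupling, membrane fluidity transitions, and
partial denaturation, so single-pathway plots of ln Vmax vs 1000/T are
strongly curved and their slopes mean nothing mechanistic.

For two *parallel* pathways of the same enzyme–substrate system these
confounders are shared, so they cancel in the ratio. The modified Arrhenius
plot fits

```
ln(Vmax,1 / Vmax,2) = ln(A1/A2) − Δ/(R·T),     Δ = ΔΔG_bind + ΔEa
```

against 1000/T. The slope (in K) gives the composite selectivity energy
Δ = −slope·R; the intercept is the relative collision efficiency ln(A1/A2),
an entropic measure of how readily each bound pose reaches its transition
state. Two further ingredients complete the decomposition:

* **Curtin–Hammett**: ΔΔG_overall = −RT·ln(Vmax,1/Vmax,2) at a single
  reference temperature (300 K, using the measured temperature nearest it);
* an **external ΔEa** (e.g., SMARTCyp or DFT — always an input, never
  computed here).

Then `ΔΔG_bind = Δ − ΔEa` and `TΔΔS‡ = Δ − ΔΔG_overall` (taking
ΔΔH‡ ≈ ΔEa). A geometric classifier of catalytically active substrate poses
(distance/angle criteria relative to the ferryl oxygen of compound I)
provides the structural cross-check for the entropic terms on MD-derived
coordinates.

## Worked example

The package ships the temperature-dependent Michaelis–Menten parameters for
mefenamic-acid hydroxylation by the bacterial mutant BM3 M11 (8 temperatures
× 3 metabolites: 3'-methyl, 4', and 5-hydroxylation) and by human CYP1A2
(4 temperatures × 2 metabolites). `python examples/01_modified_arrhenius_report.py`
prints:

```
enzyme    pair                      intercept    slope [K]     R2  delta [kJ/mol]
BM3 M11   3'-OH-MF vs 4'-OH-MF      2.94±0.25   -0.97±0.07   0.97       8.0±0.6
BM3 M11   3'-OH-MF vs 5-OH-MF       5.34±0.19   -1.00±0.06   0.98       8.3±0.5
BM3 M11   4'-OH-MF vs 5-OH-MF       2.40±0.25   -0.03±0.07   0.03       0.3±0.6
CYP1A2    4'-OH-MF vs 5-OH-MF       2.77±0.33   -0.74±0.10   0.97       6.1±0.8
```

Reading the first row: the aliphatic 3'-methyl pathway carries a composite
penalty Δ ≈ 8 kJ/mol (less favorable binding-plus-barrier than 4'
hydroxylation) but a higher collision efficiency (positive intercept:
a smaller entropic cost to reach its transition state). With the external
SMARTCyp value ΔEa = −1.8 kJ/mol, `examples/02_selectivity_decomposition.py`
splits this into ΔΔG_bind ≈ 9.8 kJ/mol and TΔΔS‡ ≈ 7.4 kJ/mol — binding
preference and transition-state entropy nearly cancel, which is why the
observed product ratio is close to 1 (ΔΔG_overall ≈ 0.7 kJ/mol).

Other entry points:

* `examples/03_fit_kinetics_from_velocities.py` — raw velocities →
  Michaelis–Menten fits → recovered Arrhenius line, with the shared
  activity envelope demonstrably cancelling;
* `examples/04_pose_classification.py` — per-frame pose classification and
  active-pose percentages on a synthetic trajectory with known truth;
* the `p450select` command-line tool (`p450select --help`) with subcommands
  `fit-kinetics`, `arrhenius`, `curtin-hammett`, `decompose`,
  `classify-poses`, `simulate-kinetics`, `simulate-poses`, `fixtures`.

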