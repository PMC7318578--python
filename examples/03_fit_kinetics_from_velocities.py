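"""From raw velocities to recovered Arrhenius parameters.

Simulates a two-pathway temperature series with known ground truth
(intercept 3.0, slope −8.1/R ≈ −0.974 K), 5% multiplicative noise and a
bell-shaped shared activity envelope, fits Michaelis–Menten curves per
(temperature, pathway), and recovers the generating line from the ratio
fit — demonstrating that the shared envelope cancels.
"""

from p450select import (
    R_GAS,
    SyntheticKineticsConfig,
    build_ratio_series,
    fit_all_groups,
    fit_modified_arrhenius,
    gen_kinetics,
)

cfg = SyntheticKineticsConfig(seed=7)  # defaults: 8 temps, 7 concs, cv=0.05
velocities, truth = gen_kinetics(cfg)
print(f"simulated {len(velocities.data)} velocity measurements "
      f"({len(cfg.temperatures)} temperatures x {len(cfg.pathways)} pathways "
      f"x {cfg.n_replicates} replicates x {len(cfg.substrate_concs)} concentrations)")

params = fit_all_groups(velocities)
fit = fit_modified_arrhenius(build_ratio_series(params, ("path1", "path2")))

print(f"recovered intercept: {fit.intercept:.2f} ± {fit.intercept_se:.2f}   (truth 3.00)")
print(f"recovered slope:     {fit.slope:.3f} ± {fit.slope_se:.3f} K (truth {-8.1 / R_GAS:.3f})")
print(f"recovered delta:     {fit.delta:.2f} ± {fit.delta_se:.2f} kJ/mol (truth 8.10)")
print(f"R2 = {fit.r_squared:.3f}")
print()
print("The bell-shaped envelope makes each pathway's own ln Vmax plot curved,")
print("but it multiplies both pathways identically and vanishes in the ratio.")
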