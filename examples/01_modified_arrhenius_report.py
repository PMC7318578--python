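"""Modified Arrhenius analysis of the packaged mefenamic-acid kinetics.

Builds ln(Vmax,1/Vmax,2) vs 1000/T series for the three BM3 M11 metabolite
pairs and the CYP1A2 pair, fits the lines, and prints intercept (relative
collision efficiency ln A1/A2), slope, R², and the composite selectivity
energy Δ = ΔΔG_bind + ΔEa = −slope·R in kJ/mol. High R² here — against
strongly curved single-pathway plots — is the signature that shared
catalytic-cycle factors cancel in the ratio.
"""

from p450select import build_ratio_series, fit_modified_arrhenius, table1_fixture

table = table1_fixture()

pairs = [
    ("BM3 M11", ("3'-OH-MF", "4'-OH-MF")),
    ("BM3 M11", ("3'-OH-MF", "5-OH-MF")),
    ("BM3 M11", ("4'-OH-MF", "5-OH-MF")),
    ("CYP1A2", ("4'-OH-MF", "5-OH-MF")),
]

print(f"{'enzyme':<9} {'pair':<22} {'intercept':>12} {'slope [K]':>12} "
      f"{'R2':>6} {'delta [kJ/mol]':>15}")
for enzyme, pair in pairs:
    fit = fit_modified_arrhenius(build_ratio_series(table.subset(enzyme), pair))
    print(f"{enzyme:<9} {pair[0]} vs {pair[1]:<10} "
          f"{fit.intercept:>7.2f}±{fit.intercept_se:.2f} "
          f"{fit.slope:>7.2f}±{fit.slope_se:.2f} {fit.r_squared:>6.2f} "
          f"{fit.delta:>9.1f}±{fit.delta_se:.1f}")

print()
print("A positive delta for the aliphatic/aromatic pair means the sum of")
print("binding free energy and activation energy is higher for 3'-methyl")
print("hydroxylation; a near-zero slope (4' vs 5) means the two aromatic")
print("pathways differ almost purely entropically (the intercept).")
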