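"""Decompose regioselectivity into binding, barrier, and entropy terms.

For the 3'-methyl vs 4' hydroxylation pair of mefenamic acid by BM3 M11:
Δ comes from the modified Arrhenius slope, ΔΔG_overall from the product
ratio at the temperature nearest 300 K (Curtin–Hammett), and ΔEa is an
external quantum-chemical input (SMARTCyp predicts −1.8 kJ/mol for this
pair). The package then reports ΔΔG_bind = Δ − ΔEa and TΔΔS‡ = Δ − ΔΔG_overall.
"""

from p450select import (
    build_ratio_series,
    curtin_hammett_from_table,
    decompose,
    fit_modified_arrhenius,
    table1_fixture,
)

bm3 = table1_fixture().subset("BM3 M11")
pair = ("3'-OH-MF", "4'-OH-MF")

fit = fit_modified_arrhenius(build_ratio_series(bm3, pair))
ddg_overall, t_meas = curtin_hammett_from_table(bm3, pair)
dec = decompose(fit, ddG_overall=ddg_overall, dEa=-1.8,
                dEa_provenance="SMARTCyp v2/v3")

print(f"pair: {pair[0]} vs {pair[1]} (BM3 M11)")
print(f"  delta        = {dec.delta:6.1f} kJ/mol   (from slope {fit.slope:.2f} K)")
print(f"  ddG_overall  = {dec.ddG_overall:6.1f} kJ/mol   (Vmax ratio at {t_meas} K, T=300 K)")
print(f"  dEa          = {dec.dEa:6.1f} kJ/mol   ({dec.dEa_provenance})")
print(f"  ddG_bind     = {dec.ddG_bind:6.1f} kJ/mol   (= delta - dEa)")
print(f"  TddS         = {dec.TddS:6.1f} kJ/mol   (= delta - ddG_overall)")
print()
print("Reading: 4'-hydroxylation binds ~10 kJ/mol more favorably in its")
print("reactive pose, but 3'-methyl hydroxylation pays a ~7 kJ/mol smaller")
print("entropy penalty to reach its transition state — the two nearly cancel,")
print("so the overall product ratio (ddG_overall) is close to zero.")
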