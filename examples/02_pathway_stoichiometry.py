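"""Diagnose the dominant sulfate-reduction pathway from dDIC:|dSO4| slopes.

Organoclastic sulfate reduction releases ~2 mol DIC per mol sulfate,
while sulfate reduction coupled to anaerobic methane oxidation releases 1.
The regression of the DIC increase on the sulfate drawdown over the
sulfate-reducing zone therefore separates the two regimes.
"""

from poregibbs import delta_vs_reference, fit_dic_so4_slope, generate_core, get_template

for name, window, use_surface in [
    ("organic_rich_CLB_like", (12.0, 40.0), False),
    ("organic_poor_WOR_like", (0.0, 47.0), True),
]:
    template = get_template(name)
    core, truth = generate_core(template, seed=1)
    if use_surface:  # reference: overlying water-column concentrations
        d_dic = delta_vs_reference(core["dic_mM"], template.dic_reference_mM)
        d_so4 = delta_vs_reference(core["so4_mM"], template.so4_surface_mM)
    else:  # reference: base of the bioirrigated layer (12 cm; grid midpoint 13)
        d_dic = delta_vs_reference(core["dic_mM"], ("depth", 13.0))
        d_so4 = delta_vs_reference(core["so4_mM"], ("depth", 13.0))
    res = fit_dic_so4_slope(d_dic, d_so4, window)
    print(f"{name}:")
    print(
        f"  slope = {res.slope:.3f} (95% CI {res.slope_ci[0]:.3f}-{res.slope_ci[1]:.3f}, "
        f"n = {res.n}), truth = {truth.dic_so4_slope}"
    )
    print(f"  classification: {res.classification}\n")

print("Slopes near 2 indicate organic matter fuels sulfate reduction;")
print("slopes near 1 indicate methane does, via anaerobic oxidation.")
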