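"""Zone-wise hydrogen statistics: tight vs released syntrophic control.

Hydrogen is the currency of fermenter-respirer syntrophy.  Where sulfate
reducers consume it reliably, its concentration is low and nearly
invariant; where that control lapses, it is higher and far more variable.
"""

from poregibbs import generate_core, get_template, welch_t_test, zone_statistics
from poregibbs.hydrostats import zone_values

core, _ = generate_core(get_template("organic_poor_WOR_like"), seed=1)
h2 = core["h2_nM"]

print("organic-poor (estuary-type) core, zones split at 15 cm:")
for zs in zone_statistics(h2, [0.0, 15.0, 62.0]):
    print(
        f"  {zs.label:>10}: n={zs.n:2d} mean={zs.mean:.3f} nM "
        f"variance={zs.variance:.5f} nM^2 range={zs.min:.2f}-{zs.max:.2f} nM"
    )

core_rich, _ = generate_core(get_template("organic_rich_CLB_like"), seed=1)
h2r = core_rich["h2_nM"]
a = zone_values(h2r, 0.0, 10.0, replicates="independent")
b = zone_values(h2r, 10.0, 62.0, replicates="independent")
t, df, p = welch_t_test(a, b)
print("\norganic-rich (bight-type) core, 0-10 cm vs deeper (replicates kept):")
print(f"  Welch t = {t:.3f}, df = {df:.2f}, p = {p:.4f}")
print("\nThe upper-zone variance orders of magnitude below the deep zone's")
print("marks obligate syntrophy; the significant organic-rich contrast shows")
print("labile surface organics sustain elevated hydrogen instead.")
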