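"""Headspace-equilibration conversions: ppm to porewater concentrations."""

from poregibbs import (
    HeadspaceMeasurement,
    ch4_aqueous_from_headspace,
    dic_from_headspace,
    h2_headspace_to_aqueous,
    h2_saturation_concentration,
)

print("H2 saturation under 1 atm pure H2:")
print(f"  24.0 C, 35.0 permil: {h2_saturation_concentration(24.0, 35.0):.1f} uM")
print(f"  28.5 C, 18.9 permil: {h2_saturation_concentration(28.5, 18.9):.1f} uM")

ppm = 1.2
print(f"\n{ppm} ppm headspace H2 at 24 C / 35 permil -> "
      f"{h2_headspace_to_aqueous(ppm, 24.0, 35.0):.3f} nM aqueous")

ch4 = HeadspaceMeasurement(
    analyte="CH4", mixing_ratio_ppm=10_000.0, headspace_volume_ml=7.0,
    sediment_volume_ml=4.0, porosity=0.8, temperature=24.0,
)
print(f"\n10,000 ppm CH4, 7 mL headspace over a 4 mL sediment plug (phi 0.8):")
print(f"  aqueous CH4 = {ch4_aqueous_from_headspace(ch4):.3f} mM")

dic = HeadspaceMeasurement(
    analyte="CO2", mixing_ratio_ppm=1500.0, headspace_volume_ml=30.0,
    temperature=24.0, dilution_chain=[(5.0, 140.0)], extraction_efficiency=0.969,
)
print(f"\n1500 ppm measured CO2 after a 5:135 dilution, 96.9% extraction,")
print(f"3 g porewater: DIC = {dic_from_headspace(dic, 3.0):.1f} mM")
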