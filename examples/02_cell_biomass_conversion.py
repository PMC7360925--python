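"""Convert measured cell-number ratios into model biomass ratios.

Microscopy and qPCR count cells, but community models are parameterized by
biomass.  One matched biomass↔cell-ratio pair calibrates the per-cell mass
factor; that factor then converts any measured cell ratio.
"""

from symbiofba import calibrate_per_cell_mass, cells_to_biomass

factor = calibrate_per_cell_mass(biomass_ratio="1:5", cell_ratio="1:130")
print(f"per-cell mass factor (g per B cell / g per H cell): {factor:g}")

value, label = cells_to_biomass("1:3.9", factor)
print(f"measured cells 1:3.9  ->  biomass {label}  ({value:.2f} g B per g H)")

_, roundtrip = cells_to_biomass("1:130", factor)
print(f"calibration pair round-trips: cells 1:130 -> biomass {roundtrip}")

print(
    "\nA factor of 26 means each obligate-symbiont cell outweighs a\n"
    "facultative-symbiont cell 26-fold, so a 1:3.9 cell deficit is still a\n"
    "6.7:1 biomass dominance."
)
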