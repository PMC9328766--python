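"""Optical-fractionator estimate of total dopamine neuron number.

Raw dissector counts from the SNc and VTA are scaled by the inverse section,
area, and thickness sampling fractions of the design: every 6th section, a
60x60 µm² counting frame on a 150 µm grid, and a 10 µm dissector in sections
of 20 µm measured mounted thickness.
"""

from exmorph import CountRecord, FractionatorDesign, estimate_total

design = FractionatorDesign(
    section_interval=6,
    frame_area=60.0 * 60.0,
    grid_step=(150.0, 150.0),
    dissector_height=10.0,
    mean_section_thickness=20.0,
)
counts = [CountRecord("SNc", 420), CountRecord("VTA", 610)]
estimates = estimate_total(counts, design)

print(f"inverse sampling fraction: {design.inverse_sampling_fraction:.1f}")
for region in ("SNc", "VTA", "combined"):
    print(f"estimated neurons, {region:8s}: {estimates[region]:,.0f}")
# Each counted cell represents interval x (grid/frame) x (thickness/dissector)
# = 6 x 6.25 x 2 = 75 cells in this design.
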