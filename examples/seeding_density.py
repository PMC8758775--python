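"""Melanocyte numbers for a target stromal volume fraction.

The stromal channel (1.5 uL) is filled with a cell-laden hydrogel. To hit a
target melanocyte volume fraction - 5% emulating the human choroid, 50% the
rhesus macaque - the suspended cell is modelled as a sphere of the measured
mean diameter, scaled by an expansion factor of 3.68 for spreading, and the
required concentration follows from straight unit conversion (1 uL = 1e9 um^3).
"""

from choroidchip import SeedingSpec, seeding_concentration

for label, fraction in [("low (human, 5%)", 0.05), ("high (macaque, 50%)", 0.50)]:
    out = seeding_concentration(
        SeedingSpec(cell_diameter_um=28.5, target_fraction=fraction)
    )
    print(f"{label}:")
    print(f"  expanded cell volume : {out['expanded_cell_volume_um3']:10.1f} um^3")
    print(f"  cells in 1.5 uL gel  : {out['cells_in_channel']:10.1f}")
    print(f"  seeding concentration: {out['cells_per_ul']:10.1f} cells/uL")
    print(f"  cells for 5 uL mix   : {out['total_cells_in_seeding_volume']:10.1f}")
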