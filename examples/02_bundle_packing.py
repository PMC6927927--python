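"""Bundle envelope diameters of the four device ring configurations.

The cross-section of an n-turn wire bundle is approximated by the smallest
circle enclosing n equal circles (circle-packing theory).  This prints the
packing ratio BW = R_bundle / R_wire and the resulting envelope diameter
for each fixture ring, cross-checked by a numerical packing optimizer for
the smaller turn counts.
"""

from ringmech import bundle_diameter, bw_ratio, verify_packing
from ringmech.io import PRESET_RINGS

for name, cfg in PRESET_RINGS.items():
    d = bundle_diameter(cfg.r_wire, cfg.n_turns, rounded=True)
    print(f"{name}: {cfg.n_turns:2d} turns of Ø{cfg.d_wire:.3f} mm wire -> "
          f"BW = {bw_ratio(cfg.n_turns):.3f}, bundle Ø {d:.2f} mm")

print("\noptimizer cross-check (n <= 8):")
for n in (2, 5, 8):
    print(f"  n={n}: table {bw_ratio(n):.3f}, optimizer {verify_packing(n):.4f}")
print("the envelope diameter sets the contact offset of the bundle surface")
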