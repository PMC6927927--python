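"""Saddle pull test of ring 4: structural stiffness with pre-strain.

Forms the largest fixture ring, pulls it into a deep saddle, and cycles
it between the shapes it would take at 30 % and 10 % vessel oversize.
Prints the settled cycling force range and the hysteresis-loop area (the
signature of superelastic transformation in the wire).
"""

import numpy as np

from ringmech import SaddleConfig, form_ring, run_saddle
from ringmech.io import PRESET_RINGS

model = form_ring(PRESET_RINGS["ring4"], n_el=32)
df = run_saddle(model, SaddleConfig(n_cycles=2, n_inc_pull=10, n_inc_cycle=6))

roi = df[df.region_of_interest]
c = df[df.step.str.startswith("cycle_2")]
area = abs(np.trapezoid(c.force_N.to_numpy(), c.displacement_mm.to_numpy()))
print(f"pull extreme force:        {df.force_N.max():.2f} N")
print(f"cycling force range:       {roi.force_N.min():.2f} .. {roi.force_N.max():.2f} N")
print(f"hysteresis loop area:      {area:.2f} N mm per cycle")
print("a positive loop area means the wire crosses its transformation "
      "plateau during the operational deflection range")
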