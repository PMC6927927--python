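"""Full scenario: crimp ring 2 into its catheter, deploy, pulse.

Reproduces the clinical loading history: forming pre-strains, radial
compaction into the delivery sheath (the severest load the wire ever
sees), release into an artery sized for 10 % oversize, and pulsation
between diastole and systole.  Prints the chronic outward force and the
fatigue-relevant strain extrema.  Takes a few minutes.
"""

from ringmech import DeploymentConfig, compact, deploy_and_pulse, form_ring, size_vessel
from ringmech.io import PRESET_RINGS

cfg = PRESET_RINGS["ring2"]
model = form_ring(cfg, n_el=32)
dc = DeploymentConfig(seed=0)

compact(model, dc)
print(f"compacted into Ø{dc.catheter_diameter} mm catheter: "
      f"peak wire strain {model.max_fiber_strain() * 100:.1f} %")

tube = size_vessel(cfg, dc.oversize_pct)
res = deploy_and_pulse(model, tube, dc)
print(f"chronic outward force COF  = {res.COF:.2f} N (at mean pressure)")
print(f"eps_Diast = {res.eps_diast * 100:.2f} %   eps_Syst = {res.eps_syst * 100:.2f} %")
print(f"M_eps (max cycle-mean)     = {res.M_eps * 100:.2f} %")
print("COF is what holds the stent against the wall; the strain amplitude "
      "between diastole and systole drives fatigue")
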