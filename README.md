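# ringmech

Mechanics of superelastic Nitinol **ring-stent wire bundles** — the
radial-support rings of ring-based aortic stent grafts — simulated through
their full load history: winding the straight wire onto the ring
(manufacturing pre-strain), crimping into the delivery catheter, release
into a hyperelastic artery, and pulsation between diastole and systole.

It is written for device and simulation engineers who need desk-scale,
scriptable answers to questions usually delegated to a commercial FE code:
how stiff is a bundle of *n* turns in its operational (saddle) deflection
range, what strains does the wire see after deployment, and how much
chronic outward force does the ring exert on the vessel wall.

## The model in brief

* **Wire**: 1-D superelastic constitutive law at 37 °C with linear
  transformation kinetics — elastic with phase-mixture modulus
  E(ξ) = E_A + ξ(E_M − E_A), forward plateau between σ_L^S = 636 and
  σ_L^E = 740 MPa, reverse plateau between σ_U^S = 430 and
  σ_U^E = 302 MPa, compression onset at 965 MPa, transformation strain
  ε^L = 0.05. The austenite branch ends at σ_L^S/E_A = 1.08 % strain.
* **Bundle**: a corotational Timoshenko beam whose circular section is
  integrated over fibers, each carrying its own superelastic state; *n*
  superimposed turns enter as a section-force multiplier, and the bundle
  envelope radius BW·r_wire (smallest circle enclosing *n* equal circles,
  from circle-packing theory) acts as the contact offset.
* **Forming**: ε_max = R_wire/R_ring bending pre-strain, locked into the
  fiber history before any other load step.
* **Saddle pull test**: four-string load–deflection test cycling the ring
  between the saddle shapes of 30 % and 10 % vessel oversize
  (oversize = (R_ring/R_vessel − 1)·100 %).
* **Artery**: 6th-order reduced-polynomial wall
  U = Σ c_i (Ī₁ − 3)^i + (1/D₁)(J−1)², solved as an incompressible
  thick-wall tube and sized for 10 % ring oversize at
  P_m = P_d + (P_s − P_d)/3 = 93.3 mmHg.
* **Outputs**: chronic outward force (COF — the radial sum of nodal
  contact forces on the vessel), ε_Diast, ε_Syst, and the maximum
  cycle-mean strain Mε.

See `docs/methods.md` for assumptions, numerics, and limitations.

## Worked example

```python
from ringmech import (DeploymentConfig, compact, deploy_and_pulse,
                      form_ring, size_vessel)
from ringmech.io import PRESET_RINGS

cfg = PRESET_RINGS["ring2"]              # 8 turns of Ø0.160 mm wire, Ø33.16 mm ring
model = form_ring(cfg, n_el=32)          # manufacturing pre-strain: 0.48 %
dc = DeploymentConfig(seed=0)
compact(model, dc)                       # crimp into the Ø6.9 mm catheter
tube = size_vessel(cfg, dc.oversize_pct) # 10 % oversize at P_m
res = deploy_and_pulse(model, tube, dc)
print(res.COF, res.eps_diast, res.eps_syst, res.M_eps)
```

Running `python examples/06_vascular_deployment.py` (this scenario)
prints, after a few minutes:

```
compacted into Ø6.9 mm catheter: peak wire strain 3.7 %
chronic outward force COF  = 1.07 N (at mean pressure)
eps_Diast = 0.83 %   eps_Syst = 0.83 %
M_eps (max cycle-mean)     = 0.83 %
COF is what holds the stent against the wall; the strain amplitude
between diastole and systole drives fatigue
```

Crimping is the severest load the wire ever sees (here 3.7 %, deep into
the transformation plateau); after deployment at 10 % oversize the peak
pulsating strains sit near 0.8 % — the fatigue-relevant number — and the
ring pushes on the wall with about 1 N of chronic outward force.

The other scripts in `examples/` each exercise one capability
(superelastic hysteresis, packing ratios, forming strains, vessel
response, the saddle test) and print a line on what the numbers mean.

A thin CLI wraps the same library:

```sh
ringmech form --config ring1 --out formed.h5
ringmech saddle --state formed.h5 --out fd_curve.csv
ringmech deploy --ring ring2 --out result.json
ringmech packing --r-wire 0.08 --check
```

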