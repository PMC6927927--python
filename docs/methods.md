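# Methods

`ringmech` simulates the mechanics of a full ring-stent wire bundle — the
radial-support element of ring-based stent grafts — through its complete
load history: winding of the straight Nitinol wire into a closed ring,
crimping into the delivery catheter, release into a hyperelastic artery,
and pulsation between diastolic and systolic pressure. This note records
the models, the parameters that matter, and the numerical choices.

## Superelastic wire model

Each section integration point ("fiber") carries a one-dimensional
superelastic state: martensite volume fraction ξ ∈ [0, 1] and signed
transformation strain ε_tr = ±ξ·ε_L. Stress is σ = E(ξ)(ε − ε_tr) with a
linear phase mixture E(ξ) = E_A + ξ(E_M − E_A). Transformation kinetics
are linear between start/end stresses:

* forward (tension): active on σ = σ_LS + ξ(σ_LE − σ_LS), with
  σ_LS = 636, σ_LE = 740 MPa;
* reverse (tension): active on σ = σ_UE + ξ(σ_US − σ_UE), with
  σ_US = 430, σ_UE = 302 MPa;
* elastic everywhere between the two lines (open hysteresis, inner loops
  handled naturally);
* compression: the same surfaces scaled by σ_CS/σ_LS = 965/636 ≈ 1.517,
  so forward transformation in compression starts at 965 MPa. Only the
  compression *start* stress is an input; the scaling of the remaining
  three surfaces is an assumption and can be overridden
  (`NitinolParams.compression_scale`).

Constants are an isothermal 37 °C calibration (E_A = 59 GPa,
E_M = 26.5 GPa, ν = 0.33, ε_L = 0.05); no temperature dependence is
modeled. The update is closed-form (a quadratic per active surface, staged
for side switches), rate-independent, and returns an algorithmically
consistent tangent. The austenite branch ends in tension at
σ_LS/E_A = 1.078 % strain.

## Beam finite elements

The wire is a corotational two-node Timoshenko beam. Local deformational
quantities (chord stretch and the two end-rotation vectors relative to the
corotated frame) are turned into section strains with one mid-element
integration point; axial force and both bending moments come from fiber
quadrature over the circular section, torsion and transverse shear stay
elastic (G from E_A and ν, shear factor 0.9). The fiber grid is 8 angular
stations × 3 radial Gauss–Lobatto layers whose outermost layer lies *on*
the wire surface, so peak outer-fiber strains are sampled exactly; the
grid integrates area and bending inertia of the section exactly.

An *n*-turn bundle is one wire whose section resultants (and GJ, GA_s) are
multiplied by *n* — identical to *n* coincident wires welded node-wise,
which the DOF-merging "weld" constraint also realizes (the equivalence is
a regression test). The bundle's circular envelope, with radius from
circle-packing theory (BW·r_wire), enters as a contact offset: rigid
cylindrical surfaces touch the beam centerline at ± the envelope radius.

Kinematic gradients (the corotational Jacobian and the tangent stiffness)
are assembled by vectorized forward finite differences (step 1e-6) over
stacked element configurations; the resulting tangent matches a brute-force
differentiation of the residual to ~1e-4 relative, which preserves fast
Newton convergence. Dense LU solves are used (a few hundred DOF).

Solver: incremental Newton with full steps (damping only on severe
blow-up), adaptive pseudo-time with bisection, and viscous-type
stabilization for unstable branches — a force −c·Δu from the increment's
start configuration, the analog of automatic stabilization in commercial
quasi-static codes. Stabilization is continuous but weak during crimping
(3e-3 · force-scale / element length) and escalates temporarily when
increments keep failing; an increment converged while leaning on more
stabilization force than 2 % of the force scale is rejected and retried
smaller, except during escalation across genuine limit points (where the
jump is logged). Converged states outside crimping carry no stabilization.

Residual tolerance is 1e-8 × the running force scale (≥ 1e-9 N); rotation
residuals are weighted by 1/L_char so the norm is in N.

## Forming (manufacturing pre-strain)

The ring is meshed as a closed circle whose *material* reference is the
straight wire stock: fiber bending strains at the circle equal z/R_ring
by construction, and the committed states are marched there monotonically
(proportional loading), which is the exact history of pure bending.
Axial strain is measured from the reference chord (initially-curved
corotational element), so the pure-bending circle is in discrete
self-equilibrium; a release solve verifies residuals < 1e-6 N. The peak
fiber strain equals the bending-theory value r_wire/R_ring to machine
precision, and the four fixture rings fall in the 0.4–0.7e-2 band.
`include_prestrain=False` instead tares the circular mesh as strain-free
(virgin material) — the comparison variant that omits manufacturing.

## Saddle pull test

Rig idealization: valleys B, D held in the ring plane, two strings (axial
connectors, slack under compression) from peaks A, C to a crosshead point
on the axis; string stiffness 7.41 N/mm per 100 mm length scaled by
1/length (default length 100 mm). Twist about the wire tangent is
suppressed at the four quarter points, mirroring the heavy rotational
restraint of the physical strings/sutures. The crosshead bound for an
oversize level is u = 2h with h = √(R_v(R − R_v)) (first-order
arc-length-conserving two-lobe saddle); the exact rig geometry is not
dimensioned anywhere, so the mapping is a documented configuration
default, and the experimental force–displacement curves themselves are out
of scope. The program is pull-to-extreme (1.5× the 30 %-oversize bound by
default), partial unload, then cycling 30 % ↔ 10 %; because the material
is rate-independent and non-damaging, the loop settles in 2–3 cycles
rather than the 100 used experimentally (successive cycles agree to
< 0.5 %).

## Artery tube

Strain energy U = Σ c_i (Ī₁ − 3)^i + (1/D₁)(J − 1)², i = 1..6, with the
aortic-wall fit c = (0.0048, 0.0911, −1.0600, 9.5292, −31.7421, 46.3921)
MPa and D₁ = 0.004593 MPa⁻¹ (higher volumetric terms absent; the implied
small-strain Poisson ratio exceeds 0.4999). The tube response is computed
semi-analytically: incompressible, axisymmetric, plane-strain thick-wall
inflation through the 2 mm wall; luminal pressure is the integral of the
hoop–radial stress difference. Sizing picks the unloaded radius so the
lumen at P_m = P_d + (P_s − P_d)/3 = 93.3 mmHg produces the prescribed
oversize; segment length is twice the ring diameter.

Coupling to the ring is the model's main fidelity reduction: the wall
remains a cylinder whose radius answers the total radial contact force
through an effective stiffness k = dP/dr · 2πr · w, with the load-spread
band w defaulting to the bundle diameter plus the wall thickness; local
indentation of the wall by the wire is folded into the contact penalty.
A fixed-point iteration (relaxation 0.5, tolerance 5e-3 mm) equilibrates
ring and wall at each pressure. This choice preserves the constitutive
pressure–radius content at desk scale; it cannot represent local wall
bulging between contact zones, which plausibly biases deployed strains
slightly upward for the smallest, stiffest ring.

## Compaction and deployment

Crimping a ring from its formed diameter into a ~6.9 mm catheter bore
traverses a bifurcation-rich path: the two-lobe fold-depth mode is nearly
neutral, and eversion (collective section rotation about the wire tangent)
is *exactly* neutral for an isotropic circular section. Three devices make
the quasi-static path well-posed, each with a physical counterpart:

1. **Guided fold.** The peak nodes A, C are driven axially along the fold
   height of an inextensible two-lobe saddle confined to the current
   sheath radius — h solves ∫√(R_v² + 4h² sin² 2φ) dφ = 2πR — while the
   frictionless sheath shrinks (the funnel's role in physical sheathing).
   At the bore the guides are converted to their reaction forces and
   ramped to zero, so the final crimped equilibrium carries only
   sheath/core contact loads. Deployment reverses the same guide law
   while the confinement opens toward the pressurized lumen.
2. **Anti-eversion restraint.** Rotation about the tangent is pinned at
   valley B throughout (the same restraint that stabilizes pulsation).
3. **Retention springs.** Weak (0.01 N/mm) axial springs at the peaks —
   standing in for the sutures/graft fabric that hold the real bundle —
   regularize the neutral axial drift; they are re-anchored at every
   scenario phase so they carry no mean load.

A seeded, deterministic out-of-plane force pattern (≈1e-3 of the ring's
bending-force scale, removed after crimping) breaks the symmetry of
secondary modes. The inner delivery-tube is a rigid cylinder (Ø 2 mm
default); the catheter bore (Ø 6.9 mm ≈ 20.7 Fr) and both diameters are
configuration inputs, as neither is dimensioned in the source data.
Contact is penalty-based (80–200 N/mm per node, C¹-smoothed over 0.02 mm)
with Coulomb-capped tangential friction: μ = 0.05 against the vessel,
frictionless against the delivery system. Wire-to-wire contact is
deliberately not modeled (the superposed-turn construction avoids it);
a diagnostic warns when non-adjacent wire segments approach within a
bundle diameter.

After release, the ring equilibrates against the vessel at P_m (the COF
report point — the extraction pressure is not fixed by the source, so
diastolic/systolic values are also emitted), then pulses 80 ↔ 120 mmHg
for two cycles. Outputs: COF (sum of radial components of the nodal
forces on the vessel), ε_Diast, ε_Syst (peak fiber strain magnitudes at
the two pressures, final cycle) and Mε = max over fibers of the cycle-mean
strain |(ε_d + ε_s)/2| — the "maximum mean strain" is read as the
per-fiber cycle mean, which is the fatigue-relevant quantity.

## Problem sizes and expected results

Default meshes: 48 elements for forming and stiffness studies, 32 for the
full deployment scenario (12 per quarter span; the acceptance script uses
28 so four complete scenarios run in a batch). Mesh halving changes the
saddle-test peak force by well under 1 %. A full single-ring scenario is
a few minutes of CPU.

Under these conditions the four fixture rings form with peak strains
0.42–0.67e-2 (equal to r_wire/R_ring to machine precision), crimp to
3.7–4.9 % peak strain, and deploy at 10 % oversize to peak pulsating
strains of roughly 0.7–1.1 %, maxima at saddle peaks/valleys, with COF of
order 1–5 N. The smallest ring lands at the top of that range, slightly
above 1 %, which we attribute mainly to the cylindrical-wall coupling
(no local bulging relief) at coarse scenario meshes.

## What the synthetic scenarios do and do not show

All inputs are parametric (geometry, material constants, wall fit); there
are no measured force–displacement curves in the package, so agreement
with physical rigs cannot be claimed — only the directional facts those
experiments established: omitting the forming pre-strain makes every ring
stiffer across the cycling region, hysteresis appears once the plateau is
entered, and the strain history through crimping changes the deployed
state. Straight, homogeneous vessels only; fabric mechanics, fatigue
damage, and turn-to-turn variability within the bundle are out of scope.

## Known limitations

* The wall-coupling idealization above (single largest fidelity cut).
* One mid-element integration point: coarse meshes under-resolve the
  strain localization angle near peaks/valleys to one element spacing.
* The crimp/deploy guide law assumes the two-lobe fold; higher-lobe
  packing patterns of very large rings are not explored.
* Stabilization-assisted traversal of limit points dissipates a small,
  logged amount of artificial work during crimping; converged reporting
  states are stabilization-free.
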