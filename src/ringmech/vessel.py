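"""Hyperelastic artery tube: 6th-order reduced-polynomial wall model.

The vascular segment receiving the ring stent is a straight, homogeneous,
isotropic, nearly incompressible tube whose strain-energy density is

    U = sum_{i=1..6} c_i (I1_bar - 3)^i  +  (1/D1) (J_el - 1)^2,

with deviatoric coefficients ``c_1..c_6`` (MPa) fitted to human aortic
pressure-radius data (males 67-77) and a single volumetric term (the
higher-order volumetric coefficients are absent; the implied small-strain
Poisson ratio exceeds 0.4999, so the wall is treated as incompressible in
the inflation kinematics).

The tube response is computed semi-analytically: incompressible,
axisymmetric, plane-strain (axially tethered) thick-wall inflation with
the luminal pressure obtained by integrating the hoop-radial stress
difference through the 2 mm wall.  Sizing follows the device convention:
the unloaded radius is chosen so that the lumen at the time-weighted mean
arterial pressure ``P_m = P_d + (P_s - P_d)/3`` produces the prescribed
ring oversize.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .forming import RingConfig

__all__ = [
    "VesselTube",
    "AORTA_COEFFS",
    "MMHG_TO_MPA",
    "strain_energy",
    "pressure_radius",
    "radial_stiffness",
    "size_vessel",
    "mean_arterial_pressure",
]

#: mmHg -> MPa conversion
MMHG_TO_MPA = 133.322e-6

#: deviatoric coefficients c1..c6 (MPa) of the aortic wall fit (males 67-77)
AORTA_COEFFS = (0.0048, 0.0911, -1.0600, 9.5292, -31.7421, 46.3921)
AORTA_D1 = 0.004593          # MPa^-1
AORTA_DENSITY = 1.16e-9      # tonne/mm^3 (informational)


@dataclass
class VesselTube:
    """Straight artery segment with a reduced-polynomial wall."""

    c: tuple = AORTA_COEFFS        # MPa
    D1: float = AORTA_D1           # MPa^-1
    thickness: float = 2.0         # mm
    length: float = 40.0           # mm
    R_ref: float = 10.0            # unloaded inner radius, mm
    density: float = AORTA_DENSITY

    def dW_dlambda(self, lam: float) -> float:
        """d/d(lambda) of the deviatoric energy under plane-strain inflation.

        With lambda_z = 1 and incompressibility, I1 = lam^2 + lam^-2 + 1.
        """
        I1 = lam * lam + 1.0 / (lam * lam) + 1.0
        x = I1 - 3.0
        dUdI1 = 0.0
        for i, ci in enumerate(self.c, start=1):
            dUdI1 += i * ci * x ** (i - 1)
        return dUdI1 * (2.0 * lam - 2.0 / lam ** 3)


def mean_arterial_pressure(P_d: float, P_s: float) -> float:
    """Time-weighted mean pressure P_m = P_d + (P_s - P_d) / 3 (mmHg)."""
    if P_s < P_d:
        raise ValueError("systolic pressure must exceed diastolic")
    return P_d + (P_s - P_d) / 3.0


def strain_energy(tube: VesselTube, I1_bar: float, J_el: float = 1.0) -> float:
    """Strain-energy density (MPa) at the given invariants.

    Higher-order volumetric terms are absent (their coefficients are zero,
    meaning the terms are dropped, not divided by zero).
    """
    if I1_bar < 3.0:
        raise ValueError("I1_bar must be >= 3")
    if J_el <= 0.0:
        raise ValueError("J_el must be positive")
    x = I1_bar - 3.0
    U = sum(ci * x ** i for i, ci in enumerate(tube.c, start=1))
    U += (J_el - 1.0) ** 2 / tube.D1
    return float(U)


def _lumen_pressure(tube: VesselTube, r_i: float) -> float:
    """Luminal pressure (MPa) producing inner radius ``r_i`` (mm).

    Incompressible plane-strain mapping r^2 = R^2 - R_ref^2 + r_i^2;
    P = integral over the wall of (sigma_theta - sigma_r) / r dr with
    sigma_theta - sigma_r = lambda dW/dlambda.
    """
    Ri, Ro = tube.R_ref, tube.R_ref + tube.thickness
    off = r_i * r_i - Ri * Ri

    def integrand(R: float) -> float:
        r2 = R * R + off
        r = math.sqrt(r2)
        lam = r / R
        return tube.dW_dlambda(lam) * lam / r2 * R

    val, _ = quad(integrand, Ri, Ro, limit=100)
    return val


def pressure_radius(tube: VesselTube, P_mmHg: float, tol: float = 1e-6) -> float:
    """Inner radius (mm) of the closed tube at luminal pressure ``P`` (mmHg)."""
    if not (0.0 <= P_mmHg <= 200.0):
        raise ValueError("pressure outside the supported 0..200 mmHg range")
    P = P_mmHg * MMHG_TO_MPA
    if P == 0.0:
        return tube.R_ref

    def f(r_i: float) -> float:
        return _lumen_pressure(tube, r_i) - P

    lo = tube.R_ref
    hi = tube.R_ref * 1.05
    for _ in range(60):
        if f(hi) > 0.0:
            break
        hi *= 1.05
    else:
        raise RuntimeError(
            "no inflation root found: pressure-radius response "
            f"reaches only {_lumen_pressure(tube, hi) / MMHG_TO_MPA:.1f} mmHg")
    return float(brentq(f, lo, hi, xtol=tol))


def radial_stiffness(tube: VesselTube, P_mmHg: float, band_width: float) -> float:
    """Effective radial line stiffness (N/mm) of the wall around ``P``.

    Linearizes the pressure-radius response at ``P`` and spreads the load
    over a circumferential contact band of axial width ``band_width``:
    k = dP/dr * 2 pi r * w.  Used to couple the tube to ring contact.
    """
    dP = 1.0  # mmHg
    r0 = pressure_radius(tube, P_mmHg)
    r1 = pressure_radius(tube, min(P_mmHg + dP, 200.0))
    dPdr = dP * MMHG_TO_MPA / max(r1 - r0, 1e-9)   # MPa/mm
    return dPdr * 2.0 * math.pi * r0 * band_width


def size_vessel(config: RingConfig, oversize_pct: float = 10.0,
                P_m: float | None = None, P_d: float = 80.0, P_s: float = 120.0,
                thickness: float = 2.0) -> VesselTube:
    """Choose the unloaded tube radius for a prescribed ring oversize.

    The inner radius at the mean arterial pressure ``P_m`` (default from
    ``P_d``/``P_s`` via the time-weighted rule) equals
    ``R_ring / (1 + oversize/100)``; length is twice the ring diameter,
    wall thickness 2 mm.
    """
    if oversize_pct <= 0.0:
        raise ValueError("oversize must be positive")
    if P_m is None:
        P_m = mean_arterial_pressure(P_d, P_s)
    target = config.R_ring / (1.0 + oversize_pct / 100.0)

    def f(R_ref: float) -> float:
        t = VesselTube(R_ref=R_ref, thickness=thickness,
                       length=2.0 * config.D_ring)
        return pressure_radius(t, P_m) - target

    lo, hi = target * 0.7, target * 1.001
    if f(hi) < 0.0:
        raise RuntimeError("target radius not attainable (tube too stiff?)")
    R_ref = brentq(f, lo, hi, xtol=1e-8)
    return VesselTube(R_ref=float(R_ref), thickness=thickness,
                      length=2.0 * config.D_ring)
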