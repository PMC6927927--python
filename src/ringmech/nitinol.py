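"""One-dimensional superelastic Nitinol constitutive model.

Implements the stress-induced austenite/martensite transformation of a
Nitinol wire fiber at body temperature (37 degC): linear-elastic response
with a phase-mixture modulus, flat forward/reverse transformation plateaus
bounded by start/end stresses, open hysteresis, and tension--compression
asymmetry (the compression plateau starts at a higher stress magnitude).

The transformation kinetics are linear: the martensite volume fraction
``xi`` evolves proportionally to the driving stress between the start and
end values of the active transformation surface.  Unloading/reloading
inside the hysteresis loop is elastic.  The model is rate-independent; no
temperature dependence is implemented (all parameters are isothermal
calibrations at 37 degC).

Units: stress in MPa, strain dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "NitinolParams",
    "MaterialState",
    "ConvergenceError",
    "update_state",
    "drive_cycle",
    "tangent_modulus",
    "NITINOL_37C",
]


class ConvergenceError(RuntimeError):
    """Raised when the local stress-update fails to find a consistent state."""


@dataclass(frozen=True)
class NitinolParams:
    """Superelastic material constants of a Nitinol wire at 37 degC.

    Attributes
    ----------
    E_A, E_M : float
        Austenite / martensite Young's moduli (MPa).
    nu_A, nu_M : float
        Poisson ratios (used for the elastic shear modulus of the wire).
    eps_L : float
        Magnitude of the full transformation strain (dimensionless).
    sigma_LS, sigma_LE : float
        Start / end stress of forward transformation in tension (MPa).
    sigma_US, sigma_UE : float
        Start / end stress of reverse transformation in tension (MPa).
    sigma_CS : float
        Start stress magnitude of forward transformation in compression
        (MPa).  The remaining compression surfaces are the tension surfaces
        scaled by ``sigma_CS / sigma_LS`` unless ``compression_scale`` is
        given explicitly.
    density : float
        Mass density (g/cm^3); informational only, the solver is
        quasi-static.
    """

    E_A: float = 59000.0
    nu_A: float = 0.33
    E_M: float = 26500.0
    nu_M: float = 0.33
    eps_L: float = 0.05
    sigma_LS: float = 636.0
    sigma_LE: float = 740.0
    sigma_US: float = 430.0
    sigma_UE: float = 302.0
    sigma_CS: float = 965.0
    density: float = 6.45
    compression_scale: float | None = None

    def __post_init__(self) -> None:
        if not (self.E_A > self.E_M > 0.0):
            raise ValueError("moduli must satisfy E_A > E_M > 0")
        if not (0.0 < self.eps_L < 1.0):
            raise ValueError("eps_L must lie in (0, 1)")
        if not (self.sigma_LS < self.sigma_LE):
            raise ValueError("sigma_LS must be below sigma_LE")
        if not (self.sigma_US > self.sigma_UE):
            raise ValueError("sigma_US must exceed sigma_UE")
        if not (self.sigma_UE < self.sigma_LS):
            raise ValueError("hysteresis loop must be open (sigma_UE < sigma_LS)")
        if not (self.sigma_CS > self.sigma_LS):
            raise ValueError("compression onset must exceed tension onset")

    @property
    def comp_scale(self) -> float:
        """Stress scale of the compression surfaces relative to tension."""
        if self.compression_scale is not None:
            return self.compression_scale
        return self.sigma_CS / self.sigma_LS

    @property
    def shear_modulus(self) -> float:
        """Elastic (austenite) shear modulus, MPa."""
        return self.E_A / (2.0 * (1.0 + self.nu_A))


@dataclass(frozen=True)
class MaterialState:
    """History-carrying state of one material fiber."""

    xi: float = 0.0         # martensite volume fraction, 0..1
    eps_tr: float = 0.0     # signed transformation strain
    eps_total: float = 0.0  # total strain
    sigma: float = 0.0      # stress, MPa


#: Wire parameters calibrated at 37 degC (the package's standard preset).
NITINOL_37C = NitinolParams()

_SURF_TOL = 1e-10  # MPa, surface-consistency tolerance
_MAX_STAGES = 6


def _mixture_modulus(p: NitinolParams, xi: np.ndarray) -> np.ndarray:
    return p.E_A + xi * (p.E_M - p.E_A)


def update_arrays(
    p: NitinolParams,
    xi: np.ndarray,
    eps_tr: np.ndarray,
    eps: np.ndarray,
):
    """Vectorized stress update.

    Maps committed internal state ``(xi, eps_tr)`` and a target total
    strain ``eps`` to ``(sigma, xi_new, eps_tr_new, tangent)``.  Pure
    function: the committed arrays are not modified, so trial evaluations
    (finite-difference tangents, line searches) are safe.
    """
    xi = np.asarray(xi, dtype=float).copy()
    eps_tr = np.asarray(eps_tr, dtype=float).copy()
    eps = np.asarray(eps, dtype=float)
    if not np.all(np.isfinite(eps)):
        raise ValueError("non-finite strain passed to Nitinol update")

    dE = p.E_M - p.E_A
    rho_c = p.comp_scale
    # per-fiber transformation side: sign of eps_tr while transformed
    side = np.where(xi > 1e-14, np.sign(eps_tr), 0.0)
    mech = np.zeros(xi.shape)  # 0 elastic, +1 forward, -1 reverse (last stage)
    sat = np.zeros(xi.shape, dtype=bool)  # clamped at xi == 1

    for _ in range(_MAX_STAGES):
        E = _mixture_modulus(p, xi)
        sig = E * (eps - eps_tr)
        s = np.where(side != 0.0, side, np.sign(sig))
        s = np.where(s == 0.0, 1.0, s)
        scale = np.where(s > 0.0, 1.0, rho_c)
        sLS, sLE = scale * p.sigma_LS, scale * p.sigma_LE
        sUS, sUE = scale * p.sigma_US, scale * p.sigma_UE
        ef = s * eps
        sf = s * sig
        fwd_line = sLS + xi * (sLE - sLS)
        rev_line = sUE + xi * (sUS - sUE)
        fwd = (sf > fwd_line + _SURF_TOL) & (xi < 1.0 - 1e-14)
        rev = (sf < rev_line - _SURF_TOL) & (xi > 1e-14)
        if not (fwd.any() or rev.any()):
            break

        again = np.zeros(xi.shape, dtype=bool)
        for mask, dS, start in ((fwd, sLE - sLS, sLS), (rev, sUS - sUE, sUE)):
            if not mask.any():
                continue
            a = -dE * p.eps_L  # > 0
            b = dE * ef - p.E_A * p.eps_L - dS
            c = p.E_A * ef - start
            disc = b * b - 4.0 * a * c
            if np.any(disc[mask] < 0.0):
                raise ConvergenceError(
                    "no consistent transformation state; min discriminant "
                    f"{disc[mask].min():.3e}"
                )
            root = (-b[mask] - np.sqrt(disc[mask])) / (2.0 * a)
            xi_new = xi.copy()
            xi_new[mask] = root
            if mask is fwd:
                over = mask & (xi_new > 1.0)
                xi = np.where(mask, np.minimum(xi_new, 1.0), xi)
                sat |= over
                mech = np.where(mask & ~over, 1.0, mech)
                mech = np.where(over, 0.0, mech)
            else:
                under = mask & (xi_new < 0.0)
                xi = np.where(mask, np.maximum(xi_new, 0.0), xi)
                side = np.where(under, 0.0, side)
                mech = np.where(mask & ~under, -1.0, mech)
                mech = np.where(under, 0.0, mech)
                again |= under  # may cross to the opposite side
            eps_tr = np.where(mask, s * xi * p.eps_L, eps_tr)
            side = np.where(mask & (xi > 1e-14), s, side)
        if not again.any():
            break

    E = _mixture_modulus(p, xi)
    sigma = E * (eps - eps_tr)

    # algorithmically consistent tangent of the final active branch
    s = np.where(side != 0.0, side, np.where(sigma >= 0.0, 1.0, -1.0))
    scale = np.where(s > 0.0, 1.0, rho_c)
    ef = s * eps
    dS_f = scale * (p.sigma_LE - p.sigma_LS)
    dS_r = scale * (p.sigma_US - p.sigma_UE)
    denom_f = dS_f + E * p.eps_L - dE * (ef - xi * p.eps_L)
    denom_r = dS_r + E * p.eps_L - dE * (ef - xi * p.eps_L)
    tangent = np.where(
        mech > 0.5,
        dS_f * E / denom_f,
        np.where(mech < -0.5, dS_r * E / denom_r, E),
    )
    return sigma, xi, eps_tr, tangent


def update_state(p: NitinolParams, state: MaterialState, eps_new: float) -> MaterialState:
    """Advance one fiber from its committed state to total strain ``eps_new``.

    Elastic below the active transformation surface (phase-mixture modulus),
    forward transformation between the loading start/end stresses (with the
    compression-shifted surfaces for negative stress), reverse transformation
    between the unloading start/end stresses.  Load-history dependent: two
    states with equal total strain may carry different stress.
    """
    if not np.isfinite(eps_new):
        raise ValueError("non-finite strain")
    sig, xi, etr, _ = update_arrays(
        p, np.array([state.xi]), np.array([state.eps_tr]), np.array([eps_new])
    )
    return MaterialState(
        xi=float(xi[0]), eps_tr=float(etr[0]), eps_total=float(eps_new),
        sigma=float(sig[0]),
    )


def drive_cycle(p: NitinolParams, eps_path: Iterable[float]) -> list[MaterialState]:
    """Apply :func:`update_state` sequentially from the virgin state."""
    state = MaterialState()
    out: list[MaterialState] = []
    for e in eps_path:
        state = update_state(p, state, float(e))
        out.append(state)
    return out


def tangent_modulus(
    p: NitinolParams, state: MaterialState, direction: str = "loading"
) -> float:
    """Consistent tangent d(sigma)/d(eps) for an infinitesimal step.

    ``direction`` selects the probing sense ("loading" increases strain,
    "unloading" decreases it); on a transformation surface the two differ.
    """
    if direction not in ("loading", "unloading"):
        raise ValueError("direction must be 'loading' or 'unloading'")
    h = 1e-7 if direction == "loading" else -1e-7
    _, _, _, tang = update_arrays(
        p,
        np.array([state.xi]),
        np.array([state.eps_tr]),
        np.array([state.eps_total + h]),
    )
    return float(tang[0])
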