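"""The 'saddle pull test': structural stiffness of a formed ring bundle.

An oversized ring deployed in a cylindrical vessel takes a saddle shape
with two peaks (A, C) and two valleys (B, D).  The laboratory version of
this deformation ties the ring at its four quarter points with
polyethylene strings and drives a tensile machine crosshead so the ring
cycles between the saddle shapes it would take at 30% and 10% oversize,
after an initial pull to an extreme that emulates compaction strains.

The simulated rig holds the valleys in the ring plane and pulls the two
peak strings toward a common crosshead point on the ring axis (symmetric
pyramidal convergence); strings are axial spring connectors of stiffness
7.41 N/mm per 100 mm length, slack under compression.  Peaks and valleys
are rotationally restrained along the wire tangent (Rotation_x = 0 at
A, C and Rotation_y = 0 at B, D), mirroring the near-total twist
restraint the physical strings and sutures provide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import beam_fe as bf
from .forming import RingConfig

__all__ = [
    "SaddleConfig",
    "string_stiffness",
    "saddle_positions_from_oversize",
    "run_saddle",
    "stiffness_deviation",
    "crosshead_force",
]

#: reference string stiffness: N/mm for a 100 mm string
STRING_STIFFNESS_REF = 7.41
STRING_LENGTH_REF = 100.0


def string_stiffness(length: float, k_ref: float = STRING_STIFFNESS_REF,
                     L_ref: float = STRING_LENGTH_REF) -> float:
    """Axial stiffness of a string of given length: k(L) = k_ref * L_ref / L."""
    if length <= 0.0:
        raise ValueError("string length must be positive")
    return k_ref * L_ref / length


@dataclass
class SaddleConfig:
    """Parameters of the saddle pull test rig and displacement program."""

    string_stiffness_ref: float = STRING_STIFFNESS_REF   # N/mm per 100 mm
    string_length: float = 100.0                         # mm
    oversize_high: float = 30.0     # % oversize at the high-deflection bound
    oversize_low: float = 10.0      # % oversize at the low-deflection bound
    pull_overshoot: float = 1.5     # extreme pull = overshoot x high bound
    n_cycles: int = 3
    n_inc_pull: int = 12
    n_inc_cycle: int = 8


def saddle_positions_from_oversize(config: RingConfig, oversize_pct: float):
    """Vessel radius and crosshead displacement for a given oversize.

    oversize = (R_ring / R_vessel - 1) * 100%, so the target vessel radius
    is ``R_ring / (1 + oversize/100)``.  The saddle half-height of a ring of
    (inextensible) radius R confined to that cylinder is
    ``h = sqrt(R_vessel (R_ring - R_vessel))`` (two-lobe mode, first-order
    arc-length conservation); the rig's peak strings travel ``2 h`` with
    the valleys held in plane.

    Returns ``(R_vessel, u_crosshead)`` in mm.
    """
    if not (0.0 < oversize_pct <= 100.0):
        raise ValueError("oversize must lie in (0, 100] percent")
    R = config.R_ring
    R_v = R / (1.0 + oversize_pct / 100.0)
    h = math.sqrt(R_v * (R - R_v))
    return R_v, 2.0 * h


def crosshead_force(model: bf.BeamModel) -> float:
    """Vertical (axis-direction) force carried by the crosshead strings, N."""
    x = model.x
    F = 0.0
    for sp in model.springs:
        d = sp.anchor - x[sp.node]
        L = float(np.linalg.norm(d))
        ext = L - sp.natural_length
        if sp.allow_slack and ext < 0.0:
            continue
        F += sp.k * ext * d[2] / L
    return float(F)


def run_saddle(model: bf.BeamModel, config: SaddleConfig | None = None) -> pd.DataFrame:
    """Execute the saddle pull program on a formed ring model.

    Returns a table with columns ``step``, ``displacement_mm``, ``force_N``,
    ``region_of_interest`` (True for the settled cycling phase, i.e. cycles
    after the first).  The model is mutated (final state = end of program).
    """
    config = config or SaddleConfig()
    ring: RingConfig = model.ring_config
    q = model.quarter_nodes
    A, B, C, D = q["A"], q["B"], q["C"], q["D"]
    R = ring.R_ring

    model._build_dofmap()
    model.fixed = {}
    # rig restraints: valleys in plane, tangential translations blocked,
    # twist about the wire tangent suppressed at all four points
    model.fix(A, (0, 3))          # Disp_x = 0, Rotation_x = 0
    model.fix(C, (0, 3))
    model.fix(B, (1, 2, 4))       # Disp_y = 0, Disp_z = 0, Rotation_y = 0
    model.fix(D, (1, 2, 4))

    k = string_stiffness(config.string_length, config.string_stiffness_ref)
    z0 = math.sqrt(max(config.string_length ** 2 - R * R, 1.0))
    anchor0 = np.array([0.0, 0.0, z0])
    model.springs = []
    sp_a = model.add_spring(A, anchor0, k)
    sp_c = model.add_spring(C, anchor0, k)

    _, u_high = saddle_positions_from_oversize(ring, config.oversize_high)
    _, u_low = saddle_positions_from_oversize(ring, config.oversize_low)
    u_ext = config.pull_overshoot * u_high

    rows: list[dict] = []

    def recorder(m: bf.BeamModel, step: str, t: float) -> None:
        z = sp_a.anchor[2]
        rows.append(
            dict(step=step, displacement_mm=z - z0, force_N=crosshead_force(m),
                 region_of_interest=step.startswith("cycle") and
                 int(step.split("_")[1]) >= 2,
                 string_slack=any(sp.slack for sp in m.springs))
        )

    def move_to(u_from: float, u_to: float):
        def apply(m: bf.BeamModel, t: float) -> None:
            z = z0 + u_from + t * (u_to - u_from)
            sp_a.anchor[2] = z
            sp_c.anchor[2] = z
        return apply

    steps = [bf.Step("pull", move_to(0.0, u_ext), n_inc=config.n_inc_pull),
             bf.Step("unload", move_to(u_ext, u_low), n_inc=config.n_inc_pull)]
    for i in range(1, config.n_cycles + 1):
        steps.append(bf.Step(f"cycle_{i}_up", move_to(u_low, u_high),
                             n_inc=config.n_inc_cycle))
        steps.append(bf.Step(f"cycle_{i}_down", move_to(u_high, u_low),
                             n_inc=config.n_inc_cycle))
    model.solve_report = bf.assemble_and_solve(model, steps, recorder=recorder)
    return pd.DataFrame(rows)


def stiffness_deviation(sim: pd.DataFrame, reference: pd.DataFrame,
                        n_grid: int = 50) -> tuple[float, float]:
    """Percent force deviation range of ``sim`` from ``reference``.

    Both tables need ``displacement_mm`` / ``force_N`` columns (the cycling
    region of a saddle run); curves are interpolated on a common
    displacement grid over the overlap and the (min, max) of
    ``|F_sim - F_ref| / F_ref * 100`` is returned.
    """
    s = sim[sim.get("region_of_interest", True) == True] if "region_of_interest" in sim else sim
    r = reference[reference.get("region_of_interest", True) == True] \
        if "region_of_interest" in reference else reference
    lo = max(s.displacement_mm.min(), r.displacement_mm.min())
    hi = min(s.displacement_mm.max(), r.displacement_mm.max())
    if not (hi > lo):
        raise ValueError("displacement ranges do not overlap")
    grid = np.linspace(lo, hi, n_grid)

    def interp(df: pd.DataFrame) -> np.ndarray:
        d = df.sort_values("displacement_mm")
        return np.interp(grid, d.displacement_mm.to_numpy(), d.force_N.to_numpy())

    fs, fr = interp(s), interp(r)
    dev = np.abs(fs - fr) / np.where(np.abs(fr) > 1e-12, np.abs(fr), np.nan) * 100.0
    dev = dev[np.isfinite(dev)]
    if dev.size == 0:
        raise ValueError("reference force is zero over the whole overlap")
    return float(dev.min()), float(dev.max())
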