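"""Manufacturing step: form a straight Nitinol wire into a closed ring.

Winding the straight wire stock onto a mandrel locks a bending-strain
field into the ring: the outer fiber carries ``eps = R_wire / R_ring``.
This pre-strain shifts the operating point of the superelastic material
and softens the ring's structural response, so it must be part of the
simulated history.

The forming program is a ramped intrinsic-curvature drive: the wire's
strain-free reference is the straight stock, the mesh lives on the closed
circle, and the fiber states are marched monotonically from zero to the
bending state of the circle before the free ring is equilibrated.  This
lands on a closed circle with the correct (proportional-bending) material
history without simulating mandrel contact.  ``include_prestrain=False``
instead creates the ring directly as a circle of virgin material — the
comparison variant that omits the manufacturing process.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import beam_fe as bf
from .nitinol import NitinolParams, update_arrays
from .packing import BundleGeometry

__all__ = ["RingConfig", "form_ring", "analytic_forming_strain"]


@dataclass(frozen=True)
class RingConfig:
    """Geometry of one ring bundle."""

    d_wire: float           # wire diameter, mm
    D_ring: float           # ring mean diameter, mm
    n_turns: int
    include_prestrain: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        if self.d_wire < 0.0 or self.D_ring <= 0.0:
            raise ValueError("diameters must be positive")
        if self.n_turns < 1:
            raise ValueError("n_turns must be >= 1")
        if self.d_wire > 0 and self.D_ring / self.d_wire < 20.0:
            warnings.warn(
                f"ring is not slender (D_ring/d_wire = {self.D_ring / self.d_wire:.1f} < 20); "
                "beam kinematics may be inaccurate",
                stacklevel=2,
            )

    @property
    def r_wire(self) -> float:
        return self.d_wire / 2.0

    @property
    def R_ring(self) -> float:
        return self.D_ring / 2.0

    @property
    def bundle(self) -> BundleGeometry:
        return BundleGeometry(self.n_turns, self.r_wire)


def analytic_forming_strain(config: RingConfig) -> float:
    """Peak bending strain of the formed wire: ``R_wire / R_ring``."""
    if config.D_ring <= 0.0:
        raise ValueError("ring diameter must be positive")
    return config.r_wire / config.R_ring


def form_ring(
    config: RingConfig,
    n_el: int = 48,
    material: NitinolParams | None = None,
    n_form_inc: int = 16,
) -> bf.BeamModel:
    """Build the closed, welded ring model with its manufacturing history.

    Returns a :class:`~ringmech.beam_fe.BeamModel` whose fibers carry the
    forming bending history (or virgin states when
    ``config.include_prestrain`` is false), equilibrated as a free ring.
    The quarter points A (+y), B (+x), C (-y), D (-x) — peaks A, C and
    valleys B, D of the in-vivo saddle — are exposed as
    ``model.quarter_nodes``.
    """
    if n_el % 4:
        n_el += 4 - n_el % 4
    material = material or NitinolParams()
    R = config.R_ring
    N = n_el
    phi = 2.0 * math.pi * np.arange(N + 1) / N
    X0 = np.stack([R * np.cos(phi), R * np.sin(phi), np.zeros(N + 1)], axis=1)
    t_hat = np.stack([-np.sin(phi), np.cos(phi), np.zeros(N + 1)], axis=1)
    r_hat = np.stack([np.cos(phi), np.sin(phi), np.zeros(N + 1)], axis=1)
    z_hat = np.tile(np.array([0.0, 0.0, 1.0]), (N + 1, 1))
    # node triads [tangent, -radial, z]: the frame rotates about +z along
    # the wire, so the forming curvature is a pure local e3 bending
    R0 = np.stack([t_hat, -r_hat, z_hat], axis=2)
    conn = np.stack([np.arange(N), np.arange(1, N + 1)], axis=1)
    L0 = np.full(N, 2.0 * math.pi * R / N)   # material (straight stock) length

    sec = bf.WireSection(r_wire=config.r_wire, material=material)
    model = bf.BeamModel(X0, R0, conn, sec, L0, turn_mult=config.n_turns)
    model.ring_config = config
    model.r_bundle = config.bundle.r_bundle
    model.quarter_nodes = {"B": 0, "A": N // 4, "D": N // 2, "C": 3 * N // 4}
    bf.weld_close(model, N, 0)

    if not config.include_prestrain:
        # ring created directly as a circle: current shape is strain-free
        bf.retare(model)
        model._build_dofmap()
        return model

    # forming ramp: march every fiber monotonically to the bending strain of
    # the closed circle (proportional loading from the straight reference).
    # Axial strain is measured from the reference *chord* (initially-curved
    # element), so the pure-bending circle carries no spurious membrane
    # compression; the bending history is still relative to straight stock.
    xa, xb, Ra, Rb = bf._gather(model, model.u, model.Rn)
    c, tha, thb = bf._local_dofs(xa, xb, Ra, Rb, model.tare_a, model.tare_b)
    model.c_ref = c.copy()
    eps0, kap, g2, g3 = bf._strains_from_dl(model, c, tha, thb)
    eps_target = (
        eps0[:, None]
        + kap[:, 1, None] * sec.fib_z
        - kap[:, 2, None] * sec.fib_y
    )
    for t in np.linspace(1.0 / n_form_inc, 1.0, n_form_inc):
        sig, xi, etr, _ = update_arrays(material, model.xi, model.eps_tr, t * eps_target)
        model.xi, model.eps_tr = xi, etr
        model.eps_fib, model.sig_fib = t * eps_target, sig

    # release: equilibrate the free welded ring (3-2-1 rigid-body support)
    model._build_dofmap()
    q = model.quarter_nodes
    model.fix(q["B"], (0, 1, 2))
    model.fix(q["A"], (0, 2))
    model.fix(q["D"], (2,))
    bf.assemble_and_solve(
        model, [bf.Step("release", lambda m, t: None, n_inc=1)]
    )
    model.fixed = {}
    return model
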