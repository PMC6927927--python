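"""Geometrically nonlinear 3-D beam finite elements for wire bundles.

A corotational two-node Timoshenko beam with fiber-discretized circular
cross-sections: every section integration point carries a superelastic
Nitinol state (:mod:`ringmech.nitinol`), so axial/bending resultants follow
the full transformation hysteresis, while torsion and transverse shear are
elastic.  A wire bundle of ``n`` superimposed turns is realized as a single
wire whose section resultants are multiplied by ``n`` (mathematically
identical to ``n`` coincident welded wires, which the model also supports
through DOF merging).

The solver is quasi-static and incremental-iterative (Newton with line
search, adaptive increment bisection, optional diagonal regularization),
with multi-point "weld" constraints, axial spring connectors, and penalty
contact against rigid cylindrical surfaces (with Coulomb-capped tangential
friction).  Units are mm / N / MPa throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from .nitinol import NitinolParams, update_arrays

__all__ = [
    "WireSection",
    "Cylinder",
    "Spring",
    "BeamModel",
    "Step",
    "SolveReport",
    "NonConvergenceError",
    "assemble_and_solve",
    "weld_close",
    "contact_forces",
    "reaction_forces",
    "make_straight_wire",
]

_FD_H = 1e-6  # finite-difference step for corotational kinematics


class NonConvergenceError(RuntimeError):
    def __init__(self, msg: str, report: "SolveReport | None" = None):
        super().__init__(msg)
        self.report = report


# --------------------------------------------------------------------------
# cross-section
# --------------------------------------------------------------------------

# Radial Gauss-Lobatto layers on [0, r] (the r = 0 node has zero area weight
# and is dropped); the surface layer is included so that peak outer-fiber
# strains are sampled exactly at the wire surface.
_LOBATTO_RHO = np.array([0.5 - 0.5 / math.sqrt(5.0), 0.5 + 0.5 / math.sqrt(5.0), 1.0])
_LOBATTO_W = np.array([5.0 / 12.0, 5.0 / 12.0, 1.0 / 12.0])


@dataclass
class WireSection:
    """Circular wire cross-section with a fiber integration grid."""

    r_wire: float                 # mm
    n_theta: int = 8
    material: NitinolParams = field(default_factory=NitinolParams)

    def __post_init__(self) -> None:
        r = self.r_wire
        th = 2.0 * math.pi * np.arange(self.n_theta) / self.n_theta
        rho = _LOBATTO_RHO * r
        self.fib_y = np.outer(rho, np.cos(th)).ravel()
        self.fib_z = np.outer(rho, np.sin(th)).ravel()
        self.fib_w = np.outer(
            _LOBATTO_W * _LOBATTO_RHO * r * r,
            np.full(self.n_theta, 2.0 * math.pi / self.n_theta),
        ).ravel()                              # sums to pi r^2
        self.area = math.pi * r * r
        self.I = math.pi * r ** 4 / 4.0
        self.J_t = math.pi * r ** 4 / 2.0
        G = self.material.shear_modulus
        self.GJ = G * self.J_t
        self.GAs = G * 0.9 * self.area         # shear coefficient ~0.9 (round)

    @property
    def n_fib(self) -> int:
        return self.fib_y.size


# --------------------------------------------------------------------------
# connectors and contact surfaces
# --------------------------------------------------------------------------


@dataclass
class Cylinder:
    """Rigid cylindrical contact surface, axis along global z.

    ``side`` = "outer": the wire lies inside the cylinder and is pushed
    inward when ``rho + offset > radius`` (compaction sheath, vessel wall);
    ``side`` = "inner": rigid core pushing the wire outward.  ``offset`` is
    the bundle envelope radius: contact acts at centerline +/- bundle
    radius, which realizes the bundle surface as a contact offset.
    """

    radius: float
    side: str = "outer"
    offset: float = 0.0
    k_pen: float = 200.0        # N/mm per node
    mu: float = 0.0
    k_tan: float = 200.0
    smooth: float = 0.02        # mm, C1 regularization width of the penalty
    active: bool = True
    anchors: np.ndarray | None = None   # committed friction anchors (n,3)


@dataclass
class Spring:
    """Axial connector between a node and a movable anchor point."""

    node: int
    anchor: np.ndarray
    k: float                    # N/mm
    natural_length: float
    allow_slack: bool = True
    slack: bool = False


@dataclass
class Step:
    """One load step, applied over pseudo-time t in [0, 1].

    ``apply(model, t)`` mutates prescribed displacements, contact radii,
    spring anchors and external forces; the solver chooses t adaptively.
    """

    name: str
    apply: Callable[["BeamModel", float], None]
    n_inc: int = 10
    record: bool = True
    #: continuous stabilization, as a fraction of force_scale / L_char;
    #: nonzero for steps that traverse unstable branches (crimping)
    stab_rel: float = 0.0


@dataclass
class SolveReport:
    steps: list = field(default_factory=list)
    converged: bool = True
    notes: list = field(default_factory=list)

    def log(self, step: str, t: float, iters: int, res: float) -> None:
        self.steps.append(dict(step=step, t=t, iterations=iters, residual=res))


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------


class BeamModel:
    """Nodes, beam elements, constraints, connectors, contacts and state."""

    def __init__(
        self,
        X0: np.ndarray,
        triads0: np.ndarray,
        conn: np.ndarray,
        section: WireSection,
        L0: np.ndarray,
        c_ref: np.ndarray | None = None,
        turn_mult: int = 1,
    ):
        self.X0 = np.asarray(X0, float)
        self.n_nodes = self.X0.shape[0]
        self.conn = np.asarray(conn, int)
        self.n_el = self.conn.shape[0]
        self.section = section
        self.L0 = np.asarray(L0, float)
        self.c_ref = self.L0.copy() if c_ref is None else np.asarray(c_ref, float)
        self.turn_mult = int(turn_mult)

        self.u = np.zeros((self.n_nodes, 3))
        self.Rn = np.array(triads0, float).copy()
        self.tare_a = np.repeat(np.eye(3)[None], self.n_el, axis=0)
        self.tare_b = np.repeat(np.eye(3)[None], self.n_el, axis=0)

        nf = section.n_fib
        self.xi = np.zeros((self.n_el, nf))
        self.eps_tr = np.zeros((self.n_el, nf))
        self.eps_fib = np.zeros((self.n_el, nf))
        self.sig_fib = np.zeros((self.n_el, nf))

        self.welds: list[tuple[int, int]] = []
        self.fixed: dict[int, float] = {}
        self.springs: list[Spring] = []
        self.contacts: dict[str, Cylinder] = {}
        self.F_ext = np.zeros((self.n_nodes, 6))
        self._dofmap: np.ndarray | None = None

    # -- topology ----------------------------------------------------------

    def _build_dofmap(self) -> None:
        parent = np.arange(self.n_nodes)

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a, b in self.welds:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
        roots = np.array([find(i) for i in range(self.n_nodes)])
        uniq, inv, counts = np.unique(roots, return_inverse=True,
                                      return_counts=True)
        self.node_group = inv
        # welded coincident nodes represent a single physical point: nodal
        # (contact) loads are shared so the point is not double-counted
        self.node_weight = 1.0 / counts[inv]
        self._dofmap = 6 * inv[:, None] + np.arange(6)[None, :]
        self.ndof = 6 * uniq.size

    @property
    def dofmap(self) -> np.ndarray:
        if self._dofmap is None:
            self._build_dofmap()
        return self._dofmap

    def add_weld(self, a: int, b: int, tol: float = 1e-6) -> None:
        gap = float(np.linalg.norm(self.X0[a] - self.X0[b]))
        if gap > tol:
            raise ValueError(
                f"weld requires coincident nodes: |x_{a} - x_{b}| = {gap:.3g} mm > {tol:g} mm"
            )
        self.welds.append((a, b))
        self._dofmap = None

    def fix(self, node: int, comps: Sequence[int], value: float = 0.0) -> None:
        for c in comps:
            self.fixed[int(self.dofmap[node, c])] = value

    def add_spring(self, node: int, anchor, k: float,
                   natural_length: float | None = None, allow_slack: bool = True) -> Spring:
        anchor = np.asarray(anchor, float).copy()
        if natural_length is None:
            natural_length = float(np.linalg.norm(self.X0[node] + self.u[node] - anchor))
        sp = Spring(node, anchor, float(k), float(natural_length), allow_slack)
        self.springs.append(sp)
        return sp

    def add_contact(self, name: str, cyl: Cylinder) -> Cylinder:
        if cyl.anchors is None:
            cyl.anchors = self.X0.copy()
        self.contacts[name] = cyl
        return cyl

    @property
    def x(self) -> np.ndarray:
        return self.X0 + self.u

    def max_fiber_strain(self) -> float:
        return float(np.abs(self.eps_fib).max())


def weld_close(model: BeamModel, node_a: int, node_b: int, tol: float = 1e-6) -> BeamModel:
    """Tie all six DOFs of two geometrically coincident nodes (wire 'weld')."""
    model.add_weld(node_a, node_b, tol=tol)
    return model


# --------------------------------------------------------------------------
# corotational kinematics
# --------------------------------------------------------------------------


def _rotvec_of(L):
    """Log map of near-identity rotation matrices, vectorized (|theta| < pi)."""
    w = 0.5 * np.stack(
        [L[..., 2, 1] - L[..., 1, 2],
         L[..., 0, 2] - L[..., 2, 0],
         L[..., 1, 0] - L[..., 0, 1]], axis=-1)
    s = np.linalg.norm(w, axis=-1)                       # sin(theta)
    c = 0.5 * (L[..., 0, 0] + L[..., 1, 1] + L[..., 2, 2] - 1.0)
    th = np.arctan2(s, c)
    fac = np.where(s > 1e-7, th / np.where(s > 1e-7, s, 1.0),
                   1.0 + th * th / 6.0)
    return w * fac[..., None]


def _matrix_of(w):
    """Exp map (Rodrigues) of rotation vectors, vectorized."""
    w = np.asarray(w, float)
    th = np.linalg.norm(w, axis=-1)
    small = th < 1e-8
    a = np.where(small, 1.0 - th * th / 6.0, np.sin(th) / np.where(small, 1.0, th))
    b = np.where(small, 0.5 - th * th / 24.0,
                 (1.0 - np.cos(th)) / np.where(small, 1.0, th * th))
    K = np.zeros(w.shape[:-1] + (3, 3))
    K[..., 0, 1], K[..., 0, 2] = -w[..., 2], w[..., 1]
    K[..., 1, 0], K[..., 1, 2] = w[..., 2], -w[..., 0]
    K[..., 2, 0], K[..., 2, 1] = -w[..., 1], w[..., 0]
    I = np.broadcast_to(np.eye(3), K.shape)
    return I + a[..., None, None] * K + b[..., None, None] * (K @ K)


def _mean_frame(xa, xb, Ra, Rb):
    """Corotated element frame E (columns e1, e2, e3) and chord length.

    The transverse reference is the (normalized) average of the two node
    triads' e2 axes — smooth, objective, and adequate for the moderate
    relative rotations a converged mesh exhibits.
    """
    d = xb - xa
    c = np.linalg.norm(d, axis=1)
    e1 = d / c[:, None]
    r2 = Ra[:, :, 1] + Rb[:, :, 1]
    e3 = np.cross(e1, r2)
    e3 /= np.linalg.norm(e3, axis=1)[:, None]
    e2 = np.cross(e3, e1)
    return np.stack([e1, e2, e3], axis=2), c


def _local_dofs(xa, xb, Ra, Rb, Ta, Tb):
    """Chord length + local deformational end rotations per element."""
    E, c = _mean_frame(xa, xb, Ra, Rb)
    Et = E.swapaxes(-1, -2)
    tha = _rotvec_of(Et @ Ra @ Ta)
    thb = _rotvec_of(Et @ Rb @ Tb)
    return c, tha, thb


def _perturb(xa, xb, Ra, Rb, k: int, h: float):
    """Perturb the k-th element DOF (0..11) by +h for all elements."""
    if k < 3:
        xa = xa.copy()
        xa[..., k] += h
    elif k < 6:
        dR = _matrix_of(h * np.eye(3)[k - 3])
        Ra = dR @ Ra
    elif k < 9:
        xb = xb.copy()
        xb[..., k - 6] += h
    else:
        dR = _matrix_of(h * np.eye(3)[k - 9])
        Rb = dR @ Rb
    return xa, xb, Ra, Rb


def _kinematic_stack(xa, xb, Ra, Rb, h: float):
    """Stack [base, 12 forward-perturbed] copies of the element end arrays.

    Input arrays have leading shape (..., m); output gains a new axis of
    length 13 in front for the unperturbed and per-DOF-perturbed variants
    used by the finite-difference corotational Jacobian.
    """
    XA = np.broadcast_to(xa, (13,) + xa.shape).copy()
    XB = np.broadcast_to(xb, (13,) + xb.shape).copy()
    RA = np.broadcast_to(Ra, (13,) + Ra.shape).copy()
    RB = np.broadcast_to(Rb, (13,) + Rb.shape).copy()
    for k in range(12):
        pa, pb, ra, rb = _perturb(xa, xb, Ra, Rb, k, h)
        XA[k + 1], XB[k + 1], RA[k + 1], RB[k + 1] = pa, pb, ra, rb
    return XA, XB, RA, RB


def _strains_from_dl(model: BeamModel, c, tha, thb):
    L0 = model.L0
    eps0 = (c - model.c_ref) / L0
    kap = (thb - tha) / L0[..., None]
    g2 = -(tha[..., 2] + thb[..., 2]) / 2.0
    g3 = (tha[..., 1] + thb[..., 1]) / 2.0
    return eps0, kap, g2, g3


def _section_state(model: BeamModel, eps0, kap, g2, g3):
    """Fiber strains -> Nitinol update -> section resultants.

    Leading dimensions broadcast: inputs may be (m,) or (P, m); the
    committed fiber state is broadcast over P (trial evaluations never
    mutate it).
    """
    sec = model.section
    eps_f = (
        eps0[..., None]
        + kap[..., 1, None] * sec.fib_z
        - kap[..., 2, None] * sec.fib_y
    )
    xi0 = np.broadcast_to(model.xi, eps_f.shape)
    etr0 = np.broadcast_to(model.eps_tr, eps_f.shape)
    sig, xi, etr, _ = update_arrays(sec.material, xi0, etr0, eps_f)
    m = float(model.turn_mult)
    w = sec.fib_w
    res = (
        m * sig @ w,                       # N
        m * sec.GJ * kap[..., 0],          # M1 (torsion)
        m * sig @ (w * sec.fib_z),         # M2
        -m * sig @ (w * sec.fib_y),        # M3
        m * sec.GAs * g2,                  # Q2
        m * sec.GAs * g3,                  # Q3
    )
    return res, (eps_f, sig, xi, etr)


def _f_dl(model: BeamModel, res):
    """Local force conjugate to (c, theta_a, theta_b)."""
    N, M1, M2, M3, Q2, Q3 = res
    L0 = model.L0
    return np.stack(
        [
            N,
            -M1,
            -M2 + 0.5 * L0 * Q3,
            -M3 - 0.5 * L0 * Q2,
            M1,
            M2 + 0.5 * L0 * Q3,
            M3 - 0.5 * L0 * Q2,
        ],
        axis=-1,
    )


def _forces_batch(model: BeamModel, xa, xb, Ra, Rb):
    """Element internal forces for stacked configurations.

    ``xa`` has shape (..., m, 3); returns ``f_el`` of shape (..., m, 12)
    plus the fiber state of the *first* leading configuration.  All 13
    kinematic variants (base + forward FD perturbations) of every
    configuration are evaluated in a single vectorized pass.
    """
    h = _FD_H
    lead = xa.shape[:-2]
    m = model.n_el
    XA, XB, RA, RB = _kinematic_stack(xa, xb, Ra, Rb, h)  # (13, ..., m, ...)
    flat = lambda A, tail: A.reshape((-1,) + tail)
    reps = int(np.prod((13,) + lead))
    Ta = np.broadcast_to(model.tare_a, (reps, m, 3, 3)).reshape(-1, 3, 3)
    Tb = np.broadcast_to(model.tare_b, (reps, m, 3, 3)).reshape(-1, 3, 3)
    c, tha, thb = _local_dofs(
        flat(XA, (3,)), flat(XB, (3,)), flat(RA, (3, 3)), flat(RB, (3, 3)), Ta, Tb
    )
    c = c.reshape((13,) + lead + (m,))
    tha = tha.reshape((13,) + lead + (m, 3))
    thb = thb.reshape((13,) + lead + (m, 3))

    strains = _strains_from_dl(model, c[0], tha[0], thb[0])
    res, fib = _section_state(model, *strains)
    fdl = _f_dl(model, res)                      # (..., m, 7)

    J = np.empty(lead + (m, 7, 12))
    dc = (c[1:] - c[0]) / h                      # (12, ..., m)
    da = (tha[1:] - tha[0]) / h
    db = (thb[1:] - thb[0]) / h
    J[..., 0, :] = np.moveaxis(dc, 0, -1)
    J[..., 1:4, :] = np.moveaxis(da, 0, -1)
    J[..., 4:7, :] = np.moveaxis(db, 0, -1)
    f_el = np.einsum("...ik,...i->...k", J, fdl)
    return f_el, fib, strains


def _gather(model: BeamModel, u, Rn):
    ca, cb = model.conn[:, 0], model.conn[:, 1]
    return model.X0[ca] + u[ca], model.X0[cb] + u[cb], Rn[ca], Rn[cb]


def _spring_force(sp: Spring, x_node: np.ndarray):
    d = x_node - sp.anchor
    L = float(np.linalg.norm(d))
    t = d / max(L, 1e-12)
    ext = L - sp.natural_length
    if sp.allow_slack and ext < 0.0:
        sp.slack = True
        return np.zeros(3), np.zeros((3, 3)), 0.0
    sp.slack = False
    f = -sp.k * ext * t                      # restoring force on the node
    K = sp.k * np.outer(t, t) + (sp.k * ext / max(L, 1e-12)) * (np.eye(3) - np.outer(t, t))
    return f, K, sp.k * ext


def _contact_node_forces(cyl: Cylinder, x: np.ndarray, anchors: np.ndarray):
    """Penalty normal + Coulomb-capped tangential force per node (n, 3)."""
    rho = np.maximum(np.hypot(x[:, 0], x[:, 1]), 1e-12)
    er = np.zeros_like(x)
    er[:, 0] = x[:, 0] / rho
    er[:, 1] = x[:, 1] / rho
    if cyl.side == "outer":
        pen = rho + cyl.offset - cyl.radius
    else:
        pen = cyl.radius - (rho - cyl.offset)
    act = pen > 0.0
    p0 = max(cyl.smooth, 1e-12)
    # C1-continuous penalty: quadratic ramp over the first p0 of penetration
    fn = np.where(
        pen <= 0.0, 0.0,
        np.where(pen < p0, cyl.k_pen * pen * pen / (2.0 * p0),
                 cyl.k_pen * (pen - 0.5 * p0)),
    )
    sgn = -1.0 if cyl.side == "outer" else 1.0
    F = sgn * fn[:, None] * er
    if cyl.mu > 0.0:
        dx = x - anchors
        dxt = dx - np.einsum("ni,ni->n", dx, er)[:, None] * er
        ft = -cyl.k_tan * dxt
        ftn = np.linalg.norm(ft, axis=1)
        cap = cyl.mu * fn
        over = act & (ftn > cap) & (ftn > 0.0)
        scale = np.ones_like(ftn)
        scale[over] = cap[over] / ftn[over]
        ft = ft * scale[:, None]
        ft[~act] = 0.0
        F = F + ft
    return F, fn, act


# --------------------------------------------------------------------------
# assembly and Newton solver
# --------------------------------------------------------------------------


def _assemble_residual(model: BeamModel, u, Rn):
    dm = model.dofmap
    r = np.zeros(model.ndof)
    f_el, fib, strains = _forces_batch(model, *_gather(model, u, Rn))
    ca, cb = model.conn[:, 0], model.conn[:, 1]
    edof = np.hstack([dm[ca], dm[cb]])
    np.add.at(r, edof.ravel(), f_el.ravel())

    x = model.X0 + u
    for sp in model.springs:
        f, _, _ = _spring_force(sp, x[sp.node])
        r[dm[sp.node, :3]] -= f
    for cyl in model.contacts.values():
        if not cyl.active:
            continue
        F, _, _ = _contact_node_forces(cyl, x, cyl.anchors)
        F = F * model.node_weight[:, None]
        np.add.at(r, dm[:, :3].ravel(), -F.ravel())

    np.add.at(r, dm.ravel(), -model.F_ext.ravel())
    return r, f_el, fib, strains, edof


def _assemble_stiffness(model: BeamModel, u, Rn, f_el, edof):
    K = np.zeros((model.ndof, model.ndof))
    h = _FD_H
    xa, xb, Ra, Rb = _gather(model, u, Rn)
    # stack [base, 12 perturbed] outer configurations; the batched force
    # evaluation uses the same forward-difference kinematic Jacobian for
    # every configuration, so the O(h) bias cancels in the columns
    XA, XB, RA, RB = _kinematic_stack(xa, xb, Ra, Rb, h)
    f_all, _, _ = _forces_batch(model, XA, XB, RA, RB)   # (13, m, 12)
    cols = np.moveaxis((f_all[1:] - f_all[0]) / h, 0, -1)  # (m, 12, 12)
    ii = np.repeat(edof, 12, axis=1).ravel()
    jj = np.tile(edof, (1, 12)).ravel()
    np.add.at(K, (ii, jj), cols.reshape(model.n_el, -1).ravel())

    dm = model.dofmap
    x = model.X0 + u
    for sp in model.springs:
        _, Ks, _ = _spring_force(sp, x[sp.node])
        idx = dm[sp.node, :3]
        K[np.ix_(idx, idx)] += Ks
    for cyl in model.contacts.values():
        if not cyl.active:
            continue
        F0, _, _ = _contact_node_forces(cyl, x, cyl.anchors)
        for k in range(3):
            xp = x.copy()
            xp[:, k] += h
            Fp, _, _ = _contact_node_forces(cyl, xp, cyl.anchors)
            dF = -(Fp - F0) / h * model.node_weight[:, None]
            for c2 in range(3):
                np.add.at(K, (dm[:, c2 + 0], dm[:, k]), dF[:, c2])
    return K


def _res_norm(model: BeamModel, r: np.ndarray, free: np.ndarray) -> float:
    w = np.ones(model.ndof)
    Lc = max(float(np.mean(model.L0)), 1e-6)
    rot = np.zeros(model.ndof, bool)
    for c in (3, 4, 5):
        rot[model.dofmap[:, c]] = True
    w[rot] = 1.0 / Lc
    return float(np.linalg.norm((r * w)[free], ord=np.inf))


def _advance(model: BeamModel, dq):
    dm = model.dofmap
    u = model.u + dq[dm[:, :3]]
    w = dq[dm[:, 3:]]
    wn = np.linalg.norm(w, axis=1)
    Rn = model.Rn.copy()
    big = wn > 1e-15
    if big.any():
        Rn[big] = _matrix_of(w[big]) @ Rn[big]
    return u, Rn


def _commit(model: BeamModel, fib) -> None:
    eps_f, sig, xi, etr = fib
    model.xi = xi
    model.eps_tr = etr
    model.eps_fib = eps_f
    model.sig_fib = sig
    x = model.X0 + model.u
    for cyl in model.contacts.values():
        if not cyl.active or cyl.mu <= 0.0:
            continue
        rho = np.maximum(np.hypot(x[:, 0], x[:, 1]), 1e-12)
        er = np.zeros_like(x)
        er[:, 0] = x[:, 0] / rho
        er[:, 1] = x[:, 1] / rho
        pen = (rho + cyl.offset - cyl.radius) if cyl.side == "outer" \
            else (cyl.radius - (rho - cyl.offset))
        p0 = max(cyl.smooth, 1e-12)
        pen_c = np.maximum(pen, 0.0)
        fn = np.where(pen_c < p0, cyl.k_pen * pen_c * pen_c / (2.0 * p0),
                      cyl.k_pen * (pen_c - 0.5 * p0))
        dx = x - cyl.anchors
        dxt = dx - np.einsum("ni,ni->n", dx, er)[:, None] * er
        ftn = cyl.k_tan * np.linalg.norm(dxt, axis=1)
        cap = cyl.mu * fn
        slip = (ftn > cap) & (ftn > 0.0)
        if slip.any():
            keep = np.where(slip, cap / np.maximum(ftn, 1e-30), 1.0)
            cyl.anchors[slip] = x[slip] - dxt[slip] * keep[slip, None]
        cyl.anchors[pen <= 0.0] = x[pen <= 0.0]


def _stab_terms(model: BeamModel, u, Rn, u_ref, R_ref, stab: float):
    """Viscous-type stabilization force and its (diagonal) stiffness.

    Penalizes motion away from the increment's starting configuration with
    coefficient ``stab`` (N/mm on translations, ``stab * Lc^2`` N mm/rad on
    rotations).  Regularizes traversal of unstable (negative-eigenvalue)
    equilibrium branches, analogous to automatic stabilization in
    commercial quasi-static solvers; the residual it adds at convergence is
    reported so runs can confirm it stays small.
    """
    dm = model.dofmap
    Lc = max(float(np.mean(model.L0)), 1e-6)
    rv = _rotvec_of(Rn @ np.swapaxes(R_ref, 1, 2))
    f = np.zeros(model.ndof)
    np.add.at(f, dm[:, :3].ravel(), (stab * (u - u_ref)).ravel())
    np.add.at(f, dm[:, 3:].ravel(), (stab * Lc * Lc * rv).ravel())
    kd = np.zeros(model.ndof)
    np.add.at(kd, dm[:, :3].ravel(), np.full(3 * model.n_nodes, stab))
    np.add.at(kd, dm[:, 3:].ravel(), np.full(3 * model.n_nodes, stab * Lc * Lc))
    return f, kd


def _newton(model: BeamModel, *, tol, max_iter, report, label, t,
            stab: float = 0.0, scale: float = 1.0, cap_bias: bool = True) -> bool:
    if stab > 0.0:
        max_iter = max_iter + 15    # snap traversal legitimately wanders
    free = np.ones(model.ndof, bool)
    for d in model.fixed:
        free[d] = False
    # prescribed translations are driven to their targets through the
    # Newton solves (via the K_fp coupling) rather than imposed as an
    # instantaneous kink; track (node, comp) pairs per prescribed dof
    dm = model.dofmap
    pres: list[tuple[int, int, int]] = []
    seen: set[int] = set()
    for n in range(model.n_nodes):
        for c in range(3):
            d = int(dm[n, c])
            if d in model.fixed and d not in seen:
                pres.append((d, n, c))
                seen.add(d)

    def _dqp() -> np.ndarray:
        v = np.zeros(model.ndof)
        for d, n, c in pres:
            v[d] = model.fixed[d] - model.u[n, c]
        return v

    u_ref, R_ref = model.u.copy(), model.Rn.copy()

    def full_residual(u, Rn):
        r, f_el, fib, strains, edof = _assemble_residual(model, u, Rn)
        if stab > 0.0:
            fs, _ = _stab_terms(model, u, Rn, u_ref, R_ref, stab)
            r = r + fs
        return r, f_el, fib, edof

    rn0 = None
    for it in range(max_iter):
        r, f_el, fib, edof = full_residual(model.u, model.Rn)
        rn = _res_norm(model, r, free)
        if not np.isfinite(rn):
            return False
        if rn0 is None:
            rn0 = rn
        elif it >= 8 and rn > 1e3 * rn0:
            return False        # clearly diverging; fail fast and bisect
        if rn < tol and float(np.abs(_dqp()).max()) < 1e-9:
            if stab > 0.0:
                fs, _ = _stab_terms(model, model.u, model.Rn, u_ref, R_ref, stab)
                fs_max = float(np.abs(fs).max())
                if cap_bias and fs_max > 0.02 * scale:
                    # converged only by leaning on the stabilization force:
                    # reject so the increment is retried smaller (the bias
                    # shrinks proportionally with the step)
                    report.notes.append(
                        f"{label}: rejected stabilized increment at t={t:.4f} "
                        f"(stab force {fs_max:.2e} N vs scale {scale:.2e})")
                    return False
                report.notes.append(
                    f"{label}: stabilized increment t={t:.4f}, "
                    f"max stabilization force {fs_max:.2e} N")
            _commit(model, fib)
            report.log(label, t, it, rn)
            return True
        K = _assemble_stiffness(model, model.u, model.Rn, f_el, edof)
        if stab > 0.0:
            _, kd = _stab_terms(model, model.u, model.Rn, u_ref, R_ref, stab)
            K = K + np.diag(kd)
        dqp = _dqp()
        rhs = -r[free]
        if np.any(dqp != 0.0):
            rhs = rhs - K[np.ix_(free, ~free)] @ dqp[~free]
        try:
            dqf = np.linalg.solve(K[np.ix_(free, free)], rhs)
        except np.linalg.LinAlgError:
            report.notes.append(
                f"{label}: singular stiffness (rigid-body mode?) at t={t:.4f}")
            return False
        dq = dqp.copy()
        dq[free] = dqf
        # full Newton step; damp only on severe blow-up (the residual may
        # legitimately rise transiently along a corotational path)
        u_try, R_try = _advance(model, dq)
        r2, _, _, _ = full_residual(u_try, R_try)
        rn2 = _res_norm(model, r2, free)
        if (not np.isfinite(rn2)) or (it > 1 and rn2 > 1e4 * max(rn, tol)):
            alpha, best = 0.5, None
            for _ in range(5):
                u_a, R_a = _advance(model, dq * alpha)
                r_a, _, _, _ = full_residual(u_a, R_a)
                rn_a = _res_norm(model, r_a, free)
                if np.isfinite(rn_a) and (best is None or rn_a < best[0]):
                    best = (rn_a, u_a, R_a)
                alpha *= 0.5
            if best is None:
                return False
            rn2, u_try, R_try = best
        model.u, model.Rn = u_try, R_try
    return False


def _force_scale(model: BeamModel) -> float:
    s = float(np.abs(model.sig_fib).max() * model.section.area) if model.sig_fib.size else 0.0
    return max(s, float(np.abs(model.F_ext).max()), 1.0)


def _snapshot(model: BeamModel):
    return (
        model.u.copy(), model.Rn.copy(), model.xi.copy(), model.eps_tr.copy(),
        model.eps_fib.copy(), model.sig_fib.copy(),
        {k: (c.radius, None if c.anchors is None else c.anchors.copy(), c.active)
         for k, c in model.contacts.items()},
        [(sp.anchor.copy(), sp.natural_length) for sp in model.springs],
        dict(model.fixed), model.F_ext.copy(),
    )


def _restore(model: BeamModel, snap) -> None:
    (u, Rn, xi, etr, epsf, sigf, cons, sps, fixed, fext) = snap
    model.u = u.copy()
    model.Rn = Rn.copy()
    model.xi = xi.copy()
    model.eps_tr = etr.copy()
    model.eps_fib = epsf.copy()
    model.sig_fib = sigf.copy()
    for k, (rad, anch, act) in cons.items():
        cyl = model.contacts[k]
        cyl.radius, cyl.active = rad, act
        if anch is not None:
            cyl.anchors = anch.copy()
    for sp, (a, ln) in zip(model.springs, sps):
        sp.anchor = a.copy()
        sp.natural_length = ln
    model.fixed = dict(fixed)
    model.F_ext = fext.copy()


def assemble_and_solve(
    model: BeamModel,
    steps: Sequence[Step],
    *,
    rtol: float = 1e-8,
    max_iter: int = 25,
    max_bisect: int = 14,
    recorder: Callable[[BeamModel, str, float], None] | None = None,
) -> SolveReport:
    """Run an ordered load program with adaptive increment bisection.

    Each converged increment commits the fiber Nitinol states and friction
    anchors, so history dependence is preserved across steps.  Raises
    :class:`NonConvergenceError` (carrying the report so far) if an
    increment keeps failing after ``max_bisect`` bisections.
    """
    report = SolveReport()
    model._build_dofmap()
    for step in steps:
        t = 0.0
        dt = 1.0 / step.n_inc
        n_fail = 0
        stab = 0.0
        Lc = max(float(np.mean(model.L0)), 1e-6)
        while t < 1.0 - 1e-12:
            t_try = min(1.0, t + dt)
            saved = _snapshot(model)
            step.apply(model, t_try)
            scale = _force_scale(model)
            stab_eff = max(stab, step.stab_rel * scale / Lc)
            ok = _newton(model, tol=max(1e-9, rtol * scale),
                         max_iter=max_iter, report=report, label=step.name,
                         t=t_try, stab=stab_eff, scale=scale,
                         cap_bias=(stab == 0.0))
            if ok:
                t = t_try
                if recorder is not None and step.record:
                    recorder(model, step.name, t)
                dt = min(dt * 1.25, 1.0 / step.n_inc)
                n_fail = 0
                stab *= 0.7
                if stab < 1e-6:
                    stab = 0.0
            else:
                _restore(model, saved)
                n_fail += 1
                dt *= 0.4
                if n_fail > 2:
                    # unstable branch: engage / strengthen viscous-type
                    # stabilization rather than bisecting further; each
                    # escalation also restores a workable step size (once
                    # the ladder tops out, plain bisection resumes)
                    base = 1e-3 * _force_scale(model) / Lc
                    new_stab = base if stab == 0.0 else min(stab * 10.0, 1e4 * base)
                    if new_stab > stab:
                        dt = max(dt, 0.05 / step.n_inc)
                    stab = new_stab
                    report.notes.append(
                        f"{step.name}: stabilization {stab:.2e} N/mm at t={t:.4f}")
                if n_fail > max_bisect or dt < 1e-7:
                    report.converged = False
                    raise NonConvergenceError(
                        f"step '{step.name}' failed to converge at t={t_try:.4f} "
                        f"(dt={dt:.2e}, {n_fail} consecutive failures)", report)
                report.notes.append(f"{step.name}: bisect to dt={dt:.3e} at t={t:.4f}")
    return report


def contact_forces(model: BeamModel, cylinder_id: str) -> np.ndarray:
    """Per-node contact force vectors (N) exerted ON the wire by a surface."""
    cyl = model.contacts[cylinder_id]
    if not cyl.active:
        return np.zeros((model.n_nodes, 3))
    _ = model.dofmap
    F, _, _ = _contact_node_forces(cyl, model.X0 + model.u, cyl.anchors)
    return F * model.node_weight[:, None]


def reaction_forces(model: BeamModel) -> dict[int, float]:
    """Reactions at constrained DOFs (N, or N mm for rotations)."""
    r, _, _, _, _ = _assemble_residual(model, model.u, model.Rn)
    return {d: float(r[d]) for d in model.fixed}


# --------------------------------------------------------------------------
# factories
# --------------------------------------------------------------------------


def make_straight_wire(length: float, n_el: int, section: WireSection,
                       turn_mult: int = 1, axis=None) -> BeamModel:
    """Straight strain-free wire along ``axis`` (default +x) from the origin."""
    axis = np.array([1.0, 0.0, 0.0]) if axis is None else np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    n_nodes = n_el + 1
    X0 = np.outer(np.linspace(0.0, length, n_nodes), axis)
    tmp = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e3 = np.cross(axis, tmp)
    e3 /= np.linalg.norm(e3)
    e2 = np.cross(e3, axis)
    R0 = np.repeat(np.stack([axis, e2, e3], axis=1)[None], n_nodes, axis=0)
    conn = np.stack([np.arange(n_el), np.arange(1, n_nodes)], axis=1)
    L0 = np.full(n_el, length / n_el)
    model = BeamModel(X0, R0, conn, section, L0, turn_mult=turn_mult)
    retare(model)
    return model


def retare(model: BeamModel) -> None:
    """Make the *current* configuration the strain-free reference."""
    xa, xb, Ra, Rb = _gather(model, model.u, model.Rn)
    E, c = _mean_frame(xa, xb, Ra, Rb)
    model.tare_a = np.einsum("mji,mjk->mik", Ra, E)
    model.tare_b = np.einsum("mji,mjk->mik", Rb, E)
    model.c_ref = c.copy()
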