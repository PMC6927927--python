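"""Beam finite-element core: closed-form oracles, constraints, contact."""

import numpy as np
import pytest

import ringmech.beam_fe as bf
from ringmech.forming import RingConfig, form_ring


def _section(r=0.1):
    return bf.WireSection(r_wire=r)


def _solve_residual(model):
    model._build_dofmap()
    r, *_ = bf._assemble_residual(model, model.u, model.Rn)
    return r


class TestSectionIntegration:
    def test_fiber_weights_integrate_area_and_inertia(self):
        sec = _section(0.37)
        assert sec.fib_w.sum() == pytest.approx(sec.area, rel=1e-12)
        I_num = float(sec.fib_w @ sec.fib_z ** 2)
        assert I_num == pytest.approx(sec.I, rel=1e-9)

    def test_surface_fibers_present(self):
        sec = _section(0.2)
        rho = np.hypot(sec.fib_y, sec.fib_z)
        assert rho.max() == pytest.approx(0.2, rel=1e-12)


class TestClosedFormOracles:
    def test_cantilever_tip_deflection(self):
        """Small-load tip deflection matches PL^3 / 3EI within 1 %."""
        sec = _section()
        m = bf.make_straight_wire(20.0, 16, sec)
        m.fix(0, range(6))
        P = 0.001

        def tip(model, t):
            model.F_ext[:] = 0.0
            model.F_ext[-1, 2] = P * t

        bf.assemble_and_solve(m, [bf.Step("tip", tip, n_inc=2)])
        w_th = P * 20.0 ** 3 / (3.0 * sec.material.E_A * sec.I)
        assert m.u[-1, 2] == pytest.approx(w_th, rel=0.01)

    def test_pure_bending_arc_strain(self):
        """End moment M = EI/R bends the wire to curvature 1/R; peak fiber
        strain equals r_wire / R within 0.5 %."""
        sec = _section()
        m = bf.make_straight_wire(30.0, 16, sec)
        m.fix(0, range(6))
        R = 60.0
        M = sec.material.E_A * sec.I / R

        def bend(model, t):
            model.F_ext[:] = 0.0
            model.F_ext[-1, 4] = -M * t

        bf.assemble_and_solve(m, [bf.Step("bend", bend, n_inc=4)])
        assert m.max_fiber_strain() == pytest.approx(0.1 / R, rel=0.005)

    def test_zero_load_zero_displacement(self):
        sec = _section()
        m = bf.make_straight_wire(10.0, 4, sec)
        m.fix(0, range(6))
        bf.assemble_and_solve(m, [bf.Step("noop", lambda mm, t: None, n_inc=1)])
        assert np.abs(m.u).max() == 0.0

    def test_pinched_ring_stiffness(self):
        """Two diametral point loads: thin-ring deflection
        delta = (pi/4 - 2/pi) P R^3 / EI within 3 %."""
        cfg = RingConfig(0.2, 40.0, 1, include_prestrain=False)
        m = form_ring(cfg, n_el=48)
        q = m.quarter_nodes
        # pull B and D outward along x (diametral pair)
        Pld = 0.002
        m.fix(q["A"], (0, 2))
        m.fix(q["C"], (0,))
        m.fix(q["B"], (1, 2))
        m.fix(q["D"], (1, 2))

        def load(model, t):
            model.F_ext[:] = 0.0
            model.F_ext[q["B"], 0] = Pld * t
            model.F_ext[q["D"], 0] = -Pld * t

        bf.assemble_and_solve(m, [bf.Step("pinch", load, n_inc=2)])
        sec = m.section
        R = cfg.R_ring
        # relative approach/separation of the two load points
        delta_th = (np.pi / 4.0 - 2.0 / np.pi) * Pld * R ** 3 / (
            sec.material.E_A * sec.I)
        delta = m.u[q["B"], 0] - m.u[q["D"], 0]
        assert delta == pytest.approx(delta_th, rel=0.03)


class TestConstraints:
    def test_weld_requires_coincidence(self):
        sec = _section()
        m = bf.make_straight_wire(10.0, 4, sec)
        with pytest.raises(ValueError, match="coincident"):
            bf.weld_close(m, 0, 2)

    def test_welded_ring_joint_does_not_open(self):
        """Welded wire ends move identically under load."""
        cfg = RingConfig(0.2, 40.0, 1, include_prestrain=False)
        m = form_ring(cfg, n_el=32)
        q = m.quarter_nodes
        m.fix(q["A"], (0, 1, 2))
        m.fix(q["C"], (1, 2))
        m.fix(q["D"], (2,))

        def load(model, t):
            model.F_ext[:] = 0.0
            model.F_ext[q["B"], 2] = 0.001 * t

        bf.assemble_and_solve(m, [bf.Step("z", load, n_inc=2)])
        gap = np.linalg.norm((m.X0[m.n_el] + m.u[m.n_el]) - (m.X0[0] + m.u[0]))
        assert gap < 1e-9

    def test_global_equilibrium(self):
        """External + reaction forces balance to < 1e-6 N."""
        sec = _section()
        m = bf.make_straight_wire(20.0, 12, sec)
        m.fix(0, range(6))
        Pld = 0.005

        def tip(model, t):
            model.F_ext[:] = 0.0
            model.F_ext[-1, 2] = Pld * t

        bf.assemble_and_solve(m, [bf.Step("tip", tip, n_inc=2)])
        reac = bf.reaction_forces(m)
        Fz_reac = reac[int(m.dofmap[0, 2])]   # force the support exerts
        assert abs(Fz_reac + Pld) < 1e-6


class TestSuperposition:
    def test_turn_multiplier_equals_coincident_welded_wires(self):
        """A bundle of n welded coincident wires and one wire with section
        multiplier n respond identically (the superposition principle)."""
        sec = _section()
        L, n_el, n_w = 20.0, 8, 3
        # model A: single wire, multiplier 3
        a = bf.make_straight_wire(L, n_el, sec, turn_mult=n_w)
        a.fix(0, range(6))
        # model B: three coincident wires, each multiplier 1, welded node-wise
        base = bf.make_straight_wire(L, n_el, sec)
        nn = n_el + 1
        X0 = np.tile(base.X0, (n_w, 1))
        R0 = np.tile(base.Rn, (n_w, 1, 1))
        conn = np.vstack([base.conn + k * nn for k in range(n_w)])
        L0 = np.tile(base.L0, n_w)
        b = bf.BeamModel(X0, R0, conn, sec, L0)
        bf.retare(b)
        for k in range(1, n_w):
            for i in range(nn):
                b.add_weld(i, k * nn + i)
        b.fix(0, range(6))

        P = 0.002

        def tip_a(model, t):
            model.F_ext[:] = 0.0
            model.F_ext[n_el, 2] = P * t

        bf.assemble_and_solve(a, [bf.Step("tip", tip_a, n_inc=2)])
        bf.assemble_and_solve(b, [bf.Step("tip", tip_a, n_inc=2)])
        assert b.u[n_el, 2] == pytest.approx(a.u[n_el, 2], rel=1e-8)


class TestContact:
    def _ring_in_cylinder(self, radius):
        cfg = RingConfig(0.2, 40.0, 1, include_prestrain=False)
        m = form_ring(cfg, n_el=32)
        m.r_bundle = 0.1
        m.add_contact("cyl", bf.Cylinder(radius=radius, side="outer",
                                         offset=0.1, k_pen=100.0))
        return m

    def test_no_penetration_no_force(self):
        m = self._ring_in_cylinder(25.0)     # ring radius 20 < 25
        m._build_dofmap()
        F = bf.contact_forces(m, "cyl")
        assert np.abs(F).max() == 0.0

    def test_frictionless_has_no_tangential_component(self):
        m = self._ring_in_cylinder(19.0)     # penetrating
        m._build_dofmap()
        F = bf.contact_forces(m, "cyl")
        x = m.x
        rho = np.hypot(x[:, 0], x[:, 1])
        er = np.stack([x[:, 0] / rho, x[:, 1] / rho, np.zeros_like(rho)], axis=1)
        tangential = F - np.einsum("ni,ni->n", F, er)[:, None] * er
        assert np.abs(tangential).max() < 1e-12

    def test_concentric_compression_self_equilibrated(self):
        """Ring pressed into a smaller concentric cylinder: net contact
        force vanishes while the radial (inward) sum is positive."""
        cfg = RingConfig(0.2, 40.0, 1, include_prestrain=False)
        m = form_ring(cfg, n_el=32)
        m.r_bundle = 0.1
        q = m.quarter_nodes
        m.fix(q["A"], (0, 2, 5))
        m.fix(q["C"], (0, 2))
        m.fix(q["B"], (1, 2))
        m.fix(q["D"], (1, 2))
        cyl = m.add_contact("cyl", bf.Cylinder(radius=19.9, side="outer",
                                               offset=0.1, k_pen=50.0))

        def shrink(model, t):
            model.contacts["cyl"].radius = 20.1 - t * 0.4   # to 19.7

        bf.assemble_and_solve(m, [bf.Step("shrink", shrink, n_inc=4)])
        F = bf.contact_forces(m, "cyl")
        net = np.linalg.norm(F.sum(axis=0))
        x = m.x
        rho = np.hypot(x[:, 0], x[:, 1])
        radial_in = -(F[:, 0] * x[:, 0] / rho + F[:, 1] * x[:, 1] / rho)
        assert radial_in.sum() > 0.01
        assert net < 1e-6 * max(radial_in.sum(), 1.0)


class TestSprings:
    def test_axial_spring_force_law(self):
        sec = _section()
        m = bf.make_straight_wire(10.0, 4, sec)
        m.fix(0, range(6))
        sp = m.add_spring(4, np.array([10.0, 0.0, 5.0]), k=2.0)
        assert sp.natural_length == pytest.approx(5.0)
        sp.anchor[2] = 8.0   # stretch the string

        def noop(model, t):
            pass

        bf.assemble_and_solve(m, [bf.Step("settle", noop, n_inc=2)])
        x = m.x[4]
        ext = np.linalg.norm(sp.anchor - x) - sp.natural_length
        f = bf._spring_force(sp, x)[0]
        assert np.linalg.norm(f) == pytest.approx(abs(sp.k * ext), rel=1e-9)

    def test_slack_spring_carries_no_force(self):
        sec = _section()
        m = bf.make_straight_wire(10.0, 4, sec)
        sp = m.add_spring(4, np.array([10.0, 0.0, 5.0]), k=2.0)
        sp.anchor[2] = 2.0    # closer than natural length
        f, K, _ = bf._spring_force(sp, m.x[4])
        assert np.all(f == 0.0) and sp.slack
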