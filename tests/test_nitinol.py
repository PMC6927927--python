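"""Superelastic constitutive model: branches, hysteresis, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ringmech.nitinol import (
    NITINOL_37C,
    ConvergenceError,
    MaterialState,
    NitinolParams,
    drive_cycle,
    tangent_modulus,
    update_state,
)

P = NITINOL_37C


class TestBranches:
    def test_virgin_zero(self):
        s = update_state(P, MaterialState(), 0.0)
        assert s.sigma == 0.0 and s.xi == 0.0

    def test_austenite_linear_branch(self):
        s = update_state(P, MaterialState(), 0.005)
        assert s.sigma == pytest.approx(P.E_A * 0.005)  # 295 MPa
        assert s.xi == 0.0

    def test_tension_onset_strain(self):
        """Forward transformation starts at sigma_LS / E_A = 1.08 %."""
        eps = np.linspace(0.0, 0.02, 2001)
        traj = drive_cycle(P, eps)
        xi = np.array([t.xi for t in traj])
        onset = eps[np.argmax(xi > 1e-12)]
        assert onset * 100 == pytest.approx(1.08, abs=0.005)

    def test_compression_onset_stress(self):
        eps = np.linspace(0.0, -0.03, 3001)
        traj = drive_cycle(P, eps)
        xi = np.array([t.xi for t in traj])
        sig = np.array([t.sigma for t in traj])
        i = np.argmax(xi > 1e-12)
        assert abs(sig[i]) == pytest.approx(965.0, rel=2e-3)

    def test_asymmetry(self):
        assert P.sigma_CS > P.sigma_LS


class TestTangent:
    def test_pure_phase_moduli(self):
        assert tangent_modulus(P, MaterialState()) == pytest.approx(59000.0)
        full = update_state(P, MaterialState(), 0.09)
        assert full.xi == pytest.approx(1.0)
        assert tangent_modulus(P, full) == pytest.approx(26500.0)

    def test_plateau_slope_positive_below_martensite(self):
        mid = update_state(P, MaterialState(), 0.03)
        k = tangent_modulus(P, mid, "loading")
        assert 0.0 < k < P.E_M

    @pytest.mark.parametrize("eps,direction", [
        (0.004, "loading"), (0.03, "loading"), (0.03, "unloading"),
        (0.06, "loading"), (-0.008, "loading"),
    ])
    def test_finite_difference_consistency(self, eps, direction):
        """Algorithmic tangent matches numerical differentiation."""
        s = update_state(P, MaterialState(), eps)
        h = 1e-7 if direction == "loading" else -1e-7
        s2 = update_state(P, s, eps + h)
        fd = (s2.sigma - s.sigma) / h
        assert tangent_modulus(P, s, direction) == pytest.approx(fd, rel=1e-6)


class TestHysteresis:
    def test_sub_plateau_cycle_is_elastic(self):
        traj = drive_cycle(P, [0.005, 0.0])
        assert traj[-1].sigma == pytest.approx(0.0, abs=1e-9)
        assert traj[-1].xi == 0.0

    def test_full_loop_plateaus(self):
        path = np.concatenate([np.linspace(0, 0.06, 200),
                               np.linspace(0.06, 0, 200)])
        sig = np.array([t.sigma for t in drive_cycle(P, path)])
        assert sig.max() <= 740.0 + 1e-6          # upper plateau cap
        # loading plateau starts at 636
        load = sig[:200]
        plateau = load[(path[:200] > 0.015) & (path[:200] < 0.05)]
        assert plateau.min() >= 636.0 - 1e-6
        # unloading plateau lies within [302, 430]
        un = sig[200:]
        rev = un[(un > 250) & (un < 450)]
        assert rev.size > 0
        assert drive_cycle(P, path)[-1].xi == pytest.approx(0.0, abs=1e-12)

    def test_dissipation_non_negative(self):
        path = np.concatenate([np.linspace(0, 0.06, 300),
                               np.linspace(0.06, 0, 300)])
        sig = np.array([t.sigma for t in drive_cycle(P, path)])
        assert np.trapezoid(sig, path) > 0.0

    def test_repeated_loop_identical(self):
        """Rate-independent model accumulates no state over cycles."""
        loop = np.concatenate([np.linspace(0, 0.08, 80),
                               np.linspace(0.08, 0, 80)])
        sig = np.array([t.sigma for t in drive_cycle(P, np.tile(loop, 2))])
        np.testing.assert_allclose(sig[:160], sig[160:], atol=1e-9)


class TestPathIndependence:
    @given(st.lists(st.floats(-0.05, 0.07), min_size=1, max_size=6),
           st.integers(2, 40))
    @settings(max_examples=60, deadline=None)
    def test_increment_subdivision(self, targets, n_sub):
        """Subdividing any strain path leaves the final state unchanged."""
        coarse = drive_cycle(P, targets)[-1]
        fine_path = []
        prev = 0.0
        for tgt in targets:
            fine_path.extend(np.linspace(prev, tgt, n_sub + 1)[1:])
            prev = tgt
        fine = drive_cycle(P, fine_path)[-1]
        assert coarse.sigma == pytest.approx(fine.sigma, abs=1e-8)
        assert coarse.xi == pytest.approx(fine.xi, abs=1e-12)

    @given(st.lists(st.floats(-0.05, 0.07), min_size=2, max_size=8))
    @settings(max_examples=60, deadline=None)
    def test_transformation_strain_bound(self, targets):
        state = MaterialState()
        for tgt in targets:
            state = update_state(P, state, tgt)
            assert 0.0 <= state.xi <= 1.0 + 1e-12
            assert abs(state.eps_tr) <= state.xi * P.eps_L + 1e-12


class TestValidation:
    def test_non_finite_strain_rejected(self):
        with pytest.raises(ValueError):
            update_state(P, MaterialState(), float("nan"))

    @pytest.mark.parametrize("kw", [
        dict(E_A=20000.0, E_M=30000.0),     # E_A must exceed E_M
        dict(eps_L=1.5),
        dict(sigma_LS=800.0, sigma_LE=700.0),
        dict(sigma_US=300.0, sigma_UE=400.0),
        dict(sigma_CS=500.0),               # compression must start later
    ])
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            NitinolParams(**kw)
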