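"""Saddle pull test: geometry mapping, string law, cycling behavior."""

import numpy as np
import pandas as pd
import pytest

from ringmech.forming import RingConfig, form_ring
from ringmech.saddle import (
    SaddleConfig,
    run_saddle,
    saddle_positions_from_oversize,
    stiffness_deviation,
    string_stiffness,
)


class TestGeometry:
    def test_vessel_radius_from_oversize(self):
        # oversize = (R_ring / R_vessel - 1) * 100 %
        cfg = RingConfig(0.160, 33.16, 8)
        R_v, _ = saddle_positions_from_oversize(cfg, 10.0)
        assert R_v == pytest.approx(16.58 / 1.1, abs=5e-3)     # 15.07 mm
        cfg1 = RingConfig(0.180, 27.02, 10)
        R_v30, _ = saddle_positions_from_oversize(cfg1, 30.0)
        assert R_v30 == pytest.approx(13.51 / 1.3, abs=5e-3)   # 10.39 mm

    def test_zero_oversize_limit(self):
        cfg = RingConfig(0.180, 27.02, 10)
        _, u = saddle_positions_from_oversize(cfg, 1e-9)
        assert u == pytest.approx(0.0, abs=1e-3)

    def test_nonpositive_oversize_rejected(self):
        with pytest.raises(ValueError):
            saddle_positions_from_oversize(RingConfig(0.18, 27.0, 10), 0.0)


class TestStringLaw:
    def test_reference_stiffness(self):
        assert string_stiffness(100.0) == pytest.approx(7.41)

    @pytest.mark.parametrize("L", [50.0, 100.0, 200.0])
    def test_inverse_length_scaling(self, L):
        assert string_stiffness(L) == pytest.approx(7.41 * 100.0 / L)


class TestStiffnessDeviation:
    @staticmethod
    def _curve(scale=1.0):
        d = np.linspace(1.0, 5.0, 20)
        return pd.DataFrame(dict(displacement_mm=d, force_N=scale * (0.2 * d + 0.1)))

    def test_identical_curves(self):
        lo, hi = stiffness_deviation(self._curve(), self._curve())
        assert lo == 0.0 and hi == 0.0

    def test_five_percent_offset(self):
        # sim such that reference = 1.05 * sim  ->  deviation 1/1.05 ~ 4.76 %
        lo, hi = stiffness_deviation(self._curve(1.0), self._curve(1.05))
        assert lo == pytest.approx(100.0 * (1.0 - 1.0 / 1.05), rel=1e-6)
        assert hi == pytest.approx(lo, rel=1e-6)

    def test_disjoint_ranges_rejected(self):
        a = self._curve()
        b = self._curve().assign(displacement_mm=lambda d: d.displacement_mm + 10)
        with pytest.raises(ValueError):
            stiffness_deviation(a, b)


@pytest.fixture(scope="module")
def saddle_run_ring4():
    """Formed ring 4 cycled through the saddle program (coarse mesh)."""
    cfg = RingConfig(0.200, 48.09, 9, name="ring4")
    model = form_ring(cfg, n_el=32)
    df = run_saddle(model, SaddleConfig(n_cycles=3, n_inc_pull=10,
                                        n_inc_cycle=6, pull_overshoot=1.5))
    return model, df


class TestSaddleRun:
    def test_settled_force_is_small_at_zero_displacement(self, saddle_run_ring4):
        _, df = saddle_run_ring4
        first = df.iloc[0]
        # early in the pull the self-equilibrated ring resists only weakly
        assert first.force_N < 0.2

    def test_prestrained_cycling_shows_hysteresis(self, saddle_run_ring4):
        """Cycling between the 30 % and 10 % oversize saddle positions
        dissipates energy once the wire has entered its plateau."""
        _, df = saddle_run_ring4
        c = df[df.step.str.startswith("cycle_3")]
        area = np.trapezoid(c.force_N.to_numpy(), c.displacement_mm.to_numpy())
        assert abs(area) > 0.05      # N mm per cycle

    def test_cycles_settle(self, saddle_run_ring4):
        """Successive settled cycles differ by < 0.5 % in force."""
        _, df = saddle_run_ring4

        def cyc(i, leg):
            d = df[df.step == f"cycle_{i}_{leg}"]
            return d.displacement_mm.to_numpy(), d.force_N.to_numpy()

        for leg in ("up", "down"):
            d2, f2 = cyc(2, leg)
            d3, f3 = cyc(3, leg)
            g = np.linspace(max(d2.min(), d3.min()) + 1e-6,
                            min(d2.max(), d3.max()) - 1e-6, 25)
            o2 = np.interp(g, np.sort(d2), f2[np.argsort(d2)])
            o3 = np.interp(g, np.sort(d3), f3[np.argsort(d3)])
            ref = np.abs(f3).max()
            assert np.abs(o3 - o2).max() <= 0.005 * ref

    def test_roi_flag_marks_settled_cycles(self, saddle_run_ring4):
        _, df = saddle_run_ring4
        assert not df[df.step == "pull"].region_of_interest.any()
        assert df[df.step == "cycle_2_up"].region_of_interest.all()


class TestPrestrainEffect:
    def test_no_prestrain_is_stiffer_in_cycling_region(self):
        """Omitting the manufacturing strains makes the structure stiffer:
        higher force at every displacement in the cycling region."""
        sc = SaddleConfig(n_cycles=1, n_inc_pull=8, n_inc_cycle=6,
                          pull_overshoot=1.2)
        curves = {}
        for pre in (True, False):
            cfg = RingConfig(0.180, 27.02, 10, include_prestrain=pre)
            model = form_ring(cfg, n_el=32)
            curves[pre] = run_saddle(model, sc)
        g = None
        interp = {}
        for pre, df in curves.items():
            c = df[df.step.str.startswith("cycle_1")]
            d, f = c.displacement_mm.to_numpy(), c.force_N.to_numpy()
            order = np.argsort(d)
            if g is None:
                g = np.linspace(d.min() + 1e-3, d.max() - 1e-3, 20)
            interp[pre] = np.interp(g, d[order], f[order])
        assert np.all(interp[False] > interp[True])
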