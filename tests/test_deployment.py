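"""Deployment scenario: compaction history, COF, strain localization."""

import numpy as np
import pytest

from ringmech.deployment import chronic_outward_force, saddle_fold_height


class TestFoldGeometry:
    def test_no_fold_when_ring_fits(self):
        assert saddle_fold_height(10.0, 10.0) == 0.0
        assert saddle_fold_height(10.0, 12.0) == 0.0

    def test_shallow_fold_matches_small_amplitude_formula(self):
        R, R_v = 13.51, 12.28
        h = saddle_fold_height(R, R_v)
        assert h == pytest.approx(np.sqrt(R_v * (R - R_v)), rel=0.05)

    def test_deep_fold_conserves_arc_length(self):
        from scipy.integrate import quad

        R, R_v = 13.51, 3.11
        h = saddle_fold_height(R, R_v)
        L, _ = quad(lambda p: np.sqrt(R_v ** 2 + 4 * h * h * np.sin(2 * p) ** 2),
                    0.0, 2.0 * np.pi)
        assert L == pytest.approx(2.0 * np.pi * R, rel=1e-6)

    def test_fold_deepens_with_compaction(self):
        hs = [saddle_fold_height(13.51, rv) for rv in (12.0, 9.0, 6.0, 3.5)]
        assert all(b > a for a, b in zip(hs, hs[1:]))


class TestDeployedScenario:
    def test_compaction_is_the_severest_load(self, deployed_ring1):
        """Max fiber strain during crimp exceeds the deployed strain."""
        d = deployed_ring1
        assert d["eps_compacted"] > d["result"].eps_diast
        assert d["eps_compacted"] > d["result"].eps_syst

    def test_cof_positive_at_oversized_deployment(self, deployed_ring1):
        res = deployed_ring1["result"]
        assert res.COF > 0.0
        assert res.COF_diast > 0.0 and res.COF_syst > 0.0

    def test_cof_equals_vessel_side_reaction(self, deployed_ring1):
        """Action-reaction: the radial sum recomputed from the per-node
        contact forces matches the reported COF."""
        model = deployed_ring1["model"]
        res = deployed_ring1["result"]
        assert chronic_outward_force(model) == pytest.approx(res.COF_syst,
                                                             rel=1e-6)

    def test_strain_extrema_at_peaks_or_valleys(self, deployed_ring1):
        """argmax fiber strain lies at a saddle peak/valley (within one
        element of the quarter points at this mesh)."""
        model = deployed_ring1["model"]
        em = np.abs(model.eps_fib).max(axis=1)
        el = int(em.argmax())
        phi = np.degrees(np.arctan2(model.X0[el, 1], model.X0[el, 0])) % 90.0
        dist = min(phi, 90.0 - phi)
        spacing = 360.0 / model.n_el
        assert dist <= 10.0 + spacing

    def test_mean_cycle_strain_between_extremes(self, deployed_ring1):
        res = deployed_ring1["result"]
        assert res.M_eps <= max(res.eps_diast, res.eps_syst) + 1e-12
        assert res.M_eps > 0.0

    def test_metadata_records_wall_idealization(self, deployed_ring1):
        meta = deployed_ring1["result"].metadata
        assert "vessel_model" in meta and "band_width" in meta

    def test_compaction_history_changes_deployed_state(self, deployed_ring1):
        """Skipping the full catheter crimp (folding only as far as the
        vessel requires) leaves the wire in a different mechanical state:
        the superelastic history is not erasable."""
        from ringmech.deployment import DeploymentConfig, compact, deploy_and_pulse
        from ringmech.forming import form_ring
        from ringmech.vessel import size_vessel

        cfg = deployed_ring1["config"]
        model = form_ring(cfg, n_el=32)
        shallow = DeploymentConfig(seed=0, catheter_diameter=23.0,
                                   n_inc_compact=12)
        compact(model, shallow)
        tube = size_vessel(cfg, shallow.oversize_pct)
        res2 = deploy_and_pulse(model, tube, shallow)
        res1 = deployed_ring1["result"]
        rel = abs(res2.eps_diast - res1.eps_diast) / res1.eps_diast
        assert rel > 1e-3

    def test_systole_presses_harder_than_diastole(self, deployed_ring1):
        """At systole the lumen is wider, so the ring opens further and
        pushes with different force; both states stay in contact."""
        res = deployed_ring1["result"]
        assert res.COF_diast > 0.0 and res.COF_syst > 0.0
        assert res.eps_diast != res.eps_syst
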