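"""Shared fixtures: fixture ring configurations and one reusable deployment.

Heavy scenario runs (saddle cycling, full deployment) are session-scoped so
several tests can interrogate a single simulation.
"""

from __future__ import annotations

import numpy as np
import pytest

from ringmech.forming import RingConfig, form_ring
from ringmech.io import PRESET_RINGS


@pytest.fixture(scope="session")
def ring_configs() -> dict[str, RingConfig]:
    return dict(PRESET_RINGS)


@pytest.fixture(scope="session")
def formed_rings(ring_configs):
    """All four fixture rings formed at the default mesh."""
    return {name: form_ring(cfg, n_el=48) for name, cfg in ring_configs.items()}


@pytest.fixture(scope="session")
def deployed_ring1():
    """One full scenario: ring 1 formed, compacted, deployed, pulsed.

    Coarse mesh keeps the run short; the returned dict carries the model,
    the sized vessel, the result object and the compacted-state peak strain.
    """
    from ringmech.deployment import DeploymentConfig, compact, deploy_and_pulse
    from ringmech.vessel import size_vessel

    cfg = PRESET_RINGS["ring1"]
    model = form_ring(cfg, n_el=32)
    dc = DeploymentConfig(seed=0)
    compact(model, dc)
    eps_compacted = model.max_fiber_strain()
    tube = size_vessel(cfg, dc.oversize_pct)
    result = deploy_and_pulse(model, tube, dc)
    return dict(model=model, tube=tube, result=result,
                eps_compacted=eps_compacted, config=cfg, deploy_config=dc)
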