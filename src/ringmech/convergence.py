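"""Mesh-convergence utility: saddle-test peak force vs element count."""

from __future__ import annotations

from .forming import RingConfig, form_ring
from .saddle import SaddleConfig, run_saddle

__all__ = ["saddle_peak_force"]


def saddle_peak_force(config: RingConfig, n_el: int = 48,
                      pull_overshoot: float = 1.0, n_inc: int = 10) -> float:
    """Peak crosshead force of a pull-only saddle test at a given mesh.

    Halving the element size at the default mesh should change this value
    by well under a percent; used to establish mesh independence.
    """
    model = form_ring(config, n_el=n_el)
    sc = SaddleConfig(n_cycles=0, n_inc_pull=n_inc,
                      pull_overshoot=pull_overshoot)
    df = run_saddle(model, sc)
    return float(df.force_N.max())
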