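"""Bundle cross-section geometry from circle packing.

A ring-stent bundle is wound from ``n`` turns of a single wire; its
cross-section is approximated by the smallest circle that can enclose
``n`` equal circles (the wire turns).  The ratio of that enclosing radius
to the wire radius, ``BW = R_bundle / R_wire``, comes from circle-packing
theory and is tabulated here for n = 1..14 (the known optimal packings).
A multi-start nonlinear optimizer provides an independent numerical
cross-check for small n.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "BundleGeometry",
    "BW_TABLE",
    "bw_ratio",
    "verify_packing",
    "bundle_diameter",
]

#: Optimal (known) ratio of enclosing-circle radius to unit-circle radius
#: for n equal circles, n = 1..14.
BW_TABLE: dict[int, float] = {
    1: 1.000,
    2: 2.000,
    3: 2.154,   # 1 + 2/sqrt(3)
    4: 2.414,   # 1 + sqrt(2)
    5: 2.701,
    6: 3.000,
    7: 3.000,   # hexagonal + center
    8: 3.304,
    9: 3.613,
    10: 3.813,
    11: 3.923,
    12: 4.029,
    13: 4.236,
    14: 4.328,
}


@dataclass(frozen=True)
class BundleGeometry:
    """Envelope geometry of an ``n_turns`` wire bundle."""

    n_turns: int
    r_wire: float  # mm

    @property
    def bw(self) -> float:
        return bw_ratio(self.n_turns)

    @property
    def r_bundle(self) -> float:
        """Envelope radius of the bundle, mm."""
        return self.bw * self.r_wire


def bw_ratio(n: int) -> float:
    """Bundle-to-wire radius ratio for ``n`` wire turns.

    Values reproduce the optimal packing ratios to three decimals.  For
    n > 14 (outside the tabulated device range) the hexagonal-packing
    asymptotic estimate is returned with a warning.
    """
    n = int(n)
    if n < 1:
        raise ValueError("number of turns must be >= 1")
    if n in BW_TABLE:
        return BW_TABLE[n]
    warnings.warn(
        f"n = {n} exceeds the tabulated packing range (1..14); "
        "using a hexagonal-density estimate",
        stacklevel=2,
    )
    # area argument with hexagonal packing density pi/sqrt(12)
    return 1.0 + math.sqrt(n / (math.pi / math.sqrt(12.0)))


def _enclosing_ratio(centers: np.ndarray) -> float:
    return float(np.max(np.hypot(centers[:, 0], centers[:, 1]))) + 1.0


def verify_packing(n: int, tol: float = 1e-3, n_starts: int = 40, seed: int = 0) -> float:
    """Numerically pack ``n`` unit circles in the smallest enclosing circle.

    Multi-start SLSQP over the circle centers: minimize the enclosing
    radius subject to pairwise non-overlap.  Independent cross-check of
    :data:`BW_TABLE`; raises :class:`RuntimeError` (carrying the best value
    found) when the best result misses the tabulated optimum by more than
    ``tol`` for n <= 8.
    """
    n = int(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return 1.0
    rng = np.random.default_rng(seed)
    best = math.inf

    def objective(x: np.ndarray) -> float:
        c = x[:-1].reshape(n, 2)
        return x[-1]

    def constraints(x: np.ndarray) -> np.ndarray:
        c = x[:-1].reshape(n, 2)
        R = x[-1]
        cons = [R - 1.0 - np.hypot(c[i, 0], c[i, 1]) for i in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                cons.append(np.hypot(*(c[i] - c[j])) - 2.0)
        return np.array(cons)

    for _ in range(n_starts):
        c0 = rng.uniform(-0.8 * n ** 0.5, 0.8 * n ** 0.5, size=(n, 2))
        x0 = np.concatenate([c0.ravel(), [np.max(np.hypot(c0[:, 0], c0[:, 1])) + 1.0]])
        res = minimize(
            objective,
            x0,
            method="SLSQP",
            constraints={"type": "ineq", "fun": constraints},
            options={"maxiter": 300, "ftol": 1e-12},
        )
        if res.success:
            cons = constraints(res.x)
            if cons.min() > -1e-7:
                best = min(best, float(res.x[-1]))

    if n <= 8 and abs(best - BW_TABLE[n]) > tol + 5e-4:
        raise RuntimeError(
            f"packing optimizer did not reach the known optimum for n={n}: "
            f"best ratio {best:.6f} vs tabulated {BW_TABLE[n]:.3f}"
        )
    return best


def bundle_diameter(r_wire: float, n: int, rounded: bool = False) -> float:
    """Bundle envelope diameter ``2 * BW(n) * r_wire`` in mm.

    ``rounded=True`` applies the round-half-up 2-decimal convention used
    when quoting bundle diameters.
    """
    if r_wire <= 0.0:
        raise ValueError("wire radius must be positive")
    d = 2.0 * bw_ratio(n) * r_wire
    if rounded:
        return float(Decimal(repr(d)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    return d
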