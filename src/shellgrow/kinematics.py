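"""Volume-growth kinematics: growth tensors and the multiplicative split.

Volume growth of the mantle acts only along the margin direction ``s2`` with
growth-strain rate ``eps2``; over one increment the growth tensor is obtained
from the exponential map

    Fg = exp(eps2 * dt * s2 (x) s2) = I + (e^{eps2 dt} - 1) s2 (x) s2,

the closed form holding because ``s2 (x) s2`` is idempotent.  Each freshly
laid strip starts from ``Fg = I`` in its own (new) reference configuration.
The elastic part of the deformation gradient is recovered from the
multiplicative decomposition ``F = Fe Fg``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GrowthIncrementSpec",
    "growth_tensor_increment",
    "evaluate_growth_rate",
    "elastic_part",
]


@dataclass(frozen=True)
class GrowthIncrementSpec:
    """One increment of coupled surface and volume growth.

    ``delta_s`` is the active mantle width laid down by surface growth,
    ``|v1 s1 - v_c| * dt``.  The volume-growth field ``eps2`` may be uniform
    (``eps2``), spatially varying over the strip-width coordinate ``xi1 in
    [0, delta_s]`` (``profile_xi1``: tabulated ``(xi1_frac, eps2)`` pairs with
    ``xi1_frac = xi1/delta_s``, interpolated by a monotone (PCHIP) cubic), or
    both.  With the package convention ``dt = 1`` the volume growth increment
    is ``delta_g = eps2 * dt = eps2``.
    """

    delta_s: float
    eps2: float = 0.0
    dt: float = 1.0
    n_rows: int = 4
    profile_xi1: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.delta_s < 0:
            raise ValueError("delta_s must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_rows < 1:
            raise ValueError("n_rows must be >= 1")

    @property
    def delta_g(self) -> float:
        """Nominal volume-growth increment ``eps2 * dt`` (uniform part)."""
        return self.eps2 * self.dt


def growth_tensor_increment(eps2_dt: float, s2: np.ndarray) -> np.ndarray:
    """Incremental growth tensor ``exp(eps2_dt * s2 (x) s2)``.

    ``s2`` must be a unit vector; the determinant of the result is
    ``e^{eps2_dt}``.  Vectors orthogonal to ``s2`` are left unchanged.
    """
    s2 = np.asarray(s2, dtype=float)
    nrm = np.linalg.norm(s2)
    if abs(nrm - 1.0) > 1e-10:
        raise ValueError(f"s2 must be a unit vector, |s2| = {nrm}")
    return np.eye(3) + (np.expm1(eps2_dt)) * np.outer(s2, s2)


def growth_tensor_field(eps2_dt: np.ndarray, s2: np.ndarray) -> np.ndarray:
    """Vectorized growth tensors for arrays of exponents and unit directions.

    ``eps2_dt``: (...,) exponents; ``s2``: (..., 3) unit vectors.  Returns
    (..., 3, 3).
    """
    eps2_dt = np.asarray(eps2_dt, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    outer = s2[..., :, None] * s2[..., None, :]
    eye = np.broadcast_to(np.eye(3), outer.shape)
    return eye + np.expm1(eps2_dt)[..., None, None] * outer


def evaluate_growth_rate(
    spec: GrowthIncrementSpec,
    xi1: np.ndarray | float,
    xi2: np.ndarray | float = 0.0,
    increment_index: int = 0,
) -> np.ndarray:
    """Growth-strain rate ``eps2`` at strip coordinates ``(xi1, xi2)``.

    ``xi1`` is measured from the trailing edge of the active strip (range
    ``[0, delta_s]``; for ``delta_s = 0`` increments the profile is evaluated
    at its trailing value).  Uniform specs return a constant; tabulated
    profiles are interpolated with a monotone (PCHIP) cubic in the normalized
    coordinate ``xi1/delta_s``, which keeps the convex shapes used for
    spatially graded growth smooth without overshoot at the knots.
    """
    xi1 = np.asarray(xi1, dtype=float)
    width = spec.delta_s
    if width > 0 and (np.any(xi1 < -1e-9) or np.any(xi1 > width * (1 + 1e-9))):
        raise ValueError("xi1 outside the active strip width")
    if spec.profile_xi1 is None:
        return np.broadcast_to(np.asarray(spec.eps2, dtype=float), xi1.shape).copy()
    from scipy.interpolate import PchipInterpolator

    knots = np.asarray([p[0] for p in spec.profile_xi1], dtype=float)
    vals = np.asarray([p[1] for p in spec.profile_xi1], dtype=float)
    spline = PchipInterpolator(knots, vals)
    frac = np.clip(xi1 / width, 0.0, 1.0) if width > 0 else np.zeros_like(xi1)
    return np.asarray(spline(frac), dtype=float)


def elastic_part(F: np.ndarray, Fg: np.ndarray) -> np.ndarray:
    """Elastic factor ``Fe = F Fg^{-1}`` of the multiplicative decomposition."""
    F = np.asarray(F, dtype=float)
    Fg = np.asarray(Fg, dtype=float)
    det = np.linalg.det(Fg)
    if np.any(det <= 0):
        raise ValueError("Fg must have positive determinant")
    return F @ np.linalg.inv(Fg)
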