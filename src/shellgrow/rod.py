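"""Reduced 1D models of the buckling mantle margin.

The growing mantle edge, elastically tethered to the rigid calcified shell,
is idealized as an axially growing rod on an elastic foundation.  Linearizing
about the flat state gives the fourth-order ODE

    y''''(X) + (gamma - 1) y''(X) + k gamma y(X) = 0,

where ``gamma > 1`` is the axial growth factor (grown length / attached
length) and ``k`` the foundation stiffness.  A Fourier ansatz
``y ~ exp(i q X)`` (with ``q = 2 pi n``, ``n`` the mode number per unit
length) yields the dispersion relation

    gamma(q) = (q^4 + q^2) / (q^2 - k),        q^2 > k,

whose minimum over admissible wavenumbers is the critical growth

    gamma* = 1 + 2 k + 2 sqrt(k + k^2),

attained at ``q*^2 = k + sqrt(k^2 + k)``, i.e. the mode number at buckling is
``n* = sqrt(gamma* - 1) / (2 sqrt(2) pi) = q* / (2 pi)``.  For large ``k``
this gives the scaling ``n* ~ sqrt(k)``.

A linearized Kirchhoff-Love plate strip (clamped along one long edge, free on
the remaining three, compressed along its length by a growth prestrain) is
provided as an independent check on the full 3D simulations: it predicts the
decrease of mode number with active mantle width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import eigh

__all__ = [
    "RodFoundationModel",
    "RodBucklingResult",
    "critical_growth",
    "dispersion_growth",
    "buckling_mode_number",
    "critical_wavenumber",
    "calibrate_foundation_stiffness",
    "plate_buckling_critical",
]


@dataclass(frozen=True)
class RodFoundationModel:
    """Growing rod on an elastic foundation: stiffness ``k``, growth ``gamma``."""

    k: float
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"foundation stiffness k must be > 0, got {self.k}")


@dataclass(frozen=True)
class RodBucklingResult:
    """Critical growth ``gamma_star``, mode number ``n_star`` (waves per unit
    length) and wavenumber ``q_star = 2 pi n_star`` for a given foundation."""

    k: float
    gamma_star: float
    n_star: float
    q_star: float


def critical_growth(k: float) -> float:
    """Critical axial growth ``gamma* = 1 + 2k + 2 sqrt(k + k^2)``."""
    if k <= 0:
        raise ValueError(f"foundation stiffness k must be > 0, got {k}")
    return 1.0 + 2.0 * k + 2.0 * np.sqrt(k + k * k)


def dispersion_growth(q: float, k: float) -> float:
    """Growth factor at which wavenumber ``q`` becomes marginally stable.

    ``gamma(q) = (q^4 + q^2)/(q^2 - k)``; only defined for ``q^2 > k`` (below
    that the foundation term cannot be balanced at positive growth).
    """
    if k <= 0:
        raise ValueError(f"foundation stiffness k must be > 0, got {k}")
    q2 = q * q
    if q2 <= k:
        raise ValueError(f"wavenumber q={q} inadmissible: q^2 must exceed k={k}")
    return (q2 * q2 + q2) / (q2 - k)


def critical_wavenumber(k: float) -> float:
    """Minimizer ``q* = sqrt(k + sqrt(k^2 + k))`` of the dispersion relation."""
    if k <= 0:
        raise ValueError(f"foundation stiffness k must be > 0, got {k}")
    return np.sqrt(k + np.sqrt(k * k + k))


def buckling_mode_number(k: float) -> float:
    """Mode number at buckling, ``n* = sqrt(gamma* - 1)/(2 sqrt(2) pi)``.

    Algebraically identical to ``q*/(2 pi)`` with ``q*`` the dispersion
    minimizer.
    """
    return np.sqrt(critical_growth(k) - 1.0) / (2.0 * np.sqrt(2.0) * np.pi)


def solve_rod(k: float) -> RodBucklingResult:
    """Bundle the closed-form critical quantities for foundation stiffness k."""
    g = critical_growth(k)
    q = critical_wavenumber(k)
    return RodBucklingResult(k=k, gamma_star=g, n_star=q / (2.0 * np.pi), q_star=q)


def calibrate_foundation_stiffness(
    mode_counts: list[tuple[float, float]],
    domain_length: float,
) -> tuple[dict[float, float], float]:
    """Invert the rod model to map FE mode counts to foundation stiffnesses.

    For each observed ``(delta_s, n_FE)`` pair, solves
    ``buckling_mode_number(k) * domain_length = n_FE`` for ``k`` (the mode
    number per unit length times the domain length is the observed wave
    count), then fits a power law ``k ~ delta_s^alpha`` on log-log axes.

    Returns ``(k_of_delta_s, alpha)``.  Raises ``ValueError`` for fewer than
    three points or a constant/non-informative mode sequence.
    """
    if len(mode_counts) < 3:
        raise ValueError("need at least 3 (delta_s, n_FE) pairs to calibrate")
    ns = np.array([n for _, n in mode_counts], dtype=float)
    if np.allclose(ns, ns[0]):
        raise ValueError("mode counts are constant; foundation fit is ill-posed")
    if np.any(ns < 1):
        raise ValueError("all mode counts must be >= 1")
    if domain_length <= 0:
        raise ValueError("domain_length must be > 0")

    k_map: dict[float, float] = {}
    for ds, n_fe in mode_counts:
        n_per_len = n_fe / domain_length

        def f(logk: float, target: float = n_per_len) -> float:
            return buckling_mode_number(np.exp(logk)) - target

        sol = optimize.brentq(f, np.log(1e-12), np.log(1e12), xtol=1e-13)
        k_map[ds] = float(np.exp(sol))

    ds_arr = np.array(sorted(k_map))
    k_arr = np.array([k_map[d] for d in ds_arr])
    slope, _ = np.polyfit(np.log(ds_arr), np.log(k_arr), 1)
    return k_map, float(slope)


def _plate_operator(
    delta_s: float, h: float, q: float, nu: float, n_grid: int
) -> tuple[np.ndarray, np.ndarray]:
    """Quadratic forms (bending, compression-work) for the strip eigenproblem.

    Deflection ``w(x, y) = f(x) cos(q y)`` on the strip ``x in [0, delta_s]``
    (x = distance from the clamped trailing edge, y = coordinate along the
    margin).  Kirchhoff-Love bending energy per unit length of margin:

        U_b = D/2 * [ int (f'' - q^2 f)^2 dx  +  2(1-nu) q^2 f(L) f'(L) ]

    where the Gaussian-curvature contribution ``2(1-nu) q^2 int (f'^2 + f f'')
    dx`` has been integrated exactly to the boundary term at the free edge
    ``L = delta_s`` (it vanishes at the clamped edge).  Work of the
    compressive membrane prestress N (per unit length) along y:

        W = N q^2 / 2 * int f^2 dx

    The critical prestrain is the smallest generalized eigenvalue of
    ``U_b = eps * (E_eff h) * W_form``.  Free-edge conditions at
    ``x = delta_s`` are natural to the energy form; the clamped edge is
    imposed by removing the first two grid values.
    """
    n = n_grid
    dx = delta_s / (n - 1)
    # second-difference matrix (interior rows only; end rows zero)
    D2 = np.zeros((n, n))
    for i in range(1, n - 1):
        D2[i, i - 1] = 1.0 / dx**2
        D2[i, i] = -2.0 / dx**2
        D2[i, i + 1] = 1.0 / dx**2
    w = np.full(n, dx)
    w[0] = w[-1] = dx / 2.0  # trapezoid weights
    I = np.eye(n)

    A_op = D2 - q * q * I  # f'' - q^2 f
    bend = A_op.T @ (w[:, None] * A_op)
    # boundary term 2(1-nu) q^2 f(L) f'(L), one-sided difference for f'(L)
    eL = np.zeros(n)
    eL[-1] = 1.0
    dL = np.zeros(n)
    dL[-3:] = np.array([0.5, -2.0, 1.5]) / dx
    gauss = 0.5 * (np.outer(eL, dL) + np.outer(dL, eL))
    U = bend + 2.0 * (1.0 - nu) * q * q * gauss
    W_form = q * q * (I * w)
    return U, W_form


def plate_buckling_critical(
    delta_s: float,
    h: float,
    mu: float = 1.0,
    lam: float = 2.0,
    n_grid: int = 60,
    q_points: int = 160,
) -> tuple[float, float]:
    """Critical growth strain and mode number of the clamped-free plate strip.

    The strip has width ``delta_s`` (the active mantle width, measured from
    the clamped trailing edge), thickness ``h``, and is compressed along the
    margin direction by a growth prestrain ``eps``.  Returns
    ``(eps_critical, n_critical)`` with ``n_critical`` the mode number per
    unit length of margin at the minimizing wavenumber.

    This linearized model is a trend oracle for the 3D simulations (mode
    number decreasing with ``delta_s``, critical strain ~ (h/delta_s)^2); its
    absolute prefactor depends on the plate reduction and is not used for
    quantitative acceptance.
    """
    if delta_s <= 0 or h <= 0:
        raise ValueError("delta_s and h must be > 0")
    lam_2d = 2 * mu * lam / (lam + 2 * mu)  # plane-stress first Lame parameter
    E = mu * (3 * lam_2d + 2 * mu) / (lam_2d + mu)
    nu = lam_2d / (2 * (lam_2d + mu))
    D = E * h**3 / (12.0 * (1.0 - nu * nu))
    stiff = E * h / (1.0 - nu * nu)  # membrane stiffness against eps

    qs = np.pi / delta_s * np.logspace(-1.3, 0.9, q_points)
    best = (np.inf, qs[0])
    for q in qs:
        U, W_form = _plate_operator(delta_s, h, q, nu, n_grid)
        keep = np.arange(2, n_grid)  # clamp f(0)=f'(0)=0
        Uk = U[np.ix_(keep, keep)]
        Wk = W_form[np.ix_(keep, keep)]
        vals = eigh(D * Uk, stiff * Wk, eigvals_only=True,
                    subset_by_index=[0, 0])
        if vals[0] < best[0]:
            best = (float(vals[0]), float(q))
    eps_c, q_c = best
    return eps_c, q_c / (2.0 * np.pi)
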