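"""Quantifying deformed-mantle morphology.

The observable that organizes all results is the transverse deflection
``w = u . s3`` of the mantle's leading edge as a function of arclength
``xi2``.  The *mode number* ``n`` is the count of discernible crests
(local extrema above a relative amplitude threshold, following the more
numerous sign family); ``n_all`` counts every crest regardless of amplitude,
which matters when a localized low mode is superposed on a broader family of
small crests.  Further metrics: crest amplitudes and positions, the up/down
amplitude ratio measuring the bias of crests toward the sign of the
reference curvature, and discrete Gaussian curvature (angle deficit) of the
deformed mid-surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "EdgeProfile",
    "MorphologyMetrics",
    "count_modes",
    "curvature_bias",
    "gaussian_curvature",
    "quads_from_structured",
    "fit_power_law",
]


@dataclass
class EdgeProfile:
    """Transverse deflection of the deformed leading edge.

    ``xi2``: strictly increasing arclength along the reference leading edge;
    ``w``: deflection ``u . s3`` per sample; ``baseline``: the reference edge
    polyline; ``u_s1``: optional in-surface displacement component along the
    growth direction (used to detect backward-arching ornamentation).
    """

    xi2: np.ndarray
    w: np.ndarray
    baseline: np.ndarray | None = None
    u_s1: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.xi2 = np.asarray(self.xi2, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if np.any(np.diff(self.xi2) <= 0):
            raise ValueError("xi2 must be strictly increasing")
        if not np.all(np.isfinite(self.w)):
            raise ValueError("deflections must be finite")


@dataclass
class MorphologyMetrics:
    """Summary of one deformed configuration."""

    n: int = 0
    n_all: int = 0
    crest_amplitudes: list = field(default_factory=list)
    crest_positions: list = field(default_factory=list)
    amplitude_max: float = 0.0
    up_down_ratio: float = 1.0
    gaussian_curvature_stats: dict = field(default_factory=dict)
    self_intersection: bool = False


_NOISE_FLOOR = 1e-12


def _crest_candidates(profile: EdgeProfile):
    """Local maxima of |w| (merged within 2 sample spacings), with signs."""
    absw = np.abs(profile.w)
    peaks, _ = find_peaks(absw, distance=2)
    return peaks


def count_modes(profile: EdgeProfile, threshold_fraction: float = 0.1) -> MorphologyMetrics:
    """Count discernible crests along the deformed leading edge.

    A crest is a local maximum of ``|w|`` with amplitude at least
    ``threshold_fraction`` of the global maximum; the mode number follows the
    dominant sign family (crests or troughs, whichever is more numerous).
    A flat profile (below machine noise) reports ``n = 0``.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    if len(profile.w) < 8:
        raise ValueError("profile needs at least 8 samples")
    wmax = float(np.max(np.abs(profile.w)))
    m = MorphologyMetrics(amplitude_max=wmax)
    if wmax < _NOISE_FLOOR:
        return m
    peaks = _crest_candidates(profile)
    signs = np.sign(profile.w[peaks])
    amps = np.abs(profile.w[peaks])

    def family_count(thresh: float) -> tuple[int, np.ndarray]:
        keep = amps >= thresh * wmax if thresh > 0 else amps > _NOISE_FLOOR
        n_pos = int(np.sum(keep & (signs > 0)))
        n_neg = int(np.sum(keep & (signs < 0)))
        dom = 1.0 if n_pos >= n_neg else -1.0
        sel = keep & (signs == dom)
        return max(n_pos, n_neg), sel

    m.n, sel = family_count(threshold_fraction)
    m.n_all, _ = family_count(0.0)
    m.crest_amplitudes = list(profile.w[peaks[sel]])
    m.crest_positions = list(profile.xi2[peaks[sel]])
    pos = profile.w[profile.w > 0]
    neg = profile.w[profile.w < 0]
    up = float(np.max(pos)) if len(pos) else 0.0
    dn = float(np.max(-neg)) if len(neg) else 0.0
    m.up_down_ratio = up / dn if dn > _NOISE_FLOOR else (1.0 if up <= _NOISE_FLOOR else np.inf)
    return m


def curvature_bias(
    profile: EdgeProfile, reference_kappa: np.ndarray
) -> tuple[float, dict]:
    """Bias of crests toward the sign of the reference curvature.

    Returns ``(up_down_ratio, report)``: the ratio of the largest deflection
    *compatible* with the local curvature sign to the largest incompatible
    one, and a report with the fraction of discernible crests whose sign
    agrees with the local reference curvature.  For a straight reference
    (kappa = 0 everywhere) compatibility is undefined and the ratio is
    computed as up/down (expected ~1 by symmetry).
    """
    kap = np.asarray(reference_kappa, dtype=float)
    if len(kap) != len(profile.w):
        raise ValueError("reference curvature must be sampled like the profile")
    w = profile.w
    wmax = float(np.max(np.abs(w)))
    if wmax < _NOISE_FLOOR:
        return 1.0, {"flag": "zero_deflection", "crest_sign_agreement": np.nan}

    kscale = float(np.max(np.abs(kap)))
    if kscale < _NOISE_FLOOR:
        pos = w[w > 0]
        neg = w[w < 0]
        up = float(np.max(pos)) if len(pos) else 0.0
        dn = float(np.max(-neg)) if len(neg) else 0.0
        ratio = up / dn if dn > _NOISE_FLOOR else 1.0
        return ratio, {"flag": "straight_reference", "crest_sign_agreement": np.nan}

    # a deflection bump of sign s has curvature -s at its extremum, so a
    # crest is *compatible* with the local reference curvature when its
    # deflection sign is opposite to sign(kappa)
    comp = -w * np.sign(kap)
    active = np.abs(kap) > 0.05 * kscale
    compat = float(np.max(comp[active])) if np.any(comp[active] > 0) else 0.0
    incompat = float(np.max(-comp[active])) if np.any(comp[active] < 0) else 0.0
    ratio = compat / incompat if incompat > _NOISE_FLOOR else np.inf

    # the sign-agreement statistic considers *prominent* crests (>= 50% of
    # the peak): in an alternating wave the suppressed opposite family always
    # disagrees by construction, and its near-threshold remnants would mask
    # the bias of the actual ornamentation
    peaks = _crest_candidates(profile)
    keep = np.abs(w[peaks]) >= 0.5 * wmax
    peaks = peaks[keep & active[peaks]]
    if len(peaks):
        agree = np.mean(np.sign(w[peaks]) == -np.sign(kap[peaks]))
    else:
        agree = np.nan
    return ratio, {"flag": None, "crest_sign_agreement": float(agree) if agree == agree else np.nan}


# ---------------------------------------------------------------------------
# Gaussian curvature (angle deficit)
# ---------------------------------------------------------------------------

def quads_from_structured(grid_pts: np.ndarray, closed_v: bool = False):
    """(nu, nv, 3) structured surface -> flat vertices and quad connectivity."""
    nu, nv, _ = grid_pts.shape
    verts = grid_pts.reshape(-1, 3)
    nvv = nv

    def vid(i, j):
        return i * nvv + (j % nvv)

    quads = []
    jmax = nv if closed_v else nv - 1
    for i in range(nu - 1):
        for j in range(jmax):
            quads.append([vid(i, j), vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1)])
    return verts, np.asarray(quads, dtype=np.int64)


def gaussian_curvature(vertices: np.ndarray, quads: np.ndarray) -> np.ndarray:
    """Angle-deficit Gaussian curvature per vertex of a quad mesh.

    Each quad is split into two triangles; at every *interior* vertex
    ``K = (2 pi - sum of incident angles) / A_mixed`` with the mixed area
    taken as one third of the incident triangle areas.  Boundary vertices
    (on edges used by a single quad) get ``K = nan``.
    """
    V = np.asarray(vertices, dtype=float)
    Q = np.asarray(quads, dtype=np.int64)
    tris = np.vstack([Q[:, [0, 1, 2]], Q[:, [0, 2, 3]]])

    # boundary detection via edge multiplicity on the quad mesh
    edges = np.vstack([Q[:, [0, 1]], Q[:, [1, 2]], Q[:, [2, 3]], Q[:, [3, 0]]])
    edges = np.sort(edges, axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    boundary_vertices = np.unique(uniq[counts == 1])

    angle_sum = np.zeros(len(V))
    area_sum = np.zeros(len(V))
    for corner in range(3):
        a = V[tris[:, corner]]
        b = V[tris[:, (corner + 1) % 3]]
        c = V[tris[:, (corner + 2) % 3]]
        u = b - a
        v = c - a
        nu_ = np.linalg.norm(u, axis=1)
        nv_ = np.linalg.norm(v, axis=1)
        if np.any(nu_ == 0) or np.any(nv_ == 0):
            raise ValueError("degenerate (zero-area) face")
        cosang = np.clip(np.sum(u * v, axis=1) / (nu_ * nv_), -1.0, 1.0)
        ang = np.arccos(cosang)
        np.add.at(angle_sum, tris[:, corner], ang)
        area = 0.5 * np.linalg.norm(np.cross(u, v), axis=1)
        np.add.at(area_sum, tris[:, corner], area / 3.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        K = (2.0 * np.pi - angle_sum) / area_sum
    K[boundary_vertices] = np.nan
    return K


def sweep_phase_diagram(
    delta_s_values,
    delta_g_values,
    kappa_values,
    base_config,
    out_dir=None,
):
    """Single-increment simulations over a (delta_s, delta_g, kappa) grid.

    ``base_config`` is a validated RunConfig whose geometry/solver blocks set
    everything except the swept parameters; ``kappa_values`` may contain
    ``None`` to keep the base geometry.  Individual run failures are recorded
    in the returned table (column ``failed``) and the sweep continues.
    Results are written incrementally to ``out_dir/phase.csv`` when given, so
    an interrupted sweep can be resumed by rerunning (completed rows are
    skipped).
    """
    import pandas as pd

    from .config import build_engine_config
    from .engine import run_simulation

    rows = []
    out_path = None
    done = set()
    if out_dir is not None:
        from pathlib import Path

        out_path = Path(out_dir) / "phase.csv"
        out_path.parent.mkdir(parents=True, exist_ok=True)
        if out_path.exists():
            prev = pd.read_csv(out_path)
            rows = prev.to_dict("records")
            done = {(r["delta_s"], r["delta_g"], r["kappa"]) for r in rows}

    for kap in kappa_values:
        for ds in delta_s_values:
            for dg in delta_g_values:
                key = (ds, dg, np.nan if kap is None else kap)
                if key in done:
                    continue
                cfg = base_config.model_copy(deep=True)
                inc = cfg.growth.increments[0]
                inc.delta_s = ds
                inc.delta_g = dg
                cfg.growth.increments = [inc]
                if kap is not None and kap > 0:
                    cfg.geometry.kind = "arc"
                    cfg.geometry.radius = 1.0 / kap
                elif kap is not None:
                    cfg.geometry.kind = "line"
                row = {"delta_s": ds, "delta_g": dg,
                       "kappa": np.nan if kap is None else kap}
                try:
                    state = run_simulation(build_engine_config(cfg))
                    m = state.metrics_history[-1]
                    row.update(
                        n=m.n, n_all=m.n_all, amplitude_max=m.amplitude_max,
                        up_down_ratio=m.up_down_ratio, failed=False, error="",
                    )
                except Exception as err:  # individual failures do not stop the sweep
                    row.update(n=-1, n_all=-1, amplitude_max=np.nan,
                               up_down_ratio=np.nan, failed=True, error=str(err))
                rows.append(row)
                if out_path is not None:
                    pd.DataFrame(rows).to_csv(out_path, index=False)
    return pd.DataFrame(rows)


def fit_power_law(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Least-squares power-law fit ``y = exp(b) x^a`` on log-log axes.

    Returns ``(exponent a, intercept b, r_squared)``.  All inputs must be
    positive; degenerate inputs (identical x) yield finite outputs with
    ``r_squared < 1``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires positive data")
    lx, ly = np.log(x), np.log(y)
    vx = np.var(lx)
    if vx == 0:
        return 0.0, float(np.mean(ly)), 0.0
    a = float(np.cov(lx, ly, bias=True)[0, 1] / vx)
    b = float(np.mean(ly) - a * np.mean(lx))
    resid = ly - (a * lx + b)
    ss_tot = float(np.sum((ly - np.mean(ly)) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return a, b, r2
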