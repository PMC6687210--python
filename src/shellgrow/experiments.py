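"""Experiment drivers binding presets to the growth engine.

These functions implement the studies that the presets parameterize: the
upward volume-growth sweep that locates the first bifurcation, growth
multiples on the same geometry, the active-mantle-width family for the
mode-number scaling law, and the three-stage hierarchical protocol.  Both
the test suite and the acceptance script call them, so a result is always
produced by the same code path.
"""

from __future__ import annotations

import numpy as np

from .config import RunConfig, build_engine_config
from .engine import SimulationState, run_growth_increment
from .metrics import MorphologyMetrics, fit_power_law
from .rod import calibrate_foundation_stiffness

__all__ = [
    "run_single_increment",
    "delta_g_upward_sweep",
    "delta_g_multiples",
    "delta_s_mode_family",
    "mode_scaling_exponents",
]


def run_single_increment(
    cfg: RunConfig,
    delta_s: float | None = None,
    delta_g: float | None = None,
    rows: int | None = None,
    n_elem_s2: int | None = None,
    seed: int | None = None,
) -> MorphologyMetrics:
    """One growth increment of the preset with optional overrides."""
    cfg = cfg.model_copy(deep=True)
    inc = cfg.growth.increments[0]
    if delta_s is not None:
        inc.delta_s = delta_s
    if delta_g is not None:
        inc.delta_g = delta_g
    if rows is not None:
        inc.rows = rows
    cfg.growth.increments = [inc]
    if n_elem_s2 is not None:
        cfg.geometry.n_elem_s2 = n_elem_s2
    if seed is not None:
        cfg.solver.imperfection_seed = seed
    engine_cfg = build_engine_config(cfg)
    state = SimulationState()
    run_growth_increment(state, engine_cfg.increments[0], engine_cfg)
    return state.metrics_history[-1]


def delta_g_upward_sweep(cfg: RunConfig, seed: int | None = None):
    """Sweep the volume-growth increment upward until a bifurcation appears.

    Runs independent single-increment simulations at ``delta_g = step, 2
    step, ...`` up to the configured bound; the first configuration whose
    leading-edge amplitude exceeds ``detection_amplitude_h * h`` is the first
    discernible bifurcation.  Returns ``(delta_g_star, metrics, trace)``
    where ``trace`` is the list of (delta_g, amplitude) pairs visited.
    """
    sw = cfg.sweep
    step = (sw.delta_g_step if sw and sw.delta_g_step else 0.01)
    gmax = (sw.delta_g_max if sw and sw.delta_g_max else 0.56)
    floor = (sw.detection_amplitude_h if sw else 0.02) * cfg.geometry.h
    trace = []
    dg = step
    while dg <= gmax + 1e-12:
        m = run_single_increment(cfg, delta_g=dg, seed=seed)
        trace.append((dg, m.amplitude_max))
        if m.amplitude_max >= floor:
            return dg, m, trace
        dg += step
    return None, None, trace


def delta_g_multiples(cfg: RunConfig, delta_g_star: float, multipliers, seed=None):
    """Independent runs at multiples of the first-bifurcation increment."""
    return {
        mult: run_single_increment(cfg, delta_g=mult * delta_g_star, seed=seed)
        for mult in multipliers
    }


def _scaled_mesh(cfg: RunConfig, delta_s: float) -> tuple[int, int]:
    """Margin-direction element count and width rows for a given strip width.

    Elements along the margin track the expected buckling wavelength
    (proportional to the strip width), bounded by the preset's base
    resolution; wider strips get more element rows across their width.
    """
    length = cfg.geometry.length
    n2 = int(np.clip(round(length / (0.35 * delta_s)), 20, cfg.geometry.n_elem_s2))
    rows = 2 if delta_s <= 3 else 3
    return n2, rows


def delta_s_mode_family(cfg: RunConfig, seed=None) -> list[tuple[float, int]]:
    """Mode number vs active mantle width at fixed volume growth."""
    sw = cfg.sweep
    mults = sw.delta_s_multipliers if sw and sw.delta_s_multipliers else [1, 2, 4, 8]
    base = cfg.growth.increments[0].delta_s
    out = []
    for mult in mults:
        ds = base * mult
        n2, rows = _scaled_mesh(cfg, ds)
        m = run_single_increment(
            cfg, delta_s=ds, rows=rows, n_elem_s2=n2, seed=seed
        )
        out.append((ds, m.n))
    return out


def mode_scaling_exponents(mode_family, domain_length: float):
    """Power-law exponents of n(delta_s) and of the rod-calibrated k(delta_s)."""
    good = [(d, n) for d, n in mode_family if n >= 1]
    ds = [d for d, _ in good]
    ns = [n for _, n in good]
    n_exp, _, r2 = fit_power_law(ds, ns)
    _, k_exp = calibrate_foundation_stiffness(good, domain_length)
    return n_exp, k_exp, r2
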