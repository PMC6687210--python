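"""Deterministic synthetic fixtures: tiny meshes and analytic fields.

These generators make every module testable in milliseconds without running
the full simulator: edge profiles with known mode content, analytic
constant-curvature surfaces for the Gaussian-curvature estimator, and a
two-element mesh for finite-difference consistency checks of the assembly.
All fixtures are pure functions of their arguments; any randomness is drawn
from a generator keyed on ``(name, seed)`` so test order cannot leak state.
"""

from __future__ import annotations

import hashlib

import numpy as np

from .geometry import StripMesh, extrude_strip, make_generating_curve, compute_frames
from .metrics import EdgeProfile

__all__ = [
    "fixture_rng",
    "make_sinusoidal_edge",
    "make_analytic_sphere_patch",
    "make_two_element_mesh",
]


def fixture_rng(name: str, seed: int = 0) -> np.random.Generator:
    """Counter-based generator keyed on (name, seed)."""
    digest = hashlib.sha256(f"{name}:{seed}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def make_sinusoidal_edge(
    length: float,
    n_waves: int,
    amplitude: float,
    envelope: str = "uniform",
    n_samples: int = 256,
    envelope_sigma_fraction: float = 0.15,
) -> EdgeProfile:
    """Edge profile ``w = A env(xi2) sin(2 pi n_waves xi2 / L)``.

    ``envelope="gaussian"`` centres a Gaussian of standard deviation
    ``envelope_sigma_fraction * length`` at mid-span, emulating the localized
    superposition of modes near onset where only the central crests are
    discernible.
    """
    if n_waves < 0:
        raise ValueError("n_waves must be >= 0")
    if n_waves > 0 and n_samples < 4 * n_waves:
        raise ValueError(
            f"n_samples = {n_samples} aliases {n_waves} waves (need >= {4 * n_waves})"
        )
    xi2 = np.linspace(0.0, length, n_samples)
    w = amplitude * np.sin(2 * np.pi * n_waves * xi2 / length)
    if envelope == "gaussian":
        sig = envelope_sigma_fraction * length
        w *= np.exp(-0.5 * ((xi2 - length / 2) / sig) ** 2)
    elif envelope != "uniform":
        raise ValueError(f"unknown envelope {envelope!r}")
    base = np.zeros((n_samples, 3))
    base[:, 1] = xi2
    return EdgeProfile(xi2=xi2, w=w, baseline=base)


def make_analytic_sphere_patch(R: float, n_u: int, n_v: int) -> np.ndarray:
    """Structured quad grid (n_u, n_v, 3) on a spherical cap of radius R.

    Covers colatitude [0.35, 1.15] rad and a matching azimuth span, away from
    the pole so all quads are well-shaped.
    """
    if R <= 0:
        raise ValueError("R must be > 0")
    if n_u < 2 or n_v < 2:
        raise ValueError("need at least 2 samples per direction")
    theta = np.linspace(0.35, 1.15, n_u)
    phi = np.linspace(0.0, 0.8, n_v)
    T, P = np.meshgrid(theta, phi, indexing="ij")
    pts = np.stack(
        [
            R * np.sin(T) * np.cos(P),
            R * np.sin(T) * np.sin(P),
            R * np.cos(T),
        ],
        axis=-1,
    )
    return pts


def make_two_element_mesh(basis_order: int = 1) -> StripMesh:
    """Two unit-cube hexahedra in a 1 x 2 x 1 strip arrangement."""
    curve = make_generating_curve("line", 2.0, n_samples=8)
    # extrude wants conforming sampling: rebuild with 3 samples via a direct call
    from .geometry import GeneratingCurve

    xi = np.linspace(0.0, 2.0, 3)
    pts = np.zeros((3, 3))
    pts[:, 1] = xi
    curve = GeneratingCurve(pts, xi, np.zeros(3))
    frames = compute_frames(curve)
    return extrude_strip(
        curve, frames, width=1.0, h=1.0, n_elem_s1=1, n_elem_s2=2,
        layers=1, basis_order=basis_order,
    )
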