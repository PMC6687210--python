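"""Generating curves, local frames, and hexahedral mantle-strip meshes.

The calcified shell edge is represented by a *generating curve* Gamma with an
arclength coordinate ``xi2`` and a signed curvature profile ``kappa(xi2)``.
Each growth increment extrudes a thin strip of mantle from the current edge:
width ``delta_s`` along the surface-growth direction ``s1``, thickness ``h``
along the surface normal ``s3``, with ``s2`` tangent to the margin.  The
frame is right-handed and orthonormal, ``s3 = s1 x s2``.

Sign convention: curves are integrated from their curvature profile with the
heading rotating so that positive ``kappa`` means the curve bends *toward*
the extrusion direction ``s1 = s2 x n_hat`` (the centre of curvature lies on
the ``+s1`` side).  The signed discrete (Menger) curvature uses the same
convention, so constructor and measurement agree.

Meshes are structured grids of 8-node hexahedra (VTK ordering): ``n1`` rows
of elements along ``s1``, ``n2`` along the curve, ``layers`` through the
thickness.  Nodes are ordered row-major in the ``s1`` index so that accretive
extension appends nodes and elements without touching existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeneratingCurve",
    "FrameField",
    "StripMesh",
    "make_generating_curve",
    "compute_frames",
    "extrude_strip",
    "extend_mesh",
    "discrete_curvature",
]


@dataclass(frozen=True)
class GeneratingCurve:
    """Sampled shell-edge curve with arclength and signed curvature."""

    points: np.ndarray        # (n, 3)
    xi2: np.ndarray           # (n,) strictly increasing arclength
    kappa: np.ndarray         # (n,) signed curvature
    closed: bool = False
    surface_normal_hint: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        xi2 = np.asarray(self.xi2, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if len(xi2) != len(pts):
            raise ValueError("xi2 and points must have equal length")
        if np.any(np.diff(xi2) <= 0):
            raise ValueError("xi2 must be strictly increasing")
        if self.closed:
            gap = np.linalg.norm(pts[0] - pts[-1])
            ds = xi2[1] - xi2[0]
            if gap > 1e-6 * max(1.0, ds):
                raise ValueError("closed curve must have coincident endpoints")
        hint = np.asarray(self.surface_normal_hint, dtype=float)
        if hint.ndim == 1:
            hint = np.broadcast_to(hint, pts.shape)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "xi2", xi2)
        object.__setattr__(self, "kappa", np.asarray(self.kappa, dtype=float))
        object.__setattr__(self, "surface_normal_hint", np.array(hint))

    @property
    def n_samples(self) -> int:
        return len(self.xi2)

    @property
    def length(self) -> float:
        return float(self.xi2[-1] - self.xi2[0])


@dataclass(frozen=True)
class FrameField:
    """Orthonormal frames {s1, s2, s3} at each curve sample.

    ``s1``: surface-growth direction, ``s2``: margin tangent, ``s3``: surface
    normal; ``s3 = s1 x s2`` and ``si . sj = delta_ij``.
    """

    s1: np.ndarray  # (n, 3)
    s2: np.ndarray  # (n, 3)
    s3: np.ndarray  # (n, 3)

    def __len__(self) -> int:
        return len(self.s1)


@dataclass
class StripMesh:
    """Structured hexahedral mesh of accreted mantle strips.

    ``shape = (n1, n2, layers)`` counts elements along (s1, s2, s3); the node
    with structured index (i, j, l) has flat id
    ``i * (n2+1) * (layers+1) + j * (layers+1) + l`` so that appending rows
    of elements along s1 (accretion) never renumbers existing nodes.
    """

    node_coords: np.ndarray          # (N, 3)
    hex_connectivity: np.ndarray     # (E, 8) VTK node order
    strip_id: np.ndarray             # (E,) int
    deposition_time: dict[int, float]
    thickness: float
    layers_through_thickness: int
    boundary_tags: dict[str, np.ndarray]
    basis_order: int
    shape: tuple[int, int, int]
    closed: bool = False

    @property
    def nodes_per_ring(self) -> int:
        """Number of distinct nodes along s2 (duplicate endpoint dropped if closed)."""
        n2 = self.shape[1]
        return n2 if self.closed else n2 + 1

    def node_id(self, i, j, l):
        n2n, ln = self.nodes_per_ring, self.shape[2] + 1
        j = np.asarray(j) % n2n
        return (np.asarray(i) * n2n + j) * ln + np.asarray(l)

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    @property
    def n_elements(self) -> int:
        return len(self.hex_connectivity)

    def copy(self) -> "StripMesh":
        return StripMesh(
            node_coords=self.node_coords.copy(),
            hex_connectivity=self.hex_connectivity.copy(),
            strip_id=self.strip_id.copy(),
            deposition_time=dict(self.deposition_time),
            thickness=self.thickness,
            layers_through_thickness=self.layers_through_thickness,
            boundary_tags={k: v.copy() for k, v in self.boundary_tags.items()},
            basis_order=self.basis_order,
            shape=self.shape,
            closed=self.closed,
        )


# ---------------------------------------------------------------------------
# generating curves
# ---------------------------------------------------------------------------

def _integrate_planar(kappa_of_xi, length: float, n_samples: int, bend: str):
    """Integrate the planar Frenet relations for a curvature profile.

    ``bend="in_surface"``: curve in the xy-plane, heading ``theta' = -kappa``
    starting along +y, so positive curvature bends toward ``s1 = s2 x z``
    (the extrusion direction).  ``bend="out_of_surface"``: curve in the
    yz-plane with ``phi' = +kappa`` starting along +y, so positive curvature
    bends toward the surface normal ``s3`` (extrusion stays along +x); this
    is the configuration in which reference curvature biases the transverse
    buckling direction.  Positions use dense trapezoidal quadrature of the
    integrated heading.
    """
    xi = np.linspace(0.0, length, n_samples)
    refine = 8
    xi_dense = np.linspace(0.0, length, (n_samples - 1) * refine + 1)
    kap_dense = kappa_of_xi(xi_dense)
    if bend == "in_surface":
        theta = np.pi / 2.0 - _cumtrapz(kap_dense, xi_dense)
        comp = (np.cos(theta), np.sin(theta))
        axes = (0, 1)
    elif bend == "out_of_surface":
        phi = _cumtrapz(kap_dense, xi_dense)
        comp = (np.cos(phi), np.sin(phi))
        axes = (1, 2)
    else:
        raise ValueError(f"unknown bend plane {bend!r}")
    pts = np.zeros((n_samples, 3))
    pts[:, axes[0]] = _cumtrapz(comp[0], xi_dense)[::refine]
    pts[:, axes[1]] = _cumtrapz(comp[1], xi_dense)[::refine]
    return pts, xi, kappa_of_xi(xi)


def _cumtrapz(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(y)
    out[1:] = np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(x))
    return out


def make_generating_curve(
    kind: str,
    length_or_radius: float,
    curvature_params: dict | None = None,
    n_samples: int = 65,
) -> GeneratingCurve:
    """Construct a sampled generating curve with analytic curvature.

    Parameters
    ----------
    kind:
        ``"line"`` (kappa = 0, ``length_or_radius`` is the length),
        ``"arc"`` (constant kappa = 1/radius; ``curvature_params["arc_length"]``
        sets the extent, default one radian of turning),
        ``"circle"`` (closed, full turn), or
        ``"varying"`` (``length_or_radius`` is the length and
        ``curvature_params`` holds a tabulated profile ``{"xi2": [...],
        "kappa": [...]}`` interpolated with a clamped cubic spline, or a
        callable under key ``"profile"``).
    """
    params = dict(curvature_params or {})
    if n_samples < 8:
        raise ValueError(f"n_samples must be >= 8, got {n_samples}")

    if kind == "line":
        length = float(length_or_radius)
        if length <= 0:
            raise ValueError("line length must be > 0")
        xi = np.linspace(0.0, length, n_samples)
        pts = np.zeros((n_samples, 3))
        pts[:, 1] = xi
        return GeneratingCurve(pts, xi, np.zeros(n_samples))

    if kind == "arc":
        r = float(length_or_radius)
        if r <= 0:
            raise ValueError("arc radius must be > 0")
        length = float(params.get("arc_length", r))
        if length >= 2 * np.pi * r:
            raise ValueError("arc_length must be below the full circumference")
        kap = 1.0 / r
        xi = np.linspace(0.0, length, n_samples)
        # exact circular arc starting at the origin with heading +y;
        # x(xi) = r (1 - cos(kappa xi)), y(xi) = r sin(kappa xi)
        pts = np.zeros((n_samples, 3))
        pts[:, 0] = r * (1.0 - np.cos(kap * xi))
        pts[:, 1] = r * np.sin(kap * xi)
        return GeneratingCurve(pts, xi, np.full(n_samples, kap))

    if kind == "circle":
        r = float(length_or_radius)
        if r <= 0:
            raise ValueError("circle radius must be > 0")
        kap = 1.0 / r
        xi = np.linspace(0.0, 2 * np.pi * r, n_samples)
        ang = kap * xi
        pts = np.zeros((n_samples, 3))
        pts[:, 0] = r * (1.0 - np.cos(ang))
        pts[:, 1] = r * np.sin(ang)
        return GeneratingCurve(pts, xi, np.full(n_samples, kap), closed=True)

    if kind == "varying":
        length = float(length_or_radius)
        if length <= 0:
            raise ValueError("curve length must be > 0")
        if "profile" in params:
            kappa_of_xi = params["profile"]
        else:
            tab_xi = np.asarray(params["xi2"], dtype=float)
            tab_k = np.asarray(params["kappa"], dtype=float)
            # monotone cubic: no overshoot, so plateau values are preserved
            from scipy.interpolate import PchipInterpolator

            spline = PchipInterpolator(tab_xi, tab_k)

            def kappa_of_xi(x, _s=spline):
                return _s(np.clip(x, tab_xi[0], tab_xi[-1]))

            # Nyquist-style guard: sampling must resolve the tabulated detail
            if n_samples < 2 * len(tab_xi):
                raise ValueError(
                    "n_samples too small to resolve the tabulated curvature "
                    f"profile ({len(tab_xi)} knots need >= {2 * len(tab_xi)} samples)"
                )
        bend = params.get("bend", "in_surface")
        pts, xi, kap = _integrate_planar(
            lambda x: np.asarray(kappa_of_xi(x), dtype=float), length, n_samples, bend
        )
        return GeneratingCurve(pts, xi, kap)

    raise ValueError(f"unknown curve kind {kind!r}")


# ---------------------------------------------------------------------------
# frames
# ---------------------------------------------------------------------------

def _polyline_tangents(points: np.ndarray, closed: bool = False) -> np.ndarray:
    t = np.zeros_like(points)
    if closed:
        ext = np.vstack([points[-2], points, points[1]])
        t = ext[2:] - ext[:-2]
    else:
        t[1:-1] = points[2:] - points[:-2]
        t[0] = points[1] - points[0]
        t[-1] = points[-1] - points[-2]
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("degenerate polyline: repeated consecutive points")
    return t / norms


def compute_frames(curve: GeneratingCurve) -> FrameField:
    """Orthonormal frames at each sample from tangents and the normal hint.

    ``s2`` is the unit tangent; the hint is orthogonalized against it to give
    the surface normal direction, then ``s1 = s2 x n_hat`` and
    ``s3 = s1 x s2``.  Raises if the hint is (numerically) parallel to the
    tangent anywhere.
    """
    s2 = _polyline_tangents(curve.points, curve.closed)
    hint = curve.surface_normal_hint
    n_hat = hint - (np.sum(hint * s2, axis=1, keepdims=True)) * s2
    norms = np.linalg.norm(n_hat, axis=1, keepdims=True)
    if np.any(norms < 1e-8):
        bad = int(np.argmin(norms))
        raise ValueError(f"surface normal hint parallel to tangent at sample {bad}")
    n_hat /= norms
    s1 = np.cross(s2, n_hat)
    s1 /= np.linalg.norm(s1, axis=1, keepdims=True)
    s3 = np.cross(s1, s2)
    return FrameField(s1=s1, s2=s2, s3=s3)


# ---------------------------------------------------------------------------
# strip extrusion and accretive extension
# ---------------------------------------------------------------------------

def _structured_connectivity(n1: int, n2: int, layers: int, closed: bool = False):
    """VTK-ordered hex connectivity for the structured (i, j, l) grid."""
    n2n = n2 if closed else n2 + 1
    ln = layers + 1

    def nid(i, j, l):
        return (i * n2n + j % n2n) * ln + l

    conn = np.empty((n1 * n2 * layers, 8), dtype=np.int64)
    e = 0
    for i in range(n1):
        for j in range(n2):
            for l in range(layers):
                conn[e] = [
                    nid(i, j, l), nid(i + 1, j, l),
                    nid(i + 1, j + 1, l), nid(i, j + 1, l),
                    nid(i, j, l + 1), nid(i + 1, j, l + 1),
                    nid(i + 1, j + 1, l + 1), nid(i, j + 1, l + 1),
                ]
                e += 1
    return conn


def _structured_tags(
    n1: int, n2: int, layers: int, closed: bool = False
) -> dict[str, np.ndarray]:
    n2n = n2 if closed else n2 + 1
    ln = layers + 1

    def nid(i, j, l):
        return (i * n2n + j) * ln + l

    ii, jj, ll = np.meshgrid(
        np.arange(n1 + 1), np.arange(n2n), np.arange(ln), indexing="ij"
    )
    flat = nid(ii, jj, ll)
    tags = {
        "trailing": flat[0].ravel(),
        "leading": flat[-1].ravel(),
        "bottom": flat[:, :, 0].ravel(),
        "top": flat[:, :, -1].ravel(),
    }
    if not closed:
        tags["lateral_minus"] = flat[:, 0, :].ravel()
        tags["lateral_plus"] = flat[:, -1, :].ravel()
    else:
        tags["lateral_minus"] = np.empty(0, dtype=np.int64)
        tags["lateral_plus"] = np.empty(0, dtype=np.int64)
    return tags


def extrude_strip(
    curve: GeneratingCurve,
    frames: FrameField,
    width: float,
    h: float,
    n_elem_s1: int,
    n_elem_s2: int,
    layers: int = 1,
    basis_order: int = 2,
    strip_id: int = 0,
    deposition_time: float = 0.0,
) -> StripMesh:
    """Extrude a mantle strip of width ``width`` and thickness ``h`` from a curve.

    The trailing face (i = 0) lies exactly on the curve; nodes advance along
    the per-sample ``s1`` up to ``width`` and are offset ``+-h/2`` along
    ``s3``.  Curve sampling must conform to ``n_elem_s2`` (n_samples =
    n_elem_s2 + 1, or for closed curves n_elem_s2 + 1 with the duplicate
    endpoint dropped).
    """
    if width <= 0 or h <= 0:
        raise ValueError("width and thickness must be > 0")
    if not (1 <= layers <= 4):
        raise ValueError("layers must be in [1, 4]")
    if basis_order not in (1, 2):
        raise ValueError("basis_order must be 1 or 2")
    if curve.n_samples != n_elem_s2 + 1:
        raise ValueError(
            f"curve sampling ({curve.n_samples}) must equal n_elem_s2 + 1 "
            f"({n_elem_s2 + 1})"
        )
    kap_side = curve.kappa * width
    if np.any(kap_side >= 1.0):
        raise ValueError(
            "extrusion self-intersects: width exceeds local radius of "
            "curvature on the concave side"
        )

    n_pts = curve.n_samples if not curve.closed else curve.n_samples - 1
    pts = curve.points[:n_pts]
    s1 = frames.s1[:n_pts]
    s3 = frames.s3[:n_pts]

    ln = layers + 1
    coords = np.empty(((n_elem_s1 + 1) * n_pts * ln, 3))
    idx = 0
    for i in range(n_elem_s1 + 1):
        r = width * i / n_elem_s1
        for j in range(n_pts):
            base = pts[j] + r * s1[j]
            for l in range(ln):
                z = (-0.5 + l / layers) * h
                coords[idx] = base + z * s3[j]
                idx += 1

    conn = _structured_connectivity(n_elem_s1, n_elem_s2, layers, closed=curve.closed)
    tags = _structured_tags(n_elem_s1, n_elem_s2, layers, closed=curve.closed)
    mesh = StripMesh(
        node_coords=coords,
        hex_connectivity=conn,
        strip_id=np.full(len(conn), strip_id, dtype=np.int64),
        deposition_time={strip_id: deposition_time},
        thickness=h,
        layers_through_thickness=layers,
        boundary_tags=tags,
        basis_order=basis_order,
        shape=(n_elem_s1, n_elem_s2, layers),
        closed=curve.closed,
    )
    _check_positive_jacobians(mesh)
    return mesh


def _check_positive_jacobians(mesh: StripMesh) -> None:
    """Corner-node Jacobian (scaled) positivity for every hexahedron."""
    X = mesh.node_coords[mesh.hex_connectivity]  # (E, 8, 3)
    # VTK corner natural coords
    nat = np.array(
        [
            [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
            [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
        ],
        dtype=float,
    )
    for c in range(8):
        g = nat[c]
        dN = np.empty((8, 3))
        for a in range(8):
            xa, ya, za = nat[a]
            dN[a, 0] = 0.125 * xa * (1 + ya * g[1]) * (1 + za * g[2])
            dN[a, 1] = 0.125 * ya * (1 + xa * g[0]) * (1 + za * g[2])
            dN[a, 2] = 0.125 * za * (1 + xa * g[0]) * (1 + ya * g[1])
        J = np.einsum("eai,aj->eij", X, dN)
        det = np.linalg.det(J)
        if np.any(det <= 0):
            bad = int(np.argmin(det))
            raise ValueError(f"non-positive Jacobian in element {bad}")


def extend_mesh(
    state_mesh: StripMesh,
    deformed_leading_coords: np.ndarray,
    delta_s: float,
    n_rows: int,
    new_strip_id: int,
    deposition_time: float | None = None,
) -> StripMesh:
    """Accretively extend the mesh by ``n_rows`` element rows of width ``delta_s``.

    New nodes are placed from the *deformed* leading face: the margin frame is
    recomputed on the deformed leading edge (tangent from the deformed
    mid-surface polyline, normal from the through-thickness fibre) and new
    rows advance along the recomputed ``s1'``.  Existing node coordinates and
    connectivity are untouched; the ``leading`` tag moves to the new face.
    """
    n1, n2, layers = state_mesh.shape
    n2n, ln = state_mesh.nodes_per_ring, layers + 1
    lead = np.asarray(deformed_leading_coords, dtype=float)
    if lead.shape != (n2n * ln, 3):
        raise ValueError(
            f"deformed leading coords must have shape {(n2n * ln, 3)}, got {lead.shape}"
        )
    if delta_s <= 0 or n_rows < 1:
        raise ValueError("delta_s must be > 0 and n_rows >= 1")

    face = lead.reshape(n2n, ln, 3)
    mid = 0.5 * (face[:, 0] + face[:, -1])
    s2p = _polyline_tangents(mid, closed=state_mesh.closed)
    fibre = face[:, -1] - face[:, 0]
    s3p = fibre / np.linalg.norm(fibre, axis=1, keepdims=True)
    s1p = np.cross(s2p, s3p)
    s1p /= np.linalg.norm(s1p, axis=1, keepdims=True)

    new_coords = np.empty((n_rows * n2n * ln, 3))
    idx = 0
    for r in range(1, n_rows + 1):
        off = delta_s * r / n_rows
        for j in range(n2n):
            for l in range(ln):
                new_coords[idx] = face[j, l] + off * s1p[j]
                idx += 1

    coords = np.vstack([state_mesh.node_coords, new_coords])
    n1_new = n1 + n_rows
    conn_new = _structured_connectivity(n1_new, n2, layers, closed=state_mesh.closed)
    conn_added = conn_new[len(state_mesh.hex_connectivity):]
    conn = np.vstack([state_mesh.hex_connectivity, conn_added])
    strip_ids = np.concatenate(
        [state_mesh.strip_id, np.full(len(conn_added), new_strip_id, dtype=np.int64)]
    )
    times = dict(state_mesh.deposition_time)
    if deposition_time is None:
        deposition_time = max(times.values()) + 1.0 if times else 0.0
    if new_strip_id in times:
        raise ValueError(f"strip id {new_strip_id} already registered")
    times[new_strip_id] = float(deposition_time)

    tags = _structured_tags(n1_new, n2, layers, closed=state_mesh.closed)
    return StripMesh(
        node_coords=coords,
        hex_connectivity=conn,
        strip_id=strip_ids,
        deposition_time=times,
        thickness=state_mesh.thickness,
        layers_through_thickness=layers,
        boundary_tags=tags,
        basis_order=state_mesh.basis_order,
        shape=(n1_new, n2, layers),
        closed=state_mesh.closed,
    )


# ---------------------------------------------------------------------------
# discrete curvature
# ---------------------------------------------------------------------------

def discrete_curvature(
    polyline: np.ndarray, normal_hint: np.ndarray | None = None
) -> np.ndarray:
    """Menger (circumscribed-circle) curvature per vertex of a polyline.

    Endpoint values are copied from their interior neighbours.  If
    ``normal_hint`` is given (a single 3-vector), the curvature is signed with
    the package convention: positive when the curve bends toward
    ``s1 = t x n_hat``.
    """
    p = np.asarray(polyline, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3 or len(p) < 3:
        raise ValueError("polyline must be an (n>=3, 3) array")
    seg = np.diff(p, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    if np.any(seglen == 0):
        raise ValueError("duplicate consecutive points in polyline")

    a = p[:-2]
    b = p[1:-1]
    c = p[2:]
    ab = b - a
    bc = c - b
    ac = c - a
    cross = np.cross(ab, bc)
    area2 = np.linalg.norm(cross, axis=1)  # = 2 * triangle area
    denom = (
        np.linalg.norm(ab, axis=1)
        * np.linalg.norm(bc, axis=1)
        * np.linalg.norm(ac, axis=1)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        kap = np.where(area2 < 1e-14 * denom, 0.0, 2.0 * area2 / denom)

    if normal_hint is not None:
        n_hat = np.asarray(normal_hint, dtype=float)
        n_hat = n_hat / np.linalg.norm(n_hat)
        t = ac / np.linalg.norm(ac, axis=1, keepdims=True)
        s1 = np.cross(t, np.broadcast_to(n_hat, t.shape))
        bend = (a - 2 * b + c)
        sign = np.sign(np.sum(bend * s1, axis=1))
        kap = kap * np.where(sign == 0, 1.0, sign)

    out = np.empty(len(p))
    out[1:-1] = kap
    out[0] = out[1]
    out[-1] = out[-2]
    return out
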