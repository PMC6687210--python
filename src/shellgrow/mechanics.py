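"""Hyperelastic constitutive model and finite-element equilibrium solver.

The mantle is a compressible neo-Hookean solid described by the strain
energy density

    psi(Fe) = mu/2 (tr(Fe^T Fe) - 3) - mu ln Je + lam/2 (ln Je)^2,

with ``Je = det Fe`` and first Piola-Kirchhoff stress ``P = d psi / d Fe``.
Growth enters through the multiplicative split ``F = Fe Fg``: equilibrium
solves minimize the total potential

    Pi(u) = int_ref  psi(F(u) Fg^{-1}) det(Fg)  dV,

the ``det Fg`` factor weighting the energy by the grown (intermediate)
volume.  Discretization uses structured grids of hexahedra with a trilinear
geometry map and tensor-product Lagrange displacement bases of order 1 or 2
(order 2 by default: one quadratic layer resolves the bending that drives
the buckling patterns; trilinear bricks are shear-locking-prone for thin
strips and are kept mainly for cheap consistency fixtures).

Equilibria are found by Newton iteration with backtracking line search,
the growth increment ramped over a number of load steps (the growth tensor
interpolated through the exponential map at fractional exponents).  Symmetry
breaking at buckling is enabled by a small deterministic transverse
geometric imperfection of the reference configuration, drawn from a seeded
generator; amplitude zero recovers the perfect structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .kinematics import growth_tensor_field

__all__ = [
    "MaterialModel",
    "SolverSettings",
    "ElementInversionError",
    "NonConvergenceError",
    "strain_energy",
    "first_pk_stress",
    "pk_tangent",
    "StructuredGrid",
    "FemModel",
    "SolveResult",
    "solve_equilibrium",
    "assemble_residual_and_tangent",
]


# ---------------------------------------------------------------------------
# constitutive law
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaterialModel:
    """Compressible neo-Hookean material (dimensionless moduli).

    ``mu`` sets the stress scale; ``lam`` the degree of compressibility
    (``lam = 2 mu`` gives a Poisson ratio of 1/3 in the small-strain limit).
    """

    mu: float = 1.0
    lam: float = 2.0
    model_id: str = "neo_hookean_compressible"

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.lam < 0:
            raise ValueError("require mu > 0 and lam >= 0")


class ElementInversionError(RuntimeError):
    """det(Fe) <= 0 encountered during an evaluation."""


class NonConvergenceError(RuntimeError):
    """Newton iteration failed; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict):
        super().__init__(message)
        self.diagnostics = diagnostics


def strain_energy(Fe: np.ndarray, material: MaterialModel) -> np.ndarray:
    """psi(Fe); batched over leading axes. Raises on element inversion."""
    Fe = np.asarray(Fe, dtype=float)
    Je = np.linalg.det(Fe)
    if np.any(Je <= 0):
        raise ElementInversionError("det(Fe) <= 0")
    lnJ = np.log(Je)
    I1 = np.einsum("...ij,...ij->...", Fe, Fe)
    return 0.5 * material.mu * (I1 - 3.0) - material.mu * lnJ + 0.5 * material.lam * lnJ**2


def first_pk_stress(Fe: np.ndarray, material: MaterialModel) -> np.ndarray:
    """P = mu (Fe - Fe^{-T}) + lam ln(Je) Fe^{-T}; batched."""
    Fe = np.asarray(Fe, dtype=float)
    Je = np.linalg.det(Fe)
    if np.any(Je <= 0):
        raise ElementInversionError("det(Fe) <= 0")
    FeInvT = np.swapaxes(np.linalg.inv(Fe), -1, -2)
    lnJ = np.log(Je)
    return material.mu * (Fe - FeInvT) + material.lam * lnJ[..., None, None] * FeInvT


def pk_tangent(Fe: np.ndarray, material: MaterialModel) -> np.ndarray:
    """dP/dFe as a (..., 3, 3, 3, 3) tensor with indices (i, J, k, L)."""
    Fe = np.asarray(Fe, dtype=float)
    Je = np.linalg.det(Fe)
    if np.any(Je <= 0):
        raise ElementInversionError("det(Fe) <= 0")
    A = np.linalg.inv(Fe)  # A[..., J, i] = (Fe^{-1})_{Ji}
    lnJ = np.log(Je)
    mu, lam = material.mu, material.lam
    eye = np.eye(3)
    term1 = np.einsum("ik,JL->iJkL", eye, eye)
    term2 = np.einsum("...Jk,...Li->...iJkL", A, A)
    term3 = np.einsum("...Ji,...Lk->...iJkL", A, A)
    coeff2 = (mu - lam * lnJ)[..., None, None, None, None]
    return mu * term1 + coeff2 * term2 + lam * term3


# ---------------------------------------------------------------------------
# structured grids and bases
# ---------------------------------------------------------------------------

def _gauss(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.polynomial.legendre.leggauss(n)


def _lagrange_1d(p: int, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Values and derivatives of the order-p Lagrange basis at points x."""
    x = np.asarray(x, dtype=float)
    if p == 1:
        N = np.stack([(1 - x) / 2, (1 + x) / 2], axis=-1)
        dN = np.stack([np.full_like(x, -0.5), np.full_like(x, 0.5)], axis=-1)
    elif p == 2:
        N = np.stack([x * (x - 1) / 2, 1 - x * x, x * (x + 1) / 2], axis=-1)
        dN = np.stack([x - 0.5, -2 * x, x + 0.5], axis=-1)
    else:
        raise ValueError("basis order must be 1 or 2")
    return N, dN


@dataclass
class StructuredGrid:
    """Structured block of hexahedra: geometry corners + displacement basis.

    ``corners``: (n1+1, n2n, layers+1, 3) trilinear geometry nodes, where
    ``n2n`` is the number of distinct nodes along s2 (closed rings wrap).
    """

    corners: np.ndarray
    closed: bool = False
    basis_order: int = 2

    def __post_init__(self) -> None:
        if self.corners.ndim != 4 or self.corners.shape[-1] != 3:
            raise ValueError("corners must be (n1+1, n2n, layers+1, 3)")
        n1p, n2n, lnp, _ = self.corners.shape
        self.n1 = n1p - 1
        self.n2 = n2n if self.closed else n2n - 1
        self.layers = lnp - 1
        p = self.basis_order
        self.dof_dims = (
            p * self.n1 + 1,
            p * self.n2 if self.closed else p * self.n2 + 1,
            p * self.layers + 1,
        )

    @property
    def n_dof_nodes(self) -> int:
        return int(np.prod(self.dof_dims))

    def dof_index(self, i, j, l):
        d1, d2, d3 = self.dof_dims
        j = np.asarray(j) % d2
        return (np.asarray(i) * d2 + j) * d3 + np.asarray(l)

    def dof_node_coords(self) -> np.ndarray:
        """Positions of displacement nodes from the trilinear geometry map."""
        p = self.basis_order
        d1, d2, d3 = self.dof_dims
        out = np.empty((d1, d2, d3, 3))
        # natural coordinates of dof nodes inside their host element
        for gi in range(d1):
            e_i, loc_i = min(gi // p, self.n1 - 1), gi - min(gi // p, self.n1 - 1) * p
            xi = -1.0 + 2.0 * loc_i / p
            for gj in range(d2):
                e_j = min(gj // p, self.n2 - 1)
                eta = -1.0 + 2.0 * (gj - e_j * p) / p
                for gl in range(d3):
                    e_l = min(gl // p, self.layers - 1)
                    zeta = -1.0 + 2.0 * (gl - e_l * p) / p
                    out[gi, gj, gl] = self._geom_point(e_i, e_j, e_l, xi, eta, zeta)
        return out.reshape(-1, 3)

    def _geom_point(self, ei, ej, el, xi, eta, zeta) -> np.ndarray:
        c = self._elem_corners(ei, ej, el)
        Nx, _ = _lagrange_1d(1, np.array([xi]))
        Ny, _ = _lagrange_1d(1, np.array([eta]))
        Nz, _ = _lagrange_1d(1, np.array([zeta]))
        w = np.einsum("a,b,c->abc", Nx[0], Ny[0], Nz[0])
        return np.einsum("abc,abci->i", w, c)

    def _elem_corners(self, ei, ej, el) -> np.ndarray:
        n2n = self.corners.shape[1]
        j0, j1 = ej % n2n, (ej + 1) % n2n
        idx_j = [j0, j1]
        c = self.corners[ei:ei + 2][:, idx_j][:, :, el:el + 2]  # (2,2,2,3)
        return c


# ---------------------------------------------------------------------------
# FE model: precomputed operators + assembly
# ---------------------------------------------------------------------------

class FemModel:
    """Precomputed element operators for a structured hexahedral block."""

    def __init__(self, grid: StructuredGrid, quadrature_order: int | None = None):
        self.grid = grid
        p = grid.basis_order
        nq1 = quadrature_order or (p + 1)
        gp, gw = _gauss(nq1)
        self.nq = nq1**3
        n1, n2, layers = grid.n1, grid.n2, grid.layers
        self.n_elems = n1 * n2 * layers

        # tensor-product displacement basis at quadrature points
        Np, dNp = _lagrange_1d(p, gp)      # (nq1, p+1)
        N1, dN1 = _lagrange_1d(1, gp)      # (nq1, 2) geometry basis
        nn = (p + 1) ** 3

        # per-qp basis arrays, ordering m = (c*(p+1)+b)*(p+1)+a -> L_a(xi)L_b(eta)L_c(zeta)
        qx, qy, qz = np.meshgrid(range(nq1), range(nq1), range(nq1), indexing="ij")
        qx, qy, qz = qx.ravel(), qy.ravel(), qz.ravel()
        self.qp_weights = gw[qx] * gw[qy] * gw[qz]
        self.qp_nat = np.stack([gp[qx], gp[qy], gp[qz]], axis=1)  # (nq, 3)

        def tensor_basis(Nt, dNt):
            nloc = Nt.shape[1]
            vals = np.empty((self.nq, nloc**3))
            grads = np.empty((self.nq, nloc**3, 3))
            for m in range(nloc**3):
                a = m % nloc
                b = (m // nloc) % nloc
                c = m // (nloc * nloc)
                vals[:, m] = Nt[qx, a] * Nt[qy, b] * Nt[qz, c]
                grads[:, m, 0] = dNt[qx, a] * Nt[qy, b] * Nt[qz, c]
                grads[:, m, 1] = Nt[qx, a] * dNt[qy, b] * Nt[qz, c]
                grads[:, m, 2] = Nt[qx, a] * Nt[qy, b] * dNt[qz, c]
            return vals, grads

        self.N_disp, dN_disp_nat = tensor_basis(Np, dNp)
        _, dN_geom_nat = tensor_basis(N1, dN1)

        # gather element corner coords (ne, 8, 3) and dof connectivity
        corners = grid.corners
        n2n = corners.shape[1]
        ei, ej, el = np.meshgrid(range(n1), range(n2), range(layers), indexing="ij")
        ei, ej, el = ei.ravel(), ej.ravel(), el.ravel()
        cc = np.empty((self.n_elems, 2, 2, 2, 3))
        for di in range(2):
            for dj in range(2):
                for dl in range(2):
                    cc[:, di, dj, dl] = corners[ei + di, (ej + dj) % n2n, el + dl]
        # corner ordering m = (c*2+b)*2+a
        Xg = cc.transpose(0, 3, 2, 1, 4).reshape(self.n_elems, 8, 3)

        # geometry Jacobian at qps: J[e,q,i,K] = dX_i/dxi_K
        J = np.einsum("eai,qaK->eqiK", Xg, dN_geom_nat)
        detJ = np.linalg.det(J)
        if np.any(detJ <= 0):
            raise ValueError("non-positive geometry Jacobian")
        Jinv = np.linalg.inv(J)  # (e,q,K,i): dxi_K/dX_i
        self.wdetJ = detJ * self.qp_weights[None, :]
        # displacement-basis gradients in reference coords
        self.G = np.einsum("qaK,eqKi->eqai", dN_disp_nat, Jinv)

        # reference margin direction s2 and width fraction xi1 at each qp
        s2 = J[:, :, :, 1]
        self.s2_qp = s2 / np.linalg.norm(s2, axis=-1, keepdims=True)
        self.xi1_frac_qp = (ei[:, None] + (self.qp_nat[None, :, 0] + 1) / 2) / n1

        # dof connectivity
        d1, d2, d3 = grid.dof_dims
        conn = np.empty((self.n_elems, nn), dtype=np.int64)
        for m in range(nn):
            a = m % (p + 1)
            b = (m // (p + 1)) % (p + 1)
            c = m // ((p + 1) ** 2)
            conn[:, m] = grid.dof_index(p * ei + a, p * ej + b, p * el + c)
        self.conn = conn
        self.nn = nn
        self.n_dofs = 3 * grid.n_dof_nodes
        edof = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(
            self.n_elems, 3 * nn
        )
        self.edof = edof
        self.K_rows = np.repeat(edof, 3 * nn, axis=1).ravel()
        self.K_cols = np.tile(edof, (1, 3 * nn)).ravel()

    # -- kinematic evaluation ------------------------------------------------

    def deformation_gradient(self, u: np.ndarray) -> np.ndarray:
        ue = u.reshape(-1, 3)[self.conn]  # (ne, nn, 3)
        F = np.einsum("eqaJ,eai->eqiJ", self.G, ue)
        F += np.eye(3)
        return F

    def _elastic_state(self, u, Fg):
        F = self.deformation_gradient(u)
        if Fg is None:
            Fe = F
            Fginv = None
            detFg = np.ones(F.shape[:2])
        else:
            Fginv = np.linalg.inv(Fg)
            detFg = np.linalg.det(Fg)
            Fe = F @ Fginv
        return Fe, Fginv, detFg

    def energy(self, u: np.ndarray, Fg: np.ndarray | None, material: MaterialModel) -> float:
        Fe, _, detFg = self._elastic_state(u, Fg)
        psi = strain_energy(Fe, material)
        return float(np.sum(self.wdetJ * detFg * psi))

    def residual(self, u, Fg, material) -> np.ndarray:
        Fe, Fginv, detFg = self._elastic_state(u, Fg)
        P = first_pk_stress(Fe, material)
        if Fginv is not None:
            Peff = np.einsum("eqiK,eqJK->eqiJ", P, Fginv)
        else:
            Peff = P
        w = self.wdetJ * detFg
        re = np.einsum("eq,eqiJ,eqaJ->eai", w, Peff, self.G, optimize=True)
        r = np.zeros(self.n_dofs)
        np.add.at(r, self.edof.ravel(), re.reshape(self.n_elems, -1).ravel())
        return r

    def residual_and_tangent(self, u, Fg, material):
        Fe, Fginv, detFg = self._elastic_state(u, Fg)
        P = first_pk_stress(Fe, material)
        C = pk_tangent(Fe, material)
        if Fginv is not None:
            Peff = np.einsum("eqiK,eqJK->eqiJ", P, Fginv)
            Ahat = np.einsum("eqiMkN,eqJM,eqLN->eqiJkL", C, Fginv, Fginv, optimize=True)
        else:
            Peff = P
            Ahat = C
        w = self.wdetJ * detFg
        re = np.einsum("eq,eqiJ,eqaJ->eai", w, Peff, self.G, optimize=True)
        r = np.zeros(self.n_dofs)
        np.add.at(r, self.edof.ravel(), re.reshape(self.n_elems, -1).ravel())

        tmp = np.einsum("eqaJ,eqiJkL->eqaikL", self.G, Ahat, optimize=True)
        Ke = np.einsum("eqaikL,eqbL,eq->eaibk", tmp, self.G, w, optimize=True)
        Ke = Ke.reshape(self.n_elems, 3 * self.nn, 3 * self.nn)
        K = sp.coo_matrix(
            (Ke.ravel(), (self.K_rows, self.K_cols)),
            shape=(self.n_dofs, self.n_dofs),
        ).tocsr()
        return r, K

    def max_stress(self, u, Fg, material) -> float:
        Fe, _, _ = self._elastic_state(u, Fg)
        P = first_pk_stress(Fe, material)
        return float(np.max(np.abs(P)))


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SolverSettings:
    """Newton/load-stepping controls.

    ``imperfection_amplitude`` is in units of the strip thickness ``h``; the
    transverse geometric imperfection that seeds symmetry breaking has
    pointwise magnitude <= amplitude * h and is drawn deterministically from
    ``imperfection_seed``.  Amplitude 0 disables it (perfect structure).
    """

    load_steps: int = 20
    newton_tol: float = 1e-8
    max_newton_iter: int = 30
    imperfection_amplitude: float = 1e-3
    imperfection_seed: int = 0
    quadrature_order: int | None = None
    stability_check: bool = True
    max_substep_halvings: int = 6
    kick_fraction: float = 0.2
    loose_tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.load_steps < 1:
            raise ValueError("load_steps must be >= 1")
        if self.newton_tol <= 0:
            raise ValueError("newton_tol must be > 0")


@dataclass
class SolveResult:
    u: np.ndarray
    converged: bool
    load_steps_completed: int
    newton_iterations: int
    residual_norm: float


def _newton(model, material, u, Fg, free, settings, f_floor=0.0):
    """Energy-minimizing Newton iteration.

    The residual is the exact gradient of the total potential, so the
    iteration minimizes energy: when the tangent is indefinite it is
    regularized Levenberg-style (K + tau I) until the step is a descent
    direction, and steps are accepted by Armijo backtracking on the energy.
    This keeps the solver off unstable (saddle) equilibria such as the flat
    compressed state above the buckling threshold.
    """
    r, K = model.residual_and_tangent(u, Fg, material)
    rn0 = np.linalg.norm(r[free])
    # convergence scale: this step's initial imbalance, floored by a fraction
    # of the largest imbalance seen in the whole solve (f_floor), so tiny
    # adaptive substeps are not held to an unattainably tight target
    ref = max(rn0, 0.01 * f_floor, 1e-14)
    rn = rn0
    tol = settings.newton_tol
    it = 0
    tau = 0.0
    try:
        E = model.energy(u, Fg, material)
    except ElementInversionError:
        return u, 0, rn, False, K, rn0
    diag_scale = None
    while rn > tol * ref + 1e-12:
        if it >= settings.max_newton_iter:
            return u, it, rn, False, K, rn0
        Kff = K[free][:, free].tocsc()
        if diag_scale is None:
            diag_scale = float(np.max(np.abs(Kff.diagonal()))) or 1.0
        n_free = Kff.shape[0]
        du = np.zeros_like(u)
        rf = r[free]
        for _ in range(30):
            A = Kff if tau == 0.0 else Kff + tau * sp.identity(n_free, format="csc")
            try:
                step = spla.spsolve(A, -rf)
            except RuntimeError:
                step = None
            if step is not None and np.all(np.isfinite(step)) and step @ rf < 0:
                break
            tau = max(4.0 * tau, 1e-8 * diag_scale)
        else:
            return u, it, rn, False, K, rn0
        du[free] = step
        slope = float(step @ rf)
        t = 1.0
        accepted = False
        for _ in range(30):
            try:
                E_new = model.energy(u + t * du, Fg, material)
            except ElementInversionError:
                t *= 0.5
                continue
            if E_new <= E + 1e-4 * t * slope:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            tau = max(4.0 * tau, 1e-8 * diag_scale)
            it += 1
            continue
        u = u + t * du
        E = E_new
        if t >= 0.99:
            tau /= 3.0
            if tau < 1e-12 * diag_scale:
                tau = 0.0
        elif t < 0.25:
            tau = max(4.0 * tau, 1e-8 * diag_scale)
        it += 1
        r, K = model.residual_and_tangent(u, Fg, material)
        rn = np.linalg.norm(r[free])
    return u, it, rn, True, K, rn0


def solve_equilibrium(
    model: FemModel,
    g_qp: np.ndarray,
    material: MaterialModel,
    fixed_dofs: np.ndarray,
    settings: SolverSettings,
    fixed_values: np.ndarray | None = None,
    u0: np.ndarray | None = None,
    g_qp_start: np.ndarray | None = None,
) -> SolveResult:
    """Ramp the growth exponent field ``g_qp`` to full value and equilibrate.

    ``g_qp`` (ne, nq) holds the per-quadrature-point growth exponent
    ``eps2 * dt``; the growth tensor at load fraction ``alpha`` is
    ``exp(g(alpha) s2 (x) s2)`` with ``s2`` the reference margin direction
    frozen at deposition and ``g(alpha)`` interpolated from ``g_qp_start``
    (default 0) to ``g_qp``.  ``fixed_dofs`` are Dirichlet dof indices, held
    at ``fixed_values`` (default 0).
    """
    free = np.ones(model.n_dofs, dtype=bool)
    free[fixed_dofs] = False
    u = np.zeros(model.n_dofs) if u0 is None else u0.copy()
    if fixed_values is not None:
        u[fixed_dofs] = fixed_values
    else:
        u[fixed_dofs] = 0.0
    g0 = np.zeros_like(g_qp) if g_qp_start is None else g_qp_start

    # thickness estimate sets the scale of stabilization kicks
    corners = model.grid.corners
    fibre = corners[:, :, -1] - corners[:, :, 0]
    h_est = float(np.mean(np.linalg.norm(fibre, axis=-1))) or 1.0

    total_iters = 0
    rn = 0.0
    # characteristic force scale: the growth imbalance of the full increment
    try:
        Fg_full = growth_tensor_field(g_qp, model.s2_qp)
        f_scale = float(np.linalg.norm(model.residual(u, Fg_full, material)[free]))
    except ElementInversionError:
        f_scale = 0.0
    g_max = float(np.max(np.abs(g_qp - g0))) if g_qp.size else 0.0
    n_steps = 1 if g_max == 0.0 else settings.load_steps
    alpha_prev = 0.0
    for step in range(1, n_steps + 1):
        alpha_target = step / n_steps

        def fg_at(a):
            return growth_tensor_field(g0 + a * (g_qp - g0), model.s2_qp)

        # adaptive substepping toward alpha_target
        a_lo, a_hi = alpha_prev, alpha_target
        halvings = 0
        while a_lo < alpha_target - 1e-12:
            Fg = fg_at(a_hi)
            u_try, it, rn, ok, K_last, rn0 = _newton(
                model, material, u, Fg, free, settings, f_floor=f_scale
            )
            f_scale = max(f_scale, rn0)
            total_iters += it
            if not ok:
                # quasi-Newton rescue, then polish
                u_resc, nit = _lbfgs_rescue(model, material, u_try, Fg, free)
                total_iters += nit
                u_try, it, rn, ok, K_last, rn0 = _newton(
                    model, material, u_resc, Fg, free, settings, f_floor=f_scale
                )
                total_iters += it
            if not ok and rn <= settings.loose_tol * max(f_scale, rn0):
                # deep post-buckling landscapes have near-zero-stiffness
                # pattern-phase modes along which the residual drains only
                # asymptotically; a stagnated state whose imbalance is a tiny
                # fraction of the peak growth force is accepted as equilibrium
                ok = True
            if ok:
                u = u_try
                a_lo, a_hi = a_hi, alpha_target
                K_at_u = K_last
            else:
                halvings += 1
                if halvings > settings.max_substep_halvings:
                    raise NonConvergenceError(
                        f"Newton failed near load fraction {a_hi:.4f} "
                        f"(residual {rn:.3e})",
                        {"load_step": step, "load_fraction": a_hi,
                         "residual_norm": rn, "iterations": total_iters},
                    )
                a_hi = 0.5 * (a_lo + a_hi)
        alpha_prev = alpha_target

        if settings.stability_check:
            Fg = fg_at(alpha_target)
            u, kicks = _stabilize(
                model, material, u, Fg, free, settings, h_est, K_at_u, f_scale
            )
            total_iters += kicks
            K_at_u = None

    return SolveResult(
        u=u,
        converged=True,
        load_steps_completed=n_steps,
        newton_iterations=total_iters,
        residual_norm=rn,
    )


def _lbfgs_rescue(model, material, u, Fg, free, maxiter=500):
    """Quasi-Newton energy descent for states Newton cannot reach directly.

    Used when the regularized Newton iteration stalls (typically while
    snapping through a cascade of closely spaced bifurcations); the result
    is then polished by Newton.
    """
    from scipy.optimize import minimize

    def fun(x):
        uu = u.copy()
        uu[free] = x
        try:
            E = model.energy(uu, Fg, material)
            g = model.residual(uu, Fg, material)[free]
        except ElementInversionError:
            return 1e30, np.zeros_like(x)
        return E, g

    res = minimize(
        fun, u[free], jac=True, method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-16, "gtol": 1e-12},
    )
    uu = u.copy()
    uu[free] = res.x
    return uu, int(res.nit)


def _lowest_mode(Kff) -> tuple[float, np.ndarray]:
    """Most negative (or smallest) eigenpair of the reduced tangent.

    Shift-invert at zero returns eigenvalues *nearest* zero, which can all be
    positive for a deeply unstable state; a window of near-zero eigenvalues
    is therefore combined with a loose smallest-algebraic Lanczos probe.
    """
    n = Kff.shape[0]
    v0 = np.ones(n)
    k = min(8, n - 1)
    scale = float(np.max(np.abs(Kff.diagonal()))) or 1.0
    best = None
    for sigma in (0.0, -2e-3 * scale):
        try:
            vals, vecs = spla.eigsh(Kff, k=k, sigma=sigma, which="LM", v0=v0)
        except (RuntimeError, spla.ArpackNoConvergence):
            continue
        i = int(np.argmin(vals))
        if best is None or vals[i] < best[0]:
            best = (float(vals[i]), vecs[:, i])
        if best[0] < 0:
            return best
    if best is None:
        vals, vecs = spla.eigsh(Kff, k=1, which="SA", v0=v0, tol=1e-3, maxiter=3000)
        best = (float(vals[0]), vecs[:, 0])
    return best


def _stabilize(model, material, u, Fg, free, settings, h_est, K0=None, f_scale=0.0):
    """Kick off unstable equilibria along their softest eigenmode.

    Newton can converge onto unstable (e.g. perfectly flat, compressed)
    branches; a converged state with a negative tangent eigenvalue is
    perturbed along the corresponding eigenvector -- sign chosen by energy
    descent, amplitude ``kick_fraction * h`` -- and re-equilibrated, until
    the state is a local minimum.
    """
    kicks = 0
    for round_ in range(12):
        if round_ == 0 and K0 is not None:
            K = K0
        else:
            _, K = model.residual_and_tangent(u, Fg, material)
        Kff = K[free][:, free]
        lam, vec = _lowest_mode(Kff)
        scale = abs(Kff.diagonal()).max()
        if lam > -1e-9 * scale:
            return u, kicks
        phi = np.zeros_like(u)
        phi[free] = vec
        amp = settings.kick_fraction * h_est
        step = amp * phi / np.max(np.abs(phi))
        c = 1.0
        for _ in range(8):
            try:
                e_plus = model.energy(u + c * step, Fg, material)
                e_minus = model.energy(u - c * step, Fg, material)
            except ElementInversionError:
                c *= 0.5
                continue
            break
        trial = u + (c if e_plus <= e_minus else -c) * step
        u_new, it, rn, ok, _K, _rn0 = _newton(
            model, material, trial, Fg, free, settings, f_floor=f_scale
        )
        kicks += it
        if ok or rn <= settings.loose_tol * max(f_scale, _rn0):
            u = u_new
        else:
            # shrink the kick and retry once; otherwise keep the stable-side state
            trial = u + 0.25 * (c if e_plus <= e_minus else -c) * step
            u_new, it, rn, ok, _K, _rn0 = _newton(
                model, material, trial, Fg, free, settings, f_floor=f_scale
            )
            kicks += it
            if ok or rn <= settings.loose_tol * max(f_scale, _rn0):
                u = u_new
            else:
                return u, kicks
    return u, kicks


def assemble_residual_and_tangent(mesh, u, Fg_field, material, bcs=None):
    """Residual and tangent for a StripMesh (thin wrapper over FemModel).

    ``u`` is flattened nodal displacements over the mesh's displacement
    nodes; ``Fg_field`` is None (identity) or an (ne, nq, 3, 3) array.
    ``bcs`` maps boundary-tag names to "fixed"; those rows/columns are
    eliminated symmetrically (unit diagonal).
    """
    from .engine import grid_from_strip_mesh, dirichlet_dofs_from_tags

    grid = grid_from_strip_mesh(mesh)
    model = FemModel(grid)
    r, K = model.residual_and_tangent(np.asarray(u, dtype=float), Fg_field, material)
    if bcs:
        fixed = dirichlet_dofs_from_tags(mesh, grid, bcs)
        keep = np.ones(model.n_dofs, dtype=bool)
        keep[fixed] = False
        K = K.tolil()
        K[fixed, :] = 0.0
        K[:, fixed] = 0.0
        for d in fixed:
            K[d, d] = 1.0
        K = K.tocsr()
        r = r.copy()
        r[fixed] = 0.0
    return r, K
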