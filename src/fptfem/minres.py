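"""Space-time minimal-residual solver on the unit square.

The residual problem for the smooth difference e = u(v) - u(v0) reads

    de/dt = T (e_xx + vhat e_x) + f,   e(t,0) = e(t,1) = 0,  e(0,x) = 0,

with forcing f = T (vhat - v0) d_x u(v0).  It is discretized with

* trial space X_h: continuous piecewise bilinears on a uniform n x n tensor
  mesh of (0,1)^2, zero at x in {0,1}, free at t in {0,1}; the initial
  condition is imposed weakly through the initial-trace mass matrix C;
* test space Y_h: (piecewise linear, discontinuous in time) x (same P1 space
  in x), so X_h is a subspace of Y_h.

The discrete solution minimizes ||B w - f||_{Y_h'}^2 + ||gamma_0 w||^2 where
the dual norm is realized through the SPD energy matrix A_s on Y_h.  The
minimizer solves the saddle-point system

    [ A_s  B  ] [mu]   [f]
    [ B^T  -C ] [w ] = [0],

equivalently the normal equations (B^T A_s^{-1} B + C) w = B^T A_s^{-1} f.

The forcing uses the integrated-by-parts form

    f(z) = Int Int T u(v0) ( -d_x vhat z - (vhat - v0) d_x z ) dx dt,

which needs only *values* of the constant-drift reference, never its
(singular) derivative, and Gauss points are interior to cells so the
discontinuity corner (0,0) is never evaluated.

Error reporting uses the discrete equivalent of the norm on
L2(H^1_0) \\cap H^1(H^{-1}):  ||w||^2 = (Bw)^T A_gram^{-1} (Bw) + w^T C w
with A_gram the plain d_x Gram matrix on Y_h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constdrift import ConstantDriftSolution
from .transform import UnitSquareProblem

__all__ = [
    "TensorMesh",
    "FemField",
    "AssembledSystem",
    "auto_shift",
    "assemble_system",
    "assemble_forcing",
    "solve",
    "solve_difference",
    "xnorm",
    "prolong",
    "convergence_study",
]


@dataclass(frozen=True)
class TensorMesh:
    """Uniform n x n tensor mesh of the unit square; h = 1/n."""

    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need n >= 2")

    @property
    def h(self) -> float:
        return 1.0 / self.n

    @property
    def n_trial(self) -> int:
        return (self.n + 1) * (self.n - 1)

    @property
    def n_test(self) -> int:
        return 2 * self.n * (self.n - 1)


@dataclass
class FemField:
    """Nodal coefficients of a trial-space function (boundary x-values are 0)."""

    mesh: TensorMesh
    coeffs: np.ndarray          # flat, time-major: (it, ix-1) -> it*(n-1)+ix-1

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float).ravel()
        if self.coeffs.size != self.mesh.n_trial:
            raise ValueError("coefficient vector size does not match mesh")

    def grid(self) -> np.ndarray:
        """Nodal values on the full (n+1) x (n+1) grid, boundary zeros included."""
        n = self.mesh.n
        full = np.zeros((n + 1, n + 1))
        full[:, 1:n] = self.coeffs.reshape(n + 1, n - 1)
        return full

    def __call__(self, t, x):
        """Bilinear interpolation at points of the closed unit square."""
        n = self.mesh.n
        t = np.clip(np.asarray(t, dtype=float), 0.0, 1.0)
        x = np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
        t, x = np.broadcast_arrays(t, x)
        full = self.grid()
        kt = np.minimum((t * n).astype(int), n - 1)
        kx = np.minimum((x * n).astype(int), n - 1)
        lt = t * n - kt
        lx = x * n - kx
        return ((1 - lt) * (1 - lx) * full[kt, kx] + (1 - lt) * lx * full[kt, kx + 1]
                + lt * (1 - lx) * full[kt + 1, kx] + lt * lx * full[kt + 1, kx + 1])


# ----------------------------------------------------------------------------
# 1D building blocks
# ----------------------------------------------------------------------------

def _mass_1d(n: int) -> sp.csr_matrix:
    """P1 mass matrix on interior nodes of (0,1) with n cells."""
    h = 1.0 / n
    main = np.full(n - 1, 2.0 * h / 3.0)
    off = np.full(n - 2, h / 6.0)
    return sp.diags([off, main, off], [-1, 0, 1], format="csr")


def _stiff_1d(n: int) -> sp.csr_matrix:
    h = 1.0 / n
    main = np.full(n - 1, 2.0 / h)
    off = np.full(n - 2, -1.0 / h)
    return sp.diags([off, main, off], [-1, 0, 1], format="csr")


def _time_deriv(n: int) -> sp.csr_matrix:
    """(2n) x (n+1): rows test dofs (cell, side), cols trial time nodes; entries
    Int zeta_{cell,side} chi_j' dt."""
    rows, cols, vals = [], [], []
    for k in range(n):
        for s in (0, 1):
            rows += [2 * k + s, 2 * k + s]
            cols += [k, k + 1]
            vals += [-0.5, 0.5]
    return sp.csr_matrix((vals, (rows, cols)), shape=(2 * n, n + 1))


def _time_mass_ty(n: int) -> sp.csr_matrix:
    """(2n) x (n+1) test-trial time mass: Int zeta_{cell,side} chi_j dt."""
    h = 1.0 / n
    rows, cols, vals = [], [], []
    for k in range(n):
        rows += [2 * k, 2 * k, 2 * k + 1, 2 * k + 1]
        cols += [k, k + 1, k, k + 1]
        vals += [h / 3.0, h / 6.0, h / 6.0, h / 3.0]
    return sp.csr_matrix((vals, (rows, cols)), shape=(2 * n, n + 1))


def _time_mass_yy(n: int) -> sp.csr_matrix:
    """(2n) x (2n) block-diagonal test-test time mass."""
    h = 1.0 / n
    block = h * np.array([[1.0 / 3.0, 1.0 / 6.0], [1.0 / 6.0, 1.0 / 3.0]])
    return sp.block_diag([block] * n, format="csr")


def _trace_select(n: int) -> sp.csr_matrix:
    e = sp.csr_matrix(([1.0], ([0], [0])), shape=(n + 1, n + 1))
    return e


# ----------------------------------------------------------------------------
# quadrature-based cell assembly for drift-dependent terms
# ----------------------------------------------------------------------------

def _gauss(order: int):
    x, w = np.polynomial.legendre.leggauss(order)
    return (x + 1.0) / 2.0, w / 2.0


def _shape_1d(pts: np.ndarray):
    """P1 shape values and derivatives at reference points: rows local node."""
    S = np.vstack([1.0 - pts, pts])           # (2, q)
    dS = np.vstack([-np.ones_like(pts), np.ones_like(pts)])
    return S, dS


class _CellData:
    """Per-mesh quadrature data: points in each direction and index maps."""

    def __init__(self, mesh: TensorMesh, quad_order: int):
        self.mesh = mesh
        n, h = mesh.n, mesh.h
        self.gx, self.gw = _gauss(quad_order)
        self.St, self.dSt = _shape_1d(self.gx)
        # global quadrature coordinates, per cell x per point
        cells = np.arange(n)
        self.t_pts = (cells[:, None] + self.gx[None, :]) * h      # (n, q)
        self.x_pts = self.t_pts                                    # same grid
        self.q = quad_order

    def eval2d(self, func):
        """func(t, x) on the (n*q) x (n*q) tensor of quadrature points ->
        (n, n, q, q) array indexed (cell_t, cell_x, qt, qx)."""
        tq = self.t_pts.ravel()
        xq = self.x_pts.ravel()
        vals = func(tq[:, None], xq[None, :])
        vals = np.broadcast_to(vals, (tq.size, xq.size))
        n, q = self.mesh.n, self.q
        return vals.reshape(n, q, n, q).transpose(0, 2, 1, 3)


def _trial_indices(mesh: TensorMesh):
    """(n, n, 2, 2) global trial index per cell/local node; -1 at x-boundary."""
    n = mesh.n
    K, L = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    idx = np.full((n, n, 2, 2), -1, dtype=np.int64)
    for at in (0, 1):
        for ax in (0, 1):
            ix = L + ax
            ok = (ix >= 1) & (ix <= n - 1)
            g = (K + at) * (n - 1) + (ix - 1)
            idx[:, :, at, ax] = np.where(ok, g, -1)
    return idx


def _test_indices(mesh: TensorMesh):
    n = mesh.n
    K, L = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    idx = np.full((n, n, 2, 2), -1, dtype=np.int64)
    for at in (0, 1):
        for ax in (0, 1):
            ix = L + ax
            ok = (ix >= 1) & (ix <= n - 1)
            g = (2 * K + at) * (n - 1) + (ix - 1)
            idx[:, :, at, ax] = np.where(ok, g, -1)
    return idx


def _scatter(local: np.ndarray, rows_idx: np.ndarray, cols_idx: np.ndarray,
             shape) -> sp.csr_matrix:
    """Assemble (n,n,2,2,2,2) local matrices into a sparse global matrix."""
    r = np.broadcast_to(rows_idx[:, :, :, :, None, None], local.shape).ravel()
    c = np.broadcast_to(cols_idx[:, :, None, None, :, :], local.shape).ravel()
    v = local.ravel()
    ok = (r >= 0) & (c >= 0)
    return sp.csr_matrix((v[ok], (r[ok], c[ok])), shape=shape)


def _convection(cd: _CellData, vhat_vals: np.ndarray, test_idx, trial_idx,
                mesh: TensorMesh) -> sp.csr_matrix:
    """Matrix of Int Int vhat d_x(trial_j) test_i dx dt (cell quadrature)."""
    h = mesh.h
    Sx, dSx = _shape_1d(cd.gx)
    W = np.multiply.outer(cd.gw, cd.gw)                 # (q, q)
    w_v = vhat_vals * W[None, None, :, :]
    # scale: dxdt = h^2, d_x carries 1/h  -> h
    local = h * np.einsum("KLqr,aq,cr,bq,dr->KLacbd", w_v, cd.St, Sx, cd.St, dSx)
    return _scatter(local, test_idx, trial_idx,
                    (mesh.n_test, mesh.n_trial))


def _convection_sym(cd: _CellData, vhat_vals: np.ndarray, test_idx,
                    mesh: TensorMesh) -> sp.csr_matrix:
    """Matrix of Int Int vhat (d_x z_j z_i + z_j d_x z_i) dx dt on Y_h."""
    h = mesh.h
    Sx, dSx = _shape_1d(cd.gx)
    W = np.multiply.outer(cd.gw, cd.gw)
    w_v = vhat_vals * W[None, None, :, :]
    l1 = h * np.einsum("KLqr,aq,cr,bq,dr->KLacbd", w_v, cd.St, Sx, cd.St, dSx)
    local = l1 + l1.transpose(0, 1, 4, 5, 2, 3)
    return _scatter(local, test_idx, test_idx, (mesh.n_test, mesh.n_test))


# ----------------------------------------------------------------------------
# assembled system
# ----------------------------------------------------------------------------

@dataclass
class AssembledSystem:
    mesh: TensorMesh
    T: float
    v0: float
    lam: float
    As: sp.csr_matrix           # SPD energy matrix on Y_h (with lam mass shift)
    B: sp.csr_matrix            # test x trial form matrix
    C: sp.csr_matrix            # initial-trace mass on X_h
    Agram: sp.csr_matrix        # pure d_x Gram on Y_h (norm evaluation)
    problem: Optional[UnitSquareProblem] = None
    quad_order: int = 4
    _agram_solve: object = field(default=None, repr=False)
    _saddle_solve: object = field(default=None, repr=False)

    def agram_solve(self, r: np.ndarray) -> np.ndarray:
        if self._agram_solve is None:
            self._agram_solve = spla.factorized(self.Agram.tocsc())
        return self._agram_solve(r)


def auto_shift(problem: UnitSquareProblem, ngrid: int = 65) -> float:
    """Mass shift making the Y_h energy matrix positive definite.

    The symmetric part of the spatial operator satisfies
    A_s(z, z) = T ||z_x||^2 + (T/2) Int (d_x vhat) z^2, so it is already SPD
    when d_x vhat >= 0 everywhere, or when sup|vhat| < pi (Poincare).
    Otherwise lam = (T/2) sup (d_x vhat)_- restores definiteness without
    touching B or the forcing (a spectrally equivalent energy is permitted).
    """
    g = np.linspace(0.0, 1.0, ngrid)
    tt, xx = np.meshgrid(g, g, indexing="ij")
    dv = np.broadcast_to(problem.dvhat_dx(tt, xx), tt.shape)
    if np.min(dv) >= 0.0:
        return 0.0
    vv = np.broadcast_to(problem.vhat(tt, xx), tt.shape)
    if np.max(np.abs(vv)) < np.pi:
        return 0.0
    return 0.5 * problem.T * float(np.max(-dv))


def assemble_system(problem: UnitSquareProblem, n: int,
                    lam: Optional[float] = None,
                    quad_order: int = 4) -> AssembledSystem:
    """Assemble all matrices of the minimal-residual system at mesh size 1/n.

    Constant-coefficient blocks are exact Kronecker products of 1D element
    matrices; drift-dependent blocks use per-cell tensor Gauss quadrature of
    order ``quad_order`` (Gauss nodes are interior, so the data corner (0,0)
    is never evaluated).
    """
    mesh = TensorMesh(n)
    T = problem.T
    if lam is None:
        lam = auto_shift(problem)
    if lam < 0:
        raise ValueError("lam must be nonnegative")

    Mx, Ax = _mass_1d(n), _stiff_1d(n)
    Dt, Mt_ty, Mt_yy = _time_deriv(n), _time_mass_ty(n), _time_mass_yy(n)

    cd = _CellData(mesh, quad_order)
    vvals = cd.eval2d(problem.vhat)
    test_idx = _test_indices(mesh)
    trial_idx = _trial_indices(mesh)

    conv = _convection(cd, vvals, test_idx, trial_idx, mesh)
    B = (sp.kron(Dt, Mx) + T * sp.kron(Mt_ty, Ax) - T * conv).tocsr()

    conv_sym = _convection_sym(cd, vvals, test_idx, mesh)
    As = (T * sp.kron(Mt_yy, Ax) - 0.5 * T * conv_sym
          + lam * sp.kron(Mt_yy, Mx)).tocsr()

    C = sp.kron(_trace_select(n), Mx).tocsr()
    Agram = sp.kron(Mt_yy, Ax).tocsr()

    return AssembledSystem(mesh=mesh, T=T, v0=problem.v0, lam=float(lam),
                           As=As, B=B, C=C, Agram=Agram, problem=problem,
                           quad_order=quad_order)


def assemble_forcing(system: AssembledSystem,
                     u0: Optional[ConstantDriftSolution] = None,
                     tol: float = 1e-12) -> np.ndarray:
    """Forcing vector of the residual problem in integrated-by-parts form.

    f(z) = Int Int T u(v0) ( -d_x vhat z - (vhat - v0) d_x z ) dx dt.
    """
    problem = system.problem
    if problem is None:
        raise ValueError("system was assembled without a problem reference")
    mesh = system.mesh
    n, h = mesh.n, mesh.h
    if u0 is None:
        u0 = ConstantDriftSolution(problem.v0, problem.T, tol=tol)

    cd = _CellData(mesh, system.quad_order)
    u0v = cd.eval2d(lambda t, x: u0(t, x))
    vv = cd.eval2d(problem.vhat)
    dvv = cd.eval2d(problem.dvhat_dx)

    Sx, dSx = _shape_1d(cd.gx)
    W = np.multiply.outer(cd.gw, cd.gw)
    T = problem.T
    g1 = -T * u0v * dvv * W[None, None]                  # coefficient of z
    g2 = -T * u0v * (vv - problem.v0) * W[None, None]    # coefficient of d_x z
    local = (h * h * np.einsum("KLqr,aq,cr->KLac", g1, cd.St, Sx)
             + h * np.einsum("KLqr,aq,cr->KLac", g2, cd.St, dSx))

    f = np.zeros(mesh.n_test)
    idx = _test_indices(mesh)
    ok = idx >= 0
    np.add.at(f, idx[ok], local[ok])
    return f


def solve(system: AssembledSystem, f: np.ndarray,
          check_residual: bool = True) -> FemField:
    """Solve the saddle-point system; returns the trial-space minimizer.

    The sparse block system [[A_s, B], [B^T, -C]] is factorized directly;
    the solution's block residual is verified below 1e-10 relative.
    """
    m, k = system.mesh.n_test, system.mesh.n_trial
    f = np.asarray(f, dtype=float)
    if f.size != m:
        raise ValueError("forcing vector has wrong size")
    if system._saddle_solve is None:
        K = sp.bmat([[system.As, system.B], [system.B.T, -system.C]],
                    format="csc")
        try:
            system._saddle_solve = spla.splu(K)
        except RuntimeError as exc:     # pragma: no cover - defensive
            raise RuntimeError(
                "saddle-point factorization failed (singular Schur complement: "
                "discrete inf-sup violated)") from exc
    rhs = np.concatenate([f, np.zeros(k)])
    sol = system._saddle_solve.solve(rhs)
    mu, w = sol[:m], sol[m:]

    if check_residual:
        r1 = system.As @ mu + system.B @ w - f
        r2 = system.B.T @ mu - system.C @ w
        scale = max(1.0, float(np.linalg.norm(f)))
        res = np.sqrt(np.linalg.norm(r1) ** 2 + np.linalg.norm(r2) ** 2) / scale
        if res > 1e-10:
            raise RuntimeError(f"block residual {res:.3e} exceeds 1e-10")
    return FemField(system.mesh, w)


def solve_difference(problem: UnitSquareProblem, n: int,
                     lam: Optional[float] = None, quad_order: int = 4,
                     series_tol: float = 1e-12):
    """Full pipeline at one mesh: assemble, force, solve; returns (field, system)."""
    system = assemble_system(problem, n, lam=lam, quad_order=quad_order)
    f = assemble_forcing(system, tol=series_tol)
    return solve(system, f), system


def xnorm(coeffs, system: AssembledSystem) -> float:
    """Discrete norm equivalent to L2(H^1_0) \\cap H^1(H^{-1}) on the trial space."""
    w = coeffs.coeffs if isinstance(coeffs, FemField) else np.asarray(coeffs, float)
    r = system.B @ w
    z = system.agram_solve(r)
    val = float(r @ z + w @ (system.C @ w))
    return float(np.sqrt(max(val, 0.0)))


def prolong(fld: FemField, n2: Optional[int] = None) -> FemField:
    """Exact nodal interpolation onto a refined mesh (bilinears are preserved)."""
    n = fld.mesh.n
    if n2 is None:
        n2 = 2 * n
    if n2 % n != 0:
        raise ValueError(f"target mesh n={n2} is not a multiple of n={n}")
    r = n2 // n
    full = fld.grid()
    # refine in time then space by linear interpolation of nodal values
    tfine = np.linspace(0.0, 1.0, n2 + 1)
    idx = np.minimum((tfine * n).astype(int), n - 1)
    lam_t = tfine * n - idx
    ft = (1 - lam_t)[:, None] * full[idx] + lam_t[:, None] * full[idx + 1]
    fx = (1 - lam_t)[None, :] * ft[:, idx] + lam_t[None, :] * ft[:, idx + 1]
    return FemField(TensorMesh(n2), fx[:, 1:n2])


def convergence_study(problem: UnitSquareProblem, n_list: Sequence[int],
                      lam: Optional[float] = None, quad_order: int = 4,
                      series_tol: float = 1e-12):
    """Consecutive-mesh error table  (h, ||e_{h/2} - e_h||)  and fitted order.

    For each n the residual solution is computed at n and 2n; the coarse
    field is prolonged and the difference measured in the discrete X-norm of
    the finer system.  Returns (table, slope) where table is a pandas
    DataFrame with columns h, err, rate.
    """
    import pandas as pd

    errs = []
    cache: dict[int, tuple] = {}

    def get(n):
        if n not in cache:
            cache[n] = solve_difference(problem, n, lam=lam,
                                        quad_order=quad_order,
                                        series_tol=series_tol)
        return cache[n]

    for n in n_list:
        fld_c, _ = get(n)
        fld_f, sys_f = get(2 * n)
        diff = fld_f.coeffs - prolong(fld_c).coeffs
        errs.append((1.0 / n, xnorm(diff, sys_f)))

    tab = pd.DataFrame(errs, columns=["h", "err"])
    tab["rate"] = np.nan
    if len(tab) > 1:
        e0, e1 = tab["err"].values[:-1], tab["err"].values[1:]
        with np.errstate(divide="ignore", invalid="ignore"):
            tab.loc[1:, "rate"] = (np.log(e0 / e1)
                                   / np.log(tab["h"].values[:-1] / tab["h"].values[1:]))
    positive = tab["err"].values > 0
    if positive.sum() >= 2:
        slope = float(np.polyfit(np.log(tab["h"].values[positive]),
                                 np.log(tab["err"].values[positive]), 1)[0])
    else:
        slope = np.nan
    return tab, slope
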