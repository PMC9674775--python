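"""Minimal-residual solver: assembly identities, exactness, norms, order."""

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from fptfem.minres import (FemField, TensorMesh, assemble_forcing,
                           assemble_system, auto_shift, convergence_study,
                           prolong, solve, solve_difference, xnorm)
from fptfem.minres import (_mass_1d, _stiff_1d, _time_deriv, _time_mass_ty,
                           _time_mass_yy)
from fptfem.models import linear_space_drift_family
from fptfem.pipeline import build_unit_problem
from fptfem.transform import UnitSquareProblem


def _const_problem(v0, T=1.0):
    return UnitSquareProblem(
        T=T,
        vhat=lambda t, x: np.full(np.broadcast(np.asarray(t), np.asarray(x)).shape, v0),
        dvhat_dx=lambda t, x: np.zeros(np.broadcast(np.asarray(t), np.asarray(x)).shape),
        v0=v0)


class TestAssembly:
    def test_one_dimensional_blocks(self):
        n = 4
        h = 1.0 / n
        Ax = _stiff_1d(n).toarray()
        assert Ax[1, 1] == pytest.approx(2.0 / h)
        assert Ax[1, 2] == pytest.approx(-1.0 / h)
        Mx = _mass_1d(n).toarray()
        assert Mx[0, 0] == pytest.approx(2 * h / 3)
        assert Mx[0, 1] == pytest.approx(h / 6)
        # time derivative couples each test cell to its two trial nodes
        Dt = _time_deriv(n).toarray()
        assert np.allclose(Dt.sum(axis=1), 0.0)
        assert Dt[0, 0] == -0.5 and Dt[0, 1] == 0.5

    def test_constant_drift_quadrature_matches_closed_form(self):
        """Cell quadrature reproduces exact Kronecker assembly for constant v."""
        n, c, T = 6, -1.7, 0.8
        sys_q = assemble_system(_const_problem(c, T), n, lam=0.0)
        h = 1.0 / n
        # exact convection: time test-trial mass (x) 1D first-derivative form
        rows, cols, vals = [], [], []
        for i in range(n - 1):
            for j in range(n - 1):
                if j == i + 1:
                    vals.append(0.5)
                elif j == i - 1:
                    vals.append(-0.5)
                else:
                    continue
                rows.append(i)
                cols.append(j)
        Cx = sp.csr_matrix((vals, (rows, cols)), shape=(n - 1, n - 1))
        B_exact = (sp.kron(_time_deriv(n), _mass_1d(n))
                   + T * sp.kron(_time_mass_ty(n), _stiff_1d(n))
                   - T * c * sp.kron(_time_mass_ty(n), Cx))
        assert np.max(np.abs((sys_q.B - B_exact).toarray())) < 1e-13
        # constant drift: symmetrized convection vanishes on H^1_0 in x
        As_exact = T * sp.kron(_time_mass_yy(n), _stiff_1d(n))
        assert np.max(np.abs((sys_q.As - As_exact).toarray())) < 1e-13

    def test_initial_trace_matrix_support(self):
        n = 5
        sys_ = assemble_system(_const_problem(0.0), n, lam=0.0)
        w = np.arange(sys_.mesh.n_trial, dtype=float)
        w[: n - 1] = 0.0          # zero initial trace
        assert np.allclose(sys_.C @ w, 0.0)
        w2 = np.zeros(sys_.mesh.n_trial)
        w2[: n - 1] = 1.0
        assert (sys_.C @ w2) @ w2 > 0

    def test_forcing_vanishes_for_reference_drift(self, constant_drift_problem):
        sys_ = assemble_system(constant_drift_problem, 8)
        f = assemble_forcing(sys_)
        assert np.linalg.norm(f) == 0.0
        fld = solve(sys_, f)
        assert np.linalg.norm(fld.coeffs) == 0.0


class TestSolve:
    def test_manufactured_solution_recovered_exactly(self, variable_drift_problem):
        """If f := B w* with zero initial trace, the minimizer is w* itself."""
        rng = np.random.default_rng(3)
        for n in (8, 16):
            sys_ = assemble_system(variable_drift_problem, n)
            w = rng.standard_normal(sys_.mesh.n_trial)
            w[: n - 1] = 0.0
            got = solve(sys_, sys_.B @ w)
            assert np.max(np.abs(got.coeffs - w)) < 1e-10

    def test_linearity_and_zero(self, variable_drift_problem):
        sys_ = assemble_system(variable_drift_problem, 8)
        f = assemble_forcing(sys_)
        w1 = solve(sys_, f).coeffs
        w2 = solve(sys_, 2.0 * f).coeffs
        assert np.allclose(w2, 2.0 * w1, atol=1e-12)
        assert np.allclose(solve(sys_, 0.0 * f).coeffs, 0.0)

    def test_reflection_symmetry_driftless(self):
        """v=0 and x-symmetric forcing give an x-symmetric solution."""
        n = 8
        sys_ = assemble_system(_const_problem(0.0), n, lam=0.0)
        rng = np.random.default_rng(5)
        f = rng.standard_normal(sys_.mesh.n_test)
        # symmetrize the test-space functional under x -> 1-x
        fr = f.reshape(2 * n, n - 1)[:, ::-1].ravel()
        fs = f + fr
        w = solve(sys_, fs).coeffs.reshape(n + 1, n - 1)
        assert np.max(np.abs(w - w[:, ::-1])) < 1e-12

    def test_quasi_optimality_vs_nodal_interpolation(self):
        """Smooth field outside X_h: solver error <= 5x interpolation error."""
        wstar = lambda t, x: np.sin(np.pi * x) * (1.0 - np.cos(np.pi * t)) / 2.0
        problem = _const_problem(0.0)
        gq, gw = np.polynomial.legendre.leggauss(6)
        gq, gw = (gq + 1) / 2, gw / 2
        for n in (8, 16, 32):
            sys_ = assemble_system(problem, n, lam=0.0)
            h = 1.0 / n
            # forcing f(z) = Int dt(w*) z + T dx(w*) dx(z), cellwise Gauss
            f = np.zeros(sys_.mesh.n_test)
            for kt in range(n):
                tq = (kt + gq) * h
                for kx in range(n):
                    xq = (kx + gq) * h
                    tt, xx = np.meshgrid(tq, xq, indexing="ij")
                    wt = np.pi / 2 * np.sin(np.pi * xx) * np.sin(np.pi * tt)
                    wx = np.pi * np.cos(np.pi * xx) * (1 - np.cos(np.pi * tt)) / 2
                    for at in (0, 1):
                        zt = (1 - gq) if at == 0 else gq
                        for ax in (0, 1):
                            ix = kx + ax
                            if ix < 1 or ix > n - 1:
                                continue
                            zx = (1 - gq) if ax == 0 else gq
                            dzx = (-np.ones(6) if ax == 0 else np.ones(6)) / h
                            integrand = (wt * np.outer(zt, zx)
                                         + wx * np.outer(zt, dzx))
                            val = h * h * gw @ integrand @ gw
                            f[(2 * kt + at) * (n - 1) + ix - 1] += val
            wh = solve(sys_, f)
            # reference: represent both errors on the doubled mesh
            fine = assemble_system(problem, 2 * n, lam=0.0)
            g2 = np.linspace(0, 1, 2 * n + 1)
            interp_fine = FemField(fine.mesh,
                                   wstar(g2[:, None], g2[None, 1:2 * n]))
            g1 = np.linspace(0, 1, n + 1)
            interp_coarse = FemField(TensorMesh(n),
                                     wstar(g1[:, None], g1[None, 1:n]))
            err_solver = xnorm(interp_fine.coeffs - prolong(wh).coeffs, fine)
            err_interp = xnorm(interp_fine.coeffs - prolong(interp_coarse).coeffs, fine)
            assert err_solver <= 5.0 * err_interp


class TestNormAndProlong:
    def test_xnorm_zero_and_homogeneity(self, variable_drift_problem):
        sys_ = assemble_system(variable_drift_problem, 8)
        assert xnorm(np.zeros(sys_.mesh.n_trial), sys_) == 0.0
        v = np.random.default_rng(0).standard_normal(sys_.mesh.n_trial)
        assert xnorm(3.0 * v, sys_) == pytest.approx(3.0 * xnorm(v, sys_), rel=1e-12)

    def test_xnorm_matches_dense_linear_algebra(self, variable_drift_problem):
        sys_ = assemble_system(variable_drift_problem, 8)
        g = np.linspace(0, 1, 9)
        fld = FemField(sys_.mesh, np.outer(np.sin(g), g[1:8] * (1 - g[1:8])))
        w = fld.coeffs
        r = (sys_.B @ w)
        dense = float(np.sqrt(r @ np.linalg.solve(sys_.Agram.toarray(), r)
                              + w @ (sys_.C @ w)))
        assert xnorm(w, sys_) == pytest.approx(dense, rel=1e-10)

    def test_prolong_preserves_bilinear_fields(self):
        rng = np.random.default_rng(2)
        fld = FemField(TensorMesh(6), rng.standard_normal(7 * 5))
        fine = prolong(fld)
        pts = rng.uniform(0, 1, (2, 50))
        assert np.max(np.abs(fine(pts[0], pts[1]) - fld(pts[0], pts[1]))) < 1e-13
        a = FemField(TensorMesh(6), rng.standard_normal(35))
        b = FemField(TensorMesh(6), rng.standard_normal(35))
        lin = prolong(FemField(TensorMesh(6), a.coeffs + 2 * b.coeffs))
        assert np.allclose(lin.coeffs, prolong(a).coeffs + 2 * prolong(b).coeffs)

    def test_prolong_rejects_incompatible_mesh(self):
        fld = FemField(TensorMesh(6), np.zeros(35))
        with pytest.raises(ValueError):
            prolong(fld, 9)


class TestShiftAndOrder:
    def test_no_shift_for_benign_drifts(self):
        # constant drift: d_x vhat = 0
        assert auto_shift(_const_problem(-2.0)) == 0.0
        # increasing drift strengthens definiteness
        p_inc = UnitSquareProblem(T=1.0, vhat=lambda t, x: 8.0 * np.asarray(x),
                                  dvhat_dx=lambda t, x: np.full(np.asarray(x).shape, 8.0),
                                  v0=0.0)
        assert auto_shift(p_inc) == 0.0
        # small drift: Poincare criterion applies regardless of slope sign
        p_small = UnitSquareProblem(T=1.0, vhat=lambda t, x: -3.0 * np.asarray(x),
                                    dvhat_dx=lambda t, x: np.full(np.asarray(x).shape, -3.0),
                                    v0=0.0)
        assert auto_shift(p_small) == 0.0

    def test_shift_restores_definiteness_for_steep_decreasing_drift(self):
        T = 0.4
        p = UnitSquareProblem(T=T, vhat=lambda t, x: -30.0 * np.asarray(x),
                              dvhat_dx=lambda t, x: np.full(np.asarray(x).shape, -30.0),
                              v0=0.0)
        lam = auto_shift(p)
        assert lam == pytest.approx(T * 15.0)
        sys_ = assemble_system(p, 8, lam=lam)
        low = spla.eigsh(sys_.As, k=1, which="SA", return_eigenvectors=False)
        assert low[0] > 0

    def test_convergence_order_linear_space_family(self):
        problem, _ = build_unit_problem(linear_space_drift_family([-1, -1, -1]))
        tab, slope = convergence_study(problem, [4, 8, 16])
        assert 0.8 <= slope <= 1.3
        assert np.all(np.diff(tab["err"].values) < 0)

    def test_zero_residual_for_constant_drift_family(self):
        problem, _ = build_unit_problem(linear_space_drift_family([0.3, 0.0, -0.2]))
        # mu1 = 0: drift constant in space and time -> e identically zero
        fld, _ = solve_difference(problem, 8)
        assert np.max(np.abs(fld.coeffs)) < 1e-12
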