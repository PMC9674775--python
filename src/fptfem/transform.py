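"""Change of variables from a moving-boundary strip to the unit square.

Starting from the rescaled problem on { (ttilde, xtilde) : a(ttilde) < xtilde
< b(ttilde) }, the spatial strip is flattened by the affine map
xi(ttilde, x) = (1-x) a + x b, and time is reparametrized by the warp theta
with theta'(t) = (b - a)^2 evaluated along the warp, so that the transformed
equation has unit diffusion on (0,1).  The warped drift is

    v(t, x) = (b - a) * [ vtilde + (1-x) a' + x b' ]   at ttilde = theta(t),

and the horizon becomes T = theta^{-1}(Ttilde) = Int_0^Ttilde (b-a)^{-2}.
A final linear rescaling t -> t/T puts the problem on the unit square, where
the PDE reads  du/dt = T (d2u/dx2 + vhat du/dx).

theta^{-1} is computed by adaptive Gauss-Legendre quadrature of (b-a)^{-2}
and represented as a cubic Hermite spline with exact nodal slopes; theta is
the spline inverse polished by Newton steps with the exact derivative from
the warp ODE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.interpolate import CubicHermiteSpline

from .models import DecisionModel, RescaledProblem

__all__ = [
    "TimeWarp",
    "compute_time_warp",
    "closed_form_collapsing_warp",
    "TransformedProblem",
    "transform_drift",
    "UnitSquareProblem",
    "to_unit_time",
    "pullback_first_passage",
    "reflect_problem",
]

# 15-point Gauss-Legendre on [0,1]
_GL_X, _GL_W = np.polynomial.legendre.leggauss(15)
_GL_X = (_GL_X + 1.0) / 2.0
_GL_W = _GL_W / 2.0


@dataclass
class TimeWarp:
    """The time reparametrization theta and its inverse.

    theta maps warped time in [0, T] to strip time in [0, Ttilde];
    theta_inv is the cumulative integral of (b-a)^{-2}.
    """

    T: float
    Ttilde: float
    theta: Callable[[np.ndarray], np.ndarray]
    theta_inv: Callable[[np.ndarray], np.ndarray]
    dtheta: Callable[[np.ndarray], np.ndarray]   # theta'(t) = (b-a)^2 at theta(t)


def _panel_integrals(f, lo, hi):
    """Vectorized 15-point GL integral of f over each [lo_i, hi_i]."""
    lo = np.asarray(lo)[:, None]
    hi = np.asarray(hi)[:, None]
    pts = lo + (hi - lo) * _GL_X[None, :]
    vals = f(pts)
    return ((hi - lo)[:, 0]) * (vals @ _GL_W)


def compute_time_warp(problem: RescaledProblem, tol: float = 1e-12,
                      max_level: int = 30) -> TimeWarp:
    """Build the warp for a rescaled problem by adaptive quadrature.

    The grid of theta^{-1} samples is refined until each panel integral of
    (b-a)^{-2} is resolved to ``tol`` (absolute, via two-half comparison).
    Raises if the integral fails to converge, which signals boundaries that
    touch before Ttilde.
    """
    Tt = problem.Ttilde
    gap2inv = lambda s: 1.0 / (problem.b(s) - problem.a(s)) ** 2

    gmin = np.min(problem.b(np.linspace(0, Tt, 257)) - problem.a(np.linspace(0, Tt, 257)))
    if not gmin > 0:
        raise ValueError("boundaries meet before Ttilde: time warp integral diverges")

    # Adaptive panel refinement of [0, Ttilde].  Each panel must satisfy two
    # tests: the GL quadrature is converged (two-half comparison) and the
    # cubic Hermite interpolant reproduces the midpoint value of theta^{-1}
    # to tol, so the spline representation is as accurate as the integrals.
    edges = np.linspace(0.0, Tt, 65)
    for level in range(max_level):
        lo, hi = edges[:-1], edges[1:]
        mid = (lo + hi) / 2.0
        left = _panel_integrals(gap2inv, lo, mid)
        right = _panel_integrals(gap2inv, mid, hi)
        whole = _panel_integrals(gap2inv, lo, hi)
        quad_err = np.abs(whole - (left + right))
        # Hermite midpoint prediction vs integrated midpoint value
        h = hi - lo
        s_lo, s_hi = gap2inv(lo), gap2inv(hi)
        vals = np.concatenate([[0.0], np.cumsum(left + right)])
        y_lo, y_hi = vals[:-1], vals[1:]
        herm_mid = 0.5 * (y_lo + y_hi) + 0.125 * h * (s_lo - s_hi)
        interp_err = np.abs(herm_mid - (y_lo + left))
        scale = tol * np.maximum(1.0, vals[-1])
        bad = (quad_err > scale) | (interp_err > scale)
        if not np.any(bad):
            break
        edges = np.sort(np.concatenate([edges, mid[bad]]))
    else:
        raise ValueError("time warp quadrature did not converge; boundaries nearly touch")

    tinv_vals = vals
    slopes = gap2inv(edges)

    T = float(tinv_vals[-1])
    inv_spline = CubicHermiteSpline(edges, tinv_vals, slopes)
    # inverse-function Hermite interpolant as the initial guess for theta
    fwd_spline = CubicHermiteSpline(tinv_vals, edges, 1.0 / slopes)

    def theta_inv(tt):
        tt = np.asarray(tt, dtype=float)
        return inv_spline(np.clip(tt, 0.0, Tt))

    def theta(t):
        t = np.asarray(t, dtype=float)
        tc = np.clip(t, 0.0, T)
        r = np.clip(fwd_spline(tc), 0.0, Tt)
        # Newton on inv_spline(r) = t with the exact ODE derivative
        for _ in range(3):
            g = inv_spline(r) - tc
            r = np.clip(r - g * (problem.b(r) - problem.a(r)) ** 2, 0.0, Tt)
        return r

    def dtheta(t):
        r = theta(t)
        return (problem.b(r) - problem.a(r)) ** 2

    return TimeWarp(T=T, Ttilde=Tt, theta=theta, theta_inv=theta_inv, dtheta=dtheta)


def closed_form_collapsing_warp(beta0: float, T0: float, sigma: float,
                                Ttilde: float) -> TimeWarp:
    """Closed-form warp for linearly collapsing boundaries.

    For a(ttilde) = beta0 (Ttilde - ttilde) / (sigma^2 T0) and
    b(ttilde) = beta0 (1 - (Ttilde - ttilde)/(sigma^2 T0)) the warp integral
    is rational:

        theta_inv(tt) = sigma^4 T0^2 tt /
                        (beta0^2 (sigma^2 T0 - 2 Ttilde)(sigma^2 T0 - 2 Ttilde + 2 tt)),
        T = sigma^2 T0 Ttilde / (beta0^2 (sigma^2 T0 - 2 Ttilde)),
        theta(t) = beta0^2 (sigma^2 T0 - 2 Ttilde)^2 t /
                   (sigma^4 T0^2 - 2 beta0^2 (sigma^2 T0 - 2 Ttilde) t).
    """
    s2T0 = sigma**2 * T0
    if not Ttilde < s2T0 / 2.0:
        raise ValueError(
            f"Ttilde={Ttilde:.4g} >= sigma^2 T0/2={s2T0 / 2:.4g}: horizon too large, boundaries meet"
        )
    d = s2T0 - 2.0 * Ttilde
    T = s2T0 * Ttilde / (beta0**2 * d)

    def theta_inv(tt):
        tt = np.asarray(tt, dtype=float)
        return sigma**4 * T0**2 * tt / (beta0**2 * d * (d + 2.0 * tt))

    def theta(t):
        t = np.asarray(t, dtype=float)
        return beta0**2 * d**2 * t / (sigma**4 * T0**2 - 2.0 * beta0**2 * d * t)

    def dtheta(t):
        r = theta(t)
        gap = beta0 * (1.0 - 2.0 * (Ttilde - r) / s2T0)
        return gap**2

    return TimeWarp(T=float(T), Ttilde=float(Ttilde), theta=theta,
                    theta_inv=theta_inv, dtheta=dtheta)


@dataclass
class TransformedProblem:
    """Problem on (0, T) x (0, 1) with warped drift v and corner value v0."""

    T: float
    v: Callable[[np.ndarray, np.ndarray], np.ndarray]
    dv_dx: Callable[[np.ndarray, np.ndarray], np.ndarray]
    v0: float
    warp: TimeWarp
    rescaled: RescaledProblem

    def xi(self, ttilde, x):
        """Affine strip coordinate (1-x) a + x b."""
        a = self.rescaled.a(ttilde)
        b = self.rescaled.b(ttilde)
        return (1.0 - x) * a + x * b


def transform_drift(problem: RescaledProblem, warp: TimeWarp) -> TransformedProblem:
    """Combine the strip drift and the moving-boundary advection into v(t, x)."""
    a, b, da, db = problem.a, problem.b, problem.da, problem.db

    def v(t, x):
        t = np.asarray(t, dtype=float)
        x = np.asarray(x, dtype=float)
        r = warp.theta(t)
        av, bv = a(r), b(r)
        xi = (1.0 - x) * av + x * bv
        return (bv - av) * (problem.vtilde(r, xi) + (1.0 - x) * da(r) + x * db(r))

    def dv_dx(t, x):
        t = np.asarray(t, dtype=float)
        x = np.asarray(x, dtype=float)
        r = warp.theta(t)
        av, bv = a(r), b(r)
        xi = (1.0 - x) * av + x * bv
        gap = bv - av
        return gap * (problem.dvtilde_dx(r, xi) * gap + db(r) - da(r))

    v0 = float(v(np.array(0.0), np.array(0.0)))
    return TransformedProblem(T=warp.T, v=v, dv_dx=dv_dx, v0=v0, warp=warp,
                              rescaled=problem)


@dataclass
class UnitSquareProblem:
    """Problem on (0,1)^2: du/dt = T (u_xx + vhat u_x), with vhat(t,x) = v(tT,x)."""

    T: float
    vhat: Callable[[np.ndarray, np.ndarray], np.ndarray]
    dvhat_dx: Callable[[np.ndarray, np.ndarray], np.ndarray]
    v0: float


def to_unit_time(problem: TransformedProblem) -> UnitSquareProblem:
    T = problem.T
    return UnitSquareProblem(
        T=T,
        vhat=lambda t, x: problem.v(np.asarray(t, float) * T, x),
        dvhat_dx=lambda t, x: problem.dv_dx(np.asarray(t, float) * T, x),
        v0=problem.v0,
    )


def reflect_problem(problem: UnitSquareProblem) -> UnitSquareProblem:
    """Reflection x -> 1-x, v -> -v: swaps the roles of the two boundaries.

    The reflected solution gives upper-boundary absorption probabilities.
    """
    return UnitSquareProblem(
        T=problem.T,
        vhat=lambda t, x: -problem.vhat(t, 1.0 - np.asarray(x, float)),
        dvhat_dx=lambda t, x: problem.dvhat_dx(t, 1.0 - np.asarray(x, float)),
        v0=float(-problem.vhat(np.array(0.0), np.array(1.0))),
    )


def pullback_first_passage(uhat_eval, model: DecisionModel, warp: TimeWarp):
    """Turn a unit-square evaluator into F(tau, y), and interior strip queries.

    F(tau, y) = uhat(1, (y - alpha(0)) / (beta(0) - alpha(0))) is the
    probability of hitting the lower boundary first, no later than tau,
    starting from y.  The returned object is also callable at interior strip
    points via ``.strip(ttilde, xtilde)``.
    """
    a0 = float(model.alpha(np.array(0.0)))
    b0 = float(model.beta(np.array(0.0)))
    resc_a = lambda tt: model.alpha((2.0 / model.sigma**2) * (warp.Ttilde - np.asarray(tt)))
    resc_b = lambda tt: model.beta((2.0 / model.sigma**2) * (warp.Ttilde - np.asarray(tt)))

    class _F:
        def __call__(self, y):
            y = np.asarray(y, dtype=float)
            if np.any(y < a0 - 1e-12) or np.any(y > b0 + 1e-12):
                raise ValueError(f"y outside [alpha(0), beta(0)] = [{a0}, {b0}]")
            x = np.clip((y - a0) / (b0 - a0), 0.0, 1.0)
            return uhat_eval(np.ones_like(x), x)

        def strip(self, ttilde, xtilde):
            ttilde = np.asarray(ttilde, dtype=float)
            xtilde = np.asarray(xtilde, dtype=float)
            av, bv = resc_a(ttilde), resc_b(ttilde)
            x = (xtilde - av) / (bv - av)
            t = warp.theta_inv(ttilde) / warp.T
            return uhat_eval(t, x)

    return _F()
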