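"""Series solution of the constant-drift absorption problem on the unit strip.

``ConstantDriftSolution`` evaluates u = u(v0, T), the solution of

    du/dt = T * (d2u/dx2 + v0 * du/dx)   on (0,1) x (0,1),
    u(t,0) = 1,  u(t,1) = 0,  u(0,x) = 0,

i.e. the probability that a Brownian motion with constant drift, started at
relative position x, is absorbed at the lower of two constant boundaries
within a fraction t of the horizon.  The solution is discontinuous at the
corner (0,0) where boundary and initial data clash; it is subtracted from
the variable-drift solution so that the numerically computed difference is
smooth.

Two independent, rapidly converging representations are used and serve as
mutual oracles:

* long-time (spectral): writing s = T*t for the physical time,

      u(s,x) = u_inf(x) - sum_n b_n e^{-v0 x/2} sin(n pi x) e^{-(n^2 pi^2 + v0^2/4) s},

  where u_inf is the steady profile and the sine coefficients of
  u_inf(x) e^{v0 x/2} come out in closed form, b_n = 2 n pi / (v0^2/4 + n^2 pi^2);

* short-time (image/Girsanov): by the Markov property,

      u(s,x) = u_inf(x) - Int_0^1 p(s,x,y) u_inf(y) dy,

  where p is the transition density of the drifted diffusion killed at 0 and 1,
  expanded as a Girsanov-tilted method-of-images sum of heat kernels; each term
  reduces to erf differences in closed form.

The two series converge fastest on complementary sides of a switchover time
``switch_s`` (in physical time s = T*t).  The truncation level is chosen from
the exponential tail bounds at tolerance ``tol``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf, erfc

__all__ = ["heat_layer", "steady_profile", "ConstantDriftSolution", "residual_check"]

_MAX_TERMS = 4000


def heat_layer(t, x):
    """Half-space heat layer Erfc(x / (2 sqrt(t))).

    This carries the corner singularity between initial data 0 and boundary
    data 1.  For t <= 0 the pointwise limit is returned: 0 for x > 0, and a
    domain error for x <= 0 (the corner itself has no limit value).
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    t, x = np.broadcast_arrays(t, x)
    if np.any((t <= 0) & (x <= 0)):
        raise ValueError("heat layer undefined at t<=0, x<=0 (corner has no limit)")
    out = np.zeros(t.shape)
    pos = t > 0
    out[pos] = erfc(x[pos] / (2.0 * np.sqrt(t[pos])))
    return out if out.ndim else float(out)


def steady_profile(v0: float, x):
    """Stationary absorption probability (e^{-v0 x} - e^{-v0}) / (1 - e^{-v0}).

    The exit-at-lower-boundary probability of the drifted diffusion without a
    time limit; equals 1 - x in the driftless limit.  Evaluated through expm1
    so the v0 -> 0 limit is seamless.
    """
    x = np.asarray(x, dtype=float)
    if v0 == 0.0:
        return 1.0 - x
    # (expm1(-v0 x) - expm1(-v0)) / (-expm1(-v0)), stable for all v0 sizes
    den = -np.expm1(-v0)
    return (np.expm1(-v0 * x) - np.expm1(-v0)) / den


def _erf_diff(lo, hi):
    """erf(hi) - erf(lo) without tail cancellation (erfc in one-sided tails)."""
    both_pos = lo >= 0.0
    both_neg = hi <= 0.0
    safe_lo = np.where(both_pos, lo, 0.0)
    safe_hi = np.where(both_pos, hi, 0.0)
    d = erfc(safe_lo) - erfc(safe_hi)
    safe_lo = np.where(both_neg, lo, 0.0)
    safe_hi = np.where(both_neg, hi, 0.0)
    d = np.where(both_neg, erfc(-safe_hi) - erfc(-safe_lo), d)
    mixed = ~(both_pos | both_neg)
    d = np.where(mixed, erf(hi) - erf(lo), d)
    return d


def _gauss_cdf_block(c, a, s):
    """Int_0^1 e^{a y} N(y; c, 2s) dy  in closed form (vectorized in c)."""
    rs = 2.0 * np.sqrt(s)
    shift = c + 2.0 * a * s
    return np.exp(a * c + a * a * s) * 0.5 * _erf_diff((0.0 - shift) / rs, (1.0 - shift) / rs)


def _phi(z, s):
    """Heat kernel with diffusion coefficient 1: e^{-z^2/(4s)} / sqrt(4 pi s)."""
    return np.exp(-z * z / (4.0 * s)) / np.sqrt(4.0 * np.pi * s)


class ConstantDriftSolution:
    """Evaluator of the constant-drift solution u(v0, T) on [0,1]^2."""

    def __init__(self, v0: float, T: float, tol: float = 1e-12, switch_s: float = 0.05):
        if T <= 0:
            raise ValueError("T must be positive")
        self.v0 = float(v0)
        self.T = float(T)
        self.tol = float(tol)
        self.switch_s = float(switch_s)

    # -- truncation levels -------------------------------------------------
    def _n_spectral(self, s_min: float) -> int:
        """Terms so that the spectral tail is below tol at physical time >= s_min."""
        v0 = self.v0
        budget = np.log(1.0 / self.tol) + abs(v0) / 2.0 - (v0 * v0 / 4.0) * s_min + np.log(4.0)
        if budget <= 0:
            return 1
        n = int(np.ceil(np.sqrt(budget / (np.pi**2 * s_min)))) + 2
        if n > _MAX_TERMS:
            raise RuntimeError(
                f"spectral series needs {n} > {_MAX_TERMS} terms at s={s_min:.3g}; "
                "tolerance not reachable, use the short-time branch"
            )
        return n

    def _n_images(self, s_max: float) -> int:
        """Image pairs so that the Gaussian tail is below tol for s <= s_max."""
        # images at distance >= 2n-1 from [0,1]; drift tilt adds |v0| s to the shift
        budget = np.log(1.0 / self.tol) + abs(self.v0) / 2.0
        n = int(np.ceil((1.0 + abs(self.v0) * s_max + 2.0 * np.sqrt(s_max * max(budget, 1.0))) / 2.0)) + 1
        if n > _MAX_TERMS:
            raise RuntimeError(f"image series needs {n} > {_MAX_TERMS} pairs at s={s_max:.3g}")
        return n

    # -- the two series ----------------------------------------------------
    def _long_time(self, s, x):
        """Spectral series; accurate (and cheap) for s not too small."""
        v0 = self.v0
        M = self._n_spectral(float(np.min(s)))
        n = np.arange(1, M + 1, dtype=float)
        lam = n * n * np.pi**2 + v0 * v0 / 4.0            # eigenvalues
        bn = 2.0 * n * np.pi / lam                        # closed-form sine coefficients
        # sum_n bn sin(n pi x) e^{-lam s}; tilt and steady profile outside the sum
        sines = np.sin(np.pi * np.multiply.outer(x, n))
        decays = np.exp(-np.multiply.outer(s, lam))
        series = np.einsum("...n,...n->...", sines * decays, np.broadcast_to(bn, sines.shape))
        return steady_profile(v0, x) - np.exp(-v0 * x / 2.0) * series

    def _short_time_pos(self, s, x):
        """Image series for s > 0 (vectorized over broadcast s, x arrays)."""
        v0 = self.v0
        a = v0 / 2.0
        N = self._n_images(float(np.max(s)))
        ns = np.arange(-N, N + 1, dtype=float)
        # image centers: direct y - (x + 2n), reflected y - (2n - x)
        c1 = np.multiply.outer(np.ones_like(x), 2.0 * ns) + x[..., None]
        c2 = np.multiply.outer(np.ones_like(x), 2.0 * ns) - x[..., None]
        ss = s[..., None]
        if abs(v0) >= 1e-8:
            # Int_0^1 sinh(a(1-y))/sinh(a) * phi_s(y - c) dy, via exponential blocks
            def block(c):
                return (np.exp(a) * _gauss_cdf_block(c, -a, ss)
                        - np.exp(-a) * _gauss_cdf_block(c, a, ss)) / (2.0 * np.sinh(a))
        else:
            # driftless limit: Int_0^1 (1 - y) phi_s(y - c) dy
            def block(c):
                P = 0.5 * (erf((1.0 - c) / (2.0 * np.sqrt(ss))) - erf((0.0 - c) / (2.0 * np.sqrt(ss))))
                return (1.0 - c) * P - 2.0 * ss * (_phi(-c, ss) - _phi(1.0 - c, ss))

        integral = np.sum(block(c1) - block(c2), axis=-1)
        tilt = np.exp(-v0 * x / 2.0 - v0 * v0 * ss[..., 0] / 4.0)
        return steady_profile(v0, x) - tilt * integral

    # -- public evaluation -------------------------------------------------
    def __call__(self, t, x):
        """Evaluate u(v0, T) at unit-square coordinates (t, x), vectorized."""
        t = np.asarray(t, dtype=float)
        x = np.asarray(x, dtype=float)
        t, x = np.broadcast_arrays(t, x)
        t = t.copy()
        x = x.copy()
        out = np.empty(t.shape)
        s = self.T * t                                    # physical time

        zero_t = s <= 1e-300
        if np.any(zero_t):
            # initial data, except the boundary limit u(t,0)=1 along x=0
            out[zero_t] = np.where(x[zero_t] <= 1e-14, 1.0, 0.0)

        small = (~zero_t) & (s < self.switch_s)
        if np.any(small):
            out[small] = self._short_time_pos(s[small], x[small])
        large = (~zero_t) & ~small
        if np.any(large):
            out[large] = self._long_time(s[large], x[large])
        return out if out.ndim else float(out)

    def long_time(self, t, x):
        """Spectral branch regardless of t (testing hook)."""
        t, x = np.broadcast_arrays(np.asarray(t, float), np.asarray(x, float))
        return self._long_time(self.T * t, x)

    def short_time(self, t, x):
        """Image branch regardless of t (testing hook)."""
        t, x = np.broadcast_arrays(np.asarray(t, float), np.asarray(x, float))
        return self._short_time_pos(self.T * t, x)


def residual_check(sol: ConstantDriftSolution, tgrid, xgrid, step: float = 1e-4) -> float:
    """Max PDE residual |u_t - T (u_xx + v0 u_x)| on an interior grid.

    Derivatives by central finite differences of the series evaluation; a
    verification device for tests, not part of the solver path.
    """
    tt, xx = np.meshgrid(np.asarray(tgrid, float), np.asarray(xgrid, float), indexing="ij")
    if np.any(tt - step <= 0) or np.any(xx - step <= 0) or np.any(xx + step >= 1):
        raise ValueError("grid must be interior with margin >= step")
    ut = (sol(tt + step, xx) - sol(tt - step, xx)) / (2 * step)
    ux = (sol(tt, xx + step) - sol(tt, xx - step)) / (2 * step)
    uxx = (sol(tt, xx + step) - 2 * sol(tt, xx) + sol(tt, xx - step)) / step**2
    res = ut - sol.T * (uxx + sol.v0 * ux)
    return float(np.max(np.abs(res)))
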