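"""Decision models in original coordinates and their unit-diffusion rescaling.

A decision model is the 1D SDE  dX_t = mu(t, X_t) dt + sigma dW_t  started at
y in [alpha(0), beta(0)], together with two absorbing boundaries alpha(t) <
beta(t) and a horizon tau.  The quantity of interest is the probability that
the lower boundary is hit first, no later than tau.

The backward Kolmogorov equation for that probability has diffusion
coefficient sigma^2/2 and runs in reversed time.  ``rescale_to_unit_diffusion``
absorbs both into the problem data: with ttilde = sigma^2/2 * (tau - t) the
rescaled problem has unit diffusion, horizon Ttilde = sigma^2 tau / 2,
boundaries a(ttilde) = alpha((2/sigma^2)(Ttilde - ttilde)) (same for b), and
drift vtilde = (2/sigma^2) mu evaluated at the reversed time.  All time
reversal bookkeeping lives here; downstream modules never see original time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "DecisionModel",
    "RescaledProblem",
    "ParameterBox",
    "rescale_to_unit_diffusion",
    "hyperbolic_drift_family",
    "linear_space_drift_family",
    "collapsing_bounds_family",
    "HYPERBOLIC_BOX",
    "LINEAR_SPACE_BOX",
    "COLLAPSING_BOX",
    "FAMILIES",
]

Scalar2D = Callable[[np.ndarray, np.ndarray], np.ndarray]
Scalar1D = Callable[[np.ndarray], np.ndarray]


@dataclass
class DecisionModel:
    """A two-boundary diffusion decision model in original coordinates.

    Functions must accept and return numpy arrays (vectorized evaluation);
    derivatives are analytic closures, never numerical differences.
    """

    sigma: float
    mu: Scalar2D                      # drift mu(t, x)
    dmu_dx: Scalar2D                  # spatial derivative of the drift
    alpha: Scalar1D                   # lower boundary
    beta: Scalar1D                    # upper boundary
    dalpha: Scalar1D                  # alpha'
    dbeta: Scalar1D                   # beta'
    tau: float                        # horizon
    y0: Optional[float] = None        # optional start point
    name: str = "custom"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.y0 is not None:
            lo, hi = float(self.alpha(np.array(0.0))), float(self.beta(np.array(0.0)))
            if not (lo <= self.y0 <= hi):
                raise ValueError(f"y0={self.y0} outside [alpha(0), beta(0)]=[{lo}, {hi}]")


@dataclass
class RescaledProblem:
    """Unit-diffusion, time-reversed form of a :class:`DecisionModel`."""

    Ttilde: float
    a: Scalar1D
    b: Scalar1D
    da: Scalar1D
    db: Scalar1D
    vtilde: Scalar2D
    dvtilde_dx: Scalar2D
    model: DecisionModel


def rescale_to_unit_diffusion(model: DecisionModel, check_points: int = 200) -> RescaledProblem:
    """Rescale a decision model to unit diffusion and reversed time.

    Raises ``ValueError`` if alpha >= beta anywhere on a dense check grid of
    [0, tau] (invalid boundaries, e.g. collapsing bounds past their meeting
    point).
    """
    tgrid = np.linspace(0.0, model.tau, check_points)
    gap = model.beta(tgrid) - model.alpha(tgrid)
    if not np.all(gap > 0):
        tbad = tgrid[np.argmin(gap)]
        raise ValueError(
            f"boundaries cross: alpha(t) >= beta(t) at t={tbad:.6g} (gap {gap.min():.3g})"
        )

    sig2 = model.sigma**2
    Ttilde = sig2 * model.tau / 2.0
    # original time as a function of rescaled (reversed) time
    back = lambda tt: (2.0 / sig2) * (Ttilde - np.asarray(tt))

    a = lambda tt: model.alpha(back(tt))
    b = lambda tt: model.beta(back(tt))
    # chain rule: d/d ttilde = -2/sigma^2 * d/dt
    da = lambda tt: (-2.0 / sig2) * model.dalpha(back(tt))
    db = lambda tt: (-2.0 / sig2) * model.dbeta(back(tt))
    vtilde = lambda tt, xx: (2.0 / sig2) * model.mu(back(tt), xx)
    dvtilde_dx = lambda tt, xx: (2.0 / sig2) * model.dmu_dx(back(tt), xx)

    return RescaledProblem(
        Ttilde=Ttilde, a=a, b=b, da=da, db=db,
        vtilde=vtilde, dvtilde_dx=dvtilde_dx, model=model,
    )


@dataclass(frozen=True)
class ParameterBox:
    """An axis-aligned parameter box with the affine chart from [-1,1]^N."""

    names: tuple
    lo: tuple
    hi: tuple

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.lo) == len(self.hi)):
            raise ValueError("names, lo, hi must have equal length")
        if not all(l < h for l, h in zip(self.lo, self.hi)):
            raise ValueError("require lo < hi componentwise")

    @property
    def N(self) -> int:
        return len(self.names)

    def map(self, rho: Sequence[float]) -> np.ndarray:
        """Affine map [-1,1]^N -> box."""
        rho = np.asarray(rho, dtype=float)
        if rho.shape != (self.N,):
            raise ValueError(f"expected rho of shape ({self.N},), got {rho.shape}")
        if np.any(np.abs(rho) > 1.0 + 1e-12):
            raise ValueError(f"rho outside [-1,1]^{self.N}: {rho}")
        lo, hi = np.asarray(self.lo), np.asarray(self.hi)
        return lo + (rho + 1.0) * (hi - lo) / 2.0

    def unmap(self, theta: Sequence[float]) -> np.ndarray:
        """Inverse affine chart box -> [-1,1]^N."""
        theta = np.asarray(theta, dtype=float)
        lo, hi = np.asarray(self.lo), np.asarray(self.hi)
        return 2.0 * (theta - lo) / (hi - lo) - 1.0


# Published practical parameter ranges for the three model families.
HYPERBOLIC_BOX = ParameterBox(
    names=("mu0", "mu1", "t0", "beta0", "tau"),
    lo=(-1.97, -2.31, 0.13, 1.38, 0.1),
    hi=(-1.64, -0.99, 0.40, 2.26, 2.5),
)

LINEAR_SPACE_BOX = ParameterBox(
    names=("mu0", "mu1", "beta0"),
    lo=(-2.0, -4.0, 0.5),
    hi=(2.0, 4.0, 2.0),
)

COLLAPSING_BOX = ParameterBox(
    names=("mu0", "beta0", "T0", "tau"),
    lo=(-5.86, 0.56, 3.0, 0.1),
    hi=(0.0, 3.93, 20.0, 2.5),
)


def hyperbolic_drift_family(rho: Sequence[float]) -> DecisionModel:
    """Constant boundaries with hyperbolically saturating time-dependent drift.

    mu(t, x) = mu0 + mu1 * t / (t + t0), alpha = 0, beta = beta0, sigma = 1.
    Parameters (mu0, mu1, t0, beta0, tau) are mapped affinely from rho in
    [-1,1]^5 onto the published practical ranges.
    """
    mu0, mu1, t0, beta0, tau = HYPERBOLIC_BOX.map(rho)
    zero = lambda t: np.zeros_like(np.asarray(t, dtype=float))
    return DecisionModel(
        sigma=1.0,
        mu=lambda t, x: mu0 + mu1 * t / (t + t0) + 0.0 * np.asarray(x),
        dmu_dx=lambda t, x: np.zeros(np.broadcast(np.asarray(t), np.asarray(x)).shape),
        alpha=zero,
        beta=lambda t: np.full_like(np.asarray(t, dtype=float), beta0),
        dalpha=zero,
        dbeta=zero,
        tau=float(tau),
        name="hyperbolic",
        params=dict(zip(HYPERBOLIC_BOX.names, (mu0, mu1, t0, beta0, tau))),
    )


def linear_space_drift_family(rho: Sequence[float]) -> DecisionModel:
    """Constant boundaries with drift linear in space.

    mu(t, x) = mu0 + mu1 * (beta0 - x), alpha = 0, beta = beta0, sigma = 1,
    tau = 2.5 fixed.  rho in [-1,1]^3 maps onto (mu0, mu1, beta0).
    """
    mu0, mu1, beta0 = LINEAR_SPACE_BOX.map(rho)
    zero = lambda t: np.zeros_like(np.asarray(t, dtype=float))
    return DecisionModel(
        sigma=1.0,
        mu=lambda t, x: mu0 + mu1 * (beta0 - np.asarray(x)) + 0.0 * np.asarray(t),
        dmu_dx=lambda t, x: np.full(np.broadcast(np.asarray(t), np.asarray(x)).shape, -mu1),
        alpha=zero,
        beta=lambda t: np.full_like(np.asarray(t, dtype=float), beta0),
        dalpha=zero,
        dbeta=zero,
        tau=2.5,
        name="linear_space",
        params=dict(zip(LINEAR_SPACE_BOX.names, (mu0, mu1, beta0)), tau=2.5),
    )


def collapsing_bounds_family(rho: Sequence[float]) -> DecisionModel:
    """Constant drift with linearly collapsing boundaries.

    mu = mu0, alpha(t) = beta0 t/(2 T0), beta(t) = beta0 (1 - t/(2 T0)),
    sigma = 1.  The boundaries meet at t = T0; the rescaled horizon must stay
    below the collapse, which for sigma = 1 requires tau < T0 (rejected
    otherwise — equivalently Ttilde < sigma^2 T0 / 2).
    """
    mu0, beta0, T0, tau = COLLAPSING_BOX.map(rho)
    sigma = 1.0
    if sigma**2 * tau / 2.0 >= sigma**2 * T0 / 2.0:
        raise ValueError(
            f"tau={tau:.4g} >= sigma^2*T0={sigma ** 2 * T0:.4g}: boundaries meet before the horizon"
        )
    return DecisionModel(
        sigma=sigma,
        mu=lambda t, x: np.full(np.broadcast(np.asarray(t), np.asarray(x)).shape, mu0),
        dmu_dx=lambda t, x: np.zeros(np.broadcast(np.asarray(t), np.asarray(x)).shape),
        alpha=lambda t: beta0 * np.asarray(t, dtype=float) / (2.0 * T0),
        beta=lambda t: beta0 * (1.0 - np.asarray(t, dtype=float) / (2.0 * T0)),
        dalpha=lambda t: np.full_like(np.asarray(t, dtype=float), beta0 / (2.0 * T0)),
        dbeta=lambda t: np.full_like(np.asarray(t, dtype=float), -beta0 / (2.0 * T0)),
        tau=float(tau),
        name="collapsing",
        params=dict(zip(COLLAPSING_BOX.names, (mu0, beta0, T0, tau))),
    )


FAMILIES = {
    "hyperbolic": (hyperbolic_drift_family, HYPERBOLIC_BOX),
    "linear_space": (linear_space_drift_family, LINEAR_SPACE_BOX),
    "collapsing": (collapsing_bounds_family, COLLAPSING_BOX),
}
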