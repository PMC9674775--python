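"""End-to-end composition: decision model -> first-passage probabilities.

Chains the rescaling, time warp, drift transform, unit-time rescaling,
constant-drift reference and the minimal-residual solve, and exposes the
hitting probability F(tau, y) in original coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .constdrift import ConstantDriftSolution
from .minres import FemField, AssembledSystem, solve_difference, xnorm
from .models import DecisionModel, rescale_to_unit_diffusion
from .transform import (TimeWarp, UnitSquareProblem, compute_time_warp,
                        pullback_first_passage, to_unit_time, transform_drift)

__all__ = ["build_unit_problem", "SolveResult", "solve_model"]


def build_unit_problem(model: DecisionModel, warp_tol: float = 1e-12):
    """Transform a decision model to its unit-square residual problem.

    Returns (unit_problem, warp).
    """
    rescaled = rescale_to_unit_diffusion(model)
    warp = compute_time_warp(rescaled, tol=warp_tol)
    transformed = transform_drift(rescaled, warp)
    return to_unit_time(transformed), warp


@dataclass
class SolveResult:
    """Solution bundle for one decision model at one mesh."""

    model: DecisionModel
    problem: UnitSquareProblem
    warp: TimeWarp
    field: FemField                  # residual part e_h on the unit square
    system: AssembledSystem
    u0: ConstantDriftSolution
    err_norm: float                  # discrete X-norm of e_h (size indicator)

    def uhat(self, t, x):
        """Full solution on the unit square: e_h + constant-drift reference."""
        return self.field(t, x) + self.u0(t, x)

    @property
    def F(self):
        """First-passage evaluator F(tau, y) in original coordinates."""
        return pullback_first_passage(self.uhat, self.model, self.warp)


def solve_model(model: DecisionModel, n: int = 64,
                lam: Optional[float] = None, quad_order: int = 4,
                series_tol: float = 1e-12, warp_tol: float = 1e-12) -> SolveResult:
    """Run the full pipeline for one model at mesh size 1/n."""
    problem, warp = build_unit_problem(model, warp_tol=warp_tol)
    field, system = solve_difference(problem, n, lam=lam, quad_order=quad_order,
                                     series_tol=series_tol)
    u0 = ConstantDriftSolution(problem.v0, problem.T, tol=series_tol)
    return SolveResult(model=model, problem=problem, warp=warp, field=field,
                       system=system, u0=u0, err_norm=xnorm(field, system))
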