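"""Shared fixtures: small models and problems used across the suite."""

import numpy as np
import pytest

from fptfem.models import DecisionModel
from fptfem.transform import UnitSquareProblem


def _zeros(t):
    return np.zeros_like(np.asarray(t, dtype=float))


@pytest.fixture
def unit_strip_model():
    """Driftless model on the fixed strip [0,1], tau=2."""
    return DecisionModel(
        sigma=1.0,
        mu=lambda t, x: np.zeros(np.broadcast(np.asarray(t), np.asarray(x)).shape),
        dmu_dx=lambda t, x: np.zeros(np.broadcast(np.asarray(t), np.asarray(x)).shape),
        alpha=_zeros,
        beta=lambda t: np.ones_like(np.asarray(t, dtype=float)),
        dalpha=_zeros,
        dbeta=_zeros,
        tau=2.0,
    )


@pytest.fixture
def constant_drift_problem():
    """Unit-square problem with constant drift -2 (zero residual downstream)."""
    return UnitSquareProblem(
        T=1.0,
        vhat=lambda t, x: np.full(np.broadcast(np.asarray(t), np.asarray(x)).shape, -2.0),
        dvhat_dx=lambda t, x: np.zeros(np.broadcast(np.asarray(t), np.asarray(x)).shape),
        v0=-2.0,
    )


@pytest.fixture
def variable_drift_problem():
    """Smooth genuinely space-time-dependent drift on the unit square."""
    return UnitSquareProblem(
        T=0.5,
        vhat=lambda t, x: -2.0 + np.sin(3.0 * np.asarray(t)) * np.asarray(x),
        dvhat_dx=lambda t, x: np.sin(3.0 * np.asarray(t)) + 0.0 * np.asarray(x),
        v0=-2.0,
    )
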