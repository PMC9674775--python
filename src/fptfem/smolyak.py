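"""Smolyak sparse tensor-product interpolation on [-1,1]^N.

The univariate family is nested Clenshaw-Curtis: level 1 is the single
abscissa {0}; level i+1 uses the 2^i + 1 cosine points cos(j pi / 2^i),
j = 0..2^i; level 0 is the zero operator.  The sparse interpolator of level
parameter q >= N is

    I_q = sum_{i in N^N, |i|_1 <= q}  (x) (I_{i_n} - I_{i_n - 1}),

realized through the combination technique: each difference product is
expanded into signed full tensor interpolants, whose coefficients are
accumulated per tensor index.  Payloads are arbitrary vectors (here: FEM
coefficient vectors on a shared mesh), combined linearly; by nestedness the
operator is interpolatory, i.e. exact at every sparse-grid node.

The operator norm on continuous functions (Lebesgue constant) is bounded by
the squared cardinality of the index set, which ``lebesgue_upper_bound``
returns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Dict, Sequence, Tuple

import numpy as np

__all__ = [
    "cc_nodes",
    "SparseGrid",
    "SparseInterpolant",
    "build",
    "lebesgue_upper_bound",
    "interp_error_study",
]


def cc_nodes(level: int) -> np.ndarray:
    """Clenshaw-Curtis abscissae of the given level, sorted ascending.

    Level 0 has no nodes (zero operator), level 1 is {0}, level i+1 has the
    2^i + 1 extrema points.  Nodes are symmetrized so that plus/minus pairs
    are exact negatives and nesting is bitwise exact.
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    if level == 0:
        return np.array([])
    if level == 1:
        return np.array([0.0])
    m = 2 ** (level - 1)
    j = np.arange(m + 1)
    raw = np.cos(j * np.pi / m)
    sym = 0.5 * (raw - raw[::-1])      # exact +/- pairing, exact 0 midpoint
    return np.sort(sym)


def _lagrange_basis(nodes: np.ndarray, x: float) -> np.ndarray:
    """Values of all Lagrange basis polynomials at x (barycentric form)."""
    if nodes.size == 1:
        return np.array([1.0])
    # barycentric weights for Chebyshev-extrema nodes are known up to scale,
    # but compute generically for robustness at these small sizes
    diff = nodes[:, None] - nodes[None, :]
    np.fill_diagonal(diff, 1.0)
    w = 1.0 / np.prod(diff, axis=1)
    d = x - nodes
    onnode = np.abs(d) < 1e-15
    if np.any(onnode):
        out = np.zeros(nodes.size)
        out[np.argmax(onnode)] = 1.0
        return out
    terms = w / d
    return terms / np.sum(terms)


@dataclass(frozen=True)
class SparseGrid:
    """Index data of the Smolyak construction for given (N, q)."""

    N: int
    q: int
    tensor_coeffs: Tuple[Tuple[Tuple[int, ...], float], ...]   # (levels, coeff)
    nodes: Tuple[Tuple[float, ...], ...]                       # distinct nodes

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def _make_grid(q: int, N: int) -> SparseGrid:
    if q < N:
        raise ValueError(f"require q >= N (got q={q}, N={N})")
    coeffs: Dict[Tuple[int, ...], float] = {}
    for levels in itertools.product(range(1, q + 1), repeat=N):
        if sum(levels) > q:
            continue
        # expand prod_n (I_{i_n} - I_{i_n-1}); terms hitting level 0 vanish
        for signs in itertools.product((0, 1), repeat=N):
            tl = tuple(l - s for l, s in zip(levels, signs))
            if any(t == 0 for t in tl):
                continue
            coeffs[tl] = coeffs.get(tl, 0.0) + (-1.0) ** sum(signs)
    coeffs = {k: v for k, v in coeffs.items() if v != 0.0}
    node_set = set()
    for tl in coeffs:
        for pt in itertools.product(*(cc_nodes(l) for l in tl)):
            node_set.add(pt)
    return SparseGrid(N=N, q=q, tensor_coeffs=tuple(sorted(coeffs.items())),
                      nodes=tuple(sorted(node_set)))


@dataclass
class SparseInterpolant:
    """Smolyak interpolant of a payload-valued map on [-1,1]^N."""

    grid: SparseGrid
    payloads: Dict[Tuple[float, ...], np.ndarray]
    meta: dict = field(default_factory=dict)

    def __call__(self, rho: Sequence[float]) -> np.ndarray:
        rho = np.asarray(rho, dtype=float)
        if rho.shape != (self.grid.N,):
            raise ValueError(f"expected rho of shape ({self.grid.N},)")
        if np.any(np.abs(rho) > 1.0 + 1e-12):
            raise ValueError("rho outside [-1,1]^N: no extrapolation")
        out = None
        for levels, coeff in self.grid.tensor_coeffs:
            basis = [_lagrange_basis(cc_nodes(l), r) for l, r in zip(levels, rho)]
            term = None
            for pt_idx in itertools.product(*(range(b.size) for b in basis)):
                wgt = 1.0
                for n, j in enumerate(pt_idx):
                    wgt *= basis[n][j]
                if wgt == 0.0:
                    continue
                pt = tuple(cc_nodes(levels[n])[j] for n, j in enumerate(pt_idx))
                contrib = wgt * self.payloads[pt]
                term = contrib if term is None else term + contrib
            if term is not None:
                out = coeff * term if out is None else out + coeff * term
        return out


def build(q: int, N: int, evaluator: Callable[[np.ndarray], np.ndarray],
          meta: dict | None = None) -> SparseInterpolant:
    """Build the level-q sparse interpolant of a deterministic payload map.

    The evaluator is called once per distinct sparse-grid node (nested
    caching across tensor grids is automatic because nodes coincide
    bitwise).
    """
    grid = _make_grid(q, N)
    payloads = {pt: np.asarray(evaluator(np.asarray(pt)), dtype=float)
                for pt in grid.nodes}
    return SparseInterpolant(grid=grid, payloads=payloads, meta=meta or {})


def lebesgue_upper_bound(q: int, N: int) -> int:
    """Published bound on the Lebesgue constant: (#{i in N_0^N : |i| <= q})^2.

    The cardinality is binom(q+N, N).
    """
    if q < N:
        raise ValueError("require q >= N")
    from math import comb
    return comb(q + N, N) ** 2


def interp_error_study(solve_at, q_list: Sequence[int], N: int,
                       test_set: Sequence[Sequence[float]],
                       norm: Callable[[np.ndarray], float]):
    """Max interpolation error over a parameter test set for each level q.

    ``solve_at(rho) -> payload`` is the expensive map being emulated (cached
    here across q); ``norm`` measures payload differences.  Returns a pandas
    DataFrame with columns q, n_nodes, max_err.
    """
    import pandas as pd

    cache: Dict[Tuple[float, ...], np.ndarray] = {}

    def ev(rho):
        key = tuple(np.asarray(rho, float))
        if key not in cache:
            cache[key] = np.asarray(solve_at(np.asarray(rho)), dtype=float)
        return cache[key]

    rows = []
    for q in q_list:
        interp = build(q, N, ev)
        err = 0.0
        for rho in test_set:
            rho = np.asarray(rho, dtype=float)
            err = max(err, norm(ev(rho) - interp(rho)))
        rows.append((q, interp.grid.n_nodes, err))
    return pd.DataFrame(rows, columns=["q", "n_nodes", "max_err"])


def default_test_set(N: int, include_zero: bool = False) -> list:
    """The published parameter test set {-1,-0.5,0.5,1}^N (optionally with 0)."""
    vals = (-1.0, -0.5, 0.0, 0.5, 1.0) if include_zero else (-1.0, -0.5, 0.5, 1.0)
    return [np.array(p) for p in itertools.product(vals, repeat=N)]
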