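"""Jacobian, vertex eigenvalues, ESS classification and feasibility search.

Because each player's payoff difference is independent of its own frequency,
the Jacobian of the replicator system is diagonal at every cube vertex, and
the vertex eigenvalues are simply ``(1 - 2 v_i) * (active - passive payoff)``
evaluated at the opponents' corner.  A vertex is an evolutionarily stable
strategy (ESS, Lyapunov's first method) when all four eigenvalues are
negative.

Canonical eigenvalue expressions are generated from the payoff tensor, never
transcribed from the published stability tables: those tables carry a few
sign/subscript typos, which :func:`condition_table` surfaces explicitly
instead of silently fixing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import sympy as sp

from .errors import ConfigurationError
from .params import PARAM_NAMES, GameParameters
from .payoffs import PROFILES, PayoffTensor, payoff_entries
from .replicator import _difference_blocks, _reduce, validate_state

__all__ = [
    "jacobian",
    "vertex_eigenvalues",
    "EquilibriumReport",
    "classify_equilibria",
    "report_frame",
    "condition_table",
    "FeasibilityResult",
    "ess_feasibility",
    "feasible_strict_profiles",
    "symbolic_vertex_eigenvalues",
]

#: Default sign tolerance for eigenvalue classification.
EIG_TOL = 1e-9

#: Default sampler settings for the feasibility search.
FEASIBILITY_DRAWS = 100_000
FEASIBILITY_SEED = 20250909
FEASIBILITY_BOUNDS = (0.0, 10.0)


# ---------------------------------------------------------------------------
# Jacobian
# ---------------------------------------------------------------------------

def jacobian(tensor: PayoffTensor, state: Sequence[float]) -> np.ndarray:
    """Exact 4x4 Jacobian of the canonical replicator right-hand side.

    Rates have the form ``p_i (1 - p_i) B_i(p_-i)`` with ``B_i`` multilinear
    in the opponents, so all partial derivatives are available in closed
    form: the diagonal is ``(1 - 2 p_i) B_i`` and the off-diagonal entries
    carry ``p_i (1 - p_i) dB_i/dp_j`` where the affine slope ``dB_i/dp_j``
    equals ``B_i`` at ``p_j = 1`` minus ``B_i`` at ``p_j = 0``.
    """
    s = validate_state(state)
    blocks = _difference_blocks(tensor)
    J = np.empty((4, 4))
    for i in range(4):
        opp_idx = [j for j in range(4) if j != i]
        probs = [s[j] for j in opp_idx]
        b = _reduce(blocks[i], probs)
        J[i, i] = (1.0 - 2.0 * s[i]) * b
        logistic = s[i] * (1.0 - s[i])
        for k, j in enumerate(opp_idx):
            hi = _reduce(blocks[i], [1.0 if m == k else probs[m] for m in range(3)])
            lo = _reduce(blocks[i], [0.0 if m == k else probs[m] for m in range(3)])
            J[i, j] = logistic * (hi - lo)
    return J


def vertex_eigenvalues(tensor: PayoffTensor, vertex: Sequence[int]) -> np.ndarray:
    """The four (real) eigenvalues at a cube vertex: the Jacobian diagonal."""
    v = [int(b) for b in vertex]
    return np.diag(jacobian(tensor, v)).copy()


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EquilibriumReport:
    vertex: tuple[int, int, int, int]
    eigenvalues: tuple[float, float, float, float]
    label: str  # "ESS" | "unstable" | "critical"


def classify_equilibria(tensor: PayoffTensor, tol: float = EIG_TOL) -> list[EquilibriumReport]:
    """Classify all 16 pure-strategy vertices by their eigenvalue signs."""
    if tol <= 0:
        raise ConfigurationError(f"tol must be positive, got {tol}")
    reports = []
    for vertex in PROFILES:
        eigs = vertex_eigenvalues(tensor, vertex)
        if np.all(eigs < -tol):
            label = "ESS"
        elif np.any(eigs > tol):
            label = "unstable"
        else:
            label = "critical"
        reports.append(EquilibriumReport(vertex=vertex, eigenvalues=tuple(eigs), label=label))
    return reports


def report_frame(reports: list[EquilibriumReport]) -> pd.DataFrame:
    """Tidy CSV-ready view: vertex, eig1..eig4, label."""
    return pd.DataFrame(
        {
            "vertex": ["".join(map(str, r.vertex)) for r in reports],
            **{f"eig{k + 1}": [r.eigenvalues[k] for r in reports] for k in range(4)},
            "label": [r.label for r in reports],
        }
    )


# ---------------------------------------------------------------------------
# Published stability tables (literal transcription, for cross-checking)
# ---------------------------------------------------------------------------

def _printed_tables() -> dict[tuple[int, int, int, int], list[tuple[str, Callable]]]:
    """Eigenvalue expressions exactly as printed in the published stability
    tables (loose- and strict-regulation blocks), including their typos."""
    return {
        # loose regulation (x = 0)
        (0, 0, 0, 0): [
            ("D_c+D_h-C_g", lambda p: p.D_c + p.D_h - p.C_g),
            ("-C_h-S_h", lambda p: -p.C_h - p.S_h),
            ("-C_c-S_c", lambda p: -p.C_c - p.S_c),
            ("-C_p", lambda p: -p.C_p),
        ],
        (0, 0, 0, 1): [
            ("alpha*(D_c+D_h)-C_g+k_g", lambda p: p.alpha * (p.D_c + p.D_h) - p.C_g + p.k_g),
            ("-C_h-S_h+2k_h", lambda p: -p.C_h - p.S_h + 2 * p.k_h),
            ("-C_c-S_c+2k_c", lambda p: -p.C_c - p.S_c + 2 * p.k_c),
            ("C_p", lambda p: p.C_p),
        ],
        (0, 0, 1, 0): [
            ("D_h-C_g", lambda p: p.D_h - p.C_g),
            ("-C_h-S_h", lambda p: -p.C_h - p.S_h),
            ("C_c+S_c", lambda p: p.C_c + p.S_c),
            ("-C_p", lambda p: -p.C_p),
        ],
        (0, 0, 1, 1): [
            ("alpha*D_h-C_g+k_g", lambda p: p.alpha * p.D_h - p.C_g + p.k_g),
            ("-C_h-S_h+2k_h", lambda p: -p.C_h - p.S_h + 2 * p.k_h),
            ("C_c+S_c-2k_c", lambda p: p.C_c + p.S_c - 2 * p.k_c),
            ("C_p", lambda p: p.C_p),
        ],
        (0, 1, 0, 0): [
            ("D_c-C_g", lambda p: p.D_c - p.C_g),
            ("C_h+S_h", lambda p: p.C_h + p.S_h),
            ("-C_c-S_c", lambda p: -p.C_c - p.S_c),
            ("-C_p", lambda p: -p.C_p),
        ],
        (0, 1, 0, 1): [
            ("alpha*D_c-C_g+k_g", lambda p: p.alpha * p.D_c - p.C_g + p.k_g),
            ("C_h+S_h-2k_h", lambda p: p.C_h + p.S_h - 2 * p.k_h),
            ("-C_c-S_c+2k_c", lambda p: -p.C_c - p.S_c + 2 * p.k_c),
            ("C_p", lambda p: p.C_p),
        ],
        (0, 1, 1, 0): [
            ("-C_g-R_c-R_h", lambda p: -p.C_g - p.R_c - p.R_h),
            ("C_h+S_h", lambda p: p.C_h + p.S_h),
            ("C_c+S_c", lambda p: p.C_c + p.S_c),
            ("-C_p", lambda p: -p.C_p),
        ],
        (0, 1, 1, 1): [
            ("2k_g-R_c-R_h-C_g", lambda p: 2 * p.k_g - p.R_c - p.R_h - p.C_g),
            ("C_h+S_h-2k_h", lambda p: p.C_h + p.S_h - 2 * p.k_h),
            ("C_c+S_c-2k_c", lambda p: p.C_c + p.S_c - 2 * p.k_c),
            ("C_p", lambda p: p.C_p),
        ],
        # strict regulation (x = 1)
        (1, 0, 0, 0): [
            ("C_g-D_c-D_h", lambda p: p.C_g - p.D_c - p.D_h),
            ("D_h-C_h-S_h", lambda p: p.D_h - p.C_h - p.S_h),
            ("D_c-C_c-S_c", lambda p: p.D_c - p.C_c - p.S_c),
            ("D_c-C_p+D_h-alpha*(D_c+D_h)", lambda p: p.D_c - p.C_p + p.D_h - p.alpha * (p.D_c + p.D_h)),
        ],
        (1, 0, 0, 1): [
            ("C_g-alpha*(D_c+D_h)-k_g", lambda p: p.C_g - p.alpha * (p.D_c + p.D_h) - p.k_g),
            ("D_h-C_h-S_h+2k_h", lambda p: p.D_h - p.C_h - p.S_h + 2 * p.k_h),
            ("D_c-C_c-S_c+2k_c", lambda p: p.D_c - p.C_c - p.S_c + 2 * p.k_c),
            ("-D_c+C_p-D_h+alpha*(D_h+D_c)", lambda p: -p.D_c + p.C_p - p.D_h + p.alpha * (p.D_h + p.D_c)),
        ],
        (1, 0, 1, 0): [
            ("C_g-D_h", lambda p: p.C_g - p.D_h),
            ("D_h-C_h+R_h-S_h", lambda p: p.D_h - p.C_h + p.R_h - p.S_h),
            ("-D_c+C_c+S_c", lambda p: -p.D_c + p.C_c + p.S_c),
            ("(1-alpha)*D_h-C_p", lambda p: (1 - p.alpha) * p.D_h - p.C_p),
        ],
        (1, 0, 1, 1): [
            ("C_g-alpha*D_h-k_g", lambda p: p.C_g - p.alpha * p.D_h - p.k_g),
            ("D_h-C_h-S_h+R_h+2k_h", lambda p: p.D_h - p.C_h - p.S_h + p.R_h + 2 * p.k_h),
            ("-D_c+C_c+S_c-2k_c", lambda p: -p.D_c + p.C_c + p.S_c - 2 * p.k_c),
            ("(1-alpha)*D_h+C_p", lambda p: (1 - p.alpha) * p.D_h + p.C_p),
        ],
        (1, 1, 0, 0): [
            ("C_g-D_c", lambda p: p.C_g - p.D_c),
            ("-D_h+C_h+S_h", lambda p: -p.D_h + p.C_h + p.S_h),
            ("D_c-C_c-S_c+R_c", lambda p: p.D_c - p.C_c - p.S_c + p.R_c),
            ("(1-alpha)*D_h-C_p", lambda p: (1 - p.alpha) * p.D_h - p.C_p),
        ],
        (1, 1, 0, 1): [
            ("C_g-alpha*D_c-k_g", lambda p: p.C_g - p.alpha * p.D_c - p.k_g),
            ("-D_h+C_h+S_h-2k_h", lambda p: -p.D_h + p.C_h + p.S_h - 2 * p.k_h),
            ("D_c-C_c-S_c+R_c+2k_c", lambda p: p.D_c - p.C_c - p.S_c + p.R_c + 2 * p.k_c),
            ("(alpha-1)*D_h+C_p", lambda p: (p.alpha - 1) * p.D_h + p.C_p),
        ],
        (1, 1, 1, 0): [
            ("C_g+R_c+R_h", lambda p: p.C_g + p.R_c + p.R_h),
            ("-D_h+C_h+S_h-R_h", lambda p: -p.D_h + p.C_h + p.S_h - p.R_h),
            ("-D_c-R_c+C_c+S_c", lambda p: -p.D_c - p.R_c + p.C_c + p.S_c),
            ("-C_p", lambda p: -p.C_p),
        ],
        (1, 1, 1, 1): [
            ("R_c+R_h+C_g-2k_g", lambda p: p.R_c + p.R_h + p.C_g - 2 * p.k_g),
            ("-D_h+C_h+S_h-R_h-2k_c", lambda p: -p.D_h + p.C_h + p.S_h - p.R_h - 2 * p.k_c),
            ("C_c-D_c-R_c+S_c-2k_c", lambda p: p.C_c - p.D_c - p.R_c + p.S_c - 2 * p.k_c),
            ("C_p", lambda p: p.C_p),
        ],
    }


def _consistency_probe_params(n: int = 8, seed: int = 7) -> list[GameParameters]:
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        draws = {name: float(rng.uniform(0.1, 9.9)) for name in PARAM_NAMES if name != "alpha"}
        draws["alpha"] = float(rng.uniform(0.05, 0.95))
        out.append(GameParameters(**draws))
    return out


def condition_table(params: GameParameters) -> pd.DataFrame:
    """Evaluate every printed stability-table eigenvalue/condition at ``params``.

    Each row carries the printed expression, its value and truth of the
    printed "< 0" condition, the canonical eigenvalue derived from the
    tensor, and a ``consistent`` flag.  The flag compares the printed
    expression against the canonical one across several random admissible
    parameter sets, so it documents formula-level typos rather than
    coincidental agreement at a single point.
    """
    from .payoffs import build_payoff_tensor

    probes = _consistency_probe_params()
    probe_tensors = [build_payoff_tensor(q) for q in probes]
    tensor = build_payoff_tensor(params)

    rows = []
    for vertex, entries in _printed_tables().items():
        canon = vertex_eigenvalues(tensor, vertex)
        canon_probe = np.array([vertex_eigenvalues(t, vertex) for t in probe_tensors])
        for k, (expr, fn) in enumerate(entries):
            printed_value = fn(params)
            printed_probe = np.array([fn(q) for q in probes])
            consistent = bool(np.allclose(printed_probe, canon_probe[:, k], atol=1e-9))
            rows.append(
                {
                    "vertex": "".join(map(str, vertex)),
                    "eigenvalue": f"lambda{k + 1}",
                    "printed_expression": expr,
                    "printed_value": float(printed_value),
                    "condition_holds": bool(printed_value < 0),
                    "canonical_value": float(canon[k]),
                    "consistent": consistent,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Feasibility search
# ---------------------------------------------------------------------------

_SYMBOLIC_CACHE: dict[tuple[int, int, int, int], list[sp.Expr]] = {}


def symbolic_vertex_eigenvalues(vertex: Sequence[int]) -> list[sp.Expr]:
    """Canonical vertex eigenvalues as sympy expressions in the 18 parameters."""
    vertex = tuple(int(b) for b in vertex)
    if vertex in _SYMBOLIC_CACHE:
        return _SYMBOLIC_CACHE[vertex]
    syms = {name: sp.Symbol(name, positive=True) for name in PARAM_NAMES}
    entries = payoff_entries(syms)
    eigs = []
    for i in range(4):
        active = list(vertex)
        passive = list(vertex)
        active[i], passive[i] = 1, 0
        diff = entries[(i, *active)] - entries[(i, *passive)]
        eigs.append(sp.expand((1 - 2 * vertex[i]) * diff))
    _SYMBOLIC_CACHE[vertex] = eigs
    return eigs


def _always_positive(expr: sp.Expr) -> bool:
    """Structural check: is the expression positive for every admissible
    parameter set (quantities > 0, alpha in (0,1))?

    Expands the expression in the monetary symbols; each coefficient is a
    polynomial in alpha.  Positive if every coefficient is non-negative on
    (0, 1) and at least one is bounded away from zero there.  Coefficients
    here are affine in alpha, so a dense sample of (0, 1) decides the sign.
    """
    alpha = sp.Symbol("alpha", positive=True)
    monetary = [sp.Symbol(n, positive=True) for n in PARAM_NAMES if n != "alpha"]
    poly = sp.Poly(sp.expand(expr), *monetary)
    if poly.total_degree() == 0:
        return False
    grid = np.linspace(0.01, 0.99, 25)
    has_strict = False
    for coeff in poly.coeffs():
        vals = np.array([float(coeff.subs(alpha, a)) for a in grid])
        if np.any(vals < -1e-12):
            return False
        if np.all(vals > 1e-9):
            has_strict = True
    # constant term (in the monetary symbols) must be zero for a sum form
    const = poly.as_dict().get(tuple([0] * len(monetary)), 0)
    if const != 0:
        return False
    return has_strict


def _sample_parameter_draws(n: int, bounds: tuple[float, float], rng: np.random.Generator):
    lo, hi = bounds
    draws = {name: rng.uniform(lo, hi, size=n) for name in PARAM_NAMES if name != "alpha"}
    draws["alpha"] = rng.uniform(0.0, 1.0, size=n)
    return draws


def _vertex_eigs_vectorized(draws: dict[str, np.ndarray], vertex: Sequence[int]) -> np.ndarray:
    """Shape (n, 4) array of canonical vertex eigenvalues for sampled draws."""
    entries = payoff_entries(draws)
    vertex = tuple(int(b) for b in vertex)
    cols = []
    for i in range(4):
        active = list(vertex)
        passive = list(vertex)
        active[i], passive[i] = 1, 0
        diff = entries[(i, *active)] - entries[(i, *passive)]
        cols.append((1 - 2 * vertex[i]) * diff)
    return np.column_stack(cols)


@dataclass(frozen=True)
class FeasibilityResult:
    profile: tuple[int, int, int, int]
    feasible: bool
    witness: GameParameters | None
    n_draws: int
    n_feasible: int
    shortcut: str | None  # set when an analytic argument decided infeasibility


def ess_feasibility(
    profile: Sequence[int],
    n_draws: int = FEASIBILITY_DRAWS,
    bounds: tuple[float, float] = FEASIBILITY_BOUNDS,
    seed: int = FEASIBILITY_SEED,
) -> FeasibilityResult:
    """Can some admissible parameter set make this vertex an ESS?

    Samples parameter sets uniformly from the box (quantities in ``bounds``,
    alpha in (0,1)) and tests whether all four canonical vertex eigenvalues
    go negative; an analytic shortcut first rules out vertices owning an
    eigenvalue that is a sum of strictly positive parameters.
    """
    if n_draws <= 0:
        raise ConfigurationError(f"n_draws must be positive, got {n_draws}")
    vertex = tuple(int(b) for b in profile)
    for k, expr in enumerate(symbolic_vertex_eigenvalues(vertex)):
        if _always_positive(expr):
            return FeasibilityResult(
                profile=vertex, feasible=False, witness=None, n_draws=0, n_feasible=0,
                shortcut=f"eigenvalue {k + 1} = {expr} is a sum of positive parameters",
            )
    rng = np.random.default_rng(seed)
    draws = _sample_parameter_draws(n_draws, bounds, rng)
    eigs = _vertex_eigs_vectorized(draws, vertex)
    feasible_mask = np.all(eigs < 0.0, axis=1)
    n_feasible = int(feasible_mask.sum())
    witness = None
    if n_feasible:
        idx = int(np.argmax(feasible_mask))
        witness = GameParameters(**{name: float(draws[name][idx]) for name in PARAM_NAMES})
    return FeasibilityResult(
        profile=vertex, feasible=bool(n_feasible), witness=witness,
        n_draws=n_draws, n_feasible=n_feasible, shortcut=None,
    )


def feasible_strict_profiles(
    n_draws: int = FEASIBILITY_DRAWS,
    seed: int = FEASIBILITY_SEED,
    bounds: tuple[float, float] = FEASIBILITY_BOUNDS,
) -> list[FeasibilityResult]:
    """Feasibility results for the 8 strict-regulation (x = 1) vertices."""
    return [
        ess_feasibility(v, n_draws=n_draws, bounds=bounds, seed=seed)
        for v in PROFILES
        if v[0] == 1
    ]
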