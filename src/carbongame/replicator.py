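"""Replicator dynamics of the four-party game on the unit 4-cube.

Each population has two strategies; the frequency of the active strategy is
``p`` and evolves as ``dp/dt = p (1 - p) (E_active - E_passive)`` where the
expected payoffs weight the player's tensor entries by the *other* three
frequencies.  The payoff difference of a player never depends on that
player's own frequency, so every face of the cube is invariant and all 16
vertices are fixed points.

Two right-hand sides are provided:

* the canonical one, derived from the payoff tensor at run time (system of
  record for every experiment), and
* ``printed_rhs``, the literal closed forms as published, kept only for
  cross-checking.  The published government equation carries a ``C_g`` term
  where the tensor derivation yields ``k_g`` (a typo propagated from the
  loose-regulation expected payoff); hospital, pharma and public closed
  forms agree with the tensor exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, IntegrationError, ParameterValidationError
from .params import PLAYERS, GameParameters
from .payoffs import PayoffTensor, _player_index

__all__ = [
    "validate_state",
    "expected_payoffs",
    "payoff_difference",
    "replicator_rhs",
    "printed_rhs",
    "make_rhs",
    "integrate",
    "Trajectory",
    "ConvergenceResult",
    "detect_convergence",
]

#: Allowed excursion outside [0, 1] attributable to solver tolerance.
CUBE_TOL = 1e-6


def validate_state(state: Sequence[float]) -> np.ndarray:
    """Coerce to a float array (x, y, z, w) and check it lies in the cube."""
    s = np.asarray(state, dtype=float)
    if s.shape != (4,):
        raise ParameterValidationError(f"state must have 4 components, got shape {s.shape}")
    if np.any(s < 0.0) or np.any(s > 1.0):
        raise ParameterValidationError(f"state components must lie in [0, 1], got {s.tolist()}")
    return s


def _difference_blocks(tensor: PayoffTensor) -> list[np.ndarray]:
    """Per player: the 2x2x2 array of (active - passive) payoffs over opponents."""
    blocks = []
    for i in range(4):
        arr = tensor.values[i]
        active = np.take(arr, 1, axis=i)
        passive = np.take(arr, 0, axis=i)
        blocks.append(active - passive)
    return blocks


def _reduce(block: np.ndarray, probs: Sequence[float]) -> float:
    # collapse one binary opponent axis at a time with weights (1-p, p)
    out = block
    for p in probs:
        out = out[0] * (1.0 - p) + out[1] * p
    return float(out)


def expected_payoffs(
    tensor: PayoffTensor, player: str | int, state: Sequence[float]
) -> tuple[float, float, float]:
    """(E_active, E_passive, E_average) for one player at a mixed state.

    E_active / E_passive weight the player's 8 relevant tensor entries by the
    opponents' frequencies; E_average mixes them with the player's own
    frequency.
    """
    i = _player_index(player)
    s = validate_state(state)
    opponents = [s[j] for j in range(4) if j != i]
    arr = tensor.values[i]
    e_active = _reduce(np.take(arr, 1, axis=i), opponents)
    e_passive = _reduce(np.take(arr, 0, axis=i), opponents)
    p = s[i]
    return e_active, e_passive, p * e_active + (1.0 - p) * e_passive


def payoff_difference(tensor: PayoffTensor, player: str | int, state: Sequence[float]) -> float:
    """E_active - E_passive; independent of the player's own frequency."""
    e_active, e_passive, _ = expected_payoffs(tensor, player, state)
    return e_active - e_passive


def replicator_rhs(tensor: PayoffTensor, state: Sequence[float]) -> np.ndarray:
    """Canonical replicator rates (dx, dy, dz, dw)/dt derived from the tensor."""
    s = validate_state(state)
    return make_rhs(tensor)(0.0, s)


def make_rhs(tensor: PayoffTensor) -> Callable[[float, np.ndarray], np.ndarray]:
    """Compile a fast ``f(t, state) -> rates`` closure for the canonical system."""
    blocks = _difference_blocks(tensor)

    def rhs(t: float, s: np.ndarray) -> np.ndarray:
        rates = np.empty(4)
        for i in range(4):
            opponents = [s[j] for j in range(4) if j != i]
            rates[i] = s[i] * (1.0 - s[i]) * _reduce(blocks[i], opponents)
        return rates

    return rhs


def printed_rhs(params: GameParameters, state: Sequence[float]) -> np.ndarray:
    """The published closed-form rates, evaluated literally (cross-check only)."""
    x, y, z, w = validate_state(state)
    p = params
    gov = x * (1 - x) * (
        w * p.k_g - p.C_g
        - y * ((p.alpha * w - w + 1) * p.D_h + z * (p.R_c + p.R_h - w * p.C_g))
        - (w - p.alpha * w - 1) * (p.D_c + p.D_h)
        - z * ((p.alpha - 1) * w + 1) * p.D_c
    )
    hosp = y * (1 - y) * (x * (p.D_h + z * p.R_h) + 2 * w * p.k_h - p.S_h - p.C_h)
    pharma = z * (1 - z) * (x * (p.D_c + y * p.R_c) + 2 * w * p.k_c - p.S_c - p.C_c)
    public = w * (1 - w) * (
        x * (1 - p.alpha) * (p.D_c + p.D_h)
        - x * ((1 - p.alpha) * y * p.D_h + (1 - p.alpha) * z * p.D_c)
        - p.C_p
    )
    return np.array([gov, hosp, pharma, public])


@dataclass
class Trajectory:
    """Time-indexed solution of the (possibly delayed) replicator system."""

    times: np.ndarray
    states: np.ndarray  # shape (n, 4)
    meta: dict = field(default_factory=dict)

    @property
    def initial_state(self) -> np.ndarray:
        return self.states[0]

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.times, "x": self.states[:, 0], "y": self.states[:, 1],
             "z": self.states[:, 2], "w": self.states[:, 3]}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _check_cube(states: np.ndarray, context: str) -> None:
    excess = max(float(np.max(states) - 1.0), float(-np.min(states)))
    if excess > CUBE_TOL:
        raise IntegrationError(
            f"{context}: trajectory left the unit cube by {excess:.3e} (> {CUBE_TOL:.0e})"
        )


def integrate(
    tensor: PayoffTensor,
    initial: Sequence[float],
    horizon: float = 100.0,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "RK45",
    n_samples: int = 2001,
    as_printed: bool = False,
) -> Trajectory:
    """Integrate the replicator ODE system on [0, horizon].

    ``as_printed=True`` swaps in the literal published closed forms (the
    parameters are taken from the tensor).  States are never clipped; the
    replicator structure preserves the cube and any excursion beyond
    ``CUBE_TOL`` raises :class:`IntegrationError`.
    """
    if horizon <= 0:
        raise ConfigurationError(f"horizon must be positive, got {horizon}")
    s0 = validate_state(initial)
    if as_printed:
        params = tensor.params
        rhs = lambda t, s: printed_rhs(params, np.clip(s, 0.0, 1.0))  # noqa: E731
    else:
        rhs = make_rhs(tensor)
    t_eval = np.linspace(0.0, horizon, n_samples)
    sol = solve_ivp(rhs, (0.0, horizon), s0, method=method, rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}")
    states = sol.y.T
    _check_cube(states, "integrate")
    meta = {
        "solver": method,
        "rtol": rtol,
        "atol": atol,
        "horizon": float(horizon),
        "n_rhs_evaluations": int(sol.nfev),
        "mode": "printed" if as_printed else "canonical",
    }
    return Trajectory(times=sol.t, states=states, meta=meta)


@dataclass(frozen=True)
class ConvergenceResult:
    """Nearest-vertex convergence verdict for a trajectory."""

    vertex: tuple[int, int, int, int] | None
    first_passage_time: float | None
    final_distance: float  # max-norm distance from the nearest vertex at the end


def detect_convergence(traj: Trajectory, tol: float = 0.01) -> ConvergenceResult:
    """Decide whether the trajectory settled at a cube vertex.

    The verdict is positive when the final state is within ``tol`` of a
    vertex in max-norm *and* stayed within ``tol`` over the final 10% of the
    time span.  The first-passage time is the earliest sampled time the
    trajectory entered the tol-ball of that vertex.
    """
    if not 0.0 < tol < 0.5:
        raise ConfigurationError(f"tol must lie in (0, 0.5), got {tol}")
    if len(traj.times) == 0:
        raise ConfigurationError("empty trajectory")
    vertex = tuple(int(round(v)) for v in traj.final_state)
    dist = np.max(np.abs(traj.states - np.array(vertex)), axis=1)
    final_distance = float(dist[-1])
    t0, t1 = traj.times[0], traj.times[-1]
    tail = traj.times >= t1 - 0.1 * (t1 - t0)
    if final_distance >= tol or not np.all(dist[tail] < tol):
        return ConvergenceResult(vertex=None, first_passage_time=None, final_distance=final_distance)
    inside = np.nonzero(dist < tol)[0]
    first_passage = float(traj.times[inside[0]])
    return ConvergenceResult(vertex=vertex, first_passage_time=first_passage, final_distance=final_distance)
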