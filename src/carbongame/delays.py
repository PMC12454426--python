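"""Time-delayed variants of the replicator system.

One player reacts with a lag tau: every occurrence of that player's
frequency -- in its own logistic factor and growth bracket *and* inside the
other three players' payoff brackets -- is evaluated at ``t - tau``; the
other frequencies stay at current time.  Three variants exist (delayed
hospital, pharma or public); the government is never the delayed player.

Integration uses the method of steps with a fixed step and classic
fourth-order Runge-Kutta stages; stored history is interpolated by a cubic
Hermite rule (continuous, exact at the nodes) and the pre-history
(``t < 0``) is the constant initial state.  The fixed step defaults to
``min(tau / 10, 0.05, 1 / maxB)`` where ``maxB`` bounds the payoff
differences over the cube corners -- discontinuity propagation at multiples
of tau makes naive adaptive stepping unreliable, and the last cap keeps the
explicit scheme stable even for large sampled parameter sets.

Unlike the plain replicator system, the delayed equations do *not*
structurally preserve the unit cube: the delayed player's own rate carries
the lagged logistic factor ``p(t-tau)[1-p(t-tau)]``, which stays nonzero
while the current frequency crosses 0 or 1, and the excursion then grows
without bound.  Frequencies are probabilities, so the integrator treats the
cube as a hard constraint: after every step the state is projected
(componentwise clamped) onto ``[0,1]^4`` -- the standard projected
dynamical-system treatment.  Once a pinned component's lag window passes,
its rate vanishes and the projection becomes inactive.  See
docs/methods.md for the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, IntegrationError
from .params import PLAYERS
from .payoffs import PayoffTensor, _player_index
from .replicator import (
    CUBE_TOL,
    ConvergenceResult,
    Trajectory,
    _check_cube,
    _difference_blocks,
    _reduce,
    detect_convergence,
    integrate,
    validate_state,
)

__all__ = ["DelaySpec", "delayed_rhs", "integrate_dde", "convergence_time_vs_delay"]

#: Players allowed to carry the delay.
DELAYABLE = ("hospital", "pharma", "public")


@dataclass(frozen=True)
class DelaySpec:
    """Which player lags, and by how much (model time units, >= 0)."""

    delayed_player: str
    tau: float

    def __post_init__(self) -> None:
        if self.delayed_player not in DELAYABLE:
            raise ConfigurationError(
                f"delayed_player must be one of {DELAYABLE}, got {self.delayed_player!r}"
            )
        if self.tau < 0:
            raise ConfigurationError(f"tau must be >= 0, got {self.tau}")

    @property
    def player_index(self) -> int:
        return _player_index(self.delayed_player)


def delayed_rhs(
    tensor: PayoffTensor,
    state_now: Sequence[float],
    state_lagged: Sequence[float],
    spec: DelaySpec,
) -> np.ndarray:
    """Rates with the delayed player's frequency read from the lagged state.

    The delayed player's own logistic factor uses the lagged frequency, so
    its rate vanishes whenever the *lagged* frequency sits at 0 or 1.
    """
    now = validate_state(state_now)
    lag = validate_state(state_lagged)
    d = spec.player_index
    effective = now.copy()
    effective[d] = lag[d]
    blocks = _difference_blocks(tensor)
    rates = np.empty(4)
    for i in range(4):
        opponents = [effective[j] for j in range(4) if j != i]
        p = effective[i] if i == d else now[i]
        rates[i] = p * (1.0 - p) * _reduce(blocks[i], opponents)
    return rates


def _max_bracket_bound(tensor: PayoffTensor) -> float:
    """Max |payoff difference| over all players and cube corners.

    Each bracket is multilinear in the opponents, so its extrema over the
    cube sit at corners; the bound governs the stable step size.
    """
    return max(float(np.max(np.abs(block))) for block in _difference_blocks(tensor))


class _History:
    """Dense solution history with cubic Hermite interpolation."""

    def __init__(self, t0: float, y0: np.ndarray, f0: np.ndarray, capacity: int):
        self.t = np.empty(capacity)
        self.y = np.empty((capacity, 4))
        self.f = np.empty((capacity, 4))
        self.n = 0
        self.initial = y0.copy()
        self.append(t0, y0, f0)

    def append(self, t: float, y: np.ndarray, f: np.ndarray) -> None:
        self.t[self.n] = t
        self.y[self.n] = y
        self.f[self.n] = f
        self.n += 1

    def __call__(self, t: float) -> np.ndarray:
        if t <= 0.0:
            return self.initial  # constant pre-history
        n = self.n
        k = int(np.searchsorted(self.t[:n], t, side="right")) - 1
        if k >= n - 1:
            return self.y[n - 1].copy()
        t0, t1 = self.t[k], self.t[k + 1]
        h = t1 - t0
        s = (t - t0) / h
        h00 = (1 + 2 * s) * (1 - s) ** 2
        h10 = s * (1 - s) ** 2
        h01 = s * s * (3 - 2 * s)
        h11 = s * s * (s - 1)
        return (
            h00 * self.y[k] + h10 * h * self.f[k]
            + h01 * self.y[k + 1] + h11 * h * self.f[k + 1]
        )


def integrate_dde(
    tensor: PayoffTensor,
    initial: Sequence[float],
    spec: DelaySpec,
    horizon: float = 100.0,
    step: float | None = None,
) -> Trajectory:
    """Method-of-steps integration of one delayed-player variant.

    ``tau = 0`` falls back to the plain ODE path.  A user-supplied ``step``
    greater than ``tau / 2`` is rejected as a configuration error.
    """
    if horizon <= 0:
        raise ConfigurationError(f"horizon must be positive, got {horizon}")
    y0 = validate_state(initial)
    if spec.tau == 0.0:
        traj = integrate(tensor, y0, horizon)
        traj.meta.update({"delayed_player": spec.delayed_player, "tau": 0.0})
        return traj
    if step is not None:
        if step <= 0:
            raise ConfigurationError(f"step must be positive, got {step}")
        if step > spec.tau / 2:
            raise ConfigurationError(
                f"step {step} exceeds tau/2 = {spec.tau / 2}; refine the step"
            )
        h = float(step)
    else:
        h = min(spec.tau / 10.0, 0.05, 1.0 / max(1e-12, _max_bracket_bound(tensor)))
    n_steps = int(np.ceil(horizon / h))
    h = horizon / n_steps  # land exactly on the horizon

    blocks = _difference_blocks(tensor)
    d = spec.player_index

    def f(t: float, y: np.ndarray, hist: _History) -> np.ndarray:
        # unvalidated fast path of delayed_rhs; brackets are multilinear, so
        # evaluating marginally outside the cube (RK stages) is harmless
        lag = hist(t - spec.tau)
        eff = y.copy()
        eff[d] = lag[d]
        rates = np.empty(4)
        for i in range(4):
            opponents = [eff[j] for j in range(4) if j != i]
            p = eff[i] if i == d else y[i]
            rates[i] = p * (1.0 - p) * _reduce(blocks[i], opponents)
        return rates

    hist = _History(0.0, y0, delayed_rhs(tensor, y0, y0, spec), n_steps + 1)
    t, y = 0.0, y0.copy()
    n_projected = 0
    for _ in range(n_steps):
        k1 = f(t, y, hist)
        k2 = f(t + h / 2, y + h / 2 * k1, hist)
        k3 = f(t + h / 2, y + h / 2 * k2, hist)
        k4 = f(t + h, y + h * k3, hist)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
        if not np.all(np.isfinite(y)):
            raise IntegrationError(f"delay integration diverged at t = {t:.3f}")
        if np.any(y < 0.0) or np.any(y > 1.0):
            y = np.clip(y, 0.0, 1.0)  # projection onto the cube, see module docstring
            n_projected += 1
        hist.append(t, y, f(t, y, hist))
    states = hist.y[: hist.n]
    _check_cube(states, "integrate_dde")
    meta = {
        "solver": "method-of-steps RK4 (cube-projected)",
        "step": h,
        "delayed_player": spec.delayed_player,
        "tau": spec.tau,
        "horizon": float(horizon),
        "n_projected_steps": n_projected,
        "mode": "canonical",
    }
    return Trajectory(times=hist.t[: hist.n].copy(), states=states.copy(), meta=meta)


def convergence_time_vs_delay(
    tensor: PayoffTensor,
    initial: Sequence[float],
    delayed_player: str,
    tau_grid: Sequence[float],
    tol: float = 0.01,
    horizon: float = 100.0,
) -> pd.DataFrame:
    """Limit vertex and first-passage time for each delay on the grid.

    The resulting table carries a ``limit_invariant`` column flagging
    whether all runs reached the same vertex; convergence *speed* versus
    delay is reported, not asserted.
    """
    taus = list(tau_grid)
    if not taus or any(tau < 0 for tau in taus):
        raise ConfigurationError("tau_grid must be non-empty and non-negative")
    rows = []
    for tau in taus:
        traj = integrate_dde(tensor, initial, DelaySpec(delayed_player, float(tau)), horizon)
        conv: ConvergenceResult = detect_convergence(traj, tol)
        rows.append(
            {
                "tau": float(tau),
                "limit_vertex": "".join(map(str, conv.vertex)) if conv.vertex else "",
                "first_passage_time": conv.first_passage_time,
                **{name: traj.final_state[k] for k, name in enumerate("xyzw")},
            }
        )
    df = pd.DataFrame(rows)
    vertices = set(df["limit_vertex"])
    df["limit_invariant"] = len(vertices) == 1 and "" not in vertices
    return df
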