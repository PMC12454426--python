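"""Indifference thresholds, basin volumes and sensitivity signs.

For each player the payoff difference ``B`` (active minus passive) depends
only on the three opponents' frequencies and is affine in each of them
separately.  Solving ``B = 0`` for one opponent frequency with the other two
fixed gives the player's indifference threshold: below/above it the player
drifts toward one of its two strategies.

The *basin volume* of a player is the fraction of the opponents' unit cube
(uniform measure) on which the drift points toward the active strategy.  It
is estimated numerically -- by midpoint-rule grid quadrature or Monte Carlo
sampling -- rather than through the published closed-form integrals, which
contain algebraic inconsistencies (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigurationError, ParameterValidationError
from .params import PLAYERS, GameParameters
from .payoffs import PayoffTensor, _player_index, build_payoff_tensor
from .replicator import _difference_blocks, _reduce

__all__ = [
    "ThresholdReport",
    "indifference_threshold",
    "VolumeReport",
    "basin_volume",
    "corollary_signs",
    "COROLLARY_CLAIMS",
]

#: Root tolerance for the (affine) indifference equations.
ROOT_TOL = 1e-10

#: Sensitivity directions of each player's active-strategy basin volume with
#: respect to game parameters, as claimed by the model's comparative statics:
#: +1 = volume increases with the parameter, -1 = decreases.
COROLLARY_CLAIMS: dict[str, dict[str, int]] = {
    "government": {"k_g": +1, "D_c": +1, "D_h": +1, "C_g": -1, "R_c": -1, "R_h": -1},
    "hospital": {"S_h": -1, "C_h": -1, "k_h": +1, "R_h": +1, "D_h": +1},
    "pharma": {"S_c": -1, "C_c": -1, "D_c": +1, "k_c": +1},
    "public": {"D_h": +1, "D_c": +1, "C_p": -1},
}


def _opponent_names(player_index: int) -> list[str]:
    state_names = ("x", "y", "z", "w")
    return [state_names[j] for j in range(4) if j != player_index]


def _bracket_of_opponents(tensor: PayoffTensor, player_index: int):
    """Return f(p0, p1, p2) -> payoff difference, opponents in axis order."""
    block = _difference_blocks(tensor)[player_index]

    def f(probs: Sequence[float]) -> float:
        return _reduce(block, probs)

    return f


@dataclass(frozen=True)
class ThresholdReport:
    player: str
    solve_for: str            # state-variable name of the opponent solved for
    fixed: dict[str, float]   # the other two opponent frequencies
    threshold: float | None   # None when the difference is flat
    in_unit_interval: bool
    slope: float              # d(payoff difference)/d(solved variable)
    drift_at_zero: float      # payoff difference at solved variable = 0
    drift_at_one: float
    indifferent_everywhere: bool


def indifference_threshold(
    tensor: PayoffTensor,
    player: str | int,
    solve_for: str,
    fixed: dict[str, float],
) -> ThresholdReport:
    """Root of the player's payoff difference in one opponent frequency.

    The difference is affine in the solved variable (asserted via a midpoint
    collinearity check), so the root is unique when the slope is nonzero.
    Roots inside [0, 1] are located by bisection; otherwise the analytic
    root is reported together with the uniform drift sign on [0, 1].
    """
    i = _player_index(player)
    opp_names = _opponent_names(i)
    if solve_for not in opp_names:
        raise ConfigurationError(
            f"{PLAYERS[i]} has opponents {opp_names}; cannot solve for {solve_for!r}"
        )
    if set(fixed) != set(opp_names) - {solve_for}:
        raise ConfigurationError(
            f"fixed must specify exactly {sorted(set(opp_names) - {solve_for})}, got {sorted(fixed)}"
        )
    for name, value in fixed.items():
        if not 0.0 <= value <= 1.0:
            raise ParameterValidationError(f"fixed frequency {name}={value} outside [0, 1]")

    f = _bracket_of_opponents(tensor, i)
    pos = opp_names.index(solve_for)

    def g(v: float) -> float:
        probs = [fixed[n] if n != solve_for else v for n in opp_names]
        return f(probs)

    g0, gmid, g1 = g(0.0), g(0.5), g(1.0)
    scale = max(1.0, abs(g0), abs(g1))
    if abs(gmid - 0.5 * (g0 + g1)) > 1e-9 * scale:  # cannot happen for this model
        raise ConfigurationError("payoff difference is not affine in the solved variable")

    slope = g1 - g0
    if abs(slope) < ROOT_TOL:
        return ThresholdReport(
            player=PLAYERS[i], solve_for=solve_for, fixed=dict(fixed),
            threshold=None, in_unit_interval=False, slope=slope,
            drift_at_zero=g0, drift_at_one=g1,
            indifferent_everywhere=abs(g0) < ROOT_TOL,
        )
    root = -g0 / slope
    in_unit = 0.0 <= root <= 1.0
    if g0 * g1 < 0:  # refine by bisection, per the geometric construction
        root = brentq(g, 0.0, 1.0, xtol=ROOT_TOL)
        in_unit = True
    return ThresholdReport(
        player=PLAYERS[i], solve_for=solve_for, fixed=dict(fixed),
        threshold=float(root), in_unit_interval=in_unit, slope=float(slope),
        drift_at_zero=float(g0), drift_at_one=float(g1),
        indifferent_everywhere=False,
    )


@dataclass(frozen=True)
class VolumeReport:
    player: str
    active_mass: float    # measure of the opponent cube where drift favours the active strategy
    passive_mass: float
    stderr: float         # Monte Carlo standard error (0 for grid quadrature)
    method: str
    n: int


def basin_volume(
    tensor: PayoffTensor,
    player: str | int,
    method: str = "grid",
    n: int = 100_000,
    seed: int | None = None,
) -> VolumeReport:
    """Fraction of the opponents' unit cube where the player drifts active.

    ``grid`` uses the midpoint rule with ``round(n ** (1/3))`` nodes per
    axis; ``montecarlo`` samples ``n`` uniform points and reports the
    binomial standard error.
    """
    if n < 1000:
        raise ConfigurationError(f"n must be >= 1000, got {n}")
    i = _player_index(player)
    block = _difference_blocks(tensor)[i]

    if method == "grid":
        m = max(2, int(round(n ** (1.0 / 3.0))))
        nodes = (np.arange(m) + 0.5) / m
        weights = np.column_stack([1.0 - nodes, nodes])  # (m, 2)
        vals = np.einsum("abc,ia,jb,kc->ijk", block, weights, weights, weights)
        active = float(np.mean(vals > 0.0))
        return VolumeReport(PLAYERS[i], active, 1.0 - active, 0.0, "grid", m ** 3)
    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        pts = rng.uniform(size=(n, 3))
        w = [np.column_stack([1.0 - pts[:, k], pts[:, k]]) for k in range(3)]
        vals = np.einsum("abc,na,nb,nc->n", block, *w)
        active = float(np.mean(vals > 0.0))
        stderr = float(np.sqrt(active * (1.0 - active) / n))
        return VolumeReport(PLAYERS[i], active, 1.0 - active, stderr, "montecarlo", n)
    raise ConfigurationError(f"unknown method {method!r}; use 'grid' or 'montecarlo'")


def corollary_signs(
    params: GameParameters,
    player: str | int,
    delta: float = 0.5,
    n: int = 64_000,
) -> pd.DataFrame:
    """Finite-difference sensitivities of the active-strategy basin volume.

    For each parameter named in the player's comparative-statics claim, the
    grid basin volume is re-estimated at ``param +/- delta`` (same nodes) and
    the sign of the central difference is compared with the claimed
    direction.  ``delta`` is an absolute step: basin volume is a fraction of
    flipped grid cells, so the step must be large enough to flip some.
    """
    i = _player_index(player)
    name = PLAYERS[i]
    claims = COROLLARY_CLAIMS[name]
    rows = []
    for pname, claim in claims.items():
        base_value = getattr(params, pname)
        lo = max(0.0, base_value - delta)
        hi = base_value + delta
        v_hi = basin_volume(build_payoff_tensor(params.with_updates(**{pname: hi})), i, "grid", n).active_mass
        v_lo = basin_volume(build_payoff_tensor(params.with_updates(**{pname: lo})), i, "grid", n).active_mass
        sens = (v_hi - v_lo) / (hi - lo)
        sign = int(np.sign(sens))
        rows.append(
            {
                "player": name,
                "parameter": pname,
                "delta": delta,
                "sensitivity": sens,
                "sensitivity_sign": sign,
                "corollary_claim": claim,
                "agrees": sign == claim,
            }
        )
    return pd.DataFrame(rows)
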