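"""Payoff tensor of the quadripartite game.

Sixteen pure strategy profiles exist, one per corner of the unit 4-cube.
A profile is encoded as four bits ``(gov, hosp, pharma, public)`` where 1
means the "active" strategy: strict regulation, strong enforcement,
self-discipline, participation.  The payoff tensor stores each of the four
players' utility at each profile, i.e. 4 x 16 = 64 numbers, all signed sums
of the 18 game parameters.

One cell deviates from the published payoff table: at the profile
(loose, weak, no self-discipline, non-participating) the pharma payoff is
``S_c`` here, not ``S_c - k_c``; the credibility term ``k_c`` only applies
under public participation, and the pharma expected-payoff expansion used by
the replicator derivation confirms ``S_c`` for that profile.  See
docs/methods.md.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np

from .errors import ParameterValidationError
from .params import PLAYERS, GameParameters

__all__ = ["PROFILES", "PayoffTensor", "build_payoff_tensor", "payoff_at", "payoff_entries"]

#: All 16 pure profiles in bit order (gov, hosp, pharma, public).
PROFILES = tuple(itertools.product((0, 1), repeat=4))


def payoff_entries(p: Mapping[str, Any]) -> dict[tuple[int, int, int, int, int], Any]:
    """Payoff expressions for all (player, profile) pairs.

    ``p`` maps parameter names to values; values may be floats, broadcastable
    numpy arrays, or symbolic quantities -- the expressions only use +, - and *.
    Keys of the result are ``(player_index, g, h, c, w)`` with player order
    (government, hospital, pharma, public).
    """
    Rg, Rh, Rc = p["R_g"], p["R_h"], p["R_c"]
    kg, kh, kc = p["k_g"], p["k_h"], p["k_c"]
    Lg, Lp, Sp = p["L_g"], p["L_p"], p["S_p"]
    Sh, Sc = p["S_h"], p["S_c"]
    Dh, Dc = p["D_h"], p["D_c"]
    Cp, Cg, Ch, Cc = p["C_p"], p["C_g"], p["C_h"], p["C_c"]
    a = p["alpha"]

    e: dict[tuple[int, int, int, int, int], Any] = {}

    # --- government (player 0) ---
    e[0, 1, 1, 1, 1] = Rg - Cg - Rc - Rh + kg
    e[0, 1, 1, 1, 0] = Rg - Cg - Rh - Rc
    e[0, 1, 1, 0, 1] = a * Dc - Cg - Lg
    e[0, 1, 1, 0, 0] = Dc - Cg - Lg
    e[0, 1, 0, 1, 1] = a * Dh - Cg - Lg
    e[0, 1, 0, 1, 0] = Dh - Cg - Lg
    e[0, 1, 0, 0, 1] = a * (Dh + Dc) - Cg - Lg
    e[0, 1, 0, 0, 0] = Dh + Dc - Cg - Lg
    e[0, 0, 1, 1, 1] = Rg - kg
    e[0, 0, 1, 1, 0] = Rg
    e[0, 0, 1, 0, 1] = -Lg - kg
    e[0, 0, 1, 0, 0] = -Lg
    e[0, 0, 0, 1, 1] = -Lg - kg
    e[0, 0, 0, 1, 0] = -Lg
    e[0, 0, 0, 0, 1] = -Lg - kg
    e[0, 0, 0, 0, 0] = -Lg

    # --- public hospitals (player 1) ---
    e[1, 1, 1, 1, 1] = Rh - Ch + kh
    e[1, 1, 1, 1, 0] = Rh - Ch
    e[1, 1, 1, 0, 1] = -Ch + kh
    e[1, 1, 1, 0, 0] = -Ch
    e[1, 1, 0, 1, 1] = Sh - Dh - kh
    e[1, 1, 0, 1, 0] = Sh - Dh
    e[1, 1, 0, 0, 1] = Sh - Dh - kh
    e[1, 1, 0, 0, 0] = Sh - Dh
    e[1, 0, 1, 1, 1] = -Ch + kh
    e[1, 0, 1, 1, 0] = -Ch
    e[1, 0, 1, 0, 1] = -Ch + kh
    e[1, 0, 1, 0, 0] = -Ch
    e[1, 0, 0, 1, 1] = Sh - kh
    e[1, 0, 0, 1, 0] = Sh
    e[1, 0, 0, 0, 1] = Sh - kh
    e[1, 0, 0, 0, 0] = Sh

    # --- pharmaceutical enterprises (player 2) ---
    e[2, 1, 1, 1, 1] = Rc - Cc + kc
    e[2, 1, 1, 1, 0] = Rc - Cc
    e[2, 1, 1, 0, 1] = Sc - Dc - kc
    e[2, 1, 1, 0, 0] = Sc - Dc
    e[2, 1, 0, 1, 1] = -Cc + kc
    e[2, 1, 0, 1, 0] = -Cc
    e[2, 1, 0, 0, 1] = Sc - Dc - kc
    e[2, 1, 0, 0, 0] = Sc - Dc
    e[2, 0, 1, 1, 1] = -Cc + kc
    e[2, 0, 1, 1, 0] = -Cc
    e[2, 0, 1, 0, 1] = Sc - kc
    e[2, 0, 1, 0, 0] = Sc
    e[2, 0, 0, 1, 1] = -Cc + kc
    e[2, 0, 0, 1, 0] = -Cc
    e[2, 0, 0, 0, 1] = Sc - kc
    e[2, 0, 0, 0, 0] = Sc  # published cell prints S_c - k_c; see module docstring

    # --- the public (player 3) ---
    e[3, 1, 1, 1, 1] = Sp - Cp
    e[3, 1, 1, 1, 0] = Sp
    e[3, 1, 1, 0, 1] = (1 - a) * Dc - Cp - Lp
    e[3, 1, 1, 0, 0] = -Lp
    e[3, 1, 0, 1, 1] = (1 - a) * Dh - Cp - Lp
    e[3, 1, 0, 1, 0] = -Lp
    e[3, 1, 0, 0, 1] = (1 - a) * (Dh + Dc) - Cp - Lp
    e[3, 1, 0, 0, 0] = -Lp
    e[3, 0, 1, 1, 1] = Sp - Cp
    e[3, 0, 1, 1, 0] = Sp
    e[3, 0, 1, 0, 1] = -Cp - Lp
    e[3, 0, 1, 0, 0] = -Lp
    e[3, 0, 0, 1, 1] = -Lp - Cp
    e[3, 0, 0, 1, 0] = -Lp
    e[3, 0, 0, 0, 1] = -Lp - Cp
    e[3, 0, 0, 0, 0] = -Lp

    return e


@dataclass(frozen=True)
class PayoffTensor:
    """Dense 4 x 2 x 2 x 2 x 2 payoff array plus the parameters it was built from.

    ``values[i, g, h, c, w]`` is player ``i``'s payoff at pure profile
    ``(g, h, c, w)``; index 1 denotes the active strategy.
    """

    values: np.ndarray
    params: GameParameters

    def payoff(self, player: str | int, profile) -> float:
        return payoff_at(self, player, profile)


def _player_index(player: str | int) -> int:
    if isinstance(player, int):
        if not 0 <= player < 4:
            raise KeyError(f"player index out of range: {player}")
        return player
    try:
        return PLAYERS.index(player)
    except ValueError:
        raise KeyError(f"unknown player label {player!r}; expected one of {PLAYERS}") from None


def build_payoff_tensor(params: GameParameters) -> PayoffTensor:
    """Construct all 64 payoffs from a validated parameter set.

    Pure function of ``params``; raises :class:`ParameterValidationError`
    via the ``GameParameters`` constructor when a field is inadmissible.
    """
    if not isinstance(params, GameParameters):
        params = GameParameters.from_dict(dict(params))
    entries = payoff_entries(params.to_dict())
    values = np.empty((4, 2, 2, 2, 2), dtype=float)
    for (i, g, h, c, w), value in entries.items():
        values[i, g, h, c, w] = value
    values.setflags(write=False)
    return PayoffTensor(values=values, params=params)


def payoff_at(tensor: PayoffTensor, player: str | int, profile) -> float:
    """Exact lookup of one payoff; no recomputation."""
    i = _player_index(player)
    g, h, c, w = (int(b) for b in profile)
    for b in (g, h, c, w):
        if b not in (0, 1):
            raise ParameterValidationError(f"profile bits must be 0 or 1, got {profile!r}")
    return float(tensor.values[i, g, h, c, w])
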