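"""Game parameters for the four-party carbon-neutrality regulation game.

The model couples four populations, each with a binary strategy:

* government -- strict vs. loose regulation (frequency ``x``),
* public hospitals -- strong vs. weak policy enforcement (``y``),
* pharmaceutical enterprises -- self-discipline vs. none (``z``),
* the public -- participation in supervision vs. none (``w``).

Eighteen named real quantities parameterize every payoff: rewards and
benefits (``R_*``, ``S_*``), credibility gains (``k_*``), losses (``L_*``),
fines (``D_*``), costs (``C_*``), and ``alpha``, the fraction of collected
fines the government keeps (the complement ``1 - alpha`` compensates a
participating public).  All monetary/utility quantities are non-negative and
``alpha`` lies strictly inside (0, 1).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields, replace
from pathlib import Path

import yaml

from .errors import ParameterValidationError

__all__ = [
    "PLAYERS",
    "GameParameters",
    "baseline_parameters",
    "PARAM_NAMES",
]

#: Fixed player order used everywhere in the package.
PLAYERS = ("government", "hospital", "pharma", "public")

PARAM_NAMES = (
    "R_g", "R_h", "R_c",
    "k_g", "k_h", "k_c",
    "L_g", "L_p", "S_p",
    "S_h", "S_c",
    "D_h", "D_c",
    "C_p", "C_g", "C_h", "C_c",
    "alpha",
)


@dataclass(frozen=True)
class GameParameters:
    """The 18 named quantities parameterizing all payoffs.

    Every field except ``alpha`` is a non-negative utility amount;
    ``alpha`` is the government's share of collected fines, in (0, 1).
    """

    R_g: float   # government benefit when hospitals enforce strongly and pharma self-disciplines
    R_h: float   # reward to hospitals for strong enforcement under strict regulation
    R_c: float   # reward to pharma for self-discipline under strict regulation
    k_g: float   # government credibility gain under public participation
    k_h: float   # hospital credibility gain under public participation
    k_c: float   # pharma credibility gain under public participation
    L_g: float   # government loss under weak enforcement or no self-discipline
    L_p: float   # public loss under weak enforcement / no self-discipline
    S_p: float   # public benefit under strong enforcement and self-discipline
    S_h: float   # hospital short-term benefit from weak enforcement
    S_c: float   # pharma short-term benefit from no self-discipline
    D_h: float   # fine paid by hospitals for weak enforcement under strict regulation
    D_c: float   # fine paid by pharma for no self-discipline under strict regulation
    C_p: float   # public participation cost
    C_g: float   # government strict-regulation cost
    C_h: float   # hospital strong-enforcement cost
    C_c: float   # pharma self-discipline cost
    alpha: float  # government share of fines, in (0, 1)

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            try:
                value = float(value)
            except (TypeError, ValueError) as exc:
                raise ParameterValidationError(
                    f"parameter {f.name!r} is not a real number: {value!r}"
                ) from exc
            object.__setattr__(self, f.name, value)
            if f.name == "alpha":
                if not 0.0 < value < 1.0:
                    raise ParameterValidationError(
                        f"parameter 'alpha' must lie strictly in (0, 1), got {value}"
                    )
            elif value < 0.0:
                raise ParameterValidationError(
                    f"parameter {f.name!r} must be non-negative, got {value}"
                )

    # -- convenience -------------------------------------------------------

    def with_updates(self, **updates: float) -> "GameParameters":
        """Return a copy with the named parameters replaced (re-validated)."""
        unknown = set(updates) - set(PARAM_NAMES)
        if unknown:
            raise ParameterValidationError(f"unknown parameter(s): {sorted(unknown)}")
        return replace(self, **updates)

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, float]) -> "GameParameters":
        unknown = set(data) - set(PARAM_NAMES)
        if unknown:
            raise ParameterValidationError(f"unknown parameter(s): {sorted(unknown)}")
        missing = set(PARAM_NAMES) - set(data)
        if missing:
            raise ParameterValidationError(f"missing parameter(s): {sorted(missing)}")
        return cls(**data)

    # -- flat key/value config IO (YAML or JSON by suffix) -----------------

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = self.to_dict()
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "GameParameters":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ParameterValidationError(f"{path}: expected a flat key/value mapping")
        return cls.from_dict({str(k): v for k, v in data.items()})


def baseline_parameters() -> GameParameters:
    """The baseline parameterization used by all headline simulations.

    ``L_g``, ``L_p`` and ``S_p`` never enter the replicator dynamics (they
    cancel out of every active-minus-passive payoff difference), so the
    baseline leaves them at the documented default of 1.0 each; they remain
    configurable regardless.
    """
    return GameParameters(
        R_g=10.0, R_h=2.0, R_c=4.0,
        k_g=5.0, k_h=2.0, k_c=6.0,
        L_g=1.0, L_p=1.0, S_p=1.0,
        S_h=10.0, S_c=5.0,
        D_h=6.0, D_c=6.0,
        C_p=1.0, C_g=6.0, C_h=4.0, C_c=3.0,
        alpha=0.5,
    )
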