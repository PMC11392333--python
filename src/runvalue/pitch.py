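"""Pitch geometry and frame-of-reference conventions.

Coordinates are in metres with the origin at the pitch centre: x runs along
the goal-to-goal axis in [-length/2, +length/2], y along the touchline-to-
touchline axis in [-width/2, +width/2].  Each team attacks one end (+x or -x)
per period; the mapping is stored on the :class:`Pitch` so every downstream
feature can be oriented without re-deriving play direction from the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

__all__ = ["Pitch"]


@dataclass(frozen=True)
class Pitch:
    """A football pitch with per-team attack directions.

    Parameters
    ----------
    length, width : float
        Pitch dimensions in metres (goal-to-goal and touchline-to-touchline).
    attack_directions : dict
        ``{(team_id, period): +1 | -1}`` — the sign of the x-coordinate of
        the goal the team attacks in that period.
    """

    length: float = 105.0
    width: float = 68.0
    attack_directions: Dict[Tuple[str, int], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValueError("pitch dimensions must be positive")
        for key, d in self.attack_directions.items():
            if d not in (-1, 1):
                raise ValueError(f"attack direction for {key} must be +1 or -1")

    def attack_direction(self, team_id: str, period: int) -> int:
        try:
            return self.attack_directions[(team_id, period)]
        except KeyError:
            raise KeyError(
                f"no attack direction registered for team {team_id!r} period {period}"
            ) from None

    def attacked_goal(self, team_id: str, period: int) -> Tuple[float, float]:
        """Centre of the goal this team is attacking (the opponent's goal)."""
        d = self.attack_direction(team_id, period)
        return (d * self.length / 2.0, 0.0)

    def defended_goal(self, team_id: str, period: int) -> Tuple[float, float]:
        """Centre of the goal this team is defending."""
        d = self.attack_direction(team_id, period)
        return (-d * self.length / 2.0, 0.0)

    def contains(self, x: float, y: float) -> bool:
        return abs(x) <= self.length / 2.0 and abs(y) <= self.width / 2.0

    @property
    def area(self) -> float:
        return self.length * self.width
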