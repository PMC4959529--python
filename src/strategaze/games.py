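"""Construction and classification of the 2x2 symmetric game space.

Games are symmetric two-player, two-action games presented as a 2x2 payoff
matrix with eight payoff regions (the player's own payoff and the other
player's payoff in each of the four cells).  Payoffs are labelled 1-8: odd
labels are the player's own payoffs, even labels the other player's, with
(1,2) in the top-left cell, (3,4) top-right, (5,6) bottom-left and (7,8)
bottom-right.

A game is defined in an abstract payoff space ``x`` and converted to money
payoffs ``y = 10*x + 30`` (GBP, range 0-90).  Because games are symmetric the
other player's payoffs are the transpose of the player's own:
``y1=y2, y3=y6, y5=y4, y7=y8``.  The strategic content of a game is captured
by the two differences ``d_left = x1-x5`` (payoff difference between the
player's actions when the opponent plays left) and ``d_right = x3-x7`` (the
same when the opponent plays right); the signs of the pair determine the
game's class (dominance-solvable with or without conflict, symmetric or
asymmetric coordination).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PayoffLabel",
    "GameClass",
    "Game",
    "PAYOFF_LABELS",
    "DEFAULT_DIFF_VALUES",
    "DEFAULT_BASE_CONFIGS",
    "payoff_from_x",
    "classify_game",
    "build_game_grid",
    "default_game_grid",
    "games_to_frame",
    "games_from_frame",
]

#: The four values each strategic difference takes in the published grid.
DEFAULT_DIFF_VALUES: tuple[int, ...] = (-3, -1, 1, 3)


@dataclass(frozen=True)
class PayoffLabel:
    """One of the eight payoff regions of a 2x2 symmetric game display."""

    index: int  # 1-8

    def __post_init__(self) -> None:
        if not 1 <= self.index <= 8:
            raise ValueError(f"payoff label index must be in 1..8, got {self.index}")

    @property
    def owner(self) -> str:
        """'self' for odd labels, 'other' for even labels."""
        return "self" if self.index % 2 == 1 else "other"

    @property
    def row(self) -> str:
        return "top" if self.index <= 4 else "bottom"

    @property
    def col(self) -> str:
        return "left" if self.index in (1, 2, 5, 6) else "right"


PAYOFF_LABELS: tuple[PayoffLabel, ...] = tuple(PayoffLabel(i) for i in range(1, 9))


class GameClass(str, Enum):
    """Strategic quadrant of a game, a pure function of (sign d_left, sign d_right)."""

    DOMINANCE_CONFLICT = "dominance_conflict"
    SYMMETRIC_COORDINATION = "symmetric_coordination"
    ASYMMETRIC_COORDINATION = "asymmetric_coordination"
    DOMINANCE_NO_CONFLICT = "dominance_no_conflict"


def payoff_from_x(x: float) -> float:
    """Map an abstract payoff value to money: ``y = 10*x + 30`` (GBP).

    Raises ``ValueError`` if the result falls outside the display range
    [0, 90].
    """
    y = 10 * x + 30
    if not 0 <= y <= 90:
        raise ValueError(f"payoff {y} from x={x} outside [0, 90]")
    return y


@dataclass(frozen=True)
class Game:
    """A 2x2 symmetric game.

    ``x`` and ``y`` are 8-vectors indexed by payoff label (position 0 holds
    label 1).  Even-labelled entries are filled in by symmetry from the odd
    ones.
    """

    game_id: str
    x: tuple[float, ...]
    y: tuple[float, ...]
    d_left: int
    d_right: int
    base_config: int
    quadrant: GameClass = field(compare=False)

    @classmethod
    def from_own_x(
        cls, x1: float, x3: float, x5: float, x7: float, base_config: int,
        game_id: str | None = None,
    ) -> "Game":
        # symmetry: the other player's payoffs are the transpose of ours
        x = (x1, x1, x3, x5, x5, x3, x7, x7)
        y = tuple(payoff_from_x(v) for v in x)
        d_left = x1 - x5
        d_right = x3 - x7
        g = cls(
            game_id=game_id or f"b{base_config}_dL{int(d_left)}_dR{int(d_right)}",
            x=x,
            y=y,
            d_left=int(d_left),
            d_right=int(d_right),
            base_config=base_config,
            quadrant=_classify(d_left, d_right),
        )
        return g

    def payoff(self, label: int | PayoffLabel) -> float:
        idx = label.index if isinstance(label, PayoffLabel) else label
        return self.y[idx - 1]


def _classify(d_left: float, d_right: float) -> GameClass:
    if d_left == 0 or d_right == 0:
        raise ValueError("game class undefined for zero strategic differences")
    if d_left < 0 and d_right < 0:
        return GameClass.DOMINANCE_CONFLICT
    if d_left > 0 and d_right < 0:
        return GameClass.SYMMETRIC_COORDINATION
    if d_left < 0 and d_right > 0:
        return GameClass.ASYMMETRIC_COORDINATION
    return GameClass.DOMINANCE_NO_CONFLICT


def classify_game(g: Game) -> GameClass:
    """Classify a game by the signs of its two strategic differences.

    ``(-,-)`` dominance-solvable with conflict (includes prisoner's
    dilemmas); ``(+,-)`` symmetric coordination (stag hunt); ``(-,+)``
    asymmetric coordination (hawk-dove); ``(+,+)`` dominance-solvable
    without conflict.
    """
    return _classify(g.d_left, g.d_right)


# Default base configurations.  Each quarter of the published game table holds
# two of the four own payoffs fixed while the other two are generated from the
# strategic differences.  The exact fixed money values in the original table
# are not machine-readable, so these defaults are NON-CANONICAL: they preserve
# the structure (quarter q fixes the pairs below, all payoffs stay in [0,90])
# and can be overridden by loading a transcribed games CSV.
#
# Each entry maps the fixed x-slots to their value; the free slots follow from
# d_left and d_right.
DEFAULT_BASE_CONFIGS: tuple[dict[str, float], ...] = (
    {"x1": 1.0, "x3": 1.0},
    {"x5": 1.0, "x3": 1.0},
    {"x1": 1.0, "x7": 1.0},
    {"x5": 1.0, "x7": 1.0},
)


def _solve_own_x(
    fixed: dict[str, float], d_left: float, d_right: float
) -> tuple[float, float, float, float]:
    if "x1" in fixed:
        x1 = fixed["x1"]
        x5 = x1 - d_left
    elif "x5" in fixed:
        x5 = fixed["x5"]
        x1 = x5 + d_left
    else:
        raise ValueError("base configuration must fix one of x1, x5")
    if "x3" in fixed:
        x3 = fixed["x3"]
        x7 = x3 - d_right
    elif "x7" in fixed:
        x7 = fixed["x7"]
        x3 = x7 + d_right
    else:
        raise ValueError("base configuration must fix one of x3, x7")
    return x1, x3, x5, x7


def build_game_grid(
    diff_values: Iterable[int] = DEFAULT_DIFF_VALUES,
    base_configs: Sequence[dict[str, float]] = DEFAULT_BASE_CONFIGS,
) -> list[Game]:
    """Build the full game grid: every (d_left, d_right) pair crossed with
    every base configuration.

    Returns ``len(diff_values)**2 * len(base_configs)`` games in
    deterministic order (base configuration major, then d_left, then
    d_right).  A base configuration that pushes any payoff outside [0, 90]
    is rejected with ``ValueError``.
    """
    diffs = sorted(set(int(v) for v in diff_values))
    if not diffs:
        raise ValueError("diff_values must be nonempty")
    games: list[Game] = []
    for b, fixed in enumerate(base_configs, start=1):
        for dl in diffs:
            for dr in diffs:
                x1, x3, x5, x7 = _solve_own_x(fixed, dl, dr)
                try:
                    games.append(Game.from_own_x(x1, x3, x5, x7, base_config=b))
                except ValueError as err:
                    raise ValueError(
                        f"base configuration {b} ({fixed}) invalid at "
                        f"(d_left={dl}, d_right={dr}): {err}"
                    ) from err
    return games


def default_game_grid() -> list[Game]:
    """The 64-game default grid: 16 difference pairs x 4 base configurations."""
    return build_game_grid()


def games_to_frame(games: Iterable[Game]) -> pd.DataFrame:
    """Tabulate games in the games-CSV schema
    (game_id, base_config, d_left, d_right, y1..y8)."""
    rows = []
    for g in games:
        row = {
            "game_id": g.game_id,
            "base_config": g.base_config,
            "d_left": g.d_left,
            "d_right": g.d_right,
        }
        row.update({f"y{i}": g.y[i - 1] for i in range(1, 9)})
        rows.append(row)
    return pd.DataFrame(rows)


def games_from_frame(df: pd.DataFrame) -> list[Game]:
    """Rebuild ``Game`` objects from a games table (inverse of
    ``games_to_frame``); validates symmetry and range invariants."""
    required = {"game_id", "base_config", "d_left", "d_right"} | {
        f"y{i}" for i in range(1, 9)
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"games table missing columns: {sorted(missing)}")
    games = []
    for _, row in df.iterrows():
        y = np.array([row[f"y{i}"] for i in range(1, 9)], dtype=float)
        if not (y[0] == y[1] and y[2] == y[5] and y[4] == y[3] and y[6] == y[7]):
            raise ValueError(f"game {row['game_id']}: symmetry violated")
        x = (y - 30) / 10
        g = Game.from_own_x(
            x[0], x[2], x[4], x[6],
            base_config=int(row["base_config"]),
            game_id=str(row["game_id"]),
        )
        if (g.d_left, g.d_right) != (int(row["d_left"]), int(row["d_right"])):
            raise ValueError(f"game {row['game_id']}: differences inconsistent with payoffs")
        games.append(g)
    return games
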