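"""Arena geometry for single-larva dish recordings.

Coordinates follow the image convention: ``(x, y) = (column, row)``, origin at
the top-left pixel centre, y increasing downward.  All distances are Euclidean
and measured in pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class ValidationError(ValueError):
    """Raised when an arena, behaviour or render specification is inconsistent."""


@dataclass(frozen=True)
class ArenaSpec:
    """Geometry of one recording arena.

    The default values describe a 520 x 400 px crop of a 100 mm cell-culture
    dish filmed from above at one frame every 3 s, with a circular diet blob
    placed off-centre inside the dish.

    Parameters
    ----------
    width_px, height_px
        Frame dimensions in pixels.
    dish_center
        ``(x, y)`` centre of the circular dish.
    dish_radius_px
        Dish radius in pixels; every valid larval position lies inside it.
    food_center, food_radius_px
        Centre and radius of the static diet blob (radius 0 = no food).
    frame_interval_s
        Nominal time between consecutive frames, in seconds.
    """

    width_px: int = 520
    height_px: int = 400
    dish_center: tuple[float, float] = (260.0, 200.0)
    dish_radius_px: float = 190.0
    food_center: tuple[float, float] = (205.0, 160.0)
    food_radius_px: float = 25.0
    frame_interval_s: float = 3.0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValidationError("frame dimensions must be positive")
        if self.dish_radius_px <= 0:
            raise ValidationError("dish_radius_px must be positive")
        if self.food_radius_px < 0:
            raise ValidationError("food_radius_px must be non-negative")
        if self.frame_interval_s <= 0:
            raise ValidationError("frame_interval_s must be positive")
        cx, cy = self.dish_center
        if (
            cx - self.dish_radius_px < -0.5
            or cx + self.dish_radius_px > self.width_px - 0.5
            or cy - self.dish_radius_px < -0.5
            or cy + self.dish_radius_px > self.height_px - 0.5
        ):
            raise ValidationError("dish circle must fit inside the frame rectangle")
        if (
            self.dist_from_center(*self.food_center) + self.food_radius_px
            > self.dish_radius_px
        ):
            raise ValidationError("food circle must lie inside the dish")

    def dist_from_center(self, x: float, y: float) -> float:
        cx, cy = self.dish_center
        return math.hypot(x - cx, y - cy)

    def contains(self, x: float, y: float, tolerance_px: float = 0.0) -> bool:
        """True when ``(x, y)`` lies within the dish (plus an optional margin)."""
        return self.dist_from_center(x, y) <= self.dish_radius_px + tolerance_px
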