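"""Geometry, item arithmetic, colour code and movement dynamics of the
abstract quantity space.

The environment is a two-dimensional "quantity space": a position is a pair
of shape counts (dimension 1 and dimension 2, e.g. circles and rectangles),
each axis running from 0 to ``axis_length`` conceptual meters, where one
conceptual meter corresponds to one shape added or removed along that
dimension.  Dimension-specific filler triangles pad every rendered view to a
constant ``total_items`` so that visual complexity is equal everywhere.

Heading is signalled by colour rather than by optic flow: the dimension-1
items are coloured by the cosine of the facing direction and the dimension-2
items by its sine, on a blue (quantity will decrease) - purple (no change) -
red (quantity will increase) scale.  Positions are continuous internally;
integer item counts exist only at render time.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .errors import BoundsError, ConfigError, DomainError

__all__ = [
    "SpaceConfig",
    "Position",
    "HeadingState",
    "ItemSet",
    "Mover",
    "colour_from_value",
    "position_to_items",
    "items_to_position",
    "render_item_list",
    "step",
    "euclidean_distance",
    "border_distance",
    "check_in_bounds",
    "RED",
    "PURPLE",
    "BLUE",
]

# Colour-scale endpoints (RGB in [0, 1]).  The exact values are a display
# constant, not an analysis quantity: the scheme keeps R + B == 1 across the
# whole range as a crude equal-luminance constraint, with G fixed at 0.
RED = (1.0, 0.0, 0.0)
PURPLE = (0.5, 0.0, 0.5)
BLUE = (0.0, 0.0, 1.0)


@dataclass(frozen=True)
class SpaceConfig:
    """Static parameters of the quantity space.

    Parameters
    ----------
    axis_length:
        Extent of each shape axis in conceptual meters (shape counts).
    total_items:
        Number of items on screen at every position.  Must equal
        ``2 * axis_length`` so that filler counts are non-negative at every
        position in the space.
    dim1_shape:
        Which shape ("circle" or "rectangle") is mapped to dimension 1; the
        other shape takes dimension 2.  Counterbalanced across participants.
    frame_rate:
        Display/sensor update rate in Hz.
    smoothing_frames:
        Number of frames over which translational velocity is averaged.
    mean_speed:
        Nominal movement speed in conceptual meters per second.
    """

    axis_length: float = 200.0
    total_items: int = 400
    dim1_shape: str = "circle"
    frame_rate: float = 90.0
    smoothing_frames: int = 4
    mean_speed: float = 9.0

    def __post_init__(self) -> None:
        if self.axis_length <= 0:
            raise ConfigError("axis_length: must be > 0")
        if self.total_items != 2 * self.axis_length:
            raise ConfigError(
                "total_items: must equal 2 * axis_length "
                f"({self.total_items} != {2 * self.axis_length})"
            )
        if self.dim1_shape not in ("circle", "rectangle"):
            raise ConfigError("dim1_shape: must be 'circle' or 'rectangle'")
        if self.frame_rate <= 0:
            raise ConfigError("frame_rate: must be > 0")
        if self.smoothing_frames < 1:
            raise ConfigError("smoothing_frames: must be >= 1")
        if self.mean_speed <= 0:
            raise ConfigError("mean_speed: must be > 0")

    @property
    def max_distance(self) -> float:
        """Largest possible distance in the space (the square's diagonal)."""
        return self.axis_length * math.sqrt(2.0)

    @property
    def smoothing_window_s(self) -> float:
        """Length of the velocity smoothing window in seconds."""
        return self.smoothing_frames / self.frame_rate

    def to_dict(self) -> dict:
        return {
            "axis_length": self.axis_length,
            "total_items": self.total_items,
            "dim1_shape": self.dim1_shape,
            "frame_rate": self.frame_rate,
            "smoothing_frames": self.smoothing_frames,
            "mean_speed": self.mean_speed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpaceConfig":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(d) - known
        if bad:
            raise ConfigError(f"space.{sorted(bad)[0]}: unknown key")
        return cls(**d)


@dataclass(frozen=True)
class Position:
    """A point in the quantity space: (dimension-1 count, dimension-2 count)."""

    q1: float
    q2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.q1, self.q2], dtype=float)

    def __iter__(self):
        yield self.q1
        yield self.q2


def check_in_bounds(pos: Position, cfg: SpaceConfig) -> None:
    """Raise :class:`BoundsError` unless ``pos`` lies in the space."""
    if not (0.0 <= pos.q1 <= cfg.axis_length and 0.0 <= pos.q2 <= cfg.axis_length):
        raise BoundsError(f"position {pos} outside [0, {cfg.axis_length}]^2")


@dataclass(frozen=True)
class HeadingState:
    """Facing direction and the two colour values it induces.

    ``theta`` is measured in degrees, counter-clockwise from the positive
    dimension-1 axis, so that the dimension-1 colour value is ``cos(theta)``
    and the dimension-2 colour value is ``sin(theta)``: red items get more
    numerous when moving forward, blue items fewer, purple items stay.
    """

    theta: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", float(self.theta) % 360.0)

    @property
    def v1(self) -> float:
        return math.cos(math.radians(self.theta))

    @property
    def v2(self) -> float:
        return math.sin(math.radians(self.theta))


def colour_from_value(v: float):
    """Map a colour value in [-1, 1] to an RGB triple.

    Linear interpolation from blue (v = -1) through purple (v = 0) to red
    (v = +1); the channel sum R + B is constant, keeping the scale roughly
    equiluminant.
    """
    if not -1.0 <= v <= 1.0 or not math.isfinite(v):
        raise DomainError(f"colour value {v} outside [-1, 1]")
    return (0.5 * (1.0 + v), 0.0, 0.5 * (1.0 - v))


@dataclass(frozen=True)
class ItemSet:
    """Integer item counts (and item colours) rendered at one position."""

    n_dim1: int
    n_dim2: int
    n_fill1: int
    n_fill2: int
    colour1: tuple = PURPLE
    colour2: tuple = PURPLE

    @property
    def total(self) -> int:
        return self.n_dim1 + self.n_dim2 + self.n_fill1 + self.n_fill2


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def position_to_items(pos: Position, heading: HeadingState, cfg: SpaceConfig) -> ItemSet:
    """Render a position as integer item counts with heading-driven colours.

    Quantities are rounded half-up; each dimension's fillers top the shape
    count up to ``axis_length``, so the total is always ``total_items``.
    """
    check_in_bounds(pos, cfg)
    n1 = _round_half_up(pos.q1)
    n2 = _round_half_up(pos.q2)
    L = int(round(cfg.axis_length))
    return ItemSet(
        n_dim1=n1,
        n_dim2=n2,
        n_fill1=L - n1,
        n_fill2=L - n2,
        colour1=colour_from_value(heading.v1),
        colour2=colour_from_value(heading.v2),
    )


def items_to_position(items: ItemSet) -> Position:
    """Recover the (rounded) position that produced an item set."""
    return Position(float(items.n_dim1), float(items.n_dim2))


def render_item_list(items: ItemSet, rng: np.random.Generator) -> list:
    """Randomized item-identity list for one visit.

    On-screen placement is randomized per visit; analyses never consume pixel
    positions, so the rendering is represented as a shuffled label list.
    """
    labels = (
        ["dim1"] * items.n_dim1
        + ["dim2"] * items.n_dim2
        + ["fill1"] * items.n_fill1
        + ["fill2"] * items.n_fill2
    )
    rng.shuffle(labels)
    return labels


def step(
    pos: Position,
    heading: HeadingState,
    raw_speed: float,
    dt: float,
    cfg: SpaceConfig,
    speed_history=None,
) -> Position:
    """Advance one time step, with velocity smoothing and boundary clamping.

    The effective speed is the mean of the last ``smoothing_frames`` raw
    speed samples (``speed_history`` holding the earlier samples, most recent
    last; the current ``raw_speed`` completes the window).  The new position
    is clamped component-wise to the space.
    """
    if raw_speed < 0:
        raise DomainError(f"raw_speed {raw_speed} must be >= 0")
    if dt <= 0:
        raise DomainError(f"dt {dt} must be > 0")
    window = list(speed_history or [])[-(cfg.smoothing_frames - 1):] if cfg.smoothing_frames > 1 else []
    window.append(raw_speed)
    smoothed = sum(window) / len(window)
    q1 = pos.q1 + smoothed * dt * math.cos(math.radians(heading.theta))
    q2 = pos.q2 + smoothed * dt * math.sin(math.radians(heading.theta))
    L = cfg.axis_length
    return Position(min(max(q1, 0.0), L), min(max(q2, 0.0), L))


class Mover:
    """Stateful wrapper around :func:`step` that tracks the speed window."""

    def __init__(self, cfg: SpaceConfig, pos: Position, heading: HeadingState):
        self.cfg = cfg
        self.pos = pos
        self.heading = heading
        self._history = deque(maxlen=max(cfg.smoothing_frames - 1, 0))

    def advance(self, raw_speed: float, dt: float) -> Position:
        self.pos = step(self.pos, self.heading, raw_speed, dt, self.cfg, self._history)
        self._history.append(raw_speed)
        return self.pos

    def turn_to(self, theta: float) -> None:
        self.heading = HeadingState(theta)


def euclidean_distance(a: Position, b: Position) -> float:
    """L2 distance between two positions in conceptual meters."""
    return math.hypot(a.q1 - b.q1, a.q2 - b.q2)


def border_distance(pos: Position, cfg: SpaceConfig) -> float:
    """Distance from a position to the nearest space boundary."""
    L = cfg.axis_length
    return min(pos.q1, L - pos.q1, pos.q2, L - pos.q2)
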