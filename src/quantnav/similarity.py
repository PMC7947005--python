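"""Item-overlap visual similarity between positions.

Two positions look alike to the extent that they share items on screen.
Because every position renders the same total number of items, the shared
count depends only on how the category totals differ.  Overlap is counted
over two pooled categories — all target shapes (dimension 1 + dimension 2)
and all fillers — as the sum of the category-wise minima.  Colour plays no
role: the tasks that probe similarity control for the colour code.

Along a circle around the space centre the overlap depends only on the
angle, not the radius direction of travel, which motivates an angle-only
normalized profile: scaled to [0, 1], it equals

    sim(theta) = 1 - |cos(theta) + sin(theta)| / sqrt(2)

with maxima at 135/315 degrees (the diagonal along which one quantity is
traded for the other, leaving both category totals unchanged) and minima at
45/225 degrees (both quantities rise or fall together).

Note on the pooling convention: counting each of the four item kinds
separately would instead give ``total_items - L1_distance``, whose extrema
sit on the axes — inconsistent with a design that treats 135/315 degrees as
maximally similar.  The pooled two-category count is the convention that
makes that design statement literal, and it is the one implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import BoundsError
from .space import Position, SpaceConfig, check_in_bounds

__all__ = [
    "SimilarityProfile",
    "item_overlap",
    "angular_profile",
    "similarity_lookup",
]


@dataclass(frozen=True)
class SimilarityProfile:
    """Angle-only lookup table of normalized visual similarity.

    ``angles`` are degrees in [0, 360); ``sim`` the min-max scaled overlap
    between the space centre and each point of a circle of the given radius.
    """

    radius: float
    angles: np.ndarray
    sim: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "angles", np.asarray(self.angles, dtype=float))
        object.__setattr__(self, "sim", np.asarray(self.sim, dtype=float))

    def to_csv(self, path) -> None:
        """Export as two-column CSV (angle_deg, sim)."""
        arr = np.column_stack([self.angles, self.sim])
        np.savetxt(path, arr, fmt="%.6f", delimiter=",", header="angle_deg,sim", comments="")


def item_overlap(a: Position, b: Position, cfg: SpaceConfig) -> float:
    """Number of items shared between the renderings of two positions.

    Pooled two-category count: shared target shapes plus shared fillers,

        overlap = min(q1a + q2a, q1b + q2b) + min(Fa, Fb),

    where ``F = total_items - q1 - q2``.  Identical positions share all
    ``total_items`` items.  Quantities are used continuously; rounding to
    integer screen counts changes the result by at most one item.
    """
    check_in_bounds(a, cfg)
    check_in_bounds(b, cfg)
    ta = a.q1 + a.q2
    tb = b.q1 + b.q2
    fa = cfg.total_items - ta
    fb = cfg.total_items - tb
    return min(ta, tb) + min(fa, fb)


def angular_profile(
    radius: float = 100.0,
    cfg: SpaceConfig | None = None,
    n_angles: int = 360,
) -> SimilarityProfile:
    """Overlap between the space centre and a surrounding circle, by angle.

    The raw overlap is min-max scaled to [0, 1] over the sampled angles,
    giving a distance-free similarity profile (1 degree resolution by
    default).  The circle must stay inside the space.
    """
    cfg = cfg or SpaceConfig()
    if radius <= 0:
        raise BoundsError("radius must be > 0")
    if radius > cfg.axis_length / 2:
        raise BoundsError(
            f"circle of radius {radius} around the centre exits the space"
        )
    centre = Position(cfg.axis_length / 2, cfg.axis_length / 2)
    angles = np.arange(n_angles) * (360.0 / n_angles)
    rad = np.radians(angles)
    raw = np.array(
        [
            item_overlap(
                centre,
                Position(centre.q1 + radius * math.cos(t), centre.q2 + radius * math.sin(t)),
                cfg,
            )
            for t in rad
        ]
    )
    sim = (raw - raw.min()) / (raw.max() - raw.min())
    return SimilarityProfile(radius=radius, angles=angles, sim=sim)


def similarity_lookup(theta, profile: SimilarityProfile):
    """Interpolate the profile at arbitrary angles (circular axis).

    Accepts a scalar or array of degrees; angles wrap modulo 360.
    """
    theta = np.asarray(theta, dtype=float) % 360.0
    # close the circle so interpolation wraps correctly past the last node
    ang = np.concatenate([profile.angles, [360.0]])
    sim = np.concatenate([profile.sim, [profile.sim[0]]])
    out = np.interp(theta, ang, sim)
    return float(out) if out.ndim == 0 else out
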