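"""Seeded generators for the three task designs and the feedback rule.

Three tasks make up the protocol, run in the order: forced choice (pre),
navigation training, distance/direction estimation, forced choice (post).

* Navigation training: 5 "notify" training trials (the task signals arrival
  when within 10% of the goal on both dimensions), 3 "press" training trials
  (the participant commits with a button press and gets point feedback),
  then self-paced test trials.  The gamepad group runs exactly 28 test
  trials; the movement group runs to a 54-minute task-time budget (minimum
  14 test trials), so its specs are generated as a pool that the simulator
  consumes until the budget is spent.  Navigation is continuous: each
  trial's start is the indicated goal of the previous trial.

* Distance/direction estimation: 3 practice trials plus a 4 (distance bin)
  x 9 (direction bin) factorial of 36 test trials, shuffled into 4 blocks
  of 9.  Distances span 20-180 conceptual meters; direction bins are 40
  degrees wide; all test positions keep 10 m from each other and from the
  axis limits.  Distance responses use a 29-increment slider spanning 0 to
  the space diagonal.

* Two-alternative forced choice: 216 test trials (+5 practice) in 4 blocks,
  two intermixed sub-tasks.  The similarity sub-task (96 trials) pits a
  10 m distortion in one visual-similarity condition against a 60/90/120 m
  distortion in the other, around central goals; the dimensional sub-task
  (120 trials) pits a 5 m distortion in one shape dimension against a
  15/30/55 m distortion in the other, around corner goals.

All generators are pure functions of (seed, config): equal seeds reproduce
identical trial lists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DomainError, GenerationError
from .space import Position, SpaceConfig, euclidean_distance

__all__ = [
    "NavProtocol",
    "EstimationProtocol",
    "ForcedChoiceProtocol",
    "NavTrialSpec",
    "EstimationTrialSpec",
    "ForcedChoiceTrialSpec",
    "FeedbackScore",
    "generate_navigation_trials",
    "generate_estimation_trials",
    "generate_forced_choice_trials",
    "score_response",
    "slider_to_distance",
    "distance_to_slider",
]


# --------------------------------------------------------------------------
# protocol parameter blocks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NavProtocol:
    """Navigation-training design constants."""

    n_notify: int = 5          # training trials with automatic arrival notice
    n_press: int = 3           # training trials ended by button press
    min_test_trials: int = 14
    gg_test_trials: int = 28   # gamepad group: fixed test-trial count
    mg_time_budget_s: float = 54 * 60.0  # movement group: simulated task time
    mg_trial_pool: int = 40    # spec pool the simulator consumes under budget
    min_start_goal: float = 30.0
    notify_frac: float = 0.10  # arrival notice: within 10% of axis, both dims
    max_points: int = 20
    points_bin_pct: float = 5.0


@dataclass(frozen=True)
class EstimationProtocol:
    """Distance/direction estimation design constants."""

    n_practice: int = 3
    n_distance_bins: int = 4
    n_direction_bins: int = 9
    distance_min: float = 20.0
    distance_max: float = 180.0
    min_separation: float = 10.0   # between positions and from axis limits
    n_blocks: int = 4
    slider_increments: int = 28    # positions 0..28
    max_tries: int = 200_000

    @property
    def direction_bin_width(self) -> float:
        return 360.0 / self.n_direction_bins

    def distance_bin_edges(self) -> np.ndarray:
        """Equal-width bin edges over [distance_min, distance_max]."""
        return np.linspace(self.distance_min, self.distance_max, self.n_distance_bins + 1)


@dataclass(frozen=True)
class ForcedChoiceProtocol:
    """Two-alternative forced-choice design constants."""

    n_practice: int = 5
    n_blocks: int = 4
    time_limit_s: float = 5.0
    # similarity sub-task
    sim_near_distortion: float = 10.0
    sim_far_distortions: tuple = (60.0, 90.0, 120.0)
    sim_reps: int = 16                  # per (far distance x near condition)
    sim_goal_margin: tuple = (90.0, 100.0)  # distance to axis limit, per dim
    similar_dirs: tuple = (135.0, 315.0)
    dissimilar_dirs: tuple = (45.0, 225.0)
    # dimensional sub-task
    dim_near_distortion: float = 5.0
    dim_far_distortions: tuple = (15.0, 30.0, 55.0)
    dim_reps_per_scenario: int = 10     # per (far distance x distorted dim)
    dim_goal_margin: tuple = (4.0, 10.0)
    dim_colour_dirs: tuple = (135.0, 315.0)
    dim_colour_jitter: float = 10.0


# --------------------------------------------------------------------------
# trial spec types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NavTrialSpec:
    index: int
    phase: str          # train_notify | train_press | test
    start: Position
    goal: Position


@dataclass(frozen=True)
class EstimationTrialSpec:
    index: int
    block: int          # 1..4 for test trials, 0 for practice
    start: Position
    goal: Position
    distance_bin: int   # 1..4
    direction_bin: int  # 1..9
    practice: bool = False

    @property
    def distance(self) -> float:
        return euclidean_distance(self.start, self.goal)

    @property
    def direction(self) -> float:
        """True direction start -> goal, degrees in [0, 360)."""
        return math.degrees(
            math.atan2(self.goal.q2 - self.start.q2, self.goal.q1 - self.start.q1)
        ) % 360.0


@dataclass(frozen=True)
class ForcedChoiceTrialSpec:
    index: int
    block: int
    subtask: str        # similarity | dimensional
    A: Position
    B: Position
    C: Position
    correct: str        # "B" or "C"
    colour_theta: float
    practice: bool = False
    # similarity sub-task condition fields
    near_condition: str | None = None     # similar | dissimilar (the 10 m side)
    far_distortion: float | None = None
    colour_aligned: bool | None = None    # defined on dissimilar-correct trials
    # dimensional sub-task condition fields
    corner: str | None = None             # lower_left | upper_right
    near_dim: int | None = None           # dimension carrying the 5 m distortion
    distance_margin: float | None = None  # how much closer the correct option is


@dataclass(frozen=True)
class FeedbackScore:
    error_pct: float
    points: int
    message_class: str


# --------------------------------------------------------------------------
# navigation training
# --------------------------------------------------------------------------

def _uniform_position(rng: np.random.Generator, cfg: SpaceConfig) -> Position:
    return Position(*(rng.uniform(0.0, cfg.axis_length, size=2)))


def generate_navigation_trials(
    seed: int,
    group: str,
    cfg: SpaceConfig | None = None,
    proto: NavProtocol | None = None,
) -> list[NavTrialSpec]:
    """Generate the chained navigation-training trial list for one participant.

    Goals are uniform over the space, at least ``min_start_goal`` from the
    start; each trial starts at the previous trial's goal.  ``group`` is
    "GG" (gamepad: exactly ``gg_test_trials`` test trials) or "MG"
    (movement: a pool of ``mg_trial_pool`` test specs that the simulator
    consumes until the 54-minute budget is reached).
    """
    cfg = cfg or SpaceConfig()
    proto = proto or NavProtocol()
    if group not in ("MG", "GG"):
        raise DomainError(f"group must be 'MG' or 'GG', got {group!r}")
    rng = np.random.default_rng(seed)
    n_test = proto.gg_test_trials if group == "GG" else proto.mg_trial_pool
    phases = (
        ["train_notify"] * proto.n_notify
        + ["train_press"] * proto.n_press
        + ["test"] * n_test
    )
    trials = []
    start = _uniform_position(rng, cfg)
    for i, phase in enumerate(phases):
        while True:
            goal = _uniform_position(rng, cfg)
            if euclidean_distance(start, goal) >= proto.min_start_goal:
                break
        trials.append(NavTrialSpec(index=i, phase=phase, start=start, goal=goal))
        start = goal  # continuous navigation: next start = indicated goal
    return trials


_FEEDBACK_CLASSES = ("excellent", "good", "fair", "poor")


def score_response(
    response: Position,
    goal: Position,
    cfg: SpaceConfig | None = None,
    proto: NavProtocol | None = None,
) -> FeedbackScore:
    """Point feedback for a goal response.

    The error percentage is the response-goal distance over the space
    diagonal; errors fall into 5% bins, each bin dropping one point from the
    maximum of 20.  The message class labels the error quartile.
    """
    cfg = cfg or SpaceConfig()
    proto = proto or NavProtocol()
    error_pct = 100.0 * euclidean_distance(response, goal) / cfg.max_distance
    points = max(0, proto.max_points - int(math.floor(error_pct / proto.points_bin_pct)))
    msg = _FEEDBACK_CLASSES[min(int(error_pct // 25.0), 3)]
    return FeedbackScore(error_pct=error_pct, points=points, message_class=msg)


# --------------------------------------------------------------------------
# distance / direction estimation
# --------------------------------------------------------------------------

def slider_to_distance(slider_pos: int, cfg: SpaceConfig | None = None,
                       proto: EstimationProtocol | None = None) -> float:
    """Map a slider increment (0..28) to a distance in conceptual meters.

    The slider spans 0 to the time needed to traverse the space diagonal;
    at constant speed, time and distance are proportional, so the map is
    linear onto [0, axis_length * sqrt(2)].
    """
    cfg = cfg or SpaceConfig()
    proto = proto or EstimationProtocol()
    if not 0 <= slider_pos <= proto.slider_increments:
        raise DomainError(
            f"slider position {slider_pos} outside 0..{proto.slider_increments}"
        )
    return slider_pos / proto.slider_increments * cfg.max_distance


def distance_to_slider(distance: float, cfg: SpaceConfig | None = None,
                       proto: EstimationProtocol | None = None) -> int:
    """Nearest slider increment for a distance (inverse of the linear map)."""
    cfg = cfg or SpaceConfig()
    proto = proto or EstimationProtocol()
    pos = int(round(distance / cfg.max_distance * proto.slider_increments))
    return min(max(pos, 0), proto.slider_increments)


def generate_estimation_trials(
    seed: int,
    cfg: SpaceConfig | None = None,
    proto: EstimationProtocol | None = None,
) -> list[EstimationTrialSpec]:
    """Generate practice + factorial test trials for the estimation task.

    Every distance-bin x direction-bin cell is used exactly once (36 test
    trials), shuffled into 4 blocks of 9.  All test positions are at least
    ``min_separation`` from each other and from the axis limits; positions
    are rejection-sampled under those constraints.
    """
    cfg = cfg or SpaceConfig()
    proto = proto or EstimationProtocol()
    rng = np.random.default_rng(seed)
    edges = proto.distance_bin_edges()
    lo = proto.min_separation
    hi = cfg.axis_length - proto.min_separation

    cells = [
        (db, dirb)
        for db in range(1, proto.n_distance_bins + 1)
        for dirb in range(1, proto.n_direction_bins + 1)
    ]
    rng.shuffle(cells)

    used: list[Position] = []

    def far_enough(p: Position) -> bool:
        return all(euclidean_distance(p, q) >= proto.min_separation for q in used)

    trials = []
    tries = 0
    for k, (db, dirb) in enumerate(cells):
        while True:
            tries += 1
            if tries > proto.max_tries:
                raise GenerationError(
                    "estimation trial generation exhausted its retry budget"
                )
            d = rng.uniform(edges[db - 1], edges[db])
            theta = math.radians(
                rng.uniform((dirb - 1) * proto.direction_bin_width,
                            dirb * proto.direction_bin_width)
            )
            start = Position(rng.uniform(lo, hi), rng.uniform(lo, hi))
            goal = Position(start.q1 + d * math.cos(theta),
                            start.q2 + d * math.sin(theta))
            if not (lo <= goal.q1 <= hi and lo <= goal.q2 <= hi):
                continue
            if far_enough(start) and far_enough(goal) and \
                    euclidean_distance(start, goal) >= proto.min_separation:
                break
        used.extend([start, goal])
        trials.append(
            EstimationTrialSpec(
                index=k,
                block=k // (len(cells) // proto.n_blocks) + 1,
                start=start,
                goal=goal,
                distance_bin=db,
                direction_bin=dirb,
            )
        )

    practice = []
    for j in range(proto.n_practice):
        while True:
            d = rng.uniform(proto.distance_min, proto.distance_max)
            theta = rng.uniform(0.0, 2 * math.pi)
            start = Position(rng.uniform(lo, hi), rng.uniform(lo, hi))
            goal = Position(start.q1 + d * math.cos(theta),
                            start.q2 + d * math.sin(theta))
            if lo <= goal.q1 <= hi and lo <= goal.q2 <= hi:
                break
        practice.append(
            EstimationTrialSpec(
                index=-proto.n_practice + j,
                block=0,
                start=start,
                goal=goal,
                distance_bin=int(np.searchsorted(edges[1:-1], d) + 1),
                direction_bin=int(math.degrees(theta) % 360.0
                                  // proto.direction_bin_width) + 1,
                practice=True,
            )
        )
    return practice + trials


# --------------------------------------------------------------------------
# two-alternative forced choice
# --------------------------------------------------------------------------

def _offset(pos: Position, direction_deg: float, dist: float) -> Position:
    t = math.radians(direction_deg)
    return Position(pos.q1 + dist * math.cos(t), pos.q2 + dist * math.sin(t))


def _similarity_trials(rng, cfg: SpaceConfig, proto: ForcedChoiceProtocol):
    """Similarity sub-task: near (10 m) vs far (60/90/120 m) distortions in
    opposite visual-similarity conditions around central goals."""
    raw = []
    for far in proto.sim_far_distortions:
        for near_cond in ("similar", "dissimilar"):
            # colour alignment is defined when the correct (near) option lies
            # in the dissimilar condition; balance aligned/misaligned halves
            aligned_flags = [True] * (proto.sim_reps // 2) + [False] * (proto.sim_reps // 2)
            rng.shuffle(aligned_flags)
            for rep in range(proto.sim_reps):
                m0, m1 = proto.sim_goal_margin
                coords = []
                for _ in range(2):
                    margin = rng.uniform(m0, m1)
                    coords.append(margin if rng.random() < 0.5
                                  else cfg.axis_length - margin)
                A = Position(*coords)
                near_dir = float(rng.choice(
                    proto.similar_dirs if near_cond == "similar"
                    else proto.dissimilar_dirs))
                far_dir = float(rng.choice(
                    proto.dissimilar_dirs if near_cond == "similar"
                    else proto.similar_dirs))
                near = _offset(A, near_dir, proto.sim_near_distortion)
                far_pos = _offset(A, far_dir, far)
                if near_cond == "dissimilar":
                    aligned = aligned_flags[rep]
                    colour = near_dir if aligned else (near_dir + 180.0) % 360.0
                else:
                    aligned = None
                    colour = float(rng.choice(proto.dissimilar_dirs))
                if rng.random() < 0.5:
                    B, C, correct = near, far_pos, "B"
                else:
                    B, C, correct = far_pos, near, "C"
                raw.append(dict(
                    subtask="similarity", A=A, B=B, C=C, correct=correct,
                    colour_theta=colour, near_condition=near_cond,
                    far_distortion=far, colour_aligned=aligned,
                    distance_margin=far - proto.sim_near_distortion,
                ))
    return raw


def _dimensional_trials(rng, cfg: SpaceConfig, proto: ForcedChoiceProtocol):
    """Dimensional sub-task: 5 m vs 15/30/55 m distortions in different shape
    dimensions around corner goals (distortions point into the space)."""
    raw = []
    for corner in ("lower_left", "upper_right"):
        for far in proto.dim_far_distortions:
            for near_dim in (1, 2):
                for _ in range(proto.dim_reps_per_scenario):
                    m0, m1 = proto.dim_goal_margin
                    a = [rng.uniform(m0, m1), rng.uniform(m0, m1)]
                    if corner == "upper_right":
                        a = [cfg.axis_length - a[0], cfg.axis_length - a[1]]
                    A = Position(*a)
                    sign = 1.0 if corner == "lower_left" else -1.0
                    far_dim = 3 - near_dim
                    near = Position(
                        A.q1 + sign * proto.dim_near_distortion * (near_dim == 1),
                        A.q2 + sign * proto.dim_near_distortion * (near_dim == 2),
                    )
                    far_pos = Position(
                        A.q1 + sign * far * (far_dim == 1),
                        A.q2 + sign * far * (far_dim == 2),
                    )
                    colour = float(rng.choice(proto.dim_colour_dirs)) + rng.uniform(
                        -proto.dim_colour_jitter, proto.dim_colour_jitter)
                    if rng.random() < 0.5:
                        B, C, correct = near, far_pos, "B"
                    else:
                        B, C, correct = far_pos, near, "C"
                    raw.append(dict(
                        subtask="dimensional", A=A, B=B, C=C, correct=correct,
                        colour_theta=colour % 360.0, corner=corner,
                        near_dim=near_dim,
                        far_distortion=far,
                        distance_margin=far - proto.dim_near_distortion,
                    ))
    return raw


def generate_forced_choice_trials(
    seed: int,
    cfg: SpaceConfig | None = None,
    proto: ForcedChoiceProtocol | None = None,
) -> list[ForcedChoiceTrialSpec]:
    """Generate the intermixed forced-choice battery for one participant.

    96 similarity + 120 dimensional test trials shuffled into one random
    order over 4 blocks, preceded by 5 practice trials.  All three positions
    of a trial share one colour code, and the "correct" label always marks
    the option strictly closer to A.
    """
    cfg = cfg or SpaceConfig()
    proto = proto or ForcedChoiceProtocol()
    rng = np.random.default_rng(seed)
    raw = _similarity_trials(rng, cfg, proto) + _dimensional_trials(rng, cfg, proto)
    order = rng.permutation(len(raw))
    per_block = len(raw) // proto.n_blocks
    trials = []
    for i, j in enumerate(order):
        d = raw[j]
        trials.append(ForcedChoiceTrialSpec(
            index=i, block=i // per_block + 1, practice=False, **d))

    # practice trials reuse the similarity layout, flagged and excluded from
    # analysis by default
    practice_raw = _similarity_trials(rng, cfg, proto)
    picks = rng.choice(len(practice_raw), size=proto.n_practice, replace=False)
    practice = [
        ForcedChoiceTrialSpec(index=-proto.n_practice + k, block=0,
                              practice=True, **practice_raw[j])
        for k, j in enumerate(picks)
    ]
    return practice + trials
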