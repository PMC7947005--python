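"""Trial-level and participant-level behavioural measures.

The navigation measures are:

* accuracy — the fraction of a uniform Monte-Carlo null of possible
  end-positions (1000 by default) lying strictly further from the goal than
  the response; 0.5 is chance, 0.95 means only 5% of random positions beat
  the response;
* excess path length — (taken path - straight start-to-goal) / straight,
  a unitless inefficiency;
* navigation time — trial time minus goal retrievals and breaks (hint
  viewing optionally excluded too);
* segment speed — mean over continuous-movement segments of at least 10 m,
  excluding stationary periods and goal/hint viewing; a participant with no
  valid segment is marked excluded;
* per-dimension mean absolute goal errors (circle vs rectangle, through the
  participant's dimension assignment) and the per-participant correlation
  of trial accuracy with the goal's distance to the border.

Estimation measures are the minimal circular absolute angular error and the
per-participant correlation of estimated with true distances (computed in
the analysis layer from the response tables).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, LogFormatError
from .space import Position, SpaceConfig, border_distance, euclidean_distance

__all__ = [
    "accuracy",
    "excess_path",
    "navigation_time",
    "mean_speed",
    "dimensional_errors",
    "angular_error",
    "border_accuracy_correlation",
    "nav_trial_metrics",
]


def accuracy(
    response: Position,
    goal: Position,
    n_null: int = 1000,
    seed: int | np.random.Generator | None = None,
    cfg: SpaceConfig | None = None,
) -> float:
    """Monte-Carlo accuracy of a goal response.

    Draws ``n_null`` positions uniformly over the space and returns the
    fraction strictly further from the goal than the response (ties count
    as not further).
    """
    cfg = cfg or SpaceConfig()
    if n_null < 1:
        raise DomainError("n_null must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null = rng.uniform(0.0, cfg.axis_length, size=(n_null, 2))
    d_null = np.hypot(null[:, 0] - goal.q1, null[:, 1] - goal.q2)
    d_resp = euclidean_distance(response, goal)
    return float(np.mean(d_null > d_resp))


def _path_positions(log: pd.DataFrame) -> np.ndarray:
    if not log["t"].is_monotonic_increasing:
        raise LogFormatError("trajectory timestamps must be increasing")
    return log[["q1", "q2"]].to_numpy(dtype=float)


def excess_path(log: pd.DataFrame, goal: Position, start: Position | None = None) -> float:
    """Normalized excess path length of one trial.

    ``(sum of segment lengths - straight start-to-goal) / straight``.  The
    start defaults to the first logged position (the realized start, since
    trials chain at the previous indicated goal).
    """
    pos = _path_positions(log)
    if start is None:
        start = Position(*pos[0])
    optimal = euclidean_distance(start, goal)
    if optimal == 0.0:
        raise DomainError("zero optimal path length")
    taken = float(np.sum(np.hypot(*np.diff(pos, axis=0).T)))
    return (taken - optimal) / optimal


_EXCLUDED_FROM_TIME = ("goal_view", "break")


def navigation_time(log: pd.DataFrame, exclude_hint: bool = False) -> float:
    """Time spent navigating in one trial.

    Response time minus trial start minus the total duration of goal-view
    and break intervals (a row's event labels the interval up to the next
    row).  ``exclude_hint`` additionally removes hint-viewing time.
    """
    if len(log) < 2:
        return 0.0
    t = log["t"].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        raise LogFormatError("trajectory timestamps must be increasing")
    ev = log["event"].to_numpy()
    resp = np.flatnonzero(ev == "response")
    if len(resp) != 1:
        raise LogFormatError(f"expected exactly one response event, got {len(resp)}")
    end = resp[0]
    excluded = set(_EXCLUDED_FROM_TIME) | ({"hint"} if exclude_hint else set())
    total = t[end] - t[0]
    dur = np.diff(t)
    cut = sum(dur[i] for i in range(end) if ev[i] in excluded)
    return float(total - cut)


def mean_speed(
    log: pd.DataFrame,
    cfg: SpaceConfig | None = None,
    stationary_speed: float = 0.1,
    stationary_min_s: float = 1.0,
    min_segment_m: float = 10.0,
) -> float | None:
    """Mean movement speed over valid continuous-movement segments.

    Trials are split into segments of continuous movement; goal/hint viewing,
    breaks and stationary periods (speed below ``stationary_speed`` for at
    least ``stationary_min_s``) end a segment.  A segment contributes its
    mean velocity (distance / duration) when it covers at least
    ``min_segment_m``; the unweighted mean over segments is returned, or
    ``None`` when no segment qualifies (the participant is excluded from
    speed averaging).
    """
    cfg = cfg or SpaceConfig()
    speeds: list[float] = []
    for _, trial_log in log.groupby("trial", sort=True):
        t = trial_log["t"].to_numpy(dtype=float)
        pos = trial_log[["q1", "q2"]].to_numpy(dtype=float)
        ev = trial_log["event"].to_numpy()
        sp = trial_log["raw_speed"].to_numpy(dtype=float)
        n = len(t)
        if n < 2:
            continue
        dur = np.diff(t)
        disp = np.hypot(*np.diff(pos, axis=0).T)
        # classify each inter-row interval
        moving = np.array([
            ev[i] == "none" and sp[i] >= stationary_speed for i in range(n - 1)
        ])
        # short stationary blips (< stationary_min_s) do not break a segment
        i = 0
        while i < n - 1:
            if not moving[i] and ev[i] == "none":
                j = i
                while j < n - 1 and not moving[j] and ev[j] == "none":
                    j += 1
                if t[j] - t[i] < stationary_min_s:
                    moving[i:j] = True
                i = j
            else:
                i += 1
        # accumulate maximal moving runs
        i = 0
        while i < n - 1:
            if moving[i]:
                j = i
                dist = 0.0
                time = 0.0
                while j < n - 1 and moving[j]:
                    dist += disp[j]
                    time += dur[j]
                    j += 1
                if dist >= min_segment_m and time > 0:
                    speeds.append(dist / time)
                i = j
            else:
                i += 1
    if not speeds:
        return None
    return float(np.mean(speeds))


def dimensional_errors(
    responses, goals, circles_are_dim1: bool = True
) -> tuple[float, float]:
    """Mean absolute goal error per shape dimension: (circles, rectangles).

    ``responses`` and ``goals`` are equal-length sequences of positions; the
    per-axis errors are mapped to shapes through the participant's
    dimension assignment.
    """
    responses = list(responses)
    goals = list(goals)
    if len(responses) != len(goals):
        raise DomainError("responses and goals must have equal length")
    e1 = float(np.mean([abs(r.q1 - g.q1) for r, g in zip(responses, goals)]))
    e2 = float(np.mean([abs(r.q2 - g.q2) for r, g in zip(responses, goals)]))
    return (e1, e2) if circles_are_dim1 else (e2, e1)


def angular_error(estimate_theta, true_theta):
    """Minimal circular absolute difference in degrees, in [0, 180]."""
    diff = (np.asarray(estimate_theta, dtype=float)
            - np.asarray(true_theta, dtype=float)) % 360.0
    out = np.minimum(diff, 360.0 - diff)
    return float(out) if out.ndim == 0 else out


def border_accuracy_correlation(acc, border_dist) -> float:
    """Per-participant Pearson r of trial accuracy with goal border distance.

    Returns NaN (undefined-correlation marker) when either input has zero
    variance; requires at least 3 trials.
    """
    acc = np.asarray(acc, dtype=float)
    border_dist = np.asarray(border_dist, dtype=float)
    if len(acc) < 3:
        raise DomainError("need at least 3 trials for a correlation")
    if np.std(acc) == 0.0 or np.std(border_dist) == 0.0:
        return float("nan")
    return float(stats.pearsonr(acc, border_dist)[0])


def nav_trial_metrics(
    nav_log: pd.DataFrame,
    nav_responses: pd.DataFrame,
    cfg: SpaceConfig | None = None,
    n_null: int = 1000,
    seed: int = 0,
    test_only: bool = True,
) -> pd.DataFrame:
    """Tidy per-trial metric table (one row per agent x trial).

    Accuracy nulls are seeded per (agent, trial) from ``seed`` so the table
    is reproducible bit-for-bit.  ``test_only`` drops training trials.
    """
    cfg = cfg or SpaceConfig()
    rows = []
    log_groups = dict(tuple(nav_log.groupby(["agent_id", "trial"])))
    for rec in nav_responses.itertuples():
        if test_only and rec.phase != "test":
            continue
        goal = Position(rec.goal_q1, rec.goal_q2)
        resp = Position(rec.response_q1, rec.response_q2)
        trial_log = log_groups[(rec.agent_id, rec.trial)]
        rng = np.random.default_rng(
            np.random.SeedSequence((seed, int(rec.agent_id), int(rec.trial))))
        rows.append(dict(
            agent_id=rec.agent_id,
            trial=rec.trial,
            test_index=rec.test_index,
            accuracy=accuracy(resp, goal, n_null, rng, cfg),
            excess_path=excess_path(trial_log, goal),
            nav_time=navigation_time(trial_log),
            optimal_path=euclidean_distance(Position(rec.start_q1, rec.start_q2), goal),
            border_distance=border_distance(goal, cfg),
            error_dim1=abs(rec.response_q1 - rec.goal_q1),
            error_dim2=abs(rec.response_q2 - rec.goal_q2),
            null_seed=seed,
        ))
    return pd.DataFrame(rows)
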