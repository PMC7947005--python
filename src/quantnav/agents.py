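"""Synthetic participants ("agents") for the quantity-space protocol.

No generative model of human behaviour is claimed here: the agents are
statistical stand-ins whose logs carry the structure the analysis pipeline
assumes, with each effect controlled by one interpretable parameter:

* goal-placement noise that shrinks per test trial (``learning_rate``) and
  grows with the goal's distance to the border (``boundary_gain``), so
  navigation time falls over trials and accuracy is higher near boundaries;
* multiplicative Weber-like perception noise per shape dimension
  (``weber_fraction``), so small quantities (corner trials) are easier to
  tell apart than large ones and asymmetric pairs yield a dimensional bias;
* a visual-similarity bias (``similarity_bias``, conceptual meters): the
  more visually similar a target direction, the shorter it is judged, both
  in slider estimates and in forced-choice comparisons;
* direction estimates whose circular noise shrinks with distance;
* a logistic forced-choice rule over perceived distances with lapses, whose
  perception noise is scaled down after training (pre vs post).

Every stochastic draw flows from one seeded generator per agent; reruns
with the same seed are byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .errors import DomainError
from .protocols import (
    EstimationProtocol,
    EstimationTrialSpec,
    ForcedChoiceProtocol,
    ForcedChoiceTrialSpec,
    NavProtocol,
    NavTrialSpec,
    distance_to_slider,
    generate_estimation_trials,
    generate_forced_choice_trials,
    generate_navigation_trials,
    slider_to_distance,
)
from .similarity import SimilarityProfile, angular_profile, similarity_lookup
from .space import Position, SpaceConfig, border_distance, euclidean_distance

__all__ = [
    "AgentParams",
    "SimConfig",
    "CohortData",
    "simulate_navigation",
    "simulate_estimation",
    "simulate_forced_choice",
    "generate_cohort",
    "default_group_params",
]


@dataclass(frozen=True)
class AgentParams:
    """Noise / learning / bias parameters of one synthetic participant.

    Magnitude parameters are in conceptual meters unless noted.  Defaults
    produce a cohort with clear learning, boundary and similarity effects at
    roughly the performance level the protocol was designed around
    (accuracy well above chance, forced choice slightly above chance).
    """

    weber_fraction: tuple = (0.10, 0.10)  # (circles, rectangles) relative sd
    heading_noise_sd: float = 8.0         # deg, per movement step
    learning_rate: float = 0.02           # per test trial, multiplicative
    similarity_bias: float = 35.0         # m judged closer at full similarity
    boundary_gain: float = 0.6            # noise growth from border to centre
    goal_sd: float = 38.0                 # baseline goal-placement noise
    wander_sd: float = 25.0               # transient aim scatter while walking
    speed_mean: float = 9.0               # conceptual m/s
    speed_sd: float = 1.0
    pause_prob: float = 0.45              # per second of continuous movement
    lapse_rate: float = 0.02              # random forced-choice responses
    # estimation-task parameters
    est_alpha: float = 10.0               # additive slider bias
    est_beta_d: float = 0.9               # gain on true distance
    est_noise_sd: float = 70.0
    dir_sd0: float = 70.0                 # deg, circular noise at distance 0
    dir_distance_gain: float = 0.6        # fractional sd reduction at max dist
    # forced-choice parameters
    decision_temp: float = 25.0           # m, logistic temperature (0 = argmin)
    timeout_prob: float = 0.01
    circles_are_dim1: bool = True         # counterbalanced shape assignment
    seed: int = 0

    def __post_init__(self):
        for name in ("heading_noise_sd", "goal_sd", "wander_sd", "speed_sd",
                     "est_noise_sd", "dir_sd0", "decision_temp",
                     "similarity_bias"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        for name in ("pause_prob", "lapse_rate", "timeout_prob",
                     "dir_distance_gain"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise DomainError(f"{name} must be in [0, 1]")
        if any(w < 0 for w in self.weber_fraction):
            raise DomainError("weber_fraction entries must be >= 0")

    def weber_for_dim(self, dim: int) -> float:
        """Weber fraction for space dimension 1 or 2, via shape assignment."""
        w_circ, w_rect = self.weber_fraction
        if dim == 1:
            return w_circ if self.circles_are_dim1 else w_rect
        return w_rect if self.circles_are_dim1 else w_circ

    def learning_factor(self, test_trial_index: int) -> float:
        return math.exp(-self.learning_rate * max(test_trial_index, 0))


@dataclass(frozen=True)
class SimConfig:
    """Discretisation and event-rate settings of the walk simulator."""

    dt: float = 0.5                 # s per simulated step
    replan_s: float = 2.0           # redraw the perceived goal this often
    arrive_radius: float = 4.0      # m: home in exactly once this close
    initial_goal_view_s: float = 2.5
    goal_view_rate: float = 0.02    # per second, extra goal retrievals
    goal_view_s: float = 2.5
    hint_rate: float = 0.05         # per second, training trials only
    hint_s: float = 1.5
    break_rate: float = 0.001       # per second
    break_s: float = 20.0
    pause_s: float = 7.0
    max_trial_s: float = 600.0
    q_floor: float = 20.0           # Weber noise floor (quantity units)
    post_training_trials: int = 28  # learning credit applied to the post test


TRAJ_COLUMNS = ["agent_id", "trial", "t", "q1", "q2", "theta", "raw_speed", "event"]
EVENTS = ("none", "goal_view", "hint", "break", "response")


def _clamp(p: Position, cfg: SpaceConfig) -> Position:
    L = cfg.axis_length
    return Position(min(max(p.q1, 0.0), L), min(max(p.q2, 0.0), L))


def _perceived_goal(goal: Position, sd: float, rng, cfg: SpaceConfig) -> Position:
    if sd == 0.0:
        return goal
    return _clamp(Position(goal.q1 + rng.normal(0.0, sd),
                           goal.q2 + rng.normal(0.0, sd)), cfg)


def simulate_navigation(
    agent: AgentParams,
    trials: list[NavTrialSpec],
    cfg: SpaceConfig | None = None,
    sim: SimConfig | None = None,
    rng: np.random.Generator | None = None,
    proto: NavProtocol | None = None,
    time_budget_s: float | None = None,
    agent_id: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the navigation training and return (trajectory, responses).

    Per trial the agent commits to one noisy goal percept (sd ``goal_sd *
    learning_factor * border factor`` — the response error) and walks toward
    transient aim points scattered around it (sd ``wander_sd * learning
    factor``, redrawn every ``replan_s`` — the path inefficiency), homing in
    exactly once close to the percept.  "notify" training trials end
    automatically when the true goal is within 10% on both dimensions.
    Trials chain: each starts where the previous response was placed.  If
    ``time_budget_s`` is given (movement group), test trials stop once the
    cumulative task time exceeds it and the minimum test count is met.
    """
    cfg = cfg or SpaceConfig()
    sim = sim or SimConfig()
    proto = proto or NavProtocol()
    rng = rng if rng is not None else np.random.default_rng(agent.seed)

    rows: list[tuple] = []
    resp_rows: list[dict] = []
    t_task = 0.0
    test_done = 0
    pos = trials[0].start

    for trial in trials:
        if (
            trial.phase == "test"
            and time_budget_s is not None
            and test_done >= proto.min_test_trials
            and t_task >= time_budget_s
        ):
            break
        goal = trial.goal
        lf = agent.learning_factor(test_done if trial.phase == "test" else 0)
        bf = 1.0 + agent.boundary_gain * (
            border_distance(goal, cfg) / (cfg.axis_length / 2.0)
        )
        sd = agent.goal_sd * lf * bf
        start = pos
        t = t_task
        t0 = t
        notify_range = proto.notify_frac * cfg.axis_length

        # the committed goal percept (drawn once: the response error) and a
        # transient aim point around it (redrawn: the path wander)
        target = _perceived_goal(goal, sd, rng, cfg)
        aim = _perceived_goal(target, agent.wander_sd * lf, rng, cfg)
        since_replan = 0.0
        moved_cont = 0.0
        n_views, n_hints = 0, 0
        theta = rng.uniform(0.0, 360.0)

        # initial goal cue
        rows.append((agent_id, trial.index, t, pos.q1, pos.q2, theta, 0.0, "goal_view"))
        t += sim.initial_goal_view_s
        n_views += 1

        arrived = False
        while not arrived and (t - t0) < sim.max_trial_s:
            if since_replan >= sim.replan_s:
                aim = _perceived_goal(target, agent.wander_sd * lf, rng, cfg)
                since_replan = 0.0
            # optional interruptions
            u = rng.random()
            if u < sim.break_rate * sim.dt:
                rows.append((agent_id, trial.index, t, pos.q1, pos.q2, theta, 0.0, "break"))
                t += sim.break_s
                moved_cont = 0.0
                continue
            if u < (sim.break_rate + sim.goal_view_rate) * sim.dt:
                rows.append((agent_id, trial.index, t, pos.q1, pos.q2, theta, 0.0, "goal_view"))
                t += sim.goal_view_s
                n_views += 1
                moved_cont = 0.0
                continue
            if trial.phase != "test" and u < (
                sim.break_rate + sim.goal_view_rate + sim.hint_rate
            ) * sim.dt:
                rows.append((agent_id, trial.index, t, pos.q1, pos.q2, theta, 0.0, "hint"))
                t += sim.hint_s
                n_hints += 1
                moved_cont = 0.0
                continue
            # stationary pause after each full second of continuous movement
            if moved_cont >= 1.0:
                moved_cont = 0.0
                if rng.random() < agent.pause_prob:
                    rows.append((agent_id, trial.index, t, pos.q1, pos.q2, theta, 0.0, "none"))
                    t += sim.pause_s
                    since_replan += sim.pause_s
                    continue

            dist_target = math.hypot(target.q1 - pos.q1, target.q2 - pos.q2)
            dx, dy = aim.q1 - pos.q1, aim.q2 - pos.q2
            theta = math.degrees(math.atan2(dy, dx)) % 360.0
            if agent.heading_noise_sd > 0.0:
                kappa = (180.0 / (math.pi * agent.heading_noise_sd)) ** 2
                theta = (theta + math.degrees(rng.vonmises(0.0, kappa))) % 360.0
            speed = max(agent.speed_mean + (rng.normal(0.0, agent.speed_sd)
                                            if agent.speed_sd > 0 else 0.0), 0.1)
            if dist_target <= max(speed * sim.dt, sim.arrive_radius):
                # final partial step: land exactly on the committed percept
                step_t = dist_target / speed if speed > 0 else sim.dt
                theta = math.degrees(math.atan2(target.q2 - pos.q2,
                                                target.q1 - pos.q1)) % 360.0
                rows.append((agent_id, trial.index, t, pos.q1, pos.q2, theta, speed, "none"))
                t += step_t
                pos = target
                arrived = True
                break
            rows.append((agent_id, trial.index, t, pos.q1, pos.q2, theta, speed, "none"))
            rad = math.radians(theta)
            pos = _clamp(Position(pos.q1 + speed * sim.dt * math.cos(rad),
                                  pos.q2 + speed * sim.dt * math.sin(rad)), cfg)
            t += sim.dt
            since_replan += sim.dt
            moved_cont += sim.dt
            if trial.phase == "train_notify" and (
                abs(pos.q1 - goal.q1) <= notify_range
                and abs(pos.q2 - goal.q2) <= notify_range
            ):
                arrived = True

        response = pos
        rows.append((agent_id, trial.index, t, response.q1, response.q2, theta, 0.0, "response"))
        resp_rows.append(dict(
            agent_id=agent_id, trial=trial.index, phase=trial.phase,
            test_index=test_done if trial.phase == "test" else -1,
            start_q1=start.q1, start_q2=start.q2,
            goal_q1=goal.q1, goal_q2=goal.q2,
            response_q1=response.q1, response_q2=response.q2,
            t_start=t0, t_end=t, n_goal_views=n_views, n_hints=n_hints,
        ))
        if trial.phase == "test":
            test_done += 1
        t_task = t
        # continuous navigation: next trial starts at the indicated goal

    traj = pd.DataFrame(rows, columns=TRAJ_COLUMNS)
    return traj, pd.DataFrame(resp_rows)


def simulate_estimation(
    agent: AgentParams,
    trials: list[EstimationTrialSpec],
    profile: SimilarityProfile | None = None,
    cfg: SpaceConfig | None = None,
    rng: np.random.Generator | None = None,
    proto: EstimationProtocol | None = None,
    agent_id: int = 0,
) -> pd.DataFrame:
    """Simulate the distance/direction estimation responses.

    Slider distance: ``est_alpha + est_beta_d * d - similarity_bias *
    sim(theta) + noise``, snapped to the 29-increment slider.  Direction:
    the true angle plus wrapped-normal noise whose sd shrinks linearly with
    distance (``dir_sd0 * (1 - dir_distance_gain * d / d_max)``).
    """
    cfg = cfg or SpaceConfig()
    proto = proto or EstimationProtocol()
    profile = profile if profile is not None else angular_profile(cfg=cfg)
    rng = rng if rng is not None else np.random.default_rng(agent.seed)

    d = np.array([t.distance for t in trials])
    theta = np.array([t.direction for t in trials])
    sim_val = similarity_lookup(theta, profile)

    est = (
        agent.est_alpha
        + agent.est_beta_d * d
        - agent.similarity_bias * sim_val
        + (rng.normal(0.0, agent.est_noise_sd, size=len(d))
           if agent.est_noise_sd > 0 else 0.0)
    )
    slider = np.array([distance_to_slider(e, cfg, proto) for e in est])
    est_snapped = np.array([slider_to_distance(s, cfg, proto) for s in slider])

    sd_dir = agent.dir_sd0 * (1.0 - agent.dir_distance_gain * d / cfg.max_distance)
    est_theta = (theta + (rng.normal(0.0, 1.0, size=len(d)) * sd_dir
                          if agent.dir_sd0 > 0 else 0.0)) % 360.0

    return pd.DataFrame(dict(
        agent_id=agent_id,
        trial=[t.index for t in trials],
        block=[t.block for t in trials],
        practice=[t.practice for t in trials],
        distance_bin=[t.distance_bin for t in trials],
        direction_bin=[t.direction_bin for t in trials],
        true_distance=d,
        true_theta=theta,
        similarity=sim_val,
        slider_pos=slider,
        est_distance=est_snapped,
        est_theta=est_theta,
    ))


def simulate_forced_choice(
    agent: AgentParams,
    trials: list[ForcedChoiceTrialSpec],
    profile: SimilarityProfile | None = None,
    cfg: SpaceConfig | None = None,
    rng: np.random.Generator | None = None,
    sim: SimConfig | None = None,
    timepoint: str = "pre",
    agent_id: int = 0,
) -> pd.DataFrame:
    """Simulate one pass of the forced-choice battery.

    Each coordinate of A, B and C is perceived with Weber noise (sd =
    weber_fraction * max(q, q_floor), dimension-specific); options are
    compared on perceived distance minus the similarity bonus, through a
    logistic choice rule with lapses and rare timeouts.  At ``timepoint=
    "post"``, perception noise is scaled by the learning factor accumulated
    over the navigation training.
    """
    cfg = cfg or SpaceConfig()
    sim = sim or SimConfig()
    profile = profile if profile is not None else angular_profile(cfg=cfg)
    rng = rng if rng is not None else np.random.default_rng(agent.seed)
    if timepoint not in ("pre", "post"):
        raise DomainError("timepoint must be 'pre' or 'post'")
    scale = 1.0 if timepoint == "pre" else agent.learning_factor(sim.post_training_trials)

    rows = []
    for tr in trials:
        def perceive(p: Position) -> np.ndarray:
            out = np.empty(2)
            for i, q in enumerate((p.q1, p.q2)):
                w = agent.weber_for_dim(i + 1) * scale
                out[i] = q + (rng.normal(0.0, w * max(q, sim.q_floor)) if w > 0 else 0.0)
            return out

        a_hat, b_hat, c_hat = perceive(tr.A), perceive(tr.B), perceive(tr.C)
        d_b = float(np.hypot(*(a_hat - b_hat)))
        d_c = float(np.hypot(*(a_hat - c_hat)))

        def sim_of(p: Position) -> float:
            ang = math.degrees(math.atan2(p.q2 - tr.A.q2, p.q1 - tr.A.q1))
            return float(similarity_lookup(ang, profile))

        u_b = d_b - agent.similarity_bias * sim_of(tr.B)
        u_c = d_c - agent.similarity_bias * sim_of(tr.C)

        if rng.random() < agent.timeout_prob:
            choice, correct = None, np.nan
        elif rng.random() < agent.lapse_rate:
            choice = "B" if rng.random() < 0.5 else "C"
            correct = float(choice == tr.correct)
        else:
            if agent.decision_temp == 0.0:
                choice = "B" if u_b < u_c else "C"
            else:
                p_b = 1.0 / (1.0 + math.exp(-(u_c - u_b) / agent.decision_temp))
                choice = "B" if rng.random() < p_b else "C"
            correct = float(choice == tr.correct)

        rows.append(dict(
            agent_id=agent_id, timepoint=timepoint, trial=tr.index,
            block=tr.block, practice=tr.practice, subtask=tr.subtask,
            near_condition=tr.near_condition, far_distortion=tr.far_distortion,
            colour_aligned=tr.colour_aligned, corner=tr.corner,
            near_dim=tr.near_dim, distance_margin=tr.distance_margin,
            colour_theta=tr.colour_theta,
            choice=choice, correct_option=tr.correct,
            timeout=choice is None, correct=correct,
        ))
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

def default_group_params(group: str) -> AgentParams:
    """Template parameters per group.

    Both groups share learning, boundary and similarity effects; the gamepad
    group carries a mild Weber asymmetry favouring rectangles (a
    dimensional bias), the movement group is symmetric but slower (longer
    trial times through a higher pause rate).
    """
    if group == "MG":
        return AgentParams(weber_fraction=(0.10, 0.10), pause_prob=0.53)
    if group == "GG":
        return AgentParams(weber_fraction=(0.125, 0.085), pause_prob=0.42)
    raise DomainError(f"group must be 'MG' or 'GG', got {group!r}")


@dataclass
class CohortData:
    """Full synthetic dataset of one simulated study run."""

    cfg: SpaceConfig
    master_seed: int
    agents: pd.DataFrame
    nav_log: pd.DataFrame
    nav_responses: pd.DataFrame
    est_responses: pd.DataFrame
    fc_responses: pd.DataFrame


def generate_cohort(
    n_per_group: int = 45,
    master_seed: int = 0,
    cfg: SpaceConfig | None = None,
    sim: SimConfig | None = None,
    group_params: dict | None = None,
    groups: tuple = ("MG", "GG"),
    nav_proto: NavProtocol | None = None,
    est_proto: EstimationProtocol | None = None,
    fc_proto: ForcedChoiceProtocol | None = None,
) -> CohortData:
    """Simulate both groups through the full protocol.

    Per-agent seeds derive deterministically from ``master_seed`` via
    ``numpy.random.SeedSequence`` spawning; the shape-to-dimension
    assignment is counterbalanced within each group.  ``group_params`` maps
    group label to an :class:`AgentParams` template (seed and assignment are
    overwritten per agent).
    """
    if n_per_group < 2:
        raise DomainError("n_per_group must be >= 2")
    cfg = cfg or SpaceConfig()
    sim = sim or SimConfig()
    nav_proto = nav_proto or NavProtocol()
    est_proto = est_proto or EstimationProtocol()
    fc_proto = fc_proto or ForcedChoiceProtocol()
    group_params = group_params or {g: default_group_params(g) for g in groups}
    profile = angular_profile(cfg=cfg)

    root = np.random.SeedSequence(master_seed)
    children = root.spawn(len(groups) * n_per_group)

    agent_rows, navs, nav_resps, ests, fcs = [], [], [], [], []
    aid = 0
    for gi, group in enumerate(groups):
        template = group_params[group]
        for j in range(n_per_group):
            child = children[gi * n_per_group + j]
            seed = int(child.generate_state(1)[0] % (2**31))
            agent = replace(template, seed=seed, circles_are_dim1=(j % 2 == 0))
            rng = np.random.default_rng(child)
            trial_seeds = rng.integers(0, 2**31, size=3)

            nav_trials = generate_navigation_trials(
                int(trial_seeds[0]), group, cfg, nav_proto)
            est_trials = generate_estimation_trials(
                int(trial_seeds[1]), cfg, est_proto)
            fc_trials = generate_forced_choice_trials(
                int(trial_seeds[2]), cfg, fc_proto)

            fc_pre = simulate_forced_choice(
                agent, fc_trials, profile, cfg, rng, sim, "pre", aid)
            budget = nav_proto.mg_time_budget_s if group == "MG" else None
            traj, resp = simulate_navigation(
                agent, nav_trials, cfg, sim, rng, nav_proto, budget, aid)
            est = simulate_estimation(
                agent, est_trials, profile, cfg, rng, est_proto, aid)
            fc_post = simulate_forced_choice(
                agent, fc_trials, profile, cfg, rng, sim, "post", aid)

            agent_rows.append(dict(
                agent_id=aid, group=group, seed=seed,
                circles_are_dim1=agent.circles_are_dim1,
                **{f"param_{k}": (str(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(agent).items()
                   if k not in ("seed", "circles_are_dim1")},
            ))
            navs.append(traj)
            nav_resps.append(resp)
            ests.append(est)
            fcs.extend([fc_pre, fc_post])
            aid += 1

    return CohortData(
        cfg=cfg,
        master_seed=master_seed,
        agents=pd.DataFrame(agent_rows),
        nav_log=pd.concat(navs, ignore_index=True),
        nav_responses=pd.concat(nav_resps, ignore_index=True),
        est_responses=pd.concat(ests, ignore_index=True),
        fc_responses=pd.concat(fcs, ignore_index=True),
    )
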