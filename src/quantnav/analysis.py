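"""End-to-end analysis of a simulated cohort dataset.

Mirrors the behavioural analysis list of the protocol:

* general navigation performance — accuracy vs chance (0.5), group
  comparisons (Welch t + JZS Bayes factor) of accuracy, navigation time and
  excess path; border-distance/accuracy correlations; dimensional bias in
  goal errors;
* learning — per-participant regressions of navigation time, path length
  (controlling for optimal length) and accuracy on trial number, taken to
  the group level with sign-flip permutation tests;
* estimation — distance-estimate correlations, two-regressor (distance +
  visual similarity) models of the estimates, absolute angular error vs the
  90-degree chance level and its two-regressor model;
* forced choice — mixed ANOVAs for the visual-similarity and colour-priming
  designs (group x time point x condition) and the dimensional-bias design
  (group x time point x shape x corner) with pairwise shape post-hocs.

Every permutation-based result records its seed and permutation count.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .agents import CohortData
from .inference import (
    StatResult,
    jzs_bayes_factor,
    mixed_anova,
    one_sample_t,
    pairwise_posthoc,
    pearson_group_test,
    per_participant_glm,
    signflip_test,
    welch_t,
)
from .metrics import (
    angular_error,
    border_accuracy_correlation,
    mean_speed,
    nav_trial_metrics,
)
from .space import SpaceConfig

__all__ = ["AnalysisResult", "analyze_cohort", "participant_summary",
           "render_report", "results_to_json"]

ANGULAR_CHANCE_DEG = 90.0
ACCURACY_CHANCE = 0.5


@dataclass
class AnalysisResult:
    """All statistics of one pipeline run, keyed by analysis name."""

    stats: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def participant_summary(
    cohort: CohortData,
    cfg: SpaceConfig | None = None,
    n_null: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trial and per-participant navigation metric tables."""
    cfg = cfg or cohort.cfg
    trial = nav_trial_metrics(cohort.nav_log, cohort.nav_responses, cfg,
                              n_null=n_null, seed=seed)
    groups = cohort.agents.set_index("agent_id")["group"]
    circ1 = cohort.agents.set_index("agent_id")["circles_are_dim1"]

    rows = []
    for aid, sub in trial.groupby("agent_id"):
        log = cohort.nav_log[cohort.nav_log["agent_id"] == aid]
        test_trials = sub["trial"].unique()
        speed = mean_speed(log[log["trial"].isin(test_trials)], cfg)
        e1, e2 = sub["error_dim1"].mean(), sub["error_dim2"].mean()
        err_c, err_r = (e1, e2) if circ1.loc[aid] else (e2, e1)
        rows.append(dict(
            agent_id=aid,
            group=groups.loc[aid],
            n_test_trials=len(sub),
            accuracy=sub["accuracy"].mean(),
            excess_path=sub["excess_path"].mean(),
            nav_time=sub["nav_time"].mean(),
            mean_speed=speed if speed is not None else np.nan,
            speed_excluded=speed is None,
            border_r=border_accuracy_correlation(
                sub["accuracy"], sub["border_distance"]),
            error_circles=err_c,
            error_rectangles=err_r,
        ))
    return trial, pd.DataFrame(rows)


def _learning_tstats(trial: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-participant regression t-statistics for the learning analyses."""
    out = []
    t_time = per_participant_glm(trial, "nav_time", ["test_index"])
    t_acc = per_participant_glm(trial, "accuracy", ["test_index"])
    # path length regressed on optimal length and trial number
    trial = trial.assign(path_len=(1.0 + trial["excess_path"]) * trial["optimal_path"])
    t_path = per_participant_glm(trial, "path_len", ["optimal_path", "test_index"])
    t_path = t_path[t_path["regressor"] == "test_index"]
    for name, tab in (("nav_time", t_time), ("path_len", t_path),
                      ("accuracy", t_acc)):
        tab = tab[tab["regressor"] == "test_index"].copy()
        tab["measure"] = name
        tab["group"] = tab["subject"].map(groups)
        out.append(tab)
    return pd.concat(out, ignore_index=True)


def analyze_cohort(
    cohort: CohortData,
    n_perm: int = 10_000,
    n_null: int = 1000,
    seed: int = 0,
) -> AnalysisResult:
    """Run the full behavioural analysis on a cohort dataset."""
    cfg = cohort.cfg
    rng = np.random.default_rng(seed)
    res = AnalysisResult(meta=dict(n_perm=n_perm, n_null=n_null, seed=seed,
                                   master_seed=cohort.master_seed))
    groups = cohort.agents.set_index("agent_id")["group"]
    labels = list(dict.fromkeys(groups))

    trial, per = participant_summary(cohort, cfg, n_null=n_null, seed=seed)
    res.tables["trial_metrics"] = trial
    res.tables["participant_metrics"] = per
    by_group = {g: per[per["group"] == g] for g in labels}

    # ---- general performance -------------------------------------------
    for g in labels:
        res.stats[f"accuracy_vs_chance_{g}"] = one_sample_t(
            by_group[g]["accuracy"], mu0=ACCURACY_CHANCE)
    for measure in ("accuracy", "nav_time", "excess_path"):
        a, b = (by_group[g][measure] for g in labels[:2])
        r = welch_t(a, b)
        r.bf10 = jzs_bayes_factor(a, b)
        res.stats[f"{measure}_between_groups"] = r
    for g in labels:
        res.stats[f"border_corr_{g}"] = one_sample_t(
            by_group[g]["border_r"].dropna(), mu0=0.0)
    res.stats["border_corr_between_groups"] = welch_t(
        *(by_group[g]["border_r"].dropna() for g in labels[:2]))
    for g in labels:
        res.stats[f"dimensional_bias_{g}"] = one_sample_t(
            by_group[g]["error_circles"] - by_group[g]["error_rectangles"])
    res.stats["dimensional_bias_between_groups"] = welch_t(
        *(by_group[g]["error_circles"] - by_group[g]["error_rectangles"]
          for g in labels[:2]))

    # ---- learning ------------------------------------------------------
    learn = _learning_tstats(trial, groups)
    res.tables["learning_tstats"] = learn
    tails = {"nav_time": "less", "path_len": "less", "accuracy": "greater"}
    for measure in ("nav_time", "path_len", "accuracy"):
        sub = learn[learn["measure"] == measure]
        for g in labels:
            res.stats[f"learning_{measure}_{g}"] = signflip_test(
                sub[sub["group"] == g]["t"], n_perm=n_perm,
                tail=tails[measure], seed=rng)
        a, b = (sub[sub["group"] == g]["t"] for g in labels[:2])
        r = welch_t(a, b)
        r.bf10 = jzs_bayes_factor(a, b)
        res.stats[f"learning_{measure}_between_groups"] = r

    # ---- distance / direction estimation -------------------------------
    est = cohort.est_responses
    est = est[~est["practice"]].copy()
    est["group"] = est["agent_id"].map(groups)
    est["abs_ang_err"] = angular_error(est["est_theta"], est["true_theta"])

    r_per = est.groupby("agent_id").apply(
        lambda s: s["est_distance"].corr(s["true_distance"]),
        include_groups=False)
    res.tables["distance_r"] = r_per.rename("r").reset_index().assign(
        group=lambda d: d["agent_id"].map(groups))
    for g in labels:
        res.stats[f"distance_r_{g}"] = pearson_group_test(
            r_per[groups.loc[r_per.index] == g])
    a, b = (r_per[groups.loc[r_per.index] == g] for g in labels[:2])
    r = welch_t(a.dropna(), b.dropna())
    r.bf10 = jzs_bayes_factor(a.dropna(), b.dropna())
    res.stats["distance_r_between_groups"] = r

    glm_d = per_participant_glm(est, "est_distance",
                                ["true_distance", "similarity"])
    glm_d["group"] = glm_d["subject"].map(groups)
    res.tables["estimation_glm"] = glm_d
    for reg in ("true_distance", "similarity"):
        for g in labels:
            res.stats[f"estimate_glm_{reg}_{g}"] = signflip_test(
                glm_d[(glm_d["group"] == g) & (glm_d["regressor"] == reg)]["t"],
                n_perm=n_perm, tail="two-sided", seed=rng)

    ang = est.groupby("agent_id")["abs_ang_err"].mean()
    for g in labels:
        res.stats[f"angular_error_{g}"] = one_sample_t(
            ang[groups.loc[ang.index] == g], mu0=ANGULAR_CHANCE_DEG,
            tail="less")
    a, b = (ang[groups.loc[ang.index] == g] for g in labels[:2])
    r = welch_t(a, b)
    r.bf10 = jzs_bayes_factor(a, b)
    res.stats["angular_error_between_groups"] = r

    glm_a = per_participant_glm(est, "abs_ang_err",
                                ["true_distance", "similarity"])
    glm_a["group"] = glm_a["subject"].map(groups)
    res.tables["angular_glm"] = glm_a
    for reg in ("true_distance", "similarity"):
        for g in labels:
            res.stats[f"angular_glm_{reg}_{g}"] = signflip_test(
                glm_a[(glm_a["group"] == g) & (glm_a["regressor"] == reg)]["t"],
                n_perm=n_perm, tail="two-sided", seed=rng)

    # ---- forced choice --------------------------------------------------
    fc = cohort.fc_responses
    fc = fc[~fc["practice"] & ~fc["timeout"]].copy()
    fc["group"] = fc["agent_id"].map(groups)

    sim_fc = fc[fc["subtask"] == "similarity"].copy()
    # "high" similarity condition: the correct (near) option is the
    # visually similar one
    sim_fc["similarity_cond"] = np.where(
        sim_fc["near_condition"] == "similar", "high", "low")
    acc_sim = (sim_fc.groupby(["agent_id", "group", "timepoint",
                               "similarity_cond"], observed=True)["correct"]
               .mean().mul(100).rename("pct_correct").reset_index())
    res.tables["fc_similarity_accuracy"] = acc_sim
    res.stats["fc_similarity_anova"] = mixed_anova(
        acc_sim, "pct_correct", "agent_id", "group",
        ["timepoint", "similarity_cond"])

    prime = sim_fc[sim_fc["near_condition"] == "dissimilar"].copy()
    prime["alignment"] = np.where(prime["colour_aligned"].astype(bool),
                                  "aligned", "misaligned")
    acc_prime = (prime.groupby(["agent_id", "group", "timepoint", "alignment"],
                               observed=True)["correct"]
                 .mean().mul(100).rename("pct_correct").reset_index())
    res.stats["fc_priming_anova"] = mixed_anova(
        acc_prime, "pct_correct", "agent_id", "group",
        ["timepoint", "alignment"])

    dim_fc = fc[fc["subtask"] == "dimensional"].copy()
    circ1 = cohort.agents.set_index("agent_id")["circles_are_dim1"]
    dim_fc["shape"] = np.where(
        dim_fc["agent_id"].map(circ1).astype(bool)
        == (dim_fc["near_dim"] == 1),
        "circles", "rectangles")
    acc_dim = (dim_fc.groupby(["agent_id", "group", "timepoint", "shape",
                               "corner"], observed=True)["correct"]
               .mean().mul(100).rename("pct_correct").reset_index())
    res.tables["fc_dimensional_accuracy"] = acc_dim
    res.stats["fc_dimensional_anova"] = mixed_anova(
        acc_dim, "pct_correct", "agent_id", "group",
        ["timepoint", "shape", "corner"])
    res.tables["fc_shape_posthoc"] = pairwise_posthoc(
        acc_dim, "pct_correct", "agent_id", "shape",
        by=["group", "timepoint", "corner"], correction="bonferroni")

    return res


# --------------------------------------------------------------------------
# reporting
# --------------------------------------------------------------------------

def _fmt_stat(name: str, s: StatResult) -> str:
    bits = [f"{name}: {s.kind}", f"stat={s.statistic:.4f}"]
    if s.df is not None:
        bits.append(f"df={s.df if not isinstance(s.df, tuple) else s.df}")
    bits.append(f"p={s.p:.4g}")
    if s.z is not None:
        bits.append(f"z={s.z:.3f}")
    if s.bf10 is not None:
        bits.append(f"BF10={s.bf10:.4g}")
    return "  ".join(str(b) for b in bits)


def render_report(res: AnalysisResult) -> str:
    """Human-readable summary of an :class:`AnalysisResult`."""
    lines = ["quantnav analysis report", "=" * 40,
             f"meta: {json.dumps(res.meta)}", ""]
    for name, s in res.stats.items():
        lines.append(_fmt_stat(name, s))
        if s.effect_table is not None:
            lines.append(s.effect_table.to_string(index=False,
                                                  float_format="%.4g"))
            lines.append("")
    return "\n".join(lines) + "\n"


def results_to_json(res: AnalysisResult) -> str:
    """Serialize all statistics (effect tables as records) to JSON."""
    out = {"meta": res.meta, "stats": {}}
    for name, s in res.stats.items():
        d = asdict(s)
        if s.effect_table is not None:
            d["effect_table"] = s.effect_table.to_dict(orient="records")
        out["stats"][name] = d
    return json.dumps(out, indent=2, default=float)
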