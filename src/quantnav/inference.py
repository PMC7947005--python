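"""Group-level statistics for the behavioural pipeline.

The workhorse is a two-stage scheme: a general linear model is fit per
participant and the t-statistic of the regressor of interest is carried to
the group level, where a sign-flipping permutation test builds the null
distribution of the mean t (10,000 flips by default).  Because the p-value
is the proportion of permuted means at least as extreme as the observed
one, it is floored at 1/n_perm — with 10,000 permutations the smallest
attainable p is 0.0001, whose z-equivalent (inverse normal CDF of 1 - p)
is 3.719.

Around that sit classical tools: one-sample and Welch two-sample t-tests,
JZS (Cauchy-prior, scale sqrt(2)/2) Bayes-factor t-tests, balanced mixed
ANOVAs with one between-subject factor and any number of within factors,
Bonferroni pairwise post-hocs, a noncentral-t power/sample-size solver, and
a group test on per-participant Pearson correlations (tested raw, without
Fisher transform).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin
import statsmodels.api as sm
from scipy import stats

from .errors import DesignError, DomainError

__all__ = [
    "StatResult",
    "per_participant_glm",
    "signflip_test",
    "one_sample_t",
    "welch_t",
    "jzs_bayes_factor",
    "mixed_anova",
    "pairwise_posthoc",
    "power_sample_size",
    "pearson_group_test",
]


@dataclass
class StatResult:
    """Outcome of one statistical test, with provenance metadata."""

    kind: str
    statistic: float
    df: float | tuple | None
    p: float
    z: float | None = None
    bf10: float | None = None
    effect_table: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 < self.p <= 1.0):
            raise DomainError(f"p-value {self.p} outside (0, 1]")
        if self.bf10 is not None and self.bf10 <= 0:
            raise DomainError("bf10 must be > 0")


def _p_to_z(p: float) -> float:
    """The documented p-to-z conversion: inverse normal CDF of 1 - p."""
    return float(stats.norm.ppf(1.0 - p))


# --------------------------------------------------------------------------
# per-participant GLM + sign-flip permutation
# --------------------------------------------------------------------------

def per_participant_glm(
    table: pd.DataFrame,
    response: str,
    regressors: list[str],
    subject: str = "agent_id",
    t_cap: float = 1e6,
) -> pd.DataFrame:
    """OLS (with intercept) per participant; one t-statistic per regressor.

    Returns a tidy frame (subject, regressor, t, coef, flagged); perfect
    fits produce unbounded t-values, which are winsorized at ``t_cap`` and
    flagged.
    """
    regressors = list(regressors)
    rows = []
    for subj, sub in table.groupby(subject):
        if len(sub) < len(regressors) + 2:
            raise DesignError(
                f"participant {subj}: need >= {len(regressors) + 2} rows")
        X = sm.add_constant(sub[regressors].to_numpy(dtype=float),
                            has_constant="add")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DesignError(f"participant {subj}: singular design matrix")
        fit = sm.OLS(sub[response].to_numpy(dtype=float), X).fit()
        for j, reg in enumerate(regressors):
            t = fit.tvalues[j + 1]
            flagged = not np.isfinite(t) or abs(t) > t_cap
            if not np.isfinite(t):
                t = math.copysign(t_cap, fit.params[j + 1] or 1.0)
            rows.append(dict(subject=subj, regressor=reg,
                             t=float(np.clip(t, -t_cap, t_cap)),
                             coef=float(fit.params[j + 1]), flagged=flagged))
    return pd.DataFrame(rows)


def signflip_test(
    tstats,
    n_perm: int = 10_000,
    tail: str = "two-sided",
    seed: int | np.random.Generator | None = None,
) -> StatResult:
    """Sign-flipping permutation test on per-participant statistics.

    The per-participant values are randomly sign-flipped ``n_perm`` times;
    the p-value is the proportion of permuted means at least as extreme as
    the observed mean, floored at ``1/n_perm``; z is the inverse normal CDF
    of ``1 - p``.
    """
    t = np.asarray(tstats, dtype=float)
    if t.size == 0:
        raise DomainError("empty input to signflip_test")
    if t.size < 2:
        raise DomainError("signflip_test needs >= 2 participants")
    if tail not in ("two-sided", "greater", "less"):
        raise DomainError(f"unknown tail {tail!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = float(t.mean())
    signs = rng.integers(0, 2, size=(n_perm, t.size)) * 2 - 1
    perm_means = signs @ t / t.size
    if tail == "greater":
        count = int(np.sum(perm_means >= obs))
    elif tail == "less":
        count = int(np.sum(perm_means <= obs))
    else:
        count = int(np.sum(np.abs(perm_means) >= abs(obs)))
    p = max(count / n_perm, 1.0 / n_perm)
    return StatResult(
        kind="signflip", statistic=obs, df=None, p=p, z=_p_to_z(p),
        meta={"n_perm": n_perm, "tail": tail, "n": int(t.size)},
    )


# --------------------------------------------------------------------------
# t-tests and Bayes factors
# --------------------------------------------------------------------------

def _tail_p(t: float, df: float, tail: str) -> float:
    if tail == "two-sided":
        return 2.0 * stats.t.sf(abs(t), df)
    if tail == "greater":
        return float(stats.t.sf(t, df))
    if tail == "less":
        return float(stats.t.cdf(t, df))
    raise DomainError(f"unknown tail {tail!r}")


def one_sample_t(values, mu0: float = 0.0, tail: str = "two-sided") -> StatResult:
    """One-sample (or paired-difference) t-test against ``mu0``."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DomainError("one_sample_t needs n >= 2")
    if np.std(x, ddof=1) == 0.0:
        raise DomainError("degenerate input: zero variance")
    t = float((x.mean() - mu0) / (x.std(ddof=1) / math.sqrt(x.size)))
    df = x.size - 1
    p = min(max(_tail_p(t, df, tail), np.finfo(float).tiny), 1.0)
    return StatResult(kind="one_sample_t", statistic=t, df=df, p=p,
                      meta={"mu0": mu0, "tail": tail, "n": int(x.size),
                            "mean": float(x.mean())})


def welch_t(group_a, group_b, tail: str = "two-sided") -> StatResult:
    """Welch two-sample t-test (unequal variances, Welch-Satterthwaite df)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError("welch_t needs n >= 2 per group")
    if np.std(a, ddof=1) == 0.0 and np.std(b, ddof=1) == 0.0:
        raise DomainError("degenerate input: zero variance in both groups")
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = float((a.mean() - b.mean()) / math.sqrt(va + vb))
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    p = min(max(_tail_p(t, df, tail), np.finfo(float).tiny), 1.0)
    return StatResult(kind="welch_t", statistic=t, df=float(df), p=p,
                      meta={"tail": tail, "n": (int(a.size), int(b.size)),
                            "mean_diff": float(a.mean() - b.mean())})


def jzs_bayes_factor(
    group_a,
    group_b=None,
    mu0: float = 0.0,
    r: float = math.sqrt(2) / 2,
    paired: bool = False,
) -> float:
    """JZS Bayes factor (BF10) for a one- or two-sample t-test.

    Cauchy prior of scale ``r`` on the effect size; BF10 < 1 favours the
    null.  Two-sample comparisons use the pooled-variance t, matching the
    default Bayesian t-test convention.
    """
    a = np.asarray(group_a, dtype=float)
    if group_b is None or paired:
        x = a - np.asarray(group_b, dtype=float) if paired else a - mu0
        if x.size < 2 or np.std(x, ddof=1) == 0.0:
            raise DomainError("degenerate input for Bayes factor")
        t = x.mean() / (x.std(ddof=1) / math.sqrt(x.size))
        bf = pingouin.bayesfactor_ttest(float(t), x.size, paired=True, r=r)
    else:
        b = np.asarray(group_b, dtype=float)
        n1, n2 = a.size, b.size
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
        if sp2 == 0.0:
            raise DomainError("degenerate input for Bayes factor")
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        bf = pingouin.bayesfactor_ttest(float(t), n1, n2, r=r)
    bf = float(bf)
    if not np.isfinite(bf) or bf <= 0:
        raise DomainError("Bayes factor integration failed")
    return bf


# --------------------------------------------------------------------------
# balanced mixed ANOVA (one between factor, >= 1 within factors)
# --------------------------------------------------------------------------

def _cell_ss(df: pd.DataFrame, dv: str, by: list[str]) -> float:
    """U-term: sum over cells of (cell total)^2 / (cell size)."""
    if not by:
        tot = df[dv].sum()
        return float(tot * tot / len(df))
    g = df.groupby(by, observed=True)[dv]
    return float((g.sum() ** 2 / g.size()).sum())


def _gg_epsilon(df, dv, subject, between, effect_within, within_levels):
    """Greenhouse-Geisser epsilon for one within effect (1 when df = 1)."""
    d = int(np.prod([len(within_levels[w]) - 1 for w in effect_within]))
    if d <= 1:
        return 1.0
    # orthonormal contrast matrix over the within cells of this effect
    mats = []
    for w in effect_within:
        k = len(within_levels[w])
        h = np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, : k - 1]
        mats.append(h.T)
    C = mats[0]
    for m in mats[1:]:
        C = np.kron(C, m)
    # subject scores on marginal cell means of this effect
    wide = df.groupby([subject] + list(effect_within), observed=True)[dv] \
        .mean().unstack(list(effect_within))
    Z = wide.to_numpy() @ C.T
    grp = df.groupby(subject, observed=True)[between].first().loc[wide.index]
    resid = np.vstack([
        Z[(grp == lev).to_numpy()] - Z[(grp == lev).to_numpy()].mean(axis=0)
        for lev in grp.unique()
    ])
    S = resid.T @ resid / (len(Z) - grp.nunique())
    tr = np.trace(S)
    eps = tr * tr / (S.shape[0] * np.trace(S @ S))
    return float(min(max(eps, 1.0 / S.shape[0]), 1.0))


def mixed_anova(
    table: pd.DataFrame,
    dv: str,
    subject: str,
    between: str,
    within: list[str],
) -> StatResult:
    """Balanced mixed ANOVA: one between factor, any number of within factors.

    Univariate approach with per-effect subject error strata (equivalent to
    type-III sums of squares with sum-to-zero contrasts on a balanced
    design).  Each within effect is tested against its interaction with
    subjects-within-groups; sphericity is Greenhouse-Geisser corrected when
    an effect has more than one numerator df (with two-level factors the
    correction is the identity).  Raises :class:`DesignError` on unbalanced
    or incomplete designs.
    """
    within = list(within)
    df = table.copy()
    # design validation
    cells = df.groupby([subject] + within, observed=True).size()
    if (cells != 1).any():
        raise DesignError("design must have exactly one observation per "
                          "subject x within-cell")
    n_cells = int(np.prod([df[w].nunique() for w in within]))
    per_subj = df.groupby(subject, observed=True).size()
    if (per_subj != n_cells).any():
        raise DesignError("incomplete within-subject design")
    grp_of = df.groupby(subject, observed=True)[between].nunique()
    if (grp_of != 1).any():
        raise DesignError("each subject must belong to exactly one group")
    sizes = df.groupby(between, observed=True)[subject].nunique()
    if sizes.nunique() != 1:
        raise DesignError("unbalanced between-subject groups")
    g = int(len(sizes))
    n_subj = int(per_subj.size)
    within_levels = {w: sorted(df[w].unique()) for w in within}

    U = {}

    def u(fs: tuple) -> float:
        key = tuple(sorted(fs))
        if key not in U:
            U[key] = _cell_ss(df, dv, list(key))
        return U[key]

    def ie_ss(effect: list[str], extra: str | None = None) -> float:
        """Inclusion-exclusion SS over subsets of ``effect`` (within factors),
        each term optionally augmented by ``extra`` (between or subject)."""
        ss = 0.0
        for k in range(len(effect) + 1):
            for T in itertools.combinations(effect, k):
                sign = (-1) ** (len(effect) - k)
                base = u(T + ((extra,) if extra else ()))
                ss += sign * base
        return ss

    rows = []
    eps_small = 1e-10

    def add_row(name, ss, df1, ss_err, df2, eps=1.0):
        ms_err = ss_err / df2 if df2 > 0 else np.nan
        if ss <= eps_small:
            F = 0.0
            p = 1.0
        elif ms_err <= eps_small:
            F = np.inf
            p = np.finfo(float).tiny
        else:
            F = (ss / df1) / ms_err
            p = max(float(stats.f.sf(F, df1, df2)), np.finfo(float).tiny)
        if eps < 1.0 and np.isfinite(F) and F > 0:
            p_corr = max(float(stats.f.sf(F, eps * df1, eps * df2)),
                         np.finfo(float).tiny)
        else:
            p_corr = p
        rows.append(dict(effect=name, SS=ss, df1=df1, df2=df2, F=F, p=p,
                         eps=eps, p_corr=p_corr))

    # between effect, tested against subjects within groups (absent when a
    # constant between column encodes a pure within design)
    ss_subj = u((subject,)) - u((between,))
    df_subj = n_subj - g
    if g > 1:
        add_row(between, u((between,)) - u(()), g - 1, ss_subj, df_subj)

    # within effects and their interactions with the between factor
    for k in range(1, len(within) + 1):
        for eff in itertools.combinations(within, k):
            eff = list(eff)
            d_eff = int(np.prod([len(within_levels[w]) - 1 for w in eff]))
            ss_w = ie_ss(eff)
            ss_err = ie_ss(eff, subject) - ie_ss(eff, between)
            df_err = df_subj * d_eff
            eps = _gg_epsilon(df, dv, subject, between, eff, within_levels)
            add_row(" x ".join(eff), ss_w, d_eff, ss_err, df_err, eps)
            if g > 1:
                ss_wb = ie_ss(eff, between) - ss_w
                add_row(" x ".join(eff + [between]), ss_wb, d_eff * (g - 1),
                        ss_err, df_err, eps)

    effect_table = pd.DataFrame(rows)
    # headline row: first within main effect, conventional summary statistic
    top = effect_table[effect_table["effect"] == within[0]].iloc[0]
    return StatResult(
        kind="mixed_anova", statistic=float(top["F"]),
        df=(float(top["df1"]), float(top["df2"])), p=float(top["p"]),
        effect_table=effect_table,
        meta={"between": between, "within": within, "n_subjects": n_subj,
              "groups": g},
    )


def pairwise_posthoc(
    table: pd.DataFrame,
    dv: str,
    subject: str,
    factor: str,
    by: list[str] | None = None,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Paired t-tests between the two levels of ``factor`` in every subgroup.

    ``by`` lists the condition columns defining subgroups; data are averaged
    per subject x level first.  ``correction`` is "none" or "bonferroni"
    (the corrected p multiplies by the number of comparisons, capped at 1).
    """
    if correction not in ("none", "bonferroni"):
        raise DomainError(f"unknown correction {correction!r}")
    by = list(by or [])
    levels = sorted(table[factor].unique())
    if len(levels) != 2:
        raise DesignError("pairwise_posthoc expects a two-level factor")
    combos = (
        [tuple()] if not by
        else list(table.groupby(by, observed=True).groups.keys())
    )
    rows = []
    for combo in combos:
        sub = table
        combo = combo if isinstance(combo, tuple) else (combo,)
        for col, val in zip(by, combo):
            sub = sub[sub[col] == val]
        wide = sub.groupby([subject, factor], observed=True)[dv].mean().unstack(factor)
        diff = (wide[levels[0]] - wide[levels[1]]).dropna()
        if diff.std(ddof=1) == 0.0:
            t, p = 0.0, 1.0
        else:
            t = float(diff.mean() / (diff.std(ddof=1) / math.sqrt(len(diff))))
            p = float(2.0 * stats.t.sf(abs(t), len(diff) - 1))
        rows.append({**dict(zip(by, combo)),
                     "contrast": f"{levels[0]} - {levels[1]}",
                     "t": t, "df": len(diff) - 1, "p": p})
    out = pd.DataFrame(rows)
    m = len(out)
    out["p_corr"] = out["p"] if correction == "none" else np.minimum(out["p"] * m, 1.0)
    return out


# --------------------------------------------------------------------------
# power analysis and correlation group test
# --------------------------------------------------------------------------

def power_sample_size(
    effect_size: float,
    alpha: float = 0.05,
    power: float = 0.95,
    design: str = "one_sample",
    tail: str = "greater",
    n_max: int = 1_000_000,
) -> int:
    """Smallest n (per group) whose noncentral-t power meets the target.

    For ``one_sample`` (or matched pairs), the noncentrality is
    ``d * sqrt(n)`` with ``n - 1`` df; for ``two_sample``, ``d * sqrt(n/2)``
    with ``2n - 2`` df.  ``tail`` is "greater" (one-sided) or "two-sided".
    """
    if not 0.0 < alpha < 1.0 or not 0.0 < power < 1.0:
        raise DomainError("alpha and power must be in (0, 1)")
    if effect_size <= 0:
        raise DomainError("effect_size must be > 0")
    if design not in ("one_sample", "two_sample"):
        raise DomainError(f"unknown design {design!r}")
    if tail not in ("greater", "two-sided"):
        raise DomainError(f"unknown tail {tail!r}")
    for n in range(2, n_max + 1):
        if design == "one_sample":
            df = n - 1
            delta = effect_size * math.sqrt(n)
        else:
            df = 2 * n - 2
            delta = effect_size * math.sqrt(n / 2.0)
        a = alpha / 2.0 if tail == "two-sided" else alpha
        crit = stats.t.isf(a, df)
        achieved = stats.nct.sf(crit, df, delta)
        if tail == "two-sided":
            achieved += stats.nct.cdf(-crit, df, delta)
        if achieved >= power:
            return n
    raise DomainError("target power unreachable within n_max")


def pearson_group_test(r_values, mu0: float = 0.0, tail: str = "two-sided") -> StatResult:
    """One-sample t on per-participant Pearson correlations (raw r scale).

    Participants with undefined correlations (NaN) are dropped with a
    warning.
    """
    r = np.asarray(r_values, dtype=float)
    bad = np.isnan(r)
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} undefined correlation(s)",
                      stacklevel=2)
        r = r[~bad]
    res = one_sample_t(r, mu0=mu0, tail=tail)
    res.kind = "pearson_group_test"
    res.meta["mean_r"] = float(r.mean())
    return res
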