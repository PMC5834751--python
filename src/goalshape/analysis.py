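"""Statistical analysis battery for event logs and screening records.

Covers everything the cohort-level reporting needs: EMA compliance tables,
goal commitment / goal-success metrics with their stratified splits,
repeated-measures Poisson trend models of weekend maxima with participant
random intercepts, Pearson chi-square 2x2 association tests, Wilcoxon
signed-rank pre/post comparisons, and the pooled two-sample proportion test.
Every proportion is reported with its numerator and denominator so each
statistic stays auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.proportion import proportions_ztest

from .engine import LOW_CONFIDENCE_CUTOFF
from .events import Event, MessageEvent, ResponseEvent, Template

__all__ = [
    "Proportion",
    "GoalMetrics",
    "DegenerateTestError",
    "response_rates",
    "goal_summary",
    "crosstab_chi2",
    "fit_weekend_trend",
    "wilcoxon_signed_rank",
    "two_sample_proportion_test",
    "weekend_records_from_log",
    "prepost_table",
]


class DegenerateTestError(ValueError):
    """A test statistic is undefined for the given data (e.g. zero margin,
    all-zero differences); raised instead of returning a silent NaN."""


@dataclass(frozen=True)
class Proportion:
    """A rate with its counts retained, printed in '% (x/n)' style."""

    numerator: int
    denominator: int

    @property
    def rate(self) -> Optional[float]:
        if self.denominator == 0:
            return None
        return self.numerator / self.denominator

    def __str__(self) -> str:
        if self.denominator == 0:
            return "undefined (0 denominator)"
        return f"{100 * self.rate:.1f}% ({self.numerator}/{self.denominator})"


_SLOT_TYPE = {
    Template.PLAN: "thu_plan",
    Template.MAX_DRINKS: "sun_max",
    Template.CONFIDENCE: "confidence",
    Template.GOAL_COMMIT: "goal_commit",
}


def _block_of(week: int) -> int:
    """4-week block index; 0 denotes the run-in."""
    return 0 if week < 1 else (week + 3) // 4


def response_rates(
    events: Iterable[Event],
    by: Sequence[str] = ("block", "slot_type"),
) -> pd.DataFrame:
    """EMA compliance: prompts issued, within-window responses, and rates.

    Aggregates over any subset of {'block', 'slot_type', 'week',
    'participant_id'}. Only the four assessment queries count as prompts;
    late replies and duplicate replies to one prompt are not counted.
    Groups with no prompts simply do not appear (no zero-filled cells).
    """
    prompts: Dict[str, MessageEvent] = {}
    answered: set = set()
    for ev in events:
        if isinstance(ev, MessageEvent):
            if ev.template_id in _SLOT_TYPE:
                prompts[ev.event_id] = ev
        elif (
            ev.received_within_window
            and ev.in_reply_to in prompts
            and ev.in_reply_to not in answered
        ):
            answered.add(ev.in_reply_to)
    if not prompts:
        return pd.DataFrame(columns=[*by, "prompts", "responses", "rate"])
    rows = [
        {
            "participant_id": m.participant_id,
            "week": m.week_index,
            "block": _block_of(m.week_index),
            "slot_type": _SLOT_TYPE[m.template_id],
            "answered": int(eid in answered),
        }
        for eid, m in prompts.items()
    ]
    frame = pd.DataFrame(rows)
    grouped = (
        frame.groupby(list(by))
        .agg(prompts=("answered", "size"), responses=("answered", "sum"))
        .reset_index()
    )
    grouped["rate"] = grouped["responses"] / grouped["prompts"]
    return grouped


@dataclass
class GoalMetrics:
    """Goal commitment and goal-success metrics from one event log."""

    commitment: Proportion
    above_binge_by_week: pd.DataFrame  # week, above_binge, prompts, rate
    success: Proportion
    success_by_confidence: Dict[str, Proportion]  # low (<4) vs high (>=4)
    success_by_goal_level: Dict[str, Proportion]  # above binge vs at threshold
    weekends: pd.DataFrame  # per committed weekend: limit, reported, met, ...


def goal_summary(events: Iterable[Event]) -> GoalMetrics:
    """Summarize goal prompts, commitments, and weekend goal success.

    A weekend counts toward the success rate when a goal was committed and
    the Sunday maximum-drinks query was answered in window. The confidence
    split uses the weekend's *lowest* reported confidence (<4 = low); goal
    weekends with no confidence report are excluded from that split only.
    """
    goal_prompts: Dict[str, MessageEvent] = {}
    committed: Dict[Tuple[str, int], dict] = {}
    commit_replies = 0
    commit_yes = 0
    confidence: Dict[Tuple[str, int], List[int]] = {}
    sunday_max: Dict[Tuple[str, int], int] = {}
    max_prompts: Dict[str, MessageEvent] = {}
    conf_prompts: Dict[str, MessageEvent] = {}

    for ev in events:
        if isinstance(ev, MessageEvent):
            if ev.template_id is Template.GOAL_COMMIT:
                goal_prompts[ev.event_id] = ev
            elif ev.template_id is Template.MAX_DRINKS:
                max_prompts[ev.event_id] = ev
            elif ev.template_id is Template.CONFIDENCE:
                conf_prompts[ev.event_id] = ev
            continue
        if not ev.received_within_window:
            continue
        if ev.in_reply_to in goal_prompts:
            prompt = goal_prompts[ev.in_reply_to]
            commit_replies += 1
            if bool(ev.value):
                commit_yes += 1
                committed[(ev.participant_id, prompt.week_index)] = {
                    "limit": int(prompt.payload["limit"]),
                    "above_binge": bool(prompt.payload.get("above_binge", False)),
                }
        elif ev.in_reply_to in conf_prompts:
            prompt = conf_prompts[ev.in_reply_to]
            key = (ev.participant_id, prompt.week_index)
            confidence.setdefault(key, []).append(int(ev.value))
        elif ev.in_reply_to in max_prompts:
            prompt = max_prompts[ev.in_reply_to]
            key = (ev.participant_id, prompt.week_index)
            if prompt.week_index >= 1 and key not in sunday_max:
                sunday_max[key] = int(ev.value)

    # above-binge share of issued goal prompts, per week
    ab_rows = [
        {"week": m.week_index, "above": int(bool(m.payload.get("above_binge")))}
        for m in goal_prompts.values()
    ]
    if ab_rows:
        ab = (
            pd.DataFrame(ab_rows)
            .groupby("week")
            .agg(above_binge=("above", "sum"), prompts=("above", "size"))
            .reset_index()
        )
        ab["rate"] = ab["above_binge"] / ab["prompts"]
    else:
        ab = pd.DataFrame(columns=["week", "above_binge", "prompts", "rate"])

    wrows = []
    for (pid, week), goal in committed.items():
        if (pid, week) not in sunday_max:
            continue
        reported = sunday_max[(pid, week)]
        conf = confidence.get((pid, week))
        wrows.append(
            {
                "participant_id": pid,
                "week": week,
                "limit": goal["limit"],
                "above_binge": goal["above_binge"],
                "reported": reported,
                "met": int(reported <= goal["limit"]),
                "min_confidence": min(conf) if conf else None,
            }
        )
    weekends = pd.DataFrame(
        wrows,
        columns=[
            "participant_id", "week", "limit", "above_binge", "reported",
            "met", "min_confidence",
        ],
    )

    def prop(mask: pd.Series) -> Proportion:
        sub = weekends[mask]
        return Proportion(int(sub["met"].sum()), int(len(sub)))

    has_conf = weekends["min_confidence"].notna()
    low = has_conf & (weekends["min_confidence"] < LOW_CONFIDENCE_CUTOFF)
    high = has_conf & (weekends["min_confidence"] >= LOW_CONFIDENCE_CUTOFF)
    return GoalMetrics(
        commitment=Proportion(commit_yes, commit_replies),
        above_binge_by_week=ab,
        success=Proportion(int(weekends["met"].sum()), int(len(weekends))),
        success_by_confidence={"low": prop(low), "high": prop(high)},
        success_by_goal_level={
            "above_binge": prop(weekends["above_binge"].astype(bool)),
            "at_threshold": prop(~weekends["above_binge"].astype(bool)),
        },
        weekends=weekends,
    )


def crosstab_chi2(
    table: Union[Sequence[Sequence[int]], np.ndarray],
    yates: bool = False,
) -> Tuple[float, float]:
    """Pearson chi-square test of association on a 2x2 table (df = 1).

    No continuity correction by default (set ``yates=True`` to apply it).
    A zero row or column margin leaves the statistic undefined and raises
    :class:`DegenerateTestError`.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("expected a 2x2 table of non-negative counts")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateTestError("chi-square undefined: zero margin")
    res = scipy.stats.chi2_contingency(arr, correction=yates)
    return float(res.statistic), float(res.pvalue)


def weekend_records_from_log(events: Iterable[Event]) -> pd.DataFrame:
    """Answered Sunday maximum-drinks reports as a tidy panel
    (participant_id, week, max_drinks)."""
    max_prompts: Dict[str, MessageEvent] = {}
    rows = []
    seen = set()
    for ev in events:
        if isinstance(ev, MessageEvent):
            if ev.template_id is Template.MAX_DRINKS:
                max_prompts[ev.event_id] = ev
        elif ev.received_within_window and ev.in_reply_to in max_prompts:
            prompt = max_prompts[ev.in_reply_to]
            key = (ev.participant_id, prompt.week_index)
            if key in seen:
                continue
            seen.add(key)
            rows.append(
                {
                    "participant_id": ev.participant_id,
                    "week": prompt.week_index,
                    "max_drinks": int(ev.value),
                }
            )
    return pd.DataFrame(rows, columns=["participant_id", "week", "max_drinks"])


def fit_weekend_trend(
    records: pd.DataFrame,
    strata: Optional[Mapping[str, str]] = None,
    method: str = "random_intercept",
    include_run_in: bool = False,
    min_participants: int = 3,
) -> pd.DataFrame:
    """Per-stratum Poisson panel regression of weekend maxima on week.

    ``records`` is the tidy panel from :func:`weekend_records_from_log`
    (participant_id, week, max_drinks), optionally with a ``stratum`` column;
    ``strata`` maps participant to stratum otherwise (one pooled stratum when
    absent). The week regressor is centered at week 1, so the intercept is
    the expected log count in the first intervention week.

    Methods: ``random_intercept`` (participant-level random-intercept Poisson
    fit via deterministic MAP estimation; the default inferential surface),
    ``gee`` (population-averaged fit, exchangeable within-participant
    correlation), and ``gee_ar1`` (autoregressive within-participant
    residual correlation, the AR refinement). Strata with fewer than
    ``min_participants`` participants are skipped with a warning.
    """
    frame = records.copy()
    if "stratum" not in frame.columns:
        if strata is not None:
            frame["stratum"] = frame["participant_id"].map(dict(strata))
        else:
            frame["stratum"] = "all"
    if not include_run_in:
        frame = frame[frame["week"] >= 1]
    out = []
    for stratum, sub in frame.groupby("stratum", sort=True):
        n_pid = sub["participant_id"].nunique()
        if n_pid < min_participants:
            warnings.warn(
                f"stratum {stratum!r}: only {n_pid} participant(s); fit skipped"
            )
            continue
        if sub.groupby("participant_id")["week"].nunique().max() < 2:
            warnings.warn(f"stratum {stratum!r}: fewer than 2 weeks per "
                          "participant; fit skipped")
            continue
        sub = sub.sort_values(["participant_id", "week"])
        y = sub["max_drinks"].to_numpy(dtype=float)
        x = sm.add_constant((sub["week"] - 1).to_numpy(dtype=float))
        pids, pid_index = np.unique(sub["participant_id"], return_inverse=True)
        if method == "random_intercept":
            params, se = _fit_poisson_random_intercept(y, x, pid_index)
        elif method in ("gee", "gee_ar1"):
            cov = (
                sm.cov_struct.Autoregressive(grid=True)
                if method == "gee_ar1"
                else sm.cov_struct.Exchangeable()
            )
            model = sm.GEE(
                y, x, groups=pid_index, time=sub["week"].to_numpy(),
                family=sm.families.Poisson(), cov_struct=cov,
            )
            fit = model.fit()
            params = np.asarray(fit.params)
            se = np.asarray(fit.bse)
        else:
            raise ValueError(f"unknown method {method!r}")
        z = scipy.stats.norm.ppf(0.975)
        out.append(
            {
                "stratum": stratum,
                "n_participants": int(n_pid),
                "n_obs": int(len(y)),
                "intercept": float(params[0]),
                "intercept_se": float(se[0]),
                "intercept_lo": float(params[0] - z * se[0]),
                "intercept_hi": float(params[0] + z * se[0]),
                "slope": float(params[1]),
                "slope_se": float(se[1]),
                "slope_lo": float(params[1] - z * se[1]),
                "slope_hi": float(params[1] + z * se[1]),
                "method": method,
            }
        )
    return pd.DataFrame(
        out,
        columns=[
            "stratum", "n_participants", "n_obs",
            "intercept", "intercept_se", "intercept_lo", "intercept_hi",
            "slope", "slope_se", "slope_lo", "slope_hi", "method",
        ],
    )


#: Gauss-Hermite nodes for the random-intercept marginal likelihood.
_AGQ_NODES = 15
#: Lower bound on the random-intercept SD (keeps the scale parameter away
#: from the degenerate zero-variance boundary).
_MIN_SIGMA = 1e-3


def _fit_poisson_random_intercept(
    y: np.ndarray, x: np.ndarray, groups: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood Poisson regression with a participant-level
    Normal(0, sigma^2) random intercept, by adaptive Gauss-Hermite
    quadrature (quadrature recentred at each participant's posterior mode).

    Returns the fixed-effect estimates and their standard errors from the
    observed information (inverted over all parameters including log sigma,
    falling back to the fixed-effect block if the scale sits on its
    boundary). Fully deterministic: fixed start values, fixed node count.
    """
    n_groups = int(groups.max()) + 1
    z_nodes, z_weights = np.polynomial.hermite.hermgauss(_AGQ_NODES)
    log_w = np.log(z_weights)
    sum_y = np.bincount(groups, weights=y, minlength=n_groups)
    log_bounds = (np.log(_MIN_SIGMA), np.log(10.0))

    def neg_loglik(theta: np.ndarray) -> float:
        beta, log_sigma = theta[:-1], float(np.clip(theta[-1], *log_bounds))
        sigma2 = np.exp(2 * log_sigma)
        eta = x @ beta
        a = np.bincount(groups, weights=np.exp(eta), minlength=n_groups)
        c = np.bincount(groups, weights=y * eta, minlength=n_groups)
        # per-group posterior mode of the random intercept, by Newton steps
        # on g(u) = -u^2/(2 s2) + S u - A e^u (strictly concave)
        u = np.zeros(n_groups)
        for _ in range(60):
            expu = np.exp(np.clip(u, -60, 60))
            grad = -u / sigma2 + sum_y - a * expu
            hess = -1.0 / sigma2 - a * expu
            step = grad / hess
            u = np.clip(u - step, -60, 60)
            if np.max(np.abs(step)) < 1e-12:
                break
        expu = np.exp(u)
        tau = 1.0 / np.sqrt(1.0 / sigma2 + a * expu)
        # adaptive nodes u_gk = u_g + sqrt(2) tau_g z_k
        u_k = u[:, None] + np.sqrt(2.0) * tau[:, None] * z_nodes[None, :]
        g_k = (
            -0.5 * np.log(2 * np.pi * sigma2)
            - u_k**2 / (2 * sigma2)
            + sum_y[:, None] * u_k
            - a[:, None] * np.exp(np.clip(u_k, -60, 60))
            + c[:, None]
        )
        log_lik = scipy.special.logsumexp(
            log_w[None, :] + z_nodes[None, :] ** 2 + g_k, axis=1
        ) + 0.5 * np.log(2.0) + np.log(tau)
        return -float(log_lik.sum())

    glm_start = sm.GLM(y, x, family=sm.families.Poisson()).fit(maxiter=200)
    theta0 = np.concatenate([glm_start.params, [np.log(0.5)]])
    p = x.shape[1]
    res = scipy.optimize.minimize(
        neg_loglik,
        theta0,
        method="L-BFGS-B",
        bounds=[(None, None)] * p + [log_bounds],
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
    )
    theta = res.x

    def hessian(fn, point, h=1e-4):
        k = len(point)
        out = np.empty((k, k))
        for i in range(k):
            for j in range(i, k):
                pp = point.copy(); pp[i] += h; pp[j] += h
                pm = point.copy(); pm[i] += h; pm[j] -= h
                mp = point.copy(); mp[i] -= h; mp[j] += h
                mm = point.copy(); mm[i] -= h; mm[j] -= h
                out[i, j] = out[j, i] = (
                    fn(pp) - fn(pm) - fn(mp) + fn(mm)
                ) / (4 * h * h)
        return out

    with np.errstate(all="ignore"):
        full = hessian(neg_loglik, theta)
        cov = None
        at_boundary = theta[-1] <= log_bounds[0] + 1e-6
        if not at_boundary:
            try:
                cand = np.linalg.inv(full)
                if np.all(np.diag(cand)[:p] > 0):
                    cov = cand[:p, :p]
            except np.linalg.LinAlgError:
                cov = None
        if cov is None:  # profile out the boundary-pinned scale
            beta_hess = full[:p, :p]
            cov = np.linalg.pinv(beta_hess)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return theta[:p], se


#: Sample-size bound below which the signed-rank null is enumerated exactly.
WILCOXON_EXACT_MAX_N = 25


def wilcoxon_signed_rank(
    pre: Sequence[float], post: Sequence[float]
) -> Tuple[float, float]:
    """Wilcoxon signed-rank test on paired pre/post values.

    Differences are ``pre - post``; zero differences are dropped and ties get
    midranks. Returns the positive-rank sum W+ and a two-sided p-value:
    exact (tie-aware, by dynamic programming over the doubled midranks) for
    n <= 25 retained pairs, a tie-corrected normal approximation without
    continuity correction beyond that.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be equal-length 1-d vectors")
    d = pre - post
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateTestError(
            "signed-rank test undefined: all paired differences are zero"
        )
    ranks = scipy.stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= WILCOXON_EXACT_MAX_N:
        p = _signed_rank_exact_p(ranks, w_plus)
    else:
        mu = ranks.sum() / 2.0
        sigma = np.sqrt(np.square(ranks).sum() / 4.0)
        z = (w_plus - mu) / sigma
        p = 2.0 * scipy.stats.norm.sf(abs(z))
    return w_plus, float(min(p, 1.0))


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p over all 2^n sign assignments, with midranks.

    Doubling the midranks makes them integers, so the null distribution of
    2*W+ is built by polynomial multiplication; symmetry around the midpoint
    gives the two-sided tail.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        counts[r:] += counts[: total + 1 - r].copy()
    support = np.arange(total + 1)
    # compare |2W+ - center| on the doubled scale, all in integers:
    # 2*|support - total/2| = |2*support - total| vs |2*(2 w+) - total|
    obs = int(round(2 * w_plus))
    extreme = np.abs(2 * support - total) >= abs(2 * obs - total)
    return float(counts[extreme].sum() / counts.sum())


def two_sample_proportion_test(
    x1: int, n1: int, x2: int, n2: int
) -> Tuple[float, float]:
    """Two-sample test of proportions (pooled-variance z, two-sided p)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    if x1 + x2 == 0 or x1 + x2 == n1 + n2:
        # pooled variance is zero; identical degenerate proportions
        if x1 * n2 == x2 * n1:
            return 0.0, 1.0
        raise DegenerateTestError("proportion test undefined: zero pooled variance")
    z, p = proportions_ztest([x1, x2], [n1, n2])
    return float(z), float(p)


# --------------------------------------------------------------------- #
# Pre/post (baseline vs 3-month) summary

def _iqr_text(values: pd.Series) -> str:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return f"{med:g} ({q1:g}-{q3:g})"


def prepost_table(
    baseline: pd.DataFrame,
    followup: pd.DataFrame,
    groups: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Change in alcohol-related outcomes between two scored screening frames.

    Outcomes per enrollment group and pooled ('any'): weekend maximum drinks
    from the heavy-week grid (Wilcoxon signed-rank), prevalence of any binge
    episode in the typical week (two-sample proportion test), and the
    consequence-scale sum (Wilcoxon signed-rank). Frames must be outputs of
    :func:`goalshape.screening.score_frame` sharing participant ids.
    """
    from .goal_policy import Sex, binge_threshold

    merged = baseline.merge(
        followup, on="participant_id", suffixes=("_pre", "_post")
    )
    if merged.empty:
        raise ValueError("no shared participants between baseline and follow-up")

    def any_binge(frame: pd.DataFrame, suffix: str) -> pd.Series:
        days = "mon tue wed thu fri sat sun".split()
        thr = frame[f"sex{suffix}"].map(
            lambda s: binge_threshold(Sex(s))
        )
        grid = frame[[f"ddq_typical_{d}{suffix}" for d in days]]
        return (grid.ge(thr, axis=0)).any(axis=1)

    merged["binge_pre"] = any_binge(merged, "_pre")
    merged["binge_post"] = any_binge(merged, "_post")
    merged["group"] = (
        merged["participant_id"].map(dict(groups)) if groups else "any"
    )

    rows = []
    group_labels = list(pd.unique(merged["group"].dropna()))
    if groups:
        group_labels.append("any")
    for label in group_labels:
        sub = merged if label == "any" else merged[merged["group"] == label]
        n = len(sub)
        if n == 0:
            continue
        for outcome, pre_col, post_col, kind in (
            ("max_weekend_drinks", "weekend_max_heavy_pre", "weekend_max_heavy_post", "wilcoxon"),
            ("any_binge_typical_week", "binge_pre", "binge_post", "proportions"),
            ("negative_consequences", "byaacq_sum_pre", "byaacq_sum_post", "wilcoxon"),
        ):
            if kind == "wilcoxon":
                try:
                    _, p = wilcoxon_signed_rank(sub[pre_col], sub[post_col])
                except DegenerateTestError:
                    p = np.nan
                base_txt = _iqr_text(sub[pre_col])
                post_txt = _iqr_text(sub[post_col])
            else:
                x1, x2 = int(sub[pre_col].sum()), int(sub[post_col].sum())
                try:
                    _, p = two_sample_proportion_test(x1, n, x2, n)
                except DegenerateTestError:
                    p = np.nan
                base_txt = f"{x1} ({100 * x1 / n:.0f}%)"
                post_txt = f"{x2} ({100 * x2 / n:.0f}%)"
            rows.append(
                {
                    "group": label,
                    "n": n,
                    "outcome": outcome,
                    "baseline": base_txt,
                    "followup": post_txt,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)
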