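"""Nonparametric evaluation battery for the two-arm question-count trial.

Within-condition pre/post comparisons use the Wilcoxon signed-rank test;
between-condition comparisons use the Mann-Whitney U test (two-sided for
raw scores, one-sided for the change metrics under the hypothesis that
the adapted arm improves more). Effect sizes are Cliff's delta for
between-group comparisons, r = Z/sqrt(n) for within-group comparisons,
and Cohen's d alongside a Welch t test for baseline-balance checks.

The subgroup analysis pools both arms and classifies each participant by
comparing the number of questions actually delivered with the number the
distress-detection model estimated as sufficient: ``same`` (delivered ==
estimated), ``fewer`` (delivered < estimated, including sessions censored
while still distressed) and ``more`` (delivered > estimated).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .scales import CENSORED

__all__ = [
    "Alternative",
    "TestResult",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "cliff_delta",
    "welch_t_and_cohen_d",
    "assign_subgroup",
    "subgroup_analysis",
    "per_question_summaries",
    "condition_summary",
    "change_summary",
]

CHANGE_METRICS = ("change_in_distress", "cognitive_change", "mood_change", "change_in_stai_s")


class Alternative(str, enum.Enum):
    TWO_SIDED = "two_sided"
    GREATER = "greater"
    LESS = "less"


_SCIPY_ALT = {
    Alternative.TWO_SIDED: "two-sided",
    Alternative.GREATER: "greater",
    Alternative.LESS: "less",
}


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    alternative: Alternative
    effect_size: float | None
    effect_size_kind: str | None
    n: tuple[int, ...]
    method: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")


def _check_nonempty(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a nonempty 1-d sample")
    return arr


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Alternative | str = Alternative.TWO_SIDED,
) -> TestResult:
    """Mann-Whitney U test of x against y.

    The p-value is exact (full enumeration over rank assignments) when
    the samples are small (n*m <= 400) and tie-free; otherwise the normal
    approximation with midrank tie correction and continuity correction
    is used. Cliff's delta is attached as the effect size.
    """
    alternative = Alternative(alternative)
    xa = _check_nonempty(x, "x")
    ya = _check_nonempty(y, "y")
    n, m = xa.size, ya.size
    has_ties = np.unique(np.concatenate([xa, ya])).size < n + m
    method = "exact" if (n * m <= 400 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        xa, ya, alternative=_SCIPY_ALT[alternative], method=method, use_continuity=True
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alternative=alternative,
        effect_size=cliff_delta(xa, ya),
        effect_size_kind="cliff_delta",
        n=(n, m),
        method=f"mann_whitney_u[{method}]",
    )


def wilcoxon_signed_rank(
    pre: Sequence[float],
    post: Sequence[float],
    alternative: Alternative | str = Alternative.TWO_SIDED,
) -> TestResult:
    """Wilcoxon signed-rank test on paired pre/post measurements.

    Zero differences are dropped (the classical Wilcoxon convention); the
    p-value is exact for effective n <= 15 and a normal approximation
    beyond that. The effect size is r = |Z|/sqrt(n) with the sign of the
    median difference, where Z comes from the normal approximation and n
    counts the non-zero pairs.
    """
    alternative = Alternative(alternative)
    pre_a = _check_nonempty(pre, "pre")
    post_a = _check_nonempty(post, "post")
    if pre_a.size != post_a.size:
        raise ValueError("pre and post must be paired (equal length)")
    d = pre_a - post_a
    nz = d[d != 0]
    n_eff = nz.size
    if n_eff == 0:
        return TestResult(
            statistic=0.0,
            p_value=1.0,
            alternative=alternative,
            effect_size=0.0,
            effect_size_kind="r",
            n=(pre_a.size,),
            method="wilcoxon[degenerate]",
            degenerate=True,
        )
    has_ties = np.unique(np.abs(nz)).size < n_eff
    method = "exact" if (n_eff <= 15 and not has_ties) else "approx"
    res = sps.wilcoxon(nz, alternative=_SCIPY_ALT[alternative], method=method)

    # signed r from the normal approximation of W+ (tie-corrected variance)
    ranks = sps.rankdata(np.abs(nz))
    w_plus = float(np.sum(ranks[nz > 0]))
    mu = n_eff * (n_eff + 1) / 4.0
    _, tie_counts = np.unique(np.abs(nz), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    sigma2 = n_eff * (n_eff + 1) * (2 * n_eff + 1) / 24.0 - tie_term
    z = (w_plus - mu) / math.sqrt(sigma2) if sigma2 > 0 else 0.0
    sign = float(np.sign(np.median(nz))) or 1.0
    r = sign * abs(z) / math.sqrt(n_eff)

    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alternative=alternative,
        effect_size=r,
        effect_size_kind="r",
        n=(n_eff,),
        method=f"wilcoxon[{method}]",
    )


def cliff_delta(x: Sequence[float], y: Sequence[float]) -> float:
    """Cliff's dominance delta: P(x > y) - P(x < y), in [-1, 1]."""
    xa = _check_nonempty(x, "x")
    ya = _check_nonempty(y, "y")
    diff = xa[:, None] - ya[None, :]
    return float((np.sum(diff > 0) - np.sum(diff < 0)) / diff.size)


def welch_t_and_cohen_d(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Welch t test with Cohen's d (pooled-SD convention)."""
    xa = _check_nonempty(x, "x")
    ya = _check_nonempty(y, "y")
    if xa.size < 2 or ya.size < 2:
        raise ValueError("Welch t requires at least 2 observations per group")
    vx, vy = xa.var(ddof=1), ya.var(ddof=1)
    if vx == 0 and vy == 0:
        if xa.mean() == ya.mean():
            return TestResult(
                statistic=0.0,
                p_value=1.0,
                alternative=Alternative.TWO_SIDED,
                effect_size=0.0,
                effect_size_kind="cohen_d",
                n=(xa.size, ya.size),
                method="welch_t[degenerate]",
                degenerate=True,
            )
        raise ValueError("zero variance in both samples with unequal means")
    res = sps.ttest_ind(xa, ya, equal_var=False)
    pooled_sd = math.sqrt(
        ((xa.size - 1) * vx + (ya.size - 1) * vy) / (xa.size + ya.size - 2)
    )
    d = (xa.mean() - ya.mean()) / pooled_sd if pooled_sd > 0 else 0.0
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alternative=Alternative.TWO_SIDED,
        effect_size=float(d),
        effect_size_kind="cohen_d",
        n=(xa.size, ya.size),
        method="welch_t",
    )


# ---------------------------------------------------------------------------
# experiment-table analyses
# ---------------------------------------------------------------------------


def assign_subgroup(delivered: int, estimated: int | str) -> str:
    """Classify a participant by delivered vs. model-estimated questions.

    A censored estimate (the session stopped while distress was still
    detected, so the model would have required at least one more
    question) is classified ``fewer``.
    """
    if estimated == CENSORED:
        return "fewer"
    est = int(estimated)
    if delivered == est:
        return "same"
    return "fewer" if delivered < est else "more"


def _metric_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Attach the four change metrics as columns (row-wise, not on means)."""
    out = table.copy()
    out["change_in_distress"] = out["k6_pre"] - out["k6_post"]
    out["cognitive_change"] = out["cci"].astype(float)
    out["mood_change"] = (out["mood_pre"] - out["mood_post"]) / out["mood_pre"]
    out["change_in_stai_s"] = out["stai_s_pre"] - out["stai_s_post"]
    return out


def change_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-arm mean (SD) of the four change metrics plus the one-sided
    adapted-greater Mann-Whitney comparison with Cliff's delta."""
    df = _metric_frame(table)
    rows = []
    for metric in CHANGE_METRICS:
        a = df.loc[df["arm"] == "adapted", metric].to_numpy()
        r = df.loc[df["arm"] == "random", metric].to_numpy()
        res = mann_whitney_u(a, r, Alternative.GREATER)
        rows.append(
            {
                "metric": metric,
                "adapted_mean": a.mean(),
                "adapted_sd": a.std(ddof=1),
                "random_mean": r.mean(),
                "random_sd": r.std(ddof=1),
                "cliff_delta": res.effect_size,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def condition_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Pre/post means per arm with between-arm two-sided Mann-Whitney
    tests and within-arm Wilcoxon signed-rank results (trial-table shape)."""
    rows = []
    specs = [
        ("k6", "k6_pre", "k6_post"),
        ("mood", "mood_pre", "mood_post"),
        ("stai_s", "stai_s_pre", "stai_s_post"),
    ]
    for name, pre_col, post_col in specs:
        a_pre = table.loc[table["arm"] == "adapted", pre_col].to_numpy(float)
        r_pre = table.loc[table["arm"] == "random", pre_col].to_numpy(float)
        a_post = table.loc[table["arm"] == "adapted", post_col].to_numpy(float)
        r_post = table.loc[table["arm"] == "random", post_col].to_numpy(float)
        between_pre = mann_whitney_u(a_pre, r_pre)
        between_post = mann_whitney_u(a_post, r_post)
        within_a = wilcoxon_signed_rank(a_pre, a_post)
        within_r = wilcoxon_signed_rank(r_pre, r_post)
        rows.append(
            {
                "measure": name,
                "adapted_pre_mean": a_pre.mean(),
                "adapted_pre_sd": a_pre.std(ddof=1),
                "adapted_post_mean": a_post.mean(),
                "adapted_post_sd": a_post.std(ddof=1),
                "random_pre_mean": r_pre.mean(),
                "random_pre_sd": r_pre.std(ddof=1),
                "random_post_mean": r_post.mean(),
                "random_post_sd": r_post.std(ddof=1),
                "between_pre_cliff_delta": between_pre.effect_size,
                "between_pre_p": between_pre.p_value,
                "between_post_cliff_delta": between_post.effect_size,
                "between_post_p": between_post.p_value,
                "within_adapted_r": within_a.effect_size,
                "within_adapted_p": within_a.p_value,
                "within_random_r": within_r.effect_size,
                "within_random_p": within_r.p_value,
            }
        )
    return pd.DataFrame(rows)


def subgroup_analysis(table: pd.DataFrame) -> dict:
    """Same/fewer/more subgroup summary with one-sided pairwise tests.

    Both arms are pooled. Returns ``summary`` (per-subgroup n, percent,
    and mean/SD of each change metric) and ``tests`` (one-sided
    Mann-Whitney same > fewer and same > more with Cliff's delta; skipped
    and flagged when a subgroup is empty).
    """
    df = _metric_frame(table)
    df["subgroup"] = [
        assign_subgroup(d, e)
        for d, e in zip(df["delivered_questions"], df["estimated_questions"])
    ]
    n_total = len(df)
    summary_rows = []
    for grp in ("same", "fewer", "more"):
        sub = df[df["subgroup"] == grp]
        row: dict = {
            "subgroup": grp,
            "n": len(sub),
            "percent": 100.0 * len(sub) / n_total,
        }
        for metric in CHANGE_METRICS:
            vals = sub[metric].to_numpy()
            row[f"{metric}_mean"] = vals.mean() if len(vals) else float("nan")
            row[f"{metric}_sd"] = vals.std(ddof=1) if len(vals) > 1 else float("nan")
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)

    tests = []
    same = df[df["subgroup"] == "same"]
    for other_name in ("fewer", "more"):
        other = df[df["subgroup"] == other_name]
        for metric in CHANGE_METRICS:
            entry: dict = {"comparison": f"same_vs_{other_name}", "metric": metric}
            if len(same) == 0 or len(other) == 0:
                entry.update({"skipped": True, "reason": "empty subgroup"})
            else:
                res = mann_whitney_u(
                    same[metric].to_numpy(), other[metric].to_numpy(), Alternative.GREATER
                )
                entry.update(
                    {
                        "skipped": False,
                        "cliff_delta": res.effect_size,
                        "p_value": res.p_value,
                    }
                )
            tests.append(entry)
    return {"summary": summary, "tests": pd.DataFrame(tests)}


def per_question_summaries(table: pd.DataFrame) -> dict:
    """Question-count and per-question detection summaries.

    ``by_count``: for each delivered question count 1..21 in the random
    arm, the mean (SD) of the four change metrics; means are NaN ("not
    available") when no participant received that count and SDs are NaN
    when fewer than two did. ``detections``: for each question index,
    how many participants' answers were detected distressed versus
    nondistressed among those who answered that question (both arms).
    """
    df = _metric_frame(table)
    rnd = df[df["arm"] == "random"]
    count_rows = []
    for k in range(1, 22):
        sub = rnd[rnd["delivered_questions"] == k]
        row: dict = {"n_questions": k, "n": len(sub)}
        for metric in CHANGE_METRICS:
            vals = sub[metric].to_numpy()
            row[f"{metric}_mean"] = vals.mean() if len(vals) >= 1 else float("nan")
            row[f"{metric}_sd"] = vals.std(ddof=1) if len(vals) >= 2 else float("nan")
        count_rows.append(row)
    by_count = pd.DataFrame(count_rows)

    det_rows = []
    for j in range(1, 22):
        distressed = nondistressed = 0
        for dets in df["detections"]:
            if len(dets) >= j:
                label = dets[j - 1]["label"] if isinstance(dets[j - 1], dict) else dets[j - 1]
                if str(label) in ("distressed", "DistressLabel.DISTRESSED"):
                    distressed += 1
                else:
                    nondistressed += 1
        det_rows.append(
            {
                "question_index": j,
                "distressed": distressed,
                "nondistressed": nondistressed,
            }
        )
    detections = pd.DataFrame(det_rows)
    return {"by_count": by_count, "detections": detections}


def holm_correction(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (offered as an option; the
    default reporting leaves the one-sided p-values unadjusted)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()
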