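"""Clinical outcome statistics for the three-timepoint open-label design.

Covers the stimulation-protocol arithmetic, the >=30% responder rule,
repeated-measures one-way ANOVA (sphericity assumed), Dunn–Bonferroni
paired comparisons with Cohen's d for paired change, Kruskal–Wallis with
an eta-squared effect size, the 3-category chi-square for patient global
impression of change, and Spearman rank correlation.

Conventions, stated once:

* Cohen's d for a paired change is mean(change)/SD(change); this is the
  variant consistent with the printed trial summaries.
* Bonferroni-adjusted CIs use the Dunn critical value t(df = n-1,
  1 - alpha/(2 m)) with the paired SD.  A pooled-error variant (the
  common stats-package behaviour) is available from the full n x 3 matrix.
* Kruskal–Wallis eta-squared is (H - k + 1)/(N - k); the three timepoints
  are treated as independent groups, so N counts patient x timepoint
  observations.
* All p-values are two-tailed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError

TIMEPOINTS = ("baseline", "post", "followup")
RESPONDER_THRESHOLD = 0.30


@dataclass(frozen=True)
class ProtocolSpec:
    """One rTMS session: pulse frequency, train/intertrain timing, dose."""

    frequency_hz: float = 10.0
    train_s: float = 5.0
    intertrain_s: float = 25.0
    n_trains: int = 36
    intensity_pct_rmt: float = 100.0

    def __post_init__(self) -> None:
        if min(self.frequency_hz, self.train_s, self.n_trains, self.intensity_pct_rmt) <= 0:
            raise InvalidParameterError("protocol parameters must be positive")
        if self.intertrain_s < 0:
            raise InvalidParameterError("intertrain interval must be >= 0")


@dataclass
class PairwiseResult:
    """A Bonferroni-corrected paired comparison (units of the input scale)."""

    mean_diff: float
    sd_diff: float
    t_stat: float
    p_adjusted: float
    ci_low: float
    ci_high: float
    cohen_d: float
    n: int
    n_comparisons: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def protocol_totals(spec: ProtocolSpec = ProtocolSpec()) -> dict:
    """Pulses per session and session duration.

    pulses = frequency x train length x number of trains; the session runs
    n trains with (n - 1) intertrain intervals.  Minutes are reported both
    raw and rounded up to the next whole minute.
    """
    pulses = spec.frequency_hz * spec.train_s * spec.n_trains
    seconds = spec.n_trains * spec.train_s + (spec.n_trains - 1) * spec.intertrain_s
    minutes = seconds / 60.0
    return {
        "pulses_per_session": int(round(pulses)),
        "session_minutes": minutes,
        "session_minutes_rounded": int(math.ceil(minutes)),
    }


def classify_responder(baseline: float, later: float, threshold: float = RESPONDER_THRESHOLD) -> bool:
    """True iff headache days dropped by at least the threshold fraction."""
    if baseline <= 0:
        raise InvalidParameterError("baseline headache days must be > 0")
    return (baseline - later) / baseline >= threshold


def response_rate(cohort: pd.DataFrame, timepoint: str = "post",
                  threshold: float = RESPONDER_THRESHOLD) -> dict:
    """Responder percentage at a timepoint under the >=30% reduction rule."""
    if timepoint not in ("post", "followup"):
        raise InvalidParameterError(f"timepoint must be 'post' or 'followup', got {timepoint!r}")
    if len(cohort) == 0:
        raise InvalidParameterError("cohort is empty")
    flags = [
        classify_responder(b, l, threshold)
        for b, l in zip(cohort["days_baseline"], cohort[f"days_{timepoint}"])
    ]
    n_resp = int(sum(flags))
    return {
        "n_responders": n_resp,
        "n_total": len(flags),
        "rate_percent": round(100.0 * n_resp / len(flags), 2),
        "responder_flags": flags,
    }


# ---------------------------------------------------------------------------
# Paired comparisons


def _dunn_critical(n: int, n_comparisons: int, alpha: float) -> float:
    return float(stats.t.ppf(1 - alpha / (2 * n_comparisons), n - 1))


def paired_bonferroni_from_summary(
    mean_diff: float, sd_diff: float, n: int, n_comparisons: int = 1, alpha: float = 0.05
) -> PairwiseResult:
    """Paired comparison from summary statistics of the differences."""
    if n < 3:
        raise InvalidParameterError("need n >= 3")
    if n_comparisons < 1:
        raise InvalidParameterError("n_comparisons must be >= 1")
    if sd_diff == 0:
        warnings.warn("zero SD of differences: effect size undefined", RuntimeWarning)
        return PairwiseResult(mean_diff, 0.0, math.inf if mean_diff else 0.0, 0.0 if mean_diff else 1.0,
                              mean_diff, mean_diff, math.inf if mean_diff else 0.0,
                              n, n_comparisons, degenerate=True)
    se = sd_diff / math.sqrt(n)
    t_stat = mean_diff / se
    p_raw = 2 * stats.t.sf(abs(t_stat), n - 1)
    tc = _dunn_critical(n, n_comparisons, alpha)
    return PairwiseResult(
        mean_diff=float(mean_diff),
        sd_diff=float(sd_diff),
        t_stat=float(t_stat),
        p_adjusted=float(min(1.0, n_comparisons * p_raw)),
        ci_low=float(mean_diff - tc * se),
        ci_high=float(mean_diff + tc * se),
        cohen_d=float(mean_diff / sd_diff),
        n=n,
        n_comparisons=n_comparisons,
    )


def paired_bonferroni(values_a, values_b, n_comparisons: int = 1, alpha: float = 0.05) -> PairwiseResult:
    """Bonferroni-corrected paired t comparison of two per-patient vectors.

    Differences are a - b; the CI uses the Dunn critical value on df n-1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidParameterError("inputs must be equal-length 1-D vectors")
    d = a - b
    return paired_bonferroni_from_summary(
        float(d.mean()), float(d.std(ddof=1)), len(d), n_comparisons, alpha
    )


def pooled_error_ci(values: np.ndarray, i: int, j: int, n_comparisons: int = 1,
                    alpha: float = 0.05) -> tuple[float, float]:
    """Pooled-error Bonferroni CI for column i - column j of an n x k matrix.

    Uses the RM-ANOVA error mean square on df (k-1)(n-1), the convention of
    several stats packages, as an alternative to the paired-SD CI.
    """
    res = rm_anova(values)
    x = np.asarray(values, dtype=float)
    n, k = x.shape
    mean_diff = float(x[:, i].mean() - x[:, j].mean())
    se = math.sqrt(2.0 * res["ms_error"] / n)
    tc = float(stats.t.ppf(1 - alpha / (2 * n_comparisons), res["df_error"]))
    return mean_diff - tc * se, mean_diff + tc * se


# ---------------------------------------------------------------------------
# Omnibus tests


def rm_anova(values) -> dict:
    """One-way repeated-measures ANOVA (sphericity assumed).

    ``values`` is an n-subjects x k-conditions matrix with no missing
    cells; df_effect = k-1, df_error = (k-1)(n-1).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise InvalidParameterError("need an n x k matrix with n >= 3, k >= 2")
    if not np.all(np.isfinite(x)):
        raise InvalidParameterError("missing or non-finite cells are not supported")
    n, k = x.shape
    grand = x.mean()
    cond_means = x.mean(axis=0)
    subj_means = x.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_err = np.sum((x - subj_means[:, None] - cond_means[None, :] + grand) ** 2)
    df_effect, df_error = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df_effect
    ms_err = ss_err / df_error
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    # relative threshold: error SS indistinguishable from 0 at double precision
    if ss_err <= 1e-10 * max(ss_cond, ss_subj, 1e-300):
        warnings.warn("degenerate error term in RM-ANOVA", RuntimeWarning)
        f = math.inf if ms_cond > 0 else 0.0
        p = 0.0 if ms_cond > 0 else 1.0
    else:
        f = ms_cond / ms_err
        p = float(stats.f.sf(f, df_effect, df_error))
    return {
        "F": float(f),
        "df_effect": df_effect,
        "df_error": df_error,
        "p": float(p),
        "ms_error": float(ms_err),
    }


def kw_eta_squared(h: float, k: int, n_total: int) -> float:
    """Eta-squared effect size for a Kruskal–Wallis H statistic."""
    if n_total <= k:
        raise InvalidParameterError("need N > k")
    return (h - k + 1) / (n_total - k)


def kruskal_wallis_eta2(groups: list) -> dict:
    """Kruskal–Wallis across groups with tie correction, plus eta-squared."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    if k < 2 or n_total < k + 2:
        raise InvalidParameterError("need k >= 2 groups and N >= k + 2")
    concat = np.concatenate(groups)
    if np.all(concat == concat[0]):
        warnings.warn("all observations identical: H undefined, reported as 0", RuntimeWarning)
        return {"H": 0.0, "p": 1.0, "eta_squared": 0.0, "k": k, "N": n_total}
    h, p = stats.kruskal(*groups)
    return {
        "H": float(h),
        "p": float(p),
        "eta_squared": float(max(0.0, kw_eta_squared(float(h), k, n_total))),
        "k": k,
        "N": n_total,
    }


def pgic_chisquare(counts) -> dict:
    """Goodness-of-fit chi-square of 3-category PGIC counts vs uniform."""
    obs = np.asarray(counts, dtype=float)
    if obs.sum() <= 0:
        raise InvalidParameterError("PGIC counts sum to zero")
    chi2, p = stats.chisquare(obs)
    return {"chi2": float(chi2), "df": len(obs) - 1, "p": float(p)}


def spearman_rho(x, y) -> dict:
    """Spearman rank correlation (mid-ranks for ties), two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise InvalidParameterError("need equal-length vectors of length >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise InvalidParameterError("Spearman correlation of a constant input is undefined")
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p)}


# ---------------------------------------------------------------------------
# Whole-cohort report


def analyze_cohort(cohort: pd.DataFrame, responder_threshold: float = RESPONDER_THRESHOLD) -> dict:
    """The trial's statistical battery on one cohort table."""
    days = cohort[["days_baseline", "days_post", "days_followup"]].to_numpy(dtype=float)
    report: dict = {"n_patients": int(len(cohort))}
    report["protocol"] = protocol_totals()
    report["rm_anova_days"] = rm_anova(days)
    report["pairwise_days"] = {
        "baseline_vs_post": paired_bonferroni(days[:, 0], days[:, 1], n_comparisons=3).to_dict(),
        "baseline_vs_followup": paired_bonferroni(days[:, 0], days[:, 2], n_comparisons=3).to_dict(),
        "post_vs_followup": paired_bonferroni(days[:, 1], days[:, 2], n_comparisons=3).to_dict(),
    }
    for rate_tp in ("post", "followup"):
        rr = response_rate(cohort, rate_tp, responder_threshold)
        rr.pop("responder_flags")
        report[f"response_rate_{rate_tp}"] = rr
    for measure, bounds in (("intensity", (0, 10)), ("psqi", (0, 21))):
        groups = [cohort[f"{measure}_{tp}"].to_numpy(dtype=float) for tp in TIMEPOINTS]
        report[f"kruskal_{measure}"] = kruskal_wallis_eta2(groups)
    for tp in ("post", "followup"):
        counts = [
            int((cohort[f"pgic_{tp}"] == cat).sum())
            for cat in ("improvement", "no_change", "worsening")
        ]
        report[f"pgic_{tp}"] = {"counts": counts, **pgic_chisquare(counts)}
    # PGIC (coded improvement=1 .. worsening=3) vs realised reduction at post
    reduction = (cohort["days_baseline"] - cohort["days_post"]) / cohort["days_baseline"]
    pgic_code = cohort["pgic_post"].map({"improvement": 1, "no_change": 2, "worsening": 3})
    try:
        report["spearman_pgic_vs_reduction"] = spearman_rho(pgic_code, reduction)
    except InvalidParameterError:
        report["spearman_pgic_vs_reduction"] = None
    return report
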