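"""Responder classification from connectivity change: ROC, AUC, group test.

AUC is computed from the Mann–Whitney U statistic (ties counted one half),
which equals the trapezoidal area under the empirical ROC curve.  Higher
scores are treated as responder-positive.  Significance comes from a
permutation test of the labels: exact enumeration of all label assignments
when that is feasible, otherwise seeded Monte-Carlo resampling; the
normal-approximation Mann–Whitney p is reported alongside for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

from .errors import InvalidParameterError

EXACT_ENUMERATION_LIMIT = 500_000


@dataclass
class RocResult:
    """ROC summary at the Youden-optimal operating point."""

    auc: float
    p_value: float
    p_method: str
    p_mann_whitney: float
    sensitivity: float  # percent
    specificity: float  # percent
    threshold: float
    curve: list[tuple[float, float]]  # (fpr, tpr), starts (0,0), ends (1,1)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["curve"] = [list(pt) for pt in self.curve]
        return d


def auc_score(scores, labels) -> float:
    """Rank-based AUC = U / (n1 * n0), ties counted one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise InvalidParameterError("both classes must be present")
    ranks = stats.rankdata(s)
    u1 = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u1 / (n1 * n0))


def _auc_from_ranksum(ranksum: np.ndarray, n1: int, n0: int) -> np.ndarray:
    return (ranksum - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def _permutation_p(scores: np.ndarray, labels: np.ndarray, auc_obs: float,
                   rng: np.random.Generator, n_mc: int = 10_000) -> tuple[float, str]:
    """Two-sided permutation p for AUC vs the chance value 0.5.

    All C(n, n1) label assignments are enumerated when their count is small
    enough; the null statistic only depends on the rank-sum of the
    positive class, so each assignment costs one sum.
    """
    n = len(scores)
    n1 = int(labels.sum())
    n0 = n - n1
    ranks = stats.rankdata(scores)
    stat_obs = abs(auc_obs - 0.5)
    if comb(n, n1) <= EXACT_ENUMERATION_LIMIT:
        assign = np.fromiter(
            (i for c in combinations(range(n), n1) for i in c),
            dtype=np.intp,
            count=comb(n, n1) * n1,
        ).reshape(-1, n1)
        sums = ranks[assign].sum(axis=1)
        null = _auc_from_ranksum(sums, n1, n0)
        p = float(np.mean(np.abs(null - 0.5) >= stat_obs - 1e-12))
        return p, "exact-permutation"
    sums = np.empty(n_mc)
    for i in range(n_mc):
        sums[i] = ranks[rng.permutation(n)[:n1]].sum()
    null = _auc_from_ranksum(sums, n1, n0)
    p = float((1 + np.sum(np.abs(null - 0.5) >= stat_obs - 1e-12)) / (1 + n_mc))
    return p, "monte-carlo-permutation"


def roc_auc(scores, labels, p_method: str = "auto", seed: int = 0) -> RocResult:
    """Full ROC analysis of responder labels against a score.

    ``p_method`` is "auto" (exact when feasible, else Monte-Carlo),
    or "none" to skip the permutation test (p_value = nan).
    The operating point maximises Youden's J; ties go to the point with
    higher specificity.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise InvalidParameterError("scores and labels must be equal-length 1-D vectors")
    auc = auc_score(s, y)  # validates both classes present

    fpr, tpr, thresholds = roc_curve(y, s, drop_intermediate=False)
    j = np.round(tpr - fpr, 12)  # rounding keeps exact J ties tied at double precision
    best = int(np.lexsort((fpr, -j))[0])  # max J, ties -> lowest fpr (higher specificity)
    sens = 100.0 * tpr[best]
    spec = 100.0 * (1.0 - fpr[best])
    thr = float(thresholds[best]) if np.isfinite(thresholds[best]) else float(s.max())

    try:
        mw = stats.mannwhitneyu(s[y], s[~y], alternative="two-sided")
        p_mw = float(mw.pvalue)
    except ValueError:
        p_mw = float("nan")

    if p_method == "none":
        p, method = float("nan"), "none"
    else:
        p, method = _permutation_p(s, y, auc, np.random.default_rng(seed))
    return RocResult(
        auc=auc,
        p_value=p,
        p_method=method,
        p_mann_whitney=p_mw,
        sensitivity=float(sens),
        specificity=float(spec),
        threshold=thr,
        curve=[(float(a), float(b)) for a, b in zip(fpr, tpr)],
    )


def group_ttest(scores, labels, equal_var: bool = True) -> dict:
    """Two-sample t-test of scores between responders and non-responders."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    g1, g0 = s[y], s[~y]
    if len(g1) < 2 or len(g0) < 2:
        raise InvalidParameterError("need at least 2 observations per class")
    if g1.std(ddof=1) == 0 and g0.std(ddof=1) == 0:
        raise InvalidParameterError("both groups are constant")
    res = stats.ttest_ind(g1, g0, equal_var=equal_var)
    df = len(g1) + len(g0) - 2 if equal_var else float(res.df)
    return {
        "t": float(res.statistic),
        "df": float(df),
        "p": float(res.pvalue),
        "mean_responders": float(g1.mean()),
        "mean_nonresponders": float(g0.mean()),
        "equal_var": equal_var,
    }
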