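"""Cohort-level evaluation of a risk index against a 0/1 phenotype.

Four views of the same question — does the index separate cases from controls:
point-biserial Pearson correlation, pooled two-sample t-test (cases minus
controls), ROC AUC (Mann-Whitney formulation, ties count 1/2), and odds ratios
from dichotomised scores. The dichotomisation behind a published OR is often
unstated, so both a median split and a top-vs-bottom-quartile contrast are
computed, plus a per-SD logistic OR, which needs no cut at all.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "EvaluationReport",
    "pearson_with_label",
    "two_sample_test",
    "roc_auc",
    "odds_ratio",
    "per_sd_logistic_or",
    "evaluate",
]


@dataclass(frozen=True)
class EvaluationReport:
    pearson_r: float
    pearson_p: float
    t_statistic: float
    t_p: float
    auc: float
    or_median_split: float
    or_median_split_ci: tuple[float, float]
    or_q4_vs_q1: float
    or_q4_vs_q1_ci: tuple[float, float]
    or_per_sd: float | None
    or_per_sd_ci: tuple[float, float] | None
    n_cases: int
    n_controls: int
    auc_ci: tuple[float, float] | None = None
    haldane_correction: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("or_median_split_ci", "or_q4_vs_q1_ci", "or_per_sd_ci", "auc_ci"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d


def _align(scores, labels):
    if isinstance(scores, pd.Series):
        s = scores.to_numpy(dtype=float)
    else:
        # MdiScores or plain array
        s = getattr(scores, "scores", scores)
        s = s.to_numpy(dtype=float) if isinstance(s, pd.Series) else np.asarray(s, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.size != y.size:
        raise ValueError("scores and labels have different lengths")
    ok = np.isfinite(s)
    return s[ok], y[ok]


def pearson_with_label(scores, labels) -> tuple[float, float]:
    """Point-biserial Pearson r and its two-sided p from t with n-2 df."""
    s, y = _align(scores, labels)
    if s.size < 3:
        raise ValueError("need at least 3 scored samples")
    if len(np.unique(y)) < 2:
        raise ValueError("both labels must be present")
    if np.ptp(s) == 0.0:
        raise ValueError("scores have zero variance")
    sd = s - s.mean()
    yd = y - y.mean()
    r = float((sd * yd).sum() / np.sqrt((sd * sd).sum() * (yd * yd).sum()))
    df = s.size - 2
    r_clip = min(max(r, -1.0), 1.0)
    if abs(r_clip) == 1.0:
        return r_clip, 0.0
    t = r_clip * np.sqrt(df / (1.0 - r_clip**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def two_sample_test(scores, labels) -> tuple[float, float]:
    """Pooled two-sample t (cases - controls) and its two-sided p."""
    s, y = _align(scores, labels)
    cases, ctrls = s[y == 1], s[y == 0]
    if cases.size < 2 or ctrls.size < 2:
        raise ValueError("each class needs at least 2 scored samples")
    res = stats.ttest_ind(cases, ctrls, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def roc_auc(scores, labels, return_curve: bool = False):
    """AUC via the Mann-Whitney formulation (ties 1/2); optionally the ROC curve."""
    s, y = _align(scores, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both labels must be present")
    auc = float(roc_auc_score(y, s))
    if return_curve:
        fpr, tpr, _ = roc_curve(y, s)
        return auc, (fpr, tpr)
    return auc


def _or_from_table(a: float, b: float, c: float, d: float):
    """OR = ad/bc with a Woolf (log-normal) 95% CI; Haldane-Anscombe 0.5 on zero cells."""
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(or_) - 1.96 * se), np.exp(np.log(or_) + 1.96 * se)
    return float(or_), (float(lo), float(hi)), corrected


def odds_ratio(scores, labels, mode: str = "median_split"):
    """Odds ratio of case status for high vs low scores.

    ``median_split`` dichotomises at the cohort median (ties at the median go
    low). ``q4_vs_q1`` contrasts only the top quartile (score > 75th
    percentile) against the bottom (score <= 25th percentile); boundary ties go
    to the lower bin. Returns (OR, (lo, hi), haldane_flag).
    """
    s, y = _align(scores, labels)
    if mode == "median_split":
        cut = np.median(s)
        high = s > cut
        low = ~high
    elif mode == "q4_vs_q1":
        q25, q75 = np.percentile(s, [25, 75])
        high = s > q75
        low = s <= q25
    else:
        raise ValueError(f"unknown mode '{mode}'")
    if not high.any() or not low.any():
        raise ValueError("all samples fall on one side of the cut")
    a = int(((y == 1) & high).sum())  # cases, high score
    b = int(((y == 0) & high).sum())
    c = int(((y == 1) & low).sum())
    d = int(((y == 0) & low).sum())
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        raise ValueError("2x2 table has an empty margin")
    return _or_from_table(a, b, c, d)


def per_sd_logistic_or(scores, labels):
    """OR per 1 SD of the score from a univariate logistic fit (Wald CI)."""
    import warnings

    import statsmodels.api as sm

    s, y = _align(scores, labels)
    z = (s - s.mean()) / s.std(ddof=1)
    X = np.column_stack([np.ones_like(z), z])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    b, se = fit.params[1], fit.bse[1]
    if not (np.isfinite(b) and np.isfinite(se)) or abs(b) > 15.0:
        raise ValueError("per-SD logistic OR unidentified (separation)")
    return float(np.exp(b)), (float(np.exp(b - 1.96 * se)), float(np.exp(b + 1.96 * se)))


def _bootstrap_auc_ci(s, y, n_boot, seed):
    rng = np.random.default_rng(seed)
    n = s.size
    aucs = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yy = y[idx]
        if yy.min() == yy.max():
            continue
        aucs.append(roc_auc_score(yy, s[idx]))
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return (float(lo), float(hi))


def evaluate(scores, labels, n_boot: int = 0, seed: int | None = None) -> EvaluationReport:
    """Full evaluation report for an index against a 0/1 phenotype."""
    s, y = _align(scores, labels)
    r, rp = pearson_with_label(s, y)
    t, tp = two_sample_test(s, y)
    auc = roc_auc(s, y)
    or_med, ci_med, hal1 = odds_ratio(s, y, "median_split")
    or_q, ci_q, hal2 = odds_ratio(s, y, "q4_vs_q1")
    try:
        or_sd, ci_sd = per_sd_logistic_or(s, y)
    except Exception:  # perfect separation etc.
        or_sd, ci_sd = None, None
    auc_ci = _bootstrap_auc_ci(s, y, n_boot, seed) if n_boot else None
    return EvaluationReport(
        pearson_r=r,
        pearson_p=rp,
        t_statistic=t,
        t_p=tp,
        auc=auc,
        or_median_split=or_med,
        or_median_split_ci=ci_med,
        or_q4_vs_q1=or_q,
        or_q4_vs_q1_ci=ci_q,
        or_per_sd=or_sd,
        or_per_sd_ci=ci_sd,
        n_cases=int((y == 1).sum()),
        n_controls=int((y == 0).sum()),
        auc_ci=auc_ci,
        haldane_correction=hal1 or hal2,
    )
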