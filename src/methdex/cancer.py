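"""Per-year breast-cancer risk models built on the mDI and blood cell counts.

The prospective cohort yields one binary modelling problem per follow-up year
y: cases are participants diagnosed by year y, controls are participants who
stayed cancer-free through the final follow-up (diagnoses after y are excluded
from year y's cohort). Predictors are the mDI plus blood cell proportions and
their ratios — monocytes, granulocytes, lymphocytes, CD4/CD8, the
granulocyte-to-lymphocyte ratio (NLR) and the monocyte-to-lymphocyte ratio
(MLR) — each z-scored on the modelling subset.

Model selection is bidirectional stepwise logistic regression driven by
deviance (likelihood-ratio) tests: the candidate with the smallest entry p
below ``p_enter`` is added, then included terms with removal p above
``p_remove`` are dropped, until nothing changes. Candidates are the 7 main
effects and all 21 pairwise interactions of the z-scored predictors. When an
interaction enters, missing parent main effects enter with it, and a parent is
never removed while its interaction stays — so a weak main effect can survive
in the final table purely to support an interaction. A random forest on the
main effects serves as a selection-free comparator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .evaluation import odds_ratio

logger = logging.getLogger("methdex")

__all__ = [
    "MAIN_EFFECTS",
    "RiskDesign",
    "RiskModelFit",
    "z_transform",
    "build_per_year_cohorts",
    "build_risk_design",
    "stepwise_logistic",
    "quartile_or",
    "rf_model",
    "r2_contribution",
    "CancerRiskModel",
    "CancerRiskResults",
]

MAIN_EFFECTS = ("mDI", "mono", "gran", "lympho", "cd4_cd8", "nlr", "mlr")
SEPARATION_COEF = 15.0  # |coef| beyond this on the z scale flags separation
RIDGE_LAMBDA = 1e-6


def z_transform(values) -> np.ndarray:
    """(x - mean) / SD with the unbiased (n-1) SD."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to z-transform")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero standard deviation")
    return (x - x.mean()) / sd


@dataclass(frozen=True)
class RiskDesign:
    """z-scored predictors, binary outcome and the follow-up year of the cohort."""

    frame: pd.DataFrame  # columns = MAIN_EFFECTS, z-scored on this subset
    y: np.ndarray
    year: int | None = None

    def __post_init__(self) -> None:
        for col in MAIN_EFFECTS:
            if col not in self.frame.columns:
                raise ValueError(f"design missing predictor '{col}'")
        if len(self.frame) != len(self.y):
            raise ValueError("design and outcome lengths differ")

    def column(self, term: str) -> np.ndarray:
        """Column for a main effect or an ``a:b`` interaction (product of parents)."""
        if ":" in term:
            a, b = term.split(":")
            return self.frame[a].to_numpy() * self.frame[b].to_numpy()
        return self.frame[term].to_numpy()


@dataclass(frozen=True)
class RiskModelFit:
    """Stepwise fit: selected terms with the Wald coefficient table and AUCs."""

    table: pd.DataFrame  # index term; columns estimate, se, t_stat, p_value
    terms: tuple[str, ...]
    auc_in_sample: float | None
    auc_cv: float | None
    pseudo_r2: float
    year: int | None = None
    separation_flagged: bool = False

    def summary(self) -> str:
        year = f" (year {self.year})" if self.year is not None else ""
        lines = [f"Stepwise logistic risk model{year}", "=" * 46]
        if self.table.empty:
            lines.append("<empty model: no term passed the entry test>")
        else:
            lines.append(self.table.to_string(float_format=lambda v: f"{v: .4f}"))
        lines.append(f"McFadden pseudo-R2: {self.pseudo_r2:.4f}")
        if self.auc_in_sample is not None:
            lines.append(f"In-sample AUC: {self.auc_in_sample:.4f}")
        if self.auc_cv is not None:
            lines.append(f"Stratified 5-fold CV AUC: {self.auc_cv:.4f}")
        if self.separation_flagged:
            lines.append("WARNING: separation detected; ridge (1e-6) fallback used")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# cohorts & designs
# ---------------------------------------------------------------------------


def build_per_year_cohorts(pheno, year_min: int = 3, min_cases: int = 10):
    """Cumulative per-year case/control cohorts from a prospective phenotype.

    For each follow-up year y >= ``year_min``: cases are samples with
    ``diagnosis_year <= y``; controls are samples never diagnosed. Years with
    fewer than ``min_cases`` cases are skipped with a warning. Returns a list
    of (year, case_ids, control_ids).
    """
    f = pheno.frame
    if "diagnosis_year" not in f.columns:
        raise ValueError("phenotype has no diagnosis_year column")
    dy = f["diagnosis_year"]
    cases_all = f.index[f["label"].eq(1)]
    if dy.loc[cases_all].isna().any():
        raise ValueError("every case needs a diagnosis_year")
    controls = list(f.index[f["label"].eq(0)])
    last_year = int(dy.max())
    out = []
    for year in range(year_min, last_year + 1):
        case_ids = list(f.index[dy.notna() & (dy <= year)])
        if len(case_ids) < min_cases:
            warnings.warn(f"year {year}: only {len(case_ids)} case(s); skipped", stacklevel=2)
            continue
        out.append((year, case_ids, controls))
    return out


def build_risk_design(scores, pheno, case_ids, control_ids, year=None) -> RiskDesign:
    """Assemble and z-score the 7-predictor design for one per-year cohort."""
    s = scores.scores if hasattr(scores, "scores") else scores
    ids = list(case_ids) + list(control_ids)
    f = pheno.frame.loc[ids]
    raw = pd.DataFrame(index=pd.Index(ids, name="sample_id"))
    raw["mDI"] = s.loc[ids].to_numpy(dtype=float)
    raw["mono"] = f["mono"].to_numpy(dtype=float)
    raw["gran"] = f["gran"].to_numpy(dtype=float)
    raw["lympho"] = f["lympho"].to_numpy(dtype=float)
    raw["cd4_cd8"] = f["cd4"].to_numpy(dtype=float) / f["cd8"].to_numpy(dtype=float)
    raw["nlr"] = raw["gran"] / raw["lympho"]
    raw["mlr"] = raw["mono"] / raw["lympho"]
    if raw.isna().any().any():
        raise ValueError("missing predictor values in the modelling subset")
    zed = raw.apply(lambda c: z_transform(c.to_numpy()), axis=0)
    y = np.array([1] * len(case_ids) + [0] * len(control_ids))
    return RiskDesign(frame=zed, y=y, year=year)


# ---------------------------------------------------------------------------
# stepwise logistic regression
# ---------------------------------------------------------------------------


def _all_candidates() -> list[str]:
    mains = list(MAIN_EFFECTS)
    inters = [f"{a}:{b}" for a, b in combinations(MAIN_EFFECTS, 2)]
    return mains + inters


def _parents(term: str) -> tuple[str, ...]:
    return tuple(term.split(":")) if ":" in term else ()


def _design_matrix(design: RiskDesign, terms) -> np.ndarray:
    cols = [np.ones(len(design.y))]
    cols += [design.column(t) for t in terms]
    return np.column_stack(cols)


def _ridge_logit(X: np.ndarray, y: np.ndarray, lam: float):
    """Penalised IRLS for logistic regression (no penalty on the intercept)."""
    n, p = X.shape
    beta = np.zeros(p)
    pen = lam * np.eye(p)
    pen[0, 0] = 0.0
    for _ in range(100):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu)
        H = X.T @ (X * W[:, None]) + 2.0 * pen
        g = X.T @ (y - mu) - 2.0 * pen @ beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    with np.errstate(divide="ignore"):
        ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    cov = np.linalg.inv(X.T @ (X * (mu * (1 - mu))[:, None]) + 2.0 * pen)
    return beta, np.sqrt(np.diag(cov)), ll, mu


class _Fit:
    """Thin wrapper holding what stepwise needs from one GLM fit."""

    __slots__ = ("params", "bse", "llf", "deviance", "fitted", "separated")

    def __init__(self, params, bse, llf, fitted, separated):
        self.params = params
        self.bse = bse
        self.llf = llf
        self.deviance = -2.0 * llf
        self.fitted = fitted
        self.separated = separated


def _fit_terms(design: RiskDesign, terms) -> _Fit:
    X = _design_matrix(design, terms)
    y = design.y
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
            params, bse, llf, fitted = res.params, res.bse, float(res.llf), res.fittedvalues
        except Exception:
            params = np.full(X.shape[1], np.inf)
            bse = llf = fitted = None
    separated = params is None or not np.all(np.isfinite(params)) or np.any(
        np.abs(params) > SEPARATION_COEF
    )
    if separated:
        params, bse, llf, fitted = _ridge_logit(X, y, RIDGE_LAMBDA)
    return _Fit(np.asarray(params), np.asarray(bse), float(llf), np.asarray(fitted), separated)


def stepwise_logistic(
    design: RiskDesign,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    candidates=None,
    forced=(),
    cv_seed: int | None = None,
    compute_cv: bool = False,
) -> RiskModelFit:
    """Bidirectional stepwise binomial GLM over main effects and interactions.

    Entry and removal are decided by deviance (chi-square) tests; the reported
    table carries Wald statistics for each selected term. Adding an ``a:b``
    interaction pulls in any missing parent in the same step (the entry test
    then has one df per added column); a parent cannot be removed while one of
    its interactions is in the model. Deterministic given the design: ties on
    p are broken by term name.
    """
    if candidates is None:
        candidates = _all_candidates()
    candidates = sorted(set(candidates) | set(forced))
    current: list[str] = list(sorted(forced))
    history = {frozenset(current)}
    separated = False
    for _ in range(200):
        changed = False
        base = _fit_terms(design, current)
        separated |= base.separated
        # forward: best candidate by entry p
        best = None
        for cand in sorted(c for c in candidates if c not in current):
            added = [p for p in _parents(cand) if p not in current and p in candidates]
            trial = current + added + [cand]
            fit = _fit_terms(design, trial)
            p = float(stats.chi2.sf(base.deviance - fit.deviance, df=len(added) + 1))
            if best is None or p < best[0]:
                best = (p, cand, added)
        if best is not None and best[0] < p_enter:
            current = current + best[2] + [best[1]]
            changed = True
        # backward: drop worst removable term(s)
        while len(current) > 0:
            full = _fit_terms(design, current)
            separated |= full.separated
            locked = set(sorted(forced))
            for t in current:
                if ":" in t:
                    locked.update(p for p in _parents(t) if p in current)
            removable = [t for t in current if t not in locked]
            worst = None
            for t in sorted(removable):
                reduced = [u for u in current if u != t]
                fit = _fit_terms(design, reduced)
                p = float(stats.chi2.sf(fit.deviance - full.deviance, df=1))
                if worst is None or p > worst[0]:
                    worst = (p, t)
            if worst is not None and worst[0] > p_remove:
                current = [u for u in current if u != worst[1]]
                changed = True
            else:
                break
        state = frozenset(current)
        if not changed or state in history:
            break
        history.add(state)

    # order terms: mains in canonical order, then interactions
    order = {t: i for i, t in enumerate(_all_candidates())}
    current = sorted(current, key=lambda t: order.get(t, len(order)))
    final = _fit_terms(design, current)
    separated |= final.separated
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = final.params / final.bse
        pvals = 2.0 * stats.norm.sf(np.abs(tstat))
    names = ["Intercept"] + current
    table = pd.DataFrame(
        {
            "estimate": final.params,
            "se": final.bse,
            "t_stat": tstat,
            "p_value": pvals,
        },
        index=pd.Index(names, name="term"),
    ).drop(index="Intercept")
    null = _fit_terms(design, [])
    pseudo_r2 = 1.0 - final.llf / null.llf if null.llf != 0 else 0.0
    auc_in = (
        float(roc_auc_score(design.y, final.fitted)) if current else None
    )
    auc_cv = None
    if compute_cv and current:
        auc_cv = _cv_auc(design, current, cv_seed)
    return RiskModelFit(
        table=table,
        terms=tuple(current),
        auc_in_sample=auc_in,
        auc_cv=auc_cv,
        pseudo_r2=float(pseudo_r2),
        year=design.year,
        separation_flagged=separated,
    )


def _cv_auc(design: RiskDesign, terms, seed) -> float:
    """Stratified 5-fold CV AUC refitting the selected terms per fold."""
    X = _design_matrix(design, terms)
    y = design.y
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    preds = np.empty_like(y, dtype=float)
    for tr, te in skf.split(X, y):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.GLM(y[tr], X[tr], family=sm.families.Binomial()).fit(maxiter=200)
                beta = res.params
            except Exception:
                beta = _ridge_logit(X[tr], y[tr], RIDGE_LAMBDA)[0]
        if not np.all(np.isfinite(beta)) or np.any(np.abs(beta) > SEPARATION_COEF):
            beta = _ridge_logit(X[tr], y[tr], RIDGE_LAMBDA)[0]
        preds[te] = 1.0 / (1.0 + np.exp(-(X[te] @ beta)))
    return float(roc_auc_score(y, preds))


def quartile_or(scores, case_ids, control_ids):
    """Top-vs-bottom-quartile OR of the mDI within one per-year cohort."""
    s = scores.scores if hasattr(scores, "scores") else scores
    ids = list(case_ids) + list(control_ids)
    y = np.array([1] * len(case_ids) + [0] * len(control_ids))
    or_, ci, _ = odds_ratio(s.loc[ids].to_numpy(dtype=float), y, mode="q4_vs_q1")
    return or_, ci


def rf_model(design: RiskDesign, n_trees: int = 500, rng_seed: int | None = None):
    """Random-forest comparator on the 7 main effects.

    Returns (cv_auc, importances) where ``importances`` is a DataFrame of
    permutation importances (mean, sd over 20 shuffles) per predictor, from a
    forest fit on the full data; the AUC is stratified 5-fold CV.
    """
    y = design.y
    if (y == 1).sum() < 20 or (y == 0).sum() < 20:
        raise ValueError("need at least 20 samples per class")
    X = design.frame[list(MAIN_EFFECTS)].to_numpy()
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=rng_seed)
    preds = np.empty_like(y, dtype=float)
    for tr, te in skf.split(X, y):
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=rng_seed)
        clf.fit(X[tr], y[tr])
        preds[te] = clf.predict_proba(X[te])[:, 1]
    cv_auc = float(roc_auc_score(y, preds))
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=rng_seed)
    clf.fit(X, y)
    imp = permutation_importance(
        clf, X, y, n_repeats=20, random_state=rng_seed, scoring="roc_auc"
    )
    importances = pd.DataFrame(
        {"importance": imp.importances_mean, "sd": imp.importances_std},
        index=pd.Index(MAIN_EFFECTS, name="predictor"),
    )
    return cv_auc, importances


def r2_contribution(design: RiskDesign, full_terms, reduced_terms):
    """McFadden pseudo-R2 of nested fits and the LR p of the removed block."""
    full_terms = list(full_terms)
    reduced_terms = list(reduced_terms)
    if not set(reduced_terms) <= set(full_terms):
        raise ValueError("reduced_terms must be a subset of full_terms")
    null = _fit_terms(design, [])
    full = _fit_terms(design, full_terms)
    reduced = _fit_terms(design, reduced_terms)
    r2_full = 1.0 - full.llf / null.llf
    r2_reduced = 1.0 - reduced.llf / null.llf
    df = len(full_terms) - len(reduced_terms)
    if df == 0:
        return float(r2_full), float(r2_reduced), 1.0
    p = float(stats.chi2.sf(reduced.deviance - full.deviance, df=df))
    return float(r2_full), float(r2_reduced), p


# ---------------------------------------------------------------------------
# Model / Results faces
# ---------------------------------------------------------------------------


class CancerRiskModel:
    """Stepwise logistic risk model for one per-year cohort.

    Parameters
    ----------
    design : RiskDesign
        z-scored predictors and outcome, e.g. from :func:`build_risk_design`.
    p_enter, p_remove : float
        Deviance-test thresholds for adding / dropping terms.
    """

    def __init__(self, design: RiskDesign, p_enter: float = 0.05, p_remove: float = 0.10):
        self.design = design
        self.p_enter = p_enter
        self.p_remove = p_remove

    @classmethod
    def from_scores(cls, scores, pheno, case_ids, control_ids, year=None, **kw):
        return cls(build_risk_design(scores, pheno, case_ids, control_ids, year=year), **kw)

    def fit(self, seed: int | None = None, compute_cv: bool = True) -> "CancerRiskResults":
        fit = stepwise_logistic(
            self.design,
            p_enter=self.p_enter,
            p_remove=self.p_remove,
            cv_seed=seed,
            compute_cv=compute_cv,
        )
        return CancerRiskResults(model=self, fit=fit, seed=seed)


@dataclass
class CancerRiskResults:
    model: CancerRiskModel
    fit: RiskModelFit
    seed: int | None = None

    @property
    def table(self) -> pd.DataFrame:
        return self.fit.table

    @property
    def terms(self) -> tuple[str, ...]:
        return self.fit.terms

    def summary(self) -> str:
        return self.fit.summary()

    def random_forest(self, n_trees: int = 500):
        return rf_model(self.model.design, n_trees=n_trees, rng_seed=self.seed)

    def mdi_contribution(self):
        """Pseudo-R2 change and LR p when the mDI and every term containing it
        are removed from the selected model."""
        full = list(self.fit.terms)
        reduced = [t for t in full if "mDI" not in t.split(":") and t != "mDI"]
        return r2_contribution(self.model.design, full, reduced)

    def plot_roc(self, ax=None):
        import matplotlib.pyplot as plt
        from sklearn.metrics import roc_curve

        final = _fit_terms(self.model.design, list(self.fit.terms))
        fpr, tpr, _ = roc_curve(self.model.design.y, final.fitted)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(fpr, tpr, label=f"stepwise (AUC={self.fit.auc_in_sample:.2f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax
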