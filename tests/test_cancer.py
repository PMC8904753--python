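"""Per-year cancer risk models: z-scaling, cohorts, stepwise GLM, RF, R2."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methdex as mx
from methdex.cancer import (
    MAIN_EFFECTS,
    RiskDesign,
    _fit_terms,
    build_per_year_cohorts,
    r2_contribution,
    rf_model,
    stepwise_logistic,
    z_transform,
)


def _design(n=400, seed=0, beta=None, intercept=-0.5, year=None):
    """Design with iid standard-normal predictors and a logistic outcome."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, len(MAIN_EFFECTS)))
    frame = pd.DataFrame(
        {c: z_transform(X[:, i]) for i, c in enumerate(MAIN_EFFECTS)}
    )
    eta = np.full(n, float(intercept))
    if beta:
        for term, b in beta.items():
            if ":" in term:
                a, bb = term.split(":")
                eta += b * frame[a].to_numpy() * frame[bb].to_numpy()
            else:
                eta += b * frame[term].to_numpy()
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return RiskDesign(frame=frame, y=y, year=year)


# ---------------------------------------------------------------------------
# z transform
# ---------------------------------------------------------------------------


def test_z_transform_basic():
    assert np.allclose(z_transform([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])


def test_z_transform_moments_and_idempotence():
    x = np.random.default_rng(1).normal(3.0, 7.0, size=50)
    z = z_transform(x)
    assert z.mean() == pytest.approx(0.0, abs=1e-12)
    assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
    assert np.allclose(z_transform(z), z, atol=1e-12)


def test_z_transform_errors():
    with pytest.raises(ValueError):
        z_transform([1.0])
    with pytest.raises(ValueError):
        z_transform([2.0, 2.0, 2.0])


# ---------------------------------------------------------------------------
# per-year cohorts
# ---------------------------------------------------------------------------


def _pheno(years, n_controls=40):
    n = len(years) + n_controls
    ids = [f"P{i}" for i in range(n)]
    frame = pd.DataFrame(
        {
            "label": [1] * len(years) + [0] * n_controls,
            "diagnosis_year": pd.array(list(years) + [pd.NA] * n_controls, dtype="Int64"),
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return mx.Phenotype(frame)


def test_per_year_all_diagnoses_late():
    pheno = _pheno([5] * 15)
    with pytest.warns(UserWarning):
        cohorts = build_per_year_cohorts(pheno, year_min=3)
    years = [y for y, _, _ in cohorts]
    assert years == [5]
    _, cases, controls = cohorts[0]
    assert len(cases) == 15 and len(controls) == 40


def test_per_year_counts_cumulative():
    rng = np.random.default_rng(2)
    pheno = _pheno(rng.integers(1, 12, size=120))
    cohorts = build_per_year_cohorts(pheno, year_min=3)
    counts = [len(c) for _, c, _ in cohorts]
    assert counts == sorted(counts)
    # uniform diagnosis years: year-y cohort holds ~y/11 of the 120 cases
    year, cases, _ = cohorts[-1]
    assert year == 11 and len(cases) == 120
    mid = dict((y, len(c)) for y, c, _ in cohorts)[6]
    assert abs(mid - 120 * 6 / 11) < 20


def test_per_year_requires_years_for_cases():
    frame = pd.DataFrame(
        {"label": [1, 0], "diagnosis_year": pd.array([pd.NA, pd.NA], dtype="Int64")},
        index=pd.Index(["a", "b"], name="sample_id"),
    )
    with pytest.raises(ValueError):
        build_per_year_cohorts(mx.Phenotype(frame))


# ---------------------------------------------------------------------------
# stepwise logistic
# ---------------------------------------------------------------------------


def test_stepwise_selects_true_predictor():
    fit = stepwise_logistic(_design(n=600, seed=4, beta={"mDI": 1.5}))
    assert "mDI" in fit.terms
    assert fit.auc_in_sample > 0.6
    assert fit.table.loc["mDI", "estimate"] > 0


def test_stepwise_single_candidate_reduces_to_lr_test():
    design = _design(n=300, seed=6, beta={"mDI": 0.8})
    fit = stepwise_logistic(design, candidates=["mDI"])
    null = _fit_terms(design, [])
    alt = _fit_terms(design, ["mDI"])
    p = stats.chi2.sf(null.deviance - alt.deviance, df=1)
    assert fit.terms == (("mDI",) if p < 0.05 else ())


def test_stepwise_candidate_order_invariance():
    design = _design(n=500, seed=8, beta={"mDI": 1.0, "gran": -0.7})
    from methdex.cancer import _all_candidates

    cands = _all_candidates()
    a = stepwise_logistic(design, candidates=cands)
    b = stepwise_logistic(design, candidates=list(reversed(cands)))
    assert a.terms == b.terms
    pd.testing.assert_frame_equal(a.table, b.table)


def test_stepwise_keeps_parents_of_selected_interaction():
    design = _design(n=800, seed=10, beta={"mDI:cd4_cd8": 1.2})
    fit = stepwise_logistic(design)
    assert "mDI:cd4_cd8" in fit.terms
    assert "mDI" in fit.terms and "cd4_cd8" in fit.terms


def test_z_scaling_is_affine_reparameterisation():
    """Fitting on z-scored columns equals fitting on raw columns up to the
    affine map of coefficients (same deviance, same fitted values)."""
    rng = np.random.default_rng(3)
    n = 300
    raw = rng.normal(5.0, 2.0, size=n)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-(0.4 * (raw - 5.0))))).astype(int)
    import statsmodels.api as sm

    Xr = np.column_stack([np.ones(n), raw])
    Xz = np.column_stack([np.ones(n), z_transform(raw)])
    fr = sm.GLM(y, Xr, family=sm.families.Binomial()).fit()
    fz = sm.GLM(y, Xz, family=sm.families.Binomial()).fit()
    assert fr.deviance == pytest.approx(fz.deviance, abs=1e-6)
    sd = raw.std(ddof=1)
    assert fz.params[1] == pytest.approx(fr.params[1] * sd, abs=1e-6)
    assert np.allclose(fr.fittedvalues, fz.fittedvalues, atol=1e-8)


def test_stepwise_entry_type_one_error_single_candidate():
    """With one null candidate, the entry test rejects at ~p_enter."""
    hits = 0
    reps = 300
    for seed in range(reps):
        design = _design(n=120, seed=seed)
        fit = stepwise_logistic(design, candidates=["mDI"])
        hits += len(fit.terms) > 0
    assert hits / reps == pytest.approx(0.05, abs=0.04)


def test_stepwise_summary_mentions_terms():
    fit = stepwise_logistic(_design(n=600, seed=4, beta={"mDI": 1.5}))
    s = fit.summary()
    assert "mDI" in s and "AUC" in s


# ---------------------------------------------------------------------------
# pseudo-R2 contribution, RF, model front end
# ---------------------------------------------------------------------------


def test_r2_reduced_equals_full_is_noop():
    design = _design(n=200, seed=1, beta={"mDI": 1.0})
    r2f, r2r, p = r2_contribution(design, ["mDI"], ["mDI"])
    assert r2f == r2r and p == 1.0


def test_r2_drop_when_removing_true_predictor():
    design = _design(n=600, seed=2, beta={"mDI": 1.0})
    r2f, r2r, p = r2_contribution(design, ["mDI", "gran"], ["gran"])
    assert r2f > r2r
    assert p < 0.05


def test_r2_non_nested_errors():
    design = _design(n=100, seed=0)
    with pytest.raises(ValueError):
        r2_contribution(design, ["mDI"], ["gran"])


def test_rf_threshold_outcome_ranks_mdi_first():
    rng = np.random.default_rng(5)
    n = 300
    X = rng.normal(size=(n, len(MAIN_EFFECTS)))
    frame = pd.DataFrame({c: z_transform(X[:, i]) for i, c in enumerate(MAIN_EFFECTS)})
    y = (frame["mDI"].to_numpy() > 0).astype(int)
    design = RiskDesign(frame=frame, y=y)
    auc, imp = rf_model(design, n_trees=150, rng_seed=0)
    assert auc > 0.95
    assert imp["importance"].idxmax() == "mDI"


def test_rf_null_labels_near_chance():
    rng = np.random.default_rng(6)
    n = 300
    X = rng.normal(size=(n, len(MAIN_EFFECTS)))
    frame = pd.DataFrame({c: z_transform(X[:, i]) for i, c in enumerate(MAIN_EFFECTS)})
    y = rng.integers(0, 2, size=n)
    auc, _ = rf_model(RiskDesign(frame=frame, y=y), n_trees=150, rng_seed=1)
    assert 0.40 <= auc <= 0.60


def test_rf_requires_class_support():
    design = _design(n=30, seed=0)
    with pytest.raises(ValueError):
        rf_model(design, n_trees=10, rng_seed=0)


def test_cancer_model_results_front_end():
    rng = np.random.default_rng(7)
    ids = [f"P{i:03d}" for i in range(400)]
    scores = mx.MdiScores(
        scores=pd.Series(rng.normal(1.0, 0.8, 400), index=ids, name="mDI"),
        genes_used=pd.DataFrame(index=ids),
    )
    pheno = mx.generate_cancer_cohort(
        mx.CancerSimulationConfig(n_samples=400, rng_seed=7), scores
    )
    cohorts = build_per_year_cohorts(pheno, year_min=3)
    year, cases, controls = cohorts[-1]
    res = mx.CancerRiskModel.from_scores(scores, pheno, cases, controls, year=year).fit(seed=0)
    assert "mDI" in res.terms
    assert res.fit.auc_cv is not None and 0.5 < res.fit.auc_cv <= 1.0
    or_q, ci = mx.quartile_or(scores, cases, controls)
    assert or_q > 1.0 and ci[0] < or_q < ci[1]
    r2f, r2r, p = res.mdi_contribution()
    assert r2f >= r2r
    assert "Stepwise" in res.summary()
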