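"""mDI: Welch-form oracle, reflection symmetry, cohort scoring and the K sweep."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import methdex as mx
from methdex.simpo import SimpoMatrix

vals = st.lists(st.floats(-5.0, 5.0), min_size=2, max_size=10)


def welch_oracle(pos, neg):
    """Independent route: 1 + scipy's Welch t."""
    return 1.0 + stats.ttest_ind(pos, neg, equal_var=False).statistic


def test_equal_means_give_unit_index():
    assert mx.mdi_score([0.0, 2.0], [-1.0, 3.0]) == pytest.approx(1.0, abs=1e-12)


def test_worked_example_welch_form():
    got = mx.mdi_score([2, 3, 4], [1, 1.5, 0.5])
    want = 1.0 + 2.0 / np.sqrt(1.0 / 3.0 + 0.25 / 3.0)
    assert got == pytest.approx(want, abs=1e-12)
    assert got == pytest.approx(4.098, abs=1e-3)
    assert got == pytest.approx(welch_oracle([2, 3, 4], [1, 1.5, 0.5]), abs=1e-12)


def test_invalid_sides():
    assert np.isnan(mx.mdi_score([1.0], [0.0, 1.0]))
    assert np.isnan(mx.mdi_score([1.0, 2.0], [3.0]))
    assert np.isnan(mx.mdi_score([1.0, 1.0], [2.0, 2.0]))  # zero denominator


@given(a=vals, b=vals)
def test_reflection_symmetry(a, b):
    """Swapping the positive and negative sets maps mDI to 2 - mDI."""
    s1, s2 = mx.mdi_score(a, b), mx.mdi_score(b, a)
    if np.isnan(s1):
        assert np.isnan(s2)
    else:
        assert s1 == pytest.approx(2.0 - s2, abs=1e-9)


@given(a=vals, b=vals, seed=st.integers(0, 50))
def test_gene_order_invariance(a, b, seed):
    rng = np.random.default_rng(seed)
    s1 = mx.mdi_score(a, b)
    s2 = mx.mdi_score(rng.permutation(a), rng.permutation(b))
    assert (np.isnan(s1) and np.isnan(s2)) or s1 == pytest.approx(s2, abs=1e-9)


# ---------------------------------------------------------------------------
# cohort scoring
# ---------------------------------------------------------------------------


def _simpo_from(arr, genes, samples=None):
    samples = samples or [f"s{j}" for j in range(np.shape(arr)[1])]
    return SimpoMatrix(values=pd.DataFrame(np.asarray(arr, float), index=genes, columns=samples))


def _model(pos, neg):
    return mx.MdiModel(
        positive_genes=tuple(pos),
        negative_genes=tuple(neg),
        k=len(pos) + len(neg),
        training_correlation=0.0,
    )


def test_score_cohort_matches_per_sample_formula():
    rng = np.random.default_rng(8)
    genes = [f"g{i}" for i in range(6)]
    sm = _simpo_from(rng.normal(size=(6, 5)), genes)
    model = _model(genes[:3], genes[3:])
    scored = mx.score_cohort(sm, model)
    for j, s in enumerate(sm.sample_ids):
        want = mx.mdi_score(sm.values.iloc[:3, j], sm.values.iloc[3:, j])
        assert scored.scores[s] == pytest.approx(want, abs=1e-12)


def test_score_cohort_missing_whole_set_errors():
    genes = ["a", "b", "c", "d"]
    sm = _simpo_from(np.ones((4, 3)), genes)
    model = _model(["a", "b"], ["x", "y"])
    with pytest.warns(UserWarning, match="absent"):
        with pytest.raises(ValueError, match="negative"):
            mx.score_cohort(sm, model)


def test_score_cohort_flags_unscorable_samples():
    genes = ["a", "b", "c", "d"]
    arr = np.random.default_rng(0).normal(size=(4, 3))
    arr[0:2, 1] = np.nan  # sample s1 loses the whole positive set
    sm = _simpo_from(arr, genes)
    scored = mx.score_cohort(sm, _model(["a", "b"], ["c", "d"]))
    assert scored.flagged_samples == ["s1"]
    assert np.isnan(scored.scores["s1"])


def test_model_json_roundtrip(tmp_path):
    model = mx.MdiModel(("a", "b"), ("c",), 3, 0.55, {"seed": 1})
    p = tmp_path / "m.json"
    model.to_json(p)
    assert mx.MdiModel.from_json(p) == model


def test_global_reflection_invariant(strong_simpo):
    """Negating the SIMPO matrix and swapping set signs negates mDI - 1."""
    simpo, pheno, _ = strong_simpo
    genes = simpo.gene_symbols
    model = _model(genes[:5], genes[5:10])
    flipped = SimpoMatrix(values=-simpo.values)
    swapped = _model(genes[5:10], genes[:5])
    s1 = mx.score_cohort(simpo, model).scores
    s2 = mx.score_cohort(flipped, swapped).scores
    assert np.allclose(s1 - 1.0, s2 - 1.0, equal_nan=True)
    labels = pheno.labels_for(simpo.sample_ids)
    auc1 = mx.roc_auc(s1, labels)
    auc2 = mx.roc_auc(s2, labels)
    assert auc1 == pytest.approx(auc2, abs=1e-12)  # identical scores both ways
    assert mx.roc_auc(2.0 - s1, labels) == pytest.approx(1.0 - auc1, abs=1e-12)


# ---------------------------------------------------------------------------
# K sweep
# ---------------------------------------------------------------------------


def test_sweep_curve_matches_direct_scoring(strong_simpo):
    """The cumulative-sum sweep reproduces explicit per-k scoring."""
    simpo, pheno, _ = strong_simpo
    labels = pheno.labels_for(simpo.sample_ids)
    sel = mx.resample_select(simpo, labels, n_iter=20, top_n=10, rng_seed=3)
    model, curve = mx.sweep_k(sel, simpo, labels, k_min=4, k_max=40)
    for k in (4, 11, 25, 40):
        row = curve.loc[curve["k"] == k].iloc[0]
        pos, neg = mx.partition_signs(sel, k)
        if min(len(pos), len(neg)) < 2:
            assert np.isnan(row["r"])
            continue
        scores = mx.score_cohort(simpo, _model(pos, neg)).scores
        r, _ = mx.pearson_with_label(scores, labels)
        assert row["r"] == pytest.approx(r, abs=1e-8)
    # chosen k maximises r, ties to the smallest k
    finite = curve.dropna(subset=["r"])
    assert model.training_correlation == pytest.approx(finite["r"].max(), abs=1e-12)
    assert model.k == int(finite.loc[finite["r"].idxmax(), "k"])


def test_sweep_prefers_informative_k(strong_simpo):
    """With 10 strong causal genes among 60, the sweep picks a k well short of
    the whole gene list, keeps every causal gene in the chosen sets, and the
    curve declines once noise genes dilute the index."""
    simpo, pheno, truth = strong_simpo
    labels = pheno.labels_for(simpo.sample_ids)
    sel = mx.resample_select(simpo, labels, n_iter=20, top_n=10, rng_seed=3)
    model, curve = mx.sweep_k(sel, simpo, labels, k_min=4, k_max=55)
    assert model.k < 55
    chosen = set(model.positive_genes) | set(model.negative_genes)
    assert set(truth["causal_genes"]) <= chosen
    r_at = lambda k: float(curve.loc[curve["k"] == k, "r"].iloc[0])
    assert model.training_correlation > r_at(55)


def test_sweep_k_bounds(strong_simpo):
    simpo, pheno, _ = strong_simpo
    labels = pheno.labels_for(simpo.sample_ids)
    sel = mx.resample_select(simpo, labels, n_iter=5, rng_seed=0)
    with pytest.raises(ValueError):
        mx.sweep_k(sel, simpo, labels, k_min=10, k_max=10_000)
    with pytest.raises(ValueError):
        mx.sweep_k(sel, simpo, labels, k_min=0, k_max=10)


def test_model_invariants():
    with pytest.raises(ValueError):
        mx.MdiModel(("a",), (), 1, 0.0)  # empty negative set
    with pytest.raises(ValueError):
        mx.MdiModel(("a", "b"), ("c",), 2, 0.0)  # sets don't sum to k
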