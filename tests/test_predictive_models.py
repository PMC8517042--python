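"""Lasso path, McNemar, random-forest evaluation, stratified regressions
and the path summary."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from usvsyntax.predictive_models import (
    TIER_WEIGHTS,
    build_path_summary,
    evaluate_rf,
    fit_lasso_path,
    mcnemar_test,
    predict_behaviors,
    read_path_summary,
    significance_tier,
    write_path_summary,
)
from usvsyntax.sequence_structure import fit_markov
from conftest import make_sequence


# ---------------------------------------------------------------------------
# Lasso path
# ---------------------------------------------------------------------------

def _orthonormal_design(n, p, rng):
    """Zero-mean columns with X'X = n*I: orthogonalize a column-centered
    matrix (its columns stay orthogonal to the ones vector), then scale so
    each column has unit population variance."""
    A = rng.standard_normal((n, p))
    A -= A.mean(axis=0)
    q, _ = np.linalg.qr(A)
    return q * np.sqrt(n)


def test_lasso_orthonormal_soft_threshold(rng):
    """Under an orthonormal design the path coefficient of the active
    feature follows sign(b)(|b| - lambda)+ exactly."""
    n, p = 40, 5
    X = _orthonormal_design(n, p, rng)
    beta = 3.0
    y = beta * X[:, 0]  # noiseless effect on the unit-variance column
    path = fit_lasso_path(pd.DataFrame(X), y, family="gaussian", cutoff=0.25)
    ols = np.array([
        (X[:, j] / X[:, j].std(ddof=0)) @ (y - y.mean()) / n for j in range(p)
    ])
    for i, lam in enumerate(path.lambdas):
        expected = np.sign(ols) * np.maximum(np.abs(ols) - lam, 0.0)
        assert np.allclose(path.coef_path.iloc[:, i].to_numpy(), expected, atol=1e-6)
    assert path.selected[0][0] == 0  # planted column enters first


def test_lasso_all_zero_at_lambda_max(rng):
    X = pd.DataFrame(rng.standard_normal((30, 10)))
    y = rng.standard_normal(30)
    path = fit_lasso_path(X, y)
    assert np.all(path.coef_path.iloc[:, 0].to_numpy() == 0.0)
    assert path.frac_dev[0] == pytest.approx(0.0, abs=1e-10)


def test_lasso_frac_dev_monotone(rng):
    X = pd.DataFrame(rng.standard_normal((25, 40)))
    y = rng.standard_normal(25)
    path = fit_lasso_path(X, y)
    assert np.all(np.diff(path.frac_dev) >= -1e-8)
    assert path.frac_dev[-1] >= 0.25 - 1e-12 or path.cutoff_index is None


def test_lasso_selected_ordered_by_entry(rng):
    X = pd.DataFrame(rng.standard_normal((30, 20)))
    y = 2.0 * X[0] + 1.0 * X[1] + 0.1 * rng.standard_normal(30)
    path = fit_lasso_path(X, y)
    entries = [e for _, e in path.selected]
    assert entries == sorted(entries)
    assert 0 in [f for f, _ in path.selected]


def test_lasso_rejects_degenerate_inputs(rng):
    X = pd.DataFrame(rng.standard_normal((10, 3)))
    with pytest.raises(ValueError, match="null response"):
        fit_lasso_path(X, np.ones(10))
    with pytest.raises(ValueError, match="n >= 3"):
        fit_lasso_path(X.iloc[:2], np.array([0.0, 1.0]))
    with pytest.raises(ValueError, match="family"):
        fit_lasso_path(X, rng.standard_normal(10), family="poisson")


def test_lasso_binomial_recovers_separating_feature(rng):
    """Binomial family: a feature strongly tied to class membership is
    selected at the deviance cutoff."""
    n = 40
    y = np.repeat([0.0, 1.0], n // 2)
    X = rng.standard_normal((n, 15))
    X[:, 4] += 2.5 * y
    path = fit_lasso_path(pd.DataFrame(X), y, family="binomial")
    assert path.family == "binomial"
    assert np.all(path.coef_path.iloc[:, 0].to_numpy() == 0.0)
    assert np.all(np.diff(path.frac_dev) >= -1e-6)
    assert path.selected and path.selected[0][0] == 4


# ---------------------------------------------------------------------------
# McNemar
# ---------------------------------------------------------------------------

def test_mcnemar_chi2_closed_form():
    """Discordant (5,15): continuity-corrected chi2 = (|5-15|-1)^2/20 = 4.05."""
    res = mcnemar_test(5, 15)
    assert res.statistic == pytest.approx(4.05)
    res_tie = mcnemar_test(10, 10)
    assert res_tie.statistic == pytest.approx(0.05)


def test_mcnemar_exact_branch():
    """b=0, c=8 under the exact branch: p = 2 * (1/2)^8 = 0.0078125."""
    res = mcnemar_test(0, 8)
    assert res.exact
    assert res.p == pytest.approx(2 * 0.5 ** 8, rel=1e-12)


def test_mcnemar_large_sample_uses_chi2_tail():
    res = mcnemar_test(10, 20)  # b + c = 30 >= 25
    assert not res.exact
    chi2 = (abs(10 - 20) - 1) ** 2 / 30
    assert res.statistic == pytest.approx(chi2)
    assert res.p == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-12)


def test_mcnemar_degenerate():
    res = mcnemar_test(0, 0)
    assert res.p == 1.0 and "degenerate" in res.method
    with pytest.raises(ValueError):
        mcnemar_test(-1, 3)


# ---------------------------------------------------------------------------
# Random forest evaluation
# ---------------------------------------------------------------------------

def _clusters(n_per_class, sep, rng, p=6):
    X = rng.standard_normal((2 * n_per_class, p))
    X[n_per_class:, :2] += sep
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return pd.DataFrame(X), y


def test_rf_metrics_consistent_with_confusion(rng):
    X, y = _clusters(20, 1.5, rng)
    rep = evaluate_rf(X, y, n_trees=200, seed=1)
    (tn, fp), (fn, tp) = rep.confusion
    assert rep.sensitivity == pytest.approx(tp / (tp + fn))
    assert rep.specificity == pytest.approx(tn / (tn + fp))
    assert rep.accuracy == pytest.approx((tp + tn) / len(y))
    assert rep.mcnemar_b == fn and rep.mcnemar_c == fp
    assert rep.confusion.sum() == len(y)


def test_rf_separable_clusters_high_sensitivity_specificity(rng):
    X, y = _clusters(25, 6.0, rng)
    rep = evaluate_rf(X, y, n_trees=300, seed=2)
    assert rep.sensitivity >= 0.95
    assert rep.specificity >= 0.95
    assert rep.accuracy_p < 1e-6


def test_rf_deterministic_under_seed(rng):
    X, y = _clusters(15, 1.0, rng)
    a = evaluate_rf(X, y, n_trees=100, seed=3)
    b = evaluate_rf(X, y, n_trees=100, seed=3)
    assert np.array_equal(a.confusion, b.confusion)
    assert a.accuracy == b.accuracy


def test_rf_rejects_single_class(rng):
    X = pd.DataFrame(rng.standard_normal((10, 3)))
    with pytest.raises(ValueError):
        evaluate_rf(X, np.zeros(10))
    with pytest.raises(ValueError):
        evaluate_rf(X, ["WT"] * 9 + ["DEL"])  # minority class of 1


def test_rf_accepts_string_labels(rng):
    X, y = _clusters(10, 4.0, rng)
    labels = np.where(y == 1, "Del/+", "+/+")
    rep = evaluate_rf(X, labels, n_trees=100, seed=4)
    assert rep.confusion.sum() == 20


# ---------------------------------------------------------------------------
# Stratified prediction + path summary
# ---------------------------------------------------------------------------

def _xy(rows):
    X = pd.DataFrame(rows)
    Y = pd.DataFrame({
        "social_interaction": X.pop("y"),
        "social_habituation": 0.5 * np.arange(len(X)),
        "olfactory_response": np.ones(len(X)),
        "olfactory_habituation": np.zeros(len(X)),
    })
    return X, Y


def test_predict_behaviors_exact_line():
    """y = 2x fits with slope 2, r = 1, r^2 = 1 in the matching stratum."""
    X, Y = _xy({
        "f": [1.0, 2.0, 3.0, 4.0],
        "genotype": [0, 0, 0, 0],
        "y": [2.0, 4.0, 6.0, 8.0],
    })
    out = predict_behaviors(X, Y, ["f"], behaviors=["social_interaction"])
    row = out[(out.genotype == "WT")].iloc[0]
    assert row["slope"] == pytest.approx(2.0)
    assert row["r"] == pytest.approx(1.0)
    assert row["r_squared"] == pytest.approx(1.0)


def test_predict_behaviors_skips_small_or_constant_strata():
    X, Y = _xy({
        "f": [1.0, 1.0, 1.0, 1.0, 2.0, 3.0],
        "genotype": [0, 0, 0, 0, 1, 1],
        "y": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
    })
    out = predict_behaviors(X, Y, ["f"], behaviors=["social_interaction"])
    # WT stratum constant -> skipped; DEL stratum n=2 < 4 -> skipped
    assert len(out) == 0


def test_predict_behaviors_bh_within_behavior(rng):
    n = 16
    X = pd.DataFrame({
        "a": rng.standard_normal(n), "b": rng.standard_normal(n),
        "genotype": [0] * (n // 2) + [1] * (n // 2),
    })
    Y = pd.DataFrame({
        "social_interaction": 3 * X["a"] + 0.1 * rng.standard_normal(n),
        "social_habituation": rng.standard_normal(n),
        "olfactory_response": rng.standard_normal(n),
        "olfactory_habituation": rng.standard_normal(n),
    })
    out = predict_behaviors(X, Y, ["a", "b"])
    from usvsyntax.stats_util import bh_adjust
    for behavior in out["behavior"].unique():
        sub = out[out["behavior"] == behavior]
        assert np.allclose(sub["fit_p_bh"], bh_adjust(sub["fit_p"].to_numpy()))
    assert np.all(out["fit_p_bh"] >= out["fit_p"] - 1e-15)


def test_significance_tiers_and_weights():
    assert significance_tier(0.04) == "p<0.05"
    assert significance_tier(0.005) == "p<0.01"
    assert significance_tier(0.0005) == "p<0.001"
    assert significance_tier(0.05) == "none"
    assert TIER_WEIGHTS == {"none": 0.0, "p<0.05": 1.0, "p<0.01": 2.0, "p<0.001": 4.0}


def _markov_models():
    seqs = [make_sequence(["Ts", "Ts", "Fs", "Fs", "Ts", "Ts"] * 3)]
    return {"WT": fit_markov(seqs, min_count=1, top_k=4)}


def test_path_summary_no_significant_fits():
    preds = pd.DataFrame(columns=["feature", "behavior", "genotype", "n", "slope",
                                  "intercept", "r", "r_squared", "fit_p",
                                  "fit_p_bh", "tier", "weight"])
    summary = build_path_summary(_markov_models(), preds)
    assert len(summary["call_edges"]) > 0
    assert len(summary["prediction_edges"]) == 0


def test_path_summary_tier_weight_mapping():
    preds = pd.DataFrame([{
        "feature": "Ha→H", "behavior": "social_interaction", "genotype": "DEL",
        "n": 10, "slope": 1.0, "intercept": 0.0, "r": 0.9, "r_squared": 0.81,
        "fit_p": 0.005, "fit_p_bh": 0.02, "tier": "p<0.01", "weight": 2.0,
    }])
    summary = build_path_summary(_markov_models(), preds)
    edge = summary["prediction_edges"].iloc[0]
    assert edge["weight"] == 2.0
    assert edge["from_call"] == "Ha" and edge["to_call"] == "H"


def test_path_summary_csv_roundtrip(tmp_path):
    preds = pd.DataFrame([{
        "feature": "U(R)", "behavior": "olfactory_response", "genotype": "WT",
        "n": 12, "slope": -1.0, "intercept": 3.0, "r": -0.7, "r_squared": 0.49,
        "fit_p": 0.02, "fit_p_bh": 0.08, "tier": "p<0.05", "weight": 1.0,
    }])
    summary = build_path_summary(_markov_models(), preds)
    write_path_summary(summary, tmp_path)
    again = read_path_summary(tmp_path)
    write_path_summary(again, tmp_path / "second")
    for name in ("call_edges", "prediction_edges"):
        assert (tmp_path / f"{name}.csv").read_bytes() == \
               (tmp_path / "second" / f"{name}.csv").read_bytes()
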