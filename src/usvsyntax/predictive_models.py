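"""Predictive modeling: Lasso-path feature extraction, random-forest
genotype classification, and genotype-stratified univariate prediction.

The Lasso path is traversed from the all-zero solution (lambda_max) down a
log-spaced grid; features are read off at the first grid point where the
fraction of null deviance explained reaches a cutoff (default 0.25).
Features entering the path earlier (at larger lambda, i.e. smaller fraction
of deviance explained) are the more robust predictors.

Random-forest genotype classification is evaluated out-of-bag with the
deletion genotype as the positive class; accuracy is tested one-sided
against the no-information rate and the sensitivity/specificity contrast
via McNemar's test on the discordance between true class and correctness.

Univariate prediction regresses each postpubertal behavior on each selected
neonatal feature separately within each genotype stratum; significance
tiers (p<0.05, p<0.01, p<0.001) carry rendering weights x, 2x, 4x.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import lasso_path

from .call_dataset import BEHAVIOR_NAMES, CALL_TYPES
from .sequence_features import parse_feature_name
from .sequence_structure import TransitionModel
from .stats_util import TestResult, bh_adjust, binom_test_exact

logger = logging.getLogger(__name__)

#: McNemar switches from the exact binomial branch to the continuity-
#: corrected chi-square when the discordant total reaches this size.
MCNEMAR_CHI2_MIN = 25

#: Significance tiers and their rendering weights (arbitrary units x, 2x, 4x).
TIER_WEIGHTS = {"none": 0.0, "p<0.05": 1.0, "p<0.01": 2.0, "p<0.001": 4.0}


def significance_tier(p: float) -> str:
    if p < 0.001:
        return "p<0.001"
    if p < 0.01:
        return "p<0.01"
    if p < 0.05:
        return "p<0.05"
    return "none"


# ---------------------------------------------------------------------------
# Lasso path
# ---------------------------------------------------------------------------

@dataclass
class LassoPath:
    """Regularization path of one response with the cutoff-selected set.

    ``selected`` lists (feature, entry_frac_dev) ordered by path entry:
    a smaller entry fraction of deviance explained means the feature entered
    at a larger lambda and is the more robust predictor.  Coefficients are
    on the standardized-predictor scale.
    """

    response_name: str
    family: str
    lambdas: np.ndarray
    frac_dev: np.ndarray
    coef_path: pd.DataFrame         # features x lambda grid
    selected: list[tuple[str, float]]
    cutoff: float
    cutoff_index: int | None        # first grid point with frac_dev >= cutoff


def _binomial_path(
    Xs: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 5000,
) -> np.ndarray:
    """L1 logistic coefficients along a descending lambda grid.

    Minimizes (1/n) * neg-loglik + lambda * ||beta||_1 with an unpenalized
    intercept by accelerated proximal gradient (FISTA) with warm starts;
    the step uses the logistic Lipschitz bound ||X||_2^2 / (4n).  At very
    small lambda on separable data the minimizer may not be finite; the
    iteration cap then acts as the usual path truncation.
    """
    n, p = Xs.shape
    L = (np.linalg.norm(Xs, 2) ** 2 / n + 1.0) / 4.0
    step = 1.0 / L
    coefs = np.zeros((p, lambdas.size))
    beta = np.zeros(p + 1)  # [intercept, coefficients]
    for i, lam in enumerate(lambdas):
        z = beta.copy()
        t_acc = 1.0
        prev = beta.copy()
        for _ in range(max_iter):
            eta = z[0] + Xs @ z[1:]
            prob = 1.0 / (1.0 + np.exp(-eta))
            grad0 = float(np.mean(prob - y))
            grad = Xs.T @ (prob - y) / n
            new = np.empty_like(z)
            new[0] = z[0] - step * grad0
            w = z[1:] - step * grad
            new[1:] = np.sign(w) * np.maximum(np.abs(w) - step * lam, 0.0)
            t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_acc ** 2)) / 2.0
            z = new + ((t_acc - 1.0) / t_next) * (new - prev)
            t_acc = t_next
            delta = np.max(np.abs(new - prev))
            prev = new
            if delta < tol * max(1.0, np.max(np.abs(new))):
                break
        beta = prev
        coefs[:, i] = beta[1:]
    return coefs


def fit_lasso_path(
    X: pd.DataFrame,
    y,
    family: str = "gaussian",
    cutoff: float = 0.25,
    response_name: str = "response",
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
) -> LassoPath:
    """Fit the full Lasso regularization path and select features at the
    deviance-explained cutoff.

    Predictors are standardized internally (zero-variance columns stay at
    coefficient zero).  The grid is log-spaced over [lambda_max *
    lambda_min_ratio, lambda_max] where lambda_max is the smallest penalty
    with an all-zero solution.  frac_dev = 1 - dev(lambda)/dev(null), which
    is R-squared for the gaussian family.  ``selected`` holds the features
    nonzero at the first (largest-lambda) grid point whose frac_dev reaches
    the cutoff, each tagged with the frac_dev at its own path entry and
    ordered by entry.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError(f"need n >= 3 observations, got {n}")
    if X.shape[0] != n:
        raise ValueError("X and y row counts differ")
    if np.ptp(y) == 0:
        raise ValueError("null response: y is constant, no deviance to explain")
    if family not in ("gaussian", "binomial"):
        raise ValueError(f"unknown family {family!r}")
    Xv = X.to_numpy(dtype=float)
    if np.any(~np.isfinite(Xv)):
        raise ValueError("X contains non-finite values")
    mean = Xv.mean(axis=0)
    scale = Xv.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    Xs = (Xv - mean) / scale

    if family == "gaussian":
        yc = y - y.mean()
        lam_max = np.max(np.abs(Xs.T @ yc)) / n
    else:
        vals = np.unique(y)
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError("binomial family needs a 0/1 response")
        lam_max = np.max(np.abs(Xs.T @ (y - y.mean()))) / n
    if lam_max == 0:
        raise ValueError("response is orthogonal to every predictor")
    lambdas = np.logspace(np.log10(lam_max), np.log10(lam_max * lambda_min_ratio), n_lambdas)

    if family == "gaussian":
        _, coefs, _ = lasso_path(Xs, yc, alphas=lambdas, tol=1e-12, max_iter=100000)
        resid = yc[:, None] - Xs @ coefs
        dev = (resid ** 2).sum(axis=0)
        dev_null = float((yc ** 2).sum())
    else:
        coefs = _binomial_path(Xs, y, lambdas)
        pbar = y.mean()
        dev_null = -2.0 * float(np.sum(y * np.log(pbar) + (1 - y) * np.log(1 - pbar)))
        dev = np.empty(lambdas.size)
        for i in range(lambdas.size):
            eta = Xs @ coefs[:, i]
            # refit intercept offset implied by the saga fit is folded into
            # coefficients' deviance via the fitted probabilities
            b0 = _binomial_intercept(eta, y)
            prob = 1.0 / (1.0 + np.exp(-(eta + b0)))
            prob = np.clip(prob, 1e-12, 1 - 1e-12)
            dev[i] = -2.0 * float(np.sum(y * np.log(prob) + (1 - y) * np.log(1 - prob)))
    frac_dev = 1.0 - dev / dev_null

    nz = coefs != 0.0
    cutoff_hits = np.nonzero(frac_dev >= cutoff)[0]
    cutoff_index = int(cutoff_hits[0]) if cutoff_hits.size else None
    selected: list[tuple[str, float]] = []
    if cutoff_index is not None:
        entries = []
        for j in np.nonzero(nz[:, cutoff_index])[0]:
            entry_idx = int(np.nonzero(nz[j])[0][0])
            entries.append((entry_idx, j))
        entries.sort(key=lambda e: (e[0], -abs(coefs[e[1], cutoff_index]), e[1]))
        selected = [(X.columns[j], float(frac_dev[idx])) for idx, j in entries]
    else:
        logger.warning(
            "lasso path for %s never reaches frac_dev cutoff %.3g (max %.3g)",
            response_name, cutoff, float(frac_dev.max()),
        )
    return LassoPath(
        response_name=response_name,
        family=family,
        lambdas=lambdas,
        frac_dev=frac_dev,
        coef_path=pd.DataFrame(coefs, index=X.columns, columns=range(n_lambdas)),
        selected=selected,
        cutoff=cutoff,
        cutoff_index=cutoff_index,
    )


def _binomial_intercept(eta: np.ndarray, y: np.ndarray) -> float:
    """Profile out the unpenalized intercept by one-dimensional Newton steps."""
    b0 = 0.0
    for _ in range(100):
        prob = 1.0 / (1.0 + np.exp(-(eta + b0)))
        grad = float(np.sum(prob - y))
        hess = float(np.sum(prob * (1 - prob)))
        if hess <= 0:
            break
        step = grad / hess
        b0 -= step
        if abs(step) < 1e-12:
            break
    return b0


# ---------------------------------------------------------------------------
# McNemar
# ---------------------------------------------------------------------------

def mcnemar_test(b: int, c: int) -> TestResult:
    """McNemar's test on discordant counts (b, c).

    Reports the continuity-corrected chi-square statistic
    (|b-c|-1)^2/(b+c); the p-value comes from the chi-square(1) tail when
    b + c >= 25 and from the exact two-sided binomial(b+c, 1/2) tail
    otherwise.  b = c = 0 returns p = 1 (degenerate case).
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    m = b + c
    if m == 0:
        return TestResult(statistic=float("nan"), p=1.0, method="mcnemar-degenerate", exact=True)
    chi2 = (abs(b - c) - 1.0) ** 2 / m
    if m >= MCNEMAR_CHI2_MIN:
        p = float(stats.chi2.sf(chi2, df=1))
        return TestResult(statistic=float(chi2), p=p, method="mcnemar-chi2-cc", exact=False)
    p = float(min(1.0, 2.0 * stats.binom.cdf(min(b, c), m, 0.5)))
    return TestResult(statistic=float(chi2), p=p, method="mcnemar-exact", exact=True)


# ---------------------------------------------------------------------------
# Random forest evaluation
# ---------------------------------------------------------------------------

@dataclass
class ClassifierReport:
    """Out-of-bag evaluation of genotype classification (positive = DEL).

    ``confusion`` rows are true (WT, DEL), columns predicted (WT, DEL).
    ``mcnemar_b``/``mcnemar_c`` are the discordant counts fed to McNemar:
    misclassified DEL (false negatives) vs misclassified WT (false
    positives), contrasting sensitivity against specificity.
    """

    confusion: np.ndarray
    sensitivity: float
    specificity: float
    accuracy: float
    accuracy_p: float
    no_information_rate: float
    mcnemar_b: int
    mcnemar_c: int
    mcnemar_chi2: float
    mcnemar_p: float
    feature_importances: pd.Series
    n_trees: int
    seed: int


def evaluate_rf(
    X: pd.DataFrame,
    labels: Sequence,
    n_trees: int = 1000,
    seed: int = 0,
) -> ClassifierReport:
    """Train a seeded random forest and evaluate it out-of-bag.

    ``labels`` are genotype codes (0 = WT, 1 = DEL) or the strings
    themselves.  Accuracy is tested one-sided (exact binomial) against the
    no-information rate (majority-class frequency).
    """
    y = np.asarray([
        (1 if v in ("DEL", "Del/+") else 0) if isinstance(v, str) else int(round(float(v)))
        for v in labels
    ])
    if not np.all(np.isin(y, (0, 1))):
        raise ValueError("labels must code genotype as WT/DEL or 0/1")
    if y.min() == y.max():
        raise ValueError("both genotype classes must be present")
    for cls in (0, 1):
        if (y == cls).sum() < 2:
            raise ValueError("each class needs at least 2 samples")
    forest = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, bootstrap=True, random_state=seed,
    )
    forest.fit(X.to_numpy(dtype=float), y)
    votes = forest.oob_decision_function_
    no_vote = votes.sum(axis=1) == 0
    pred = np.where(votes[:, -1] > 0.5, 1, 0)
    if no_vote.any():
        # samples drawn into every bootstrap get the forest's in-bag vote
        logger.warning("evaluate_rf: %d sample(s) had no out-of-bag trees", int(no_vote.sum()))
        pred[no_vote] = forest.predict(X.to_numpy(dtype=float))[no_vote]

    tn = int(np.sum((y == 0) & (pred == 0)))
    fp = int(np.sum((y == 0) & (pred == 1)))
    fn = int(np.sum((y == 1) & (pred == 0)))
    tp = int(np.sum((y == 1) & (pred == 1)))
    confusion = np.array([[tn, fp], [fn, tp]])
    n = len(y)
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    accuracy = (tp + tn) / n
    nir = max(np.mean(y), 1 - np.mean(y))
    acc_test = binom_test_exact(tp + tn, n, float(nir), side="greater")
    mc = mcnemar_test(fn, fp)
    return ClassifierReport(
        confusion=confusion,
        sensitivity=float(sensitivity),
        specificity=float(specificity),
        accuracy=float(accuracy),
        accuracy_p=acc_test.p,
        no_information_rate=float(nir),
        mcnemar_b=fn,
        mcnemar_c=fp,
        mcnemar_chi2=mc.statistic,
        mcnemar_p=mc.p,
        feature_importances=pd.Series(forest.feature_importances_, index=X.columns),
        n_trees=n_trees,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Genotype-stratified univariate prediction
# ---------------------------------------------------------------------------

def predict_behaviors(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    features: Sequence[str],
    behaviors: Sequence[str] = BEHAVIOR_NAMES,
    min_n: int = 4,
) -> pd.DataFrame:
    """Ordinary least squares of each behavior on each feature per genotype.

    Returns one row per (feature, behavior, genotype) with slope, intercept,
    Pearson r, r^2, the regression F-test p (``fit_p``), its BH adjustment
    within the behavior's family, and the significance tier/weight used for
    path rendering.  Strata with fewer than ``min_n`` complete pairs or a
    zero-variance feature are skipped with a warning.
    """
    if "genotype" not in X.columns:
        raise ValueError("X must carry the genotype column")
    rows = []
    for behavior in behaviors:
        yfull = Y[behavior]
        for geno_code, geno in ((0, "WT"), (1, "DEL")):
            mask = X["genotype"] == geno_code
            for feat in features:
                x = X.loc[mask, feat]
                y = yfull[mask]
                ok = x.notna() & y.notna()
                x, y = x[ok].to_numpy(), y[ok].to_numpy()
                if len(x) < min_n:
                    logger.warning("predict_behaviors: %s/%s/%s skipped (n=%d < %d)",
                                   feat, behavior, geno, len(x), min_n)
                    continue
                if np.ptp(x) == 0:
                    logger.warning("predict_behaviors: %s/%s/%s skipped (zero-variance feature)",
                                   feat, behavior, geno)
                    continue
                fit = stats.linregress(x, y)
                rows.append({
                    "feature": feat, "behavior": behavior, "genotype": geno,
                    "n": len(x), "slope": fit.slope, "intercept": fit.intercept,
                    "r": fit.rvalue, "r_squared": fit.rvalue ** 2, "fit_p": fit.pvalue,
                })
    out = pd.DataFrame(rows, columns=["feature", "behavior", "genotype", "n", "slope",
                                      "intercept", "r", "r_squared", "fit_p"])
    if len(out):
        out["fit_p_bh"] = np.nan
        for behavior in out["behavior"].unique():
            m = out["behavior"] == behavior
            out.loc[m, "fit_p_bh"] = bh_adjust(out.loc[m, "fit_p"].to_numpy())
        out["tier"] = out["fit_p"].map(significance_tier)
        out["weight"] = out["tier"].map(TIER_WEIGHTS)
    else:
        out["fit_p_bh"], out["tier"], out["weight"] = [], [], []
    return out


# ---------------------------------------------------------------------------
# Path summary (call -> call -> behavior graph tables)
# ---------------------------------------------------------------------------

def build_path_summary(
    markov: Mapping[str, TransitionModel],
    preds: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Edge tables for the developmental-path graph.

    ``call_edges``: per-genotype frequent two-call connections weighted by
    pooled transition probability.  ``prediction_edges``: feature→behavior
    links for fits with a significant tier only, weighted x/2x/4x; the
    source/target calls of transition and type features are split out so the
    graph can route feature edges through call nodes.
    """
    call_rows = []
    for geno, model in markov.items():
        for src, dst, prob in model.frequent_edges:
            call_rows.append({"genotype": geno, "from_call": src, "to_call": dst,
                              "weight": prob})
    call_edges = pd.DataFrame(call_rows, columns=["genotype", "from_call", "to_call", "weight"])

    pred_rows = []
    if len(preds):
        for _, row in preds[preds["tier"] != "none"].iterrows():
            src, dst, kind = parse_feature_name(str(row["feature"]))
            pred_rows.append({
                "genotype": row["genotype"], "feature": row["feature"],
                "feature_kind": kind, "from_call": src or "", "to_call": dst or "",
                "behavior": row["behavior"], "r": row["r"], "fit_p": row["fit_p"],
                "fit_p_bh": row["fit_p_bh"], "tier": row["tier"], "weight": row["weight"],
            })
    prediction_edges = pd.DataFrame(
        pred_rows,
        columns=["genotype", "feature", "feature_kind", "from_call", "to_call",
                 "behavior", "r", "fit_p", "fit_p_bh", "tier", "weight"],
    )
    return {"call_edges": call_edges, "prediction_edges": prediction_edges}


def write_path_summary(summary: Mapping[str, pd.DataFrame], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in summary.items():
        df.to_csv(outdir / f"{name}.csv", index=False)


def read_path_summary(outdir: str | Path) -> dict[str, pd.DataFrame]:
    outdir = Path(outdir)
    out = {}
    for name in ("call_edges", "prediction_edges"):
        out[name] = pd.read_csv(outdir / f"{name}.csv", keep_default_na=False,
                                na_values=[""], encoding="utf-8")
    return out
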