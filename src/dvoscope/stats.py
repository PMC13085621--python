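"""Group comparison, correlation, adjusted logistic modeling, and
stratified cross-validated classification.

Conventions fixed here: the Mann-Whitney test is exact (full enumeration,
via scipy) when both groups have <= 8 observations and tie-corrected
normal with continuity correction otherwise; Bonferroni is applied to the
eight group comparisons only; logistic CIs are Wald on the log-odds
scale; a pooled out-of-fold probability of exactly 0.50 classifies as
PAD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

DEFAULT_ALPHA = 0.05
N_COMPARISONS = 8
DEFAULT_THRESHOLD = 0.50
ADJUSTMENT_COVARIATES = ("age", "dm_duration", "htn_duration", "sex_male", "bmi", "smoking")
MEDICATION_COVARIATES = ("statin", "antiplatelet", "antihypertensive")


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# rank tests and correlation
# ---------------------------------------------------------------------------

def mann_whitney(x, y) -> tuple[float, float, bool]:
    """Two-sided Mann-Whitney U.

    Returns ``(U, p, degenerate)``; ``degenerate`` marks the all-values-
    identical case where p = 1 by convention. U is reported for the first
    sample. Exact enumeration when both samples have <= 8 observations
    and no ties; tie-corrected continuity-corrected normal approximation
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return x.size * y.size / 2.0, 1.0, True
    has_ties = np.unique(pooled).size < pooled.size
    if x.size <= 8 and y.size <= 8 and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                               use_continuity=True)
    return float(res.statistic), float(res.pvalue), False


def bonferroni_threshold(alpha: float = DEFAULT_ALPHA, m: int = N_COMPARISONS) -> float:
    """Family-wise threshold alpha / m."""
    if not (0 < alpha < 1):
        raise StatsError("alpha must be in (0, 1)")
    if m < 1 or int(m) != m:
        raise StatsError("m must be a positive integer")
    return alpha / m


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation (midrank ties, t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise StatsError("need equal-length samples with >= 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise StatsError("zero variance in ranks; rho undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# logistic modeling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MLRTerm:
    name: str
    coef: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class MLRResult:
    terms: tuple[MLRTerm, ...]
    converged: bool
    separation: bool
    covariates: tuple[str, ...]
    model: object = field(repr=False, compare=False, default=None)

    def term(self, name: str) -> MLRTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def fit_mlr(
    feature: np.ndarray,
    covariates: pd.DataFrame | None,
    labels: np.ndarray,
    *,
    feature_name: str = "feature",
    maxiter: int = 200,
) -> MLRResult:
    """Maximum-likelihood binary logistic regression with intercept.

    Continuous covariates enter on their natural scale; CIs are Wald 95%
    on the log-odds scale, exponentiated to odds ratios per unit.
    Complete or quasi-complete separation is flagged (not silently
    penalized); flagged results should not be interpreted.
    """
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise StatsError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise StatsError("need at least one subject per class")
    cols = {feature_name: np.asarray(feature, dtype=float)}
    if covariates is not None:
        for c in covariates.columns:
            cols[c] = np.asarray(covariates[c], dtype=float)
    X = pd.DataFrame(cols)
    if X.isna().any().any() or np.isnan(y).any():
        raise StatsError("missing values are not allowed")
    Xc = sm.add_constant(X, has_constant="add")
    separation = False
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=maxiter)
            converged = bool(fit.mle_retvals.get("converged", True))
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                np.linalg.LinAlgError, ValueError):
            separation = True
            converged = False
            try:  # salvage diagnostics with a gradient method
                fit = sm.Logit(y, Xc).fit(disp=0, maxiter=maxiter, method="bfgs")
            except Exception:
                fit = None
    if fit is None:  # results withheld entirely
        return MLRResult(terms=(), converged=False, separation=True,
                         covariates=tuple(X.columns), model=None)
    # quasi-separation shows up as exploding coefficients / SEs
    with np.errstate(over="ignore"):
        if np.any(np.abs(fit.params.values) > 50) or np.any(fit.bse.values > 1e3):
            separation = True
    ci = fit.conf_int(alpha=0.05)
    with np.errstate(over="ignore"):
        terms = tuple(
            MLRTerm(
                name=name,
                coef=float(fit.params[name]),
                odds_ratio=float(np.exp(fit.params[name])),
                ci_low=float(np.exp(ci.loc[name, 0])),
                ci_high=float(np.exp(ci.loc[name, 1])),
                p_value=float(fit.pvalues[name]),
            )
            for name in Xc.columns
        )
    return MLRResult(terms=terms, converged=converged and not separation,
                     separation=separation, covariates=tuple(X.columns), model=fit)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def stratified_kfold(labels: np.ndarray, k: int = 5, seed: int = 0) -> np.ndarray:
    """Deterministic stratified fold assignment (0..k-1 per subject)."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise StatsError(f"every class needs >= {k} members for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.full(len(y), -1, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        folds[test_idx] = fold
    return folds


def roc_auc(probabilities, labels) -> float:
    """Trapezoidal AUC over all unique thresholds (ties step together)."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise StatsError("AUC requires both classes present")
    return float(roc_auc_score(y, np.asarray(probabilities, dtype=float)))


@dataclass(frozen=True)
class FoldMetrics:
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float


@dataclass(frozen=True)
class CVReport:
    fold_metrics: tuple[FoldMetrics, ...]
    mean: FoldMetrics
    sd: FoldMetrics
    pooled_auc: float
    pooled_probabilities: np.ndarray
    pooled_roc: pd.DataFrame              # fpr, tpr, threshold
    confusion: dict                       # tn, fp, fn, tp at the fixed threshold
    threshold: float
    seed: int
    fold_assignments: np.ndarray
    incomplete_folds: tuple[int, ...] = ()

    @property
    def complete(self) -> bool:
        return not self.incomplete_folds


def _threshold_metrics(y, prob, threshold, auc) -> FoldMetrics:
    pred = (np.asarray(prob) >= threshold).astype(int)
    y = np.asarray(y).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    prec = tp / (tp + fp) if tp + fp else np.nan
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else np.nan
    acc = (tp + tn) / len(y)
    return FoldMetrics(auc=auc, accuracy=acc, sensitivity=sens, specificity=spec,
                       precision=prec, f1=f1)


def cross_validated_classification(
    data: pd.DataFrame,
    parameter: str,
    covariates: tuple[str, ...] = ADJUSTMENT_COVARIATES,
    *,
    label_column: str = "pad",
    k: int = 5,
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold CV of a one-parameter adjusted logistic model.

    Per fold: train on k-1 folds, predict the held-out fold. Out-of-fold
    probabilities are pooled for the pooled ROC/AUC and the pooled
    confusion matrix at the fixed threshold (prob >= threshold -> PAD);
    threshold metrics are also computed per fold (with fold-local AUC)
    and summarized as mean +/- SD.
    """
    y = data[label_column].to_numpy().astype(int)
    folds = stratified_kfold(y, k=k, seed=seed)
    prob = np.full(len(y), np.nan)
    incomplete = []
    for fold in range(k):
        test = folds == fold
        train = ~test
        res = fit_mlr(
            data.loc[train, parameter].to_numpy(),
            data.loc[train, list(covariates)] if covariates else None,
            y[train], feature_name=parameter,
        )
        if res.separation or not res.converged:
            incomplete.append(fold)
        if res.model is None:
            continue  # probabilities stay NaN for this fold
        Xt = pd.DataFrame({parameter: data.loc[test, parameter].to_numpy()})
        for c in covariates:
            Xt[c] = data.loc[test, c].to_numpy()
        with np.errstate(over="ignore"):
            prob[test] = res.model.predict(sm.add_constant(Xt, has_constant="add"))
    per_fold = []
    for fold in range(k):
        test = folds == fold
        if np.isnan(prob[test]).any():
            per_fold.append(FoldMetrics(*([np.nan] * 6)))
            continue
        fold_auc = roc_auc(prob[test], y[test])
        per_fold.append(_threshold_metrics(y[test], prob[test], threshold, fold_auc))
    arr = np.array([[getattr(m, f) for f in FoldMetrics.__dataclass_fields__]
                    for m in per_fold])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = FoldMetrics(*np.nanmean(arr, axis=0))
        sd = FoldMetrics(*np.nanstd(arr, axis=0, ddof=1))
    valid = ~np.isnan(prob)
    if valid.all():
        fpr, tpr, thr = roc_curve(y, prob)
        pooled_auc_val = roc_auc(prob, y)
        pred = (prob >= threshold).astype(int)
        confusion = {
            "tn": int(np.sum((pred == 0) & (y == 0))),
            "fp": int(np.sum((pred == 1) & (y == 0))),
            "fn": int(np.sum((pred == 0) & (y == 1))),
            "tp": int(np.sum((pred == 1) & (y == 1))),
        }
    else:  # incomplete report: pooled quantities undefined
        fpr = tpr = thr = np.array([])
        pooled_auc_val = np.nan
        confusion = {"tn": 0, "fp": 0, "fn": 0, "tp": 0}
    return CVReport(
        fold_metrics=tuple(per_fold), mean=mean, sd=sd,
        pooled_auc=pooled_auc_val, pooled_probabilities=prob,
        pooled_roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
        confusion=confusion, threshold=threshold, seed=seed,
        fold_assignments=folds, incomplete_folds=tuple(incomplete),
    )


def medication_sensitivity(
    data: pd.DataFrame,
    parameter: str,
    *,
    k: int = 5,
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
) -> dict:
    """Re-run the CV pipeline with medication indicators added.

    Returns ``{"base", "extended", "delta"}`` where delta holds the
    extended-minus-base change in the mean fold metrics. Fold
    assignments are identical between the two runs (stratification does
    not depend on covariates).
    """
    for c in MEDICATION_COVARIATES:
        if c not in data.columns:
            raise StatsError(f"medication column {c!r} missing")
    base = cross_validated_classification(data, parameter, ADJUSTMENT_COVARIATES,
                                          k=k, seed=seed, threshold=threshold)
    extended = cross_validated_classification(
        data, parameter, ADJUSTMENT_COVARIATES + MEDICATION_COVARIATES,
        k=k, seed=seed, threshold=threshold)
    delta = {
        f: getattr(extended.mean, f) - getattr(base.mean, f)
        for f in FoldMetrics.__dataclass_fields__
    }
    delta["pooled_auc"] = extended.pooled_auc - base.pooled_auc
    return {"base": base, "extended": extended, "delta": delta}


# ---------------------------------------------------------------------------
# table-style summaries
# ---------------------------------------------------------------------------

def group_comparison_table(
    data: pd.DataFrame,
    parameters: tuple[str, ...],
    *,
    label_column: str = "pad",
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-parameter group means +/- SD, U, p, and Bonferroni significance."""
    thresh = bonferroni_threshold(alpha, len(parameters))
    rows = []
    y = data[label_column].to_numpy().astype(bool)
    for param in parameters:
        x0 = data.loc[~y, param].to_numpy()
        x1 = data.loc[y, param].to_numpy()
        u, p, degenerate = mann_whitney(x0, x1)
        rows.append({
            "parameter": param,
            "mean_nonpad": float(np.mean(x0)), "sd_nonpad": float(np.std(x0, ddof=1)),
            "mean_pad": float(np.mean(x1)), "sd_pad": float(np.std(x1, ddof=1)),
            "u_statistic": u, "p_value": p,
            "significant": bool(p < thresh), "degenerate": degenerate,
        })
    return pd.DataFrame(rows)
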