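"""Iterated grouped cross-validation and the quantitative analysis battery.

Evaluation is by repeated k-fold cross-validation *grouped at the patient
level*: all of a patient's samples share a fold, so no patient appears in
both the train and test side of any split (asserted at run time).  Metrics
per outer fold are ROC AUC, PR AUC (average precision), Brier score and log
loss, summarized two ways: **micro** (mean ± sd over all iteration-by-fold
results) and **macro** (mean ± sd over per-iteration means).

System pairs are compared with the Bayesian correlated t-test: the
posterior of the mean metric difference over paired folds is a
location-scale Student-t with ``n - 1`` degrees of freedom, location the
sample mean and squared scale ``(1/n + rho/(1 - rho)) s^2`` where
``rho = 1/k`` accounts for the overlap of training sets in k-fold CV.
Reported is the posterior mass left of, inside, and right of a region of
practical equivalence (ROPE) of half-width ``r/2`` around zero.

The error analyses mirror the fairness battery: L1-penalized regressions of
absolute error on demographic blocks after stratifying by outcome, error by
hospital-utilization bin, per-sample prediction variance over iterations,
leave-one-patient-out coefficient perturbation, and percentile bootstrap
confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso
from sklearn.metrics import (
    average_precision_score,
    brier_score_loss,
    log_loss as _sk_log_loss,
    roc_auc_score,
)

from .features import FeatureInfo, FeatureMatrix
from .modeling import VariantConfig, fit_pipeline

__all__ = [
    "FoldResult",
    "MetricSummary",
    "CalibrationCurve",
    "PosteriorComparison",
    "grouped_kfold",
    "run_cv",
    "roc_auc",
    "pr_auc",
    "brier",
    "log_loss",
    "calibration_curve",
    "micro_macro_summary",
    "patient_level_aggregate",
    "bayes_correlated_ttest",
    "compare_systems",
    "error_regression",
    "utilization_analysis",
    "coefficient_perturbation",
    "prediction_variance",
    "bootstrap_ci",
]

METRICS = ("roc_auc", "pr_auc", "brier", "log_loss")


@dataclass
class FoldResult:
    """Predictions and metrics of one outer test fold."""

    iteration: int
    fold: int
    admit_ids: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    roc_auc: float
    pr_auc: float
    brier: float
    log_loss: float

    def metric(self, name: str) -> float:
        if name not in METRICS:
            raise KeyError(name)
        return getattr(self, name)


@dataclass(frozen=True)
class MetricSummary:
    micro_mean: float
    micro_sd: float
    macro_mean: float
    macro_sd: float


@dataclass(frozen=True)
class CalibrationCurve:
    """Equal-width reliability bins over [0, 1]; empty bins keep count 0
    and NaN means."""

    mean_predicted: np.ndarray
    observed_frequency: np.ndarray
    counts: np.ndarray

    @property
    def mean_absolute_deviation(self) -> float:
        """Count-weighted mean |observed - predicted| over occupied bins."""
        occ = self.counts > 0
        dev = np.abs(self.observed_frequency[occ] - self.mean_predicted[occ])
        return float(np.average(dev, weights=self.counts[occ]))


@dataclass(frozen=True)
class PosteriorComparison:
    """Posterior mass of a metric difference left of / inside / right of
    the ROPE.  The three probabilities sum to 1."""

    p_left: float
    p_rope: float
    p_right: float
    rope: float
    rho: float

    def as_tuple(self) -> tuple[float, float, float]:
        """(P(i better), P(practically equivalent), P(j better)) ordering
        used when the metric is higher-is-better."""
        return (self.p_right, self.p_rope, self.p_left)


# ---------------------------------------------------------------------------
# metrics

def roc_auc(labels: np.ndarray, probabilities: np.ndarray) -> float:
    """Probability a random positive outranks a random negative (ties 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("roc_auc requires both classes")
    return float(roc_auc_score(labels, probabilities))


def pr_auc(labels: np.ndarray, probabilities: np.ndarray) -> float:
    """Step-wise average precision."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("pr_auc requires both classes")
    return float(average_precision_score(labels, probabilities))


def brier(labels: np.ndarray, probabilities: np.ndarray) -> float:
    """Mean squared error of the probabilities."""
    return float(brier_score_loss(labels, probabilities))


def log_loss(labels: np.ndarray, probabilities: np.ndarray) -> float:
    """Mean negative log-likelihood."""
    return float(_sk_log_loss(labels, probabilities, labels=[0, 1]))


def calibration_curve(
    labels: np.ndarray, probabilities: np.ndarray, bins: int = 10
) -> CalibrationCurve:
    """Reliability curve with ``bins`` equal-width bins on [0, 1]."""
    y = np.asarray(labels, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    edges = np.linspace(0.0, 1.0, bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, bins - 1)
    counts = np.bincount(idx, minlength=bins).astype(int)
    mean_pred = np.full(bins, np.nan)
    obs = np.full(bins, np.nan)
    for b in range(bins):
        if counts[b]:
            mean_pred[b] = p[idx == b].mean()
            obs[b] = y[idx == b].mean()
    return CalibrationCurve(mean_pred, obs, counts)


# ---------------------------------------------------------------------------
# cross-validation

def grouped_kfold(patient_ids: Sequence, k: int, seed: int) -> np.ndarray:
    """Random patient-level fold assignment: every sample of a patient
    shares a fold.  Returns the fold index (0..k-1) per sample."""
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = np.asarray(patient_ids)
    patients = np.unique(ids)
    if len(patients) < k:
        raise ValueError(f"need at least k={k} patients, got {len(patients)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(patients)
    fold_of_patient = {pid: i % k for i, pid in enumerate(order)}
    return np.array([fold_of_patient[pid] for pid in ids])


def run_cv(
    fm: FeatureMatrix,
    config: VariantConfig,
    iterations: int = 5,
    k: int = 5,
    base_seed: int = 0,
) -> list[FoldResult]:
    """Iterated grouped k-fold CV of one variant.

    Each iteration draws a fresh grouped split; each outer fold trains the
    full pipeline on the k-1 training folds and scores the held-out fold.
    Patient-level train/test disjointness is asserted for every fold.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    results: list[FoldResult] = []
    for it in range(iterations):
        folds = grouped_kfold(fm.groups, k, seed=base_seed + 7919 * (it + 1))
        for f in range(k):
            test = folds == f
            train = ~test
            train_patients = set(fm.groups[train])
            test_patients = set(fm.groups[test])
            assert not (train_patients & test_patients), "patient leakage"
            fold_seed = (base_seed * 100003 + it * k + f) % (2**31 - 1)
            model = fit_pipeline(
                fm.X.loc[train],
                fm.y[train],
                fm.groups[train],
                fm.schema,
                VariantConfig(
                    variant=config.variant,
                    hp=config.hp,
                    calibration_fraction=config.calibration_fraction,
                    stability_threshold=config.stability_threshold,
                    c_reference_n=config.c_reference_n,
                    seed=fold_seed,
                ),
            )
            y_pred = model.predict(fm.X.loc[test])
            y_true = fm.y[test]
            results.append(
                FoldResult(
                    iteration=it,
                    fold=f,
                    admit_ids=np.asarray(fm.X.index[test]),
                    y_true=y_true,
                    y_pred=y_pred,
                    roc_auc=roc_auc(y_true, y_pred),
                    pr_auc=pr_auc(y_true, y_pred),
                    brier=brier(y_true, y_pred),
                    log_loss=log_loss(y_true, y_pred),
                )
            )
    return results


def micro_macro_summary(
    results: Sequence[FoldResult], metric: str
) -> MetricSummary:
    """Micro (over all folds) and macro (over per-iteration means) mean/sd."""
    if len(results) == 0:
        raise ValueError("no fold results")
    values = np.array([r.metric(metric) for r in results])
    iters = np.array([r.iteration for r in results])
    per_iter = np.array([values[iters == it].mean() for it in np.unique(iters)])

    def sd(x: np.ndarray) -> float:
        return float(x.std(ddof=1)) if len(x) > 1 else 0.0

    return MetricSummary(
        micro_mean=float(values.mean()),
        micro_sd=sd(values),
        macro_mean=float(per_iter.mean()),
        macro_sd=sd(per_iter),
    )


# ---------------------------------------------------------------------------
# patient-level aggregation and comparisons

def _per_sample_mean_prediction(
    results: Sequence[FoldResult],
) -> pd.DataFrame:
    """Macro-average predictions per sample over iterations (each sample is
    scored exactly once per iteration)."""
    rows = []
    for r in results:
        for aid, yt, yp in zip(r.admit_ids, r.y_true, r.y_pred):
            rows.append((aid, r.iteration, yt, yp))
    df = pd.DataFrame(rows, columns=["admit_id", "iteration", "y_true", "y_pred"])
    return (
        df.groupby("admit_id")
        .agg(y_true=("y_true", "first"), y_pred=("y_pred", "mean"))
        .reset_index()
    )


def patient_level_aggregate(
    results: Sequence[FoldResult],
    patient_of_admit: Mapping[str, str],
    bins: int = 10,
) -> tuple[pd.DataFrame, CalibrationCurve]:
    """Average observed and (macro-averaged) predicted risk per patient.

    A patient with one AKI and one non-AKI hospitalization has observed
    risk 0.5.  The returned reliability curve is computed over the patients
    whose mean observed risk is exactly 0 or 1, where observed frequency is
    well defined.
    """
    per_sample = _per_sample_mean_prediction(results)
    per_sample["patient_id"] = per_sample["admit_id"].map(patient_of_admit)
    per_patient = (
        per_sample.groupby("patient_id")[["y_true", "y_pred"]]
        .mean()
        .rename(columns={"y_true": "mean_observed", "y_pred": "mean_predicted"})
        .reset_index()
    )
    pure = per_patient[per_patient["mean_observed"].isin([0.0, 1.0])]
    curve = calibration_curve(
        pure["mean_observed"].to_numpy(), pure["mean_predicted"].to_numpy(), bins
    )
    return per_patient, curve


def bayes_correlated_ttest(
    differences: Sequence[float], k: int, rope: float
) -> PosteriorComparison:
    """Posterior of a mean metric difference from paired fold results.

    ``differences`` are per-fold metric differences of two systems
    evaluated on identical splits; ``k`` is the fold count (the test
    fraction ``1/k`` is the assumed correlation between folds); ``rope``
    the width of the region of practical equivalence (half-width
    ``rope/2`` each side of zero).
    """
    d = np.asarray(differences, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("need at least two paired differences")
    rho = 1.0 / k
    xbar = float(d.mean())
    s2 = float(d.var(ddof=1))
    half = rope / 2.0
    if s2 == 0.0:
        p_left = 1.0 if xbar < -half else 0.0
        p_right = 1.0 if xbar > half else 0.0
        return PosteriorComparison(
            p_left, 1.0 - p_left - p_right, p_right, rope, rho
        )
    scale = np.sqrt((1.0 / n + rho / (1.0 - rho)) * s2)
    dist = stats.t(df=n - 1, loc=xbar, scale=scale)
    p_left = float(dist.cdf(-half))
    p_right = float(1.0 - dist.cdf(half))
    return PosteriorComparison(p_left, 1.0 - p_left - p_right, p_right, rope, rho)


def compare_systems(
    results_i: Sequence[FoldResult],
    results_j: Sequence[FoldResult],
    metric: str,
    k: int,
    rope: float,
) -> PosteriorComparison:
    """Correlated t-test of system i minus system j on identical splits."""
    key = lambda r: (r.iteration, r.fold)
    bi = {key(r): r.metric(metric) for r in results_i}
    bj = {key(r): r.metric(metric) for r in results_j}
    if set(bi) != set(bj):
        raise ValueError("fold results are not paired on the same splits")
    diffs = [bi[kk] - bj[kk] for kk in sorted(bi)]
    return bayes_correlated_ttest(diffs, k=k, rope=rope)


# ---------------------------------------------------------------------------
# error analyses

def _lasso_alpha_by_gap(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    alphas: Sequence[float],
    seed: int,
) -> float:
    """Pick the L1 penalty whose train and validation errors are closest
    on one grouped split (the train-approximates-validation heuristic)."""
    folds = grouped_kfold(groups, 2, seed)
    tr, va = folds == 0, folds == 1
    best, best_gap = alphas[0], np.inf
    for a in alphas:
        est = Lasso(alpha=a, max_iter=5000)
        est.fit(X[tr], y[tr])
        gap = abs(
            np.mean((y[tr] - est.predict(X[tr])) ** 2)
            - np.mean((y[va] - est.predict(X[va])) ** 2)
        )
        if gap < best_gap:
            best, best_gap = a, gap
    return best


def error_regression(
    errors: np.ndarray,
    covariates: pd.DataFrame,
    outcome: np.ndarray,
    groups: np.ndarray,
    iterations: int = 5,
    k: int = 5,
    seed: int = 0,
    alphas: Sequence[float] = (0.0005, 0.002, 0.01, 0.05),
    n_boot: int = 1000,
) -> pd.DataFrame:
    """L1-penalized linear regression of absolute error on one covariate
    block, per outcome stratum, under iterated grouped CV.

    ``errors`` must be |label - predicted| in [0, 1].  Returns one row per
    (stratum, covariate) with the mean coefficient over CV fits and a
    percentile bootstrap interval over the per-fold coefficients.  Empty or
    single-patient strata are skipped with a warning.
    """
    errors = np.clip(np.asarray(errors, dtype=float), 0.0, 1.0)
    outcome = np.asarray(outcome)
    rows = []
    for stratum in (0, 1):
        mask = outcome == stratum
        if mask.sum() < 4 or len(np.unique(groups[mask])) < k:
            warnings.warn(f"stratum {stratum} too small; skipped", stacklevel=2)
            continue
        Xs = covariates.loc[mask].to_numpy(dtype=float)
        ys = errors[mask]
        gs = groups[mask]
        alpha = _lasso_alpha_by_gap(Xs, ys, gs, alphas, seed)
        coefs = []
        for it in range(iterations):
            folds = grouped_kfold(gs, k, seed=seed + 31 * (it + 1))
            for f in range(k):
                tr = folds != f
                est = Lasso(alpha=alpha, max_iter=5000)
                est.fit(Xs[tr], ys[tr])
                coefs.append(est.coef_)
        coefs = np.asarray(coefs)
        for j, name in enumerate(covariates.columns):
            lo, hi = bootstrap_ci(coefs[:, j], n_boot=n_boot, seed=seed + j)
            rows.append(
                {
                    "stratum": stratum,
                    "covariate": name,
                    "coefficient": float(coefs[:, j].mean()),
                    "ci_low": lo,
                    "ci_high": hi,
                    "alpha": alpha,
                }
            )
    return pd.DataFrame(rows)


def utilization_analysis(
    results: Sequence[FoldResult],
    utilization_of_admit: Mapping[str, int],
) -> pd.DataFrame:
    """Mean absolute error and prediction spread by utilization bin.

    Samples are binned by how many hospitalizations their patient
    contributes; rows are (utilization, outcome stratum) with the mean
    |error|, the sd of predictions, and the sample count.
    """
    rows = []
    for r in results:
        for aid, yt, yp in zip(r.admit_ids, r.y_true, r.y_pred):
            rows.append((utilization_of_admit[aid], int(yt), abs(yt - yp), yp))
    df = pd.DataFrame(rows, columns=["utilization", "outcome", "abs_error", "pred"])
    out = (
        df.groupby(["utilization", "outcome"])
        .agg(
            mean_abs_error=("abs_error", "mean"),
            sd_prediction=("pred", lambda x: x.std(ddof=1) if len(x) > 1 else 0.0),
            n=("pred", "size"),
        )
        .reset_index()
    )
    return out


def prediction_variance(results: Sequence[FoldResult]) -> pd.DataFrame:
    """Per-sample mean and sd of predicted probability across iterations."""
    rows = []
    for r in results:
        for aid, yp in zip(r.admit_ids, r.y_pred):
            rows.append((aid, r.iteration, yp))
    df = pd.DataFrame(rows, columns=["admit_id", "iteration", "y_pred"])
    n_iter = df["iteration"].nunique()
    if n_iter < 2:
        raise ValueError("prediction_variance needs >= 2 iterations")
    return (
        df.groupby("admit_id")["y_pred"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1))
        .reset_index()
    )


def coefficient_perturbation(
    fm: FeatureMatrix,
    config: VariantConfig,
) -> pd.Series:
    """Leave-one-patient-out L1 distance of the (HPLR1-style) coefficient
    vector from the full-data fit, per patient."""
    full = fit_pipeline(fm.X, fm.y, fm.groups, fm.schema, config)
    ref = full.coefficients
    if ref is None:
        raise ValueError("coefficient perturbation needs a linear variant")
    out = {}
    for pid in np.unique(fm.groups):
        keep = fm.groups != pid
        model = fit_pipeline(
            fm.X.loc[keep], fm.y[keep], fm.groups[keep], fm.schema, config
        )
        coef = model.coefficients.reindex(ref.index).fillna(0.0)
        out[pid] = float(np.abs(coef.to_numpy() - ref.to_numpy()).sum())
    return pd.Series(out, name="l1_distance")


def bootstrap_ci(
    values: Sequence[float],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval of the mean; deterministic per seed."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    x = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    means = x[idx].mean(axis=1)
    lo = (1.0 - level) / 2.0
    return (
        float(np.quantile(means, lo)),
        float(np.quantile(means, 1.0 - lo)),
    )
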