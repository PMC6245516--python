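"""Classifier variants in a leak-free impute/scale/fit/calibrate pipeline.

Every trained system follows the same recipe inside each cross-validation
training fold: a grouped 75/25 split; on the 75% — most-frequent-value
imputation, optional Anscombe transform of count columns, standard scaling
(logistic-regression family only), and the learner fit; on the held-out 25%
— selection of the candidate with the lowest log loss and Platt sigmoid
calibration of its scores.  All transform states (imputation modes, scaler
statistics, the non-present code maxima, selected features, Platt
parameters) are learned strictly from training data.

Variants (hyperparameters are fixed, not searched):

========  =================================================================
GBC       main system: candidates are gradient boosting (depth-2 trees,
          min split 150, min leaf 100) and L1 logistic regression (C=2e-3),
          chosen by calibration-split log loss
LR1       L1 logistic regression alone
ALR1      LR1 with an Anscombe transform of count/categorical columns
HPLR1     highly penalized LR1 (C=2e-4, aiming at a ~12-feature model)
RLR1      stability selection (C1=0.5, 50 resamples at fraction 0.75) then
          near-unpenalized logistic fit (C2=1) on the stable features
RHPLR1    stability selection at C1=0.2, C2=1
W*        patient-weighted (each sample weighted 1/its patient's samples)
S*        one randomly chosen sample per patient
RGBC      only the most recent prior hospitalization as input
MGBC/MLR1 medication features only
CLR       ridge logistic (C=1000) on four clinically known risk factors
NGBC      labels uniformly permuted before fitting (noise control)
========  =================================================================

The reference-scale L1 penalties were fixed for a ~67.5k-sample training fold;
``VariantConfig.c_reference_n`` optionally rescales the effective C by
``c_reference_n / n_fit`` so the per-sample penalty matches that operating
point on smaller corpora.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import GroupShuffleSplit

from .features import FeatureInfo, add_nonpresent_features

__all__ = [
    "GBC_HP",
    "VariantSpec",
    "VARIANTS",
    "VariantConfig",
    "CalibratedModel",
    "impute_most_frequent",
    "standard_scale",
    "anscombe_transform",
    "compute_sample_weights",
    "sample_one_per_patient",
    "permute_labels",
    "platt_calibrate",
    "platt_apply",
    "fit_learner",
    "stability_select",
    "fit_pipeline",
]

GBC_HP = {"max_depth": 2, "min_samples_split": 150, "min_samples_leaf": 100}

DEFAULT_HP = {
    "C_lr1": 2e-3,
    "C_hplr1": 2e-4,
    "rlr1_C1": 0.5,
    "rlr1_C2": 1.0,
    "rhplr1_C1": 0.2,
    "rhplr1_C2": 1.0,
    "stability_fraction": 0.75,
    "stability_resamples": 50,
    "C_clr": 1000.0,
    **GBC_HP,
}


@dataclass(frozen=True)
class VariantSpec:
    """Static description of a variant: which learners compete and which
    data manipulations apply before fitting."""

    candidates: tuple[str, ...]
    weighting: bool = False
    sampling: bool = False
    subset: str = "full"
    recent: bool = False
    anscombe: bool = False
    permute: bool = False


VARIANTS: dict[str, VariantSpec] = {
    "GBC": VariantSpec(("gbc", "lr1")),
    "LR1": VariantSpec(("lr1",)),
    "ALR1": VariantSpec(("lr1",), anscombe=True),
    "HPLR1": VariantSpec(("hplr1",)),
    "RLR1": VariantSpec(("rlr1",)),
    "RHPLR1": VariantSpec(("rhplr1",)),
    "WGBC": VariantSpec(("gbc",), weighting=True),
    "WLR1": VariantSpec(("lr1",), weighting=True),
    "WHPLR1": VariantSpec(("hplr1",), weighting=True),
    "SGBC": VariantSpec(("gbc",), sampling=True),
    "SLR1": VariantSpec(("lr1",), sampling=True),
    "SHPLR1": VariantSpec(("hplr1",), sampling=True),
    "RGBC": VariantSpec(("gbc",), recent=True),
    "MGBC": VariantSpec(("gbc",), subset="medications"),
    "MLR1": VariantSpec(("lr1",), subset="medications"),
    "CLR": VariantSpec(("clr",), subset="clinical"),
    "NGBC": VariantSpec(("gbc", "lr1"), permute=True),
}


@dataclass(frozen=True)
class VariantConfig:
    """A variant name plus the knobs shared by all variants."""

    variant: str = "GBC"
    hp: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_HP))
    calibration_fraction: float = 0.25
    stability_threshold: float = 0.6
    c_reference_n: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if not (0.0 < self.calibration_fraction < 1.0):
            raise ValueError("calibration_fraction must be in (0, 1)")

    @property
    def spec(self) -> VariantSpec:
        return VARIANTS[self.variant]

    def hp_value(self, key: str) -> float:
        return self.hp.get(key, DEFAULT_HP[key])


# ---------------------------------------------------------------------------
# transforms

def impute_most_frequent(
    matrix: np.ndarray, state: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Replace missing entries with the per-feature training-set mode.

    Ties break toward the smaller value; a feature entirely missing in
    training falls back to 0 (with a warning).  Pass the returned ``state``
    to apply training modes to held-out data unchanged.
    """
    X = np.asarray(matrix, dtype=float)
    if state is None:
        modes = np.empty(X.shape[1])
        all_missing = []
        for j in range(X.shape[1]):
            col = X[:, j]
            col = col[~np.isnan(col)]
            if col.size == 0:
                modes[j] = 0.0
                all_missing.append(j)
                continue
            values, counts = np.unique(col, return_counts=True)
            modes[j] = values[np.argmax(counts)]  # unique is sorted: ties -> smaller
        if all_missing:
            warnings.warn(
                f"{len(all_missing)} features entirely missing in training; "
                "imputing 0",
                stacklevel=2,
            )
        state = modes
    out = X.copy()
    mask = np.isnan(out)
    out[mask] = np.broadcast_to(state, out.shape)[mask]
    return out, state


def standard_scale(
    matrix: np.ndarray, state: tuple[np.ndarray, np.ndarray] | None = None
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Center/scale by training mean and (population) standard deviation.

    Zero-variance features divide by 1.  The state is fit once on training
    data and applied unchanged to held-out data.
    """
    X = np.asarray(matrix, dtype=float)
    if state is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)  # ddof=0 convention
        sd = np.where(sd == 0.0, 1.0, sd)
        state = (mean, sd)
    mean, sd = state
    return (X - mean) / sd, state


def anscombe_transform(x):
    """Variance-stabilizing transform for counts: ``2 sqrt(x + 3/8)``."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("anscombe_transform requires non-negative input")
    return 2.0 * np.sqrt(arr + 0.375)


def compute_sample_weights(patient_ids: Sequence) -> np.ndarray:
    """Weight each sample by 1 / (its patient's number of samples), giving
    every patient equal total representation."""
    ids = pd.Series(list(patient_ids))
    counts = ids.map(ids.value_counts())
    return (1.0 / counts).to_numpy(dtype=float)


def sample_one_per_patient(patient_ids: Sequence, seed: int) -> np.ndarray:
    """Indices of one uniformly chosen sample per patient (deterministic
    per seed)."""
    rng = np.random.default_rng(seed)
    by_patient: dict = {}
    for i, pid in enumerate(patient_ids):
        by_patient.setdefault(pid, []).append(i)
    return np.sort(
        np.array([idxs[rng.integers(len(idxs))] for idxs in by_patient.values()])
    )


def permute_labels(labels: np.ndarray, seed: int) -> np.ndarray:
    """Uniform random permutation of the response (positive count
    preserved exactly)."""
    rng = np.random.default_rng(seed)
    return np.asarray(labels)[rng.permutation(len(labels))]


# ---------------------------------------------------------------------------
# Platt calibration

def platt_calibrate(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Fit the sigmoid ``p = 1 / (1 + exp(A f + B))`` by maximum likelihood.

    ``A`` is constrained non-positive so the calibrated predictor is
    monotone non-decreasing in the raw score; the unconstrained plain
    sigmoid ``(A, B) = (-1, 0)`` is inside the feasible set, so the fit
    never has higher log loss than the uncalibrated mapping.  A single-class
    calibration split falls back to the identity mapping with a warning.
    """
    f = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        warnings.warn(
            "single-class calibration split; using identity calibration",
            stacklevel=2,
        )
        return (-1.0, 0.0)

    def nll_and_grad(params):
        a, b = params
        z = -(a * f + b)  # p = expit(z)
        p = expit(z)
        eps = 1e-12
        nll = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
        # d nll / dz = -(y - p)/n ; dz/da = -f, dz/db = -1
        common = (p - y) / len(y)
        return nll, np.array([-np.sum(common * f), -np.sum(common)])

    res = minimize(
        nll_and_grad,
        x0=np.array([-1.0, 0.0]),
        jac=True,
        method="L-BFGS-B",
        bounds=[(None, 0.0), (None, None)],
    )
    a, b = res.x
    return float(a), float(b)


def platt_apply(scores: np.ndarray, params: tuple[float, float]) -> np.ndarray:
    a, b = params
    return expit(-(a * np.asarray(scores, dtype=float) + b))


# ---------------------------------------------------------------------------
# learners

def _effective_c(c: float, n_fit: int, c_reference_n: int | None) -> float:
    if c_reference_n is None:
        return c
    return c * c_reference_n / max(n_fit, 1)


def fit_learner(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None,
    learner: str,
    config: VariantConfig,
    seed: int,
):
    """Fit one candidate learner with the fixed hyperparameters.

    ``"gbc"`` is depth-2 gradient boosting; ``"lr1"``/``"hplr1"`` are
    L1-penalized logistic regressions with prevalence-balanced class
    weights; ``"clr"`` is a near-unpenalized ridge logistic regression.
    Raises on single-class training data.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("single-class training data")
    if learner == "gbc":
        est = GradientBoostingClassifier(
            max_depth=int(config.hp_value("max_depth")),
            min_samples_split=int(config.hp_value("min_samples_split")),
            min_samples_leaf=int(config.hp_value("min_samples_leaf")),
            random_state=seed,
        )
    elif learner in ("lr1", "hplr1"):
        c = config.hp_value("C_lr1" if learner == "lr1" else "C_hplr1")
        est = LogisticRegression(
            l1_ratio=1,
            C=_effective_c(c, len(y), config.c_reference_n),
            solver="liblinear",
            class_weight="balanced",
            random_state=seed,
            max_iter=1000,
        )
    elif learner == "clr":
        est = LogisticRegression(
            C=config.hp_value("C_clr"),
            solver="lbfgs",
            class_weight="balanced",
            max_iter=2000,
        )
    else:
        raise ValueError(f"unknown learner {learner!r}")
    est.fit(X, y, sample_weight=sample_weight)
    return est


def stability_select(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    c1: float,
    fraction: float,
    resamples: int,
    threshold: float,
    seed: int,
    c_reference_n: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stability selection by grouped subsampling.

    Each resample draws ``floor(fraction * n_patients)`` patients without
    replacement, fits an L1 logistic regression at inverse penalty ``c1``
    and records the support.  Returns ``(kept boolean mask, selection
    frequencies)`` where a feature is kept iff selected in at least
    ``threshold`` of the resamples.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    patients = np.unique(groups)
    n_draw = max(int(np.floor(fraction * len(patients))), 1)
    hits = np.zeros(X.shape[1])
    done = 0
    for _ in range(resamples):
        chosen = set(rng.choice(patients, size=n_draw, replace=False))
        idx = np.array([i for i, g in enumerate(groups) if g in chosen])
        if len(np.unique(y[idx])) < 2:
            continue
        est = LogisticRegression(
            l1_ratio=1,
            C=_effective_c(c1, len(idx), c_reference_n),
            solver="liblinear",
            class_weight="balanced",
            random_state=int(rng.integers(2**31 - 1)),
            max_iter=1000,
        )
        est.fit(X[idx], y[idx])
        hits += (np.abs(est.coef_[0]) > 1e-10).astype(float)
        done += 1
    freq = hits / max(done, 1)
    return freq >= threshold, freq


# ---------------------------------------------------------------------------
# the pipeline

@dataclass
class CalibratedModel:
    """All fitted state of one trained system.

    ``columns`` are the model's input features (after the non-present
    transform, helpers dropped); transform states were learned from
    training data only.  ``predict`` returns calibrated probabilities in
    (0, 1).
    """

    variant: str
    seed: int
    columns: list[str]
    np_state: dict | None
    impute_state: np.ndarray
    anscombe_mask: np.ndarray | None
    scale_state: tuple[np.ndarray, np.ndarray] | None
    learner_name: str
    learner: object
    platt: tuple[float, float]
    selected_mask: np.ndarray | None = None
    stability_freq: np.ndarray | None = None
    train_fingerprint: str = ""
    schema: Mapping[str, FeatureInfo] | None = None

    def _design(self, X: pd.DataFrame) -> np.ndarray:
        if self.np_state is not None:
            X, _, _ = add_nonpresent_features(X, self.schema, state=self.np_state)
        mat = X[self.columns].to_numpy(dtype=float)
        mat, _ = impute_most_frequent(mat, self.impute_state)
        if self.anscombe_mask is not None:
            mat[:, self.anscombe_mask] = anscombe_transform(
                np.clip(mat[:, self.anscombe_mask], 0.0, None)
            )
        if self.scale_state is not None:
            mat, _ = standard_scale(mat, self.scale_state)
        if self.selected_mask is not None:
            mat = mat[:, self.selected_mask]
            if mat.shape[1] == 0:
                mat = np.zeros((len(X), 1))
        return mat

    def raw_scores(self, X: pd.DataFrame) -> np.ndarray:
        return self.learner.decision_function(self._design(X))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        p = platt_apply(self.raw_scores(X), self.platt)
        return np.clip(p, 1e-9, 1.0 - 1e-9)

    @property
    def coefficients(self) -> pd.Series | None:
        """Signed coefficients on the model's input columns (linear
        learners only), zeros for unselected features."""
        if not hasattr(self.learner, "coef_"):
            return None
        coefs = np.zeros(len(self.columns))
        if self.selected_mask is not None:
            sel = np.flatnonzero(self.selected_mask)
            if len(sel):
                coefs[sel] = self.learner.coef_[0]
        else:
            coefs = np.asarray(self.learner.coef_[0], dtype=float)
        return pd.Series(coefs, index=self.columns)


def _model_columns(
    columns: Sequence[str], schema: Mapping[str, FeatureInfo], subset: str
) -> list[str]:
    if subset == "full":
        return [
            c
            for c in columns
            if schema[c].category not in ("clinical", "helper")
        ]
    if subset == "medications":
        return [c for c in columns if schema[c].category == "med"]
    if subset == "clinical":
        return [c for c in columns if schema[c].category == "clinical"] + [
            c for c in columns if c == "max|value|age"
        ]
    raise ValueError(f"unknown subset {subset!r}")


def fit_pipeline(
    X: pd.DataFrame,
    y: np.ndarray,
    groups: np.ndarray,
    schema: Mapping[str, FeatureInfo],
    config: VariantConfig,
) -> CalibratedModel:
    """Train one system on a training fold.

    Applies the variant's data manipulations (label permutation, one-sample
    -per-patient subsampling, patient weighting), splits the fold 75/25
    grouped by patient, fits every candidate learner on the 75%, selects
    the one with the lowest log loss on the 25% and Platt-calibrates it on
    that same 25%.
    """
    spec = config.spec
    y = np.asarray(y, dtype=int)
    groups = np.asarray(groups)

    if spec.permute:
        y = permute_labels(y, config.seed)
    if spec.sampling:
        idx = sample_one_per_patient(groups, config.seed)
        X, y, groups = X.iloc[idx], y[idx], groups[idx]
    weights = compute_sample_weights(groups) if spec.weighting else None

    splitter = GroupShuffleSplit(
        n_splits=1, test_size=config.calibration_fraction, random_state=config.seed
    )
    fit_idx, cal_idx = next(splitter.split(X, y, groups))
    X_fit, X_cal = X.iloc[fit_idx], X.iloc[cal_idx]
    y_fit, y_cal = y[fit_idx], y[cal_idx]
    w_fit = weights[fit_idx] if weights is not None else None

    np_state = None
    if spec.subset == "full" and "helper|count|nstays" in X.columns:
        X_fit, schema_fit, np_state = add_nonpresent_features(X_fit, schema)
        X_cal, _, _ = add_nonpresent_features(X_cal, schema, state=np_state)
        schema = schema_fit

    columns = _model_columns(X_fit.columns, schema, spec.subset)
    mat_fit = X_fit[columns].to_numpy(dtype=float)
    mat_cal = X_cal[columns].to_numpy(dtype=float)
    mat_fit, impute_state = impute_most_frequent(mat_fit)
    mat_cal, _ = impute_most_frequent(mat_cal, impute_state)

    anscombe_mask = None
    if spec.anscombe:
        anscombe_mask = np.array(
            [schema[c].kind in ("count", "indicator") for c in columns]
        )
        mat_fit[:, anscombe_mask] = anscombe_transform(
            np.clip(mat_fit[:, anscombe_mask], 0.0, None)
        )
        mat_cal[:, anscombe_mask] = anscombe_transform(
            np.clip(mat_cal[:, anscombe_mask], 0.0, None)
        )

    scaled = None  # lazily computed shared scaling for LR-family candidates

    def scaled_pair():
        nonlocal scaled
        if scaled is None:
            sf, state = standard_scale(mat_fit)
            sc, _ = standard_scale(mat_cal, state)
            scaled = (sf, sc, state)
        return scaled

    candidates = []
    for i, name in enumerate(spec.candidates):
        seed_i = (config.seed * 1000003 + i * 101) % (2**31 - 1)
        selected_mask = None
        stability_freq = None
        if name in ("rlr1", "rhplr1"):
            sf, sc, state = scaled_pair()
            c1 = config.hp_value(f"{name}_C1")
            c2 = config.hp_value(f"{name}_C2")
            selected_mask, stability_freq = stability_select(
                sf,
                y_fit,
                groups[fit_idx],
                c1=c1,
                fraction=config.hp_value("stability_fraction"),
                resamples=int(config.hp_value("stability_resamples")),
                threshold=config.stability_threshold,
                seed=seed_i,
                c_reference_n=config.c_reference_n,
            )
            design_fit = sf[:, selected_mask]
            design_cal = sc[:, selected_mask]
            if design_fit.shape[1] == 0:
                design_fit = np.zeros((len(y_fit), 1))
                design_cal = np.zeros((len(y_cal), 1))
            est = LogisticRegression(
                C=c2,
                solver="lbfgs",
                class_weight="balanced",
                max_iter=2000,
            )
            est.fit(design_fit, y_fit, sample_weight=w_fit)
            scale_state = state
        elif name in ("lr1", "hplr1", "clr"):
            sf, sc, state = scaled_pair()
            est = fit_learner(sf, y_fit, w_fit, name, config, seed_i)
            design_cal = sc
            scale_state = state
        else:  # gbc: trees are scale-invariant, fit on unscaled data
            est = fit_learner(mat_fit, y_fit, w_fit, name, config, seed_i)
            design_cal = mat_cal
            scale_state = None
        cal_probs = est.predict_proba(design_cal)[:, 1]
        ll = log_loss(y_cal, cal_probs, labels=[0, 1])
        candidates.append(
            (ll, name, est, scale_state, selected_mask, stability_freq, design_cal)
        )

    ll, name, est, scale_state, selected_mask, stability_freq, design_cal = min(
        candidates, key=lambda c: c[0]
    )
    platt = platt_calibrate(est.decision_function(design_cal), y_cal)

    fingerprint = hashlib.sha1(
        ("|".join(map(str, X_fit.index)) + f"::{config.variant}").encode()
    ).hexdigest()[:16]
    return CalibratedModel(
        variant=config.variant,
        seed=config.seed,
        columns=columns,
        np_state=np_state,
        impute_state=impute_state,
        anscombe_mask=anscombe_mask,
        scale_state=scale_state,
        learner_name=name,
        learner=est,
        platt=platt,
        selected_mask=selected_mask,
        stability_freq=stability_freq,
        train_fingerprint=fingerprint,
        schema=dict(schema),
    )
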