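"""Synthetic EHR cohorts with the statistical structure the pipeline assumes.

Real inpatient EHR extracts of the kind this package analyzes cannot be
shared, so every stage is exercised against generated cohorts that emulate
the relevant structure: roughly a third of patients rehospitalized (heavy
right tail of stays per patient), low AKI prevalence among rehospitalization
samples (~6%), irregular and misaligned lab sampling, imperfect agreement
between code-based and creatinine-based AKI labels, and risk that rises
with age, prior AKI/CKD, and urea nitrogen and falls with albumin and
hemoglobin.

The generative model, per patient: a latent frailty ``z ~ N(0,1)`` drives
chronic-condition indicators (CKD, diabetes, heart failure) and standardized
lab latents (urea up, albumin and hemoglobin down with frailty).  Stays per
patient follow a truncated geometric on ``{1..cap}`` tuned so ``P(>=2)``
matches the rehospitalization target.  Each stay's true-AKI indicator is
Bernoulli with logit ``intercept + x . beta`` over the named attributes
(including a dynamic prior-AKI indicator); the intercept is calibrated by
bisection so the realized true prevalence among rehospitalization stays
matches the configured target.  True AKI manifests a KDIGO-triggering sCr
trajectory with probability ``scr_event_prob_given_aki`` and an ICD-9 584.x
code with probability ``code_sensitivity``; non-AKI stays receive a 584.x
code with probability ``1 - code_specificity``.  Lab observation times are
homogeneous Poisson within the stay, with the sCr/urea sampling rate
inflated during true-AKI stays (closer monitoring), and lognormal
multiplicative measurement noise around patient-level baselines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .ehr import RawEHR
from .phenotype import SCR_TEST_NAME

__all__ = [
    "ConfigurationError",
    "InfeasibleTrajectoryError",
    "LabSpec",
    "GeneratorConfig",
    "generate_cohort",
    "plant_aki_trajectory",
    "planted_risk",
    "planted_feature_signs",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration; the message names the field."""


class InfeasibleTrajectoryError(ValueError):
    """The requested sCr trajectory cannot exist in the given stay."""


@dataclass(frozen=True)
class LabSpec:
    """One panel entry: normal range, sampling rate and noise scale."""

    name: str
    low: float
    high: float
    rate_per_day: float
    noise_sd: float  # sd of log-multiplicative measurement noise
    center: float  # population-typical baseline


DEFAULT_LAB_PANEL: tuple[LabSpec, ...] = (
    LabSpec(SCR_TEST_NAME, 0.5, 1.2, 1.5, 0.08, 0.9),
    LabSpec("urea_nitrogen", 7.0, 20.0, 1.5, 0.15, 13.0),
    LabSpec("albumin", 3.5, 5.0, 0.8, 0.06, 4.2),
    LabSpec("hemoglobin", 12.0, 16.0, 1.2, 0.05, 13.5),
    LabSpec("potassium", 3.5, 5.1, 1.5, 0.05, 4.2),
    LabSpec("sodium", 135.0, 145.0, 1.5, 0.02, 140.0),
)

DEFAULT_MED_VOCABULARY: tuple[tuple[str, str, str], ...] = (
    ("Furosemide 40 MG tablet", "DIURETICS", "LOOP DIURETICS"),
    ("Spironolactone 25 MG tablet", "DIURETICS", "K-SPARING DIURETICS"),
    ("Lisinopril 10 MG tablet", "ANTIHYPERTENSIVES", "ACE INHIBITORS"),
    ("Metformin 500 MG tablet", "ANTIDIABETICS", "BIGUANIDES"),
    ("Insulin Glargine 100 UNITS/ML", "ANTIDIABETICS", "INSULINS"),
    ("Heparin Sodium 5,000 UNITS/ML", "ANTICOAGULANTS", "HEPARINS"),
    ("Vancomycin 1 G injection", "ANTIBIOTICS", "GLYCOPEPTIDES"),
    ("Ibuprofen 600 MG tablet", "ANALGESICS", "NSAIDS"),
    ("Omeprazole 20 MG capsule", "GI AGENTS", "PPIS"),
    ("Tacrolimus 1 MG capsule", "IMMUNOSUPPRESSANTS", "CALCINEURIN INHIBITORS"),
)

DEFAULT_CODE_VOCABULARY: Mapping[str, tuple[str, ...]] = {
    # background diagnoses (the AKI/CKD/diabetes/HF codes are handled
    # explicitly by the risk structure)
    "ICD9-DX": (
        "401.9", "272.4", "530.81", "311", "486", "599.0",
        "780.79", "414.01", "285.9", "276.51", "327.23", "496",
    ),
    "ICD9-PX": ("38.93", "96.71", "99.04", "39.95"),
    "CPT4": ("99213", "99232", "71020", "80053", "36415", "93000"),
    "DRG": ("470", "871", "291", "392", "690", "194"),
}

#: signed effects on the log-odds of true AKI, by attribute
DEFAULT_RISK_COEFFICIENTS: Mapping[str, float] = {
    "age_std": 0.5,
    "prior_aki": 1.0,
    "ckd": 0.9,
    "diabetes": 0.35,
    "heart_failure": 0.5,
    "urea_std": 0.7,
    "albumin_std": -0.5,
    "hemoglobin_std": -0.4,
}

_GENDERS = (("M", 0.48), ("F", 0.52))
_RACES = (("white", 0.75), ("black", 0.15), ("asian", 0.03), ("other", 0.07))
_MARITAL = (("married", 0.45), ("single", 0.35), ("widowed", 0.12), ("divorced", 0.08))
_INSURANCE = (("medicare", 0.4), ("commercial", 0.35), ("medicaid", 0.18), ("other", 0.07))
_LOCATIONS = ("ICU", "MED_SURG", "TELEMETRY", "OR", "L_AND_D")


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything the cohort generator needs; defaults are the study
    conditions the package is tested under."""

    n_patients: int = 1000
    rehosp_target_fraction: float = 0.32
    aki_prevalence_target: float = 0.062
    hosp_count_cap: int = 20
    lab_panel: tuple[LabSpec, ...] = DEFAULT_LAB_PANEL
    med_vocabulary: tuple[tuple[str, str, str], ...] = DEFAULT_MED_VOCABULARY
    code_vocabulary: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CODE_VOCABULARY)
    )
    risk_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RISK_COEFFICIENTS)
    )
    code_sensitivity: float = 0.65
    code_specificity: float = 0.995
    scr_event_prob_given_aki: float = 0.8
    aki_lab_rate_multiplier: float = 1.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        for name in (
            "rehosp_target_fraction",
            "aki_prevalence_target",
            "code_sensitivity",
            "code_specificity",
            "scr_event_prob_given_aki",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.hosp_count_cap < 1:
            raise ConfigurationError("hosp_count_cap must be >= 1")
        for lab in self.lab_panel:
            if lab.noise_sd <= 0:
                raise ConfigurationError(
                    f"lab_panel entry {lab.name!r} needs a positive noise_sd"
                )
        for k, v in self.risk_coefficients.items():
            if not math.isfinite(v):
                raise ConfigurationError(f"risk_coefficients[{k!r}] must be finite")

    def hosp_count_pmf(self) -> np.ndarray:
        """Truncated geometric pmf over {1..cap} with ``P(>=2)`` matched to
        the rehospitalization target."""
        cap = self.hosp_count_cap
        target_p1 = 1.0 - self.rehosp_target_fraction
        if cap == 1 or target_p1 >= 1.0:
            pmf = np.zeros(cap)
            pmf[0] = 1.0
            return pmf

        def p1(p: float) -> float:
            return p / (1.0 - (1.0 - p) ** cap)

        p = brentq(lambda q: p1(q) - target_p1, 1e-9, 1.0 - 1e-12)
        k = np.arange(1, cap + 1)
        pmf = p * (1.0 - p) ** (k - 1)
        return pmf / pmf.sum()


def planted_risk(
    attributes: Mapping[str, float],
    coefficients: Mapping[str, float],
    intercept: float = 0.0,
) -> float:
    """Ground-truth probability: logistic transform of intercept + x . beta."""
    eta = intercept
    for name, beta in coefficients.items():
        if name not in attributes:
            raise KeyError(f"missing attribute {name!r}")
        eta += beta * attributes[name]
    return float(expit(eta))


def planted_feature_signs() -> dict[str, int]:
    """Expected coefficient signs of extracted features under the default
    planted risk model (used by sign-recovery checks)."""
    return {
        "max|value|age": +1,
        "sum|count|dx:584": +1,
        "sum|count|dx:585": +1,
        "sum|count|dx:250": +1,
        "sum|count|dx:428": +1,
        "mean|mean|urea_nitrogen": +1,
        "mean|mean|albumin": -1,
        "mean|mean|hemoglobin": -1,
    }


# ---------------------------------------------------------------------------
# planted sCr trajectories

_RATIO = 1.5
_ABS = 0.3


def plant_aki_trajectory(
    baseline_scr: float,
    mode: str,
    stay_duration: float,
    seed: int | np.random.Generator = 0,
) -> list[tuple[float, float]]:
    """A timestamped sCr series inside a stay triggering exactly one pattern.

    ``mode``:

    * ``"both"`` — a jump within 48 h satisfying both the 1.5x and the
      0.3 mg/dL rules;
    * ``"absolute"`` — a >=0.3 mg/dL rise within 48 h whose ratio stays
      below 1.5 over 7 days (needs ``baseline_scr`` comfortably above 0.6);
    * ``"ratio"`` — a >=1.5x rise within 168 h built from steps each below
      0.3 mg/dL per 48 h (needs enough stay time for the step spacing);
    * ``"none"`` — fluctuations below both thresholds.

    Times are hours from admission, strictly inside ``[0, stay_duration]``.
    Raises :class:`InfeasibleTrajectoryError` when the geometry is
    impossible (e.g. mode="ratio" in too short a stay).
    """
    b = float(baseline_scr)
    if b <= 0:
        raise ValueError("baseline_scr must be positive")
    if stay_duration <= 0:
        raise ValueError("stay_duration must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    def jitter(lo: float, hi: float) -> float:
        return float(rng.uniform(lo, hi))

    if mode == "both":
        if stay_duration < 3.0:
            raise InfeasibleTrajectoryError("stay too short for a 48 h jump")
        t0 = jitter(0.25, min(6.0, stay_duration / 4))
        t1 = t0 + jitter(2.0, min(46.0, stay_duration - t0 - 0.5))
        peak = max(_RATIO * b, b + _ABS) * (1.0 + jitter(0.02, 0.10))
        pts = [(t0, b), (t1, peak)]
        if t1 + 6.0 < stay_duration:
            pts.append((t1 + jitter(4.0, 6.0), peak * jitter(0.85, 0.95)))
        return pts

    if mode == "absolute":
        if b <= 0.8:
            raise InfeasibleTrajectoryError(
                "absolute-only pattern needs baseline > 0.8 mg/dL "
                "(0.3 rise would also be a 1.5x rise)"
            )
        if stay_duration < 3.0:
            raise InfeasibleTrajectoryError("stay too short for a 48 h jump")
        t0 = jitter(0.25, min(6.0, stay_duration / 4))
        t1 = t0 + jitter(2.0, min(46.0, stay_duration - t0 - 0.5))
        rise = jitter(_ABS + 0.02, min(0.42, 0.49 * b))  # keep ratio < 1.5
        return [(t0, b), (t1, b + rise)]

    if mode == "ratio":
        total_rise = (_RATIO + 0.02) * b - b  # overshoot the threshold a bit
        if total_rise < _ABS - 0.02:
            # a single sub-0.3 jump reaches 1.5x (small baselines)
            if stay_duration < 3.0:
                raise InfeasibleTrajectoryError("stay too short")
            t0 = jitter(0.25, min(6.0, stay_duration / 4))
            t1 = t0 + jitter(2.0, min(40.0, stay_duration - t0 - 0.5))
            return [(t0, b), (t1, b + total_rise)]
        spacing = 48.5  # keeps any 48 h window to a single step
        k = math.ceil(total_rise / 0.28)
        span = k * spacing
        if span > 168.0 - 1.0:
            raise InfeasibleTrajectoryError(
                "ratio-only pattern impossible: required sub-0.3 steps do not "
                "fit a 7-day window for this baseline"
            )
        if span + 1.0 > stay_duration:
            raise InfeasibleTrajectoryError(
                f"ratio-only pattern needs a stay of at least {span + 1.0:.0f} h"
            )
        step = total_rise / k
        return [(0.5 + i * spacing, b + i * step) for i in range(k + 1)]

    if mode == "none":
        m = int(rng.integers(3, 7))
        amp = 0.25 * min(_ABS, 0.5 * b)
        times = np.sort(rng.uniform(0.25, stay_duration - 0.25, size=m))
        vals = b + rng.uniform(-amp, amp, size=m)
        return [(float(t), float(v)) for t, v in zip(times, vals)]

    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# cohort generation

def _draw_cat(rng, pairs):
    names = [n for n, _ in pairs]
    probs = np.array([p for _, p in pairs])
    return names[rng.choice(len(names), p=probs / probs.sum())]


def generate_cohort(config: GeneratorConfig) -> RawEHR:
    """Generate a full synthetic cohort; reproducible for a fixed seed.

    Returns a :class:`RawEHR` with the ``truth`` table populated
    (per-stay true AKI indicator and true risk).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    beta = dict(config.risk_coefficients)
    labs_by_name = {lab.name: lab for lab in config.lab_panel}
    pmf = config.hosp_count_pmf()

    # ---- phase 1: patients, stays, attributes (everything but prior AKI)
    patients = []
    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        z = rng.normal()
        age0 = float(np.clip(rng.normal(62.0, 18.0), 18.0, 100.0))
        ckd = rng.random() < expit(-2.2 + 1.2 * z)
        diabetes = rng.random() < expit(-1.6 + 0.6 * z)
        heart_failure = rng.random() < expit(-2.2 + 0.8 * z)
        lab_latents = {
            "urea_std": 0.6 * z + 0.8 * rng.normal(),
            "albumin_std": -0.5 * z + 0.87 * rng.normal(),
            "hemoglobin_std": -0.4 * z + 0.92 * rng.normal(),
            "scr_std": 0.5 * z + 0.87 * rng.normal(),
        }
        n_hosp = int(rng.choice(len(pmf), p=pmf)) + 1
        first_admit = rng.uniform(0.0, 17000.0)
        stays = []
        t = first_admit
        for j in range(n_hosp):
            los = float(np.clip(np.exp(rng.normal(np.log(84.0), 0.6)), 8.0, 720.0))
            age = age0 + t / 8766.0
            stays.append({"admit_time": t, "los": los, "age": age})
            t = t + los + rng.exponential(1440.0)
        patients.append(
            {
                "pid": pid,
                "z": z,
                "gender": _draw_cat(rng, _GENDERS),
                "race": _draw_cat(rng, _RACES),
                "marital": _draw_cat(rng, _MARITAL),
                "insurance": _draw_cat(rng, _INSURANCE),
                "ckd": ckd,
                "diabetes": diabetes,
                "heart_failure": heart_failure,
                "lab_latents": lab_latents,
                "stays": stays,
                # pre-drawn uniforms make the intercept calibration and the
                # final realization use identical randomness
                "aki_u": rng.random(n_hosp),
            }
        )

    # base linear predictor per stay (prior-AKI term added dynamically)
    for p in patients:
        base = (
            beta.get("ckd", 0.0) * p["ckd"]
            + beta.get("diabetes", 0.0) * p["diabetes"]
            + beta.get("heart_failure", 0.0) * p["heart_failure"]
            + beta.get("urea_std", 0.0) * p["lab_latents"]["urea_std"]
            + beta.get("albumin_std", 0.0) * p["lab_latents"]["albumin_std"]
            + beta.get("hemoglobin_std", 0.0) * p["lab_latents"]["hemoglobin_std"]
        )
        p["eta0"] = [
            base + beta.get("age_std", 0.0) * (s["age"] - 60.0) / 15.0
            for s in p["stays"]
        ]

    b_prior = beta.get("prior_aki", 0.0)

    def realize(intercept: float):
        outcomes = []
        n_rehosp = 0
        n_aki_rehosp = 0
        for p in patients:
            prior = 0.0
            outs = []
            for j, eta0 in enumerate(p["eta0"]):
                prob = expit(intercept + eta0 + b_prior * prior)
                aki = p["aki_u"][j] < prob
                outs.append((bool(aki), float(prob)))
                if j >= 1:
                    n_rehosp += 1
                    n_aki_rehosp += int(aki)
                if aki:
                    prior = 1.0
            outcomes.append(outs)
        prev = n_aki_rehosp / n_rehosp if n_rehosp else 0.0
        return outcomes, prev

    # bisection on the realized rehospitalization-sample prevalence; the
    # realized count is monotone in the intercept for fixed uniforms
    lo, hi = -12.0, 6.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        _, prev = realize(mid)
        if prev < config.aki_prevalence_target:
            lo = mid
        else:
            hi = mid
    intercept = 0.5 * (lo + hi)
    outcomes, _ = realize(intercept)

    # ---- phase 2: materialize tables
    adm_rows, lab_rows, med_rows, code_rows, truth_rows = [], [], [], [], []
    med_vocab = list(config.med_vocabulary)
    dx_vocab = list(config.code_vocabulary.get("ICD9-DX", ()))
    px_vocab = list(config.code_vocabulary.get("ICD9-PX", ()))
    cpt_vocab = list(config.code_vocabulary.get("CPT4", ()))
    drg_vocab = list(config.code_vocabulary.get("DRG", ()))

    for p, outs in zip(patients, outcomes):
        lat = p["lab_latents"]
        baselines = {}
        for lab in config.lab_panel:
            scale = {
                "urea_nitrogen": ("urea_std", 0.35),
                "albumin": ("albumin_std", 0.08),
                "hemoglobin": ("hemoglobin_std", 0.10),
                SCR_TEST_NAME: ("scr_std", 0.22),
            }.get(lab.name)
            if scale is None:
                baselines[lab.name] = lab.center * math.exp(0.05 * rng.normal())
            else:
                baselines[lab.name] = lab.center * math.exp(scale[1] * lat[scale[0]])
        if p["ckd"]:
            baselines[SCR_TEST_NAME] *= 1.3

        med_weights = np.ones(len(med_vocab))
        for i, (_, cls, _sub) in enumerate(med_vocab):
            if cls == "DIURETICS" and (p["heart_failure"] or p["ckd"]):
                med_weights[i] *= 3.0
            if cls == "ANTIDIABETICS":
                med_weights[i] *= 3.0 if p["diabetes"] else 0.1
        med_weights /= med_weights.sum()

        for j, s in enumerate(p["stays"]):
            admit_id = f"{p['pid']}A{j:02d}"
            aki, risk = outs[j]
            t0, t1 = s["admit_time"], s["admit_time"] + s["los"]

            locations = ["ED"] if rng.random() < 0.7 else []
            n_extra = int(rng.integers(0, 3))
            extra_p = np.array([0.25 if aki else 0.08, 0.45, 0.2, 0.1, 0.02])
            for _ in range(n_extra):
                locations.append(
                    _LOCATIONS[rng.choice(len(_LOCATIONS), p=extra_p / extra_p.sum())]
                )
            dispo_p = np.array(
                [0.7, 0.12, 0.12 + 0.1 * (s["age"] > 75), 0.03, 0.03]
            )
            disposition = ("home", "home_health", "snf", "hospice", "expired")[
                rng.choice(5, p=dispo_p / dispo_p.sum())
            ]
            adm_rows.append(
                (
                    p["pid"], admit_id, t0, t1, s["age"], p["gender"], p["race"],
                    p["marital"], p["insurance"], disposition, "|".join(locations),
                )
            )
            truth_rows.append((admit_id, int(aki), risk))

            # labs
            scr_event = aki and rng.random() < config.scr_event_prob_given_aki
            for lab in config.lab_panel:
                rate = lab.rate_per_day
                if aki and lab.name in (SCR_TEST_NAME, "urea_nitrogen"):
                    rate *= config.aki_lab_rate_multiplier
                n_obs = rng.poisson(rate * s["los"] / 24.0)
                if lab.name == SCR_TEST_NAME and scr_event:
                    mode = ("both", "absolute", "ratio")[
                        rng.choice(3, p=(0.6, 0.25, 0.15))
                    ]
                    try:
                        traj = plant_aki_trajectory(
                            baselines[lab.name], mode, s["los"], rng
                        )
                    except InfeasibleTrajectoryError:
                        traj = plant_aki_trajectory(
                            baselines[lab.name], "both", max(s["los"], 4.0), rng
                        )
                    for dt, v in traj:
                        lab_rows.append((admit_id, lab.name, t0 + min(dt, s["los"] - 0.1), v))
                    continue
                if n_obs == 0:
                    continue
                times = np.sort(rng.uniform(t0, t1, size=n_obs))
                if lab.name == SCR_TEST_NAME:
                    # creatinine is strongly autocorrelated within a stay:
                    # stay-level shift plus small measurement jitter, so
                    # noise alone rarely fakes a KDIGO delta
                    stay_level = baselines[lab.name] * math.exp(
                        rng.normal(0.0, lab.noise_sd)
                    )
                    vals = stay_level * np.exp(rng.normal(0.0, 0.03, size=n_obs))
                else:
                    vals = baselines[lab.name] * np.exp(
                        rng.normal(0.0, lab.noise_sd, size=n_obs)
                    )
                for t, v in zip(times, vals):
                    lab_rows.append((admit_id, lab.name, float(t), float(v)))

            # medications
            n_meds = rng.poisson(3.0)
            for _ in range(n_meds):
                desc, cls, sub = med_vocab[rng.choice(len(med_vocab), p=med_weights)]
                med_rows.append(
                    (admit_id, float(rng.uniform(t0, t1)), desc, cls, sub)
                )

            # codes
            if aki:
                if rng.random() < config.code_sensitivity:
                    code_rows.append(
                        (admit_id, "ICD9-DX",
                         ("584.9", "584.5", "584.8")[rng.choice(3, p=(0.8, 0.12, 0.08))])
                    )
            elif rng.random() < 1.0 - config.code_specificity:
                code_rows.append((admit_id, "ICD9-DX", "584.9"))
            if p["ckd"]:
                u = rng.random()
                if u < 0.45:
                    code_rows.append((admit_id, "ICD9-DX", "585.3"))
                elif u < 0.55:
                    code_rows.append((admit_id, "ICD9-DX", "585.4"))
                elif u < 0.57:
                    code_rows.append((admit_id, "ICD9-DX", "585.9"))
            if p["diabetes"] and rng.random() < 0.6:
                code_rows.append((admit_id, "ICD9-DX", "250.00"))
            if p["heart_failure"] and rng.random() < 0.55:
                code_rows.append((admit_id, "ICD9-DX", "428.0"))
            for _ in range(rng.poisson(2.5)):
                code_rows.append(
                    (admit_id, "ICD9-DX", dx_vocab[rng.choice(len(dx_vocab))])
                )
            for _ in range(rng.poisson(0.7)):
                code_rows.append(
                    (admit_id, "ICD9-PX", px_vocab[rng.choice(len(px_vocab))])
                )
            for _ in range(rng.poisson(1.5)):
                code_rows.append(
                    (admit_id, "CPT4", cpt_vocab[rng.choice(len(cpt_vocab))])
                )
            code_rows.append((admit_id, "DRG", drg_vocab[rng.choice(len(drg_vocab))]))

    admissions = pd.DataFrame(
        adm_rows,
        columns=[
            "patient_id", "admit_id", "admit_time", "discharge_time",
            "age_at_admit", "gender", "race", "marital_status", "insurance",
            "discharge_disposition", "locations",
        ],
    )
    labs = pd.DataFrame(
        lab_rows, columns=["admit_id", "test_name", "time", "value"]
    )
    flag = pd.Series("none", index=labs.index, dtype=object)
    if len(labs):
        lows = labs["test_name"].map({l.name: l.low for l in config.lab_panel})
        highs = labs["test_name"].map({l.name: l.high for l in config.lab_panel})
        flag[labs["value"] < lows] = "low"
        flag[labs["value"] > highs] = "high"
    labs["abnormal_flag"] = flag
    medications = pd.DataFrame(
        med_rows,
        columns=["admit_id", "time", "description", "pharm_class", "pharm_subclass"],
    )
    codes = pd.DataFrame(code_rows, columns=["admit_id", "system", "code"])
    truth = pd.DataFrame(truth_rows, columns=["admit_id", "true_aki", "true_risk"])
    ehr = RawEHR(
        admissions=admissions,
        labs=labs,
        medications=medications,
        codes=codes,
        truth=truth,
    )
    ehr.validate()
    return ehr
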