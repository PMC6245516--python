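"""AKI phenotyping and cohort construction.

A hospitalization is labeled for acute kidney injury (AKI) two ways and the
results are OR-ed:

* **by code** — any ICD-9 diagnosis code in 584.5-584.9 (acute kidney
  failure) assigned during the stay;
* **by lab** — the KDIGO serum-creatinine (sCr) deltas within a single stay:
  a >=1.5-fold rise from baseline within 7 days (168 h), or a >=0.3 mg/dL
  rise within 48 h, where the baseline for each measurement is the *minimum*
  earlier in-stay value inside the criterion's window (a sliding baseline;
  the first documented inpatient sCr is automatically the baseline for early
  measurements).

Cohort selection removes stays with age at admission < 18 years and every
stay that follows an ESRD-coded (585.9) stay of the same patient, unless a
renal-transplant procedure intervenes.  Each patient with ``n`` surviving
hospitalizations then contributes ``n - 1`` training samples: one per
rehospitalization, predicted from all strictly earlier stays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AKI_DX_CODES",
    "ESRD_CODE",
    "RENAL_TRANSPLANT_PX_CODES",
    "SCR_TEST_NAME",
    "RATIO_THRESHOLD",
    "RATIO_WINDOW_HOURS",
    "ABSOLUTE_THRESHOLD_MGDL",
    "ABSOLUTE_WINDOW_HOURS",
    "DataError",
    "AKILabel",
    "Hospitalization",
    "CohortSample",
    "detect_aki_by_code",
    "detect_aki_by_scr",
    "label_hospitalization",
    "select_cohort",
    "build_samples",
    "cohort_samples",
]

#: ICD-9 diagnosis codes counting as AKI (acute kidney failure, 584.x).
AKI_DX_CODES = frozenset({"584.5", "584.6", "584.7", "584.8", "584.9"})

#: ICD-9 diagnosis code for end-stage renal disease.
ESRD_CODE = "585.9"

#: ICD-9 procedure codes recognized as renal transplant (configurable).
RENAL_TRANSPLANT_PX_CODES = frozenset({"55.69"})

#: Lab test name carrying serum creatinine in this package's tables.
SCR_TEST_NAME = "serum_creatinine"

RATIO_THRESHOLD = 1.5
RATIO_WINDOW_HOURS = 168.0
ABSOLUTE_THRESHOLD_MGDL = 0.3
ABSOLUTE_WINDOW_HOURS = 48.0


class DataError(ValueError):
    """Raised for malformed clinical input (non-positive sCr, unsorted times)."""


@dataclass(frozen=True)
class AKILabel:
    """Per-hospitalization AKI label.

    ``combined`` is ``by_code OR by_lab``.  ``lab_trigger_time`` is the time
    (hours) of the earliest measurement satisfying a KDIGO delta, present iff
    ``by_lab``; ``criterion`` records which rule(s) fired at that trigger:
    ``"ratio"``, ``"absolute"`` or ``"both"``.
    """

    by_code: bool
    by_lab: bool
    combined: bool
    lab_trigger_time: float | None = None
    criterion: str | None = None

    def __post_init__(self) -> None:
        if self.combined != (self.by_code or self.by_lab):
            raise ValueError("combined must equal by_code OR by_lab")
        if self.by_lab != (self.lab_trigger_time is not None):
            raise ValueError("lab_trigger_time present iff by_lab")


@dataclass
class Hospitalization:
    """One hospital stay with its clinical content.

    Times are continuous hours from a global epoch.  ``labs`` rows are
    ``(test_name, time, value, abnormal_flag)`` with ``abnormal_flag`` in
    ``{"low", "high", "none"}``; ``medications`` rows are ``(time,
    description, pharm_class, pharm_subclass)``; ``codes`` is a list of
    ``(system, code)`` pairs with system in ``{"ICD9-DX", "ICD9-PX",
    "CPT4", "DRG"}``.
    """

    patient_id: str
    admit_id: str
    admit_time: float
    discharge_time: float
    age_at_admit: float
    gender: str = ""
    race: str = ""
    marital_status: str = ""
    insurance: str = ""
    discharge_disposition: str = ""
    locations: list[str] = field(default_factory=list)
    labs: pd.DataFrame | None = None
    medications: pd.DataFrame | None = None
    codes: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.admit_time < self.discharge_time:
            raise ValueError(
                f"admit_time must precede discharge_time for {self.admit_id!r}"
            )
        if self.age_at_admit < 0:
            raise ValueError(f"negative age_at_admit for {self.admit_id!r}")

    @property
    def length_of_stay_days(self) -> float:
        return (self.discharge_time - self.admit_time) / 24.0

    def codes_for(self, system: str) -> list[str]:
        return [c for s, c in self.codes if s == system]

    @property
    def scr_series(self) -> list[tuple[float, float]]:
        """Time-ordered (time, value) serum-creatinine measurements."""
        if self.labs is None or len(self.labs) == 0:
            return []
        rows = self.labs[self.labs["test_name"] == SCR_TEST_NAME]
        rows = rows.sort_values("time", kind="stable")
        return list(zip(rows["time"].tolist(), rows["value"].tolist()))


@dataclass(frozen=True)
class CohortSample:
    """One training sample: a target rehospitalization plus its history.

    ``utilization`` is the number of hospitalizations the patient contributes
    to the cohort (used by the error-by-utilization analysis).
    """

    patient_id: str
    target_admit_id: str
    prior_admit_ids: tuple[str, ...]
    label: int
    utilization: int

    def __post_init__(self) -> None:
        if len(self.prior_admit_ids) < 1:
            raise ValueError("a sample needs at least one prior hospitalization")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


def detect_aki_by_code(codes: Iterable[str]) -> bool:
    """True iff any ICD-9 diagnosis code is an acute-kidney-failure code."""
    return any(c in AKI_DX_CODES for c in codes)


def detect_aki_by_scr(
    scr_series: Sequence[tuple[float, float]],
) -> tuple[bool, float | None, str | None]:
    """Apply the KDIGO creatinine deltas with a sliding in-window baseline.

    For each measurement ``(t, v)`` the baselines are the minima of strictly
    earlier in-stay values within 168 h (ratio rule) and within 48 h
    (absolute rule).  Fires iff ``v/b >= 1.5`` (168 h window) or
    ``v - b >= 0.3`` mg/dL (48 h window), thresholds and windows inclusive.

    Returns ``(detected, trigger_time, criterion)`` where ``trigger_time``
    is the earliest firing measurement's time and ``criterion`` in
    ``{"ratio", "absolute", "both"}`` records which rule(s) fired there.
    Series of length <= 1 cannot fire.
    """
    n = len(scr_series)
    for t, v in scr_series:
        if not (v > 0) or not math.isfinite(v):
            raise DataError(f"non-positive or non-finite sCr value {v!r}")
    for i in range(1, n):
        if scr_series[i][0] < scr_series[i - 1][0]:
            raise DataError("sCr series times must be non-decreasing")

    for i in range(1, n):
        t, v = scr_series[i]
        ratio_fired = False
        abs_fired = False
        for j in range(i):
            u, b = scr_series[j]
            dt = t - u
            if dt <= RATIO_WINDOW_HOURS and v / b >= RATIO_THRESHOLD:
                ratio_fired = True
            if dt <= ABSOLUTE_WINDOW_HOURS and v - b >= ABSOLUTE_THRESHOLD_MGDL:
                abs_fired = True
        if ratio_fired or abs_fired:
            criterion = "both" if (ratio_fired and abs_fired) else (
                "ratio" if ratio_fired else "absolute"
            )
            return True, t, criterion
    return False, None, None


def label_hospitalization(h: Hospitalization) -> AKILabel:
    """Label one stay by code, by lab, and combined (OR)."""
    by_code = detect_aki_by_code(h.codes_for("ICD9-DX"))
    by_lab, trigger, criterion = detect_aki_by_scr(h.scr_series)
    return AKILabel(
        by_code=by_code,
        by_lab=by_lab,
        combined=by_code or by_lab,
        lab_trigger_time=trigger,
        criterion=criterion,
    )


def _hospitalization_sort_key(h: Hospitalization) -> tuple:
    return (h.admit_time, h.discharge_time, h.admit_id)


def select_cohort(
    ehr,
    transplant_px_codes: frozenset[str] = RENAL_TRANSPLANT_PX_CODES,
    min_age: float = 18.0,
) -> tuple[list[Hospitalization], list[tuple[str, str]]]:
    """Apply the cohort inclusion rules to a raw EHR extract.

    Excludes (a) stays with age at admission below ``min_age`` and (b) stays
    preceded, for the same patient, by an ESRD-coded (585.9) stay with no
    renal-transplant procedure between that stay and the one under
    consideration.  ESRD history is evaluated over the patient's full raw
    admission history.  Returns the surviving stays ordered per patient by
    admission time (ties broken by discharge time then admit id) and an
    exclusion log of ``(admit_id, reason)``.
    """
    hosps = ehr.to_hospitalizations()
    by_patient: dict[str, list[Hospitalization]] = {}
    for h in hosps:
        by_patient.setdefault(h.patient_id, []).append(h)

    survivors: list[Hospitalization] = []
    log: list[tuple[str, str]] = []
    for pid in by_patient:
        stays = sorted(by_patient[pid], key=_hospitalization_sort_key)
        esrd_time: float | None = None  # admit time of earliest un-cleared ESRD stay
        for h in stays:
            excluded_for_esrd = esrd_time is not None

            if h.age_at_admit < min_age:
                log.append((h.admit_id, "age_under_18"))
            elif excluded_for_esrd:
                log.append((h.admit_id, "prior_esrd"))
            else:
                survivors.append(h)

            # Update history *after* judging this stay: only strictly earlier
            # ESRD codes exclude.  A transplant at or after the ESRD-coded
            # stay (including in the same stay) clears the exclusion for
            # later hospitalizations.
            if ESRD_CODE in h.codes_for("ICD9-DX") and esrd_time is None:
                esrd_time = h.admit_time
            if esrd_time is not None and any(
                c in transplant_px_codes for c in h.codes_for("ICD9-PX")
            ):
                esrd_time = None
    survivors.sort(key=lambda h: (h.patient_id, *_hospitalization_sort_key(h)))
    return survivors, log


def build_samples(
    patient_hospitalizations: Sequence[Hospitalization],
    labels: Mapping[str, AKILabel] | None = None,
) -> list[CohortSample]:
    """Emit the ``n - 1`` training samples for one patient's ordered stays.

    For each stay after the first, the target is that stay and the predictors
    are all strictly earlier stays; the label is the target's combined AKI
    label.  ``labels`` may carry precomputed :class:`AKILabel` by admit id;
    otherwise labels are computed here.
    """
    hs = list(patient_hospitalizations)
    for a, b in zip(hs, hs[1:]):
        if a.patient_id != b.patient_id:
            raise ValueError("build_samples expects a single patient's stays")
        if _hospitalization_sort_key(a) > _hospitalization_sort_key(b):
            raise ValueError("hospitalizations must be ordered by admit time")
    n = len(hs)
    out: list[CohortSample] = []
    for j in range(1, n):
        target = hs[j]
        lab = (
            labels[target.admit_id]
            if labels is not None
            else label_hospitalization(target)
        )
        out.append(
            CohortSample(
                patient_id=target.patient_id,
                target_admit_id=target.admit_id,
                prior_admit_ids=tuple(h.admit_id for h in hs[:j]),
                label=int(lab.combined),
                utilization=n,
            )
        )
    return out


def cohort_samples(
    ehr,
    transplant_px_codes: frozenset[str] = RENAL_TRANSPLANT_PX_CODES,
) -> tuple[list[CohortSample], dict[str, Hospitalization], list[tuple[str, str]]]:
    """Full path raw EHR -> cohort samples.

    Returns ``(samples, hospitalizations-by-admit-id, exclusion log)``.
    """
    survivors, log = select_cohort(ehr, transplant_px_codes=transplant_px_codes)
    hosp_by_id = {h.admit_id: h for h in survivors}
    by_patient: dict[str, list[Hospitalization]] = {}
    for h in survivors:
        by_patient.setdefault(h.patient_id, []).append(h)
    samples: list[CohortSample] = []
    for pid in by_patient:
        samples.extend(build_samples(by_patient[pid]))
    return samples, hosp_by_id, log
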