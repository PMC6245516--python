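"""The raw EHR container: four linked tables plus optional ground truth.

``admissions`` is keyed by ``(patient_id, admit_id)``; ``labs``,
``medications`` and ``codes`` join to it on ``admit_id``.  All timestamps
are continuous hours from a global epoch (2010-01-01T00:00Z when rendered
as calendar time), which avoids calendar edge cases; day-of-week style
fields can be derived modulo 168 h.

CSV schema (UTF-8, header row):

* ``admissions.csv`` — patient_id, admit_id, admit_time, discharge_time,
  age_at_admit, gender, race, marital_status, insurance,
  discharge_disposition, locations (``|``-separated)
* ``labs.csv`` — admit_id, test_name, time, value, abnormal_flag
  (low/high/none)
* ``medications.csv`` — admit_id, time, description, pharm_class,
  pharm_subclass
* ``codes.csv`` — admit_id, system (ICD9-DX/ICD9-PX/CPT4/DRG), code
* ``truth.csv`` (synthetic cohorts only) — admit_id, true_aki, true_risk

Timestamps are written either as raw epoch hours or ISO-8601, selectable
when writing; reading detects which was used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .phenotype import Hospitalization

__all__ = ["RawEHR", "EPOCH", "write_ehr_csv", "read_ehr_csv"]

#: calendar anchor for hour-zero when rendering ISO timestamps
EPOCH = pd.Timestamp("2010-01-01T00:00:00")

_TIME_COLS = {
    "admissions": ["admit_time", "discharge_time"],
    "labs": ["time"],
    "medications": ["time"],
}


@dataclass
class RawEHR:
    """Four linked EHR tables plus (for synthetic cohorts) ground truth."""

    admissions: pd.DataFrame
    labs: pd.DataFrame
    medications: pd.DataFrame
    codes: pd.DataFrame
    truth: pd.DataFrame | None = None

    def validate(self) -> None:
        """Check referential integrity and elementary invariants."""
        adm = self.admissions
        ids = set(adm["admit_id"])
        if len(ids) != len(adm):
            raise ValueError("duplicate admit_id in admissions")
        for name, table in (
            ("labs", self.labs),
            ("medications", self.medications),
            ("codes", self.codes),
        ):
            if len(table) and not set(table["admit_id"]).issubset(ids):
                raise ValueError(f"{name} rows with admit_id not in admissions")
        if not (adm["admit_time"] < adm["discharge_time"]).all():
            raise ValueError("admit_time must precede discharge_time")
        if (adm["age_at_admit"] < 0).any():
            raise ValueError("negative age_at_admit")
        if len(self.labs):
            joined = self.labs.merge(
                adm[["admit_id", "admit_time", "discharge_time"]], on="admit_id"
            )
            inside = (joined["time"] >= joined["admit_time"]) & (
                joined["time"] <= joined["discharge_time"]
            )
            if not inside.all():
                raise ValueError("lab times outside their stay")

    def to_hospitalizations(self) -> list[Hospitalization]:
        """Materialize one :class:`Hospitalization` per admissions row."""
        labs_by = dict(tuple(self.labs.groupby("admit_id"))) if len(self.labs) else {}
        meds_by = (
            dict(tuple(self.medications.groupby("admit_id")))
            if len(self.medications)
            else {}
        )
        codes_by: dict[str, list[tuple[str, str]]] = {}
        for admit_id, system, code in zip(
            self.codes["admit_id"], self.codes["system"], self.codes["code"]
        ):
            codes_by.setdefault(admit_id, []).append((system, code))

        out = []
        for row in self.admissions.itertuples(index=False):
            locations = (
                [x for x in str(row.locations).split("|") if x]
                if isinstance(row.locations, str) and row.locations
                else []
            )
            out.append(
                Hospitalization(
                    patient_id=row.patient_id,
                    admit_id=row.admit_id,
                    admit_time=float(row.admit_time),
                    discharge_time=float(row.discharge_time),
                    age_at_admit=float(row.age_at_admit),
                    gender=row.gender,
                    race=row.race,
                    marital_status=row.marital_status,
                    insurance=row.insurance,
                    discharge_disposition=row.discharge_disposition,
                    locations=locations,
                    labs=labs_by.get(row.admit_id),
                    medications=meds_by.get(row.admit_id),
                    codes=codes_by.get(row.admit_id, []),
                )
            )
        return out


def _hours_to_iso(series: pd.Series) -> pd.Series:
    return (EPOCH + pd.to_timedelta(series, unit="h")).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )


def _to_hours(series: pd.Series) -> pd.Series:
    if series.dtype == object:
        return (
            (pd.to_datetime(series) - EPOCH).dt.total_seconds() / 3600.0
        ).astype(float)
    return series.astype(float)


def write_ehr_csv(ehr: RawEHR, out_dir: str | Path, timestamps: str = "hours") -> None:
    """Write the cohort as CSV files under ``out_dir``.

    ``timestamps`` is ``"hours"`` (epoch hours, lossless) or ``"iso"``
    (ISO-8601, second resolution).
    """
    if timestamps not in ("hours", "iso"):
        raise ValueError("timestamps must be 'hours' or 'iso'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "admissions": ehr.admissions,
        "labs": ehr.labs,
        "medications": ehr.medications,
        "codes": ehr.codes,
    }
    for name, table in tables.items():
        df = table.copy()
        if timestamps == "iso":
            for col in _TIME_COLS.get(name, []):
                df[col] = _hours_to_iso(df[col])
        df.to_csv(out / f"{name}.csv", index=False)
    if ehr.truth is not None:
        ehr.truth.to_csv(out / "truth.csv", index=False)


def read_ehr_csv(in_dir: str | Path) -> RawEHR:
    """Read a cohort written by :func:`write_ehr_csv` (either timestamp style)."""
    d = Path(in_dir)
    admissions = pd.read_csv(d / "admissions.csv", keep_default_na=False)
    labs = pd.read_csv(d / "labs.csv", keep_default_na=False)
    medications = pd.read_csv(d / "medications.csv", keep_default_na=False)
    codes = pd.read_csv(d / "codes.csv", dtype={"code": str}, keep_default_na=False)
    for name, df in (
        ("admissions", admissions),
        ("labs", labs),
        ("medications", medications),
    ):
        for col in _TIME_COLS[name]:
            df[col] = _to_hours(df[col])
    labs["value"] = labs["value"].astype(float)
    admissions["age_at_admit"] = admissions["age_at_admit"].astype(float)
    truth_path = d / "truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else None
    return RawEHR(
        admissions=admissions,
        labs=labs,
        medications=medications,
        codes=codes,
        truth=truth,
    )
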