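"""Longitudinal feature compression for prior-hospitalization histories.

Each hospitalization is viewed as a bundle of irregular, misaligned time
series.  The compression has three stages:

1. ``s`` — convert each raw input (a lab, a medication, a code) into an
   ordered sequence of observations within the stay;
2. ``F`` — summarize each within-stay sequence: min/max/mean/var/sum for
   continuous inputs, sum (a count) for categorical inputs;
3. ``G`` — aggregate the per-stay summaries across a patient's prior
   hospitalizations with per-category rules: labs and abnormal-flag counts
   get min/mean/max/sum/var; medications, codes, dispositions, locations,
   length of stay and non-present counts are summed; age takes the max;
   race takes the first value and marital status/gender/insurance the last.

Feature names encode the (G, F, base) triple as ``"<G>|<F>|<base>"``, e.g.
``"mean|max|urea_nitrogen"`` is the mean over hospitalizations of the
within-stay maximum urea nitrogen.  Unobserved continuous inputs stay
missing (never imputed here); count-type inputs that simply did not occur
are zero.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .phenotype import (
    CohortSample,
    Hospitalization,
    detect_aki_by_code,
    detect_aki_by_scr,
)

__all__ = [
    "FeatureSpec",
    "FeatureInfo",
    "FeatureMatrix",
    "parse_feature_name",
    "to_sequences",
    "summarize_within",
    "truncate_code",
    "add_nonpresent_counts",
    "build_abnormal_flags",
    "strip_medication",
    "hospitalization_vector",
    "aggregate_over_hospitalizations",
    "featurize_sample",
    "featurize_corpus",
    "add_nonpresent_features",
    "filter_sparse",
]

CONTINUOUS_F_STATS = ("min", "max", "mean", "var", "sum")
LAB_G_STATS = ("min", "mean", "max", "sum", "var")

#: code-system -> feature prefix
_CODE_PREFIX = {"ICD9-DX": "dx", "ICD9-PX": "px", "CPT4": "cpt", "DRG": "drg"}

#: categories whose per-stay counts gain "non-present" shortfall features
NONPRESENT_CATEGORIES = ("dx", "cpt", "drg")

#: diagnosis prefixes used by the condensed clinical feature set
_CLINICAL_DX_PREFIXES = {
    "renal_insufficiency": ("584", "585"),
    "diabetes": ("250",),
    "heart_failure": ("428",),
}


@dataclass(frozen=True)
class FeatureSpec:
    """Knobs of the feature extractor.

    ``code_precision`` is the number of leading characters kept when
    truncating hierarchical codes (dots stripped first); ``sparsity_threshold``
    is the minimum number of non-zero, non-missing entries a feature needs to
    survive the sparsity filter.
    """

    code_precision: int = 3
    sparsity_threshold: int = 100

    def __post_init__(self) -> None:
        if self.code_precision < 1:
            raise ValueError("code_precision must be >= 1")
        if self.sparsity_threshold < 0:
            raise ValueError("sparsity_threshold must be >= 0")


@dataclass(frozen=True)
class FeatureInfo:
    """Provenance of one feature column: its (G, F, base) triple plus
    bookkeeping ``category`` (lab/flag/med/code/admin/nonpresent/clinical/helper)
    and ``kind`` ("continuous" columns stay NaN when unobserved; "count"
    columns fill with 0)."""

    g: str
    f: str
    base: str
    category: str
    kind: str

    @property
    def name(self) -> str:
        return f"{self.g}|{self.f}|{self.base}"


def parse_feature_name(name: str) -> tuple[str, str, str]:
    """Split ``"<G>|<F>|<base>"`` back into its triple."""
    g, f, base = name.split("|", 2)
    return g, f, base


def truncate_code(code: str, precision: int) -> str:
    """Truncate a hierarchical code to ``precision`` leading characters.

    The dot is stripped first; codes shorter than the precision map to
    themselves (e.g. ``("585.9", 3) -> "585"``, ``("V58", 3) -> "V58"``).
    """
    if precision < 1:
        raise ValueError("precision must be >= 1")
    if not code:
        raise ValueError("empty code")
    return code.replace(".", "")[:precision]


_DOSE_UNIT = r"(?:MG/ML|MCG/ML|UNITS?/ML|MEQ/ML|MG|MCG|GM?|ML|L|MEQ|UNITS?|IU|%|HR)"
_DOSE_RE = re.compile(
    rf"\b\d[\d,]*(?:\.\d+)?\s*(?:{_DOSE_UNIT})\b|\b\d[\d,]*(?:\.\d+)?\b|%"
)
_WS_RE = re.compile(r"\s+")


def strip_medication(description: str) -> str:
    """Normalize a free-text medication description.

    Removes dosage tokens (numbers with or without units such as MG, MCG,
    ML, UNITS/ML, %, including comma-grouped strengths like ``5,000``),
    uppercases and collapses whitespace:
    ``"Furosemide 40 MG tablet" -> "FUROSEMIDE TABLET"``.
    """
    if not description:
        raise ValueError("empty medication description")
    s = description.upper()
    s = _DOSE_RE.sub(" ", s)
    s = _WS_RE.sub(" ", s).strip()
    return s


def summarize_within(seq: Sequence[float], kind: str) -> dict[str, float]:
    """The within-stay summary ``F``.

    Continuous sequences yield min/max/mean/var/sum (sample variance,
    ``var = 0`` for singletons); categorical sequences yield their sum.
    Empty sequences yield nothing (all statistics missing).
    """
    if kind not in ("continuous", "categorical"):
        raise ValueError(f"unknown kind {kind!r}")
    if len(seq) == 0:
        return {}
    arr = np.asarray(seq, dtype=float)
    if kind == "categorical":
        return {"count": float(arr.sum())}
    var = float(arr.var(ddof=1)) if arr.size > 1 else 0.0
    return {
        "min": float(arr.min()),
        "max": float(arr.max()),
        "mean": float(arr.mean()),
        "var": var,
        "sum": float(arr.sum()),
    }


def build_abnormal_flags(lab_rows: pd.DataFrame) -> dict[tuple[str, str], int]:
    """Count abnormal-flag occurrences per (test, flag) pair for one stay.

    Rows flagged ``"none"`` emit nothing; an unknown flag value is a data
    error.  Returned counts feed the within-stay summary as counts that are
    treated as continuous downstream (e.g. "mean count abnormally high
    urea nitrogen" across stays).
    """
    counts: dict[tuple[str, str], int] = {}
    if lab_rows is None or len(lab_rows) == 0:
        return counts
    for test, flag in zip(lab_rows["test_name"], lab_rows["abnormal_flag"]):
        if flag not in ("low", "high", "none"):
            raise ValueError(f"unknown abnormal flag {flag!r}")
        if flag != "none":
            counts[(test, flag)] = counts.get((test, flag), 0) + 1
    return counts


def add_nonpresent_counts(
    counts: Sequence[int], d_max: int | None = None
) -> tuple[list[int], int]:
    """Shortfall counts ``D - D'`` for per-stay code counts.

    ``D`` is the corpus maximum (learned on training data and frozen when
    given); each stay with ``D'`` codes gains ``max(D - D', 0)``
    "non-present" codes.
    """
    if len(counts) == 0:
        raise ValueError("need at least one hospitalization")
    if d_max is None:
        d_max = int(max(counts))
    return [max(d_max - int(c), 0) for c in counts], d_max


# ---------------------------------------------------------------------------
# per-stay extraction

_FKey = tuple[str, str, str, str]  # (f, base, category, kind)


def to_sequences(h: Hospitalization) -> dict[tuple[str, str, str], list[float]]:
    """The ``s`` operator: one time-ordered value sequence per base input.

    Keys are ``(base, category, kind)``.  Lab values are the measurements in
    time order; medications (at description, class and subclass level) and
    codes contribute occurrence sequences of ones.  No imputation happens
    here — inputs never observed in the stay simply have no key.
    """
    seqs: dict[tuple[str, str, str], list[float]] = {}

    if h.labs is not None and len(h.labs):
        labs = h.labs.sort_values("time", kind="stable")
        for test, value in zip(labs["test_name"], labs["value"]):
            seqs.setdefault((str(test), "lab", "continuous"), []).append(float(value))
        for (test, flag), c in build_abnormal_flags(labs).items():
            key = (f"abnormal_{flag}:{test}", "flag", "categorical")
            seqs[key] = [1.0] * c

    if h.medications is not None and len(h.medications):
        meds = h.medications.sort_values("time", kind="stable")
        for desc, cls, sub in zip(
            meds["description"], meds["pharm_class"], meds["pharm_subclass"]
        ):
            name = strip_medication(str(desc))
            seqs.setdefault((f"med:{name}", "med", "categorical"), []).append(1.0)
            if cls:
                seqs.setdefault(
                    (f"medclass:{cls}", "med", "categorical"), []
                ).append(1.0)
            if sub:
                seqs.setdefault(
                    (f"medsubclass:{sub}", "med", "categorical"), []
                ).append(1.0)

    for system, code in h.codes:
        prefix = _CODE_PREFIX.get(system)
        if prefix is None:
            continue
        seqs.setdefault((f"{prefix}:{code}", "codeitem", "categorical"), []).append(1.0)

    for loc in h.locations:
        seqs.setdefault((f"location:{loc}", "admin", "categorical"), []).append(1.0)
    if h.discharge_disposition:
        seqs[(f"disposition:{h.discharge_disposition}", "admin", "categorical")] = [1.0]

    return seqs


def hospitalization_vector(
    h: Hospitalization, spec: FeatureSpec
) -> dict[_FKey, float]:
    """``F(s(H))``: the fixed-length within-stay representation.

    Codes are truncated to ``spec.code_precision`` before counting.  Also
    carries the admin scalars (age, length of stay, the categorical admin
    strings) and the raw per-category code counts that the non-present
    transform needs.
    """
    vec: dict[_FKey, float] = {}
    for (base, category, kind), seq in to_sequences(h).items():
        if category == "codeitem":
            prefix, code = base.split(":", 1)
            base = f"{prefix}:{truncate_code(code, spec.code_precision)}"
            category = "code"
        stats = summarize_within(seq, kind)
        for f_name, value in stats.items():
            key = (f_name, base, category, "count" if kind == "categorical" else "continuous")
            if kind == "categorical":
                # truncation can merge distinct raw codes into one base
                vec[key] = vec.get(key, 0.0) + value
            else:
                vec[key] = value

    vec[("value", "age", "admin_age", "continuous")] = float(h.age_at_admit)
    vec[("value", "los_days", "admin_num", "continuous")] = h.length_of_stay_days
    for fieldname, val in (
        ("race", h.race),
        ("marital_status", h.marital_status),
        ("gender", h.gender),
        ("insurance", h.insurance),
    ):
        if val:
            vec[("value", f"{fieldname}={val}", f"admin_{fieldname}", "indicator")] = 1.0

    # per-category raw code counts (inputs to the non-present transform)
    for prefix in NONPRESENT_CATEGORIES:
        system = {v: k for k, v in _CODE_PREFIX.items()}[prefix]
        vec[("count", f"_rawcodes:{prefix}", "helper", "count")] = float(
            len(h.codes_for(system))
        )
    return vec


# ---------------------------------------------------------------------------
# across-stay aggregation

_ADMIN_CAT_RULE = {
    "admin_race": "first",
    "admin_marital_status": "last",
    "admin_gender": "last",
    "admin_insurance": "last",
}


def aggregate_over_hospitalizations(
    stay_vectors: Sequence[dict[_FKey, float]],
) -> tuple[dict[str, float], dict[str, FeatureInfo]]:
    """``G(s(F(s(H))))``: collapse per-stay summaries into one vector.

    ``stay_vectors`` must be ordered by admission time.  Labs and abnormal
    flag counts receive min/mean/max/sum/var across the stays where they
    were observed (all-missing stays are skipped; all missing -> missing);
    count-type inputs are summed with absent stays contributing zero; age is
    maxed; race keeps its first observed value, the other demographic
    strings their last.
    """
    if len(stay_vectors) == 0:
        raise ValueError("need at least one hospitalization vector")

    values: dict[str, float] = {}
    schema: dict[str, FeatureInfo] = {}

    def emit(info: FeatureInfo, value: float) -> None:
        values[info.name] = value
        schema[info.name] = info

    keys: list[_FKey] = []
    seen = set()
    for sv in stay_vectors:
        for key in sv:
            if key not in seen:
                seen.add(key)
                keys.append(key)

    for f_name, base, category, kind in keys:
        key = (f_name, base, category, kind)
        observed = [sv[key] for sv in stay_vectors if key in sv]
        if category in ("lab", "flag"):
            arr = np.asarray(observed, dtype=float)
            g_vals = {
                "min": float(arr.min()),
                "mean": float(arr.mean()),
                "max": float(arr.max()),
                "sum": float(arr.sum()),
                "var": float(arr.var(ddof=1)) if arr.size > 1 else 0.0,
            }
            for g_name, value in g_vals.items():
                emit(FeatureInfo(g_name, f_name, base, category, "continuous"), value)
        elif category == "admin_age":
            emit(
                FeatureInfo("max", "value", "age", "admin", "continuous"),
                float(max(observed)),
            )
        elif category in _ADMIN_CAT_RULE:
            pass  # handled at field level below (one indicator per field)
        elif category == "helper":
            # non-present transform needs both the total and the per-stay max
            emit(
                FeatureInfo("sum", f_name, base, category, "count"),
                float(np.sum(observed)),
            )
            emit(
                FeatureInfo("max", f_name, base, category, "count"),
                float(np.max(observed)),
            )
        else:
            # med, code, admin counts: sum with absent stays = 0
            emit(
                FeatureInfo("sum", f_name, base, category, "count"),
                float(np.sum(observed)),
            )

    # first/last rules pick exactly one level per demographic field
    for category, rule in _ADMIN_CAT_RULE.items():
        order = stay_vectors if rule == "first" else list(reversed(stay_vectors))
        for sv in order:
            level = [k for k in sv if k[2] == category]
            if level:
                base = level[0][1]
                emit(FeatureInfo(rule, "value", base, "admin", "indicator"), 1.0)
                break
    return values, schema


def _clinical_history(priors: Sequence[Hospitalization]) -> dict[str, float]:
    """Condensed clinically-known risk factors from the prior stays."""
    dx = [truncate_code(c, 3) for h in priors for c in h.codes_for("ICD9-DX")]
    out = {}
    for name, prefixes in _CLINICAL_DX_PREFIXES.items():
        out[name] = float(any(d.startswith(p) for d in dx for p in prefixes))
    if out["renal_insufficiency"] == 0.0:
        for h in priors:
            if detect_aki_by_code(h.codes_for("ICD9-DX")) or detect_aki_by_scr(
                h.scr_series
            )[0]:
                out["renal_insufficiency"] = 1.0
                break
    return out


def featurize_sample(
    sample: CohortSample,
    hosp_by_id: Mapping[str, Hospitalization],
    spec: FeatureSpec,
    recent: bool = False,
) -> tuple[dict[str, float], dict[str, FeatureInfo]]:
    """Fixed-length feature vector for one training sample.

    Only the sample's *prior* hospitalizations are touched — the target stay
    contributes nothing but its label.  With ``recent=True`` the aggregation
    sees only the most recent prior stay (the "recent"-input variant).
    """
    prior_ids = sample.prior_admit_ids[-1:] if recent else sample.prior_admit_ids
    priors = [hosp_by_id[a] for a in prior_ids]
    stay_vectors = [hospitalization_vector(h, spec) for h in priors]
    values, schema = aggregate_over_hospitalizations(stay_vectors)

    values["helper|count|nstays"] = float(len(priors))
    schema["helper|count|nstays"] = FeatureInfo(
        "helper", "count", "nstays", "helper", "count"
    )
    for name, value in _clinical_history(priors).items():
        info = FeatureInfo("any", "history", name, "clinical", "indicator")
        values[info.name] = value
        schema[info.name] = info
    return values, schema


@dataclass
class FeatureMatrix:
    """A samples-by-features table plus per-column provenance.

    ``X`` is indexed by target admit id; ``y`` holds the AKI labels;
    ``groups`` the patient ids (for grouped CV); ``utilization`` the number
    of hospitalizations each sample's patient contributes.
    """

    X: pd.DataFrame
    y: np.ndarray
    groups: np.ndarray
    utilization: np.ndarray
    schema: dict[str, FeatureInfo] = field(repr=False)

    def columns_for(self, subset: str = "full") -> list[str]:
        """Column subsets: "full" (everything except the condensed clinical
        composites and helper columns), "medications", "clinical"."""
        if subset == "full":
            return [
                c
                for c in self.X.columns
                if self.schema[c].category not in ("clinical",)
            ]
        if subset == "medications":
            return [c for c in self.X.columns if self.schema[c].category == "med"]
        if subset == "clinical":
            return ["max|value|age"] + [
                c for c in self.X.columns if self.schema[c].category == "clinical"
            ]
        raise ValueError(f"unknown subset {subset!r}")


def featurize_corpus(
    samples: Sequence[CohortSample],
    hosp_by_id: Mapping[str, Hospitalization],
    spec: FeatureSpec | None = None,
    recent: bool = False,
) -> FeatureMatrix:
    """Featurize every sample and align columns across the corpus.

    Count-type columns a sample never observed fill with 0 (the event did
    not occur); continuous lab/flag columns stay missing for downstream
    imputation inside the modeling pipeline.
    """
    spec = spec or FeatureSpec()
    if len(samples) == 0:
        raise ValueError("empty sample list")
    rows = []
    schema: dict[str, FeatureInfo] = {}
    for sample in samples:
        values, s = featurize_sample(sample, hosp_by_id, spec, recent=recent)
        rows.append(values)
        for name, info in s.items():
            schema.setdefault(name, info)
    columns = sorted(schema)
    X = pd.DataFrame(rows, columns=columns, index=[s.target_admit_id for s in samples])
    count_cols = [c for c in columns if schema[c].kind in ("count", "indicator")]
    X[count_cols] = X[count_cols].fillna(0.0)
    return FeatureMatrix(
        X=X,
        y=np.array([s.label for s in samples], dtype=int),
        groups=np.array([s.patient_id for s in samples]),
        utilization=np.array([s.utilization for s in samples], dtype=int),
        schema=schema,
    )


def add_nonpresent_features(
    X: pd.DataFrame,
    schema: Mapping[str, FeatureInfo],
    state: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, dict[str, FeatureInfo], dict[str, int]]:
    """Add "non-present" code-shortfall features to a feature table.

    For each code category (diagnoses, CPT-4 procedures, DRGs), the corpus
    maximum per-stay code count ``D`` is learned from the helper columns
    (training data only — pass the returned ``state`` to transform held-out
    data) and each sample gains ``sum over its stays of max(D - D', 0)``.
    Because a sample's helper columns carry the per-stay max and the total,
    the sum of shortfalls equals ``n_stays * D - total`` when ``D`` bounds
    every stay, and is floored at zero otherwise.
    """
    out = X.copy()
    new_schema = dict(schema)
    fitted: dict[str, int] = {} if state is None else dict(state)
    nstays = X["helper|count|nstays"]
    for prefix in NONPRESENT_CATEGORIES:
        helper = f"sum|count|_rawcodes:{prefix}"
        maxcol = f"max|count|_rawcodes:{prefix}"
        if helper not in X.columns:
            continue
        if state is None:
            fitted[prefix] = int(X[maxcol].max()) if maxcol in X.columns else 0
        d = fitted.get(prefix, 0)
        shortfall = (nstays * d - X[helper]).clip(lower=0.0)
        info = FeatureInfo("sum", "count", f"nonpresent:{prefix}", "nonpresent", "count")
        out[info.name] = shortfall
        new_schema[info.name] = info
    return out, new_schema, fitted


def filter_sparse(
    X: pd.DataFrame,
    threshold: int,
    schema: Mapping[str, FeatureInfo] | None = None,
    protect: tuple[str, ...] = ("helper", "clinical"),
) -> tuple[pd.DataFrame, list[str]]:
    """Drop extremely sparse features.

    A feature is kept iff its number of non-missing AND non-zero entries is
    at least ``threshold``.  Applied once to the full table before
    cross-validation (response-independent).  Columns whose category is in
    ``protect`` (helpers needed by the pipeline, the condensed clinical set)
    are always kept.
    """
    qualifying = (X.notna() & (X != 0)).sum(axis=0)
    kept = []
    for c in X.columns:
        if schema is not None and schema[c].category in protect:
            kept.append(c)
        elif qualifying[c] >= threshold:
            kept.append(c)
    return X[kept], kept
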