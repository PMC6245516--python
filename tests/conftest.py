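"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (exhaustive pairwise scans,
brute-force threshold sweeps) so they stay independent of the package's
implementations they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import akirisk as ak


# ---------------------------------------------------------------------------
# independent oracles

def kdigo_brute_force(series) -> bool:
    """Exhaustive ordered-pair scan of the KDIGO creatinine deltas."""
    n = len(series)
    for i in range(n):
        t, v = series[i]
        for j in range(i):
            u, b = series[j]
            if t - u <= 168.0 and v / b >= 1.5:
                return True
            if t - u <= 48.0 and v - b >= 0.3:
                return True
    return False


def roc_auc_pairwise(labels, scores) -> float:
    """O(n^2) count of positive-negative pairs, ties worth 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def pr_auc_brute(labels, scores) -> float:
    """Average precision accumulated threshold by threshold."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    order = np.argsort(-scores, kind="stable")
    labels = labels[order]
    scores = scores[order]
    n_pos = labels.sum()
    ap = 0.0
    prev_recall = 0.0
    tp = 0
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and scores[j] == scores[i]:
            j += 1
        tp += labels[i:j].sum()
        precision = tp / j
        recall = tp / n_pos
        ap += precision * (recall - prev_recall)
        prev_recall = recall
        i = j
    return float(ap)


def random_scr_series(rng, max_len: int = 30):
    """A random creatinine series: positive values, sorted times."""
    m = int(rng.integers(0, max_len + 1))
    times = np.sort(rng.uniform(0.0, 240.0, size=m))
    values = np.exp(rng.normal(0.0, 0.35, size=m))
    return list(zip(times.tolist(), values.tolist()))


# ---------------------------------------------------------------------------
# fixtures

def make_hospitalization(
    patient_id="P0",
    admit_id="P0A00",
    admit_time=0.0,
    los=96.0,
    age=60.0,
    scr=(),
    labs_extra=(),
    dx=(),
    px=(),
    meds=(),
    **kwargs,
):
    """Compact hand-built stay for unit tests.

    ``scr`` is a list of (time, value); ``labs_extra`` of
    (test, time, value, flag); ``dx``/``px`` code lists; ``meds`` of
    (time, description, cls, sub).
    """
    lab_rows = [
        {"test_name": ak.phenotype.SCR_TEST_NAME, "time": admit_time + t,
         "value": v, "abnormal_flag": "none"}
        for t, v in scr
    ]
    lab_rows += [
        {"test_name": n, "time": admit_time + t, "value": v, "abnormal_flag": f}
        for n, t, v, f in labs_extra
    ]
    med_rows = [
        {"time": admit_time + t, "description": d, "pharm_class": c,
         "pharm_subclass": s}
        for t, d, c, s in meds
    ]
    codes = [("ICD9-DX", c) for c in dx] + [("ICD9-PX", c) for c in px]
    return ak.Hospitalization(
        patient_id=patient_id,
        admit_id=admit_id,
        admit_time=admit_time,
        discharge_time=admit_time + los,
        age_at_admit=age,
        labs=pd.DataFrame(lab_rows) if lab_rows else None,
        medications=pd.DataFrame(med_rows) if med_rows else None,
        codes=codes,
        **kwargs,
    )


@pytest.fixture(scope="session")
def small_ehr():
    """A 600-patient synthetic cohort shared by cheap integration tests."""
    return ak.generate_cohort(ak.GeneratorConfig(n_patients=600, seed=7))


@pytest.fixture(scope="session")
def small_corpus(small_ehr):
    """Feature matrix of the small cohort, sparsity-filtered at a
    corpus-appropriate threshold."""
    samples, hosp_by_id, _ = ak.cohort_samples(small_ehr)
    fm = ak.featurize_corpus(samples, hosp_by_id)
    X, _ = ak.filter_sparse(fm.X, threshold=15, schema=fm.schema)
    fm.X = X
    return fm, samples, hosp_by_id
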