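"""Baseline feature constructions and classical classifier harness.

Fixed-width feature vectors for classifiers that cannot consume variable-
length visit sequences, built three ways from a patient's history:

* aggregate — per-feature summary over all historical visits (mean for
  continuous, median for ordinal, mode for nominal features);
* recent_r — the raw feature vectors of the most recent r visits merged
  into one r*Q-wide vector (the study uses r = 2);
* last_visit — the Nth visit's vector alone (identically recent_r with
  r = 1).

Aggregation operates on raw (pre-encoding) values; the aggregated or
merged rows are then imputed, normalized and one-hot encoded with the
same machinery as the sequence model. Time intervals ride along: each
merged visit keeps its interval-to-next-visit (the last one being the
prediction horizon), and the aggregate construction additionally appends
the prediction horizon since its averaged interval column blends it away.

The classifiers themselves (multinomial logistic regression, RBF SVM,
CART decision tree, 100-tree random forest) are injected standard
components satisfying a fit/predict contract over the five stage indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .evaluation import evaluate_predictions
from .preprocess import (
    PreprocessPipeline,
    _lower_median,
    one_hot_encode,
)
from .schema import STAGES, TIME_INTERVAL_NAME, SchemaTable, encode_stage

CONSTRUCTIONS = ("aggregate", "recent_r", "last_visit")


def _first_observed_mode(values: np.ndarray) -> float:
    """Mode with ties broken by the first-observed level in visit order."""
    uniq, first_pos, counts = np.unique(values, return_index=True,
                                        return_counts=True)
    best = counts.max()
    tied = counts == best
    return float(uniq[tied][np.argmin(first_pos[tied])])


def _aggregate_value(values: np.ndarray, dtype: str) -> float:
    if dtype == "continuous":
        return float(np.mean(values))
    if dtype == "ordinal":
        return _lower_median(values)
    return _first_observed_mode(values)


def aggregate_all_visits(patient_visits: pd.DataFrame,
                         schema: SchemaTable) -> dict[str, float]:
    """Per-feature aggregation over all of one patient's historical visits.

    Missing cells are skipped; a feature missing at every visit stays
    missing (NaN) and is filled later by the fitted imputation plan.
    """
    if patient_visits.empty:
        raise ValueError("patient has no visits")
    ordered = patient_visits.sort_values("month_offset")
    out: dict[str, float] = {}
    for f in schema.features:
        values = ordered[f.name].dropna().to_numpy(dtype=float)
        out[f.name] = _aggregate_value(values, f.dtype) if values.size else np.nan
    return out


def merge_recent_visits(patient_visits: pd.DataFrame, r: int,
                        schema: SchemaTable) -> pd.DataFrame:
    """The most recent r visits, oldest first, as raw rows.

    Rejects r larger than the patient's visit count.
    """
    n = len(patient_visits)
    if r < 1 or r > n:
        raise ValueError(f"r={r} invalid for a patient with {n} visits")
    return patient_visits.sort_values("month_offset").iloc[n - r:]


def last_visit_features(patient_visits: pd.DataFrame,
                        schema: SchemaTable) -> pd.DataFrame:
    """The Nth (most recent) visit's raw row."""
    return merge_recent_visits(patient_visits, 1, schema)


# ---------------------------------------------------------------------------
# Matrix construction
# ---------------------------------------------------------------------------


def _with_intervals(rows: pd.DataFrame, months: np.ndarray,
                    all_months: np.ndarray, pred_interval: float,
                    ti_name: str) -> pd.DataFrame:
    """Set each kept row's interval feature to the months until its successor."""
    rows = rows.copy()
    ti = []
    for m in months:
        later = all_months[all_months > m]
        ti.append(float(later.min() - m) if later.size else float(pred_interval))
    rows[ti_name] = ti
    return rows


def build_feature_matrix(visits: pd.DataFrame, truth: pd.DataFrame,
                         schema: SchemaTable, construction: str,
                         pipeline: PreprocessPipeline,
                         r: int = 2) -> tuple[np.ndarray, list[str]]:
    """Encoded fixed-width matrix for one construction, rows sorted by patient.

    Widths: aggregate -> 234 + 1 (appended prediction horizon); recent_r ->
    r * 234; last_visit -> 234 (equals recent_r with r = 1).
    """
    if construction not in CONSTRUCTIONS:
        raise ValueError(f"unknown construction {construction!r}")
    if construction == "last_visit":
        construction, r = "recent_r", 1

    pred = truth.set_index("patient_id")["prediction_interval"].to_dict()
    patient_ids = sorted(truth["patient_id"])
    grouped = dict(tuple(visits.groupby("patient_id")))

    min_visits = min(len(g) for g in grouped.values())
    if construction == "recent_r" and r > min_visits:
        raise ValueError(
            f"r={r} exceeds the dataset's minimum visit count {min_visits}")

    if construction == "aggregate":
        rows = []
        horizons = []
        for pid in patient_ids:
            g = grouped[pid]
            months = g["month_offset"].to_numpy(dtype=float)
            agg = aggregate_all_visits(g, schema)
            # mean interval over the history including the prediction horizon
            deltas = np.diff(np.sort(months))
            agg[TIME_INTERVAL_NAME] = float(
                np.mean(np.append(deltas, pred[pid])))
            rows.append(agg)
            horizons.append(pred[pid])
        raw = pd.DataFrame(rows)
        raw.insert(0, "patient_id", patient_ids)
        raw.insert(1, "visit_index", 1)
        raw.insert(2, "month_offset", 0)
        transformed = pipeline.transform(raw)
        X = one_hot_encode(transformed, schema)
        X = np.hstack([X, np.asarray(horizons, dtype=float)[:, None]])
        return X, patient_ids

    # recent_r: keep the last r raw visit rows per patient, encode, concat
    blocks: list[np.ndarray] = []
    for pid in patient_ids:
        g = grouped[pid]
        months = np.sort(g["month_offset"].to_numpy(dtype=float))
        kept = merge_recent_visits(g, r, schema)
        kept = _with_intervals(kept, kept["month_offset"].to_numpy(dtype=float),
                               months, pred[pid], TIME_INTERVAL_NAME)
        transformed = pipeline.transform(kept)
        enc = one_hot_encode(transformed, schema)
        blocks.append(enc.reshape(-1))
    return np.vstack(blocks), patient_ids


# ---------------------------------------------------------------------------
# Classifier harness
# ---------------------------------------------------------------------------


def make_default_classifiers(seed: int = 0) -> dict[str, object]:
    """The four injected standard classifiers keyed by their usual initials."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    return {
        "LR": LogisticRegression(max_iter=1000),
        "SVM": SVC(kernel="rbf"),
        "DT": DecisionTreeClassifier(random_state=seed),
        "RF": RandomForestClassifier(n_estimators=100, random_state=seed),
    }


def run_baseline(train_visits: pd.DataFrame, train_truth: pd.DataFrame,
                 test_visits: pd.DataFrame, test_truth: pd.DataFrame,
                 schema: SchemaTable, construction: str,
                 classifier, r: int = 2) -> dict:
    """Fit one classifier on one construction; return metrics on the test set.

    The preprocessing pipeline is fitted on the training visits only and
    reused for the test patients. ``classifier`` must implement
    fit(X, y)/predict(X) over integer stage indices. Classifier failures
    propagate with the construction named.
    """
    pipeline = PreprocessPipeline.fit(train_visits, schema)
    X_tr, ids_tr = build_feature_matrix(train_visits, train_truth, schema,
                                        construction, pipeline, r=r)
    X_te, ids_te = build_feature_matrix(test_visits, test_truth, schema,
                                        construction, pipeline, r=r)
    stage_index = {s: i for i, s in enumerate(STAGES)}
    truth_tr = train_truth.set_index("patient_id")["true_next_stage"]
    y_tr = np.array([stage_index[float(truth_tr.loc[p])] for p in ids_tr])
    try:
        classifier.fit(X_tr, y_tr)
        pred_idx = classifier.predict(X_te)
    except Exception as exc:  # propagate with context
        raise RuntimeError(
            f"classifier failed on construction {construction!r}: {exc}") from exc
    pred = np.asarray(STAGES)[np.asarray(pred_idx, dtype=int)]
    ordered_truth = (test_truth.sort_values("patient_id")
                     .reset_index(drop=True))
    return evaluate_predictions(pred, ordered_truth)
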