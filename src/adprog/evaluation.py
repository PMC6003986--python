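"""Metrics, patient-level cross-validation, and the feature-impact harness.

Three metrics are reported for every model: overall accuracy (fraction of
patients whose next-visit stage is predicted exactly), PPIA (the same
accuracy restricted to patients whose true next-visit stage is higher
than their current stage — pejoratively progressing patients), and SPIA
(restricted to patients whose true next-visit stage is CDR 2 or 3 —
severe patients). PPIA/SPIA are reported as absent (None) when their
denominator group is empty.

Cross-validation is patient-level: a patient's visits all fall in one
fold, and imputation/normalization statistics are refitted per fold on
the training patients only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .schema import STAGES, SchemaTable

SEVERE_STAGES = (2.0, 3.0)


def accuracy(pred: Sequence[float], true: Sequence[float]) -> float:
    """Fraction of exact stage matches; rejects empty or unequal inputs."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.size == 0 or pred.shape != true.shape:
        raise ValueError("prediction and truth must be non-empty and equal length")
    return float(np.mean(pred == true))


def ppia(pred_next: Sequence[float], true_next: Sequence[float],
         true_current: Sequence[float]) -> float | None:
    """Exact-stage accuracy over truly-worsening patients; None if no such patient."""
    pred_next = np.asarray(pred_next, dtype=float)
    true_next = np.asarray(true_next, dtype=float)
    true_current = np.asarray(true_current, dtype=float)
    worsening = true_next > true_current
    if not worsening.any():
        return None
    return float(np.mean(pred_next[worsening] == true_next[worsening]))


def spia(pred_next: Sequence[float], true_next: Sequence[float]) -> float | None:
    """Exact-stage accuracy over patients whose true next stage is CDR 2 or 3."""
    pred_next = np.asarray(pred_next, dtype=float)
    true_next = np.asarray(true_next, dtype=float)
    severe = np.isin(true_next, SEVERE_STAGES)
    if not severe.any():
        return None
    return float(np.mean(pred_next[severe] == true_next[severe]))


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldAssignment:
    k: int
    seed: int
    assignment: dict[str, int]

    def fold_patients(self, fold: int) -> list[str]:
        return sorted(p for p, f in self.assignment.items() if f == fold)

    def split(self, fold: int) -> tuple[list[str], list[str]]:
        """(train patient ids, test patient ids) for one fold."""
        test = self.fold_patients(fold)
        train = sorted(p for p, f in self.assignment.items() if f != fold)
        return train, test


def kfold_split(patient_ids: Iterable[str], k: int, seed: int) -> FoldAssignment:
    """Deterministic patient-level folds with sizes differing by at most 1."""
    ids = sorted(set(patient_ids))
    if len(ids) < k:
        raise ValueError(f"need at least k={k} patients, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment = {ids[j]: int(i % k) for i, j in enumerate(order)}
    return FoldAssignment(k=k, seed=seed, assignment=assignment)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Per-fold metrics with mean +- sample standard deviation."""

    model_tag: str
    fold_metrics: list[dict] = field(default_factory=list)
    failed_folds: list[int] = field(default_factory=list)

    def _values(self, metric: str) -> list[float]:
        return [m[metric] for m in self.fold_metrics if m.get(metric) is not None]

    def mean(self, metric: str) -> float | None:
        vals = self._values(metric)
        return float(np.mean(vals)) if vals else None

    def std(self, metric: str) -> float | None:
        vals = self._values(metric)
        if len(vals) < 2:
            return 0.0 if vals else None
        return float(np.std(vals, ddof=1))

    def summary(self) -> dict:
        out: dict = {"model": self.model_tag, "failed_folds": self.failed_folds}
        for metric in ("accuracy", "ppia", "spia"):
            out[metric] = self.mean(metric)
            out[f"{metric}_sd"] = self.std(metric)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(fold=i, **m) for i, m in enumerate(self.fold_metrics)]
        return pd.DataFrame(rows)


ModelBuilder = Callable[..., Callable[[pd.DataFrame, pd.DataFrame], np.ndarray]]


def evaluate_predictions(pred_next: np.ndarray, truth: pd.DataFrame) -> dict:
    """All three metrics for one prediction table."""
    return {
        "accuracy": accuracy(pred_next, truth["true_next_stage"]),
        "ppia": ppia(pred_next, truth["true_next_stage"], truth["current_stage"]),
        "spia": spia(pred_next, truth["true_next_stage"]),
    }


def cross_validate(visits: pd.DataFrame, truth: pd.DataFrame,
                   schema: SchemaTable, model_builder: ModelBuilder,
                   k: int = 10, seed: int = 0,
                   model_tag: str = "model") -> MetricsReport:
    """Patient-level k-fold evaluation of a model builder.

    ``model_builder(train_visits, train_truth, schema, seed)`` must return
    a predictor ``predict(test_visits, test_truth) -> predicted stages``
    (Global CDR values, ordered like ``test_truth``). A failing fold is
    recorded and the run continues.
    """
    folds = kfold_split(truth["patient_id"], k, seed)
    report = MetricsReport(model_tag=model_tag)
    for fold in range(k):
        train_ids, test_ids = folds.split(fold)
        tr_v = visits[visits["patient_id"].isin(train_ids)]
        te_v = visits[visits["patient_id"].isin(test_ids)]
        tr_t = truth[truth["patient_id"].isin(train_ids)].reset_index(drop=True)
        te_t = (truth[truth["patient_id"].isin(test_ids)]
                .sort_values("patient_id").reset_index(drop=True))
        try:
            predictor = model_builder(tr_v, tr_t, schema, seed)
            pred = np.asarray(predictor(te_v, te_t), dtype=float)
            report.fold_metrics.append(evaluate_predictions(pred, te_t))
        except Exception:
            report.failed_folds.append(fold)
    return report


# ---------------------------------------------------------------------------
# Feature-impact harness
# ---------------------------------------------------------------------------

ABLATABLE_CATEGORIES = ("CDR", "GDS", "FAQ")

#: Categories (plus the time interval) always retained as basic information.
BASIC_CATEGORIES = ("demographics", "health_history", "physical", "time_interval")


def ablation_schema(schema: SchemaTable, removed: Iterable[str],
                    keep_features: Iterable[str] = ()) -> SchemaTable:
    """Schema with the given optional categories removed.

    Only CDR, GDS and FAQ may be removed; demographics, health history,
    physical information (including MMSE) and the time interval stay.
    """
    removed = tuple(removed)
    bad = set(removed) - set(ABLATABLE_CATEGORIES)
    if bad:
        raise ValueError(f"cannot ablate categories {sorted(bad)}; "
                         f"only {ABLATABLE_CATEGORIES} are removable")
    return schema.without_categories(removed, keep=keep_features)


def ablation_study(visits: pd.DataFrame, truth: pd.DataFrame,
                   schema: SchemaTable,
                   category_subsets: Sequence[Sequence[str]],
                   make_builder: Callable[[SchemaTable], ModelBuilder],
                   k: int = 10, seed: int = 0) -> dict[str, MetricsReport]:
    """One cross-validated report per category-removal configuration.

    ``category_subsets`` lists the categories removed in each run; the
    empty subset is the full model and {CDR, GDS, FAQ} the basic model.
    """
    results: dict[str, MetricsReport] = {}
    for removed in category_subsets:
        sub = ablation_schema(schema, removed)
        tag = "full" if not removed else "without_" + "_".join(sorted(removed))
        results[tag] = cross_validate(visits, truth, sub, make_builder(sub),
                                      k=k, seed=seed, model_tag=tag)
    return results


def single_feature_incorporation(visits: pd.DataFrame, truth: pd.DataFrame,
                                 schema: SchemaTable, feature_name: str,
                                 make_builder: Callable[[SchemaTable], ModelBuilder],
                                 k: int = 10, seed: int = 0) -> dict[str, float | None]:
    """Metric improvements of basic-model-plus-one-feature over the basic model.

    The feature must belong to the CDR or FAQ category; both runs share
    the same folds and seed.
    """
    spec = schema.feature(feature_name)  # KeyError on unknown feature
    if spec.category not in ("CDR", "FAQ"):
        raise ValueError(f"{feature_name} is in category {spec.category}; "
                         "only CDR/FAQ features are incorporated")
    basic = ablation_schema(schema, ABLATABLE_CATEGORIES)
    plus = ablation_schema(schema, ABLATABLE_CATEGORIES,
                           keep_features=[feature_name])
    base_report = cross_validate(visits, truth, basic, make_builder(basic),
                                 k=k, seed=seed, model_tag="basic")
    plus_report = cross_validate(visits, truth, plus, make_builder(plus),
                                 k=k, seed=seed, model_tag=f"basic+{feature_name}")
    out: dict[str, float | None] = {}
    for metric in ("accuracy", "ppia", "spia"):
        a, b = plus_report.mean(metric), base_report.mean(metric)
        out[f"delta_{metric}"] = None if a is None or b is None else a - b
    return out
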