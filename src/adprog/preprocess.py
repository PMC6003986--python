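"""Preprocessing: imputation, normalization, one-hot encoding, model inputs.

Two steps mirror the study pipeline: (1) simple statistic imputation with
the statistic chosen by data type (continuous -> mean, ordinal -> median,
nominal -> mode) and the pool chosen by temporal behaviour (static ->
first visits of all patients, dynamic -> all visits of all patients,
patient-specific dynamic -> other visits of the same patient); (2)
mean/variance normalization of continuous features and one-hot encoding of
every categorical, expanding the 78 raw predictors to 234 columns.

All statistics are fitted on training folds only, so held-out patients
never leak into the fill values or normalization constants.

The assembled model input for a patient with N observed visits is an
(N x 234) matrix whose time-interval column at step n holds the interval
to the following visit; at the final step it holds the user-supplied
prediction interval to the future visit being predicted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .schema import (
    N_STAGES,
    TIME_INTERVAL_NAME,
    FeatureSpec,
    SchemaTable,
    encode_stage,
)

STATISTIC_BY_DTYPE = {"continuous": "mean", "ordinal": "median", "nominal": "mode"}

POOL_BY_BEHAVIOR = {
    "static": "first_visits_all_patients",
    "dynamic": "all_visits_all_patients",
    "patient_specific_dynamic": "other_visits_same_patient",
}


def _lower_median(values: np.ndarray) -> float:
    """Median that stays on the admissible grid: lower of the two middle values."""
    v = np.sort(values)
    return float(v[(len(v) - 1) // 2])


def _mode(values: np.ndarray) -> float:
    """Most frequent value; ties broken toward the smallest value."""
    uniq, counts = np.unique(values, return_counts=True)
    return float(uniq[np.argmax(counts)])


def _statistic(values: np.ndarray, stat: str) -> float:
    if stat == "mean":
        return float(np.mean(values))
    if stat == "median":
        return _lower_median(values)
    if stat == "mode":
        return _mode(values)
    raise ValueError(f"unknown statistic {stat!r}")


@dataclass(frozen=True)
class ImputationRule:
    feature: str
    statistic: str
    pool: str
    #: Global fill value; for patient-specific rules this is the fallback
    #: (all-visits statistic) used when a patient has no observed value.
    fill: float


@dataclass(frozen=True)
class ImputationPlan:
    rules: dict[str, ImputationRule]

    def rule(self, feature: str) -> ImputationRule:
        return self.rules[feature]


def build_imputation_plan(train_visits: pd.DataFrame,
                          schema: SchemaTable) -> ImputationPlan:
    """Fit one imputation rule per feature on training visits.

    Raises ``ValueError`` naming any feature with no observed value in its
    pool (patient-specific rules fall back to the all-visits pool for the
    stored global fill).
    """
    if train_visits.empty:
        raise ValueError("training visits are empty")
    first_mask = train_visits["visit_index"] == 1
    rules: dict[str, ImputationRule] = {}
    for f in schema.features:
        stat = STATISTIC_BY_DTYPE[f.dtype]
        pool = POOL_BY_BEHAVIOR[f.temporal_behavior]
        if pool == "first_visits_all_patients":
            observed = train_visits.loc[first_mask, f.name].dropna().to_numpy()
        else:  # all-visits pool, also the patient-specific fallback
            observed = train_visits[f.name].dropna().to_numpy()
        if observed.size == 0:
            raise ValueError(
                f"feature {f.name!r} has no observed value in its imputation pool"
            )
        rules[f.name] = ImputationRule(f.name, stat, pool,
                                       _statistic(observed, stat))
    return ImputationPlan(rules=rules)


def impute(visits: pd.DataFrame, plan: ImputationPlan,
           schema: SchemaTable) -> pd.DataFrame:
    """Fill every missing cell per the fitted plan; observed cells unchanged."""
    out = visits.copy()
    for f in schema.features:
        rule = plan.rule(f.name)
        col = out[f.name]
        missing = col.isna()
        if not missing.any():
            continue
        if rule.pool == "other_visits_same_patient":
            grouped = out.groupby("patient_id")[f.name]
            if rule.statistic == "mean":
                fills = grouped.transform("mean")  # fast path
            else:
                def patient_fill(s: pd.Series) -> float:
                    observed = s.dropna().to_numpy()
                    if observed.size == 0:
                        return np.nan
                    return _statistic(observed, rule.statistic)

                fills = grouped.transform(patient_fill)
            fills = fills.fillna(rule.fill)
            out.loc[missing, f.name] = fills[missing]
        else:
            out.loc[missing, f.name] = rule.fill
    return out


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Normalizer:
    """Per-continuous-feature training mean and population variance."""

    means: dict[str, float]
    variances: dict[str, float]
    #: Whether the time-interval column is z-scored (default: passed raw).
    normalize_time_interval: bool = False


def fit_normalizer(train_visits: pd.DataFrame, schema: SchemaTable,
                   normalize_time_interval: bool = False) -> Normalizer:
    """Fit mean/variance on training folds; rejects zero-variance features."""
    means: dict[str, float] = {}
    variances: dict[str, float] = {}
    for f in schema.features:
        if f.dtype != "continuous":
            continue
        if f.name == TIME_INTERVAL_NAME and not normalize_time_interval:
            continue
        values = train_visits[f.name].dropna().to_numpy(dtype=float)
        if values.size == 0:
            raise ValueError(f"no observed values for {f.name}")
        var = float(np.var(values))  # population variance
        if var <= 0.0:
            raise ValueError(f"feature {f.name} has zero variance")
        means[f.name] = float(np.mean(values))
        variances[f.name] = var
    return Normalizer(means=means, variances=variances,
                      normalize_time_interval=normalize_time_interval)


def apply_normalizer(visits: pd.DataFrame, normalizer: Normalizer) -> pd.DataFrame:
    """Z-score the fitted continuous columns; categoricals untouched."""
    out = visits.copy()
    for name, mu in normalizer.means.items():
        sd = np.sqrt(normalizer.variances[name])
        out[name] = (out[name] - mu) / sd
    return out


# ---------------------------------------------------------------------------
# One-hot encoding
# ---------------------------------------------------------------------------


def one_hot_encode(visits: pd.DataFrame, schema: SchemaTable) -> np.ndarray:
    """Encode completed visit rows to the schema's full encoded width.

    Continuous features occupy one column; each categorical occupies one
    column per declared level with exactly one 1. Raises ``ValueError``
    naming the feature and value on any out-of-vocabulary level.
    """
    n = len(visits)
    X = np.zeros((n, schema.encoded_width))
    pos = 0
    for f in schema.features:
        col = visits[f.name].to_numpy(dtype=float)
        if np.isnan(col).any():
            raise ValueError(f"feature {f.name} still has missing values; impute first")
        if f.is_categorical:
            levels = np.asarray(f.levels, dtype=float)
            # match to nearest level within tolerance
            diffs = np.abs(col[:, None] - levels[None, :])
            idx = np.argmin(diffs, axis=1)
            bad = diffs[np.arange(n), idx] > 1e-9
            if bad.any():
                value = col[np.argmax(bad)]
                raise ValueError(
                    f"value {value!r} of feature {f.name} not in levels {f.levels}"
                )
            X[np.arange(n), pos + idx] = 1.0
            pos += len(levels)
        else:
            X[:, pos] = col
            pos += 1
    return X


def decode_onehot_block(block: np.ndarray, feature: FeatureSpec) -> float:
    """Recover the categorical value from its one-hot block."""
    if not feature.is_categorical:
        raise ValueError(f"{feature.name} is not categorical")
    if block.sum() != 1:
        raise ValueError("block is not one-hot")
    return float(feature.levels[int(np.argmax(block))])


# ---------------------------------------------------------------------------
# Model-input assembly
# ---------------------------------------------------------------------------


@dataclass
class EncodedDataset:
    """Batched shifted many-to-one inputs.

    ``X`` has shape (n_patients, T, width) with zero pad rows beyond each
    patient's N observed steps; ``mask`` is 1 on real steps. ``y`` holds
    the one-hot next-visit stage when ground truth is available.
    """

    X: np.ndarray
    mask: np.ndarray
    lengths: np.ndarray
    y: np.ndarray | None
    patient_ids: list[str]
    ti_column: int
    schema: SchemaTable

    @property
    def n_patients(self) -> int:
        return self.X.shape[0]


def assemble_model_inputs(visits: pd.DataFrame, schema: SchemaTable,
                          prediction_intervals: pd.Series | dict,
                          truth: pd.DataFrame | None = None,
                          include_time_intervals: bool = True,
                          min_visits: int = 3,
                          add_shift_pad: bool = True) -> EncodedDataset:
    """Build padded (X, mask, y) batches from completed, normalized visits.

    The time-interval column at step n is the months to the following
    visit, derived from month offsets; at the last observed step it is the
    supplied prediction interval. With ``include_time_intervals`` off the
    whole column is zeroed (the without-TI model variant). A masked
    all-zero pad row is appended after the last step for the shifted
    many-to-one layout; pad rows never influence the prediction.
    """
    offsets = schema.block_offsets()
    ti_col = offsets[TIME_INTERVAL_NAME][0]
    pred = dict(prediction_intervals) if not isinstance(prediction_intervals, dict) \
        else prediction_intervals

    encoded = one_hot_encode(visits, schema)
    order = visits[["patient_id", "month_offset"]].reset_index(drop=True)
    groups: dict[str, list[int]] = {}
    for i, pid in enumerate(order["patient_id"]):
        groups.setdefault(pid, []).append(i)

    patient_ids = sorted(groups)
    seqs: list[np.ndarray] = []
    for pid in patient_ids:
        rows = groups[pid]
        months = order.loc[rows, "month_offset"].to_numpy(dtype=float)
        ordering = np.argsort(months, kind="stable")
        rows = [rows[j] for j in ordering]
        months = months[ordering]
        if len(rows) < min_visits:
            raise ValueError(
                f"patient {pid} has {len(rows)} visits; at least {min_visits} required"
            )
        if np.any(np.diff(months) <= 0):
            raise ValueError(f"patient {pid} has non-increasing month offsets")
        if pid not in pred:
            raise ValueError(f"no prediction interval supplied for patient {pid}")
        seq = encoded[rows].copy()
        deltas = np.diff(months)
        seq[:-1, ti_col] = deltas
        seq[-1, ti_col] = float(pred[pid])
        if not include_time_intervals:
            seq[:, ti_col] = 0.0
        seqs.append(seq)

    lengths = np.array([s.shape[0] for s in seqs])
    T = int(lengths.max()) + (1 if add_shift_pad else 0)
    width = schema.encoded_width
    X = np.zeros((len(seqs), T, width))
    mask = np.zeros((len(seqs), T))
    for i, s in enumerate(seqs):
        X[i, : s.shape[0]] = s
        mask[i, : s.shape[0]] = 1.0

    y = None
    if truth is not None:
        lookup = truth.set_index("patient_id")["true_next_stage"]
        y = np.zeros((len(patient_ids), N_STAGES))
        for i, pid in enumerate(patient_ids):
            y[i, encode_stage(float(lookup.loc[pid])).index] = 1.0

    return EncodedDataset(X=X, mask=mask, lengths=lengths, y=y,
                          patient_ids=patient_ids, ti_column=ti_col,
                          schema=schema)


@dataclass
class PreprocessPipeline:
    """Plan + normalizer fitted on training visits, applied to any fold."""

    plan: ImputationPlan
    normalizer: Normalizer
    schema: SchemaTable

    @staticmethod
    def fit(train_visits: pd.DataFrame, schema: SchemaTable,
            normalize_time_interval: bool = False) -> "PreprocessPipeline":
        plan = build_imputation_plan(train_visits, schema)
        completed = impute(train_visits, plan, schema)
        normalizer = fit_normalizer(completed, schema,
                                    normalize_time_interval=normalize_time_interval)
        return PreprocessPipeline(plan=plan, normalizer=normalizer, schema=schema)

    def transform(self, visits: pd.DataFrame) -> pd.DataFrame:
        completed = impute(visits, self.plan, self.schema)
        return apply_normalizer(completed, self.normalizer)

    def encode(self, visits: pd.DataFrame, truth: pd.DataFrame,
               include_time_intervals: bool = True) -> EncodedDataset:
        transformed = self.transform(visits)
        pred = truth.set_index("patient_id")["prediction_interval"].to_dict()
        return assemble_model_inputs(
            transformed, self.schema, pred, truth=truth,
            include_time_intervals=include_time_intervals)
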