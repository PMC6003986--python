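"""Synthetic longitudinal AD cohort generator.

Emulates the statistical structure of the study cohort: stage paths follow
the printed per-visit Global-CDR transition matrix, visit counts lie in
[3, 12] with mean 4.98, inter-visit intervals concentrate at 12 months
(~46%) and span 5-60 months, first-visit stages concentrate at CDR 0.5
(47.7%) and CDR 1 (34.9%), per-visit features are stage-linked (CDR
elements with configurable fidelity, FAQ means increasing in stage, GDS
as stage-independent noise, static demographics/history per patient), and
per-feature missingness follows the schema's assigned rates.

Each simulated patient carries N observed visits plus a held-out
(N+1)-th-visit stage, the prediction target, reached after a prediction
interval drawn from the same interval distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .schema import (
    CDR_STANDARD_ELEMENTS,
    FAQ_ITEMS,
    GDS_ITEMS,
    N_STAGES,
    STAGES,
    TIME_INTERVAL_NAME,
    SchemaTable,
    default_schema,
)

# ---------------------------------------------------------------------------
# Packaged transition matrix (per-visit Global CDR stage transitions)
# ---------------------------------------------------------------------------

#: Row-stochastic 5x5 matrix: P[s, s'] = Pr(next-visit stage s' | current s).
#: Rows/columns ordered as STAGES = (0, 0.5, 1, 2, 3).
TRANSITION_MATRIX = np.array(
    [
        [0.5286, 0.4320, 0.0384, 0.0010, 0.0],
        [0.0201, 0.6304, 0.3151, 0.0299, 0.0045],
        [0.0004, 0.0488, 0.6134, 0.2982, 0.0392],
        [0.0, 0.0023, 0.0454, 0.6165, 0.3358],
        [0.0, 0.0, 0.0019, 0.0254, 0.9727],
    ]
)

#: First-visit stage probabilities. The CDR 0.5 and CDR 1 entries are the
#: printed cohort fractions; the remainder is the packaged fixture choice.
FIRST_STAGE_PROBS = np.array([0.074, 0.477, 0.349, 0.070, 0.030])

#: Printed mean number of observed visits per patient.
MEAN_VISIT_COUNT = 4.98

VISIT_COUNT_SUPPORT = np.arange(3, 13)

#: Fraction of inter-visit intervals equal to 12 months.
TWELVE_MONTH_MASS = 0.46

INTERVAL_SUPPORT = np.arange(5, 61)


def _visit_count_probs(target_mean: float = MEAN_VISIT_COUNT) -> np.ndarray:
    """Geometric-decay weights on {3..12} tilted so the mean hits the target."""
    k = VISIT_COUNT_SUPPORT.astype(float)

    def mean_for(rho: float) -> float:
        w = rho ** (k - 3)
        w = w / w.sum()
        return float(w @ k)

    rho = brentq(lambda r: mean_for(r) - target_mean, 1e-9, 1.0 - 1e-9)
    w = rho ** (k - 3)
    return w / w.sum()


def _interval_probs(p12: float = TWELVE_MONTH_MASS, decay: float = 0.90) -> np.ndarray:
    """Point mass at 12 months plus geometric decay over the rest of {5..60}."""
    probs = np.zeros_like(INTERVAL_SUPPORT, dtype=float)
    at12 = INTERVAL_SUPPORT == 12
    w = decay ** np.abs(INTERVAL_SUPPORT - 12).astype(float)
    w[at12] = 0.0
    probs = (1.0 - p12) * w / w.sum()
    probs[at12] = p12
    return probs


DEFAULT_VISIT_COUNT_PROBS = _visit_count_probs()
DEFAULT_INTERVAL_PROBS = _interval_probs()


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; the defaults are the packaged study conditions."""

    n_patients: int = 1000
    seed: int = 0
    first_stage_probs: np.ndarray = field(
        default_factory=lambda: FIRST_STAGE_PROBS.copy())
    visit_count_probs: np.ndarray = field(
        default_factory=lambda: DEFAULT_VISIT_COUNT_PROBS.copy())
    interval_probs: np.ndarray = field(
        default_factory=lambda: DEFAULT_INTERVAL_PROBS.copy())
    #: When on, longer intervals raise per-transition worsening probability.
    interval_modulation: bool = False
    #: Peak multiplier on worsening probabilities under modulation.
    modulation_strength: float = 4.0
    #: Steepness of the logistic ramp in (dt - 12)/12.
    modulation_sharpness: float = 3.0
    #: Probability that a CDR element equals the true stage value exactly.
    p_fid: float = 0.7
    #: Per-stage success probability slope for FAQ items (binomial(4, .)).
    faq_base: float = 0.10
    faq_slope: float = 0.18
    #: Bernoulli rate for stage-independent GDS items.
    gds_rate: float = 0.30
    #: Categories whose emissions carry stage signal.
    signal_categories: tuple[str, ...] = ("CDR", "FAQ", "physical")
    #: Apply the schema's per-feature missingness rates.
    inject_missing: bool = True

    def validate(self) -> None:
        for name in ("first_stage_probs", "visit_count_probs", "interval_probs"):
            p = np.asarray(getattr(self, name), dtype=float)
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
                raise ValueError(f"{name} is not a probability vector")
        if len(self.visit_count_probs) != len(VISIT_COUNT_SUPPORT):
            raise ValueError("visit_count_probs must live on {3..12}")
        if not 0.0 <= self.p_fid <= 1.0:
            raise ValueError("p_fid must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Validation and elementary samplers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatrixReport:
    passed: bool
    problems: tuple[str, ...]
    row_sums: tuple[float, ...]


def validate_transition_matrix(P: np.ndarray, tol: float = 5e-4) -> MatrixReport:
    """Check that P is a nonnegative 5x5 matrix with rows summing to 1.

    The tolerance accommodates four-decimal rounding of the printed rows.
    """
    P = np.asarray(P, dtype=float)
    problems: list[str] = []
    if P.shape != (N_STAGES, N_STAGES):
        problems.append(f"shape {P.shape}, expected {(N_STAGES, N_STAGES)}")
        return MatrixReport(False, tuple(problems), ())
    if np.any(P < 0):
        problems.append("negative entries present")
    sums = P.sum(axis=1)
    for s, total in enumerate(sums):
        if abs(total - 1.0) > tol:
            problems.append(f"row {s} (stage {STAGES[s]}) sums to {total:.6f}")
    return MatrixReport(not problems, tuple(problems), tuple(float(x) for x in sums))


def sample_visit_count(config: CohortConfig, rng: np.random.Generator,
                       size: int | None = None):
    """Draw observed-visit counts N from the packaged distribution on {3..12}."""
    draws = rng.choice(VISIT_COUNT_SUPPORT, size=size, p=config.visit_count_probs)
    return draws


def sample_intervals(config: CohortConfig, rng: np.random.Generator,
                     count: int) -> np.ndarray:
    """Draw inter-visit intervals (months) from the packaged distribution."""
    if count < 1:
        raise ValueError("count must be >= 1")
    return rng.choice(INTERVAL_SUPPORT, size=count, p=config.interval_probs)


def modulation_factor(intervals: np.ndarray, strength: float = 4.0,
                      sharpness: float = 3.0) -> np.ndarray:
    """Multiplier on worsening probabilities under interval modulation.

    A logistic ramp in the scaled interval x = (dt - 12)/12 on a log
    multiplier scale: strength ** (2*logistic(sharpness * x) - 1). Equals
    1 at the modal 12-month interval, approaches ``strength`` for very
    long gaps and 1/strength for the shortest admissible gap, so longer
    gaps between visits carry a genuinely higher worsening probability.
    """
    x = (np.asarray(intervals, dtype=float) - 12.0) / 12.0
    return strength ** (2.0 * expit(sharpness * x) - 1.0)


def _modulated_rows(P: np.ndarray, states: np.ndarray,
                    factors: np.ndarray) -> np.ndarray:
    """Per-patient transition rows with worsening entries scaled and renormalised."""
    rows = P[states].copy()  # (n, 5)
    col = np.arange(N_STAGES)
    worsening = col[None, :] > states[:, None]
    rows[worsening] *= np.repeat(factors, worsening.sum(axis=1))
    rows /= rows.sum(axis=1, keepdims=True)
    return rows


def simulate_stage_path(P: np.ndarray, first_stage_probs: np.ndarray,
                        n_stages: int, intervals: np.ndarray,
                        config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Simulate one stage-index path of length ``n_stages``.

    Transition k -> k+1 uses the row of P for the current stage, optionally
    modulated by the interval between those visits.
    """
    path = np.empty(n_stages, dtype=np.int64)
    path[0] = rng.choice(N_STAGES, p=first_stage_probs)
    for k in range(n_stages - 1):
        row = P[path[k]]
        if config.interval_modulation:
            factors = modulation_factor(intervals[k:k + 1],
                                        config.modulation_strength,
                                        config.modulation_sharpness)
            row = _modulated_rows(P, path[k:k + 1], factors)[0]
        path[k + 1] = rng.choice(N_STAGES, p=row)
    return path


def _simulate_paths_vectorized(P: np.ndarray, config: CohortConfig,
                               lengths: np.ndarray, intervals: np.ndarray,
                               rng: np.random.Generator) -> np.ndarray:
    """Stage paths for all patients at once, advanced step-by-step.

    ``lengths`` holds per-patient path lengths (N observed + 1 held out);
    ``intervals`` is (n_patients, max_transitions), padded with zeros.
    Returns (n_patients, max_len) of stage indices, -1 past each path end.
    """
    n = len(lengths)
    max_len = int(lengths.max())
    paths = np.full((n, max_len), -1, dtype=np.int64)
    u0 = rng.random(n)
    cum0 = np.cumsum(config.first_stage_probs)
    paths[:, 0] = np.searchsorted(cum0, u0, side="right").clip(0, N_STAGES - 1)
    for k in range(max_len - 1):
        active = lengths > k + 1
        if not active.any():
            break
        states = paths[active, k]
        if config.interval_modulation:
            factors = modulation_factor(intervals[active, k],
                                        config.modulation_strength,
                                        config.modulation_sharpness)
            rows = _modulated_rows(P, states, factors)
        else:
            rows = P[states]
        u = rng.random(active.sum())
        cum = np.cumsum(rows, axis=1)
        nxt = (cum < u[:, None]).sum(axis=1).clip(0, N_STAGES - 1)
        paths[np.where(active)[0], k + 1] = nxt
    return paths


def bayes_accuracy(P: np.ndarray, state_dist: np.ndarray) -> float:
    """Best achievable next-stage accuracy when the current stage is known.

    With the current stage distributed as ``state_dist``, an oracle that
    predicts the modal row entry of P attains sum_s pi_s * max_s' P[s, s'].
    """
    P = np.asarray(P, dtype=float)
    pi = np.asarray(state_dist, dtype=float)
    if abs(pi.sum() - 1.0) > 1e-6:
        raise ValueError("state_dist must sum to 1")
    return float(pi @ P.max(axis=1))


# ---------------------------------------------------------------------------
# Feature emission (vectorised over all visits)
# ---------------------------------------------------------------------------

_STATIC_CONT_PARAMS = {"BASEAGE": (75.0, 8.0), "EDUC": (14.0, 3.0)}

_PHYS_CONT_PARAMS = {
    "HEIGHT": (165.0, 10.0), "WEIGHT": (72.0, 12.0), "BMI": (26.0, 4.0),
    "BPSYS": (132.0, 15.0), "BPDIAS": (78.0, 10.0), "HRATE": (70.0, 9.0),
    "GAITSPD": (1.0, 0.2),
}

#: MMSE declines with stage when physical features carry signal.
_MMSE_BY_STAGE = 28.5 - 3.2 * np.arange(N_STAGES)


def _emit_columns(schema: SchemaTable, stage_idx: np.ndarray,
                  patient_row_index: np.ndarray, n_patients: int,
                  config: CohortConfig, rng: np.random.Generator
                  ) -> dict[str, np.ndarray]:
    """Emit every feature column for all visit rows at once.

    ``stage_idx`` is the per-row true stage index; ``patient_row_index``
    maps each row to its patient (used to broadcast per-patient statics).
    """
    n_rows = len(stage_idx)
    stage_values = np.asarray(STAGES)
    cols: dict[str, np.ndarray] = {}
    cdr_signal = "CDR" in config.signal_categories
    faq_signal = "FAQ" in config.signal_categories
    phys_signal = "physical" in config.signal_categories

    for f in schema.features:
        if f.category == "time_interval":
            continue  # filled by the caller from the sampled intervals
        if f.temporal_behavior == "static":
            if f.dtype == "continuous":
                mu, sd = _STATIC_CONT_PARAMS.get(f.name, (0.0, 1.0))
                per_patient = rng.normal(mu, sd, size=n_patients)
            else:
                per_patient = rng.choice(np.asarray(f.levels), size=n_patients)
            cols[f.name] = per_patient[patient_row_index]
        elif f.category == "CDR":
            if f.name == "CDRSUM":
                continue  # derived below from the six standard elements
            if cdr_signal:
                keep = rng.random(n_rows) < config.p_fid
                shift = rng.choice([-1, 1], size=n_rows)
                idx = np.where(keep, stage_idx,
                               np.clip(stage_idx + shift, 0, N_STAGES - 1))
            else:
                idx = rng.integers(0, N_STAGES, size=n_rows)
            cols[f.name] = stage_values[idx]
        elif f.category == "FAQ":
            if faq_signal:
                p = config.faq_base + config.faq_slope * stage_idx
            else:
                p = np.full(n_rows, 0.3)
            cols[f.name] = rng.binomial(4, np.clip(p, 0.0, 1.0)).astype(float)
        elif f.category == "GDS":
            if f.name == "GDSTOTAL":
                continue  # derived below
            cols[f.name] = rng.binomial(1, config.gds_rate, size=n_rows).astype(float)
        elif f.category == "physical":
            if f.dtype == "continuous":
                if f.name == "MMSE":
                    base = rng.normal(0.0, 1.0, size=n_patients)[patient_row_index]
                    center = (_MMSE_BY_STAGE[stage_idx] if phys_signal
                              else np.full(n_rows, 24.0))
                    cols[f.name] = center + base + rng.normal(0.0, 1.5, size=n_rows)
                else:
                    mu, sd = _PHYS_CONT_PARAMS[f.name]
                    baseline = rng.normal(mu, sd, size=n_patients)
                    cols[f.name] = (baseline[patient_row_index]
                                    + rng.normal(0.0, sd * 0.05, size=n_rows))
            else:
                cols[f.name] = rng.choice(np.asarray(f.levels), size=n_rows)
        else:  # dynamic features of other categories: uninformative noise
            if f.dtype == "continuous":
                cols[f.name] = rng.normal(0.0, 1.0, size=n_rows)
            else:
                cols[f.name] = rng.choice(np.asarray(f.levels), size=n_rows)

    if any(f.name == "CDRSUM" for f in schema.features):
        cols["CDRSUM"] = np.sum(
            [cols[e] for e in CDR_STANDARD_ELEMENTS], axis=0).astype(float)
    if any(f.name == "GDSTOTAL" for f in schema.features):
        cols["GDSTOTAL"] = np.sum([cols[i] for i in GDS_ITEMS], axis=0).astype(float)
    return cols


def emit_visit_features(stage_idx: int, schema: SchemaTable,
                        rng: np.random.Generator,
                        patient_statics: Mapping[str, float] | None = None,
                        config: CohortConfig | None = None) -> dict[str, float]:
    """Emit one visit's feature map for a single patient (convenience path).

    Static features are taken from ``patient_statics`` when provided so
    they stay constant across a patient's visits.
    """
    config = config or CohortConfig()
    cols = _emit_columns(schema, np.array([stage_idx]), np.array([0]), 1,
                         config, rng)
    values = {name: float(arr[0]) for name, arr in cols.items()}
    if patient_statics:
        for f in schema.features:
            if f.temporal_behavior == "static" and f.name in patient_statics:
                values[f.name] = patient_statics[f.name]
        if "CDRSUM" in values:
            values["CDRSUM"] = float(sum(values[e] for e in CDR_STANDARD_ELEMENTS))
    return values


def draw_patient_statics(schema: SchemaTable,
                         rng: np.random.Generator) -> dict[str, float]:
    """Draw one patient's static feature values."""
    statics: dict[str, float] = {}
    for f in schema.features:
        if f.temporal_behavior != "static":
            continue
        if f.dtype == "continuous":
            mu, sd = _STATIC_CONT_PARAMS.get(f.name, (0.0, 1.0))
            statics[f.name] = float(rng.normal(mu, sd))
        else:
            statics[f.name] = float(rng.choice(np.asarray(f.levels)))
    return statics


# ---------------------------------------------------------------------------
# Missingness injection
# ---------------------------------------------------------------------------


def inject_missingness(visits: pd.DataFrame, schema: SchemaTable,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Blank each feature cell independently at the feature's missing rate.

    The label and the time-interval feature are never blanked.
    """
    out = visits.copy()
    for f in schema.features:
        if f.category == "time_interval" or f.missing_rate <= 0:
            continue
        mask = rng.random(len(out)) < f.missing_rate
        out.loc[mask, f.name] = np.nan
    return out


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


@dataclass
class CohortResult:
    """Simulated cohort: observed visit table, ground truth, complete table."""

    visits: pd.DataFrame  #: observed table, with missingness injected
    truth: pd.DataFrame   #: patient_id, current/true-next stage, pred interval
    complete: pd.DataFrame  #: pre-missingness visit table
    schema: SchemaTable
    config: CohortConfig


def simulate_cohort(config: CohortConfig,
                    schema: SchemaTable | None = None) -> CohortResult:
    """Simulate a full cohort; deterministic given ``config.seed``.

    Per patient: an observed-visit count N ~ packaged distribution, N
    intervals (the last is the prediction interval to the held-out visit),
    a stage path of length N+1 from the transition matrix, stage-linked
    feature emissions for the N observed visits, then per-feature
    missingness. The held-out (N+1)-th stage goes to the ground-truth
    table only.
    """
    config.validate()
    schema = schema or default_schema()
    report = validate_transition_matrix(TRANSITION_MATRIX)
    if not report.passed:
        raise RuntimeError(f"packaged transition matrix invalid: {report.problems}")

    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_path, rng_emit, rng_miss = (
        np.random.default_rng(child) for child in ss.spawn(4))

    n = config.n_patients
    counts = sample_visit_count(config, rng_struct, size=n)  # observed visits
    lengths = counts + 1  # + held-out next visit
    max_trans = int(lengths.max()) - 1
    intervals = np.zeros((n, max_trans), dtype=np.int64)
    for k in range(max_trans):
        need = counts > k  # interval k exists for patients with > k transitions
        intervals[need, k] = sample_intervals(config, rng_struct, int(need.sum()))

    paths = _simulate_paths_vectorized(TRANSITION_MATRIX, config, lengths,
                                       intervals, rng_path)

    # flatten observed visits into row arrays
    patient_row_index = np.repeat(np.arange(n), counts)
    visit_index = np.concatenate([np.arange(1, c + 1) for c in counts])
    stage_idx = paths[patient_row_index, visit_index - 1]
    # month offsets: cumulative intervals before each visit
    cum = np.cumsum(intervals, axis=1)
    offsets = np.where(visit_index == 1, 0,
                       cum[patient_row_index, np.maximum(visit_index - 2, 0)])
    # time-interval feature at visit j is the interval to the next visit;
    # for the last observed visit it is the prediction interval.
    ti = intervals[patient_row_index, visit_index - 1]

    cols = _emit_columns(schema, stage_idx, patient_row_index, n,
                         config, rng_emit)
    pid = np.array([f"P{i:06d}" for i in range(n)])
    frame = {
        "patient_id": pid[patient_row_index],
        "visit_index": visit_index,
        "month_offset": offsets,
    }
    for f in schema.features:
        if f.category == "time_interval":
            frame[f.name] = ti.astype(float)
        else:
            frame[f.name] = cols[f.name]
    frame[schema.label_name] = np.asarray(STAGES)[stage_idx]
    complete = pd.DataFrame(frame)

    visits = (inject_missingness(complete, schema, rng_miss)
              if config.inject_missing else complete.copy())

    last = counts - 1
    truth = pd.DataFrame({
        "patient_id": pid,
        "current_stage": np.asarray(STAGES)[paths[np.arange(n), last]],
        "true_next_stage": np.asarray(STAGES)[paths[np.arange(n), counts]],
        "prediction_interval": intervals[np.arange(n), last].astype(float),
    })
    return CohortResult(visits=visits, truth=truth, complete=complete,
                        schema=schema, config=config)
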