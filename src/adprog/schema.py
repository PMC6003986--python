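"""Feature dictionary, stage coding, and the visit/trajectory data model.

The cohort abstraction used throughout the package: one row per patient
visit carrying 77 mixed-type clinical features plus a derived *time
interval* feature (whole months between successive visits), labelled with
the Global Clinical Dementia Rating score (CDRGLOB) in {0, 0.5, 1, 2, 3}.
The packaged fixture schema allocates the 78 predictors across seven
categories (demographics, health history, physical, CDR, GDS, FAQ, time
interval) so that one-hot encoding of the categoricals expands the row to
exactly 234 columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

# ---------------------------------------------------------------------------
# Stage coding
# ---------------------------------------------------------------------------

#: Admissible Global CDR scores, ordered from no impairment to severe.
STAGES: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 3.0)

N_STAGES = len(STAGES)

LABEL_NAME = "CDRGLOB"

CATEGORIES = (
    "demographics",
    "health_history",
    "physical",
    "CDR",
    "GDS",
    "FAQ",
    "time_interval",
)

DTYPES = ("continuous", "ordinal", "nominal")

TEMPORAL_BEHAVIORS = ("static", "dynamic", "patient_specific_dynamic")

#: Scale shared by the eight CDR rating elements.
CDR_ELEMENT_LEVELS: tuple[float, ...] = STAGES

#: The six standard CDR elements whose scores sum to CDRSUM.
CDR_STANDARD_ELEMENTS = (
    "MEMORY",
    "ORIENT",
    "JUDGMENT",
    "COMMUN",
    "HOMEHOBB",
    "PERSCARE",
)

TIME_INTERVAL_NAME = "TIMEINTERVAL"


@dataclass(frozen=True)
class StageLabel:
    """A Global CDR score together with its ordinal index and one-hot form."""

    cdrglob: float
    index: int
    onehot: tuple[int, ...]


def encode_stage(cdrglob: float) -> StageLabel:
    """Map a Global CDR score to its stage index and 5-dim one-hot vector.

    Raises ``ValueError`` for any value outside {0, 0.5, 1, 2, 3}.
    """
    value = float(cdrglob)
    try:
        index = STAGES.index(value)
    except ValueError:
        raise ValueError(
            f"{cdrglob!r} is not an admissible Global CDR score; "
            f"expected one of {STAGES}"
        ) from None
    onehot = tuple(1 if i == index else 0 for i in range(N_STAGES))
    return StageLabel(cdrglob=value, index=index, onehot=onehot)


def decode_stage(index: int) -> float:
    """Inverse of :func:`encode_stage` on the index component."""
    if not 0 <= index < N_STAGES:
        raise ValueError(f"stage index {index} outside 0..{N_STAGES - 1}")
    return STAGES[index]


# ---------------------------------------------------------------------------
# Feature dictionary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureSpec:
    """One predictor: its type, category, temporal behaviour and levels.

    ``temporal_behavior`` selects the imputation pool: ``static`` features
    do not change across visits (pool: first visits of all patients),
    ``dynamic`` features change (pool: all visits of all patients), and
    ``patient_specific_dynamic`` features change but are only meaningful
    within a patient (pool: other visits of the same patient).
    """

    name: str
    category: str
    dtype: str
    temporal_behavior: str
    levels: tuple[float, ...] | None = None
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for {self.name}")
        if self.dtype not in DTYPES:
            raise ValueError(f"unknown dtype {self.dtype!r} for {self.name}")
        if self.temporal_behavior not in TEMPORAL_BEHAVIORS:
            raise ValueError(
                f"unknown temporal behavior {self.temporal_behavior!r} for {self.name}"
            )

    @property
    def is_categorical(self) -> bool:
        return self.dtype in ("ordinal", "nominal")

    @property
    def encoded_width(self) -> int:
        """Columns this feature occupies after one-hot encoding."""
        return len(self.levels) if self.is_categorical else 1


@dataclass(frozen=True)
class ValidationReport:
    passed: bool
    problems: tuple[str, ...]
    n_features: int
    encoded_width: int


@dataclass(frozen=True)
class SchemaTable:
    """Ordered feature dictionary plus the label column name."""

    features: tuple[FeatureSpec, ...]
    label_name: str = LABEL_NAME

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in schema")

    # -- lookups ----------------------------------------------------------

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features)

    def feature(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def category_features(self, category: str) -> tuple[FeatureSpec, ...]:
        return tuple(f for f in self.features if f.category == category)

    @property
    def encoded_width(self) -> int:
        return sum(f.encoded_width for f in self.features)

    def block_offsets(self) -> dict[str, tuple[int, int]]:
        """Map feature name -> (column offset, width) in the encoded row."""
        offsets: dict[str, tuple[int, int]] = {}
        pos = 0
        for f in self.features:
            offsets[f.name] = (pos, f.encoded_width)
            pos += f.encoded_width
        return offsets

    # -- derivation -------------------------------------------------------

    def without_categories(self, categories: Iterable[str],
                           keep: Iterable[str] = ()) -> "SchemaTable":
        """Drop all features of the given categories, except names in ``keep``.

        Used by the ablation harness; the time-interval feature and the
        basic-information categories are never dropped this way.
        """
        drop = set(categories)
        keep_names = set(keep)
        kept = tuple(
            f for f in self.features
            if f.category not in drop or f.name in keep_names
        )
        if not kept:
            raise ValueError("schema would be empty after category removal")
        return SchemaTable(features=kept, label_name=self.label_name)

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "label_name": self.label_name,
            "features": [
                {
                    "name": f.name,
                    "category": f.category,
                    "dtype": f.dtype,
                    "temporal_behavior": f.temporal_behavior,
                    "levels": list(f.levels) if f.levels is not None else None,
                    "missing_rate": f.missing_rate,
                }
                for f in self.features
            ],
        }
        return json.dumps(doc, indent=1)

    @staticmethod
    def from_json(text: str) -> "SchemaTable":
        doc = json.loads(text)
        feats = tuple(
            FeatureSpec(
                name=d["name"],
                category=d["category"],
                dtype=d["dtype"],
                temporal_behavior=d["temporal_behavior"],
                levels=tuple(d["levels"]) if d.get("levels") is not None else None,
                missing_rate=float(d.get("missing_rate", 0.0)),
            )
            for d in doc["features"]
        )
        return SchemaTable(features=feats, label_name=doc.get("label_name", LABEL_NAME))


def validate_schema(schema: SchemaTable) -> ValidationReport:
    """Check the study's structural constraints on a feature dictionary.

    Passes iff the raw feature count is 78 (time interval included), the
    one-hot encoded width is 234, the CDR category holds 9 features and the
    FAQ category 10, and every feature's own invariants hold.
    """
    problems: list[str] = []
    n = len(schema.features)
    if n != 78:
        problems.append(f"raw feature count is {n}, expected 78")
    width = schema.encoded_width
    if width != 234:
        problems.append(f"encoded width is {width}, expected 234")
    n_cdr = len(schema.category_features("CDR"))
    if n_cdr != 9:
        problems.append(f"CDR category has {n_cdr} features, expected 9")
    n_faq = len(schema.category_features("FAQ"))
    if n_faq != 10:
        problems.append(f"FAQ category has {n_faq} features, expected 10")
    ti = [f for f in schema.features if f.category == "time_interval"]
    if len(ti) != 1:
        problems.append(f"expected exactly one time-interval feature, got {len(ti)}")
    for f in schema.features:
        if f.dtype == "continuous" and f.levels is not None:
            problems.append(f"continuous feature {f.name} declares levels")
        if f.is_categorical and (f.levels is None or len(f.levels) < 2):
            problems.append(f"categorical feature {f.name} has <2 levels")
        if not 0.0 <= f.missing_rate <= 0.30:
            problems.append(
                f"feature {f.name} missing_rate {f.missing_rate} outside [0, 0.30]"
            )
    return ValidationReport(
        passed=not problems,
        problems=tuple(problems),
        n_features=n,
        encoded_width=width,
    )


# ---------------------------------------------------------------------------
# Packaged fixture schema
# ---------------------------------------------------------------------------

# Missing-data band representatives: one rate per band of the study's
# missingness profile (<=5%, 5-10%, 10-15%, 15-20%, 20-25%, 25-30%).
_BAND = {1: 0.03, 2: 0.08, 3: 0.13, 4: 0.18, 5: 0.23, 6: 0.28}


def default_schema() -> SchemaTable:
    """The packaged 78-feature fixture schema (encoded width 234).

    Allocation: time interval 1 continuous; demographics 10 (2 continuous,
    8 categoricals); health history 25 (20 binary, 5 five-level ordinals);
    physical 12 (8 continuous incl. MMSE, 4 categoricals); CDR 9 (8
    five-level ordinal elements, CDRSUM continuous); GDS 11 (10 binary
    items, total score continuous); FAQ 10 (five-level ordinals).
    """
    feats: list[FeatureSpec] = []

    def cont(name, cat, tb, band):
        feats.append(FeatureSpec(name, cat, "continuous", tb,
                                 missing_rate=_BAND[band]))

    def catf(name, cat, dtype, tb, levels, band):
        feats.append(FeatureSpec(name, cat, dtype, tb, levels=tuple(levels),
                                 missing_rate=_BAND[band]))

    # time interval: derived, never missing
    feats.append(FeatureSpec(TIME_INTERVAL_NAME, "time_interval",
                             "continuous", "dynamic", missing_rate=0.0))

    # demographics: static, 2 continuous + 8 categoricals (levels 2,6,2,6,5,4,4,3)
    cont("BASEAGE", "demographics", "static", 1)
    cont("EDUC", "demographics", "static", 1)
    catf("SEX", "demographics", "nominal", "static", range(2), 1)
    catf("RACE", "demographics", "nominal", "static", range(6), 1)
    catf("HISPANIC", "demographics", "nominal", "static", range(2), 1)
    catf("MARISTAT", "demographics", "nominal", "static", range(6), 1)
    catf("LIVSIT", "demographics", "nominal", "static", range(5), 1)
    catf("INDEPEND", "demographics", "ordinal", "static", range(4), 1)
    catf("RESIDENC", "demographics", "nominal", "static", range(4), 1)
    catf("HANDED", "demographics", "nominal", "static", range(3), 1)

    # health history: static, 20 binary + 5 five-level ordinals
    binary_hist = (
        "CVHATT", "CVAFIB", "CVANGIO", "CVBYPASS", "CVPACE", "CVCHF",
        "CVOTHR", "CBSTROKE", "CBTIA", "SEIZURES", "TRAUMBRF", "TRAUMEXT",
        "TRAUMCHR", "NCOTHR", "HYPERTEN", "HYPERCHO", "DIABETES", "B12DEF",
        "THYROID", "INCONTU",
    )
    for name in binary_hist:
        catf(name, "health_history", "nominal", "static", range(2), 2)
    catf("ALCFREQ", "health_history", "ordinal", "static", range(5), 3)
    for name in ("TOBACFREQ", "DEPSEV", "ANXSEV", "SLEEPDIS"):
        catf(name, "health_history", "ordinal", "static", range(5), 4)

    # physical: 8 continuous (patient-specific dynamic) + 4 categoricals (dynamic)
    for name in ("HEIGHT", "WEIGHT", "BMI", "BPSYS", "BPDIAS", "HRATE",
                 "MMSE", "GAITSPD"):
        cont(name, "physical", "patient_specific_dynamic", 1)
    catf("HEARAID", "physical", "nominal", "dynamic", range(2), 2)
    catf("VISION", "physical", "ordinal", "dynamic", range(3), 3)
    catf("GAIT", "physical", "ordinal", "dynamic", range(4), 3)
    catf("MOBILITY", "physical", "ordinal", "dynamic", range(5), 3)

    # CDR: 8 five-level ordinal elements + CDRSUM continuous, all dynamic
    for name in CDR_STANDARD_ELEMENTS + ("COMPORT", "CDRLANG"):
        catf(name, "CDR", "ordinal", "dynamic", CDR_ELEMENT_LEVELS, 1)
    cont("CDRSUM", "CDR", "dynamic", 1)

    # GDS: 10 binary items + total score, all dynamic
    gds_items = (
        "SATIS", "DROPACT", "EMPTY", "BORED", "SPIRITS", "AFRAID",
        "HAPPY", "HELPLESS", "STAYHOME", "MEMPROB",
    )
    for name in gds_items:
        catf(name, "GDS", "nominal", "dynamic", range(2), 6)
    cont("GDSTOTAL", "GDS", "dynamic", 6)

    # FAQ: ten five-level ordinal items, dynamic
    faq_bands = {
        "BILLS": 4, "TAXES": 4, "SHOPPING": 5, "GAMES": 5, "STOVE": 5,
        "MEALPREP": 5, "EVENTS": 5, "PAYATTN": 5, "REMDATES": 6, "TRAVEL": 6,
    }
    for name, band in faq_bands.items():
        catf(name, "FAQ", "ordinal", "dynamic", range(5), band)

    return SchemaTable(features=tuple(feats))


#: Names of the GDS item features in the fixture schema (used by the simulator).
GDS_ITEMS = (
    "SATIS", "DROPACT", "EMPTY", "BORED", "SPIRITS", "AFRAID",
    "HAPPY", "HELPLESS", "STAYHOME", "MEMPROB",
)

#: Names of the FAQ item features in the fixture schema.
FAQ_ITEMS = (
    "BILLS", "TAXES", "SHOPPING", "GAMES", "STOVE",
    "MEALPREP", "EVENTS", "PAYATTN", "REMDATES", "TRAVEL",
)


# ---------------------------------------------------------------------------
# Visits and trajectories
# ---------------------------------------------------------------------------


@dataclass
class VisitRecord:
    """One patient-visit: feature values (possibly missing) plus the label."""

    patient_id: str
    visit_index: int  # 1-based
    month_offset: int
    values: dict[str, float]
    label: StageLabel | None = None


@dataclass
class PatientTrajectory:
    """A patient's ordered visits; offsets strictly increasing in months."""

    patient_id: str
    visits: list[VisitRecord] = field(default_factory=list)

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    @property
    def month_offsets(self) -> list[int]:
        return [v.month_offset for v in self.visits]


def derive_intervals(offsets: "Sequence[float] | PatientTrajectory") -> list[float]:
    """Time intervals (months) between successive visit offsets.

    Accepts a trajectory or a plain offset sequence. Returns N-1 intervals
    for N visits; the prediction interval to the future visit is supplied
    separately at prediction time. Rejects non-increasing offsets.
    """
    if isinstance(offsets, PatientTrajectory):
        offsets = offsets.month_offsets
    if len(offsets) < 2:
        raise ValueError("need at least 2 visits to derive intervals")
    deltas = [float(b) - float(a) for a, b in zip(offsets[:-1], offsets[1:])]
    if any(d <= 0 for d in deltas):
        raise ValueError(f"visit month offsets must be strictly increasing: {list(offsets)}")
    return deltas


def months_between(days: float) -> int:
    """Whole-month rounding (half-up) of a day count, 30.44 days/month."""
    months = days / 30.44
    return int(np.floor(months + 0.5))
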