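import numpy as np
import pandas as pd
import pytest

from adprog import (
    PreprocessPipeline,
    apply_normalizer,
    assemble_model_inputs,
    build_imputation_plan,
    fit_normalizer,
    impute,
    one_hot_encode,
)
from adprog.preprocess import decode_onehot_block
from adprog.schema import FeatureSpec, SchemaTable


@pytest.fixture()
def mini_schema():
    """One feature per imputation-grid cell plus the time interval."""
    return SchemaTable(features=(
        FeatureSpec("TIMEINTERVAL", "time_interval", "continuous", "dynamic"),
        FeatureSpec("AGE", "demographics", "continuous", "static"),
        FeatureSpec("COLOR", "physical", "nominal", "dynamic",
                    levels=(0, 1, 2)),
        FeatureSpec("SCORE", "FAQ", "ordinal", "patient_specific_dynamic",
                    levels=(0, 1, 2, 3, 4)),
        FeatureSpec("WEIGHT", "physical", "continuous",
                    "patient_specific_dynamic"),
    ))


@pytest.fixture()
def mini_visits():
    return pd.DataFrame({
        "patient_id": ["a", "a", "a", "b", "b", "b"],
        "visit_index": [1, 2, 3, 1, 2, 3],
        "month_offset": [0, 12, 24, 0, 6, 18],
        "TIMEINTERVAL": [12, 12, 12, 6, 12, 12],
        "AGE": [70, 70, 70, np.nan, 80, 80],
        "COLOR": [0, 1, np.nan, 1, 1, 2],
        "SCORE": [1, np.nan, 3, 2, 2, np.nan],
        "WEIGHT": [5, np.nan, 7, 60, 60, 60],
    })


def test_plan_follows_type_by_behavior_grid(mini_visits, mini_schema):
    plan = build_imputation_plan(mini_visits, mini_schema)
    assert (plan.rule("AGE").statistic, plan.rule("AGE").pool) == (
        "mean", "first_visits_all_patients")
    assert (plan.rule("COLOR").statistic, plan.rule("COLOR").pool) == (
        "mode", "all_visits_all_patients")
    assert (plan.rule("SCORE").statistic, plan.rule("SCORE").pool) == (
        "median", "other_visits_same_patient")
    assert (plan.rule("WEIGHT").statistic, plan.rule("WEIGHT").pool) == (
        "mean", "other_visits_same_patient")


def test_impute_fill_values(mini_visits, mini_schema):
    plan = build_imputation_plan(mini_visits, mini_schema)
    done = impute(mini_visits, plan, mini_schema)
    assert done.notna().all().all()
    # static continuous: mean of first visits (70 only, b's first is missing)
    assert done.loc[3, "AGE"] == 70
    # nominal dynamic: mode over all visits = 1
    assert done.loc[2, "COLOR"] == 1
    # patient-specific continuous: mean of the patient's other visits
    assert done.loc[1, "WEIGHT"] == 6
    # patient-specific ordinal: lower median of a's {1, 3} is 1
    assert done.loc[1, "SCORE"] == 1
    # observed cells unchanged
    assert done.loc[4, "AGE"] == 80


def test_impute_is_idempotent(mini_visits, mini_schema):
    plan = build_imputation_plan(mini_visits, mini_schema)
    once = impute(mini_visits, plan, mini_schema)
    twice = impute(once, plan, mini_schema)
    pd.testing.assert_frame_equal(once, twice)


def test_patient_specific_fallback_to_global(mini_schema):
    v = pd.DataFrame({
        "patient_id": ["a", "a", "b", "b"],
        "visit_index": [1, 2, 1, 2],
        "month_offset": [0, 12, 0, 12],
        "TIMEINTERVAL": [12, 12, 12, 12],
        "AGE": [70, 70, 80, 80],
        "COLOR": [0, 0, 0, 0],
        "SCORE": [1, 1, np.nan, np.nan],
        "WEIGHT": [5.0, 5.0, np.nan, np.nan],
    })
    plan = build_imputation_plan(v, mini_schema)
    done = impute(v, plan, mini_schema)
    # patient b has no observed WEIGHT: global all-visits mean = 5
    assert (done.loc[done.patient_id == "b", "WEIGHT"] == 5.0).all()


def test_plan_rejects_feature_with_no_observations(mini_schema):
    v = pd.DataFrame({
        "patient_id": ["a"], "visit_index": [1], "month_offset": [0],
        "TIMEINTERVAL": [12.0], "AGE": [np.nan], "COLOR": [0],
        "SCORE": [1], "WEIGHT": [5.0],
    })
    with pytest.raises(ValueError, match="AGE"):
        build_imputation_plan(v, mini_schema)


def test_normalizer_population_zscores(mini_visits, mini_schema):
    plan = build_imputation_plan(mini_visits, mini_schema)
    done = impute(mini_visits, plan, mini_schema)
    done.loc[:, "WEIGHT"] = [1, 2, 3, 1, 2, 3]
    norm = fit_normalizer(done, mini_schema)
    out = apply_normalizer(done, norm)
    expected = np.array([-1.22474487, 0.0, 1.22474487] * 2)
    np.testing.assert_allclose(out["WEIGHT"], expected, atol=1e-8)
    # training-fold transform has mean 0 variance 1
    assert out["WEIGHT"].mean() == pytest.approx(0.0, abs=1e-8)
    assert np.var(out["WEIGHT"]) == pytest.approx(1.0, abs=1e-8)
    # categoricals untouched
    pd.testing.assert_series_equal(out["COLOR"], done["COLOR"])
    # time interval passed raw by default
    pd.testing.assert_series_equal(out["TIMEINTERVAL"], done["TIMEINTERVAL"])


def test_normalizer_rejects_constant_feature(mini_visits, mini_schema):
    plan = build_imputation_plan(mini_visits, mini_schema)
    done = impute(mini_visits, plan, mini_schema)
    done.loc[:, "WEIGHT"] = 7.0
    with pytest.raises(ValueError, match="WEIGHT"):
        fit_normalizer(done, mini_schema)


def test_one_hot_width_and_blocks(schema, clean_cohort):
    v = clean_cohort.complete.head(50)
    X = one_hot_encode(v, schema)
    assert X.shape == (50, 234)
    offsets = schema.block_offsets()
    for f in schema.features:
        start, width = offsets[f.name]
        if f.is_categorical:
            np.testing.assert_allclose(X[:, start:start + width].sum(axis=1), 1.0)


def test_one_hot_five_level_block_and_round_trip(schema, clean_cohort):
    v = clean_cohort.complete.head(5).copy()
    v.loc[:, "BILLS"] = 2.0  # third of the five levels
    X = one_hot_encode(v, schema)
    start, width = schema.block_offsets()["BILLS"]
    np.testing.assert_array_equal(X[0, start:start + width], [0, 0, 1, 0, 0])
    assert decode_onehot_block(X[0, start:start + width],
                               schema.feature("BILLS")) == 2.0


def test_one_hot_rejects_out_of_vocabulary(schema, clean_cohort):
    v = clean_cohort.complete.head(5).copy()
    v.loc[:, "BILLS"] = 7.0
    with pytest.raises(ValueError, match="BILLS"):
        one_hot_encode(v, schema)


def _toy_encoded(schema, cohort, include_ti=True):
    pipeline = PreprocessPipeline.fit(cohort.visits, schema)
    return pipeline, pipeline.encode(cohort.visits, cohort.truth,
                                     include_time_intervals=include_ti)


def test_assembled_interval_column(schema):
    """The interval column holds months-to-next-visit, then the horizon."""
    from adprog import CohortConfig, simulate_cohort

    cohort = simulate_cohort(CohortConfig(n_patients=20, seed=2))
    pipeline, ds = _toy_encoded(schema, cohort)
    truth = cohort.truth.set_index("patient_id")
    v = cohort.visits
    for i, pid in enumerate(ds.patient_ids[:5]):
        months = np.sort(v.loc[v.patient_id == pid, "month_offset"].to_numpy())
        n = len(months)
        expected = np.append(np.diff(months),
                             truth.loc[pid, "prediction_interval"])
        np.testing.assert_allclose(ds.X[i, :n, ds.ti_column], expected)
        # pad rows zero and masked
        assert ds.mask[i, :n].all() and not ds.mask[i, n:].any()
        np.testing.assert_allclose(ds.X[i, n:], 0.0)


def test_without_ti_zeroes_only_interval_column(schema):
    from adprog import CohortConfig, simulate_cohort

    cohort = simulate_cohort(CohortConfig(n_patients=20, seed=2))
    _, with_ti = _toy_encoded(schema, cohort, include_ti=True)
    _, without = _toy_encoded(schema, cohort, include_ti=False)
    assert np.all(without.X[..., without.ti_column] == 0)
    others = [c for c in range(234) if c != with_ti.ti_column]
    np.testing.assert_allclose(without.X[..., others], with_ti.X[..., others])


def test_assemble_rejects_missing_horizon_and_short_patients(schema, clean_cohort):
    pipeline = PreprocessPipeline.fit(clean_cohort.visits, schema)
    transformed = pipeline.transform(clean_cohort.visits)
    with pytest.raises(ValueError, match="prediction interval"):
        assemble_model_inputs(transformed, schema, {})
    short = transformed.groupby("patient_id").head(2)
    pred = {p: 12.0 for p in short.patient_id.unique()}
    with pytest.raises(ValueError, match="visits"):
        assemble_model_inputs(short, schema, pred)


def test_no_leakage_from_test_fold(schema, small_cohort):
    """Transforms of a test patient do not depend on other test patients."""
    v, t = small_cohort.visits, small_cohort.truth
    train_ids = t.patient_id[:200]
    pipeline = PreprocessPipeline.fit(
        v[v.patient_id.isin(train_ids)], schema)
    test_ids = t.patient_id[200:].tolist()
    full = pipeline.transform(v[v.patient_id.isin(test_ids)])
    one = pipeline.transform(v[v.patient_id == test_ids[0]])
    pd.testing.assert_frame_equal(
        full[full.patient_id == test_ids[0]].reset_index(drop=True),
        one.reset_index(drop=True))
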