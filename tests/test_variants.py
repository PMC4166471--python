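"""Variant validation, mutation matrices, event classes, artifact model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tumorevo.variants import (MutationMatrix, StepwiseArtifactModel,
                               ValidationStatus, assign_driver_category,
                               build_mutation_matrix, classify_artifact,
                               classify_events, mutational_load,
                               validate_variant, validation_rate)


# ---------------------------------------------------------------------------
# per-cell validation rules
# ---------------------------------------------------------------------------

def test_vaf_boundary_inclusive():
    # exactly 1% of reads validates
    assert validate_variant(depth=100, alt_count=1).status is ValidationStatus.VALIDATED


def test_low_vaf_fails():
    res = validate_variant(depth=200, alt_count=1)  # 0.5%
    assert res.status is ValidationStatus.FAILED
    assert "1%" in res.reason


def test_zero_alt_fails():
    assert validate_variant(depth=100, alt_count=0).status is ValidationStatus.FAILED


def test_depth_threshold_strict():
    res = validate_variant(depth=49, alt_count=20)
    assert res.status is ValidationStatus.INCONCLUSIVE
    assert "coverage" in res.reason
    # exactly 50x is evaluable
    assert validate_variant(depth=50, alt_count=20).status is ValidationStatus.VALIDATED


def test_malformed_counts_raise():
    with pytest.raises(ValueError):
        validate_variant(depth=-1, alt_count=0)
    with pytest.raises(ValueError):
        validate_variant(depth=100, alt_count=-2)
    with pytest.raises(ValueError):
        validate_variant(depth=10, alt_count=20)
    with pytest.raises(ValueError):
        validate_variant()


def test_mapping_and_observation_inputs():
    assert validate_variant({"depth": 100, "alt_count": 30}).status \
        is ValidationStatus.VALIDATED


@settings(max_examples=100, deadline=None)
@given(depth=st.integers(50, 1000), alt=st.integers(0, 1000), extra=st.integers(1, 50))
def test_more_alt_reads_never_demote(depth, alt, extra):
    alt = min(alt, depth)
    before = validate_variant(depth=depth, alt_count=alt).status
    after = validate_variant(depth=depth, alt_count=min(alt + extra, depth)).status
    if before is ValidationStatus.VALIDATED:
        assert after is ValidationStatus.VALIDATED


# ---------------------------------------------------------------------------
# validation rate
# ---------------------------------------------------------------------------

def test_validation_rates():
    assert validation_rate(97, 16) == 83.5
    assert validation_rate(33, 7) == 78.8
    assert validation_rate(10, 0) == 100.0


def test_validation_rate_half_up():
    # 7/8 = 87.5 stays 87.5; 1/16 failed -> 93.75 rounds half-up to 93.8
    assert validation_rate(8, 1) == 87.5
    assert validation_rate(16, 1) == 93.8


def test_validation_rate_errors():
    with pytest.raises(ValueError):
        validation_rate(0, 0)
    with pytest.raises(ValueError):
        validation_rate(10, 11)
    with pytest.raises(ValueError):
        validation_rate(10, -1)


# ---------------------------------------------------------------------------
# mutation matrix
# ---------------------------------------------------------------------------

def _calls(rows):
    return pd.DataFrame(rows, columns=["variant_id", "region", "depth", "alt_count"])


def test_build_matrix_excludes_germline():
    calls = _calls([("m1", "R1", 100, 40), ("m1", "R2", 100, 35),
                    ("g1", "R1", 100, 55), ("g1", "R2", 100, 45)])
    normal = _calls([("m1", "normal", 100, 0), ("g1", "normal", 100, 48)])
    matrix = build_mutation_matrix(calls, normal)
    assert list(matrix.somatic.index) == ["m1"]
    assert matrix.meta.loc["g1", "event_class"] == "germline"
    assert matrix.presence.loc["m1"].tolist() == [1, 1]


def test_build_matrix_drops_nowhere_validated():
    calls = _calls([("m1", "R1", 100, 40), ("m2", "R1", 100, 0),
                    ("m3", "R1", 30, 20)])  # m3 inconclusive everywhere
    matrix = build_mutation_matrix(calls)
    assert list(matrix.presence.index) == ["m1"]


def test_build_matrix_undeclared_region_errors():
    with pytest.raises(ValueError):
        build_mutation_matrix(_calls([("m1", "R1", 100, 40)]), regions=["R2"])


def test_copy_events_appended_as_cna_rows():
    calls = _calls([("m1", "R1", 100, 40), ("m1", "R2", 100, 40)])
    cn = pd.DataFrame([("loss_3p", "R1", 1), ("loss_3p", "R2", 1)],
                      columns=["event_id", "region", "present"])
    matrix = build_mutation_matrix(calls, copy_events=cn)
    assert matrix.meta.loc["loss_3p", "kind"] == "cna"
    assert matrix.somatic.loc["loss_3p"].tolist() == [1, 1]
    # CNA rows count for classification but not for mutational load
    assert "loss_3p" not in matrix.somatic_mutations().index


def test_matrix_invariants():
    presence = pd.DataFrame([[1, 0]], index=["m"], columns=["R1", "R2"])
    meta = pd.DataFrame({"kind": ["snv"], "event_class": ["somatic"]}, index=["x"])
    with pytest.raises(ValueError):
        MutationMatrix(presence, presence.astype(float), meta)


def test_restrict_drops_all_zero_rows():
    calls = _calls([("m1", "R1", 100, 40), ("m2", "R2", 100, 40)])
    matrix = build_mutation_matrix(calls)
    sub = matrix.restrict(["R1"])
    assert list(sub.presence.index) == ["m1"]


# ---------------------------------------------------------------------------
# ubiquitous/shared/private classification
# ---------------------------------------------------------------------------

def presence_matrix(n_ubiq, pattern_rows, regions):
    rows = {f"u{i}": [1] * len(regions) for i in range(n_ubiq)}
    for i, pat in enumerate(pattern_rows):
        rows[f"p{i}"] = pat
    presence = pd.DataFrame.from_dict(rows, orient="index", columns=regions)
    meta = pd.DataFrame({"kind": "snv", "event_class": "somatic"}, index=presence.index)
    return MutationMatrix(presence, presence.astype(float), meta)


def test_classify_events_fractions():
    regions = ["R1", "R2", "R3"]
    m = presence_matrix(14, [[1, 1, 0]], regions)           # 14/15 ubiquitous
    classes, frac = classify_events(m, regions)
    assert frac == 93
    assert (classes == "ubiquitous").sum() == 14
    assert classes["p0"] == "shared"

    m = presence_matrix(13, [[1, 1, 0], [1, 0, 0], [0, 0, 1]], regions)  # 13/16
    classes, frac = classify_events(m, regions)
    assert frac == 81
    assert classes["p1"] == "private"

    m = presence_matrix(5, [], regions)
    assert classify_events(m, regions)[1] == 100


def test_classify_events_errors():
    m = presence_matrix(2, [], ["R1", "R2"])
    with pytest.raises(ValueError):
        classify_events(m, [])
    with pytest.raises(ValueError):
        classify_events(m, ["R1", "R9"])


def test_mutational_load():
    regions = ["R1", "R2", "R3"]
    m = presence_matrix(13, [[1, 1, 0]] * 10, regions)
    counts, median, rng = mutational_load(m)
    assert counts.tolist() == [23, 23, 13]
    assert median == 23.0 and rng == (13, 23)


def test_driver_lookup():
    table = pd.DataFrame({"gene": ["VHL", "PBRM1"], "category": [1, 2]})
    assert assign_driver_category("VHL", table) == 1
    assert assign_driver_category("PBRM1", {"PBRM1": 2}) == 2
    assert assign_driver_category("NOVEL", table) is None


# ---------------------------------------------------------------------------
# stepwise artifact classifier
# ---------------------------------------------------------------------------

def artifact_training(n=400, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    return pd.DataFrame({
        "strand_bias": y * 2.0 + rng.normal(0, 0.8, n),     # informative
        "mapping_quality": rng.normal(50, 5, n),             # noise
        "base_quality": np.full(n, 30.0),                    # zero variance
        "artifact": y,
    })


def test_stepwise_selects_informative_feature_first():
    model = StepwiseArtifactModel().fit(artifact_training())
    assert model.selected_[0] == "strand_bias"
    assert "base_quality" not in model.selected_  # constant column pre-excluded


def test_stepwise_single_class_errors():
    df = artifact_training()
    df["artifact"] = 1
    with pytest.raises(ValueError):
        StepwiseArtifactModel().fit(df)


def test_stepwise_no_signal_falls_back_to_prevalence():
    rng = np.random.default_rng(1)
    df = pd.DataFrame({"noise": rng.normal(size=300),
                       "artifact": rng.integers(0, 2, 300)})
    model = StepwiseArtifactModel(entry_p=1e-6).fit(df)
    assert model.selected_ == []
    prob = model.predict_proba({"noise": 0.0})
    assert prob[0] == pytest.approx(model.prevalence_)


def test_classify_artifact_keep_rule():
    training = artifact_training()
    prob_bad, keep_bad = classify_artifact(
        {"strand_bias": 3.0, "mapping_quality": 50.0, "base_quality": 30.0}, training)
    prob_good, keep_good = classify_artifact(
        {"strand_bias": -1.0, "mapping_quality": 50.0, "base_quality": 30.0}, training)
    assert prob_bad > 0.5 and not keep_bad
    assert prob_good < 0.5 and keep_good
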