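import numpy as np
import pytest
from hypothesis import given, strategies as st
from pydantic import ValidationError

from phenovalid import (
    ConfigError,
    GeneratorConfig,
    calibrate_age_model,
    extract_profiles,
    generate_cohort,
    largest_remainder,
    select_cohort,
    table1_report,
)
from phenovalid.io import write_cohort_jsonl
from phenovalid.reconstruction import PATTERNS


def test_exact_mode_at_219_reproduces_the_published_table(table1_profiles):
    cohort = generate_cohort(GeneratorConfig(n_patients=219, seed=11, mode="exact"))
    generated = table1_report(extract_profiles(cohort))
    reference = table1_report(table1_profiles)
    for got, want in zip(
        (generated.baseline, *generated.rows), (reference.baseline, *reference.rows)
    ):
        assert (got.n_selected, got.n_confirmed, got.pct_selected, got.ppv) == (
            want.n_selected, want.n_confirmed, want.pct_selected, want.ppv,
        )


def test_same_seed_gives_byte_identical_cohorts(tmp_path):
    cfg = GeneratorConfig(n_patients=300, seed=42, mode="stochastic")
    write_cohort_jsonl(generate_cohort(cfg), tmp_path / "a.jsonl")
    write_cohort_jsonl(generate_cohort(cfg), tmp_path / "b.jsonl")
    assert (tmp_path / "a.jsonl").read_bytes() == (tmp_path / "b.jsonl").read_bytes()


def test_generated_patients_are_structurally_valid():
    cfg = GeneratorConfig(n_patients=400, seed=5, mode="stochastic")
    cohort = generate_cohort(cfg)
    assert select_cohort(cohort, "L88", 30) == cohort
    for prof in extract_profiles(cohort):
        # realized age respects the criterion-3 band the pattern dictates
        if prof.c3:
            assert 30 <= prof.age_at_first_l88 <= 61
        else:
            assert prof.age_at_first_l88 >= 62


def test_exact_mode_pattern_counts_are_apportioned_expectations():
    cfg = GeneratorConfig(n_patients=219, seed=0, mode="exact")
    profiles = extract_profiles(generate_cohort(cfg))
    n_confirmed = sum(p.confirmed for p in profiles)
    assert n_confirmed == 155  # 219 · 155/219 is an exact expectation
    counts = {}
    for p in profiles:
        if p.confirmed:
            counts[p.flags()] = counts.get(p.flags(), 0) + 1
    expected = {
        pat: round(155 * pr)
        for pat, pr in zip(PATTERNS, cfg.pattern_probabilities["confirmed"])
    }
    assert counts == {k: v for k, v in expected.items() if v}


@given(
    total=st.integers(min_value=0, max_value=500),
    weights=st.lists(st.floats(min_value=0.01, max_value=10), min_size=1, max_size=8),
)
def test_largest_remainder_apportions_all_units(total, weights):
    probs = np.asarray(weights) / np.sum(weights)
    counts = largest_remainder(total, probs)
    assert sum(counts) == total
    assert all(c >= 0 for c in counts)
    # never off by a full unit from the real-valued quota
    assert all(abs(c - q) < 1 for c, q in zip(counts, probs * total))


def test_probability_vectors_must_sum_to_one():
    bad = {
        "confirmed": tuple([0.5] + [0.0] * 7),
        "not_confirmed": tuple([1.0] + [0.0] * 7),
    }
    with pytest.raises(ValidationError):
        GeneratorConfig(n_patients=10, pattern_probabilities=bad)


def test_infeasible_age_band_is_a_config_error():
    with pytest.raises(ConfigError):
        # min_age above the cutoff empties the criterion-3 band while the
        # default joint still puts mass on c3-true patterns
        generate_cohort(GeneratorConfig(n_patients=10, min_age=70, age_cutoff=61))


def test_age_model_calibration_matches_target_moments():
    model = calibrate_age_model(58.0, 15.0, p_low=105 / 219)
    low = model._dist(model.low_band, model.mu_low)
    high = model._dist(model.high_band, model.mu_high)
    w = 105 / 219
    mean = w * low.mean() + (1 - w) * high.mean()
    var = (
        w * (low.var() + (low.mean() - mean) ** 2)
        + (1 - w) * (high.var() + (high.mean() - mean) ** 2)
    )
    assert mean == pytest.approx(58.0, abs=1e-3)
    assert np.sqrt(var) == pytest.approx(15.0, abs=1e-3)
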