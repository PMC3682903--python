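import dataclasses

import pytest
from hypothesis import given, strategies as st
from pydantic import ValidationError

from phenovalid import (
    AlgorithmSpec,
    CriterionProfile,
    DomainError,
    MedicationCatalog,
    apply_algorithm,
    criterion1,
    criterion2,
    criterion3,
    extract_profile,
)

from conftest import make_patient


def profile_from_flags(i, c1, c2, c3, confirmed=False):
    """A CriterionProfile with feature fields consistent with the flags."""
    return CriterionProfile(
        patient_id=f"R{i}",
        n_l88_contacts=4 if c2 else 1,
        has_l88_episode=False,
        n_l88_linked_rx_non_dmard=2 if c2 else 0,
        has_repeat_dmard=c1,
        age_at_first_l88=50 if c3 else 70,
        c1=c1, c2=c2, c3=c3,
        confirmed=confirmed,
    )


# ------------------------------------------------------------ single criteria

def test_repeat_dmard_prescription_sets_criterion1():
    p = make_patient(
        birth="1950-01-01",
        contacts=[("2005-03-01", "L88")],
        prescriptions=[("2005-03-15", "L04AX03", None, True)],
    )
    prof = extract_profile(p)
    assert prof.has_repeat_dmard and prof.c1


@pytest.mark.parametrize(
    "atc, is_repeat, expected_c1",
    [
        ("L04AX03", True, True),    # repeat methotrexate
        ("L04AX03", False, False),  # DMARD but not a repeat prescription
        ("M01AE01", True, False),   # repeat NSAID, not in the catalog
    ],
)
def test_criterion1_requires_both_repeat_and_catalog_drug(atc, is_repeat, expected_c1):
    p = make_patient(
        birth="1950-01-01",
        contacts=[("2005-03-01", "L88")],
        prescriptions=[("2005-03-15", atc, None, is_repeat)],
    )
    assert extract_profile(p).c1 is expected_c1


@pytest.mark.parametrize(
    "n_contacts, episode, n_rx, expected_c2",
    [
        (4, False, 2, True),
        (1, True, 2, True),    # episode route
        (3, False, 5, False),  # contact clause fails
        (4, False, 1, False),  # prescription clause fails
        (5, True, 0, False),
    ],
)
def test_criterion2_contact_or_episode_plus_two_linked_rx(
    n_contacts, episode, n_rx, expected_c2
):
    contacts = [(f"2005-0{m}-01", "L88") for m in range(1, n_contacts + 1)]
    p = make_patient(
        birth="1950-01-01",
        contacts=contacts,
        episodes=[("L88", "2005-01-01", "2005-09-01")] if episode else [],
        prescriptions=[(f"2005-0{m}-10", "M01AE01", "L88", False) for m in range(1, n_rx + 1)],
    )
    assert extract_profile(p).c2 is expected_c2


def test_dmard_prescriptions_do_not_count_toward_criterion2():
    p = make_patient(
        birth="1950-01-01",
        contacts=[(f"2005-0{m}-01", "L88") for m in range(1, 5)],
        prescriptions=[(f"2005-0{m}-10", "L04AX03", "L88", False) for m in range(1, 3)],
    )
    prof = extract_profile(p)
    assert prof.n_l88_linked_rx_non_dmard == 0 and not prof.c2


@pytest.mark.parametrize(
    "age, expected_c3", [(29, False), (30, True), (55, True), (61, True), (62, False), (70, False)]
)
def test_criterion3_age_band_is_inclusive_30_to_61(age, expected_c3):
    prof = dataclasses.replace(profile_from_flags(0, False, False, False),
                               age_at_first_l88=age)
    assert criterion3(prof) is expected_c3


def test_extract_profile_requires_an_index_event():
    with pytest.raises(DomainError):
        extract_profile(make_patient(contacts=[("2005-01-01", "K74")]))


def test_catalog_prefix_matching_and_validation():
    cat = MedicationCatalog()
    assert cat.contains("L04AX03") and cat.contains("l04ab01")
    assert not cat.contains("M01AE01")
    with pytest.raises(ValidationError):
        MedicationCatalog(dmard_biologic_atc_prefixes=set())


def test_stored_flags_are_rederivable_from_features(table1_profiles):
    for prof in table1_profiles:
        assert prof.c1 is criterion1(prof)
        assert prof.c2 is criterion2(prof)
        assert prof.c3 is criterion3(prof)


# ---------------------------------------------------------------- combinators

def test_algorithm_spec_validation():
    with pytest.raises(ValidationError):
        AlgorithmSpec(criteria_used=frozenset(), min_satisfied=1)
    with pytest.raises(ValidationError):
        AlgorithmSpec(criteria_used=frozenset({1, 2}), min_satisfied=3)
    with pytest.raises(ValidationError):
        AlgorithmSpec(criteria_used=frozenset({1, 4}), min_satisfied=1)


def test_published_combination_counts(table1_profiles):
    any_of_3 = AlgorithmSpec(criteria_used=frozenset({1, 2, 3}), min_satisfied=1)
    all_3 = AlgorithmSpec(criteria_used=frozenset({1, 2, 3}), min_satisfied=3)
    assert len(apply_algorithm(table1_profiles, any_of_3)) == 140
    assert len(apply_algorithm(table1_profiles, all_3)) == 9


flag_cohorts = st.lists(
    st.tuples(st.booleans(), st.booleans(), st.booleans()), min_size=0, max_size=40
)


@given(flags=flag_cohorts)
def test_selection_nests_as_k_increases(flags):
    profiles = [profile_from_flags(i, *f) for i, f in enumerate(flags)]
    crits = frozenset({1, 2, 3})
    sels = [
        apply_algorithm(profiles, AlgorithmSpec(criteria_used=crits, min_satisfied=k))
        for k in (1, 2, 3)
    ]
    assert sels[2] <= sels[1] <= sels[0]


@given(flags=flag_cohorts)
def test_pairwise_union_and_intersection_identities(flags):
    profiles = [profile_from_flags(i, *f) for i, f in enumerate(flags)]

    def sel(crits, k):
        return apply_algorithm(
            profiles, AlgorithmSpec(criteria_used=frozenset(crits), min_satisfied=k)
        )

    only1, only2 = sel({1}, 1), sel({2}, 1)
    assert sel({1, 2}, 1) == only1 | only2
    assert sel({1, 2}, 2) == only1 & only2
    # inclusion-exclusion against the brute-force set sizes
    assert len(sel({1, 2}, 1)) == len(only1) + len(only2) - len(sel({1, 2}, 2))
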