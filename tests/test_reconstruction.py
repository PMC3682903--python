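import pytest
from hypothesis import given, strategies as st

from phenovalid import (
    InconsistencyError,
    JointDistribution,
    compute_marginals,
    extract_profiles,
    materialize_fixture,
    reconstruct_joint,
    verify_consistency,
)
from phenovalid.reconstruction import CLASSES, PATTERNS, ClassMarginals, MarginalTable


def test_pairwise_intersections_follow_inclusion_exclusion(table1_joint):
    # |C1 ∩ C2| = |C1| + |C2| − |C1 ∪ C2|, computed by hand from the
    # published marginals: confirmed 43+44−64=23, not-confirmed 4+5−9=0.
    def i12(cls):
        return sum(
            table1_joint.cell(cls, p) for p in PATTERNS if p[0] and p[1]
        )

    assert i12("confirmed") == 23
    assert i12("not_confirmed") == 0


def test_disjoint_toy_marginals_give_empty_intersection():
    toy = ClassMarginals(
        n_total=2, c1=1, c2=1, c3=0,
        c1_or_c2=2, c1_or_c3=1, c2_or_c3=1,
        all_three=0, at_least_two=0, at_least_one=2,
    )
    m = MarginalTable(confirmed=toy, not_confirmed=toy)
    j = reconstruct_joint(m)
    assert j.cell("confirmed", (True, True, False)) == 0
    assert j.cell("confirmed", (True, False, False)) == 1


def test_inconsistent_marginals_raise_naming_the_pattern(table1_marginals):
    broken = table1_marginals.model_copy(
        update={
            "confirmed": table1_marginals.confirmed.model_copy(
                update={"c1_or_c2": 90}
            )
        }
    )
    with pytest.raises(InconsistencyError, match="confirmed"):
        reconstruct_joint(broken)


def test_held_out_at_least_k_rows_have_zero_residual(table1_joint, table1_marginals):
    residuals = verify_consistency(table1_joint, table1_marginals)
    assert all(v == 0 for v in residuals.values())
    # the at-least-k rows were never consulted during reconstruction
    for cls in CLASSES:
        assert residuals[(cls, "at_least_one")] == 0
        assert residuals[(cls, "at_least_two")] == 0


joints = st.builds(
    lambda counts: JointDistribution(
        {(cls, pat): c for (cls, pat), c in zip(
            [(c, p) for c in CLASSES for p in PATTERNS], counts)}
    ),
    st.lists(st.integers(min_value=0, max_value=50), min_size=16, max_size=16),
)


@given(j=joints)
def test_reconstruction_inverts_forward_marginalization(j):
    assert reconstruct_joint(compute_marginals(j)).counts == j.counts


@given(j=joints)
def test_self_consistency_round_trip(j):
    assert all(v == 0 for v in verify_consistency(j, compute_marginals(j)).values())


def test_fixture_has_one_patient_per_unit_count(table1_joint, table1_fixture):
    assert len(table1_fixture) == table1_joint.total() == 219


def test_empty_joint_gives_empty_cohort():
    assert materialize_fixture(JointDistribution({})) == []


def test_fixture_profiles_reproduce_the_joint_exactly(table1_joint, table1_profiles):
    observed = {(cls, pat): 0 for cls in CLASSES for pat in PATTERNS}
    for prof in table1_profiles:
        cls = "confirmed" if prof.confirmed else "not_confirmed"
        observed[(cls, prof.flags())] += 1
    assert observed == table1_joint.counts


def test_fixture_is_deterministic_in_the_seed(table1_joint):
    a = materialize_fixture(table1_joint, seed=5)
    b = materialize_fixture(table1_joint, seed=5)
    c = materialize_fixture(table1_joint, seed=6)
    assert a == b
    assert a != c


def test_joint_serialization_round_trip(table1_joint):
    assert JointDistribution.from_dict(table1_joint.to_dict()).counts == table1_joint.counts
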