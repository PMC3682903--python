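"""Evaluate custom at-least-k criterion combinations on the reconstructed cohort.

Any subset of the three criteria with any threshold k defines a case-finding
algorithm; the trade-off is always PPV against coverage: stricter rules keep
fewer patients but more of them are true cases.
"""

from phenovalid import (
    AlgorithmSpec,
    evaluate_algorithms,
    extract_profiles,
    load_table1_marginals,
    materialize_fixture,
    reconstruct_joint,
    report_to_frame,
)

profiles = extract_profiles(
    materialize_fixture(reconstruct_joint(load_table1_marginals()), seed=1)
)

specs = [
    AlgorithmSpec(criteria_used=frozenset({1}), min_satisfied=1),
    AlgorithmSpec(criteria_used=frozenset({1, 2}), min_satisfied=2),
    AlgorithmSpec(criteria_used=frozenset({1, 2, 3}), min_satisfied=2),
    AlgorithmSpec(criteria_used=frozenset({1, 2, 3}), min_satisfied=1),
]
report = evaluate_algorithms(profiles, specs)
print(report_to_frame(report).to_string(index=False))
# Requiring both the DMARD criterion and the consultation criterion (row
# "2 out of 2") selects very few patients but with high validity; the
# published choice — any 1 of 3 — keeps 63.9% of the cohort at 77.9% PPV.
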