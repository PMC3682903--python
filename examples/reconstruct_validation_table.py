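"""Reconstruct the patient-level cohort behind the published validation table.

The published table reports only marginal counts per confirmation class
(single criteria, pairwise unions, triple intersection, totals, at-least-k
rows). Inclusion–exclusion inverts those marginals to the full 8-pattern x
2-class joint; one synthetic patient is built per unit count; and running the
criterion engine over that cohort reproduces every printed cell.
"""

from phenovalid import (
    extract_profiles,
    load_table1_marginals,
    materialize_fixture,
    reconstruct_joint,
    report_to_frame,
    table1_report,
    verify_consistency,
)

marginals = load_table1_marginals()
joint = reconstruct_joint(marginals)

residuals = verify_consistency(joint, marginals)
print("non-zero residuals:", {k: v for k, v in residuals.items() if v} or "none")
# 'none' means the overdetermined marginal system is internally consistent:
# the at-least-1 and at-least-2 rows, which the reconstruction never reads,
# are recovered exactly.

fixture = materialize_fixture(joint, seed=1)
report = table1_report(extract_profiles(fixture))
print(report_to_frame(report).to_string(index=False))
# Each row: patients selected by that criterion combination, the share of the
# 219-patient cohort they represent, and the share of the selected whose
# diagnosis chart review confirms (the PPV, or "validity"). The baseline PPV
# of the diagnosis code alone is 70.8%; requiring at least 1 of 3 criteria
# raises it to 77.9% while keeping 140 patients.
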