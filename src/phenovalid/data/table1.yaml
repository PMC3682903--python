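# Transcription of the published validation table for the L88-coded cohort
# (n=219): number of patients fulfilling each criterion combination, split by
# chart-review confirmation of the inflammatory-arthritis diagnosis.
# Fields: singles (c1..c3), pairwise unions, the triple intersection, and the
# at-least-k rows; the at-least-k rows are redundant given the others and are
# used as held-out consistency checks.
confirmed:
  n_total: 155
  c1: 43
  c2: 44
  c3: 80
  c1_or_c2: 64
  c1_or_c3: 101
  c2_or_c3: 102
  all_three: 9
  at_least_two: 49
  at_least_one: 109
not_confirmed:
  n_total: 64
  c1: 4
  c2: 5
  c3: 25
  c1_or_c2: 9
  c1_or_c3: 26
  c2_or_c3: 30
  all_three: 0
  at_least_two: 3
  at_least_one: 31
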