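# Default EPPM grading rules: the published point scheme for the seven
# predictors of poor early prognosis after TBI.
#
# Numeric bins are left-closed: a bin covers [lower edge, upper) where
# "upper" is the next bin's lower edge; the last bin is open above. At an
# abutting edge the higher-severity bin therefore wins (CRP 15 -> 5 points,
# IL-8 20 -> 4 points, age 60 -> 6 points). Age and GCS are integer-valued,
# so "46-59" is the half-open real interval [46, 60).
age:
  kind: numeric
  domain: [15, 75]
  bins:
    - {upper: 46, points: 4}   # <= 45 years
    - {upper: 60, points: 5}   # 46-59
    - {points: 6}              # >= 60
damaged_area:
  kind: categorical
  levels: {parietal: 2, occipital: 2, temporal: 3, frontal: 4}
gcs:
  kind: numeric
  domain: [3, 15]
  bins:
    - {upper: 9, points: 6}    # <= 8, severe
    - {upper: 13, points: 3}   # 9-12, moderate
    - {points: 1}              # 13-15, mild
apoe_e4_carrier:
  kind: categorical
  levels: {"no": 0, "yes": 2}
crp:
  kind: numeric
  domain: [0, .inf]
  bins:
    - {upper: 10, points: 2}   # < 10 mg/L
    - {upper: 15, points: 3}   # 10-15
    - {points: 5}              # >= 15
il8:
  kind: numeric
  domain: [0, .inf]
  bins:
    - {upper: 10, points: 0}   # < 10 pg/mL
    - {upper: 20, points: 2}   # 10-20
    - {points: 4}              # >= 20
marshall:
  kind: categorical
  levels: {I: 1, II: 1, III: 4, IV: 4, V: 6, VI: 6}
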