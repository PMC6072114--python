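"""Worked-example reference data used in the documentation and tests.

Two small tables from a serum-peptidome MGUS/HC classification study design:
a 16-sample blinded validation set (biological group vs majority-voted
predicted class, containing two false negatives) and ten outer-fold
performance estimates from a double cross-validation run.  They exercise the
confusion-matrix and aggregation arithmetic on realistic desk-scale numbers.
"""

#: (biological group, predicted class) per blinded validation sample 1T..16T.
BLINDED_TEST_PAIRS = (
    ("HC", "HC"), ("HC", "HC"), ("HC", "HC"), ("MGUS", "MGUS"),
    ("MGUS", "MGUS"), ("MGUS", "HC"), ("MGUS", "HC"), ("HC", "HC"),
    ("HC", "HC"), ("HC", "HC"), ("MGUS", "MGUS"), ("MGUS", "MGUS"),
    ("MGUS", "MGUS"), ("MGUS", "MGUS"), ("HC", "HC"), ("HC", "HC"),
)

#: Ten outer-fold (sensitivity, specificity, accuracy) estimates from a
#: double cross-validation run on a ~200-sample serum cohort.
OUTER_CV_ESTIMATES = (
    (1.00, 1.00, 1.00),
    (0.64, 0.93, 0.80),
    (1.00, 0.86, 0.94),
    (1.00, 0.75, 0.89),
    (0.82, 1.00, 0.92),
    (0.91, 0.82, 0.86),
    (0.62, 0.69, 0.65),
    (1.00, 0.90, 0.92),
    (1.00, 0.89, 0.95),
    (0.94, 0.80, 0.88),
)

#: Cohort replicate-correlation statistics observed in the same study design.
QC_EXAMPLE_MU = 0.984
QC_EXAMPLE_SIGMA = 0.028
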