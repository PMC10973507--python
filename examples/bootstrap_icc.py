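"""Bolus-bootstrap repeatability: choose 4 of 8 holds, 70 combinations.

Builds a synthetic panel of subjects whose gray-matter CBV estimates vary
between subjects (true physiology) and across bolus combinations
(measurement noise), then summarizes repeatability with a one-way
random-effects intraclass correlation.
"""

import numpy as np

from bhdsc.repro import bolus_bootstrap_icc, bolus_combinations

rng = np.random.default_rng(0)
n_subjects = 10
subject_cbv = 5.0 + 1.5 * rng.standard_normal(n_subjects)  # between-subject
noise_sd = 1.1                                             # within-subject


def pipeline(subject_mean, combo):
    return subject_mean + noise_sd * rng.standard_normal()


icc, table = bolus_bootstrap_icc(list(subject_cbv), pipeline)
print(f"combinations enumerated: {len(bolus_combinations())}")
print(f"subjects: {n_subjects}, values computed: {len(table)}")
print(f"ICC(1,1) = {icc:.2f}")
print("\nAn ICC in the 0.5-0.75 band marks moderate-to-substantial "
      "repeatability of the\nbolus-averaged CBV estimate.")
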