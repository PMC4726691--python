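"""NHANES III spirometric reference-equation coefficients.

Source: Hankinson JL, Odencrantz JR, Fedan KB. Spirometric reference values
from a sample of the general U.S. population. Am J Respir Crit Care Med
1999;159:179-187 (Tables 4 and 5).

Equation form, volumes in liters, age in years, height in cm:

    value = b0 + b1*age + b2*age**2 + b3*height**2

The lower limit of normal (LLN) uses the same intercept and age terms with
an alternative height-squared coefficient (the last tuple entry).

Age-group split: males use the "<20" coefficient set below age 20, females
below age 18.
"""

RACES = ("caucasian", "african_american", "mexican_american")

AGE_SPLIT = {"male": 20.0, "female": 18.0}

# (sex, race, measure, agegroup) -> (b0, b1_age, b2_age2, b3_ht2, b3_ht2_lln)
COEFFICIENTS = {
    # --- males, youth (< 20 y) ---
    ("male", "caucasian", "fvc", "youth"): (-0.2584, -0.20415, 0.010133, 0.00018642, 0.00015695),
    ("male", "caucasian", "fev1", "youth"): (-0.7453, -0.04106, 0.004477, 0.00014098, 0.00011607),
    ("male", "african_american", "fvc", "youth"): (-0.4971, -0.15497, 0.007701, 0.00016643, 0.00013670),
    ("male", "african_american", "fev1", "youth"): (-0.7048, -0.05711, 0.004316, 0.00013194, 0.00010561),
    ("male", "mexican_american", "fvc", "youth"): (-0.7571, -0.09520, 0.006619, 0.00017823, 0.00014947),
    ("male", "mexican_american", "fev1", "youth"): (-0.8218, -0.04248, 0.004291, 0.00015104, 0.00012670),
    # --- males, adult (>= 20 y) ---
    ("male", "caucasian", "fvc", "adult"): (-0.1933, 0.00064, -0.000269, 0.00018642, 0.00015695),
    ("male", "caucasian", "fev1", "adult"): (0.5536, -0.01303, -0.000172, 0.00014098, 0.00011607),
    ("male", "african_american", "fvc", "adult"): (-0.1517, -0.01821, 0.0, 0.00016643, 0.00013670),
    ("male", "african_american", "fev1", "adult"): (0.3411, -0.02309, 0.0, 0.00013194, 0.00010561),
    ("male", "mexican_american", "fvc", "adult"): (0.2376, -0.00891, -0.000182, 0.00017823, 0.00014947),
    ("male", "mexican_american", "fev1", "adult"): (0.6306, -0.02928, 0.0, 0.00015104, 0.00012670),
    # --- females, youth (< 18 y) ---
    ("female", "caucasian", "fvc", "youth"): (-1.2082, 0.05916, 0.0, 0.00014815, 0.00012198),
    ("female", "caucasian", "fev1", "youth"): (-0.8710, 0.06537, 0.0, 0.00011496, 0.00009283),
    ("female", "african_american", "fvc", "youth"): (-0.6166, -0.04687, 0.003602, 0.00013606, 0.00010916),
    ("female", "african_american", "fev1", "youth"): (-0.9630, 0.05799, 0.0, 0.00010846, 0.00008546),
    ("female", "mexican_american", "fvc", "youth"): (-1.2507, 0.07501, 0.0, 0.00014246, 0.00011570),
    ("female", "mexican_american", "fev1", "youth"): (-0.9641, 0.06490, 0.0, 0.00012154, 0.00010079),
    # --- females, adult (>= 18 y) ---
    ("female", "caucasian", "fvc", "adult"): (-0.3560, 0.01870, -0.000382, 0.00014815, 0.00012198),
    ("female", "caucasian", "fev1", "adult"): (0.4333, -0.00361, -0.000194, 0.00011496, 0.00009283),
    ("female", "african_american", "fvc", "adult"): (-0.3039, 0.00536, -0.000265, 0.00013606, 0.00010916),
    ("female", "african_american", "fev1", "adult"): (0.3433, -0.01283, -0.000097, 0.00010846, 0.00008546),
    ("female", "mexican_american", "fvc", "adult"): (0.1210, 0.00307, -0.000237, 0.00014246, 0.00011570),
    ("female", "mexican_american", "fev1", "adult"): (0.4529, -0.01178, -0.000113, 0.00012154, 0.00010079),
}
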