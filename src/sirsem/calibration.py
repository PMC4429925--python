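"""Default calibration of the synthetic-data generator.

The generator emulates a test-day recording scheme for first-lactation
Italian Holstein cows in which four traits are measured jointly on each milk
sample: somatic cell score (SCS, log units), casein percentage (CAS, %),
rennet coagulation time (RCT, min) and curd firmness 30 minutes after rennet
addition (a30, mm).  The constants below are the published field estimates
for that system and serve as the package's default "truth": descriptive
statistics of the traits, multi-trait-scale heritabilities and correlations
from the baseline no-causal-path model, posterior-mean causal coefficients
for each fitted causal structure, and the curd-firmness variance components
under each structure.

Only :mod:`sirsem.simulate` turns these numbers into full covariance
matrices; the completion procedure (variance shares, PSD projection) is
documented there and in the methods note.
"""

from __future__ import annotations

import numpy as np

TRAITS = ("SCS", "CAS", "RCT", "a30")

#: Observed trait means (log units, %, min, mm).
TRAIT_MEANS = {"SCS": 2.35, "CAS": 2.46, "RCT": 18.9, "a30": 23.0}

#: Observed trait standard deviations, used for SD-unit transforms.
TRAIT_SDS = {"SCS": 1.66, "CAS": 0.23, "RCT": 3.80, "a30": 8.53}

#: Baseline-model (no causal paths) heritabilities on the multi-trait scale.
H2_M0 = {"SCS": 0.030, "CAS": 0.157, "RCT": 0.167, "a30": 0.187}

#: Baseline-model genetic correlations (upper-triangle pairs).
GENETIC_CORR_M0 = {
    ("SCS", "CAS"): -0.096,
    ("SCS", "RCT"): -0.081,
    ("SCS", "a30"): -0.072,
    ("CAS", "RCT"): -0.157,
    ("CAS", "a30"): 0.374,
    ("RCT", "a30"): -0.918,
}

#: Baseline-model phenotypic correlations (upper-triangle pairs).
PHENOTYPIC_CORR_M0 = {
    ("SCS", "CAS"): 0.042,
    ("SCS", "RCT"): 0.182,
    ("SCS", "a30"): -0.192,
    ("CAS", "RCT"): -0.046,
    ("CAS", "a30"): 0.291,
    ("RCT", "a30"): -0.851,
}

#: Posterior-mean structural coefficients per model preset, keyed (x, y)
#: meaning "x -> y".
CAUSAL_EFFECTS = {
    "M1": {
        ("SCS", "RCT"): 0.242,
        ("CAS", "RCT"): -3.043,
        ("SCS", "a30"): -0.730,
        ("CAS", "a30"): 18.823,
    },
    "M2": {("RCT", "a30"): -1.901},
    "M3": {
        ("SCS", "a30"): -0.267,
        ("CAS", "a30"): 12.845,
        ("RCT", "a30"): -1.792,
    },
}

#: Curd-firmness (a30) sire genetic variance under each structure, on the
#: structural (direct-effect) scale for M1-M3 and the multi-trait scale for
#: the baseline M0.
A30_SIRE_VARIANCE = {"M0": 3.829, "M1": 3.135, "M2": 0.536, "M3": 0.128}

#: Curd-firmness phenotypic variance (sire + permanent environment + herd +
#: residual) under each structure, same convention as above.
A30_PHENOTYPIC_VARIANCE = {"M0": 81.998, "M1": 70.192, "M2": 22.108, "M3": 11.902}

#: Curd-firmness heritability under each structure.
A30_H2 = {"M0": 0.187, "M1": 0.179, "M2": 0.097, "M3": 0.043}

#: Study design of the emulated recording scheme.
N_COWS = 3266
N_HERDS = 309
N_SIRES = 128
N_RECORDS = 8783
N_PEDIGREE = 1254

#: Days-in-milk classes (early lactation only), class 4 is the reference.
DIM_CLASSES = ("5-34", "35-64", "65-94", "95-125")


def trait_sd_vector() -> np.ndarray:
    return np.array([TRAIT_SDS[t] for t in TRAITS])


def trait_mean_vector() -> np.ndarray:
    return np.array([TRAIT_MEANS[t] for t in TRAITS])
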