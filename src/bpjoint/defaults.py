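"""Default study conditions for the hypertension remission cohort.

These defaults parameterize the synthetic cohort generator and the model
designs after a retrospective cohort of 301 hypertensive outpatients
followed roughly monthly for up to 30 months, with systolic/diastolic
blood pressure (SBP/DBP, mmHg) measured at each visit and first remission
of hypertension as the time-to-event outcome.  Baseline covariate
frequencies, the age distribution, the mixed-model coefficients, the
random-effect covariance and the residual SDs are the published cohort
estimates; laboratory moments that the study does not report are set at
physiological midpoints and are fully configurable.
"""
from __future__ import annotations

import numpy as np

from .params import (
    DesignSpec,
    HazardParams,
    JointParams,
    LMMParams,
    ShrinkageHyper,
    covariance_from_sd_corr,
)

N_SUBJECTS = 301
FOLLOW_UP_MONTHS = 30.0
#: monthly visits, enrolment visit at t = 0
VISIT_SCHEDULE = tuple(float(t) for t in range(30))

#: category probabilities from the observed cohort margins (counts / 301)
COVARIATE_FREQUENCIES = {
    "sex": {"female": 148 / 301, "male": 153 / 301},
    "residence": {"rural": 124 / 301, "urban": 177 / 301},
    "dm": {"no": 218 / 301, "yes": 83 / 301},
    "ckd": {"no": 243 / 301, "yes": 58 / 301},
    "stroke": {"no": 219 / 301, "yes": 82 / 301},
    "hiv": {"no": 276 / 301, "yes": 25 / 301},
    "regimen": {
        "monotherapy": 38 / 301,
        "two_drug": 100 / 301,
        "three_plus": 163 / 301,
    },
    "drug_type": {
        "enalapril": 103 / 301,
        "nifedipine": 85 / 301,
        "both": 77 / 301,
        "other": 36 / 301,
    },
}

#: observed (censored, event) counts per baseline category in the source
#: cohort of 301, in the order reported; inputs to the association tests
OUTCOME_COUNTS = {
    "sex": {"male": (30, 123), "female": (28, 120)},
    "residence": {"urban": (33, 144), "rural": (25, 99)},
    "dm": {"yes": (30, 53), "no": (28, 190)},
    "ckd": {"yes": (16, 42), "no": (42, 201)},
    "stroke": {"yes": (25, 57), "no": (33, 186)},
    "hiv": {"yes": (9, 16), "no": (49, 227)},
    "regimen": {
        "monotherapy": (6, 32),
        "two_drug": (20, 80),
        "three_plus": (32, 131),
    },
    "drug_type": {
        "enalapril": (20, 83),
        "nifedipine": (13, 72),
        "both": (19, 58),
        "other": (6, 30),
    },
}

#: continuous covariates: (mean, SD, lower bound, upper bound).
#: Age moments are the cohort's; adults only (>= 15 y inclusion rule).
#: Laboratory moments are physiological midpoints (units in comments).
COVARIATE_MOMENTS = {
    "age": (51.77, 13.88, 15.0, 100.0),         # years
    "bcl": (190.0, 40.0, 80.0, 400.0),          # blood cholesterol, mg/dl
    "gbl": (100.0, 25.0, 40.0, 400.0),          # blood glucose, mg/dl
    "bun": (15.0, 5.0, 2.0, 60.0),              # blood urea nitrogen, mg/dl
    "creatinine": (1.0, 0.3, 0.2, 5.0),         # mg/dl
    "calcium": (2.35, 0.15, 1.5, 3.5),          # mmol/l
    "sodium": (140.0, 4.0, 120.0, 160.0),       # mmol/l
    "potassium": (4.2, 0.5, 2.5, 6.5),          # mmol/l
    "chlorine": (102.0, 4.0, 85.0, 120.0),      # mmol/l
    "hemoglobin": (14.0, 1.8, 6.0, 20.0),       # g/dl
}

#: expanded (dummy-coded) covariate names entering each sub-model
SBP_COVARIATES = (
    "age",
    "residence_urban",
    "bcl",
    "bun",
    "creatinine",
    "calcium",
    "hemoglobin",
    "dm",
    "ckd",
    "stroke",
    "hiv",
    "drug_nifedipine",
    "drug_both",
    "drug_other",
)
DBP_COVARIATES = (
    "age",
    "residence_urban",
    "bcl",
    "bun",
    "calcium",
    "sodium",
    "chlorine",
    "hemoglobin",
    "ckd",
    "hiv",
    "drug_nifedipine",
    "drug_both",
    "drug_other",
)
SURVIVAL_COVARIATES = (
    "sex_male",
    "age",
    "dm",
    "drug_nifedipine",
    "drug_both",
    "drug_other",
)

#: posterior-mean fixed effects of the fitted bivariate mixed sub-model
SBP_FIXED = {
    "intercept": 96.9114,
    "time": -0.8399,
    "age": 0.3791,
    "residence_urban": 4.2451,
    "bcl": 0.0139,
    "bun": 0.0551,
    "creatinine": -0.6129,
    "calcium": 1.9366,
    "hemoglobin": 1.2274,
    "dm": 4.3695,
    "ckd": 4.9710,
    "stroke": 2.4524,
    "hiv": 2.0087,
    "drug_nifedipine": 1.8783,
    "drug_both": 6.9160,
    "drug_other": 0.6605,
}
DBP_FIXED = {
    "intercept": 36.7942,
    "time": -0.6199,
    "age": 0.0453,
    "residence_urban": 1.2731,
    "bcl": 0.0090,
    "bun": 0.0319,
    "calcium": 0.5437,
    "sodium": 0.1856,
    "chlorine": 0.0932,
    "hemoglobin": 0.6380,
    "ckd": 2.3889,
    "hiv": 1.6150,
    "drug_nifedipine": 1.8687,
    "drug_both": 3.6535,
    "drug_other": 0.6838,
}

#: random-effect SDs for (SBP intercept, SBP slope, DBP intercept, DBP slope)
RANDOM_EFFECT_SD = np.array([10.8131, 0.8605, 6.7399, 0.5223])
#: and their correlation matrix (same ordering)
RANDOM_EFFECT_CORR = np.array(
    [
        [1.0, -0.3422, 0.7720, -0.4394],
        [-0.3422, 1.0, -0.3151, 0.9398],
        [0.7720, -0.3151, 1.0, -0.4257],
        [-0.4394, 0.9398, -0.4257, 1.0],
    ]
)
#: residual SDs (SBP, DBP), mmHg
RESIDUAL_SD = np.array([15.0348, 9.5268])

#: association of the hazard with (value SBP, slope SBP, value DBP, slope DBP);
#: only the SBP-value coefficient is reported (-0.1128, HR 0.89 per mmHg)
ASSOCIATION_RHO = np.array([-0.1128, 0.0, 0.0, 0.0])

#: survival log hazard ratios implied by the reported HRs:
#: male 0.63, per-year age 0.9987, diabetes history 0.54, "other" drugs 1.76
SURVIVAL_GAMMA = {
    "sex_male": float(np.log(0.63)),
    "age": float(np.log(0.9987)),
    "dm": float(np.log(0.54)),
    "drug_nifedipine": 0.0,
    "drug_both": 0.0,
    "drug_other": float(np.log(1.76)),
}

#: piecewise-constant baseline hazard knots (months)
BASELINE_KNOTS = np.array([0.0, 6.0, 12.0, 18.0, 24.0])
#: constant default log-level, calibrated once so that the default cohort
#: reproduces the study's remission rate (~80.7% within the 30-month
#: window) and median remission time (~11 months).  The level looks large
#: because it absorbs the association offset exp(rho_sbp * SBP) with SBP
#: around 150 mmHg.
BASELINE_LOG_HAZARD = np.full(5, 13.6)


def default_design() -> DesignSpec:
    return DesignSpec(SBP_COVARIATES, DBP_COVARIATES, SURVIVAL_COVARIATES)


def default_truth(design: DesignSpec | None = None) -> JointParams:
    """Generating parameters for the default synthetic cohort."""
    design = design or default_design()
    lmm = LMMParams(
        beta_sbp=np.array([SBP_FIXED["intercept"], SBP_FIXED["time"]]),
        beta_dbp=np.array([DBP_FIXED["intercept"], DBP_FIXED["time"]]),
        delta_sbp=np.array([SBP_FIXED[c] for c in design.sbp_covariates]),
        delta_dbp=np.array([DBP_FIXED[c] for c in design.dbp_covariates]),
        Sigma=covariance_from_sd_corr(RANDOM_EFFECT_SD, RANDOM_EFFECT_CORR),
        sigma_eps=RESIDUAL_SD.copy(),
    )
    hazard = HazardParams(
        log_baseline=BASELINE_LOG_HAZARD.copy(),
        knots=BASELINE_KNOTS.copy(),
        gamma=np.array([SURVIVAL_GAMMA[c] for c in design.survival_covariates]),
        rho=ASSOCIATION_RHO.copy(),
    )
    truth = JointParams(lmm=lmm, hazard=hazard, shrinkage=ShrinkageHyper())
    truth.validate()
    return truth
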