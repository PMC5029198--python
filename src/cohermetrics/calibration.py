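"""Published reference summaries the synthetic cohort is calibrated to.

This package models a reference adult study (N = 106; 64 female, 42 male)
of global motion and global form perception across a continuum of reading
ability.  No participant-level data from that study are available, so the
synthetic-cohort generator is calibrated against the study's *published
summary statistics*, reproduced here verbatim:

* group psychometric scores for the dyslexia (nonword-decoding standard
  score <= 85) and good-reader groups, 43 participants each;
* coherence-threshold descriptives (%) by gender for the whole sample and
  by gender x group;
* the two-step hierarchical regression summaries (R2, delta-R2, B, SE B,
  beta) for the four visual tasks in whole-sample and between-group modes;
* the reading-composite PCA summary (eigenvalues and loadings).

These tables serve two purposes: they are the targets the synthetic-data
defaults are derived from, and they are the printed inputs to desk-scale
identity checks (pooled t from group summaries, local Cohen's f-squared
from step-2 increments).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "SAMPLE",
    "GROUP_PSYCHOMETRICS",
    "THRESHOLDS_BY_GENDER",
    "THRESHOLDS_BY_GROUP_GENDER",
    "WHOLE_SAMPLE_REGRESSION",
    "BETWEEN_GROUP_REGRESSION",
    "PCA_SUMMARY",
    "STAIRCASE_TRACKED_LEVEL_PCT",
]

TASKS = ("rdk", "bar1d", "static_form", "temporal_form")

SAMPLE = {"n": 106, "n_female": 64, "n_male": 42, "n_dyslexia": 43, "n_good": 43}

#: tracked performance level of the 3-down/1-up staircase (percent correct)
STAIRCASE_TRACKED_LEVEL_PCT = 79.3

#: group psychometric summaries (standard scores unless marked raw)
GROUP_PSYCHOMETRICS = pd.DataFrame(
    [
        ("nart_raw", 23.72, 24.00, 6.03, 29.63, 29.00, 4.32),
        ("towre_swe_std", 78.16, 77.00, 6.24, 92.53, 90.00, 12.06),
        ("towre_pd_std", 80.72, 83.00, 4.91, 104.33, 103.00, 9.61),
        ("spm_raw", 50.02, 51.00, 5.63, 50.79, 51.00, 3.91),
    ],
    columns=["measure", "dyslexia_mean", "dyslexia_median", "dyslexia_sd",
             "good_mean", "good_median", "good_sd"],
).set_index("measure")

#: whole-sample coherence-threshold (%) descriptives by gender
THRESHOLDS_BY_GENDER = pd.DataFrame(
    [
        ("rdk", 16.80, 15.64, 6.68, 21.89, 18.47, 10.78),
        ("bar1d", 18.74, 13.97, 11.32, 18.15, 15.53, 11.67),
        ("static_form", 14.87, 14.04, 4.31, 14.90, 14.54, 3.81),
        ("temporal_form", 91.47, 91.88, 6.10, 91.96, 92.92, 5.45),
    ],
    columns=["task", "male_mean", "male_median", "male_sd",
             "female_mean", "female_median", "female_sd"],
).set_index("task")

#: group coherence-threshold (%) descriptives, gender x reading group
#: (male: 17 dyslexia / 16 good; female: 26 dyslexia / 27 good)
THRESHOLDS_BY_GROUP_GENDER = pd.DataFrame(
    [
        ("rdk", 16.61, 5.91, 15.61, 5.27, 27.77, 12.76, 18.84, 7.68),
        ("bar1d", 21.72, 12.98, 14.60, 8.94, 21.00, 14.68, 17.41, 9.59),
        ("static_form", 14.37, 3.57, 15.49, 5.70, 15.06, 3.30, 14.78, 4.58),
        ("temporal_form", 93.49, 4.09, 88.33, 7.89, 92.75, 5.05, 90.76, 5.89),
    ],
    columns=["task",
             "male_dyslexia_mean", "male_dyslexia_sd",
             "male_good_mean", "male_good_sd",
             "female_dyslexia_mean", "female_dyslexia_sd",
             "female_good_mean", "female_good_sd"],
).set_index("task")

#: whole-sample hierarchical regression summaries (predictor at step 2 is the
#: continuous reading composite; female coded 1)
WHOLE_SAMPLE_REGRESSION = {
    "rdk": {
        "n": 106, "r2_step1": 0.16, "r2_full": 0.22, "delta_r2": 0.06,
        "step2": {"gender": {"B": 4.79, "SE_B": 1.73, "beta": 0.24},
                  "spm": {"B": -0.56, "SE_B": 0.18, "beta": -0.27},
                  "reading": {"B": -2.39, "SE_B": 0.85, "beta": -0.25}},
        "f2_reading": 0.08,
    },
    "bar1d": {
        "n": 106, "r2_step1": 0.08, "r2_full": 0.12, "delta_r2": 0.04,
        "step2": {"gender": {"B": -0.94, "SE_B": 2.18, "beta": -0.04},
                  "spm": {"B": -0.61, "SE_B": 0.23, "beta": -0.25},
                  "reading": {"B": -2.44, "SE_B": 1.08, "beta": -0.21}},
        "f2_reading": 0.05,
    },
    "static_form": {
        "n": 106, "r2_step1": 0.01, "r2_full": 0.01, "delta_r2": 0.00,
        "step2": {"gender": {"B": -0.01, "SE_B": 0.81, "beta": -0.00},
                  "spm": {"B": -0.06, "SE_B": 0.09, "beta": -0.07},
                  "reading": {"B": -0.18, "SE_B": 0.40, "beta": -0.04}},
        "f2_reading": None,  # not reported (null effect)
    },
    "temporal_form": {
        "n": 106, "r2_step1": 0.03, "r2_full": 0.13, "delta_r2": 0.10,
        "step2": {"gender": {"B": 0.52, "SE_B": 1.08, "beta": 0.04},
                  "spm": {"B": -0.15, "SE_B": 0.11, "beta": -0.13},
                  "reading": {"B": -1.78, "SE_B": 0.53, "beta": -0.31}},
        "f2_reading": 0.11,
    },
}

#: between-group regression summaries (step-2 predictor: Good = 0, Dyslexia = 1)
BETWEEN_GROUP_REGRESSION = {
    "rdk": {
        "n": 86, "r2_step1": 0.19, "r2_full": 0.27, "delta_r2": 0.08,
        "step2": {"gender": {"B": 6.80, "SE_B": 1.96, "beta": 0.33},
                  "spm": {"B": -0.52, "SE_B": 0.20, "beta": -0.25},
                  "group": {"B": 5.47, "SE_B": 1.91, "beta": 0.27}},
        "f2_group": 0.11,
    },
    "bar1d": {
        "n": 86, "r2_step1": 0.06, "r2_full": 0.09, "delta_r2": 0.03,
        "step2": {"gender": {"B": 0.56, "SE_B": 2.59, "beta": 0.02},
                  "spm": {"B": -0.55, "SE_B": 0.26, "beta": -0.22},
                  "group": {"B": 4.51, "SE_B": 2.52, "beta": 0.19}},
        "f2_group": None,  # not significant
    },
    "static_form": {
        "n": 86, "r2_step1": 0.00, "r2_full": 0.00, "delta_r2": 0.00,
        "step2": {"gender": {"B": -0.04, "SE_B": 0.96, "beta": -0.00},
                  "spm": {"B": -0.05, "SE_B": 0.10, "beta": -0.05},
                  "group": {"B": -0.29, "SE_B": 0.93, "beta": -0.03}},
        "f2_group": None,
    },
    "temporal_form": {
        # the published f2 (0.07) is inconsistent with its own rounded
        # delta_r2/(1 - r2) = 0.078; excluded from identity checks
        "n": 86, "r2_step1": 0.03, "r2_full": 0.10, "delta_r2": 0.07,
        "step2": {"gender": {"B": 0.67, "SE_B": 1.28, "beta": 0.05},
                  "spm": {"B": -0.19, "SE_B": 0.13, "beta": -0.16},
                  "group": {"B": 3.06, "SE_B": 1.25, "beta": 0.26}},
        "f2_group": 0.07,
    },
}

#: reading-composite PCA summary (correlation-matrix PCA over three tests)
PCA_SUMMARY = {
    "eigenvalues": (1.93, 0.74, 0.33),
    "loadings": {"nart_raw": 0.71, "towre_swe_std": 0.79, "towre_pd_std": 0.90},
    "variance_explained_pct": 64.0,
}
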