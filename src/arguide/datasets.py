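"""Packaged fixture data: the printed clinical-evaluation survey tables.

Two questionnaires accompanied the clinical deployment of the AR
workflow: a 15-item surgeon survey (six respondents scored 1-5) and a
3-item patient survey (two respondents).  The score tables are embedded
verbatim as printed, including their published averages' conventions
(arithmetic mean, rounded half-up to one decimal); they serve as exact
fixtures for :func:`arguide.evaluation.survey_summary`.
"""

from __future__ import annotations

import numpy as np

from .evaluation import SurveyTable

__all__ = ["surgeon_survey", "patient_survey"]

_SURGEON_QUESTIONS = [
    "1. AR in surgeries (general)",
    "2. AR in surgeon's operations (general)",
    "3. DEMO: surgeon understanding",
    "4. DEMO: surgical planning",
    "5. DEMO: patient communication",
    "6. CLINIC: PLA bone fragment",
    "7. CLINIC: practice with AR",
    "8. CLINIC: patient communication",
    "9. SURGERY: tumor location",
    "10. SURGERY: increase of accuracy",
    "11. SURGERY: phone case",
    "12. GENERIC: easiness of interpretation",
    "13. GENERIC: patient communication",
    "14. GENERIC: surgeon's confidently",
    "15. GENERIC: use this workflow",
]

_SURGEON_SCORES = [
    [5, 4, 5, 5, 3, 5],
    [5, 4, 3, 3, 4, 5],
    [5, 4, 5, 5, 4, 5],
    [5, 4, 5, 5, 5, 5],
    [5, 5, 5, 5, 5, 5],
    [5, 4, 4, 5, 4, 5],
    [5, 3, 4, 5, 5, 5],
    [5, 3, 5, 5, 3, 5],
    [5, 5, 4, 5, 4, 5],
    [5, 4, 4, 5, 5, 5],
    [5, 4, 5, 5, 5, 5],
    [5, 5, 4, 5, 4, 5],
    [5, 5, 5, 5, 5, 5],
    [4, 4, 5, 5, 4, 5],
    [5, 4, 4, 5, 4, 5],
]

_PATIENT_QUESTIONS = [
    "1. Pathology understanding before ARHealth",
    "2. Pathology understanding after ARHealth",
    "3. General opinion about AR",
]

_PATIENT_SCORES = [
    [2, 4],
    [5, 5],
    [5, 5],
]


def surgeon_survey() -> SurveyTable:
    """The surgeons' questionnaire scores (15 questions x 6 surgeons)."""
    return SurveyTable(list(_SURGEON_QUESTIONS),
                       [str(i) for i in range(1, 7)],
                       np.array(_SURGEON_SCORES))


def patient_survey() -> SurveyTable:
    """The patients' questionnaire scores (3 questions x 2 patients)."""
    return SurveyTable(list(_PATIENT_QUESTIONS), ["1", "2"], np.array(_PATIENT_SCORES))
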