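"""Questionnaire scales, treatment arms and the assessment schedule.

Each treatment arm has one primary self-report questionnaire; all three are
scored from 0 to a scale-specific maximum:

* depression       -> MADRS-S  (Montgomery-Asberg Depression Rating Scale,
                     self-report), max 54
* panic            -> PDSS-SR  (Panic Disorder Severity Scale, self-report),
                     max 28
* social_anxiety   -> LSAS-SR  (Liebowitz Social Anxiety Scale, self-report),
                     max 144

Assessments happen at screening, immediately before treatment (pre), weekly
during the 12-week treatment, and after treatment (post).
"""

from __future__ import annotations

TREATMENTS = ("depression", "panic", "social_anxiety")

SCALE_BY_TREATMENT = {
    "depression": "MADRS-S",
    "panic": "PDSS-SR",
    "social_anxiety": "LSAS-SR",
}

SCALE_MAX = {"MADRS-S": 54, "PDSS-SR": 28, "LSAS-SR": 144}

VALID_SCALE_MAXIMA = frozenset(SCALE_MAX.values())

TIMEPOINTS = ("screening", "pre") + tuple(f"week{i}" for i in range(1, 13)) + ("post",)

#: timepoints available at prediction time (through day 28 of treatment)
EARLY_TIMEPOINTS = ("screening", "pre", "week1", "week2", "week3", "week4")


def scale_for_treatment(treatment: str) -> tuple[str, int]:
    """Return ``(scale_id, scale_max)`` for a treatment arm."""
    if treatment not in SCALE_BY_TREATMENT:
        raise ValueError(f"unknown treatment {treatment!r}; expected one of {TREATMENTS}")
    scale_id = SCALE_BY_TREATMENT[treatment]
    return scale_id, SCALE_MAX[scale_id]
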