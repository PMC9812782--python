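"""Linear human-to-mouse duration translation.

Cross-species scaling of clinical duration criteria rests on a
developmental-stage matrix summarized by two anchor pairs: 10 human months
correspond to 52 mouse hours (about 2.16 days) for young adult mice
(10-64 weeks of age) and to 176.5 mouse hours (about 7.35 days) for
presenescent mice (65-72 weeks).  Translation is linear through the origin,
so the DSM/ICD 2-week criterion maps to a biologically implausible 2.4 h
(0.1 days) in young adults — the motivation for the framework's fixed
7-day minimum phenotype duration instead.

A month is fixed at 365.25 / 12 = 30.4375 days; this convention reproduces
the printed 2.4 h value from the 52 h anchor.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "AgeClass",
    "AgeClassAnchor",
    "ANCHORS",
    "DAYS_PER_MONTH",
    "HUMAN_ANCHOR_MONTHS",
    "mouse_age_class",
    "human_to_mouse_hours",
    "mouse_hours_to_human_days",
]

DAYS_PER_MONTH = 365.25 / 12.0
HUMAN_ANCHOR_MONTHS = 10.0


class AgeClass(str, enum.Enum):
    YOUNG_ADULT = "young_adult"  # 10-64 weeks
    PRESENESCENT = "presenescent"  # 65-72 weeks


@dataclass(frozen=True)
class AgeClassAnchor:
    """One anchor pair: 10 human months <-> ``mouse_hours_anchor`` hours."""

    age_class: AgeClass
    min_weeks: float
    max_weeks: float
    mouse_hours_anchor: float
    human_months_anchor: float = HUMAN_ANCHOR_MONTHS
    days_per_month: float = DAYS_PER_MONTH

    def __post_init__(self) -> None:
        if self.mouse_hours_anchor <= 0:
            raise ValueError("mouse_hours_anchor must be > 0")

    @property
    def human_days_anchor(self) -> float:
        return self.human_months_anchor * self.days_per_month


ANCHORS: dict[AgeClass, AgeClassAnchor] = {
    AgeClass.YOUNG_ADULT: AgeClassAnchor(AgeClass.YOUNG_ADULT, 10.0, 64.0, 52.0),
    AgeClass.PRESENESCENT: AgeClassAnchor(AgeClass.PRESENESCENT, 65.0, 72.0, 176.5),
}


def mouse_age_class(age_weeks: float) -> AgeClass:
    """Map a mouse age in weeks to its supported age class.

    Ages outside 10-64 (young adult) and 65-72 (presenescent) weeks —
    including the 64-65 week gap between the published ranges — raise
    ``ValueError``: juvenile and senescent mice are not covered by the
    anchor pairs.
    """
    if age_weeks <= 0:
        raise ValueError(f"age_weeks must be > 0, got {age_weeks}")
    for anchor in ANCHORS.values():
        if anchor.min_weeks <= age_weeks <= anchor.max_weeks:
            return anchor.age_class
    raise ValueError(
        f"mouse age {age_weeks} weeks is outside the supported ranges "
        "(young adult 10-64, presenescent 65-72)"
    )


def human_to_mouse_hours(
    human_duration_days: float, age_class: AgeClass | str
) -> float:
    """Translate a human duration (days) into mouse-equivalent hours.

    Linear through the origin:  hours = days * anchor_hours / anchor_days,
    where anchor_days = 10 months * 30.4375 days/month = 304.375.

    >>> human_to_mouse_hours(10 * DAYS_PER_MONTH, AgeClass.YOUNG_ADULT)
    52.0
    """
    if human_duration_days < 0:
        raise ValueError("duration must be >= 0")
    anchor = ANCHORS[AgeClass(age_class)]
    return human_duration_days * anchor.mouse_hours_anchor / anchor.human_days_anchor


def mouse_hours_to_human_days(mouse_hours: float, age_class: AgeClass | str) -> float:
    """Inverse translation: mouse hours back to human days."""
    if mouse_hours < 0:
        raise ValueError("duration must be >= 0")
    anchor = ANCHORS[AgeClass(age_class)]
    return mouse_hours * anchor.human_days_anchor / anchor.mouse_hours_anchor
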