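"""Stenosis-degree triage: grade vocabulary and the combined decision rule.

Coronary CT angiography (CCTA) reads assign each vessel an ordinal
degree-of-stenosis (DS) category.  The triage rule decides the extremes
from the grade alone — patients whose maximum grade is at most 24% DS
are called non-significant (probability 0), patients at >=70% DS are
called significant (probability 1) — and defers the intermediate band
(25–69% DS) to a learned classifier operating on the myocardium.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "StenosisGrade",
    "TriageResult",
    "patient_max_grade",
    "triage_group",
    "combined_probability",
]


class StenosisGrade(enum.Enum):
    """Ordinal CCTA degree-of-stenosis category.

    G0..G4 are totally ordered; ND (non-diagnostic segment) sits outside
    the ordering and is ignored whenever a diagnostic grade exists.
    """

    G0 = "0%"
    G1 = "1-24%"
    G2 = "25-49%"
    G3 = "50-69%"
    G4 = ">=70%"
    ND = "ND"

    @property
    def ordinal(self) -> int:
        """Rank 0..4 for diagnostic grades; ND has no rank."""
        if self is StenosisGrade.ND:
            raise ValueError("ND has no ordinal rank")
        return "G0 G1 G2 G3 G4".split().index(self.name)

    @classmethod
    def from_token(cls, token: str) -> "StenosisGrade":
        token = str(token).strip()
        by_name = {g.name: g for g in cls}
        by_value = {g.value: g for g in cls}
        if token in by_name:
            return by_name[token]
        if token in by_value:
            return by_value[token]
        raise ValueError(
            f"unknown stenosis grade token {token!r}; expected one of "
            f"{sorted(by_name)} or {sorted(by_value)}"
        )


@dataclass(frozen=True)
class TriageResult:
    patient_id: str
    group: str  # non_significant | intermediate | significant
    probability: float
    source: str  # grade_rule | classifier

    def __post_init__(self):
        if self.group == "non_significant" and (
            self.probability != 0.0 or self.source != "grade_rule"
        ):
            raise ValueError("non_significant requires probability 0 from grade_rule")
        if self.group == "significant" and (
            self.probability != 1.0 or self.source != "grade_rule"
        ):
            raise ValueError("significant requires probability 1 from grade_rule")
        if self.group == "intermediate" and self.source != "classifier":
            raise ValueError("intermediate probability must come from the classifier")


def patient_max_grade(vessel_grades) -> StenosisGrade:
    """Maximum grade over a patient's vessels, ignoring ND segments.

    If every segment is non-diagnostic the result is ND; such patients
    are flagged for exclusion downstream rather than triaged.
    """
    grades = list(vessel_grades)
    if not grades:
        raise ValueError("patient has no vessel grades")
    diagnostic = [g for g in grades if g is not StenosisGrade.ND]
    if not diagnostic:
        return StenosisGrade.ND
    return max(diagnostic, key=lambda g: g.ordinal)


_GROUP = {
    "G0": "non_significant",
    "G1": "non_significant",
    "G2": "intermediate",
    "G3": "intermediate",
    "G4": "significant",
}


def triage_group(grade: StenosisGrade) -> str:
    """Map a diagnostic maximum grade to its triage group."""
    if grade is StenosisGrade.ND:
        raise ValueError(
            "all segments non-diagnostic: patient must be excluded, not triaged"
        )
    return _GROUP[grade.name]


def combined_probability(group: str, classifier_prob: float | None = None) -> float:
    """Probability of functionally significant stenosis under the combined rule.

    Extremes are decided by the grade alone (0.0 / 1.0); the classifier
    probability is passed through unchanged for intermediates.  Supplying
    a classifier probability for an extreme is rejected to guard against
    silent misuse.
    """
    if group == "non_significant":
        if classifier_prob is not None:
            raise ValueError("classifier probability not used for non_significant")
        return 0.0
    if group == "significant":
        if classifier_prob is not None:
            raise ValueError("classifier probability not used for significant")
        return 1.0
    if group == "intermediate":
        if classifier_prob is None:
            raise ValueError("intermediate patients require a classifier probability")
        p = float(classifier_prob)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0, 1]")
        return p
    raise ValueError(f"unknown triage group {group!r}")
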