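"""Clinical data model: CSVD marker grades, cognitive battery, eligibility.

The cerebral small vessel disease (CSVD) markers are visual ratings, not
image segmentations: white matter lesion (WML) severity is a modified
Fazekas grade 0–3 rated separately in the periventricular and deep
regions and then summed; lacunes (3–15 mm cavities) and cerebral
microbleeds (CMBs, <10 mm) enter as counts; enlarged perivascular spaces
(PVS) are graded 0–4 from the count in the worst slice per region, with
grade >2 in either centrum semiovale or basal ganglia called moderate to
severe.

Cognitive impairment is classified from the MoCA with education-adjusted
cutoffs: scores of 13/14, 19/20 and 24/25 separate impaired from normal
for 0, 1–6 and >=7 years of education respectively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

__all__ = [
    "CsvdMarkers",
    "CognitiveBattery",
    "SubjectRecord",
    "ClinicalError",
    "EligibilityResult",
    "wml_total",
    "pvs_grade",
    "is_moderate_severe_pvs",
    "classify_cognition",
    "check_inclusion",
    "CLINICAL_COLUMNS",
]

Group = Literal["CN", "CI"]

#: column dictionary for the delimited clinical table (missing = empty cell,
#: booleans as 0/1)
CLINICAL_COLUMNS = {
    "subject_id": "unique subject identifier",
    "group": "cognitive classification: CN or CI",
    "age": "age in years",
    "male": "1 = male, 0 = female",
    "education": "education in years",
    "hypertension": "history of hypertension (0/1, may be missing)",
    "diabetes": "history of diabetes mellitus (0/1, may be missing)",
    "smoking": "current or former smoking (0/1, may be missing)",
    "alcohol": "alcohol abuse (0/1, may be missing)",
    "wml_pv": "periventricular Fazekas grade 0-3",
    "wml_deep": "deep white matter Fazekas grade 0-3",
    "wml_sum": "summed Fazekas grade (periventricular + deep)",
    "lacunes": "total lacune count",
    "cmbs": "total cerebral microbleed count",
    "pvs_cso": "PVS grade, centrum semiovale (0-4)",
    "pvs_bg": "PVS grade, basal ganglia (0-4)",
    "pvs_moderate_severe": "1 if either PVS grade > 2",
    "alps_index": "DTI-ALPS index",
    "moca": "Montreal Cognitive Assessment (0-30)",
    "tmt_b_a": "Trail Making Test B minus A time, seconds",
    "avlt_sum": "Auditory Verbal Learning Test, sum of five recalls",
    "sdmt": "Symbol Digit Modalities Test, correct count",
    "vft": "Verbal Fluency Test total",
    "bnt": "Boston Naming Test",
    "rcft_c": "Rey Complex Figure Test, copy trial",
}


class ClinicalError(ValueError):
    pass


def wml_total(pv_grade: int, deep_grade: int) -> int:
    """Summed Fazekas grade: periventricular + deep, each 0–3."""
    for name, g in (("periventricular", pv_grade), ("deep", deep_grade)):
        if int(g) != g or not 0 <= g <= 3:
            raise ClinicalError(f"{name} Fazekas grade {g!r} outside 0-3")
    return int(pv_grade) + int(deep_grade)


def pvs_grade(count_in_worst_slice: int) -> int:
    """Ordinal PVS grade from the count in the worst slice.

    0 -> 0, 1-10 -> 1, 11-20 -> 2, 21-40 -> 3, >40 -> 4.
    """
    c = count_in_worst_slice
    if int(c) != c or c < 0:
        raise ClinicalError(f"PVS count must be a non-negative integer, got {c!r}")
    if c == 0:
        return 0
    if c <= 10:
        return 1
    if c <= 20:
        return 2
    if c <= 40:
        return 3
    return 4


def is_moderate_severe_pvs(cso_grade: int, bg_grade: int) -> bool:
    """Moderate-to-severe PVS: grade strictly greater than 2 in either the
    centrum semiovale or the basal ganglia."""
    for name, g in (("centrum semiovale", cso_grade), ("basal ganglia", bg_grade)):
        if int(g) != g or not 0 <= g <= 4:
            raise ClinicalError(f"{name} PVS grade {g!r} outside 0-4")
    return cso_grade > 2 or bg_grade > 2


def classify_cognition(moca: int, education_years: float | None) -> Group:
    """Education-adjusted MoCA classification into CN / CI.

    CI iff MoCA <= 13 (0 years of education), <= 19 (1–6 years) or <= 24
    (7 or more years).
    """
    if education_years is None:
        raise ClinicalError("education is required for the MoCA cutoff")
    if not 0 <= moca <= 30:
        raise ClinicalError(f"MoCA {moca!r} outside 0-30")
    if education_years < 0:
        raise ClinicalError("education years must be non-negative")
    if education_years == 0:
        cutoff = 13
    elif education_years <= 6:
        cutoff = 19
    else:
        cutoff = 24
    return "CI" if moca <= cutoff else "CN"


@dataclass
class CsvdMarkers:
    wml_pv: int
    wml_deep: int
    lacunes: int
    cmbs: int
    pvs_cso: int
    pvs_bg: int

    def __post_init__(self) -> None:
        self.wml_sum = wml_total(self.wml_pv, self.wml_deep)
        if self.lacunes < 0 or self.cmbs < 0:
            raise ClinicalError("lesion counts must be non-negative")
        self.pvs_moderate_severe = is_moderate_severe_pvs(self.pvs_cso, self.pvs_bg)


@dataclass
class CognitiveBattery:
    moca: int
    tmt_b_a: float
    avlt_sum: float
    sdmt: float
    vft: float
    bnt: float
    rcft_c: float

    def __post_init__(self) -> None:
        if not 0 <= self.moca <= 30 or int(self.moca) != self.moca:
            raise ClinicalError(f"MoCA {self.moca!r} must be an integer in 0-30")
        # negative TMT(B-A) is possible in principle but suspicious
        self.tmt_flag = self.tmt_b_a < 0


@dataclass
class SubjectRecord:
    subject_id: str
    age: float
    male: bool
    education: float
    markers: CsvdMarkers
    battery: CognitiveBattery
    hypertension: Optional[bool] = None
    diabetes: Optional[bool] = None
    smoking: Optional[bool] = None
    alcohol: Optional[bool] = None
    alps_index: Optional[float] = None

    @property
    def group(self) -> Group:
        return classify_cognition(self.battery.moca, self.education)


@dataclass
class EligibilityResult:
    eligible: bool
    reasons: list[str]


def check_inclusion(record: SubjectRecord) -> EligibilityResult:
    """Study eligibility: Fazekas 2–3 WMLs (at least one region graded >=2),
    at least one further CSVD marker (lacune, CMB, or moderate-to-severe
    PVS), and age 50–80. Report-only."""
    reasons: list[str] = []
    m = record.markers
    if max(m.wml_pv, m.wml_deep) < 2:
        reasons.append("WML criterion: no region with Fazekas grade >= 2")
    has_marker = m.lacunes > 0 or m.cmbs > 0 or m.pvs_moderate_severe
    if not has_marker:
        reasons.append("no additional CSVD marker (lacune, CMB, or moderate-severe PVS)")
    if not 50 <= record.age <= 80:
        reasons.append(f"age {record.age:g} outside the 50-80 band")
    return EligibilityResult(eligible=not reasons, reasons=reasons)
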