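"""Risk-factor computation.

Each present, non-vetoed clinical feature scores an integer 0-3; features
typical of the elderly score higher when they manifest early (the age
modifier). The per-patient risk factor is the plain integer sum of feature
scores — a transparent screening statistic that is thresholded at a cut-off
to flag patients for confirmatory testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .phenotype import ClinicalFeature, FeatureAssignment, FeatureCatalog, PatientRecord

__all__ = ["RiskProfile", "score_feature", "compute_risk_factor", "rank_cohort"]


@dataclass(frozen=True)
class RiskProfile:
    patient_id: str
    feature_scores: dict[str, int]
    risk_factor: int
    age_boost_applied: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.risk_factor != sum(self.feature_scores.values()):
            raise ValueError("risk_factor must equal the sum of feature scores")
        for fid, s in self.feature_scores.items():
            if not (0 <= s <= 3):
                raise ValueError(f"score of {fid} out of range: {s}")


def score_feature(feature: ClinicalFeature, present: bool, age: float) -> int:
    """Score one feature for one patient: 0 if absent, else the base score,
    raised to the age modifier's boosted value for early manifestation.
    Never exceeds 3."""
    if age < 0:
        raise ValueError("age must be >= 0")
    if not present:
        return 0
    score = feature.base_score
    if feature.age_modifier is not None and age < feature.age_modifier.below_age:
        score = max(score, feature.age_modifier.boosted_score)
    return min(score, 3)


def compute_risk_factor(
    assignment: FeatureAssignment,
    record: PatientRecord,
    catalog: FeatureCatalog,
) -> RiskProfile:
    """Sum the scores of all present features into the patient's risk factor.

    The assignment must be final (feature exclusions already applied):
    vetoed and absent features score zero.
    """
    scores: dict[str, int] = {}
    boosted: set[str] = set()
    for feat in catalog:
        present = feat.feature_id in assignment.present
        s = score_feature(feat, present, record.age)
        scores[feat.feature_id] = s
        if (
            present
            and feat.age_modifier is not None
            and record.age < feat.age_modifier.below_age
            and s > feat.base_score
        ):
            boosted.add(feat.feature_id)
    return RiskProfile(
        patient_id=assignment.patient_id or record.patient_id,
        feature_scores=scores,
        risk_factor=sum(scores.values()),
        age_boost_applied=frozenset(boosted),
    )


def rank_cohort(profiles: Sequence[RiskProfile]) -> list[RiskProfile]:
    """Profiles sorted by risk factor, highest first; ties keep input order."""
    return sorted(profiles, key=lambda p: -p.risk_factor)
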