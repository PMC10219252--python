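"""End-to-end orchestration: record -> entities -> features -> risk profile.

Ties the NER, phenotype-mapping and scoring layers together for whole
records and cohorts. Text evidence comes from the patient's notes; ICD-10
codes contribute by prefix matching (their expanded descriptions are used
for human-readable evidence strings); structured labs contribute through
the catalog's threshold rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .extract import AFFIRMED, ExtractedEntity, MatcherConfig, extract_entities
from .lexicon import Lexicon
from .phenotype import (
    Eligibility,
    FeatureAssignment,
    FeatureCatalog,
    PatientRecord,
    apply_exclusions,
    assign_features,
    cohort_filter,
    expand_icd10,
    parse_labs,
)
from .scoring import RiskProfile, compute_risk_factor

__all__ = ["NoteEntity", "ScoredRecord", "extract_record", "score_record", "score_cohort"]


@dataclass(frozen=True)
class NoteEntity:
    """An extracted entity located within one of a record's notes."""

    note_index: int
    entity: ExtractedEntity


@dataclass
class ScoredRecord:
    patient_id: str
    eligibility: Eligibility
    assignment: Optional[FeatureAssignment]
    profile: Optional[RiskProfile]
    icd_evidence: dict[str, str]  # code -> expanded description


def extract_record(
    record: PatientRecord,
    lexicon: Lexicon,
    config: Optional[MatcherConfig] = None,
) -> list[NoteEntity]:
    """Run entity extraction over every note of a record."""
    out: list[NoteEntity] = []
    for n_idx, note in enumerate(record.notes):
        for ent in extract_entities(note, lexicon, config):
            out.append(NoteEntity(note_index=n_idx, entity=ent))
    return out


def score_record(
    record: PatientRecord,
    lexicon: Lexicon,
    catalog: FeatureCatalog,
    config: Optional[MatcherConfig] = None,
    icd_table: Optional[Mapping[str, str]] = None,
    entities: Optional[Iterable[NoteEntity]] = None,
) -> ScoredRecord:
    """Filter, map and score one record.

    Pre-extracted entities may be supplied (e.g. from an entities file);
    otherwise extraction runs here. Ineligible patients get no profile.
    """
    if entities is None:
        entities = extract_record(record, lexicon, config)
    flat = [ne.entity for ne in entities]
    affirmed = [e for e in flat if e.polarity == AFFIRMED]
    icd_evidence = {
        code: expand_icd10(code, icd_table) if icd_table is not None else ""
        for code in record.icd10_codes
    }
    eligibility = cohort_filter(record, catalog, affirmed)
    if not eligibility.eligible:
        return ScoredRecord(
            patient_id=record.patient_id,
            eligibility=eligibility,
            assignment=None,
            profile=None,
            icd_evidence=icd_evidence,
        )
    findings = parse_labs(record.labs, catalog.lab_rules)
    assignment = assign_features(
        affirmed, record.icd10_codes, findings, catalog, patient_id=record.patient_id
    )
    assignment = apply_exclusions(assignment, record, catalog, affirmed)
    profile = compute_risk_factor(assignment, record, catalog)
    return ScoredRecord(
        patient_id=record.patient_id,
        eligibility=eligibility,
        assignment=assignment,
        profile=profile,
        icd_evidence=icd_evidence,
    )


def score_cohort(
    records: Iterable[PatientRecord],
    lexicon: Lexicon,
    catalog: FeatureCatalog,
    config: Optional[MatcherConfig] = None,
    icd_table: Optional[Mapping[str, str]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a cohort; returns (scores, excluded) data frames.

    ``scores`` has one row per eligible patient: patient_id, one column per
    catalog feature, risk_factor and true_label (when present). ``excluded``
    lists ineligible patients with the first triggered criterion.
    """
    score_rows = []
    excluded_rows = []
    for record in records:
        scored = score_record(record, lexicon, catalog, config, icd_table)
        if not scored.eligibility.eligible:
            excluded_rows.append(
                {"patient_id": record.patient_id, "reason": scored.eligibility.reason}
            )
            continue
        row = {"patient_id": record.patient_id}
        row.update(scored.profile.feature_scores)
        row["risk_factor"] = scored.profile.risk_factor
        row["true_label"] = record.true_label
        score_rows.append(row)
    feature_cols = list(catalog.feature_ids)
    scores = pd.DataFrame(
        score_rows, columns=["patient_id", *feature_cols, "risk_factor", "true_label"]
    )
    excluded = pd.DataFrame(excluded_rows, columns=["patient_id", "reason"])
    return scores, excluded
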