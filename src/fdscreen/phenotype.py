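"""Mapping heterogeneous evidence onto the 13 scored clinical features.

Evidence from three channels — affirmed text mentions, ICD-10 codes
(matched by prefix) and structured lab findings — is mapped to feature
presence. A present feature is vetoed when a confirmed alternative cause is
documented in the same record (e.g. amyloidosis explains renal failure, a
patent foramen ovale explains stroke). Cohort-level inclusion (age 18-75)
and exclusion conditions (palliative care, alcohol dependency, disseminated
cancer, blood cancer, chemotherapy) are applied before any scoring.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .extract import AFFIRMED, ExtractedEntity
from .lexicon import Lexicon

__all__ = [
    "PatientRecord",
    "LabResult",
    "ClinicalFeature",
    "AgeModifier",
    "Condition",
    "LabRule",
    "FeatureCatalog",
    "FeatureAssignment",
    "Eligibility",
    "expand_icd10",
    "parse_labs",
    "cohort_filter",
    "assign_features",
    "apply_exclusions",
    "load_catalog",
    "default_catalog",
    "load_icd10_table",
    "default_icd10_table",
    "check_consistency",
]

logger = logging.getLogger(__name__)

SIGN_GROUPS = frozenset({"cardiovascular", "kidney", "skin", "neurological", "eye"})

_ICD10_RE = re.compile(r"^[A-Za-z]\d{2}(\.[A-Za-z0-9]{1,4})?$")


@dataclass(frozen=True)
class LabResult:
    analyte: str
    value: float
    unit: str
    flag: Optional[str] = None


@dataclass
class PatientRecord:
    patient_id: str
    age: float
    sex: str  # female | male
    notes: list[str] = field(default_factory=list)
    icd10_codes: list[str] = field(default_factory=list)
    labs: list[LabResult] = field(default_factory=list)
    true_label: Optional[str] = None  # case | control (evaluation only)

    def __post_init__(self):
        if self.age < 0:
            raise ValueError("age must be >= 0")
        if self.sex not in ("female", "male"):
            raise ValueError(f"invalid sex: {self.sex!r}")
        for code in self.icd10_codes:
            if not _ICD10_RE.match(code):
                raise ValueError(f"malformed ICD-10 code: {code!r}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "PatientRecord":
        labs = [
            lab if isinstance(lab, LabResult) else LabResult(**lab)
            for lab in d.get("labs", [])
        ]
        return cls(
            patient_id=str(d["patient_id"]),
            age=float(d["age"]),
            sex=d["sex"],
            notes=list(d.get("notes", [])),
            icd10_codes=list(d.get("icd10_codes", [])),
            labs=labs,
            true_label=d.get("true_label"),
        )

    def to_dict(self) -> dict:
        d = {
            "patient_id": self.patient_id,
            "age": self.age,
            "sex": self.sex,
            "notes": self.notes,
            "icd10_codes": self.icd10_codes,
            "labs": [vars(lab) for lab in self.labs],
        }
        if self.true_label is not None:
            d["true_label"] = self.true_label
        return d


@dataclass(frozen=True)
class AgeModifier:
    """Raise a feature's score for early manifestation.

    ``boosted_score`` replaces the base score when the patient is younger
    than ``below_age``; it never exceeds 3.
    """

    below_age: float
    boosted_score: int

    def __post_init__(self):
        if not (0 <= self.boosted_score <= 3):
            raise ValueError("boosted score must be within 0..3")


@dataclass(frozen=True)
class ClinicalFeature:
    feature_id: str
    name: str
    sign_group: str
    base_score: int
    evidence_terms: tuple[str, ...] = ()
    icd10_prefixes: tuple[str, ...] = ()
    lab_findings: tuple[str, ...] = ()
    exclusion_conditions: tuple[str, ...] = ()
    age_modifier: Optional[AgeModifier] = None

    def __post_init__(self):
        if self.sign_group not in SIGN_GROUPS:
            raise ValueError(f"unknown sign group: {self.sign_group!r}")
        if not (0 <= self.base_score <= 3):
            raise ValueError("base score must be within 0..3")


@dataclass(frozen=True)
class Condition:
    """A confounder or cohort-exclusion condition and its evidence."""

    condition_id: str
    name: str
    terms: tuple[str, ...] = ()
    icd10_prefixes: tuple[str, ...] = ()


@dataclass(frozen=True)
class LabRule:
    """Threshold rule turning a structured lab value into a finding."""

    finding: str
    analyte: str
    op: str  # < <= > >=
    threshold: float
    unit: str

    _OPS = {
        "<": lambda v, t: v < t,
        "<=": lambda v, t: v <= t,
        ">": lambda v, t: v > t,
        ">=": lambda v, t: v >= t,
    }

    def applies(self, value: float) -> bool:
        return self._OPS[self.op](value, self.threshold)


class FeatureCatalog:
    """The scored feature list plus cohort- and feature-level exclusion rules."""

    def __init__(
        self,
        features: Sequence[ClinicalFeature],
        conditions: Sequence[Condition] = (),
        cohort_inclusion: tuple[float, float] = (18.0, 75.0),
        cohort_exclusions: Sequence[str] = (),
        lab_rules: Sequence[LabRule] = (),
    ):
        ids = [f.feature_id for f in features]
        if len(set(ids)) != len(ids):
            raise ValueError("feature ids must be unique")
        self.features = list(features)
        self._by_id = {f.feature_id: f for f in features}
        self.conditions = {c.condition_id: c for c in conditions}
        self.cohort_inclusion = cohort_inclusion
        self.cohort_exclusions = list(cohort_exclusions)
        for cid in self.cohort_exclusions:
            if cid not in self.conditions:
                raise ValueError(f"cohort exclusion references unknown condition {cid!r}")
        for f in features:
            for cid in f.exclusion_conditions:
                if cid not in self.conditions:
                    raise ValueError(
                        f"feature {f.feature_id!r} references unknown condition {cid!r}"
                    )
        self.lab_rules = list(lab_rules)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def get(self, feature_id: str) -> ClinicalFeature:
        return self._by_id[feature_id]

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    @property
    def sign_groups(self) -> set[str]:
        return {f.sign_group for f in self.features}

    @property
    def max_risk_factor(self) -> int:
        return 3 * len(self.features)


@dataclass
class FeatureAssignment:
    """Presence/absence of the catalog features for one patient.

    ``present`` maps feature id to the evidence references supporting it;
    ``vetoed`` maps feature id to the condition that vetoed it. The two sets
    are disjoint.
    """

    patient_id: str
    present: dict[str, list[str]] = field(default_factory=dict)
    vetoed: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        overlap = set(self.present) & set(self.vetoed)
        if overlap:
            raise ValueError(f"features both present and vetoed: {sorted(overlap)}")


@dataclass(frozen=True)
class Eligibility:
    eligible: bool
    reason: Optional[str] = None


# -- operations ---------------------------------------------------------------


def expand_icd10(code: str, code_table: Mapping[str, str]) -> str:
    """Full description of an ICD-10 code; longest-prefix fallback.

    Unknown codes yield an empty description (with a logged warning);
    syntactically invalid codes raise ``ValueError``.
    """
    if not _ICD10_RE.match(code or ""):
        raise ValueError(f"malformed ICD-10 code: {code!r}")
    code_u = code.upper()
    if code_u in code_table:
        return code_table[code_u]
    best = ""
    for key in code_table:
        if code_u.startswith(key.upper()) and len(key) > len(best):
            best = key
    if best:
        return code_table[best]
    logger.warning("ICD-10 code %s not found in code table", code)
    return ""


def parse_labs(labs: Iterable[LabResult], rules: Sequence[LabRule]) -> list[str]:
    """Lab-derived findings (e.g. reduced eGFR) from structured results.

    A finding is emitted iff a rule's comparator holds for a lab value with a
    matching analyte and unit. Unit mismatches are skipped with a warning.
    """
    findings: list[str] = []
    for lab in labs:
        for rule in rules:
            if lab.analyte.lower() != rule.analyte.lower():
                continue
            if lab.unit != rule.unit:
                logger.warning(
                    "lab %s: unit %r does not match rule unit %r; skipped",
                    lab.analyte,
                    lab.unit,
                    rule.unit,
                )
                continue
            if rule.applies(lab.value) and rule.finding not in findings:
                findings.append(rule.finding)
    return findings


def _condition_evidence(
    condition: Condition,
    entities: Iterable[ExtractedEntity],
    icd10_codes: Iterable[str],
) -> Optional[str]:
    """First evidence item documenting a condition, or None."""
    term_set = set(condition.terms)
    for ent in entities:
        if ent.polarity == AFFIRMED and ent.term_id in term_set:
            return f"entity:{ent.term_id}"
    for code in icd10_codes:
        for prefix in condition.icd10_prefixes:
            if code.upper().startswith(prefix.upper()):
                return f"icd10:{code}"
    return None


def cohort_filter(
    record: PatientRecord,
    catalog: FeatureCatalog,
    entities: Iterable[ExtractedEntity] = (),
) -> Eligibility:
    """Apply the cohort inclusion/exclusion criteria to one record.

    A patient is excluded iff their age falls outside the inclusive age
    bounds or any cohort-exclusion condition is evidenced by an affirmed
    mention or a matching ICD-10 code. The reason names the first triggered
    criterion (age first, then catalog order).
    """
    lo, hi = catalog.cohort_inclusion
    if not (lo <= record.age <= hi):
        return Eligibility(eligible=False, reason="age")
    entities = list(entities)
    for cid in catalog.cohort_exclusions:
        cond = catalog.conditions[cid]
        if _condition_evidence(cond, entities, record.icd10_codes) is not None:
            return Eligibility(eligible=False, reason=cid)
    return Eligibility(eligible=True)


def assign_features(
    entities: Iterable[ExtractedEntity],
    icd10_codes: Iterable[str],
    lab_findings: Iterable[str],
    catalog: FeatureCatalog,
    patient_id: str = "",
) -> FeatureAssignment:
    """Pre-exclusion feature assignment from affirmed evidence.

    A feature is present iff at least one of its evidence terms matches an
    affirmed entity, one of its ICD-10 prefixes matches a code, or one of
    its lab findings was emitted. Negated entities must not be passed in.
    """
    entities = list(entities)
    for ent in entities:
        if ent.polarity != AFFIRMED:
            raise ValueError("assign_features accepts affirmed entities only")
    icd10_codes = list(icd10_codes)
    lab_findings = list(lab_findings)
    present: dict[str, list[str]] = {}
    for feat in catalog:
        evidence: list[str] = []
        term_set = set(feat.evidence_terms)
        for ent in entities:
            if ent.term_id in term_set:
                evidence.append(f"entity:{ent.term_id}")
        for code in icd10_codes:
            if any(code.upper().startswith(p.upper()) for p in feat.icd10_prefixes):
                evidence.append(f"icd10:{code}")
        for finding in lab_findings:
            if finding in feat.lab_findings:
                evidence.append(f"lab:{finding}")
        if evidence:
            present[feat.feature_id] = evidence
    return FeatureAssignment(patient_id=patient_id, present=present)


def apply_exclusions(
    assignment: FeatureAssignment,
    record: PatientRecord,
    catalog: FeatureCatalog,
    entities: Iterable[ExtractedEntity] = (),
) -> FeatureAssignment:
    """Veto present features whose confounder conditions are documented.

    A present feature moves to the vetoed set iff any of its exclusion
    conditions is evidenced (affirmed entity or ICD-10 code) in the same
    record; all other features are unchanged. Idempotent.
    """
    entities = list(entities)
    present = dict(assignment.present)
    vetoed = dict(assignment.vetoed)
    for fid in list(present):
        feat = catalog.get(fid)
        for cid in feat.exclusion_conditions:
            cond = catalog.conditions[cid]
            if _condition_evidence(cond, entities, record.icd10_codes) is not None:
                del present[fid]
                vetoed[fid] = cid
                break
    return FeatureAssignment(
        patient_id=assignment.patient_id, present=present, vetoed=vetoed
    )


# -- configuration loading ----------------------------------------------------


def load_catalog(source) -> FeatureCatalog:
    """Load a feature catalog from a YAML/JSON mapping (path, file or dict)."""
    if isinstance(source, dict):
        cfg = source
    elif hasattr(source, "read"):
        cfg = yaml.safe_load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
    features = []
    for item in cfg["features"]:
        mod = item.get("age_modifier")
        features.append(
            ClinicalFeature(
                feature_id=item["id"],
                name=item.get("name", item["id"]),
                sign_group=item["sign_group"],
                base_score=int(item["base_score"]),
                evidence_terms=tuple(item.get("evidence_terms", [])),
                icd10_prefixes=tuple(item.get("icd10_prefixes", [])),
                lab_findings=tuple(item.get("lab_findings", [])),
                exclusion_conditions=tuple(item.get("exclusion_conditions", [])),
                age_modifier=(
                    AgeModifier(
                        below_age=float(mod["below_age"]),
                        boosted_score=int(mod["boosted_score"]),
                    )
                    if mod
                    else None
                ),
            )
        )
    conditions = [
        Condition(
            condition_id=item["id"],
            name=item.get("name", item["id"]),
            terms=tuple(item.get("terms", [])),
            icd10_prefixes=tuple(item.get("icd10_prefixes", [])),
        )
        for item in cfg.get("conditions", [])
    ]
    inclusion = cfg.get("cohort_inclusion", {"min_age": 18, "max_age": 75})
    lab_rules = [
        LabRule(
            finding=item["finding"],
            analyte=item["analyte"],
            op=item["op"],
            threshold=float(item["threshold"]),
            unit=item["unit"],
        )
        for item in cfg.get("lab_rules", [])
    ]
    return FeatureCatalog(
        features=features,
        conditions=conditions,
        cohort_inclusion=(float(inclusion["min_age"]), float(inclusion["max_age"])),
        cohort_exclusions=cfg.get("cohort_exclusions", []),
        lab_rules=lab_rules,
    )


def default_catalog() -> FeatureCatalog:
    """The packaged 13-feature catalog (a documented, reconstructed default)."""
    ref = resources.files("fdscreen.data").joinpath("catalog.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return load_catalog(fh)


def load_icd10_table(source) -> dict[str, str]:
    """Two-column CSV (code, description) -> mapping."""
    if hasattr(source, "read"):
        reader = csv.reader(source)
        return {row[0].strip().upper(): row[1].strip() for row in reader if row}
    with open(source, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        return {row[0].strip().upper(): row[1].strip() for row in reader if row}


def default_icd10_table() -> dict[str, str]:
    """Minimal bundled code table covering the codes the catalog references."""
    ref = resources.files("fdscreen.data").joinpath("icd10.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return load_icd10_table(fh)


def check_consistency(catalog: FeatureCatalog, lexicon: Lexicon) -> None:
    """Validate that catalog and lexicon reference each other coherently.

    Raises ``ValueError`` if a lexicon entry names an unknown feature, a
    feature has no realizable evidence channel, or a condition references an
    unknown term.
    """
    feature_ids = set(catalog.feature_ids)
    known_terms = set(lexicon.term_ids)
    for entry in lexicon:
        if entry.feature_id is not None and entry.feature_id not in feature_ids:
            raise ValueError(
                f"lexicon term {entry.term_id!r} references unknown feature "
                f"{entry.feature_id!r}"
            )
    for feat in catalog:
        has_terms = any(t in known_terms for t in feat.evidence_terms)
        if not (has_terms or feat.icd10_prefixes or feat.lab_findings):
            raise ValueError(f"feature {feat.feature_id!r} has no realizable evidence")
    for cond in catalog.conditions.values():
        for t in cond.terms:
            if t not in known_terms:
                raise ValueError(
                    f"condition {cond.condition_id!r} references unknown term {t!r}"
                )
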