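"""Seeded synthetic EHR cohorts with mention- and diagnosis-level ground truth.

Real screening cohorts for an ultra-rare disease are private hospital data,
so testing happens on generated ones: free-text notes built from sentence
templates with planted affirmed/negated symptom mentions, single-character
typos, morphological paraphrases and near-miss distractors, plus ICD-10
codes, structured labs and group-specific demographics. The generator
emulates a highly imbalanced hospital population — a handful of true cases
against thousands of mixed-ward controls — with case risk factors
concentrating above the screening cut-off and control risk factors below
it. Every record is paired with a gold annotation describing exactly what
was planted, which makes both the NLP precision audit and end-to-end
score-recovery tests possible.

All randomness flows from one ``numpy`` generator seeded from the spec;
draws happen in a fixed documented order (per patient: age, sex, feature
Bernoullis in catalog order, then per planted feature its channel, surface
form, template and noise draws, then confounder draws, distractor count and
picks, sentence order), so a seed fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .extract import AFFIRMED, NEGATED
from .lexicon import Lexicon
from .phenotype import FeatureCatalog, LabResult, PatientRecord, check_consistency
from .scoring import score_feature
from .textproc import tokenize

__all__ = [
    "CohortSpec",
    "AuditNoiseSettings",
    "GoldMention",
    "GoldAnnotation",
    "generate_cohort",
    "generate_audit_corpus",
    "plant_noise",
]

# Per-feature presence probabilities. Control values are chosen so that the
# five sign-group marginals echo a mixed-ward hospital population
# (cardiovascular ~34%, neurological ~26%, kidney ~10%, eye ~1.5%, skin
# ~0.8%) and control risk factors concentrate in 0-3; case values are chosen
# so case risk factors concentrate in 3-11, with myocardial infarction the
# most frequent case feature and eye findings absent among cases.
DEFAULT_CASE_FEATURE_PROBS = {
    "hypertrophic_cardiomyopathy": 0.28,
    "myocardial_infarction": 0.48,
    "arrhythmia": 0.24,
    "renal_failure": 0.24,
    "proteinuria": 0.20,
    "angiokeratoma": 0.48,
    "hypohidrosis": 0.28,
    "stroke": 0.20,
    "neuropathic_pain": 0.52,
    "hearing_loss": 0.20,
    "gastrointestinal_symptoms": 0.28,
    "recurrent_fever": 0.24,
    "cornea_verticillata": 0.0,
}
DEFAULT_CONTROL_FEATURE_PROBS = {
    "hypertrophic_cardiomyopathy": 0.004,
    "myocardial_infarction": 0.04,
    "arrhythmia": 0.22,
    "renal_failure": 0.02,
    "proteinuria": 0.035,
    "angiokeratoma": 0.001,
    "hypohidrosis": 0.007,
    "stroke": 0.015,
    "neuropathic_pain": 0.004,
    "hearing_loss": 0.04,
    "gastrointestinal_symptoms": 0.16,
    "recurrent_fever": 0.06,
    "cornea_verticillata": 0.01,
}

_AFFIRMED_TEMPLATES = (
    "patient reports {x} today .",
    "examination revealed {x} .",
    "history of {x} noted .",
    "the patient presented with {x} .",
)
_NEGATED_TEMPLATES = (
    "no {x} observed .",
    "patient denies {x} .",
    "without {x} at this visit .",
)
_NEAR_MISS_TEMPLATE = "patient also mentions {x} during interview ."

# Benign filler; wording vetted to stay clear of the default lexicon
# vocabulary (no token within edit distance 1 of a dictionary token).
_DISTRACTOR_SENTENCES = (
    "blood pressure within normal limits .",
    "routine follow up visit completed .",
    "patient slept well and appetite remains good .",
    "vital signs stable on admission .",
    "medication list reviewed and continued unchanged .",
    "physiotherapy sessions planned twice weekly .",
    "dietary counselling provided during the stay .",
    "laboratory samples collected for the routine panel .",
    "chest auscultation clear bilaterally .",
    "discharge planned for tomorrow morning .",
    "family meeting held to discuss the ongoing care plan .",
    "ambulation improving steadily on the ward .",
)

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class CohortSpec:
    """Conditions under which a synthetic cohort is generated.

    The default cohort is a scaled-down, highly imbalanced screening
    population: 5 cases against 7,450 controls (~1:1,490), case ages drawn
    from N(45.2, 10.5) and control ages from N(55.5, 13.3) clipped to the
    18-75 inclusion window, 38.5% female cases and 50.5% female controls.
    """

    n_cases: int = 5
    n_controls: int = 7450
    seed: int = 0
    case_feature_probs: dict = field(
        default_factory=lambda: dict(DEFAULT_CASE_FEATURE_PROBS)
    )
    control_feature_probs: dict = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_FEATURE_PROBS)
    )
    negation_rate: float = 0.10
    typo_rate: float = 0.05
    paraphrase_rate: float = 0.05
    confounder_rate: float = 0.15
    min_case_features: int = 3
    distractor_sentences_per_note: tuple[int, int] = (1, 4)
    case_age: tuple[float, float] = (45.2, 10.5)
    control_age: tuple[float, float] = (55.5, 13.3)
    case_female_rate: float = 0.385
    control_female_rate: float = 0.505

    def __post_init__(self):
        for name in (
            "negation_rate",
            "typo_rate",
            "paraphrase_rate",
            "confounder_rate",
            "case_female_rate",
            "control_female_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("cohort sizes must be >= 0")


@dataclass(frozen=True)
class AuditNoiseSettings:
    """Noise applied to the precision-audit corpus."""

    typo_rate: float = 0.08
    negation_rate: float = 0.15
    near_miss_rate: float = 0.10
    distractor_range: tuple[int, int] = (1, 3)


@dataclass(frozen=True)
class GoldMention:
    term_id: str
    note_index: int
    sentence_index: int
    token_span: tuple[int, int]
    polarity: str


@dataclass(frozen=True)
class GoldAnnotation:
    patient_id: str
    mentions: tuple[GoldMention, ...]
    true_features: frozenset[str]
    intended_risk_factor: int
    true_label: str
    vetoed_features: frozenset[str] = frozenset()


# -- low-level text assembly --------------------------------------------------


def _render_tokens(tokens: Sequence[str], capitalize: bool = True) -> str:
    parts: list[str] = []
    for tok in tokens:
        if parts and (tok.isalnum() or tok.startswith("'")):
            parts.append(" ")
        parts.append(tok)
    text = "".join(parts)
    if capitalize and text:
        text = text[0].upper() + text[1:]
    return text


def _fill_template(template: str, term_surface: str) -> tuple[list[str], tuple[int, int]]:
    """Template tokens with {x} replaced by the term tokens, plus the span."""
    pre, _, post = template.partition("{x}")
    pre_toks = tokenize(pre)
    term_toks = tokenize(term_surface)
    post_toks = tokenize(post)
    start = len(pre_toks)
    return pre_toks + term_toks + post_toks, (start, start + len(term_toks))


def _typo_token(token: str, rng: np.random.Generator) -> str:
    pos = int(rng.integers(0, len(token)))
    orig = token[pos]
    choices = [c for c in _ALPHABET if c != orig]
    repl = choices[int(rng.integers(0, len(choices)))]
    return token[:pos] + repl + token[pos + 1 :]


def _apply_typo_in_span(
    tokens: list[str],
    span: tuple[int, int],
    rng: np.random.Generator,
) -> list[str]:
    eligible = [i for i in range(*span) if tokens[i].isalpha() and len(tokens[i]) >= 4]
    if not eligible:
        return tokens
    idx = eligible[int(rng.integers(0, len(eligible)))]
    out = list(tokens)
    out[idx] = _typo_token(out[idx], rng)
    return out


def _variant(canonical: str) -> str:
    """A morphological neighbor of a single-token term (plural/adjectival)."""
    if canonical.endswith("oma"):
        return canonical + "ta"
    if canonical.endswith("ia"):
        return canonical[:-1] + "c"
    if canonical.endswith("is"):
        return canonical[:-2] + "ic"
    return canonical + "s"


def plant_noise(
    sentence: str,
    mentions: Sequence[dict],
    noise: AuditNoiseSettings,
    rng: np.random.Generator,
    negation_cues: Sequence[str] = ("no",),
    negation_window: int = 5,
) -> tuple[str, list[dict]]:
    """Apply typo/negation noise to one sentence, keeping gold consistent.

    Typos are single-character substitutions in non-cue alphabetic tokens of
    length >= 4. A planted negation prepends a cue token, shifting every gold
    span by one and flipping to ``negated`` the polarity of mentions whose
    start lands within the negation window of the cue. With all rates zero
    the sentence and mentions are returned unchanged.
    """
    mentions = [dict(m) for m in mentions]
    apply_typo = rng.random() < noise.typo_rate
    apply_neg = rng.random() < noise.negation_rate
    if not (apply_typo or apply_neg):
        return sentence, mentions
    tokens = tokenize(sentence)
    cue_set = set(negation_cues)
    if apply_typo:
        eligible = [
            i
            for i, t in enumerate(tokens)
            if t.isalpha() and len(t) >= 4 and t not in cue_set
        ]
        if eligible:
            idx = eligible[int(rng.integers(0, len(eligible)))]
            tokens[idx] = _typo_token(tokens[idx], rng)
    if apply_neg:
        cue = negation_cues[int(rng.integers(0, len(negation_cues)))]
        tokens = [cue] + tokens
        for m in mentions:
            s, e = m["token_span"]
            m["token_span"] = (s + 1, e + 1)
            if m["token_span"][0] <= negation_window:
                m["polarity"] = NEGATED
    return _render_tokens(tokens), mentions


# -- cohort generation --------------------------------------------------------


def _feature_text_term(feature, lexicon: Lexicon, rng: np.random.Generator):
    """Pick a lexicon entry and surface form realizing a feature in text."""
    candidates = [lexicon.get(t) for t in feature.evidence_terms if lexicon.get(t)]
    entry = candidates[int(rng.integers(0, len(candidates)))]
    surfaces = [entry.canonical] + list(entry.synonyms)
    weights = [0.7] + [0.3 / len(entry.synonyms)] * len(entry.synonyms) if entry.synonyms else [1.0]
    surface = surfaces[int(rng.choice(len(surfaces), p=np.array(weights) / np.sum(weights)))]
    return entry, surface


def _sample_icd_code(prefixes: Sequence[str], rng: np.random.Generator) -> str:
    prefix = prefixes[int(rng.integers(0, len(prefixes)))]
    if "." in prefix:
        return prefix
    return f"{prefix}.{int(rng.integers(0, 10))}"


def _sample_lab(finding: str, rng: np.random.Generator) -> LabResult:
    if finding == "reduced_egfr":
        return LabResult(
            analyte="egfr",
            value=float(np.round(rng.uniform(15, 55), 1)),
            unit="mL/min/1.73m2",
        )
    if finding == "proteinuria_lab":
        return LabResult(
            analyte="urine_protein",
            value=float(np.round(rng.uniform(200, 800), 0)),
            unit="mg/24h",
        )
    raise ValueError(f"no lab sampler for finding {finding!r}")


def _generate_patient(
    patient_id: str,
    label: str,
    spec: CohortSpec,
    catalog: FeatureCatalog,
    lexicon: Lexicon,
    rng: np.random.Generator,
) -> tuple[PatientRecord, GoldAnnotation]:
    mean, sd = spec.case_age if label == "case" else spec.control_age
    female_rate = spec.case_female_rate if label == "case" else spec.control_female_rate
    probs = spec.case_feature_probs if label == "case" else spec.control_feature_probs
    lo_age, hi_age = catalog.cohort_inclusion

    age = float(np.clip(rng.normal(mean, sd), lo_age, hi_age))
    age = round(age, 1)
    sex = "female" if rng.random() < female_rate else "male"

    sentences: list[tuple[list[str], list[dict]]] = []
    icd_codes: list[str] = []
    labs: list[LabResult] = []
    planted: dict[str, str] = {}  # feature_id -> affirmed|negated|structured
    vetoed: set[str] = set()

    # Draw the documented feature set. Cases carry a minimum number of
    # documented features: the study group exists because their records
    # documented the phenotype (ascertainment), so a diagnosed case with an
    # empty chart would not be in it. The top-up draw is weighted by the
    # same per-feature probabilities.
    sampled = {
        f.feature_id
        for f in catalog
        if rng.random() < probs.get(f.feature_id, 0.0)
    }
    if label == "case" and len(sampled) < spec.min_case_features:
        pool = [
            f.feature_id
            for f in catalog
            if f.feature_id not in sampled and probs.get(f.feature_id, 0.0) > 0
        ]
        if pool:
            w = np.array([probs[fid] for fid in pool], dtype=float)
            extra = rng.choice(
                pool,
                size=min(spec.min_case_features - len(sampled), len(pool)),
                replace=False,
                p=w / w.sum(),
            )
            sampled.update(str(fid) for fid in extra)

    for feature in catalog:
        if feature.feature_id not in sampled:
            continue
        has_terms = any(lexicon.get(t) for t in feature.evidence_terms)
        channels = ["text"] if has_terms else []
        weights = [0.7] if has_terms else []
        if feature.icd10_prefixes:
            channels.append("icd")
            weights.append(0.2)
        if feature.lab_findings:
            channels.append("lab")
            weights.append(0.1)
        w = np.array(weights) / np.sum(weights)
        channel = channels[int(rng.choice(len(channels), p=w))]

        if channel == "icd":
            icd_codes.append(_sample_icd_code(feature.icd10_prefixes, rng))
            planted[feature.feature_id] = "structured"
        elif channel == "lab":
            finding = feature.lab_findings[int(rng.integers(0, len(feature.lab_findings)))]
            labs.append(_sample_lab(finding, rng))
            planted[feature.feature_id] = "structured"
        else:
            entry, surface = _feature_text_term(feature, lexicon, rng)
            negate = rng.random() < spec.negation_rate
            if not negate and rng.random() < spec.paraphrase_rate and " " not in surface:
                surface = _variant(surface)
            templates = _NEGATED_TEMPLATES if negate else _AFFIRMED_TEMPLATES
            template = templates[int(rng.integers(0, len(templates)))]
            tokens, span = _fill_template(template, surface)
            if not negate and rng.random() < spec.typo_rate:
                tokens = _apply_typo_in_span(tokens, span, rng)
            polarity = NEGATED if negate else AFFIRMED
            sentences.append(
                (tokens, [{"term_id": entry.term_id, "token_span": span, "polarity": polarity}])
            )
            planted[feature.feature_id] = polarity

        realized = planted[feature.feature_id] in ("structured", AFFIRMED)
        if realized and feature.exclusion_conditions and rng.random() < spec.confounder_rate:
            cid = feature.exclusion_conditions[
                int(rng.integers(0, len(feature.exclusion_conditions)))
            ]
            cond = catalog.conditions[cid]
            term = lexicon.get(cond.terms[0]) if cond.terms else None
            if term is not None:
                template = _AFFIRMED_TEMPLATES[int(rng.integers(0, len(_AFFIRMED_TEMPLATES)))]
                tokens, span = _fill_template(template, term.canonical)
                sentences.append(
                    (tokens, [{"term_id": term.term_id, "token_span": span, "polarity": AFFIRMED}])
                )
            else:
                icd_codes.append(_sample_icd_code(cond.icd10_prefixes, rng))
            vetoed.add(feature.feature_id)

    lo_d, hi_d = spec.distractor_sentences_per_note
    n_distr = int(rng.integers(lo_d, hi_d + 1))
    picks = rng.choice(len(_DISTRACTOR_SENTENCES), size=min(n_distr, len(_DISTRACTOR_SENTENCES)), replace=False)
    for p in picks:
        sentences.append((tokenize(_DISTRACTOR_SENTENCES[int(p)]), []))

    order = rng.permutation(len(sentences))
    note_parts: list[str] = []
    mentions: list[GoldMention] = []
    for s_idx, orig in enumerate(order):
        tokens, ms = sentences[int(orig)]
        note_parts.append(_render_tokens(tokens))
        for m in ms:
            mentions.append(
                GoldMention(
                    term_id=m["term_id"],
                    note_index=0,
                    sentence_index=s_idx,
                    token_span=tuple(m["token_span"]),
                    polarity=m["polarity"],
                )
            )
    note = " ".join(note_parts)

    true_features = frozenset(
        fid
        for fid, status in planted.items()
        if status in ("structured", AFFIRMED) and fid not in vetoed
    )
    intended = sum(
        score_feature(catalog.get(fid), True, age) for fid in true_features
    )
    record = PatientRecord(
        patient_id=patient_id,
        age=age,
        sex=sex,
        notes=[note] if note else [""],
        icd10_codes=icd_codes,
        labs=labs,
        true_label=label,
    )
    gold = GoldAnnotation(
        patient_id=patient_id,
        mentions=tuple(mentions),
        true_features=true_features,
        intended_risk_factor=int(intended),
        true_label=label,
        vetoed_features=frozenset(vetoed),
    )
    return record, gold


def generate_cohort(
    spec: CohortSpec,
    catalog: FeatureCatalog,
    lexicon: Lexicon,
) -> tuple[list[PatientRecord], list[GoldAnnotation]]:
    """Generate a labeled cohort of patient records plus gold annotations.

    Reproducible: the spec's seed fully determines the output. Raises a
    config error if the catalog and lexicon are inconsistent (a feature with
    no realizable evidence channel).
    """
    check_consistency(catalog, lexicon)
    rng = np.random.default_rng(spec.seed)
    records: list[PatientRecord] = []
    golds: list[GoldAnnotation] = []
    for i in range(spec.n_cases):
        rec, gold = _generate_patient(f"case_{i:04d}", "case", spec, catalog, lexicon, rng)
        records.append(rec)
        golds.append(gold)
    for i in range(spec.n_controls):
        rec, gold = _generate_patient(f"ctrl_{i:06d}", "control", spec, catalog, lexicon, rng)
        records.append(rec)
        golds.append(gold)
    return records, golds


# -- precision-audit corpus ---------------------------------------------------


def generate_audit_corpus(
    term_ids: Optional[Sequence[str]] = None,
    n_per_term: int = 100,
    noise: Optional[AuditNoiseSettings] = None,
    seed: int = 0,
    lexicon: Optional[Lexicon] = None,
) -> list[dict]:
    """Annotated descriptions for the per-term extraction precision audit.

    Each description contains exactly one target mention (possibly negated
    or typo'd) plus distractor sentences; at the configured rate a
    description additionally carries a near-miss distractor — a
    morphological neighbor of a different, single-token dictionary term —
    which is deliberately absent from the gold mentions, so an extractor
    that over-links pays for it in precision.
    """
    from .lexicon import default_lexicon

    if lexicon is None:
        lexicon = default_lexicon()
    if term_ids is None:
        term_ids = lexicon.term_ids
    if n_per_term < 1:
        raise ValueError("n_per_term must be >= 1")
    noise = noise or AuditNoiseSettings()
    rng = np.random.default_rng(seed)
    single_token_ids = [
        e.term_id for e in lexicon if " " not in e.canonical
    ]
    docs: list[dict] = []
    for term_id in term_ids:
        entry = lexicon.get(term_id)
        if entry is None:
            raise ValueError(f"unknown term_id {term_id!r}")
        for d in range(n_per_term):
            negate = rng.random() < noise.negation_rate
            templates = _NEGATED_TEMPLATES if negate else _AFFIRMED_TEMPLATES
            template = templates[int(rng.integers(0, len(templates)))]
            tokens, span = _fill_template(template, entry.canonical)
            if not negate and rng.random() < noise.typo_rate:
                tokens = _apply_typo_in_span(tokens, span, rng)
            polarity = NEGATED if negate else AFFIRMED
            sentences: list[tuple[list[str], list[dict]]] = [
                (tokens, [{"term_id": term_id, "token_span": span, "polarity": polarity}])
            ]
            lo_d, hi_d = noise.distractor_range
            n_distr = int(rng.integers(lo_d, hi_d + 1))
            picks = rng.choice(
                len(_DISTRACTOR_SENTENCES),
                size=min(n_distr, len(_DISTRACTOR_SENTENCES)),
                replace=False,
            )
            for p in picks:
                sentences.append((tokenize(_DISTRACTOR_SENTENCES[int(p)]), []))
            if rng.random() < noise.near_miss_rate:
                others = [t for t in single_token_ids if t != term_id]
                if others:
                    other = lexicon.get(others[int(rng.integers(0, len(others)))])
                    nm_tokens, _ = _fill_template(
                        _NEAR_MISS_TEMPLATE, _variant(other.canonical)
                    )
                    sentences.append((nm_tokens, []))
            order = rng.permutation(len(sentences))
            parts: list[str] = []
            mentions: list[dict] = []
            for s_idx, orig in enumerate(order):
                toks, ms = sentences[int(orig)]
                parts.append(_render_tokens(toks))
                for m in ms:
                    mentions.append(
                        {
                            "term_id": m["term_id"],
                            "sentence_index": s_idx,
                            "token_span": tuple(m["token_span"]),
                            "polarity": m["polarity"],
                        }
                    )
            docs.append(
                {
                    "doc_id": f"{term_id}_{d:04d}",
                    "target_term": term_id,
                    "text": " ".join(parts),
                    "mentions": mentions,
                }
            )
    return docs
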