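"""Entity extraction: pattern matching, negation detection, similarity linking.

A raw note is split into sentences, each sentence normalized into tokens,
dictionary patterns searched over the token sequence, and every match
classified as affirmed or negated from the tokens preceding it. Tokens not
covered by a pattern match are linked to the dictionary by embedding cosine
similarity, catching variants the patterns do not know. Pattern matches take
precedence over similarity links on the same span.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .lexicon import Lexicon, similarity_link
from .textproc import normalize_tokens, split_sentences

__all__ = [
    "MatcherConfig",
    "ExtractedEntity",
    "PrecisionAuditResult",
    "match_patterns",
    "detect_negation",
    "extract_entities",
    "precision_audit",
]

AFFIRMED = "affirmed"
NEGATED = "negated"


@dataclass(frozen=True)
class MatcherConfig:
    """Tunable matcher settings.

    similarity_threshold:
        Minimum cosine similarity for linking an unknown token to a
        dictionary term. Default 0.85.
    negation_window:
        How many tokens before a mention a negation cue may sit. Default 5.
    typo_correction:
        Whether edit-distance-1 correction against the dictionary vocabulary
        is applied during normalization.
    enable_similarity:
        Whether the similarity-linking fallback runs at all.
    min_similarity_token_len:
        Tokens shorter than this are never similarity-linked (too ambiguous).
    """

    similarity_threshold: float = 0.85
    negation_window: int = 5
    typo_correction: bool = True
    enable_similarity: bool = True
    min_similarity_token_len: int = 4


@dataclass(frozen=True, order=True)
class ExtractedEntity:
    """One detected mention of a dictionary term in a note."""

    sentence_index: int
    token_span: tuple[int, int]  # 0-based, half-open
    term_id: str
    polarity: str  # affirmed | negated
    link_method: str = "pattern"  # pattern | similarity
    similarity: float = 1.0

    def __post_init__(self):
        if self.token_span[1] <= self.token_span[0]:
            raise ValueError("token_span must be non-empty")
        if self.polarity not in (AFFIRMED, NEGATED):
            raise ValueError(f"invalid polarity: {self.polarity!r}")


@dataclass(frozen=True)
class Candidate:
    term_id: str
    token_span: tuple[int, int]


def match_patterns(tokens: Sequence[str], lexicon: Lexicon) -> list[Candidate]:
    """All dictionary pattern matches over a normalized token sequence.

    Overlapping candidates are resolved longest-match-first, ties broken by
    leftmost start, then by lexicon entry order (then pattern order within
    the entry). The survivors are returned in span order.
    """
    raw: list[tuple[int, int, int, int, str]] = []  # (start, length, entry#, pat#, id)
    # index patterns by first literal token for a fast candidate lookup
    literal_index: dict[str, list[tuple[int, int, object, str]]] = {}
    scan_all: list[tuple[int, int, object, str]] = []
    for e_idx, entry in enumerate(lexicon):
        for p_idx, pat in enumerate(entry.patterns):
            item = (e_idx, p_idx, pat, entry.term_id)
            if pat.first_literal is not None:
                literal_index.setdefault(pat.first_literal, []).append(item)
            else:
                scan_all.append(item)
    n = len(tokens)
    for start in range(n):
        candidates = literal_index.get(tokens[start], ())
        for e_idx, p_idx, pat, term_id in candidates:
            if pat.matches_at(tokens, start):
                raw.append((start, len(pat), e_idx, p_idx, term_id))
        for e_idx, p_idx, pat, term_id in scan_all:
            if pat.matches_at(tokens, start):
                raw.append((start, len(pat), e_idx, p_idx, term_id))
    raw.sort(key=lambda c: (-c[1], c[0], c[2], c[3]))
    covered: set[int] = set()
    kept: list[tuple[int, int, str]] = []
    for start, length, _e, _p, term_id in raw:
        span = range(start, start + length)
        if covered.isdisjoint(span):
            covered.update(span)
            kept.append((start, length, term_id))
    kept.sort()
    return [Candidate(term_id=t, token_span=(s, s + ln)) for s, ln, t in kept]


def detect_negation(
    tokens: Sequence[str],
    span: tuple[int, int],
    cues: Sequence[str],
    window: int = 5,
    reset_tokens: Sequence[str] = (),
) -> str:
    """Polarity of a mention from the tokens preceding it.

    A mention is negated iff a negation cue occurs within ``window`` tokens
    before the span start (within the sentence the tokens belong to), with no
    polarity-resetting token (adversative conjunction) between the cue and the
    mention. Otherwise it is affirmed.
    """
    start, end = span
    if start < 0 or end > len(tokens) or end <= start:
        raise ValueError(f"span {span} out of bounds for {len(tokens)} tokens")
    cue_set = set(cues)
    reset_set = set(reset_tokens)
    for i in range(start - 1, max(-1, start - window - 1), -1):
        if tokens[i] in reset_set:
            return AFFIRMED
        if tokens[i] in cue_set:
            return NEGATED
    return AFFIRMED


def extract_entities(
    note: str, lexicon: Lexicon, config: Optional[MatcherConfig] = None
) -> list[ExtractedEntity]:
    """Run the full pipeline over one note.

    Composition of sentence splitting, normalization, pattern matching,
    negation detection and similarity linking. Output is ordered by
    (sentence index, span start) and deterministic for fixed inputs.
    """
    config = config or MatcherConfig()
    entities: list[ExtractedEntity] = []
    for s_idx, sentence in enumerate(split_sentences(note)):
        tokens = normalize_tokens(sentence, lexicon, typo_correction=config.typo_correction)
        covered: set[int] = set()
        for cand in match_patterns(tokens, lexicon):
            covered.update(range(*cand.token_span))
            polarity = detect_negation(
                tokens,
                cand.token_span,
                lexicon.negation_cues,
                window=config.negation_window,
                reset_tokens=lexicon.reset_tokens,
            )
            entities.append(
                ExtractedEntity(
                    sentence_index=s_idx,
                    token_span=cand.token_span,
                    term_id=cand.term_id,
                    polarity=polarity,
                    link_method="pattern",
                    similarity=1.0,
                )
            )
        if config.enable_similarity:
            for i, tok in enumerate(tokens):
                if (
                    i in covered
                    or len(tok) < config.min_similarity_token_len
                    or not tok.isalpha()
                    or tok in lexicon.typo_vocabulary_set
                ):
                    continue
                link = similarity_link(tok, lexicon, config.similarity_threshold)
                if link is None:
                    continue
                term_id, sim = link
                polarity = detect_negation(
                    tokens,
                    (i, i + 1),
                    lexicon.negation_cues,
                    window=config.negation_window,
                    reset_tokens=lexicon.reset_tokens,
                )
                entities.append(
                    ExtractedEntity(
                        sentence_index=s_idx,
                        token_span=(i, i + 1),
                        term_id=term_id,
                        polarity=polarity,
                        link_method="similarity",
                        similarity=sim,
                    )
                )
    entities.sort(key=lambda e: (e.sentence_index, e.token_span[0]))
    return entities


# -- precision audit ---------------------------------------------------------


@dataclass(frozen=True)
class PrecisionAuditResult:
    term_id: str
    n_detections: int
    n_correct: int

    @property
    def undefined(self) -> bool:
        return self.n_detections == 0

    @property
    def precision(self) -> float:
        if self.undefined:
            return math.nan
        return self.n_correct / self.n_detections


def _spans_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def precision_audit(
    gold_docs: Iterable[dict],
    lexicon: Lexicon,
    config: Optional[MatcherConfig] = None,
) -> list[PrecisionAuditResult]:
    """Per-term precision of affirmed detections against gold annotations.

    Each gold document is a mapping with ``text`` and ``mentions``, the
    latter a list of mappings with ``term_id``, ``sentence_index``,
    ``token_span`` and ``polarity`` in the extractor's own tokenization. A
    detection is correct iff a gold affirmed mention of the same term
    overlaps it in the same sentence. Terms with zero affirmed detections
    are reported with an undefined-precision flag.
    """
    config = config or MatcherConfig()
    detections: dict[str, int] = {t: 0 for t in lexicon.term_ids}
    correct: dict[str, int] = {t: 0 for t in lexicon.term_ids}
    for doc in gold_docs:
        gold = [
            (m["term_id"], m["sentence_index"], tuple(m["token_span"]))
            for m in doc.get("mentions", [])
            if m.get("polarity", AFFIRMED) == AFFIRMED
        ]
        for ent in extract_entities(doc["text"], lexicon, config):
            if ent.polarity != AFFIRMED:
                continue
            detections[ent.term_id] = detections.get(ent.term_id, 0) + 1
            hit = any(
                t == ent.term_id
                and s == ent.sentence_index
                and _spans_overlap(span, ent.token_span)
                for t, s, span in gold
            )
            if hit:
                correct[ent.term_id] = correct.get(ent.term_id, 0) + 1
    return [
        PrecisionAuditResult(term_id=t, n_detections=detections[t], n_correct=correct[t])
        for t in detections
    ]
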