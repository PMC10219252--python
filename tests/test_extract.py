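import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fdscreen.extract import (
    AFFIRMED,
    NEGATED,
    MatcherConfig,
    detect_negation,
    extract_entities,
    match_patterns,
    precision_audit,
    PrecisionAuditResult,
)
from fdscreen.lexicon import Lexicon


# -- pattern matching against a naive scan oracle -----------------------------


def _oracle_matches(tokens, entries):
    """Independent O(n*m) scan: collect every (start, len, order) match, then
    resolve overlaps longest-first, leftmost, then entry order."""
    hits = []
    for order, (term_id, phrases) in enumerate(entries):
        for phrase in phrases:
            L = len(phrase)
            for start in range(len(tokens) - L + 1):
                if tokens[start : start + L] == list(phrase):
                    hits.append((start, L, order, term_id))
    hits.sort(key=lambda h: (-h[1], h[0], h[2]))
    taken = set()
    kept = []
    for start, L, order, term_id in hits:
        if all(i not in taken for i in range(start, start + L)):
            taken.update(range(start, start + L))
            kept.append((start, start + L, term_id))
    return sorted(kept)


vocab = ["alpha", "beta", "gamma", "delta", "epsilon"]


@settings(max_examples=100, derandomize=True)
@given(
    st.lists(st.sampled_from(vocab + ["filler", "xx"]), max_size=50),
    st.lists(
        st.lists(st.sampled_from(vocab), min_size=1, max_size=3), min_size=1, max_size=10
    ),
)
def test_match_patterns_equals_naive_scan_oracle(tokens, phrases):
    lex = Lexicon(typo_correction=False)
    entries = []
    seen = set()
    for i, phrase in enumerate(phrases):
        canonical = " ".join(phrase)
        if canonical in seen:
            continue
        seen.add(canonical)
        tid = f"t{i}"
        lex.add_term(tid, canonical)
        entries.append((tid, [tuple(phrase)]))
    got = [(c.token_span[0], c.token_span[1], c.term_id) for c in match_patterns(tokens, lex)]
    assert got == _oracle_matches(tokens, entries)


def test_longest_match_wins_at_overlap(tiny_lexicon):
    cands = match_patterns(["cornea", "verticillata", "and", "cornea"], tiny_lexicon)
    assert [(c.term_id, c.token_span) for c in cands] == [
        ("cornea_verticillata", (0, 2)),
        ("cornea", (3, 4)),
    ]


def test_empty_token_list_matches_nothing(tiny_lexicon):
    assert match_patterns([], tiny_lexicon) == []


def test_candidate_found_after_negation_cue(tiny_lexicon):
    cands = match_patterns(["no", "angiokeratoma"], tiny_lexicon)
    assert len(cands) == 1
    assert cands[0].token_span == (1, 2)
    assert cands[0].term_id == "angiokeratoma"


# -- negation detection -------------------------------------------------------


class TestDetectNegation:
    CUES = ["no", "not", "without"]

    def test_cue_directly_before_mention_negates(self):
        assert detect_negation(["no", "angiokeratoma"], (1, 2), self.CUES, 5) == NEGATED

    def test_no_cue_is_affirmed(self):
        assert (
            detect_negation(["angiokeratoma", "present"], (0, 1), self.CUES, 5)
            == AFFIRMED
        )

    def test_cue_beyond_window_is_ignored(self):
        tokens = ["no", "a", "b", "c", "d", "e", "angiokeratoma"]
        assert detect_negation(tokens, (6, 7), self.CUES, window=5) == AFFIRMED
        assert detect_negation(tokens, (6, 7), self.CUES, window=6) == NEGATED

    def test_adversative_conjunction_resets_polarity(self):
        tokens = ["no", "edema", "but", "angiokeratoma"]
        assert (
            detect_negation(tokens, (3, 4), self.CUES, 5, reset_tokens=["but"])
            == AFFIRMED
        )

    def test_out_of_bounds_span_raises(self):
        with pytest.raises(ValueError):
            detect_negation(["a"], (0, 2), self.CUES, 5)


# -- end-to-end extraction ----------------------------------------------------


class TestExtractEntities:
    def test_hand_annotated_two_sentence_note(self, tiny_lexicon):
        ents = extract_entities(
            "No angiokeratoma. Proteinuria found.", tiny_lexicon
        )
        assert [(e.term_id, e.polarity, e.sentence_index) for e in ents] == [
            ("angiokeratoma", NEGATED, 0),
            ("proteinuria", AFFIRMED, 1),
        ]
        assert all(e.link_method == "pattern" and e.similarity == 1.0 for e in ents)

    def test_empty_note_yields_nothing(self, tiny_lexicon):
        assert extract_entities("", tiny_lexicon) == []

    def test_typod_known_term_recovered_via_pattern(self, tiny_lexicon):
        ents = extract_entities("Patient has angiokertoma on exam.", tiny_lexicon)
        assert len(ents) == 1
        assert ents[0].term_id == "angiokeratoma"
        assert ents[0].polarity == AFFIRMED
        assert ents[0].link_method == "pattern"

    def test_unseen_variant_recovered_via_similarity(self, tiny_lexicon):
        ents = extract_entities("Examination revealed angiokeratomata.", tiny_lexicon)
        assert len(ents) == 1
        assert ents[0].term_id == "angiokeratoma"
        assert ents[0].link_method == "similarity"
        assert ents[0].similarity >= 0.85

    def test_extraction_is_deterministic(self, lexicon, matcher):
        note = "No angiokeratoma. Proteinuria found. Patient denies stroke."
        assert extract_entities(note, lexicon, matcher) == extract_entities(
            note, lexicon, matcher
        )

    def test_flipping_a_no_prefix_flips_only_adjacent_polarity(self, tiny_lexicon):
        base = extract_entities(
            "Angiokeratoma seen. Proteinuria found.", tiny_lexicon
        )
        flipped = extract_entities(
            "No angiokeratoma seen. Proteinuria found.", tiny_lexicon
        )
        assert [e.term_id for e in base] == [e.term_id for e in flipped]
        assert base[0].polarity == AFFIRMED and flipped[0].polarity == NEGATED
        assert base[1].polarity == flipped[1].polarity == AFFIRMED


# -- precision audit ----------------------------------------------------------


def test_precision_is_plain_arithmetic():
    r = PrecisionAuditResult(term_id="x", n_detections=100, n_correct=70)
    assert r.precision == pytest.approx(0.70)
    assert not r.undefined


def test_zero_detections_flagged_undefined():
    r = PrecisionAuditResult(term_id="x", n_detections=0, n_correct=0)
    assert r.undefined


def test_perfect_extractor_scores_precision_one(tiny_lexicon):
    docs = [
        {
            "text": "Angiokeratoma present today.",
            "mentions": [
                {"term_id": "angiokeratoma", "sentence_index": 0,
                 "token_span": (0, 1), "polarity": AFFIRMED}
            ],
        },
        {
            "text": "Cornea verticillata observed.",
            "mentions": [
                {"term_id": "cornea_verticillata", "sentence_index": 0,
                 "token_span": (0, 2), "polarity": AFFIRMED}
            ],
        },
    ]
    results = {r.term_id: r for r in precision_audit(docs, tiny_lexicon)}
    assert results["angiokeratoma"].precision == 1.0
    assert results["cornea_verticillata"].precision == 1.0


def test_unannotated_detection_counts_against_precision(tiny_lexicon):
    docs = [{"text": "Angiokeratoma present.", "mentions": []}]
    results = {r.term_id: r for r in precision_audit(docs, tiny_lexicon)}
    assert results["angiokeratoma"].n_detections == 1
    assert results["angiokeratoma"].precision == 0.0
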