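"""Sentence splitting, tokenization and token normalization.

The note-processing pipeline is deliberately rule-based and deterministic:
sentences split on terminal punctuation followed by a capital, tokens split
on whitespace with punctuation separated, typos corrected against the
dictionary vocabulary at edit distance one, and lemmatization performed by
an ordered suffix-rewrite table. All rules live in the lexicon config so the
pipeline is language-portable.
"""

from __future__ import annotations

import re
from typing import TYPE_CHECKING, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .lexicon import Lexicon

__all__ = [
    "split_sentences",
    "tokenize",
    "normalize_tokens",
    "edit_distance_at_most_one",
]

_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)
# Split after ., ! or ? when followed by whitespace and an upper-case letter
# or digit. "e.g. something" (lower-case continuation) does not split.
_SENT_BOUNDARY = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9])")


def split_sentences(text: str) -> list[str]:
    """Break a raw note into sentences, preserving content and order."""
    if not text or not text.strip():
        return []
    return [part for part in _SENT_BOUNDARY.split(text.strip()) if part]


def tokenize(sentence: str, lower: bool = True) -> list[str]:
    """Whitespace/punctuation tokenizer. Punctuation marks become tokens."""
    if lower:
        sentence = sentence.lower()
    return _TOKEN_RE.findall(sentence)


def edit_distance_at_most_one(a: str, b: str) -> bool:
    """True iff Levenshtein distance(a, b) <= 1 (O(len) two-pointer scan)."""
    la, lb = len(a), len(b)
    if abs(la - lb) > 1:
        return False
    if la > lb:
        a, b, la, lb = b, a, lb, la
    i = j = 0
    edited = False
    while i < la and j < lb:
        if a[i] == b[j]:
            i += 1
            j += 1
            continue
        if edited:
            return False
        edited = True
        if la == lb:
            i += 1
        j += 1
    return True  # any trailing char in b is the single allowed edit


def correct_typo(
    token: str, vocabulary: Sequence[str], vocab_set: set[str], min_len: int = 4
) -> str:
    """Replace an out-of-vocabulary token by a vocabulary token at distance 1.

    In-vocabulary tokens are never rewritten. Tokens shorter than ``min_len``
    or containing non-alphabetic characters are left alone (short function
    words are too easily one edit away from a dictionary token). The first
    candidate in ``vocabulary`` order wins, which makes correction
    deterministic for a fixed lexicon.
    """
    if len(token) < min_len or not token.isalpha() or token in vocab_set:
        return token
    for cand in vocabulary:
        if abs(len(cand) - len(token)) <= 1 and edit_distance_at_most_one(token, cand):
            return cand
    return token


def apply_lemma_rules(token: str, rules: Sequence[tuple[str, str]]) -> str:
    """Ordered suffix rewrites; the first matching rule wins."""
    for suffix, repl in rules:
        if token.endswith(suffix) and len(token) > len(suffix):
            return token[: -len(suffix)] + repl
    return token


def normalize_tokens(
    sentence: str, lexicon: "Lexicon", typo_correction: bool = True
) -> list[str]:
    """Lower-case, tokenize, typo-correct against the lexicon, lemmatize."""
    tokens = tokenize(sentence, lower=True)
    out = []
    for tok in tokens:
        if typo_correction and lexicon.typo_correction:
            tok = correct_typo(
                tok,
                lexicon.typo_vocabulary,
                lexicon.typo_vocabulary_set,
                min_len=lexicon.typo_min_len,
            )
        tok = apply_lemma_rules(tok, lexicon.lemma_rules)
        out.append(tok)
    return out
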