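"""The medical-term dictionary (lexicon) and similarity linking.

Each dictionary entry carries token-level patterns compiled from its
canonical form and synonyms, plus an embedding of the canonical form used to
link unseen variants by cosine similarity. Entries evidencing one of the
scored clinical features carry that feature's id; entries for confounder or
cohort-exclusion conditions carry none (the feature catalog references them
by term id).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml

from .embedding import EmbeddingProvider, HashedTrigramEmbedder, cosine_similarity
from .textproc import tokenize

__all__ = [
    "TokenPattern",
    "LexiconEntry",
    "Lexicon",
    "compile_term_patterns",
    "add_to_lexicon",
    "similarity_link",
    "load_lexicon",
    "default_lexicon",
]

DEFAULT_RESET_TOKENS = ("but", "however", "although", "though", "yet", "except")


@dataclass(frozen=True)
class TokenPattern:
    """A sequence of token-level regexes, anchored per token (fullmatch).

    ``first_literal`` is set when the first token regex is a plain literal,
    enabling an index lookup instead of scanning every pattern at every
    position.
    """

    regexes: tuple[re.Pattern, ...]
    first_literal: Optional[str] = None

    def __len__(self) -> int:
        return len(self.regexes)

    def matches_at(self, tokens: Sequence[str], start: int) -> bool:
        if start + len(self.regexes) > len(tokens):
            return False
        return all(
            rx.fullmatch(tokens[start + i]) for i, rx in enumerate(self.regexes)
        )


def _compile_phrase(phrase: str) -> TokenPattern:
    toks = tokenize(phrase, lower=True)
    if not toks:
        raise ValueError(f"term {phrase!r} is empty after normalization")
    return TokenPattern(
        regexes=tuple(re.compile(re.escape(t)) for t in toks),
        first_literal=toks[0],
    )


def compile_term_patterns(
    canonical: str,
    synonyms: Iterable[str] = (),
    extra_patterns: Iterable[Sequence[str]] = (),
) -> list[TokenPattern]:
    """Compile token-boundary-anchored patterns for a term.

    One literal pattern per surface form (canonical first, then synonyms);
    ``extra_patterns`` are user-supplied lists of raw token regexes for forms
    a literal cannot express.
    """
    if not canonical or not canonical.strip():
        raise ValueError("canonical term must be non-empty")
    patterns = [_compile_phrase(canonical)]
    seen = {tuple(r.pattern for r in patterns[0].regexes)}
    for syn in synonyms:
        pat = _compile_phrase(syn)
        key = tuple(r.pattern for r in pat.regexes)
        if key not in seen:
            seen.add(key)
            patterns.append(pat)
    for token_regexes in extra_patterns:
        if not token_regexes:
            raise ValueError("an extra pattern must have at least one token regex")
        compiled = tuple(re.compile(rx) for rx in token_regexes)
        lit = token_regexes[0] if re.escape(token_regexes[0]) == token_regexes[0] else None
        patterns.append(TokenPattern(regexes=compiled, first_literal=lit))
    return patterns


@dataclass
class LexiconEntry:
    term_id: str
    canonical: str
    patterns: list[TokenPattern]
    synonyms: list[str] = field(default_factory=list)
    embedding: Optional[np.ndarray] = None
    feature_id: Optional[str] = None

    def __post_init__(self):
        if not self.canonical or not self.canonical.strip():
            raise ValueError("canonical form must be non-empty")
        if self.canonical != self.canonical.lower():
            raise ValueError("canonical form must be lower-case")
        if not self.patterns:
            raise ValueError("entry must have at least one pattern")


class Lexicon:
    """Ordered collection of term entries plus the text-normalization rules.

    Entry order is significant: it breaks ties in overlap resolution and in
    similarity linking, and fixes the typo-correction candidate order.
    """

    def __init__(
        self,
        entries: Iterable[LexiconEntry] = (),
        negation_cues: Sequence[str] = ("no", "not", "without", "denies", "negative", "absent", "never"),
        reset_tokens: Sequence[str] = DEFAULT_RESET_TOKENS,
        lemma_rules: Sequence[tuple[str, str]] = (),
        typo_correction: bool = True,
        typo_min_len: int = 4,
        embedder: Optional[EmbeddingProvider] = None,
    ):
        self.embedder: EmbeddingProvider = embedder or HashedTrigramEmbedder()
        self.negation_cues = list(negation_cues)
        self.reset_tokens = list(reset_tokens)
        self.lemma_rules = [tuple(r) for r in lemma_rules]
        self.typo_correction = typo_correction
        self.typo_min_len = typo_min_len
        self.entries: list[LexiconEntry] = []
        self._by_id: dict[str, LexiconEntry] = {}
        self._by_canonical: dict[str, LexiconEntry] = {}
        self._vocab: list[str] = []
        self._vocab_set: set[str] = set()
        self._matrix: Optional[np.ndarray] = None
        for entry in entries:
            self.add(entry)

    # -- construction -----------------------------------------------------

    def add(self, entry: LexiconEntry) -> "Lexicon":
        """Add an entry; duplicate canonical forms or term ids are conflicts."""
        if entry.canonical in self._by_canonical:
            raise ValueError(f"duplicate canonical form: {entry.canonical!r}")
        if entry.term_id in self._by_id:
            raise ValueError(f"duplicate term_id: {entry.term_id!r}")
        if entry.embedding is None:
            entry.embedding = self.embedder.embed(entry.canonical)
        self.entries.append(entry)
        self._by_id[entry.term_id] = entry
        self._by_canonical[entry.canonical] = entry
        for phrase in [entry.canonical, *entry.synonyms]:
            for tok in tokenize(phrase, lower=True):
                if tok.isalpha() and tok not in self._vocab_set:
                    self._vocab.append(tok)
                    self._vocab_set.add(tok)
        self._matrix = None
        return self

    def add_term(
        self,
        term_id: str,
        canonical: str,
        synonyms: Iterable[str] = (),
        feature_id: Optional[str] = None,
        extra_patterns: Iterable[Sequence[str]] = (),
    ) -> LexiconEntry:
        entry = LexiconEntry(
            term_id=term_id,
            canonical=" ".join(canonical.lower().split()),
            patterns=compile_term_patterns(canonical.lower(), [s.lower() for s in synonyms], extra_patterns),
            synonyms=[" ".join(s.lower().split()) for s in synonyms],
            feature_id=feature_id,
        )
        self.add(entry)
        return entry

    # -- lookup -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, term_id: str) -> Optional[LexiconEntry]:
        return self._by_id.get(term_id)

    def by_canonical(self, canonical: str) -> Optional[LexiconEntry]:
        return self._by_canonical.get(canonical)

    @property
    def term_ids(self) -> list[str]:
        return [e.term_id for e in self.entries]

    @property
    def typo_vocabulary(self) -> list[str]:
        return self._vocab

    @property
    def typo_vocabulary_set(self) -> set[str]:
        return self._vocab_set

    @property
    def embedding_matrix(self) -> np.ndarray:
        """(n_entries, dim) matrix of entry embeddings, rows unit-norm."""
        if self._matrix is None:
            if not self.entries:
                self._matrix = np.zeros((0, self.embedder.dim))
            else:
                self._matrix = np.vstack([e.embedding for e in self.entries])
        return self._matrix


def add_to_lexicon(lexicon: Lexicon, entry: LexiconEntry) -> Lexicon:
    """Functional alias for :meth:`Lexicon.add` (returns the lexicon)."""
    return lexicon.add(entry)


def similarity_link(
    token_or_phrase: str, lexicon: Lexicon, threshold: float = 0.85
) -> Optional[tuple[str, float]]:
    """Link a phrase to the most-similar dictionary entry.

    Returns ``(term_id, cosine_similarity)`` for the entry with maximal
    similarity if that maximum reaches ``threshold``, else ``None``. Ties are
    broken by lexicon order (argmax returns the first maximum). An empty
    lexicon yields ``None``.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    if len(lexicon) == 0:
        return None
    q = lexicon.embedder.embed(token_or_phrase)
    sims = lexicon.embedding_matrix @ q
    idx = int(np.argmax(sims))
    sim = float(np.clip(sims[idx], -1.0, 1.0))
    if sim >= threshold:
        return lexicon.entries[idx].term_id, sim
    return None


# -- serialization ---------------------------------------------------------


def load_lexicon(source, embedder: Optional[EmbeddingProvider] = None) -> Lexicon:
    """Load a lexicon from a YAML/JSON mapping (path, file object or dict)."""
    if isinstance(source, dict):
        cfg = source
    elif hasattr(source, "read"):
        cfg = yaml.safe_load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
    lex = Lexicon(
        # str() guards against YAML 1.1 parsing cue words like "no" as booleans
        negation_cues=[str(c).lower() for c in cfg.get("negation_cues", ["no", "not", "without", "denies"])],
        reset_tokens=[str(c).lower() for c in cfg.get("reset_tokens", list(DEFAULT_RESET_TOKENS))],
        lemma_rules=[tuple(r) for r in cfg.get("lemma_rules", [])],
        typo_correction=cfg.get("typo_correction", True),
        typo_min_len=cfg.get("typo_min_len", 4),
        embedder=embedder,
    )
    for item in cfg.get("entries", []):
        lex.add_term(
            term_id=item["term_id"],
            canonical=item["canonical"],
            synonyms=item.get("synonyms", []),
            feature_id=item.get("feature_id"),
            extra_patterns=item.get("patterns", []),
        )
    return lex


def default_lexicon(embedder: Optional[EmbeddingProvider] = None) -> Lexicon:
    """The packaged English screening lexicon."""
    ref = resources.files("fdscreen.data").joinpath("lexicon.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return load_lexicon(fh, embedder=embedder)
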