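"""Text normalization, tokenization, and the lexicon context document.

The relevance signal the pipeline scores against is a *context document*: a
pseudo-document assembled from a domain lexicon (antimicrobial-resistance
terms drawn from resources such as CARD and the Gene Ontology).  Multiword
lexicon terms are collapsed to single underscore-joined tokens both in the
lexicon and — by maximal left-to-right phrase matching — in document text, so
that a term like "antibiotic efflux" survives as one feature everywhere.
"""

from __future__ import annotations

import string
import unicodedata
import warnings
from dataclasses import dataclass, field

from .corpus_io import ArticleId, RawDocument

__all__ = [
    "Lexicon",
    "TokenizedDocument",
    "CONTEXT_DOC_ID",
    "normalize_term",
    "tokenize",
    "tokenize_corpus",
    "build_context_document",
]

CONTEXT_DOC_ID = "__context__"

# Punctuation is removed outright (never replaced by a space) so that
# hyphenated spellings like "beta-lactamase" match the lexicon form
# "betalactamase".  Underscores are preserved: they carry collapsed
# multiword terms.
_PUNCT = str.maketrans("", "", string.punctuation.replace("_", ""))


def _clean(text: str) -> str:
    return unicodedata.normalize("NFKC", text).lower().translate(_PUNCT)


def normalize_term(term: str) -> str:
    """Normalize a lexicon term to its canonical single-token form.

    NFKC-normalized, lowercased, punctuation stripped, and internal
    whitespace collapsed to single underscores so multiword terms become one
    token.  Raises ``ValueError`` if nothing is left.
    """
    if not term:
        raise ValueError("term must be non-empty")
    normalized = "_".join(_clean(term).split())
    if not normalized.strip("_"):
        raise ValueError(f"term {term!r} is empty after normalization")
    return normalized


@dataclass(frozen=True)
class Lexicon:
    """An ordered, duplicate-free set of normalized domain terms."""

    terms: tuple[str, ...]
    source_tag: str = "unspecified"

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("lexicon must contain at least one term")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("lexicon contains duplicate normalized terms")

    @classmethod
    def from_terms(cls, raw_terms, source_tag: str = "unspecified") -> "Lexicon":
        """Build a lexicon from raw strings, normalizing and deduplicating."""
        seen: dict[str, None] = {}
        for term in raw_terms:
            seen.setdefault(normalize_term(term), None)
        return cls(terms=tuple(seen), source_tag=source_tag)

    def sorted_terms(self) -> tuple[str, ...]:
        return tuple(sorted(self.terms))

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, token: str) -> bool:
        return token in set(self.terms)


@dataclass(frozen=True)
class TokenizedDocument:
    doc_id: ArticleId
    tokens: tuple[str, ...]

    @property
    def is_empty(self) -> bool:
        return len(self.tokens) == 0


def _phrase_table(lexicon: Lexicon) -> dict[str, list[tuple[tuple[str, ...], str]]]:
    """Index multiword lexicon terms by first word, longest phrases first."""
    table: dict[str, list[tuple[tuple[str, ...], str]]] = {}
    for term in lexicon.terms:
        words = tuple(term.split("_"))
        if len(words) > 1:
            table.setdefault(words[0], []).append((words, term))
    for phrases in table.values():
        phrases.sort(key=lambda p: len(p[0]), reverse=True)
    return table


def tokenize(doc: RawDocument, lexicon: Lexicon | None = None) -> TokenizedDocument:
    """Lowercase, strip punctuation, split on whitespace, and collapse phrases.

    When a lexicon is given, any in-text occurrence of a multiword lexicon
    term is rewritten (maximal left-to-right match) into its single
    underscore-joined token.  A document that tokenizes to nothing is
    returned empty and flagged with a warning; callers exclude such
    documents from training.
    """
    words = _clean(doc.body).split()
    if lexicon is not None:
        table = _phrase_table(lexicon)
        if table:
            out: list[str] = []
            i = 0
            while i < len(words):
                matched = False
                for phrase, term in table.get(words[i], ()):
                    if tuple(words[i : i + len(phrase)]) == phrase:
                        out.append(term)
                        i += len(phrase)
                        matched = True
                        break
                if not matched:
                    out.append(words[i])
                    i += 1
            words = out
    if not words:
        warnings.warn(f"document {doc.doc_id!r} tokenized to an empty stream; excluded")
    return TokenizedDocument(doc_id=doc.doc_id, tokens=tuple(words))


def tokenize_corpus(documents, lexicon: Lexicon | None = None) -> list[TokenizedDocument]:
    """Tokenize a corpus, dropping documents that tokenize to nothing."""
    tokenized = [tokenize(doc, lexicon) for doc in documents]
    return [t for t in tokenized if not t.is_empty]


def build_context_document(lexicon: Lexicon) -> TokenizedDocument:
    """The lexicon as a pseudo-document: each term once, in sorted order.

    Sorting makes the context representation independent of the order the
    lexicon file happened to list its terms in; a single occurrence per term
    avoids weighting the context by term frequency in the source resources.
    """
    return TokenizedDocument(doc_id=CONTEXT_DOC_ID, tokens=lexicon.sorted_terms())
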