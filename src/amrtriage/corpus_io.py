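"""Retrieval and persistence of corpora, lexica, scores, and labels.

Documents come either from PubMed Central through the NCBI E-utilities
(ESearch for PMCID discovery, EFetch for full text) or from local JSON-lines
corpus files.  All HTTP traffic goes through an injectable ``transport``
callable so the full pipeline runs offline against recorded responses.

On-disk formats
---------------
corpus   JSONL, one ``{"doc_id", "title", "body"}`` object per line
lexicon  plain text, one term per line, ``#`` comments allowed
scores   CSV ``doc_id,method,score``
labels   CSV ``doc_id,method,score,label``
gold     CSV ``doc_id,label`` with label in {0,1} or {relevant,irrelevant}
"""

from __future__ import annotations

import json
import time
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

from lxml import etree

__all__ = [
    "ArticleId",
    "RawDocument",
    "SearchSpec",
    "FetchResult",
    "RetrievalError",
    "ResponseParseError",
    "EmptyCorpusError",
    "ESEARCH_URL",
    "EFETCH_URL",
    "DEFAULT_SEARCH_TERM",
    "OPEN_ACCESS_FILTER",
    "build_esearch_url",
    "search_pmc",
    "fetch_fulltext",
    "urllib_transport",
    "read_corpus",
    "write_corpus",
    "read_lexicon",
    "read_gold",
    "write_scores",
    "read_scores",
    "write_labels",
    "read_labels",
]

ArticleId = str

ESEARCH_URL = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/esearch.fcgi"
EFETCH_URL = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"

# MeSH-based query for the antimicrobial-resistance domain, as issued against
# the PMC full-text database.  The trailing unbalanced parenthesis is part of
# the query as issued by the original retrieval run and is preserved verbatim.
DEFAULT_SEARCH_TERM = (
    '"drug resistance, microbial"[MeSH Terms]'
    ' OR ("drug"[All Fields] AND "resistance"[All Fields] AND "microbial"[All Fields])'
    ' OR "microbial drug resistance"[All Fields]'
    ' OR ("drug"[All Fields] AND "resistance"[All Fields] AND "microbial"[All Fields])'
    ' OR "drug resistance, microbial"[All Fields])'
)
OPEN_ACCESS_FILTER = '"open access"[filter]'

#: transport: maps a URL to raw response bytes.  Injectable for offline tests.
Transport = Callable[[str], bytes]


class RetrievalError(RuntimeError):
    """Transport-level failure; the request may be retried."""


class ResponseParseError(ValueError):
    """The service answered but the payload was not understood."""


class EmptyCorpusError(RuntimeError):
    """No requested document resolved to retrievable full text."""


@dataclass(frozen=True)
class RawDocument:
    """One retrieved article: PMCID, title (may be empty), and body text."""

    doc_id: ArticleId
    title: str
    body: str

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        if not self.body.strip():
            raise ValueError(f"document {self.doc_id!r} has an empty body")


@dataclass(frozen=True)
class SearchSpec:
    """Parameters of an ESearch request against the PMC full-text index."""

    db: str = "pmc"
    term: str = DEFAULT_SEARCH_TERM
    retmax: int = 10000
    open_access_only: bool = True

    def __post_init__(self) -> None:
        if self.retmax < 1:
            raise ValueError(f"retmax must be >= 1, got {self.retmax}")
        if not self.term.strip():
            raise ValueError("search term must be non-empty")


@dataclass
class FetchResult:
    """Outcome of an EFetch round: resolved documents plus failed ids."""

    documents: list[RawDocument]
    failed_ids: list[ArticleId] = field(default_factory=list)


def urllib_transport(url: str, timeout: float = 60.0) -> bytes:
    """Default network transport built on the standard library."""
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            return resp.read()
    except (urllib.error.URLError, OSError) as exc:  # pragma: no cover - network
        raise RetrievalError(f"E-utilities request failed: {exc}") from exc


def build_esearch_url(spec: SearchSpec) -> str:
    """Assemble the ESearch URL for *spec*.

    The open-access restriction is expressed by appending the PMC
    ``"open access"[filter]`` clause to the term, matching how the query
    appears in the service's own URL encoding.
    """
    term = spec.term
    if spec.open_access_only:
        term = f"{term} AND {OPEN_ACCESS_FILTER}"
    query = urllib.parse.urlencode(
        {"db": spec.db, "term": term, "retmax": str(spec.retmax)},
        quote_via=urllib.parse.quote,
        safe='"[](),',
    )
    return f"{ESEARCH_URL}?{query}"


def _as_pmcid(raw: str) -> ArticleId:
    raw = raw.strip()
    return f"PMC{raw}" if raw.isdigit() else raw


def search_pmc(spec: SearchSpec, transport: Transport = urllib_transport) -> list[ArticleId]:
    """Run an ESearch query and return the PMCIDs of the matching articles.

    Returns at most ``spec.retmax`` ids in the order the service lists them.
    """
    payload = transport(build_esearch_url(spec))
    try:
        root = etree.fromstring(payload)
    except etree.XMLSyntaxError as exc:
        raise ResponseParseError(f"ESearch response is not well-formed XML: {exc}") from exc
    id_list = root.find("IdList")
    if id_list is None:
        raise ResponseParseError("ESearch response lacks an <IdList> element")
    return [_as_pmcid(el.text or "") for el in id_list.findall("Id")]


def _extract_article_text(article: etree._Element) -> tuple[str, str]:
    """Flatten a JATS ``<article>`` into (title, body).

    The body is the title, abstract paragraphs, and body paragraphs
    concatenated in document order, one paragraph per line.
    """
    def text_of(el: etree._Element | None) -> str:
        if el is None:
            return ""
        return " ".join("".join(el.itertext()).split())

    title = text_of(article.find(".//front//article-title"))
    parts = [title] if title else []
    for section in ("front//abstract", "body"):
        holder = article.find(f".//{section}")
        if holder is not None:
            for p in holder.iter("p"):
                txt = text_of(p)
                if txt:
                    parts.append(txt)
    return title, "\n".join(parts)


def _article_pmcid(article: etree._Element) -> ArticleId | None:
    for el in article.findall(".//front//article-id"):
        if el.get("pub-id-type") in ("pmc", "pmcid") and el.text:
            return _as_pmcid(el.text)
    return None


def fetch_fulltext(
    ids: Sequence[ArticleId],
    batch_size: int = 200,
    transport: Transport = urllib_transport,
    delay: float = 0.34,
) -> FetchResult:
    """Fetch full-text XML for *ids* from PMC in batches via EFetch.

    One :class:`RawDocument` is produced per id that resolves to retrievable
    full text; ids that do not are collected in ``FetchResult.failed_ids``
    rather than dropped.  Raises :class:`EmptyCorpusError` if nothing at all
    resolves.  A politeness *delay* separates consecutive requests.
    """
    if not ids:
        raise ValueError("id list must be non-empty")
    if batch_size < 1:
        raise ValueError(f"batch_size must be >= 1, got {batch_size}")

    documents: list[RawDocument] = []
    resolved: set[ArticleId] = set()
    for start in range(0, len(ids), batch_size):
        batch = list(ids[start : start + batch_size])
        if start > 0 and delay > 0:
            time.sleep(delay)
        numeric = ",".join(i.removeprefix("PMC") for i in batch)
        url = (
            f"{EFETCH_URL}?"
            + urllib.parse.urlencode({"db": "pmc", "id": numeric, "retmode": "xml"})
        )
        payload = transport(url)
        try:
            root = etree.fromstring(payload)
        except etree.XMLSyntaxError as exc:
            raise ResponseParseError(f"EFetch response is not well-formed XML: {exc}") from exc
        for article in root.iter("article"):
            pmcid = _article_pmcid(article)
            if pmcid is None or pmcid not in batch:
                continue
            title, body = _extract_article_text(article)
            if not body.strip():
                continue
            documents.append(RawDocument(doc_id=pmcid, title=title, body=body))
            resolved.add(pmcid)

    failed = [i for i in ids if i not in resolved]
    if not documents:
        raise EmptyCorpusError(f"none of the {len(ids)} requested ids resolved to full text")
    return FetchResult(documents=documents, failed_ids=failed)


# ---------------------------------------------------------------------------
# Local persistence
# ---------------------------------------------------------------------------

def write_corpus(documents: Sequence[RawDocument], path: str | Path) -> None:
    """Write a corpus as JSON-lines, one document per line."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in documents:
            fh.write(json.dumps(
                {"doc_id": doc.doc_id, "title": doc.title, "body": doc.body},
                ensure_ascii=False,
            ))
            fh.write("\n")


def read_corpus(path: str | Path) -> list[RawDocument]:
    """Read a JSON-lines corpus; validates id uniqueness."""
    docs: list[RawDocument] = []
    seen: set[str] = set()
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ResponseParseError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            doc = RawDocument(rec["doc_id"], rec.get("title", ""), rec["body"])
            if doc.doc_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)
            docs.append(doc)
    return docs


def read_lexicon(path: str | Path, source_tag: str | None = None):
    """Load a plain-text lexicon (one term per line) into a normalized Lexicon."""
    from .preprocess import Lexicon  # deferred: preprocess imports this module

    terms = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            term = line.strip()
            if term and not term.startswith("#"):
                terms.append(term)
    return Lexicon.from_terms(terms, source_tag=source_tag or str(path))


_LABEL_SYNONYMS = {"0": 0, "1": 1, "relevant": 0, "irrelevant": 1}


def _parse_label(token: str, where: str) -> int:
    try:
        return _LABEL_SYNONYMS[token.strip().lower()]
    except KeyError:
        raise ResponseParseError(
            f"{where}: unknown label token {token!r} "
            "(expected 0/1 or relevant/irrelevant)"
        ) from None


def read_gold(path: str | Path):
    """Read an expert label file: ``doc_id,label`` per line, header optional.

    Word labels are normalized to the numeric convention (0 = relevant,
    1 = irrelevant).  Duplicate ids are a validation error.
    """
    from .labeling import LabelRecord

    records: list[LabelRecord] = []
    seen: set[str] = set()
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            if lineno == 1 and parts[:2] == ["doc_id", "label"]:
                continue
            if len(parts) < 2:
                raise ResponseParseError(f"{path}:{lineno}: expected 'doc_id,label'")
            doc_id = parts[0]
            if doc_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate doc_id {doc_id!r}")
            seen.add(doc_id)
            records.append(LabelRecord(
                doc_id=doc_id,
                label=_parse_label(parts[1], f"{path}:{lineno}"),
                method="gold",
            ))
    return records


def write_scores(scores, path: str | Path) -> None:
    """Write score records as CSV ``doc_id,method,score``."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("doc_id,method,score\n")
        for rec in scores:
            fh.write(f"{rec.doc_id},{rec.method},{rec.score!r}\n")


def read_scores(path: str | Path):
    from .scoring import ScoreRecord

    records: list[ScoreRecord] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if header.strip() != "doc_id,method,score":
            raise ResponseParseError(f"{path}: unexpected score header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            doc_id, method, score = (p.strip() for p in line.split(","))
            records.append(ScoreRecord(doc_id=doc_id, method=method, score=float(score)))
    return records


def write_labels(labels, path: str | Path) -> None:
    """Write label records as CSV ``doc_id,method,score,label``."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("doc_id,method,score,label\n")
        for rec in labels:
            fh.write(f"{rec.doc_id},{rec.method},{rec.score!r},{rec.label}\n")


def read_labels(path: str | Path):
    from .labeling import LabelRecord

    records: list[LabelRecord] = []
    seen: set[str] = set()
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if header.strip() != "doc_id,method,score,label":
            raise ResponseParseError(f"{path}: unexpected label header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            doc_id, method, score, label = (p.strip() for p in line.split(","))
            if doc_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate doc_id {doc_id!r}")
            seen.add(doc_id)
            records.append(LabelRecord(
                doc_id=doc_id,
                label=_parse_label(label, f"{path}:{lineno}"),
                score=float(score),
                method=method,
            ))
    return records
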