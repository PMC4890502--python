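"""Reading abstract corpora and segmenting them into sentences.

Publication corpora arrive as PubMed/MEDLINE article-set XML. This module
parses them into :class:`Article` records, splits abstracts into
:class:`Sentence` units (the granularity at which disease-gene co-occurrence
is asserted downstream), and computes per-year cumulative publication counts.

The sentence splitter is deliberately rule-based and frozen: a boundary is a
run of ``.!?`` followed by whitespace and an uppercase letter or digit,
unless the token ending at the period is on a fixed abbreviation list.
Keeping the rules explicit makes segmentation reproducible across runs and
machines, which a statistical tokenizer would not guarantee.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "Article",
    "Sentence",
    "CorpusParseError",
    "ABBREVIATIONS",
    "parse_corpus",
    "write_corpus_xml",
    "split_sentences",
    "publications_per_year",
    "write_corpus_jsonl",
    "read_corpus_jsonl",
    "write_year_counts_tsv",
]

#: Tokens (lower-cased, final period included) that never end a sentence.
#: Frozen so that segmentation is reproducible; extend only deliberately.
ABBREVIATIONS = frozenset(
    {
        "i.e.",
        "e.g.",
        "vs.",
        "cf.",
        "ca.",
        "etc.",
        "fig.",
        "figs.",
        "eq.",
        "ref.",
        "refs.",
        "no.",
        "al.",  # covers "et al."
        "dr.",
        "st.",
        "approx.",
    }
)


class CorpusParseError(ValueError):
    """Raised when a corpus XML stream cannot be parsed."""


@dataclass(frozen=True)
class Article:
    """One publication: identifier, title, abstract text, publication year.

    ``year`` is ``None`` when the source record carries no parseable
    publication year; such articles are kept (their title and abstract are
    still minable) but excluded from per-year counts.
    """

    pmid: str
    title: str = ""
    abstract: str = ""
    year: int | None = None

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("Article pmid must be non-empty")
        if self.year is not None and not (1800 <= self.year <= 2100):
            raise ValueError(f"Article year {self.year} outside [1800, 2100]")


@dataclass(frozen=True)
class Sentence:
    """A sentence of an abstract, addressed by (pmid, 0-based index).

    Index -1 is reserved for the article title when title mining is on.
    """

    article_pmid: str
    index: int
    text: str

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError("Sentence text must be non-empty")
        if self.index < -1:
            raise ValueError("Sentence index must be >= -1")


# ---------------------------------------------------------------------------
# XML corpus I/O (PubmedArticleSet dialect)
# ---------------------------------------------------------------------------

def parse_corpus(xml_source: IO[bytes] | IO[str] | str) -> list[Article]:
    """Parse a PubMed article-set XML stream into a list of articles.

    Parameters
    ----------
    xml_source:
        A path or a readable (binary or text) stream containing
        ``<PubmedArticleSet>`` XML.

    Returns
    -------
    list of Article
        One record per ``<PubmedArticle>``. Articles without an
        ``AbstractText`` element get an empty abstract (warning logged);
        duplicate PMIDs collapse to the first occurrence (warning logged).

    Raises
    ------
    CorpusParseError
        If the XML is malformed; the message names the parser's position.
    """
    try:
        tree = etree.parse(xml_source)
    except etree.XMLSyntaxError as exc:  # pragma: no cover - message content
        raise CorpusParseError(f"malformed corpus XML: {exc}") from exc

    articles: list[Article] = []
    seen: set[str] = set()
    for node in tree.iter("PubmedArticle"):
        pmid_node = node.find(".//PMID")
        if pmid_node is None or not (pmid_node.text or "").strip():
            logger.warning("article without PMID skipped")
            continue
        pmid = pmid_node.text.strip()
        if pmid in seen:
            logger.warning("duplicate PMID %s: keeping first occurrence", pmid)
            continue
        seen.add(pmid)

        title = _text_of(node.find(".//ArticleTitle"))
        abstract_parts = [
            _text_of(t) for t in node.findall(".//Abstract/AbstractText")
        ]
        abstract = " ".join(p for p in abstract_parts if p).strip()
        if not abstract:
            logger.warning("article %s has no abstract text", pmid)

        year = _parse_year(node)
        articles.append(Article(pmid=pmid, title=title, abstract=abstract, year=year))
    return articles


def _text_of(node: etree._Element | None) -> str:
    if node is None:
        return ""
    return "".join(node.itertext()).strip()


def _parse_year(article_node: etree._Element) -> int | None:
    # Prefer the journal issue's publication year, as plotted in per-year
    # publication counts; fall back to any <Year> under the article.
    for xpath in (".//JournalIssue/PubDate/Year", ".//PubDate/Year", ".//Year"):
        node = article_node.find(xpath)
        if node is not None and (node.text or "").strip().isdigit():
            year = int(node.text.strip())
            if 1800 <= year <= 2100:
                return year
    return None


def write_corpus_xml(articles: Iterable[Article], destination: IO[bytes] | str) -> None:
    """Serialize articles back to PubmedArticleSet XML (round-trip safe)."""
    root = etree.Element("PubmedArticleSet")
    for art in articles:
        pa = etree.SubElement(root, "PubmedArticle")
        cit = etree.SubElement(pa, "MedlineCitation")
        etree.SubElement(cit, "PMID").text = art.pmid
        article_el = etree.SubElement(cit, "Article")
        if art.year is not None:
            journal = etree.SubElement(article_el, "Journal")
            issue = etree.SubElement(journal, "JournalIssue")
            pubdate = etree.SubElement(issue, "PubDate")
            etree.SubElement(pubdate, "Year").text = str(art.year)
        etree.SubElement(article_el, "ArticleTitle").text = art.title
        if art.abstract:
            abstract_el = etree.SubElement(article_el, "Abstract")
            etree.SubElement(abstract_el, "AbstractText").text = art.abstract
    payload = etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
    if isinstance(destination, str):
        with open(destination, "wb") as handle:
            handle.write(payload)
    else:
        destination.write(payload)


# ---------------------------------------------------------------------------
# Sentence segmentation
# ---------------------------------------------------------------------------

# A candidate boundary: terminator run, then whitespace, then upper/digit.
_BOUNDARY = re.compile(r"[.!?]+(?=\s+[A-Z0-9])")
_TRAILING_TOKEN = re.compile(r"(\S+)$")


def split_sentences(abstract: str, article_pmid: str = "") -> list[Sentence]:
    """Split an abstract into sentences with the frozen rule set.

    Boundaries occur at ``.``/``!``/``?`` followed by whitespace and an
    uppercase letter or digit, except after known abbreviations (see
    :data:`ABBREVIATIONS`). The concatenation of the returned texts equals
    the input modulo inter-sentence whitespace, and re-splitting any output
    sentence returns it unchanged.
    """
    text = abstract.strip()
    if not text:
        return []

    cut_points: list[int] = []
    for match in _BOUNDARY.finditer(text):
        end = match.end()
        token_match = _TRAILING_TOKEN.search(text, 0, end)
        token = token_match.group(1).lower() if token_match else ""
        if token in ABBREVIATIONS:
            continue
        # Single uppercase initial ("J. Smith") is not a boundary either.
        if re.fullmatch(r"[A-Z]\.", token_match.group(1) if token_match else ""):
            continue
        cut_points.append(end)

    sentences: list[Sentence] = []
    start = 0
    for cut in cut_points:
        chunk = text[start:cut].strip()
        if chunk:
            sentences.append(Sentence(article_pmid, len(sentences), chunk))
        start = cut
    tail = text[start:].strip()
    if tail:
        sentences.append(Sentence(article_pmid, len(sentences), tail))
    return sentences


# ---------------------------------------------------------------------------
# Per-year publication counts
# ---------------------------------------------------------------------------

def publications_per_year(articles: Iterable[Article]) -> dict[int, int]:
    """Cumulative number of publications per year.

    Articles of unknown year are excluded. The mapping covers every year
    present in the corpus (sorted ascending); values are running totals, so
    the last value equals the number of dated articles.
    """
    per_year: dict[int, int] = {}
    for art in articles:
        if art.year is not None:
            per_year[art.year] = per_year.get(art.year, 0) + 1
    cumulative: dict[int, int] = {}
    running = 0
    for year in sorted(per_year):
        running += per_year[year]
        cumulative[year] = running
    return cumulative


# ---------------------------------------------------------------------------
# Normalized corpus serialization (JSON-lines) and count export
# ---------------------------------------------------------------------------

def write_corpus_jsonl(articles: Iterable[Article], path: str) -> None:
    """One Article per line as a JSON object; the pipeline's normalized form."""
    with open(path, "w", encoding="utf-8") as handle:
        for art in articles:
            handle.write(
                json.dumps(
                    {
                        "pmid": art.pmid,
                        "title": art.title,
                        "abstract": art.abstract,
                        "year": art.year,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_corpus_jsonl(path: str) -> list[Article]:
    articles = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            if line.strip():
                rec = json.loads(line)
                articles.append(
                    Article(rec["pmid"], rec["title"], rec["abstract"], rec["year"])
                )
    return articles


def write_year_counts_tsv(counts: Mapping[int, int], path: str) -> None:
    """Two-column TSV (year, cumulative_count), one row per year."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("year\tcumulative_count\n")
        for year in sorted(counts):
            handle.write(f"{year}\t{counts[year]}\n")
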