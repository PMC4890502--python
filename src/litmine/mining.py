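"""Dictionary-based gene mention tagging and co-occurrence extraction.

Gene mentions are found by exact, token-boundary-respecting string matching
against a synonym dictionary built from Entrez ``gene_info``-style records.
A disease-gene association is asserted when an *unambiguous* gene mention
and a disease keyword occur in the same sentence; ambiguous mentions that
co-occur with a disease keyword are never silently resolved — they go to a
machine-readable review queue, optionally resolvable with a curated override
file (synonym -> gene_id), the reproducible stand-in for manual curation.

Matching policy: case-insensitive, except synonyms that are all-uppercase
and at most 3 characters long (``WAS``, ``CAT``, ...), which match
case-sensitively — naive case-folding of those floods the extractor with
false positives from ordinary English words. The policy is configurable via
``case_sensitive_short_upper``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .corpus import Article, Sentence, split_sentences

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "SynonymDictionary",
    "GeneMention",
    "Association",
    "DEFAULT_DISEASE_TERMS",
    "build_dictionary",
    "read_gene_info_tsv",
    "write_gene_info_tsv",
    "tag_sentence",
    "extract_associations",
    "aggregate_gene_counts",
    "write_associations_tsv",
    "write_review_queue_tsv",
    "write_gene_counts_tsv",
]

#: The disease keyword combination used for atherosclerosis mining.
DEFAULT_DISEASE_TERMS = frozenset(
    {"atherosclerosis", "atherogenesis", "atheroma", "atherosclerotic"}
)

_SHORT_UPPER_LEN = 3


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its stable integer id, canonical symbol, and synonyms."""

    gene_id: int
    symbol: str
    synonyms: frozenset[str] = frozenset()

    def all_names(self) -> frozenset[str]:
        return self.synonyms | {self.symbol}


@dataclass
class SynonymDictionary:
    """Normalized synonym -> candidate gene-id lookup.

    ``entries`` maps the case-folded synonym to the set of gene ids carrying
    it. ``case_sensitive`` holds, for keys whose only origin is a short
    all-uppercase synonym, the exact surface forms required for a match.
    A key may carry both a case-insensitive id set and surface-restricted
    ids (e.g. gene A has synonym "Cat", gene B has "CAT").
    """

    entries: dict[str, frozenset[int]] = field(default_factory=dict)
    case_sensitive: dict[str, dict[str, frozenset[int]]] = field(default_factory=dict)
    blacklist: frozenset[str] = frozenset()
    symbols: dict[int, str] = field(default_factory=dict)
    max_key_length: int = 0

    def lookup(self, surface: str) -> frozenset[int]:
        """Gene ids matchable by this exact surface form (may be empty)."""
        key = surface.casefold()
        ids = self.entries.get(key, frozenset())
        restricted = self.case_sensitive.get(key)
        if restricted:
            ids = ids | restricted.get(surface, frozenset())
        return ids

    def __len__(self) -> int:
        return len(set(self.entries) | set(self.case_sensitive))


@dataclass(frozen=True)
class GeneMention:
    """A matched gene name within a sentence.

    ``span`` is the (start, end) half-open character interval; ``status`` is
    ``"ambiguous"`` exactly when more than one gene carries the surface form.
    """

    pmid: str
    sentence_index: int
    span: tuple[int, int]
    surface: str
    gene_ids: frozenset[int]
    sentence_text: str = ""

    @property
    def status(self) -> str:
        return "ambiguous" if len(self.gene_ids) > 1 else "unambiguous"


@dataclass(frozen=True)
class Association:
    """Sentence-level disease-gene co-occurrence evidence."""

    gene_id: int
    pmid: str
    sentence_index: int
    evidence: str


# ---------------------------------------------------------------------------
# Dictionary construction
# ---------------------------------------------------------------------------

def build_dictionary(
    records: Sequence[GeneRecord],
    blacklist: Iterable[str] = (),
    case_sensitive_short_upper: bool = True,
) -> SynonymDictionary:
    """Build the synonym lookup from gene records.

    Every non-blacklisted synonym becomes a key; synonyms shared by two or
    more genes map to the union of their ids (ambiguity is preserved, never
    dropped). Duplicate gene ids across records are an error.
    """
    if not records:
        raise ValueError("cannot build a dictionary from zero records")
    seen_ids: set[int] = set()
    for rec in records:
        if rec.gene_id in seen_ids:
            raise ValueError(f"duplicate gene_id {rec.gene_id} across records")
        seen_ids.add(rec.gene_id)

    black = frozenset(term.casefold() for term in blacklist)
    entries: dict[str, set[int]] = {}
    case_sensitive: dict[str, dict[str, set[int]]] = {}
    symbols: dict[int, str] = {}
    for rec in records:
        symbols[rec.gene_id] = rec.symbol
        for name in rec.all_names():
            if not name or name.casefold() in black:
                continue
            key = name.casefold()
            if (
                case_sensitive_short_upper
                and len(name) <= _SHORT_UPPER_LEN
                and name.isupper()
                and name.isalpha()
            ):
                case_sensitive.setdefault(key, {}).setdefault(name, set()).add(
                    rec.gene_id
                )
            else:
                entries.setdefault(key, set()).add(rec.gene_id)

    return SynonymDictionary(
        entries={k: frozenset(v) for k, v in entries.items()},
        case_sensitive={
            k: {s: frozenset(v) for s, v in surf.items()}
            for k, surf in case_sensitive.items()
        },
        blacklist=black,
        symbols=symbols,
        max_key_length=max(
            (len(k) for k in list(entries) + list(case_sensitive)), default=0
        ),
    )


def read_gene_info_tsv(path: str) -> list[GeneRecord]:
    """Read an Entrez ``gene_info``-style TSV.

    Expected columns (tab-separated, ``#`` header lines skipped):
    tax_id, GeneID, Symbol, Synonyms (pipe-separated, ``-`` for none).
    """
    records: list[GeneRecord] = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                logger.warning("gene_info line with <4 columns skipped: %r", line)
                continue
            _tax, gene_id, symbol, synonyms = parts[:4]
            syn_set = frozenset(
                s for s in synonyms.split("|") if s and s != "-"
            )
            records.append(GeneRecord(int(gene_id), symbol, syn_set))
    return records


def write_gene_info_tsv(records: Iterable[GeneRecord], path: str, tax_id: int = 9606) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("#tax_id\tGeneID\tSymbol\tSynonyms\n")
        for rec in records:
            extra = sorted(rec.synonyms - {rec.symbol})
            handle.write(
                f"{tax_id}\t{rec.gene_id}\t{rec.symbol}\t{'|'.join(extra) or '-'}\n"
            )


# ---------------------------------------------------------------------------
# Tagging
# ---------------------------------------------------------------------------

def _is_word_char(ch: str) -> bool:
    return ch.isalnum() or ch == "_"


def tag_sentence(sentence: Sentence, dictionary: SynonymDictionary) -> list[GeneMention]:
    """Tag gene mentions: longest match wins, left-to-right, non-overlapping.

    Matches must sit on token boundaries — a dictionary key never matches
    inside a longer alphanumeric word ("APOEX" does not contain "APOE").
    """
    text = sentence.text
    mentions: list[GeneMention] = []
    i = 0
    n = len(text)
    max_len = dictionary.max_key_length
    while i < n:
        if i > 0 and _is_word_char(text[i - 1]):
            i += 1
            continue
        if not _is_word_char(text[i]):
            i += 1
            continue
        hit: tuple[int, frozenset[int]] | None = None
        limit = min(max_len, n - i)
        for length in range(limit, 0, -1):
            end = i + length
            if end < n and _is_word_char(text[end]):
                continue
            surface = text[i:end]
            ids = dictionary.lookup(surface)
            if ids:
                hit = (end, ids)
                break
        if hit is None:
            i += 1
            continue
        end, ids = hit
        mentions.append(
            GeneMention(
                pmid=sentence.article_pmid,
                sentence_index=sentence.index,
                span=(i, end),
                surface=text[i:end],
                gene_ids=ids,
                sentence_text=text,
            )
        )
        i = end
    return mentions


def _contains_term(text_folded: str, term: str) -> bool:
    """Boundary-aware case-insensitive substring test for a disease keyword."""
    term = term.casefold()
    start = 0
    while True:
        pos = text_folded.find(term, start)
        if pos < 0:
            return False
        end = pos + len(term)
        left_ok = pos == 0 or not _is_word_char(text_folded[pos - 1])
        right_ok = end == len(text_folded) or not _is_word_char(text_folded[end])
        if left_ok and right_ok:
            return True
        start = pos + 1


# ---------------------------------------------------------------------------
# Association extraction
# ---------------------------------------------------------------------------

def extract_associations(
    articles: Iterable[Article],
    dictionary: SynonymDictionary,
    disease_terms: Iterable[str] = DEFAULT_DISEASE_TERMS,
    overrides: Mapping[str, int] | None = None,
    mine_titles: bool = False,
) -> tuple[list[Association], list[GeneMention]]:
    """Extract sentence-level disease-gene associations from a corpus.

    For every abstract sentence containing at least one disease keyword,
    each unambiguous gene mention yields one :class:`Association`; each
    ambiguous mention is appended to the review queue instead, unless the
    curated ``overrides`` map (surface form, case-folded -> gene_id) names a
    resolution. Only abstracts are mined by default; ``mine_titles=True``
    additionally treats the title as one pseudo-sentence at index -1.

    Returns ``(associations, review_queue)`` with associations deduplicated
    on (gene_id, pmid, sentence_index) and deterministically ordered.
    """
    terms = [t.casefold() for t in disease_terms]
    if not terms:
        raise ValueError("disease_terms must be non-empty")
    if len(dictionary) == 0:
        raise ValueError("synonym dictionary is empty")
    overrides = {k.casefold(): v for k, v in (overrides or {}).items()}

    seen: set[tuple[int, str, int]] = set()
    associations: list[Association] = []
    queue: list[GeneMention] = []
    for article in articles:
        sentences = split_sentences(article.abstract, article.pmid)
        if mine_titles and article.title.strip():
            sentences = [Sentence(article.pmid, -1, article.title)] + [
                Sentence(article.pmid, s.index, s.text) for s in sentences
            ]
        for sent in sentences:
            folded = sent.text.casefold()
            if not any(_contains_term(folded, t) for t in terms):
                continue
            for mention in tag_sentence(sent, dictionary):
                gene_ids = mention.gene_ids
                if len(gene_ids) > 1:
                    resolved = overrides.get(mention.surface.casefold())
                    if resolved is not None and resolved in gene_ids:
                        gene_ids = frozenset({resolved})
                    else:
                        queue.append(mention)
                        continue
                (gene_id,) = gene_ids
                key = (gene_id, sent.article_pmid, sent.index)
                if key in seen:
                    continue
                seen.add(key)
                associations.append(
                    Association(gene_id, sent.article_pmid, sent.index, sent.text)
                )
    associations.sort(key=lambda a: (a.pmid, a.sentence_index, a.gene_id))
    return associations, queue


def aggregate_gene_counts(associations: Iterable[Association]) -> dict[int, int]:
    """Distinct supporting publications per gene (a pmid counts once)."""
    pmids: dict[int, set[str]] = {}
    for assoc in associations:
        pmids.setdefault(assoc.gene_id, set()).add(assoc.pmid)
    return {gene: len(ps) for gene, ps in pmids.items()}


# ---------------------------------------------------------------------------
# TSV exports
# ---------------------------------------------------------------------------

def write_associations_tsv(
    associations: Iterable[Association],
    path: str,
    symbols: Mapping[int, str] | None = None,
) -> None:
    symbols = symbols or {}
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("gene_id\tsymbol\tpmid\tsentence_index\tevidence\n")
        for a in associations:
            sym = symbols.get(a.gene_id, "")
            evidence = a.evidence.replace("\t", " ").replace("\n", " ")
            handle.write(f"{a.gene_id}\t{sym}\t{a.pmid}\t{a.sentence_index}\t{evidence}\n")


def write_review_queue_tsv(queue: Iterable[GeneMention], path: str) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("pmid\tsentence_index\tsurface\tcandidate_gene_ids\tevidence\n")
        for m in queue:
            ids = ",".join(str(i) for i in sorted(m.gene_ids))
            evidence = m.sentence_text.replace("\t", " ").replace("\n", " ")
            handle.write(f"{m.pmid}\t{m.sentence_index}\t{m.surface}\t{ids}\t{evidence}\n")


def write_gene_counts_tsv(
    counts: Mapping[int, int], path: str, symbols: Mapping[int, str] | None = None
) -> None:
    symbols = symbols or {}
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("gene_id\tsymbol\tn_publications\n")
        for gene_id, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
            handle.write(f"{gene_id}\t{symbols.get(gene_id, '')}\t{count}\n")
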