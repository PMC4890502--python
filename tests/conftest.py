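"""Shared fixtures: tiny in-memory corpora and dictionaries."""

from __future__ import annotations

import io

import pytest

from litmine import Article, GeneRecord, build_dictionary


MINI_CORPUS_XML = b"""<?xml version="1.0" encoding="UTF-8"?>
<PubmedArticleSet>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>1</PMID>
      <Article>
        <Journal><JournalIssue><PubDate><Year>2001</Year></PubDate></JournalIssue></Journal>
        <ArticleTitle>First article</ArticleTitle>
        <Abstract><AbstractText>A. B.</AbstractText></Abstract>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>2</PMID>
      <Article>
        <Journal><JournalIssue><PubDate><Year>2003</Year></PubDate></JournalIssue></Journal>
        <ArticleTitle>Second article, no abstract</ArticleTitle>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
</PubmedArticleSet>
"""


@pytest.fixture
def mini_corpus_stream():
    return io.BytesIO(MINI_CORPUS_XML)


@pytest.fixture
def gene_records():
    return [
        GeneRecord(348, "APOE", frozenset({"APOE", "ApoE", "apolipoprotein E"})),
        GeneRecord(5970, "RELA", frozenset({"RELA", "p65", "NFKB3"})),
        GeneRecord(7124, "TNF", frozenset({"TNF", "p65", "tumor necrosis factor"})),
        GeneRecord(847, "CAT", frozenset({"CAT", "catalase"})),
    ]


@pytest.fixture
def dictionary(gene_records):
    return build_dictionary(gene_records)


@pytest.fixture
def articles_one_assoc():
    return [
        Article(
            pmid="10",
            title="t",
            abstract="ApoE deficiency accelerates atherosclerosis. Nothing else here.",
            year=2000,
        )
    ]
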