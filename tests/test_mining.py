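"""Dictionary construction, mention tagging, and association extraction."""

from __future__ import annotations

import pytest

from litmine import (
    Article,
    GeneRecord,
    Sentence,
    aggregate_gene_counts,
    build_dictionary,
    extract_associations,
    tag_sentence,
)


class TestBuildDictionary:
    def test_single_record_case_folded_key(self):
        records = [GeneRecord(1, "APOE", frozenset({"APOE", "ApoE"}))]
        d = build_dictionary(records)
        assert d.entries["apoe"] == frozenset({1})

    def test_shared_synonym_maps_to_union_of_ids(self, dictionary):
        assert dictionary.lookup("p65") == frozenset({5970, 7124})

    def test_blacklist_removes_key_even_if_carried_by_a_gene(self):
        records = [GeneRecord(1, "WAS", frozenset({"WAS", "WASP"}))]
        d = build_dictionary(records, blacklist={"WAS"})
        assert d.lookup("WAS") == frozenset()
        assert d.lookup("WASP") == frozenset({1})

    def test_duplicate_gene_id_rejected(self):
        records = [GeneRecord(1, "A"), GeneRecord(1, "B")]
        with pytest.raises(ValueError, match="duplicate gene_id"):
            build_dictionary(records)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            build_dictionary([])

    def test_short_uppercase_synonym_requires_exact_case(self, dictionary):
        # "CAT" (gene symbol) must not be matched by the English word "cat",
        # but the long synonym "catalase" stays case-insensitive.
        assert dictionary.lookup("cat") == frozenset()
        assert dictionary.lookup("CAT") == frozenset({847})
        assert dictionary.lookup("CATALASE") == frozenset({847})

    def test_case_policy_can_be_disabled(self, gene_records):
        d = build_dictionary(gene_records, case_sensitive_short_upper=False)
        assert d.lookup("cat") == frozenset({847})


class TestTagSentence:
    def _sentence(self, text):
        return Sentence("1", 0, text)

    def test_direct_hit_with_span(self, dictionary):
        mentions = tag_sentence(
            self._sentence("ApoE deficiency accelerates atherosclerosis."), dictionary
        )
        assert len(mentions) == 1
        assert mentions[0].span == (0, 4)
        assert mentions[0].gene_ids == frozenset({348})
        assert mentions[0].status == "unambiguous"

    def test_no_match_inside_longer_word(self, dictionary):
        assert tag_sentence(self._sentence("APOEX protein binds."), dictionary) == []

    def test_ambiguous_mention_propagates_all_ids(self, dictionary):
        mentions = tag_sentence(self._sentence("Here p65 is induced."), dictionary)
        assert len(mentions) == 1
        assert mentions[0].status == "ambiguous"
        assert mentions[0].gene_ids == frozenset({5970, 7124})

    def test_longest_match_wins(self, dictionary):
        # "tumor necrosis factor" must match as one mention, not stop early.
        mentions = tag_sentence(
            self._sentence("Induction of tumor necrosis factor was seen."), dictionary
        )
        assert [m.surface for m in mentions] == ["tumor necrosis factor"]
        assert mentions[0].gene_ids == frozenset({7124})

    def test_mentions_non_overlapping_and_left_to_right(self, dictionary):
        mentions = tag_sentence(self._sentence("APOE and RELA and CAT."), dictionary)
        spans = [m.span for m in mentions]
        assert spans == sorted(spans)
        for (a, b), (c, d) in zip(spans, spans[1:]):
            assert b <= c

    def test_spans_index_into_sentence(self, dictionary):
        sent = self._sentence("The catalase enzyme and ApoE were assayed.")
        for m in tag_sentence(sent, dictionary):
            assert sent.text[m.span[0]:m.span[1]] == m.surface


class TestExtractAssociations:
    def test_single_sentence_co_occurrence(self, dictionary, articles_one_assoc):
        associations, queue = extract_associations(articles_one_assoc, dictionary)
        assert len(associations) == 1
        assert associations[0].gene_id == 348
        assert associations[0].sentence_index == 0
        assert queue == []

    def test_gene_and_disease_in_different_sentences_not_associated(self, dictionary):
        articles = [
            Article(
                pmid="11",
                abstract="ApoE was measured. Atherosclerosis progressed regardless.",
            )
        ]
        associations, _ = extract_associations(articles, dictionary)
        assert associations == []

    def test_ambiguous_mention_goes_to_queue_not_associations(self, dictionary):
        articles = [
            Article(pmid="12", abstract="Induction of p65 aggravates atherosclerosis.")
        ]
        associations, queue = extract_associations(articles, dictionary)
        assert associations == []
        assert len(queue) == 1
        assert queue[0].surface == "p65"

    def test_override_resolves_ambiguity_reproducibly(self, dictionary):
        articles = [
            Article(pmid="12", abstract="Induction of p65 aggravates atherosclerosis.")
        ]
        associations, queue = extract_associations(
            articles, dictionary, overrides={"p65": 5970}
        )
        assert [a.gene_id for a in associations] == [5970]
        assert queue == []

    def test_titles_not_mined_by_default_but_configurable(self, dictionary):
        articles = [
            Article(pmid="13", title="ApoE in atherosclerosis", abstract="Nothing here.")
        ]
        assert extract_associations(articles, dictionary)[0] == []
        associations, _ = extract_associations(articles, dictionary, mine_titles=True)
        assert [(a.gene_id, a.sentence_index) for a in associations] == [(348, -1)]

    def test_disease_term_requires_token_boundary(self, dictionary):
        articles = [Article(pmid="14", abstract="ApoE and pseudoatheroma were noted.")]
        assert extract_associations(articles, dictionary)[0] == []

    def test_empty_disease_terms_rejected(self, dictionary, articles_one_assoc):
        with pytest.raises(ValueError):
            extract_associations(articles_one_assoc, dictionary, disease_terms=set())

    def test_determinism_byte_identical_tables(self, dictionary, articles_one_assoc):
        first = extract_associations(articles_one_assoc, dictionary)
        second = extract_associations(articles_one_assoc, dictionary)
        assert first == second

    def test_no_association_carries_ambiguous_id(self, dictionary):
        articles = [
            Article(
                pmid="15",
                abstract=(
                    "ApoE and p65 both rise in atherosclerosis. "
                    "RELA drives atherogenesis."
                ),
            )
        ]
        associations, queue = extract_associations(articles, dictionary)
        assert {a.gene_id for a in associations} == {348, 5970}
        assert [m.surface for m in queue] == ["p65"]


class TestAggregateGeneCounts:
    @pytest.mark.parametrize(
        "pairs, expected",
        [
            ([(1, "a"), (1, "a"), (1, "b")], {1: 2}),
            ([], {}),
            ([(1, "a"), (2, "a")], {1: 1, 2: 1}),
        ],
    )
    def test_distinct_pmid_counting(self, pairs, expected):
        from litmine import Association

        associations = [
            Association(gene_id=g, pmid=p, sentence_index=i, evidence="e")
            for i, (g, p) in enumerate(pairs)
        ]
        assert aggregate_gene_counts(associations) == expected
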