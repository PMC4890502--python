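"""Seeded synthetic inputs with planted ground truth.

Every pipeline stage gets a generator that emits the same file formats the
real inputs use (PubMed-dialect XML, gene_info TSV, GMT, edge-list TSV)
together with a machine-readable truth object, so extraction, enrichment,
hub detection and prioritization can each be checked against a known
answer without any download.

What is emulated: abstracts whose sentences mix neutral filler with
planted disease-gene co-occurrences (and, in noise mode, gene-only and
disease-only decoy sentences that a correct extractor must ignore); a gene
synonym dictionary with a controllable rate of synonyms shared between
genes (the ambiguity the normalizer must surface, not resolve); an
annotation universe with exactly one term over-represented in the study
set at a stated fold; and a scale-free interaction network grown by
preferential attachment from an initial clique, optionally with a planted
densely wired disease module.

What is *not* emulated: real biomedical language (mentions are clean
dictionary surface forms in template sentences), citation structure, and
the error modes of statistical named-entity taggers. Passing tests on this
data therefore demonstrate correctness of the pipeline's logic, not its
recall on free text.

All generators are pure functions of their parameters and a seed; a single
study-level seed fans out to per-generator child seeds by fixed offsets.
"""

from __future__ import annotations

import io
import json
import os
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from .corpus import Article, write_corpus_xml
from .mining import DEFAULT_DISEASE_TERMS, GeneRecord, write_gene_info_tsv

__all__ = [
    "SyntheticTruth",
    "child_seed",
    "generate_dictionary",
    "generate_corpus",
    "generate_annotation",
    "generate_ppi",
    "write_edge_list_tsv",
    "generate_study",
    "PLANTED_TERM_ID",
]

PLANTED_TERM_ID = "T9999"

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"


@dataclass
class SyntheticTruth:
    """Planted ground truth for one synthetic study (JSON-serializable)."""

    rng_seed: int = 0
    planted_associations: set[tuple[int, str, int]] = field(default_factory=set)
    planted_ambiguous: set[tuple[str, str, int]] = field(default_factory=set)  # (surface, pmid, idx)
    decoy_sentences: int = 0
    ambiguous_synonyms: set[str] = field(default_factory=set)
    planted_enriched_terms: dict[str, float] = field(default_factory=dict)
    planted_module: set[int] = field(default_factory=set)
    n_articles: int = 0

    @property
    def planted_genes(self) -> set[int]:
        return {g for g, _, _ in self.planted_associations}

    def to_json(self, path: str) -> None:
        payload = {
            "rng_seed": self.rng_seed,
            "planted_associations": sorted(
                [g, p, i] for g, p, i in self.planted_associations
            ),
            "planted_ambiguous": sorted(
                [s, p, i] for s, p, i in self.planted_ambiguous
            ),
            "decoy_sentences": self.decoy_sentences,
            "ambiguous_synonyms": sorted(self.ambiguous_synonyms),
            "planted_enriched_terms": self.planted_enriched_terms,
            "planted_module": sorted(self.planted_module),
            "n_articles": self.n_articles,
        }
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "SyntheticTruth":
        with open(path, encoding="utf-8") as handle:
            raw = json.load(handle)
        return cls(
            rng_seed=raw["rng_seed"],
            planted_associations={(g, p, i) for g, p, i in raw["planted_associations"]},
            planted_ambiguous={(s, p, i) for s, p, i in raw["planted_ambiguous"]},
            decoy_sentences=raw["decoy_sentences"],
            ambiguous_synonyms=set(raw["ambiguous_synonyms"]),
            planted_enriched_terms=dict(raw["planted_enriched_terms"]),
            planted_module=set(raw["planted_module"]),
            n_articles=raw["n_articles"],
        )


def child_seed(seed: int, offset: int) -> int:
    """Deterministic per-generator seed derived from the study seed."""
    return (seed * 1_000_003 + offset) % (2**31 - 1)


# ---------------------------------------------------------------------------
# Synonym dictionary
# ---------------------------------------------------------------------------

def _pronounceable(rng: np.random.Generator, n_syllables: int = 3) -> str:
    return "".join(
        _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]
        for _ in range(n_syllables)
    )


def generate_dictionary(
    n_genes: int,
    synonyms_per_gene: int = 3,
    ambiguity_rate: float = 0.1,
    seed: int = 0,
) -> tuple[list[GeneRecord], SyntheticTruth]:
    """Generate gene records with pronounceable, digit-suffixed names.

    Each gene gets a unique uppercase symbol plus ``synonyms_per_gene - 1``
    alias synonyms. Each alias is, with probability ``ambiguity_rate``, also
    granted to a second randomly chosen gene, making it ambiguous. Every
    name carries a numeric suffix, so generated names can never collide
    with the English filler text of synthetic abstracts.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if synonyms_per_gene < 1:
        raise ValueError("synonyms_per_gene must be >= 1")
    if not (0.0 <= ambiguity_rate < 1.0):
        raise ValueError("ambiguity_rate must be in [0, 1)")

    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(rng_seed=seed)
    gene_ids = list(range(1, n_genes + 1))
    symbols = {g: f"{_pronounceable(rng).upper()}{g}" for g in gene_ids}
    synonyms: dict[int, set[str]] = {g: set() for g in gene_ids}

    alias_counter = 0
    for g in gene_ids:
        for _ in range(synonyms_per_gene - 1):
            alias_counter += 1
            alias = f"{_pronounceable(rng).capitalize()}{n_genes + alias_counter}"
            synonyms[g].add(alias)
            if n_genes > 1 and rng.random() < ambiguity_rate:
                partner = int(rng.choice([x for x in gene_ids if x != g]))
                synonyms[partner].add(alias)
                truth.ambiguous_synonyms.add(alias)

    records = [
        GeneRecord(g, symbols[g], frozenset(synonyms[g]) | {symbols[g]})
        for g in gene_ids
    ]
    return records, truth


# ---------------------------------------------------------------------------
# Abstract corpus
# ---------------------------------------------------------------------------

_FILLER_TEMPLATES = [
    "Samples were collected from twelve subjects over two years.",
    "Statistical analysis relied on standard regression models.",
    "The cohort was recruited at a single tertiary center.",
    "Imaging was performed at baseline and at follow-up.",
    "All participants provided written informed consent.",
    "Laboratory measurements followed established protocols.",
    "The findings were consistent across both study arms.",
    "Further replication in larger cohorts is warranted.",
]

_ASSOC_TEMPLATES = [
    "Expression of {gene} was markedly elevated in {disease} lesions.",
    "We found that {gene} promotes {disease} in murine models.",
    "Serum levels of {gene} correlated with {disease} severity.",
    "Knockdown of {gene} attenuated {disease} progression.",
]

_GENE_ONLY_TEMPLATES = [
    "Baseline activity of {gene} was measured in cultured cells.",
    "The promoter of {gene} was cloned and sequenced.",
]

_DISEASE_ONLY_TEMPLATES = [
    "{disease} remains a major cause of cardiovascular morbidity.",
    "Early detection of {disease} is clinically challenging.",
]


def generate_corpus(
    records: Sequence[GeneRecord],
    n_articles: int,
    assoc_density: float = 0.5,
    noise_mode: bool = False,
    seed: int = 0,
    disease_terms: Iterable[str] = DEFAULT_DISEASE_TERMS,
    ambiguous_density: float = 0.1,
    ambiguous_synonyms: Iterable[str] = (),
) -> tuple[bytes, SyntheticTruth]:
    """Generate a PubMed-dialect XML corpus with planted co-occurrences.

    Each article carries 2-6 template sentences. With probability
    ``assoc_density`` an article contains one planted sentence pairing a
    disease keyword with an *unambiguous* gene synonym (recorded in the
    truth as an expected association). With probability
    ``ambiguous_density`` — and only if the dictionary carries ambiguous
    synonyms — an article additionally plants an ambiguous synonym next to
    a disease keyword, which must surface in the review queue, never as an
    association. ``noise_mode`` adds decoy sentences (gene without disease,
    disease without gene) that a correct extractor ignores.
    """
    if n_articles < 1:
        raise ValueError("n_articles must be >= 1")
    if not (0.0 <= assoc_density <= 1.0):
        raise ValueError("assoc_density must be in [0, 1]")

    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(rng_seed=seed, n_articles=n_articles)
    disease_list = sorted(disease_terms)
    ambiguous = sorted(ambiguous_synonyms)

    # Unambiguous (gene, surface) pairs available for planting.
    surface_owner: dict[str, set[int]] = {}
    for rec in records:
        for name in rec.all_names():
            surface_owner.setdefault(name, set()).add(rec.gene_id)
    unambiguous_pairs = sorted(
        (next(iter(owners)), surface)
        for surface, owners in surface_owner.items()
        if len(owners) == 1 and surface not in set(ambiguous)
    )
    if not unambiguous_pairs:
        raise ValueError("dictionary offers no unambiguous synonym to plant")

    articles: list[Article] = []
    for i in range(n_articles):
        pmid = f"{900000 + i}"
        year = int(rng.integers(1996, 2016))
        n_filler = int(rng.integers(2, 7))
        sentences = [
            _FILLER_TEMPLATES[int(rng.integers(len(_FILLER_TEMPLATES)))]
            for _ in range(n_filler)
        ]

        if rng.random() < assoc_density:
            gene_id, surface = unambiguous_pairs[int(rng.integers(len(unambiguous_pairs)))]
            template = _ASSOC_TEMPLATES[int(rng.integers(len(_ASSOC_TEMPLATES)))]
            disease = disease_list[int(rng.integers(len(disease_list)))]
            idx = int(rng.integers(len(sentences) + 1))
            sentences.insert(idx, template.format(gene=surface, disease=disease))
            truth.planted_associations.add((gene_id, pmid, idx))

        if ambiguous and rng.random() < ambiguous_density:
            surface = ambiguous[int(rng.integers(len(ambiguous)))]
            disease = disease_list[int(rng.integers(len(disease_list)))]
            sentence = f"Levels of {surface} were increased in {disease} plaques."
            sentences.append(sentence)
            truth.planted_ambiguous.add((surface, pmid, len(sentences) - 1))

        if noise_mode:
            gene_id, surface = unambiguous_pairs[int(rng.integers(len(unambiguous_pairs)))]
            tmpl = _GENE_ONLY_TEMPLATES[int(rng.integers(len(_GENE_ONLY_TEMPLATES)))]
            sentences.append(tmpl.format(gene=surface))
            tmpl = _DISEASE_ONLY_TEMPLATES[int(rng.integers(len(_DISEASE_ONLY_TEMPLATES)))]
            disease = disease_list[int(rng.integers(len(disease_list)))]
            sentences.append(tmpl.format(disease=disease.capitalize()))
            truth.decoy_sentences += 2

        abstract = " ".join(sentences)
        articles.append(
            Article(
                pmid=pmid,
                title=f"A study of vascular biology, report {i + 1}.",
                abstract=abstract,
                year=year,
            )
        )

    buffer = io.BytesIO()
    write_corpus_xml(articles, buffer)
    return buffer.getvalue(), truth


# ---------------------------------------------------------------------------
# Annotation (GMT) with one planted over-represented term
# ---------------------------------------------------------------------------

def generate_annotation(
    genes: Iterable[int],
    n_terms: int,
    planted_term_fold: float,
    study_set: Iterable[int],
    seed: int = 0,
) -> tuple[dict[str, tuple[str, frozenset[int]]], SyntheticTruth]:
    """Generate gene sets with one term enriched in the study set.

    Background terms draw members uniformly from the gene universe. The
    planted term (id ``T9999``) is built to overlap the study set at
    ``planted_term_fold`` times the expected uniform overlap, capped by
    feasibility; with fold 1 it is drawn uniformly like any other term, so
    it is statistically indistinguishable from the background terms.
    """
    universe = sorted(set(genes))
    study = sorted(set(study_set))
    if not set(study) <= set(universe):
        raise ValueError("study_set must be a subset of genes")
    if planted_term_fold < 1:
        raise ValueError("planted_term_fold must be >= 1")
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")

    rng = np.random.default_rng(seed)
    n_universe, n_study = len(universe), len(study)
    size_lo = max(2, n_universe // 50)
    size_hi = max(size_lo + 1, n_universe // 12)

    gene_sets: dict[str, tuple[str, frozenset[int]]] = {}
    for t in range(n_terms):
        size = int(rng.integers(size_lo, size_hi + 1))
        members = frozenset(int(g) for g in rng.choice(universe, size=size, replace=False))
        term_id = f"T{t:04d}"
        gene_sets[term_id] = (f"background process {t}", members)

    truth = SyntheticTruth(rng_seed=seed)
    planted_size = size_hi
    expected = planted_size * n_study / n_universe
    if planted_term_fold == 1.0:
        members = frozenset(
            int(g) for g in rng.choice(universe, size=planted_size, replace=False)
        )
        realized_fold = 1.0
    else:
        k_target = round(planted_term_fold * expected)
        k_max = min(planted_size, n_study)
        if k_target > k_max:
            raise ValueError(
                f"infeasible fold {planted_term_fold}; feasible maximum is "
                f"{k_max / expected:.2f}"
            )
        in_study = [int(g) for g in rng.choice(study, size=k_target, replace=False)]
        outside = sorted(set(universe) - set(study))
        out_members = [
            int(g)
            for g in rng.choice(outside, size=planted_size - k_target, replace=False)
        ]
        members = frozenset(in_study + out_members)
        realized_fold = k_target / expected if expected else float("inf")
    gene_sets[PLANTED_TERM_ID] = ("planted disease process", members)
    truth.planted_enriched_terms[PLANTED_TERM_ID] = realized_fold
    return gene_sets, truth


# ---------------------------------------------------------------------------
# Scale-free interaction network with planted module
# ---------------------------------------------------------------------------

def generate_ppi(
    n_nodes: int,
    m_attach: int = 3,
    module_size: int = 0,
    module_density: float = 0.0,
    seed: int = 0,
    module_members: Iterable[int] | None = None,
) -> tuple[list[tuple[int, int]], SyntheticTruth]:
    """Grow a preferential-attachment network, then plant a dense module.

    Growth starts from a clique on nodes ``1..m_attach+1``; every further
    node attaches ``m_attach`` edges to distinct existing nodes chosen with
    probability proportional to current degree, so the edge count is
    exactly ``C(m+1, 2) + (n - m - 1) * m`` before module planting. The
    module then receives each missing within-module edge independently
    with probability ``module_density``.
    """
    if not (1 <= m_attach < n_nodes):
        raise ValueError("need 1 <= m_attach < n_nodes")
    if module_size > n_nodes:
        raise ValueError("module_size must be <= n_nodes")
    if not (0.0 <= module_density <= 1.0):
        raise ValueError("module_density must be in [0, 1]")

    rng = np.random.default_rng(seed)
    edges: set[tuple[int, int]] = set()
    repeated: list[int] = []  # node repeated once per incident edge

    clique = list(range(1, m_attach + 2))
    for i, a in enumerate(clique):
        for b in clique[i + 1:]:
            edges.add((a, b))
            repeated.extend((a, b))

    for new in range(m_attach + 2, n_nodes + 1):
        targets: set[int] = set()
        while len(targets) < m_attach:
            targets.add(repeated[int(rng.integers(len(repeated)))])
        for t in sorted(targets):
            edges.add((min(new, t), max(new, t)))
            repeated.extend((new, t))

    truth = SyntheticTruth(rng_seed=seed)
    if module_size >= 2:
        if module_members is not None:
            module = sorted(set(int(g) for g in module_members))
            if len(module) != module_size or not all(1 <= g <= n_nodes for g in module):
                raise ValueError("module_members must be module_size valid node ids")
        else:
            module = sorted(
                int(g) for g in rng.choice(np.arange(1, n_nodes + 1), size=module_size, replace=False)
            )
        truth.planted_module = set(module)
        for i, a in enumerate(module):
            for b in module[i + 1:]:
                if (a, b) not in edges and rng.random() < module_density:
                    edges.add((a, b))

    return sorted(edges), truth


def write_edge_list_tsv(edges: Iterable[tuple[int, int]], path: str) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("#gene_a\tgene_b\n")
        for a, b in edges:
            handle.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Whole synthetic study
# ---------------------------------------------------------------------------

def generate_study(
    out_dir: str,
    seed: int = 42,
    n_genes: int = 150,
    n_articles: int = 200,
    assoc_density: float = 0.5,
    noise_mode: bool = True,
    n_network_nodes: int = 1000,
    m_attach: int = 3,
    module_size: int = 50,
    module_density: float = 0.3,
    n_terms: int = 50,
    planted_term_fold: float = 4.0,
) -> SyntheticTruth:
    """Generate the complete input bundle for one synthetic study.

    Writes ``corpus.xml``, ``gene_info.tsv``, ``annotation.gmt``,
    ``interactions.tsv`` and ``truth.json`` under ``out_dir``. Gene ids
    1..n_genes belong to the dictionary; the interaction network spans ids
    1..n_network_nodes (a superset). The planted network module is seeded
    from the genes that received planted literature associations, so the
    mined gene list, the enriched term and the dense module all concern the
    same planted disease genes.
    """
    os.makedirs(out_dir, exist_ok=True)
    records, dict_truth = generate_dictionary(
        n_genes, synonyms_per_gene=3, ambiguity_rate=0.1, seed=child_seed(seed, 1)
    )
    write_gene_info_tsv(records, os.path.join(out_dir, "gene_info.tsv"))

    xml, corpus_truth = generate_corpus(
        records,
        n_articles=n_articles,
        assoc_density=assoc_density,
        noise_mode=noise_mode,
        seed=child_seed(seed, 2),
        ambiguous_synonyms=dict_truth.ambiguous_synonyms,
    )
    with open(os.path.join(out_dir, "corpus.xml"), "wb") as handle:
        handle.write(xml)

    planted_genes = sorted(corpus_truth.planted_genes)
    universe = list(range(1, n_network_nodes + 1))
    gene_sets, annot_truth = generate_annotation(
        universe,
        n_terms=n_terms,
        planted_term_fold=planted_term_fold,
        study_set=planted_genes,
        seed=child_seed(seed, 3),
    )
    from .enrichment import write_gmt

    write_gmt(gene_sets, os.path.join(out_dir, "annotation.gmt"))

    rng = np.random.default_rng(child_seed(seed, 4))
    module_from_seeds = planted_genes[: min(len(planted_genes), module_size * 4 // 5)]
    others = sorted(set(universe) - set(module_from_seeds))
    padding = [
        int(g)
        for g in rng.choice(others, size=module_size - len(module_from_seeds), replace=False)
    ]
    module = sorted(module_from_seeds + padding)
    edges, ppi_truth = generate_ppi(
        n_network_nodes,
        m_attach=m_attach,
        module_size=module_size,
        module_density=module_density,
        seed=child_seed(seed, 4),
        module_members=module,
    )
    write_edge_list_tsv(edges, os.path.join(out_dir, "interactions.tsv"))

    truth = SyntheticTruth(
        rng_seed=seed,
        planted_associations=corpus_truth.planted_associations,
        planted_ambiguous=corpus_truth.planted_ambiguous,
        decoy_sentences=corpus_truth.decoy_sentences,
        ambiguous_synonyms=dict_truth.ambiguous_synonyms,
        planted_enriched_terms=annot_truth.planted_enriched_terms,
        planted_module=ppi_truth.planted_module,
        n_articles=n_articles,
    )
    truth.to_json(os.path.join(out_dir, "truth.json"))
    return truth
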