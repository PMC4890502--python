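# Methods

## Pipeline model

`litmine` treats disease-gene discovery as four chained inferences over an
abstract corpus, an annotation resource, and an interaction network.

**Sentence-level co-occurrence.** The unit of evidence is the sentence: a
gene is linked to the disease only when a disease keyword and a gene
mention occur in the *same* sentence of an abstract. This is deliberately
stricter than abstract-level co-occurrence — the assumption is that
sentence co-mention is a high-precision, lower-recall proxy for an asserted
biological relation. The default disease keyword set is
{atherosclerosis, atherogenesis, atheroma, atherosclerotic}; any keyword
set can be configured for other diseases. Titles are not mined by default
(an abstract sentence is the evidence unit); `mine_titles` adds the title
as pseudo-sentence index −1.

**Mention tagging and normalization.** Gene mentions are found by exact
dictionary matching: left-to-right, longest-match-wins, non-overlapping,
and only on token boundaries (a key never matches inside a longer
alphanumeric word). Statistical NER taggers are intentionally out of
scope; the tagger sits behind this simple contract precisely so the whole
pipeline stays deterministic. Matching is case-insensitive **except** for
all-uppercase synonyms of ≤3 characters (`WAS`, `CAT`, `MET`, ...), which
match case-sensitively: case-folding those floods the extractor with
English-word false positives. The policy is a flag
(`case_sensitive_short_upper`, default on). Synonyms shared by several
genes are kept in the dictionary as ambiguous entries; an ambiguous
mention co-occurring with a disease keyword is routed to a review-queue
TSV and never becomes an association. A curated override file
(synonym → gene id) provides reproducible resolution where a human has
adjudicated.

**Sentence segmentation** is rule-based and frozen: a boundary is a run of
`.!?` followed by whitespace and an uppercase letter or digit, suppressed
after a fixed abbreviation list (`i.e.`, `e.g.`, `vs.`, `cf.`, `ca.`,
`etc.`, `fig(s).`, `eq.`, `ref(s).`, `no.`, `al.`, `dr.`, `st.`,
`approx.`) and after single-initial tokens (`J.`). Splitting is idempotent
and reconstructs the input modulo whitespace. Freezing the rules trades
linguistic coverage for bit-reproducibility.

## Enrichment statistics

With background size N (default: every gene appearing in the annotation
file; overridable), K annotated genes, study size n and overlap k, the
over-representation p-value is the hypergeometric upper tail
P(X ≥ k). Fisher's exact test in the enrichment direction is the same
tail and is exposed under its own name because term analysis and pathway
analysis conventionally quote the two tests separately. Both are evaluated
through `scipy.stats.hypergeom.sf` (log-space internally); the test suite
checks them exhaustively against rational-arithmetic enumeration for all
tables with N ≤ 25 at 1e−10.

Multiple testing uses Benjamini–Hochberg step-up
(`statsmodels.stats.multitest`). The default significance cut is adjusted
p < 0.01, with 0.05 selectable — both thresholds circulate in practice for
this kind of analysis, so the choice is configuration, not code. Tests are
one-sided (over-representation) throughout. Gene sets are taken as flat
GMT sets; ontology-hierarchy propagation is out of scope.

**Discreteness caveat.** An exact test on a discrete statistic is
conservative: P(p < α) ≤ α strictly, with the gap set by the sizes of the
hypergeometric atoms near the α-quantile. At desk-scale table sizes the
gap is material — the suite therefore checks null calibration against the
*exact* discrete expectation (summing atoms with tail < 0.05) rather than
against the nominal α, and checks one-sided conservatism. For the same
reason, a fold-1 "planted" term is checked for indistinguishability via
its rank distribution among terms, not via a Kolmogorov–Smirnov test of
p-values against Uniform(0,1), which rejects for any correct discrete
test.

## Network analysis

Interactions load from PSI-MITAB 2.5 (identifiers in columns 1–2, taxa in
columns 10–11, restrictable to e.g. {9606, 10090}) or 2-column TSV. The
graph is simple and undirected: orientations merged, self-loops removed,
degree = number of distinct neighbors. The handshake lemma
(Σ deg = 2|E|) is asserted on every construction. Mapping a gene list
onto the network keeps only nodes that retain at least one within-list
edge; isolated mapped genes are counted and reported separately, so node
counts refer to the connected subnetwork.

**Hub calling.** A hub is a node with degree *strictly* greater than
mean + 2·SD of the degree distribution. Design choices the rule leaves
open: the SD is the sample flavor (n−1) — the common default, and
configurable — and the threshold is used unrounded; any particular integer
cutoff reported for a given snapshot is the realized value of this
statistic, not a universal constant. The multiplier (default 2) is the
`sd_multiplier` parameter.

**Scale-free diagnostic.** The degree histogram c(k) is fit by least
squares on (log k, log c(k)) over nonzero bins; the exponent is the
negated slope and r² is reported. This is the conventional
log-log-regression statement of scale-freeness, not a rigorous
maximum-likelihood power-law test (Clauset-style fitting is a non-goal);
the unbinned tail of counts equal to 1 biases the regression exponent
downward, which is why the fit is read as a diagnostic, with the paired
comparison against a uniform random graph of equal size as the meaningful
contrast.

**Guilt-by-association.** Every non-seed node is scored by
|neighbors ∩ seeds|, ranked descending with ties broken by gene id for
reproducibility; zero-connection candidates are retained. The candidate
universe is all non-seed network nodes (the conservative superset of
first neighbors). A strict cut "more than m connections" is available but
off by default, because any specific m is meaningful only relative to one
network snapshot. Diffusion-based prioritization is out of scope.

## Synthetic data: what it emulates

The generators emit exactly the formats the pipeline reads and serialize
their planted truth as JSON.

- `generate_dictionary(n_genes, synonyms_per_gene=3, ambiguity_rate=0.1)`:
  pronounceable symbols and aliases, each carrying a numeric suffix so
  they can never collide with English filler text; each alias is shared
  with a second gene with probability `ambiguity_rate`, creating the
  ambiguity the normalizer must queue.
- `generate_corpus(records, n_articles, assoc_density=0.5, noise_mode)`:
  2–6 template sentences per article; with probability `assoc_density` a
  sentence pairing an unambiguous synonym with a disease keyword is
  planted (the truth association); with probability 0.1 an ambiguous
  synonym is planted next to a disease keyword (must end in the review
  queue); noise mode adds gene-only and disease-only decoy sentences that
  a correct extractor ignores. Output is valid PubMed-dialect XML.
- `generate_annotation(genes, n_terms, planted_term_fold, study_set)`:
  uniform background terms with sizes between |genes|/50 and |genes|/12,
  plus one planted term overlapping the study set at `fold` × the uniform
  expectation (capped by feasibility, error otherwise); fold 1 degenerates
  to a uniform draw.
- `generate_ppi(n_nodes, m_attach=3, module_size, module_density)`:
  preferential attachment from an initial clique on m+1 nodes, each new
  node attaching m distinct degree-proportional edges — so the
  pre-module edge count is exactly C(m+1,2) + (n−m−1)·m — followed by
  independent within-module edges at rate `module_density`. The clique
  start (rather than the edgeless-core variant found elsewhere) is what
  makes that count identity hold.

A study-level seed fans out to per-generator child seeds by fixed offsets
(`child_seed`), so one integer reproduces a whole study byte for byte.

Default study conditions: 150 dictionary genes, 200 articles at
association density 0.5 with noise on, a 1000-node network (m = 3) with a
50-gene module at density 0.3 seeded from the genes that received planted
associations, and 50 background terms with the planted term at 4-fold.
These sizes keep a full end-to-end run in seconds while leaving every
statistic far from degenerate (≈100 associations over ≈75 genes, a module
recoverable by direct neighbor counts).

**Not emulated:** real biomedical language (morphology, coordination,
anaphora), tagger error modes, inter-database identifier conflicts,
citation structure. Green tests on synthetic data certify the pipeline's
logic — co-occurrence discipline, ambiguity routing, exact statistics,
threshold arithmetic — not free-text recall.

## Numerical and degenerate-input choices

- Tail probabilities are clamped to (0, 1]; k = 0 gives exactly 1.
- BH inputs must lie in (0, 1]; empty input returns empty.
- Degree statistics require ≥2 nodes; the power-law fit requires ≥3
  distinct nonzero degrees; hub calling on all-equal degrees returns the
  empty set (strict inequality).
- Duplicate PMIDs keep the first record; missing abstracts are kept with
  empty text (titles stay searchable) and contribute no sentences; years
  outside [1800, 2100] are treated as unknown and excluded from per-year
  counts.
- Associations are deduplicated on (gene, PMID, sentence index) and
  sorted; all outputs have deterministic order, making reports
  byte-identical across reruns.

## Known limitations

- Dictionary tagging cannot find mentions absent from the dictionary;
  recall on real text is bounded by synonym coverage.
- The log-log regression exponent is a biased power-law estimator (see
  above); it is reported as a diagnostic only.
- Cross-species identifier unification is delegated to an optional
  mapping table; by default identifiers are taken as given.
- Enrichment treats gene sets as flat; GO-hierarchy effects (a gene
  propagating to ancestor terms) are not modeled.
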