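# Methods

## Corpus model and parsing

The unit of analysis is a MEDLINE bibliographic record: a PMID, title,
abstract, a list of MeSH headings, a publication date (DP) and an author
affiliation (AD). Parsing of the tagged plain-text format is done with
Biopython's MEDLINE parser behind a validation pre-pass: a line that is
neither a tagged field (`TAG - value`) nor an indented continuation is
logged and skipped, because the underlying parser would otherwise misread
it as a new field. Records without a PMID are dropped and counted in the
corpus provenance trail, which records before/after counts for every
processing step.

A MeSH heading such as `*Myocardial Infarction/epidemiology` is reduced to
its descriptor; the asterisk — whether on the descriptor or on a qualifier —
marks the entity as a *major topic*. The major-topic flag is part of entity
identity: starred and plain forms of the same descriptor are different
nodes. This convention matters because degree rankings in curated
literature networks routinely show both forms of a term separately.

**Year extraction** takes the first 4-digit token of the DP field lying in
[1900, 2100]. **Country resolution** matches the trailing comma-separated
tokens of the *first* affiliation against a gazetteer of country names and
synonyms (longest trailing run first, then token by token from the end,
tolerating trailing e-mail addresses and postcodes). Multi-affiliation
records therefore resolve to the first affiliation's country — a
deterministic proxy for the corresponding author, which MEDLINE exports do
not identify explicitly. Unresolvable affiliations yield `"Unknown"`.

## Screening codebook

Corpus curation is declarative. The shipped default codebook encodes:

- **inclusion** — a record must carry at least one of four
  cardiovascular-disease descriptors (acute coronary syndrome, myocardial
  infarction, heart diseases, angina pectoris);
- **exclusion** — records carrying social-determinants studies of *other*
  diseases (rheumatic fever, lung diseases, lupus, neoplasms, pneumonia,
  dementia, Parkinson disease) are dropped;
- **risk-factor-only** — records whose substantive content, after setting
  aside demographic check-tags, the CVD terms themselves and stop-listed
  terms, consists entirely of classic risk factors (obesity, smoking,
  physical inactivity, diabetes, stress, metabolic syndrome, hypertension,
  cholesterol) are dropped. A record with an *empty* remainder is retained:
  it passed inclusion and there is no risk-factor-only content to object
  to. The risk-factor terms themselves remain legitimate network nodes —
  only records that discuss *nothing else* are removed;
- **stoplist** — boilerplate descriptors (humans, statistical analysis,
  methods) plus every gazetteer country name are removed before network
  construction.

Each record's fate depends only on its own descriptors, so screening is
idempotent and order-independent, and the filter report's arithmetic
(retrieved = assessed + Σ per-rule drops) is checked on every run.

Every descriptor also maps to at most one category of the WHO Commission
on Social Determinants of Health framework — structural (context or
socioeconomic position) versus intermediary (health system or other
mediators), plus a CVD-outcome class. Edges are classified `structural`
when both endpoints are structural, `intermediary` when both are
intermediary, `mixed` otherwise. Manual, hermeneutic screening of titles
and abstracts (as performed with qualitative-analysis tooling in the
original studies of this kind) is out of scope by design; only MeSH-level
rules are operationalized, and the codebook is a user-editable YAML file.

## Trend matrices

The year × country matrix counts records per cell over a configurable
window (default 1980–2016, the usual search window for this literature).
Rows are the years observed in-window (ascending); columns are countries by
descending total. Records that are undated, out of window, or of unknown
country are excluded from the matrix but tallied, so
`matrix total + unknown + undated + out-of-range = corpus size` always
holds. Yearly counts (which keep unknown-country records) equal the row
marginals plus the unknown-country records of each year. The heatmap
renderer is a convenience; the CSV matrix is the tested contract.

## Networks

Each article contributes a clique over its retained entities; edge weight
is the number of supporting articles and the sorted PMID list is stored on
the edge, giving `Σ_edges w = Σ_articles C(m_a, 2)` exactly, where `m_a` is
the article's retained entity count. No weight threshold is applied by
default (a minimum-weight filter is exposed as an option). Ego subnetworks
are induced subgraphs on a focal term and its neighbors; the largest
connected component is selected with ties broken by the lexicographically
smallest member label. GraphML exports round-trip all node and edge
attributes; edge/node CSV tables carry degree, category, local clustering,
edge class and raw edge betweenness for downstream renderers.

## Topology statistics

Implemented over networkx with fixed conventions:

- **clustering**: `C_i = 0` for degree < 2; the network value averages over
  all nodes by default. The alternative (average over degree ≥ 2 nodes
  only) is a flag, since published tables rarely say which convention was
  used; the default is chosen because it is defined on any graph.
- **characteristic path length**: mean hop distance over unordered
  connected pairs, computed on the largest component (and flagged) when the
  graph is disconnected. Edge weights never enter path computations: path
  lengths in the source tables of this field are hop-based.
- **centralization**: Freeman degree centralization
  `(N·k_max − 2M)/((N−1)(N−2))`; undefined below N = 3. Closed-form
  variants (`mean_neighbors_from`, `density_from`, `centralization_from`)
  accept printed (N, M, k_max) triples so published tables can be checked
  without the underlying corpus. Note: in the published topology table this
  package is designed to reproduce, three subnetwork rows print
  centralization values inconsistent with Freeman's formula given their own
  N, M and maximum degree; only the internally consistent rows are used for
  verification.
- **edge betweenness**: raw (unnormalized) shortest-path betweenness, each
  pair's unit contribution split equally among its shortest paths;
  normalization is optional.
- CSV output rounds fractions to 3 decimals (the precision of the tables it
  mirrors); full precision is kept internally. Reports assert the analytic
  identities `⟨k⟩·N = 2M` and `ρ = 2M/(N(N−1))` to 1e−12 on construction.

All four statistic families are verified in the test suite against
brute-force oracles (adjacency-set counting, numpy Floyd–Warshall, BFS
components, explicit shortest-path enumeration) on hundreds of random
graphs of up to 40 nodes.

## Synthetic corpus generator

The generator emulates the features of a real SDCVD corpus that the
pipeline's behavior depends on, with defaults fixed once as the study
conditions:

- **1,000 records** per corpus (matching the scale of a realistic screening
  yield of ~1,200 retrieved records);
- **thematic blocks**: each record draws its substantive terms from one of
  five blocks mirroring the WHO-framework strata (structural position,
  structural context, health system, other intermediary, risk factors).
  Block sampling induces the high clustering observed in real term
  networks; a degree-preserving rewire destroys it, which is tested;
- **hub terms**: demographic check-tags Female (0.55), Male (0.50), Middle
  Aged (0.45), Risk Factors (0.40), Adult (0.35), Aged (0.30) joined to
  records independently, emulating the hub-dominated degree rankings of
  curated networks;
- **terms per record**: 2 + Poisson(4) block terms (min 2 so nearly every
  record contributes pairs), each term starred major-topic with
  probability 0.2, qualifiers appended with probability 0.3 to exercise
  stripping;
- **eligibility mix**: an inclusion (CVD) term with probability 0.30, an
  exclusion disease with probability 0.10; risk-factor-only records arise
  naturally from the risk block;
- **years 1980–2015** with linearly increasing weights (publication growth)
  and 2% undated records; **countries** drawn from a skewed distribution
  led by the US, UK and Canada, rendered through varied gazetteer synonyms,
  with 5% countryless affiliations.

A single `random.Random(seed)` stream with documented draw order makes the
emitted text byte-identical across runs and platforms. Every draw is logged
in a ground-truth bundle from which eligibility labels, (year, country)
tallies and per-article pair counts are recomputed independently of the
pipeline, enabling exact-recovery tests. `expected_properties` provides
closed-form expectations (hub frequencies, yearly counts, E[C(m,2)] with
the Poisson block-size truncation handled by exact tail enumeration) for
statistical tests.

What the generator does **not** emulate: correlated MeSH assignment beyond
the single-block structure, real MeSH vocabulary breadth (a ~60-term
vocabulary versus tens of thousands), affiliation free-text noise beyond
synonyms/postcodes/e-mails, and any attempt to fit the original corpus's
empirical distributions. Passing the exact-recovery tests therefore
demonstrates correctness of the pipeline's bookkeeping and graph
construction, not that real-corpus statistics would be reproduced; the
published-table checks are analytic identities on printed counts, the only
corpus-independent quantities available.

## Problem sizes

Test-suite simulations use 80–2,000 records per corpus and random graphs of
4–40 nodes (200 graphs in the oracle-equivalence test); the acceptance
script uses 1,000-record corpora and two 400-record pipeline runs for the
determinism check. These sizes give exact (non-statistical) checks wherever
the contract is exact, and ≥4σ slack on binomial checks.

## Known limitations

- Country assignment uses the first affiliation; corresponding-author
  country is not recoverable from standard MEDLINE exports.
- The inclusion/exclusion rules are purely descriptor-level; no
  title/abstract text classification is attempted.
- No bipartite article–term network or article–article projection is
  offered; the term co-occurrence reading is the one consistent with
  term-count node statistics in the tables this package mirrors.
- Weighted path lengths, weighted clustering and node centralities other
  than degree are out of scope.
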