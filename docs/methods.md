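# Methods

## Keyword normalization and lexical matching

A label is tokenized by splitting on every maximal run of non-alphanumeric
characters (space, punctuation, underscore — the separator set is closed by
definition rather than enumerated), each token is case-folded, and the
tokens are sorted by code-point order and concatenated with no separator
into a *keyword*. Code-point order means digit tokens sort before letters
(`"Type 2 diabetes mellitus"` → `2diabetesmellitustype`); the choice is
deterministic and locale-independent. Diacritics are not stripped — only
case is folded — so fixture vocabularies avoid diacritics.

A term's keyword set is the deduplicated union of the keyword of its name
and of every synonym, regardless of synonym scope: scope is a
curation-time concept and does not weight matching. The target ontology is
indexed keyword → {(term id, origin)}; a source term's keywords are looked
up, and each target term hit by at least one keyword yields a candidate
whose tally is the number of *distinct source keywords* that hit it (not
keyword × origin pairs — two synonyms that normalize to the same keyword
count once). Candidates are ranked by tally descending with ties broken by
target CURIE ascending, making the prioritized list total-ordered and
byte-reproducible. Sources with no hit produce nothing: a zero tally is
never materialized. Obsolete terms on either side never participate.

Complexity is O(total keywords) for indexing and O(source keywords ×
bucket size) for lookup; the test suite verifies exact agreement with the
O(|S|·|T|) brute-force double loop over keyword sets on one hundred random
ontology pairs of up to 50×50 terms.

## XREF matching

Cross-references are canonicalized before comparison: whitespace removed,
prefix upper-cased, and OBO-style URIs reduced to their trailing
`PREFIX_LOCAL` component (`.../efo/EFO_0000400` → `EFO:0000400`); the
transformation is idempotent. Prefix synonymy (MeSH/MESH/msh) is resolved
by case-insensitive comparison only — no external prefix registry is
consulted, and every prefix is an eligible mediator, because restricting
to a whitelist would silently hide evidence a curator should judge. A
candidate is emitted when a source xref equals a target id, a target xref
equals the source id, or the two terms share any normalized third-party
xref; the mediating CURIEs are the evidence and their count the tally.
Un-normalizable xrefs are skipped with a logged warning rather than
aborting a whole ontology. Transitive (distance-2) closure through a third
ontology is deliberately out of scope. A pair found by both the lexical
and the xref matcher is reported once per method, never merged silently —
the methods column distinguishes them downstream.

## Curation model

Candidates become mapping records through a two-pass workflow: a curator
*decides* (assigning a scope) and an editor *reviews* (accept / reject /
change), so every accepted record carries both a curator and an editor.
Records proposed from either matcher carry the justification
`LEXICAL_AUTOMATED` (serialized `semapv:LexicalMatching`); hand-entered
pairs carry `MANUAL_CURATION` (`semapv:ManualMappingCuration`). CHANGE is
modelled as reject-plus-new-accepted-record with cross-linking comments,
keeping the audit trail of both passes; the decision journal can be dumped
as TSV. Uniqueness of (subject, object) is enforced over non-rejected
records.

Scope direction follows the synonym-loading convention: the source term is
added as a synonym *of the target term*, so a NARROW synonym means the
subject is narrower than the object and the predicate is
`skos:broadMatch` (and BROAD ↔ `skos:narrowMatch`). The alternative,
subject-perspective convention would swap the two; the convention used
here is declared in one place (`scope_to_predicate`) and derived
everywhere else, so the predicate and scope can never drift apart.

## SSSOM serialization

Mapping sets serialize as a `#`-prefixed YAML metadata block (requiring at
least `mapping_set_id` and a `curie_map`; license defaults to a CC0
notice) followed by a TSV body with the SSSOM-mandated core columns plus
provenance columns (`subject_id, subject_label, predicate_id, object_id,
object_label, mapping_justification, author_id, reviewer_id, comment`).
Rows are sorted by (subject, object) and only accepted records are
exported by default — a published set represents validated mappings. All
prefixes are validated against the curie_map before any output is written.

Reading is the exact inverse on self-produced files. External files parse
forgivingly: unknown columns are preserved in a side map, unknown
justifications become manual curation with the original string kept in the
comment, unknown predicates degrade to `skos:relatedMatch` with the
original predicate kept in the comment (never dropped), and records come
back accepted, with the editor placeholder `imported` when the reviewer
column is empty, since published mappings are curated upstream.

## GWAS parsing and annotation translation

Association tables are read as TSV with GWAS-catalog column spellings
(`SNPS`, `DISEASE/TRAIT`, `MAPPED_TRAIT_URI`, optional background-trait
and p-value columns); trait URI cells may hold several URIs separated by
`|` or `", "`. Rows with no parseable trait URI are skipped, warned about
and counted. When no QTL-name column exists, names are minted as
`GWAS<row>_H`. Trait CURIEs with HP or MONDO prefixes are treated exactly
like EFO subjects — mappings are keyed by full CURIE, so hybrid terms
resolve naturally.

Translation fans each (association, trait, accepted mapping) triple whose
object lies in the requested target prefix into one annotation, filtered
to `skos:exactMatch` by default: propagating an annotation through a
broader/narrower/related mapping changes its meaning, so non-exact
propagation is opt-in. Background traits are translated too but keep a
`background` flag, since their annotation semantics are a consumer
decision. Output is deduplicated on (qtl, target term, source term) — a
trait that is both primary and background for the same QTL keeps the
primary annotation — and sorted, so identical inputs give byte-identical
outputs. Trait terms with no accepted mapping of any kind are collected
into a sorted unmapped-term log, the feed for monitoring newly arriving
trait terms.

## Mapping statistics

Per target prefix the report counts *distinct subject terms* with at least
one accepted mapping into that prefix (a subject mapped to two targets in
one prefix counts once), split into automated (any accepted mapping with
lexical/automated justification — automation found it) versus manual-only.
The automated percentage is rounded half-up to a whole percent; half-up
reproduces the published rates from the published per-ontology counts
(77/469 → 16 %, 82/2052 → 4 %, 347/518 → 67 %), where banker's rounding
would not in general.

## Synthetic fixtures

The generator emulates the structural features matching actually depends
on: a source ontology, a target ontology, and planted term pairs of five
classes — identical labels, word-permuted labels, punctuation/case
variants, synonym-only matches, and xref-only matches (shared MESH id) —
plus per-side distractors. Labels are drawn as distinct 3-word
combinations from a fixed 40-word biomedical vocabulary, so distinct
planted pairs can never collide on a keyword; distractor labels use
per-side synthetic token namespaces (`srcnoise*`/`tgtnoise*`) disjoint
from the word bank, so non-collision holds by construction rather than by
rejection sampling. The intended property, verified in the acceptance
suite, is that the lexical and xref matchers together recover exactly the
planted truth with zero distractor hits.

The association generator mints rs-style SNP ids, draws trait URIs from
the source terms, plants `round(frac_unmapped·n)` rows (half-up, for
determinism) carrying minted URIs from a reserved local-id block (≥
9 000 000) absent from any fixture ontology, and gives
`round(frac_background·n)` rows a background trait. Defaults (20
associations, 20 % unmapped, 25 % background, ~30-term ontologies with 16
planted pairs) keep every end-to-end test and the acceptance script under
a few seconds while exercising all code paths.

What the fixtures do *not* emulate: ontology-scale vocabularies with
near-miss labels, DAG structure, real synonym noise (typos, abbreviations,
British/American spelling), or the skew of real xref coverage. Passing
tests therefore demonstrate algorithmic correctness — tallying, ranking,
round-trips, the partition of traits into translated vs unmapped — not
real-world recall of curator-grade mappings, which depends on the
vocabularies being aligned.

## Published-tally statistics in the acceptance script

The real per-ontology mapping tallies are curation outcomes over specific
external ontology releases and thousands of hours of curator labour; they
cannot be recomputed from code. The acceptance script instead enters the
published per-ontology (automated, manual) subject counts as fixture
input — synthesizing one accepted record per counted subject — and lets
the statistics module compute totals and automated-match percentages from
them, verifying the arithmetic identities (total = automated + manual)
and the printed rates.

## Numerical and degenerate-input choices

Empty labels tokenize to an empty list and produce the empty keyword,
which is never indexed or looked up. Empty ontologies parse, write and
match as empty without error. OBO synonym lines with a missing or unknown
scope token default to RELATED, which keeps the scope domain closed.
Duplicate synonyms (same text and scope) and duplicate xrefs are
deduplicated on ingestion. Term stanzas missing an `id` raise a parse
error naming the line; duplicate term ids raise an error. Encoding is
fixed to UTF-8 throughout. CLI exit codes: 0 success, 1 data error, 2
usage error; outputs are never overwritten without `--force`; all
randomness flows through a single `--seed` (default 0).

## Known limitations

* No fuzzy, stemmed or embedding-based matching: a singular/plural or
  spelling variant that changes a token changes the keyword.
* Xref matching is direct (distance 1); no closure through intermediary
  ontologies.
* The curation layer models one curator and one editor per record, not
  multi-editor consensus.
* SSSOM support covers the TSV serialization only (no JSON/RDF) and
  merging is concatenate-plus-dedupe on (subject, object).
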