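# efomap

Cross-ontology term mapping and GWAS trait annotation translation.

## The problem

Human GWAS catalog associations are annotated with Experimental Factor
Ontology (EFO) terms, but model-organism databases curate phenotype and
disease data with different vocabularies — a disease ontology (DO/RDO), the
Human Phenotype Ontology (HPO), the Mammalian Phenotype ontology (MP), the
Clinical Measurement Ontology (CMO), the Vertebrate Trait ontology (VT).
Making human SNP–trait associations interoperable with curated
model-organism data therefore requires term-to-term mappings between EFO
and each target ontology, and a way to push trait annotations through
those mappings.

`efomap` implements that pipeline for curation teams and bioinformaticians:

1. **Lexical matching.** Every term name and synonym is reduced to a
   *keyword*: case-folded, split on separators (any non-alphanumeric run),
   tokens alphabetized and concatenated. `"Blood pressure, systolic"` and
   `"systolic blood pressure"` both become `bloodpressuresystolic`. Source
   keywords are looked up in an index of target keywords and matches are
   tallied per target term (no match = 0, one match = 1, ...), producing a
   prioritized candidate list for curators.
2. **XREF matching.** Database cross-references are canonicalized to
   CURIEs and compared: a source xref equal to a target id, a target xref
   equal to the source id, or a shared third-party xref (e.g. both terms
   carry `MESH:D006973`) each propose a candidate.
3. **Two-pass curation.** A curator assigns each accepted pair a synonym
   scope — exact, broad, narrow or related — and an editor accepts,
   rejects or changes it. Scope maps to a skos predicate
   (EXACT→`skos:exactMatch`, NARROW→`skos:broadMatch`,
   BROAD→`skos:narrowMatch`, RELATED→`skos:relatedMatch`).
4. **SSSOM exchange.** Mapping sets serialize to SSSOM TSV (metadata block
   + mandated columns) and externally curated SSSOM files can be imported.
5. **Annotation translation.** GWAS associations are minted as QTL-like
   records and their EFO trait annotations are translated into each target
   ontology through the accepted mappings (exact matches only, by
   default), with unmapped trait terms logged for curators.

A synthetic fixture generator plants ground-truth matches of every class
(identical labels, word permutations, punctuation variants, synonym-only,
xref-only) among non-colliding distractors, so the whole pipeline is
testable without downloading any ontology.

## Worked example

```sh
efomap fixtures --out-dir fxt --seed 5
efomap match --source fxt/source.obo --target fxt/target.obo --out fxt/cand.tsv
efomap export-sssom --candidates fxt/cand.tsv --out fxt/maps.sssom.tsv
efomap translate --gwas fxt/associations.tsv --sssom fxt/maps.sssom.tsv \
    --target-prefix TGT --out fxt/ann.tsv --unmapped-out fxt/unmapped.txt
efomap report --sssom fxt/maps.sssom.tsv
```

prints

```
fixtures: 26 source terms, 26 target terms, 16 planted pairs, 20 associations -> fxt
match: 26 source terms x 26 target terms -> 16 candidates (LEXICAL=14, XREF=2)
export-sssom: 16 candidates in -> 16 mappings out
translate: 20 associations in -> 15 TGT annotations out
translate: 8 unmapped trait terms logged
prefix  total_mapped    automated       manual  pct_automated
TGT     16      16      0       100
```

The 16 candidates are exactly the 16 planted pairs (14 lexical, 2 via a
shared MESH xref); no distractor is ever matched. Translation annotates
every association whose trait has an accepted exact mapping into the `TGT`
ontology and logs the traits that have none — both the minted "novel"
trait URIs planted by the generator and the distractor source terms the
matcher correctly left unmapped.

The same machinery is a library:

```python
from efomap import FixtureSpec, gen_ontology_pair, match_ontology

source, target, truth = gen_ontology_pair(FixtureSpec(n_exact_label=5, seed=7))
for c in match_ontology(source, target):
    print(c.source_id, c.target_id, c.tally, c.evidence)
```

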