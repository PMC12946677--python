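"""Keyword normalization and lexical matching, including the brute-force oracle."""

import random
import string

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from efomap import (
    FixtureSpec,
    MatchMethod,
    Ontology,
    OntologyTerm,
    SynonymScope,
    build_index,
    gen_ontology_pair,
    make_keyword,
    match_ontology,
    match_term,
    term_keywords,
    tokenize,
)


# ---------------------------------------------------------------- tokenize

@pytest.mark.parametrize(
    "label,tokens",
    [
        ("Type 2 diabetes mellitus", ["type", "2", "diabetes", "mellitus"]),
        ("", []),
        ("blood pressure, systolic", ["blood", "pressure", "systolic"]),
        ("HDL-cholesterol  (serum)", ["hdl", "cholesterol", "serum"]),
        ("a_b", ["a", "b"]),
        ("...", []),
    ],
)
def test_tokenize(label, tokens):
    assert tokenize(label) == tokens


@pytest.mark.parametrize(
    "label,keyword",
    [
        ("Type 2 diabetes mellitus", "2diabetesmellitustype"),
        ("systolic blood pressure", "bloodpressuresystolic"),
        ("Blood pressure, systolic", "bloodpressuresystolic"),
        ("", ""),
    ],
)
def test_make_keyword(label, keyword):
    assert make_keyword(label) == keyword


# ------------------------------------------------------ keyword invariance

_words = st.lists(
    st.text(alphabet=string.ascii_letters + string.digits, min_size=1, max_size=8),
    min_size=1,
    max_size=6,
)
_separators = st.sampled_from([" ", ", ", "-", "_", "  ", " / ", "; "])


@settings(max_examples=200, derandomize=True)
@given(words=_words, sep=_separators, shuffle_seed=st.integers(0, 999))
def test_keyword_invariant_under_permutation_and_separator_choice(
    words, sep, shuffle_seed
):
    baseline = make_keyword(" ".join(words))
    permuted = list(words)
    random.Random(shuffle_seed).shuffle(permuted)
    assert make_keyword(sep.join(permuted)) == baseline
    assert make_keyword(sep.join(permuted).upper()) == baseline


# ----------------------------------------------------------- term_keywords

def test_term_keywords_label_plus_synonyms():
    term = OntologyTerm(id="EFO:1", label="heart attack")
    term.add_synonym("myocardial infarction", SynonymScope.EXACT)
    assert term_keywords(term) == {"attackheart", "infarctionmyocardial"}


def test_term_keywords_dedupes_reordered_synonym():
    term = OntologyTerm(id="EFO:1", label="blood pressure")
    term.add_synonym("pressure blood", SynonymScope.RELATED)
    assert term_keywords(term) == {"bloodpressure"}


def test_term_keywords_no_synonyms():
    term = OntologyTerm(id="EFO:1", label="anemia")
    assert term_keywords(term) == {"anemia"}


# ------------------------------------------------------------------- index

def _ontology(*terms: OntologyTerm, prefix="TGT") -> Ontology:
    return Ontology(prefix=prefix, terms={t.id: t for t in terms})


def test_build_index_empty():
    assert build_index(_ontology()).entries == {}


def test_shared_synonym_indexes_both_terms():
    a = OntologyTerm(id="TGT:1", label="cardiac hypertrophy")
    a.add_synonym("pressure overload", SynonymScope.RELATED)
    b = OntologyTerm(id="TGT:2", label="aortic banding")
    b.add_synonym("pressure overload", SynonymScope.RELATED)
    index = build_index(_ontology(a, b))
    assert {tid for tid, _ in index.lookup("overloadpressure")} == {"TGT:1", "TGT:2"}


def test_obsolete_terms_contribute_no_entries():
    dead = OntologyTerm(id="TGT:1", label="anemia", obsolete=True)
    assert build_index(_ontology(dead)).entries == {}


# -------------------------------------------------------------- match_term

def test_match_term_tallies_distinct_keywords():
    source = OntologyTerm(id="EFO:1", label="heart attack")
    source.add_synonym("myocardial infarction", SynonymScope.EXACT)
    target = OntologyTerm(id="TGT:1", label="myocardial infarction")
    target.add_synonym("heart attack", SynonymScope.EXACT)
    (candidate,) = match_term(source, build_index(_ontology(target)))
    assert candidate.tally == 2
    assert candidate.method is MatchMethod.LEXICAL
    assert set(candidate.evidence) == {"attackheart", "infarctionmyocardial"}


def test_match_term_no_hits_yields_empty_list():
    source = OntologyTerm(id="EFO:1", label="unrelated")
    target = OntologyTerm(id="TGT:1", label="anemia")
    assert match_term(source, build_index(_ontology(target))) == []


def test_ranking_by_tally_then_target_id():
    source = OntologyTerm(id="EFO:1", label="blood pressure")
    source.add_synonym("arterial pressure", SynonymScope.EXACT)
    two_hits = OntologyTerm(id="TGT:9", label="blood pressure")
    two_hits.add_synonym("arterial pressure", SynonymScope.EXACT)
    one_hit = OntologyTerm(id="TGT:1", label="arterial pressure")
    candidates = match_term(source, build_index(_ontology(two_hits, one_hit)))
    assert [(c.target_id, c.tally) for c in candidates] == [("TGT:9", 2), ("TGT:1", 1)]


def test_tie_break_is_target_id_ascending():
    source = OntologyTerm(id="EFO:1", label="anemia")
    t1 = OntologyTerm(id="TGT:2", label="anemia")
    t2 = OntologyTerm(id="TGT:1", label="anemia")
    candidates = match_term(source, build_index(_ontology(t1, t2)))
    assert [c.target_id for c in candidates] == ["TGT:1", "TGT:2"]


def test_adding_a_synonym_never_decreases_a_tally():
    source = OntologyTerm(id="EFO:1", label="blood pressure")
    target = OntologyTerm(id="TGT:1", label="blood pressure")
    target.add_synonym("arterial pressure", SynonymScope.EXACT)
    index = build_index(_ontology(target))
    before = {c.target_id: c.tally for c in match_term(source, index)}
    source.add_synonym("arterial pressure", SynonymScope.RELATED)
    after = {c.target_id: c.tally for c in match_term(source, index)}
    for target_id, tally in before.items():
        assert after[target_id] >= tally


# ---------------------------------------------------- brute-force oracle

def brute_force_match(source: Ontology, target: Ontology):
    """O(|S|x|T|) reference: compare keyword sets pairwise."""
    out = {}
    for s in source.active_terms():
        for t in target.active_terms():
            shared = term_keywords(s) & term_keywords(t)
            if shared:
                out[(s.id, t.id)] = len(shared)
    return out


def _random_ontology(rng: random.Random, prefix: str, n_terms: int) -> Ontology:
    vocab = ["blood", "pressure", "serum", "glucose", "mass", "body", "heart",
             "rate", "bone", "density", "urine", "level", "trait", "index"]
    onto = Ontology(prefix=prefix)
    for i in range(n_terms):
        words = rng.sample(vocab, rng.randint(1, 3))
        term = OntologyTerm(id=f"{prefix}:{i:04d}", label=" ".join(words))
        for _ in range(rng.randint(0, 2)):
            syn_words = rng.sample(vocab, rng.randint(1, 3))
            term.add_synonym(" ".join(syn_words), rng.choice(list(SynonymScope)))
        if rng.random() < 0.1:
            term.obsolete = True
        onto.add(term)
    return onto


@pytest.mark.parametrize("seed", range(20))
def test_match_ontology_equals_brute_force(seed):
    rng = random.Random(seed)
    source = _random_ontology(rng, "EFO", rng.randint(1, 50))
    target = _random_ontology(rng, "TGT", rng.randint(1, 50))
    expected = brute_force_match(source, target)
    got = {(c.source_id, c.target_id): c.tally for c in match_ontology(source, target)}
    assert got == expected


def test_match_ontology_is_deterministic(fixture_pair):
    source, target, _ = fixture_pair
    assert match_ontology(source, target) == match_ontology(source, target)


def test_disjoint_vocabulary_gives_empty_table():
    source = _ontology(OntologyTerm(id="EFO:1", label="alpha beta"), prefix="EFO")
    target = _ontology(OntologyTerm(id="TGT:1", label="gamma delta"))
    assert match_ontology(source, target) == []


def test_planted_exact_matches_all_recovered():
    spec = FixtureSpec(n_exact_label=6, seed=11)
    source, target, truth = gen_ontology_pair(spec)
    candidates = match_ontology(source, target)
    assert {(c.source_id, c.target_id, "LEXICAL") for c in candidates} == truth
    assert all(c.tally >= 1 for c in candidates)
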