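import io

import pytest

from efomap import (
    FixtureSpec,
    MappingSet,
    MatchCandidate,
    MatchMethod,
    MappingStore,
    ReviewAction,
    SynonymScope,
    default_metadata,
    gen_ontology_pair,
)


@pytest.fixture
def mixed_spec() -> FixtureSpec:
    """A fixture spec covering every planted match class plus distractors."""
    return FixtureSpec(
        n_exact_label=5,
        n_permuted=3,
        n_punct=3,
        n_synonym_only=3,
        n_xref_only=2,
        n_distractor_source=10,
        n_distractor_target=10,
        seed=7,
    )


@pytest.fixture
def fixture_pair(mixed_spec):
    return gen_ontology_pair(mixed_spec)


def make_candidate(
    source_id: str,
    target_id: str,
    method: MatchMethod | None = MatchMethod.LEXICAL,
    evidence: tuple[str, ...] = ("kw",),
    source_label: str = "",
    target_label: str = "",
) -> MatchCandidate:
    return MatchCandidate(
        source_id=source_id,
        target_id=target_id,
        tally=len(set(evidence)) if method else 0,
        method=method,
        evidence=evidence,
        source_label=source_label,
        target_label=target_label,
    )


def accepted_mapping_set(
    pairs,
    scope: SynonymScope = SynonymScope.EXACT,
    method: MatchMethod | None = MatchMethod.LEXICAL,
) -> MappingSet:
    """Build an all-accepted mapping set from (subject, object[, label]) pairs."""
    store = MappingStore()
    prefixes: set[str] = {"EFO", "TGT"}
    for pair in pairs:
        subject, obj = pair[0], pair[1]
        label = pair[2] if len(pair) > 2 else ""
        record = store.decide(
            make_candidate(subject, obj, method=method, target_label=label),
            scope,
            "curator",
        )
        store.review(record, ReviewAction.ACCEPT, "editor")
        prefixes.add(subject.partition(":")[0])
        prefixes.add(obj.partition(":")[0])
    curie_map = {p: f"https://example.org/{p}_" for p in prefixes}
    return MappingSet(
        metadata=default_metadata("https://example.org/sets/test", curie_map),
        records=store.records,
    )


def roundtrip_text(write, *args):
    buf = io.StringIO()
    write(*args, buf)
    return buf.getvalue()
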