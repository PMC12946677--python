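"""Keyword-based lexical term matching between two ontologies.

The matcher reduces every term name and synonym to a *keyword*: the text is
case-folded, split on every maximal run of non-alphanumeric characters, the
tokens are sorted (code-point order, so digits sort before letters) and
concatenated with no separator.  Two labels that differ only in word order,
case or punctuation therefore collapse to the same keyword —
``"Blood pressure, systolic"`` and ``"systolic blood pressure"`` both become
``"bloodpressuresystolic"``.

A target ontology is indexed keyword → terms; each source term's keyword set
(name plus all synonyms, any scope) is then looked up and hits are tallied
per target term: one distinct matching keyword counts one.  The result is a
prioritized candidate list for curator review, ranked by tally descending
with ties broken by target id so output is fully deterministic.

Obsolete terms never participate on either side.  Diacritics are not
stripped; case is folded via ``str.casefold``.
"""

from __future__ import annotations

import csv
import enum
import re
from dataclasses import dataclass, field
from typing import IO, Iterable

from .ontology_io import Ontology, OntologyTerm

__all__ = [
    "MatchMethod",
    "MatchCandidate",
    "KeywordIndex",
    "tokenize",
    "make_keyword",
    "term_keywords",
    "build_index",
    "match_term",
    "match_ontology",
    "write_candidates",
    "read_candidates",
]

# maximal runs of Unicode alphanumerics; underscore is a separator too
_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


class MatchMethod(str, enum.Enum):
    LEXICAL = "LEXICAL"
    XREF = "XREF"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Origin(str, enum.Enum):
    NAME = "NAME"
    SYNONYM = "SYNONYM"


@dataclass(frozen=True)
class MatchCandidate:
    """A proposed source→target pairing with its supporting evidence.

    ``tally`` counts distinct evidence entries: matching keywords for
    lexical candidates, mediating CURIEs for xref candidates.  A candidate
    with ``method=None`` represents a hand-entered pair (manual curation).
    """

    source_id: str
    target_id: str
    tally: int
    method: MatchMethod | None
    evidence: tuple[str, ...]
    source_label: str = ""
    target_label: str = ""

    def __post_init__(self) -> None:
        if self.method is not None:
            if self.tally < 1:
                raise ValueError("emitted candidates must have tally >= 1")
            if self.tally != len(set(self.evidence)):
                raise ValueError("tally must equal the number of distinct evidence entries")


@dataclass
class KeywordIndex:
    """Inverted index keyword → {(term id, origin)} over a target ontology."""

    prefix: str = ""
    entries: dict[str, set[tuple[str, Origin]]] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)

    def add(self, keyword: str, term_id: str, origin: Origin) -> None:
        self.entries.setdefault(keyword, set()).add((term_id, origin))

    def lookup(self, keyword: str) -> set[tuple[str, Origin]]:
        return self.entries.get(keyword, set())


def tokenize(label: str) -> list[str]:
    """Split a label into lowercase tokens, discarding all separators.

    Splits on every maximal run of non-alphanumeric characters (spaces,
    punctuation, underscores); tokens are case-folded; original order is
    preserved.  An empty label yields an empty list.
    """
    return _TOKEN_RE.findall(label.casefold())


def make_keyword(label: str) -> str:
    """Collapse a label to its order-insensitive keyword.

    Tokens are sorted by code-point order and concatenated without a
    separator, so any permutation of the same words — under any separators
    and casing — produces the same keyword.
    """
    return "".join(sorted(tokenize(label)))


def term_keywords(term: OntologyTerm) -> set[str]:
    """All distinct keywords of a term: its label plus every synonym.

    Synonym scope does not matter at this stage (scope is a curation-time
    concept); empty keywords are excluded.
    """
    keywords = {make_keyword(term.label)}
    keywords.update(make_keyword(s.text) for s in term.synonyms)
    keywords.discard("")
    return keywords


def build_index(target: Ontology) -> KeywordIndex:
    """Index every non-obsolete target term under all of its keywords."""
    index = KeywordIndex(prefix=target.prefix)
    for term in target.active_terms():
        index.labels[term.id] = term.label
        kw = make_keyword(term.label)
        if kw:
            index.add(kw, term.id, Origin.NAME)
        for syn in term.synonyms:
            kw = make_keyword(syn.text)
            if kw:
                index.add(kw, term.id, Origin.SYNONYM)
    return index


def match_term(source: OntologyTerm, index: KeywordIndex) -> list[MatchCandidate]:
    """Match one source term against an indexed target ontology.

    Each target term hit by at least one source keyword yields a candidate
    whose tally is the number of distinct source keywords that hit it and
    whose evidence lists those keywords.  Candidates are ranked by tally
    descending, ties broken by target id ascending; a source with no hits
    yields an empty list (a zero tally is never materialized).
    """
    hits: dict[str, set[str]] = {}
    for keyword in sorted(term_keywords(source)):
        for target_id, _origin in index.lookup(keyword):
            hits.setdefault(target_id, set()).add(keyword)
    candidates = [
        MatchCandidate(
            source_id=source.id,
            target_id=target_id,
            tally=len(keywords),
            method=MatchMethod.LEXICAL,
            evidence=tuple(sorted(keywords)),
            source_label=source.label,
            target_label=index.labels.get(target_id, ""),
        )
        for target_id, keywords in hits.items()
    ]
    candidates.sort(key=lambda c: (-c.tally, c.target_id))
    return candidates


def match_ontology(source: Ontology, target: Ontology) -> list[MatchCandidate]:
    """Match every non-obsolete source term against a target ontology.

    Returns the concatenation of :func:`match_term` results, grouped by
    source id (ascending) with each group internally ranked — a prioritized
    list of matches for curators to check.
    """
    index = build_index(target)
    out: list[MatchCandidate] = []
    for source_id in sorted(source.terms):
        term = source.terms[source_id]
        if term.obsolete:
            continue
        out.extend(match_term(term, index))
    return out


_CANDIDATE_COLUMNS = [
    "source_id",
    "source_label",
    "target_id",
    "target_label",
    "tally",
    "method",
    "evidence",
]


def write_candidates(candidates: Iterable[MatchCandidate], stream: IO[str]) -> int:
    """Write a candidate table as TSV; evidence is pipe-delimited. Returns row count."""
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(_CANDIDATE_COLUMNS)
    n = 0
    for c in candidates:
        writer.writerow(
            [
                c.source_id,
                c.source_label,
                c.target_id,
                c.target_label,
                c.tally,
                c.method.value if c.method else "",
                "|".join(c.evidence),
            ]
        )
        n += 1
    return n


def read_candidates(stream: IO[str]) -> list[MatchCandidate]:
    """Read a candidate TSV written by :func:`write_candidates`."""
    reader = csv.DictReader(stream, delimiter="\t")
    out = []
    for row in reader:
        method = MatchMethod(row["method"]) if row.get("method") else None
        evidence = tuple(row["evidence"].split("|")) if row.get("evidence") else ()
        out.append(
            MatchCandidate(
                source_id=row["source_id"],
                target_id=row["target_id"],
                tally=int(row["tally"]),
                method=method,
                evidence=evidence,
                source_label=row.get("source_label", ""),
                target_label=row.get("target_label", ""),
            )
        )
    return out
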