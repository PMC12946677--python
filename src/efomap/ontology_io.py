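"""Read and write ontologies in OBO flat-file format.

The OBO 1.2/1.4 flat-file format is a line-oriented tag-value format.  Only
``[Term]`` stanzas are modelled here, and within them only the tags that
matter for lexical and cross-reference matching: ``id``, ``name``,
``synonym``, ``xref`` and ``is_obsolete``.  Everything else (typedefs,
relationships, subsets, definitions) is ignored without error — term
hierarchy plays no role in keyword or XREF matching.

Synonyms carry a scope (EXACT / BROAD / NARROW / RELATED) taken from the
token that follows the quoted synonym text; any other or missing token maps
to RELATED, which keeps the scope domain closed.  Obsolete terms are parsed
and retained but flagged, so downstream matchers can skip them.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

__all__ = [
    "SynonymScope",
    "Synonym",
    "OntologyTerm",
    "Ontology",
    "OboParseError",
    "parse_obo",
    "write_obo",
    "load_obo",
    "dump_obo",
]


class SynonymScope(str, enum.Enum):
    """Closeness class of a synonym (OBO synonym scopes)."""

    EXACT = "EXACT"
    BROAD = "BROAD"
    NARROW = "NARROW"
    RELATED = "RELATED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class Synonym:
    """A scoped synonym attached to an ontology term."""

    text: str
    scope: SynonymScope = SynonymScope.RELATED

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError("synonym text must be non-empty")


@dataclass
class OntologyTerm:
    """One ontology term: CURIE id, label, scoped synonyms, xrefs."""

    id: str
    label: str = ""
    synonyms: list[Synonym] = field(default_factory=list)
    xrefs: list[str] = field(default_factory=list)
    obsolete: bool = False

    def add_synonym(self, text: str, scope: SynonymScope = SynonymScope.RELATED) -> None:
        """Append a synonym, silently deduplicating identical (text, scope) pairs."""
        syn = Synonym(text, scope)
        if syn not in self.synonyms:
            self.synonyms.append(syn)

    def add_xref(self, xref: str) -> None:
        xref = xref.strip()
        if xref and xref not in self.xrefs:
            self.xrefs.append(xref)


@dataclass
class Ontology:
    """A collection of terms keyed by id, with a default CURIE prefix."""

    prefix: str = ""
    terms: dict[str, OntologyTerm] = field(default_factory=dict)

    def add(self, term: OntologyTerm) -> None:
        if term.id in self.terms:
            raise OboParseError(f"duplicate term id {term.id!r}")
        self.terms[term.id] = term

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self) -> Iterator[OntologyTerm]:
        return iter(self.terms.values())

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __getitem__(self, term_id: str) -> OntologyTerm:
        return self.terms[term_id]

    def get(self, term_id: str) -> OntologyTerm | None:
        return self.terms.get(term_id)

    def active_terms(self) -> Iterator[OntologyTerm]:
        """Iterate over non-obsolete terms."""
        return (t for t in self.terms.values() if not t.obsolete)


class OboParseError(ValueError):
    """Raised on a malformed OBO document (missing id, duplicate id, ...)."""


# A synonym tag value: quoted text, optional scope token, anything after.
_SYNONYM_RE = re.compile(r'^"((?:[^"\\]|\\.)*)"\s*(\S*)')
_SCOPE_TOKENS = {s.value for s in SynonymScope}


def _unescape(text: str) -> str:
    return re.sub(r"\\(.)", r"\1", text)


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def _split_tag(line: str) -> tuple[str, str]:
    tag, _, value = line.partition(":")
    # strip trailing OBO comments only on unquoted values; the tags we keep
    # quoted (synonym) are handled by their own regex before this matters
    return tag.strip(), value.strip()


def _parse_synonym(value: str, lineno: int) -> Synonym:
    m = _SYNONYM_RE.match(value)
    if not m or not _unescape(m.group(1)).strip():
        raise OboParseError(f"line {lineno}: malformed synonym value {value!r}")
    text = _unescape(m.group(1))
    token = m.group(2)
    scope = SynonymScope(token) if token in _SCOPE_TOKENS else SynonymScope.RELATED
    return Synonym(text, scope)


def _parse_xref(value: str) -> str:
    # xref values may carry a trailing quoted description: DOID:1234 "label"
    return value.split('"')[0].split("{")[0].strip()


def parse_obo(stream: IO[str] | str | Iterable[str], prefix: str = "") -> Ontology:
    """Parse an OBO flat file into an :class:`Ontology`.

    Parameters
    ----------
    stream:
        A file-like object, a string holding the whole document, or any
        iterable of lines.
    prefix:
        Default CURIE prefix recorded on the ontology; when empty it is
        inferred from the first term id.

    Raises
    ------
    OboParseError
        If a ``[Term]`` stanza lacks an ``id`` tag (the error names the
        stanza's starting line) or if two stanzas share an id.
    """
    if isinstance(stream, str):
        lines: Iterable[str] = stream.splitlines()
    else:
        lines = stream

    ontology = Ontology(prefix=prefix)
    in_term = False
    in_header = True
    stanza_start = 0
    current: OntologyTerm | None = None

    def flush() -> None:
        nonlocal current
        if not in_term:
            return
        if current is None:
            raise OboParseError(
                f"line {stanza_start}: [Term] stanza has no id tag"
            )
        ontology.add(current)
        current = None

    lineno = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        stripped = line.strip()
        if not stripped or stripped.startswith("!"):
            continue
        if stripped.startswith("["):
            flush()
            in_term = stripped == "[Term]"
            in_header = False
            stanza_start = lineno
            continue
        if not in_term:
            if in_header:
                tag, value = _split_tag(stripped)
                if tag == "default-namespace" and not ontology.prefix:
                    ontology.prefix = value
            continue  # header tags and non-Term stanza contents
        tag, value = _split_tag(stripped)
        if tag == "id":
            if current is not None:
                raise OboParseError(f"line {lineno}: duplicate id tag in stanza")
            current = OntologyTerm(id=value)
        elif current is None:
            # OBO requires id first; tolerate nothing before it except noise
            raise OboParseError(
                f"line {stanza_start}: [Term] stanza has no leading id tag "
                f"(found {tag!r} at line {lineno})"
            )
        elif tag == "name":
            current.label = value
        elif tag == "synonym":
            syn = _parse_synonym(value, lineno)
            if syn not in current.synonyms:
                current.synonyms.append(syn)
        elif tag == "xref":
            current.add_xref(_parse_xref(value))
        elif tag == "is_obsolete":
            current.obsolete = value.lower().startswith("true")
        # all other tags ignored

    flush()

    if not ontology.prefix and ontology.terms:
        first = next(iter(ontology.terms))
        ontology.prefix = first.partition(":")[0]
    return ontology


def write_obo(ontology: Ontology, stream: IO[str]) -> None:
    """Serialize an ontology as an OBO flat file.

    Stanzas are emitted in ascending term-id order so output is canonical;
    ``parse_obo(write_obo(x))`` reproduces ``x`` field for field.
    """
    stream.write("format-version: 1.2\n")
    if ontology.prefix:
        stream.write(f"default-namespace: {ontology.prefix}\n")
    for term_id in sorted(ontology.terms):
        term = ontology.terms[term_id]
        stream.write("\n[Term]\n")
        stream.write(f"id: {term.id}\n")
        if term.label:
            stream.write(f"name: {term.label}\n")
        for syn in term.synonyms:
            stream.write(f'synonym: "{_escape(syn.text)}" {syn.scope.value} []\n')
        for xref in term.xrefs:
            stream.write(f"xref: {xref}\n")
        if term.obsolete:
            stream.write("is_obsolete: true\n")


def load_obo(path: str, prefix: str = "") -> Ontology:
    """Read an OBO file from disk (UTF-8)."""
    with open(path, encoding="utf-8") as fh:
        return parse_obo(fh, prefix=prefix)


def dump_obo(ontology: Ontology, path: str) -> None:
    """Write an ontology to disk as OBO (UTF-8)."""
    with open(path, "w", encoding="utf-8") as fh:
        write_obo(ontology, fh)
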