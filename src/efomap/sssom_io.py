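"""SSSOM TSV serialization of mapping sets.

SSSOM (Simple Standard for Sharing Ontological Mappings) exchanges term
mappings as a TSV body preceded by a ``#``-prefixed YAML metadata block.
This module writes the SSSOM-mandated core columns plus provenance columns::

    subject_id  subject_label  predicate_id  object_id  object_label
    mapping_justification  author_id  reviewer_id  comment

Internal justifications serialize to the semapv vocabulary
(``semapv:LexicalMatching`` / ``semapv:ManualMappingCuration``).  Only
accepted records are exported by default: a published mapping set
represents validated mappings.

Reading is the exact inverse on files this module wrote.  For external
files (e.g. the Monarch MP–HP mapping set) the reader is forgiving:
unknown columns are preserved in a side map, unknown justifications become
MANUAL_CURATION with the original string kept in the comment, unknown
predicates degrade to ``skos:relatedMatch`` (original kept in the comment),
and records are marked ACCEPTED since published mappings are curated.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import IO

import yaml

from .mapping_store import (
    Justification,
    MappingRecord,
    Status,
    predicate_to_scope,
    scope_to_predicate,
)
from .ontology_io import SynonymScope

__all__ = [
    "MappingSet",
    "SssomError",
    "write_sssom",
    "read_sssom",
    "load_sssom",
    "dump_sssom",
    "default_metadata",
]


class SssomError(ValueError):
    """Raised on invalid mapping sets or malformed SSSOM input."""


#: CURIE prefixes every mapping set needs for its predicate/justification columns.
BUILTIN_CURIE_MAP = {
    "skos": "http://www.w3.org/2004/02/skos/core#",
    "semapv": "https://w3id.org/semapv/vocab/",
}

_JUSTIFICATION_TO_SEMAPV = {
    Justification.LEXICAL_AUTOMATED: "semapv:LexicalMatching",
    Justification.MANUAL_CURATION: "semapv:ManualMappingCuration",
}
_SEMAPV_TO_JUSTIFICATION = {v: k for k, v in _JUSTIFICATION_TO_SEMAPV.items()}

COLUMNS = [
    "subject_id",
    "subject_label",
    "predicate_id",
    "object_id",
    "object_label",
    "mapping_justification",
    "author_id",
    "reviewer_id",
    "comment",
]
MANDATORY_COLUMNS = ["subject_id", "predicate_id", "object_id"]


def default_metadata(mapping_set_id: str, curie_map: dict[str, str] | None = None) -> dict:
    """Minimal metadata: id, a CC0 license placeholder, and the builtin prefixes."""
    merged = dict(BUILTIN_CURIE_MAP)
    if curie_map:
        merged.update(curie_map)
    return {
        "mapping_set_id": mapping_set_id,
        "license": "https://creativecommons.org/publicdomain/zero/1.0/",
        "curie_map": merged,
    }


@dataclass
class MappingSet:
    """A set of mapping records plus SSSOM metadata (id, license, curie_map)."""

    metadata: dict = field(default_factory=dict)
    records: list[MappingRecord] = field(default_factory=list)
    extra_columns: dict[str, list[str]] = field(default_factory=dict)

    @property
    def curie_map(self) -> dict[str, str]:
        return self.metadata.get("curie_map", {})

    def accepted(self) -> list[MappingRecord]:
        return [r for r in self.records if r.status is Status.ACCEPTED]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MappingSet):
            return NotImplemented
        def keyed(records: list[MappingRecord]):
            return sorted(records, key=lambda r: (r.subject_id, r.object_id))
        return (
            self.metadata == other.metadata
            and keyed(self.records) == keyed(other.records)
            and self.extra_columns == other.extra_columns
        )


def _check_prefixes(records: list[MappingRecord], curie_map: dict[str, str]) -> None:
    known = {p.casefold() for p in curie_map}
    for record in records:
        for curie in (
            record.subject_id,
            record.object_id,
            record.predicate,
            _JUSTIFICATION_TO_SEMAPV[record.justification],
        ):
            prefix = curie.partition(":")[0]
            if prefix.casefold() not in known:
                raise SssomError(
                    f"prefix {prefix!r} (from {curie!r}) missing from curie_map"
                )


def write_sssom(
    mapping_set: MappingSet,
    stream: IO[str],
    statuses: frozenset[Status] = frozenset({Status.ACCEPTED}),
) -> int:
    """Serialize a mapping set as SSSOM TSV; returns the number of rows written.

    Records are filtered to ``statuses`` (accepted only by default) and
    sorted by (subject_id, object_id).  All prefixes are validated against
    the set's curie_map before any output is produced.
    """
    exported = [r for r in mapping_set.records if r.status in statuses]
    _check_prefixes(exported, mapping_set.curie_map)

    buffer = io.StringIO()
    meta = dict(mapping_set.metadata)
    curie_map = meta.pop("curie_map", {})
    header = {**meta, "curie_map": dict(sorted(curie_map.items()))}
    for line in yaml.safe_dump(header, sort_keys=False, default_flow_style=False).splitlines():
        buffer.write(f"# {line}\n")

    writer = csv.writer(buffer, delimiter="\t", lineterminator="\n")
    writer.writerow(COLUMNS)
    for r in sorted(exported, key=lambda r: (r.subject_id, r.object_id)):
        writer.writerow(
            [
                r.subject_id,
                r.subject_label,
                r.predicate,
                r.object_id,
                r.object_label,
                _JUSTIFICATION_TO_SEMAPV[r.justification],
                r.curator,
                r.editor,
                r.comment,
            ]
        )
    stream.write(buffer.getvalue())
    return len(exported)


def read_sssom(stream: IO[str]) -> MappingSet:
    """Parse an SSSOM TSV file into a :class:`MappingSet`.

    Inverse of :func:`write_sssom` on self-produced files; degrades
    gracefully on external files (see module docstring).  All records come
    back ACCEPTED; a record whose reviewer column is empty gets the editor
    placeholder ``imported`` so the accepted-implies-reviewed invariant
    holds for externally curated sets.
    """
    meta_lines: list[str] = []
    body_lines: list[str] = []
    for raw in stream:
        line = raw.rstrip("\n")
        if line.startswith("#"):
            meta_lines.append(line.lstrip("#").removeprefix(" "))
        elif line.strip():
            body_lines.append(line)

    metadata = yaml.safe_load("\n".join(meta_lines)) if meta_lines else {}
    if not isinstance(metadata, dict):
        metadata = {}

    reader = csv.DictReader(body_lines, delimiter="\t")
    columns = reader.fieldnames or []
    missing = [c for c in MANDATORY_COLUMNS if c not in columns]
    if missing:
        raise SssomError(f"missing mandatory SSSOM columns: {', '.join(missing)}")
    unknown_columns = [c for c in columns if c not in COLUMNS]

    records: list[MappingRecord] = []
    extra_columns: dict[str, list[str]] = {c: [] for c in unknown_columns}
    for row in reader:
        comment = row.get("comment", "") or ""
        predicate = row["predicate_id"]
        scope = predicate_to_scope(predicate, default=None)  # type: ignore[arg-type]
        if scope is None:
            scope = SynonymScope.RELATED
            note = f"original predicate: {predicate}"
            comment = f"{comment}; {note}" if comment else note
        raw_justification = row.get("mapping_justification", "") or ""
        justification = _SEMAPV_TO_JUSTIFICATION.get(raw_justification)
        if justification is None:
            justification = Justification.MANUAL_CURATION
            if raw_justification:
                note = f"original justification: {raw_justification}"
                comment = f"{comment}; {note}" if comment else note
        records.append(
            MappingRecord(
                subject_id=row["subject_id"],
                object_id=row["object_id"],
                scope=scope,
                justification=justification,
                status=Status.ACCEPTED,
                subject_label=row.get("subject_label", "") or "",
                object_label=row.get("object_label", "") or "",
                curator=row.get("author_id", "") or "",
                editor=row.get("reviewer_id", "") or "imported",
                comment=comment,
            )
        )
        for column in unknown_columns:
            extra_columns[column].append(row.get(column, "") or "")

    return MappingSet(metadata=metadata, records=records, extra_columns=extra_columns)


def load_sssom(path: str) -> MappingSet:
    with open(path, encoding="utf-8") as fh:
        return read_sssom(fh)


def dump_sssom(mapping_set: MappingSet, path: str, **kwargs) -> int:
    with open(path, "w", encoding="utf-8") as fh:
        return write_sssom(mapping_set, fh, **kwargs)
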