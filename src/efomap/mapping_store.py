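"""Curated mapping records and the two-pass curation workflow.

Automated candidates (and hand-entered pairs) are turned into mapping
records by a first curator, who assigns a synonym scope — exact, broad,
narrow or related — describing how close the match is.  A second
curator/editor then accepts, rejects or changes each proposed record; only
accepted records are exported or used for annotation translation.

Scope is recorded from the *target* term's perspective, because the source
term is added as a synonym of the target term: a NARROW synonym means the
subject (source term) is narrower than the object, hence the predicate is
``skos:broadMatch`` (the subject has a broader object).  The full
scope→predicate convention:

==========  ==================
scope       predicate
==========  ==================
EXACT       skos:exactMatch
NARROW      skos:broadMatch
BROAD       skos:narrowMatch
RELATED     skos:relatedMatch
==========  ==================

A CHANGE decision is modelled as reject-plus-new-record so both curator
passes stay auditable; every event is journaled and replayable as TSV.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass
from typing import IO, Iterator

from .lexical_matcher import MatchCandidate
from .ontology_io import SynonymScope

__all__ = [
    "Justification",
    "Status",
    "ReviewAction",
    "MappingRecord",
    "MappingStore",
    "scope_to_predicate",
    "predicate_to_scope",
]

logger = logging.getLogger(__name__)


class Justification(str, enum.Enum):
    LEXICAL_AUTOMATED = "LEXICAL_AUTOMATED"
    MANUAL_CURATION = "MANUAL_CURATION"


class Status(str, enum.Enum):
    PROPOSED = "PROPOSED"
    ACCEPTED = "ACCEPTED"
    REJECTED = "REJECTED"


class ReviewAction(str, enum.Enum):
    ACCEPT = "ACCEPT"
    REJECT = "REJECT"
    CHANGE = "CHANGE"


_SCOPE_TO_PREDICATE = {
    SynonymScope.EXACT: "skos:exactMatch",
    SynonymScope.NARROW: "skos:broadMatch",
    SynonymScope.BROAD: "skos:narrowMatch",
    SynonymScope.RELATED: "skos:relatedMatch",
}
_PREDICATE_TO_SCOPE = {v: k for k, v in _SCOPE_TO_PREDICATE.items()}


def scope_to_predicate(scope: SynonymScope) -> str:
    """Map a synonym scope to its skos match predicate (target-perspective)."""
    try:
        return _SCOPE_TO_PREDICATE[SynonymScope(scope)]
    except (KeyError, ValueError) as exc:
        raise ValueError(f"invalid synonym scope {scope!r}") from exc


def predicate_to_scope(predicate: str, default: SynonymScope = SynonymScope.RELATED) -> SynonymScope:
    """Inverse of :func:`scope_to_predicate`; unknown predicates map to ``default``."""
    return _PREDICATE_TO_SCOPE.get(predicate, default)


@dataclass
class MappingRecord:
    """One curated (or proposed) cross-ontology mapping, SSSOM-row shaped."""

    subject_id: str
    object_id: str
    scope: SynonymScope
    justification: Justification
    status: Status = Status.PROPOSED
    subject_label: str = ""
    object_label: str = ""
    curator: str = ""
    editor: str = ""
    comment: str = ""

    def __post_init__(self) -> None:
        self.scope = SynonymScope(self.scope)
        self.justification = Justification(self.justification)
        self.status = Status(self.status)
        if self.status is Status.ACCEPTED and not self.editor:
            raise ValueError(
                f"accepted mapping {self.subject_id}->{self.object_id} lacks an editor"
            )

    @property
    def predicate(self) -> str:
        """The skos predicate; always derived from scope so the two never drift."""
        return scope_to_predicate(self.scope)

    @property
    def key(self) -> tuple[str, str]:
        return (self.subject_id, self.object_id)


class MappingStore:
    """Holds mapping records and enforces the curation workflow.

    Uniqueness of (subject, object) is enforced over non-rejected records;
    a rejected pair may be re-proposed (that is how CHANGE works).
    """

    def __init__(self) -> None:
        self._records: list[MappingRecord] = []
        self._journal: list[tuple[str, ...]] = []

    def __iter__(self) -> Iterator[MappingRecord]:
        return iter(self._records)

    def __len__(self) -> int:
        return len(self._records)

    @property
    def records(self) -> list[MappingRecord]:
        return list(self._records)

    def accepted(self) -> list[MappingRecord]:
        return [r for r in self._records if r.status is Status.ACCEPTED]

    def _live_keys(self) -> set[tuple[str, str]]:
        return {r.key for r in self._records if r.status is not Status.REJECTED}

    def _log(self, event: str, record: MappingRecord, actor: str) -> None:
        self._journal.append(
            (
                event,
                record.subject_id,
                record.object_id,
                record.scope.value,
                record.status.value,
                actor,
            )
        )

    def decide(
        self,
        candidate: MatchCandidate,
        scope: SynonymScope,
        curator: str,
    ) -> MappingRecord:
        """First-pass curator decision: turn a candidate into a PROPOSED record.

        Candidates produced by either matcher (lexical or xref) are
        justified as LEXICAL_AUTOMATED; a hand-constructed candidate with
        ``method=None`` is MANUAL_CURATION.
        """
        justification = (
            Justification.LEXICAL_AUTOMATED
            if candidate.method is not None
            else Justification.MANUAL_CURATION
        )
        record = MappingRecord(
            subject_id=candidate.source_id,
            object_id=candidate.target_id,
            scope=SynonymScope(scope),
            justification=justification,
            status=Status.PROPOSED,
            subject_label=candidate.source_label,
            object_label=candidate.target_label,
            curator=curator,
        )
        if record.key in self._live_keys():
            raise ValueError(
                f"mapping {record.subject_id} -> {record.object_id} already exists"
            )
        self._records.append(record)
        self._log("DECIDE", record, curator)
        return record

    def review(
        self,
        record: MappingRecord,
        action: ReviewAction,
        editor: str,
        new_object_id: str | None = None,
        new_scope: SynonymScope | None = None,
        new_object_label: str = "",
    ) -> MappingRecord:
        """Second-pass editor review: accept, reject, or change a proposal.

        CHANGE rejects the original (with a comment linking its replacement)
        and creates a replacement record that is immediately accepted, so
        both curator passes leave a trace.  Returns the record that carries
        the final decision (the replacement, for CHANGE).
        """
        action = ReviewAction(action)
        if record.status is not Status.PROPOSED:
            raise ValueError(
                f"cannot review a {record.status.value} record "
                f"({record.subject_id} -> {record.object_id})"
            )
        if editor == record.curator:
            logger.info(
                "editor %s is also the curator of %s -> %s",
                editor, record.subject_id, record.object_id,
            )
        if action is ReviewAction.ACCEPT:
            record.editor = editor
            record.status = Status.ACCEPTED
            self._log("ACCEPT", record, editor)
            return record
        if action is ReviewAction.REJECT:
            record.editor = editor
            record.status = Status.REJECTED
            self._log("REJECT", record, editor)
            return record
        # CHANGE
        if new_object_id is None and new_scope is None:
            raise ValueError("CHANGE requires new_object_id and/or new_scope")
        replacement = MappingRecord(
            subject_id=record.subject_id,
            object_id=new_object_id or record.object_id,
            scope=SynonymScope(new_scope) if new_scope is not None else record.scope,
            justification=Justification.MANUAL_CURATION,
            status=Status.PROPOSED,
            subject_label=record.subject_label,
            object_label=new_object_label or (
                record.object_label if new_object_id is None else ""
            ),
            curator=record.curator,
            comment=f"replaces {record.subject_id} -> {record.object_id}",
        )
        record.editor = editor
        record.status = Status.REJECTED
        record.comment = (
            f"changed by {editor}; replaced by "
            f"{replacement.subject_id} -> {replacement.object_id}"
        )
        self._log("CHANGE", record, editor)
        if replacement.key in self._live_keys():
            raise ValueError(
                f"replacement mapping {replacement.subject_id} -> "
                f"{replacement.object_id} already exists"
            )
        self._records.append(replacement)
        replacement.editor = editor
        replacement.status = Status.ACCEPTED
        self._log("ACCEPT", replacement, editor)
        return replacement

    # -- journal persistence ------------------------------------------------

    _JOURNAL_COLUMNS = ("event", "subject_id", "object_id", "scope", "status", "actor")

    def write_journal(self, stream: IO[str]) -> int:
        """Persist the decision journal as TSV, one row per decide/review event."""
        writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
        writer.writerow(self._JOURNAL_COLUMNS)
        writer.writerows(self._journal)
        return len(self._journal)
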