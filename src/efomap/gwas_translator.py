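"""Translate GWAS trait annotations into mapped target-ontology annotations.

GWAS-catalog association tables attach one or more EFO trait terms (plus
optional background traits) to each SNP.  Each association is minted into a
QTL-like record, and its trait annotations are propagated through an
accepted cross-ontology mapping set: for every trait term with an accepted
mapping into the requested target ontology, a translated annotation is
emitted carrying full provenance — the original trait CURIE and the
mapping predicate it travelled through.

Only ``skos:exactMatch`` mappings are propagated by default; broader,
narrower and related mappings can be enabled explicitly.  Background
traits are translated too but keep a ``background`` flag.  Trait terms
with no accepted mapping into *any* target ontology are collected by
:func:`detect_unmapped_terms`, the feed for a new-term curation log.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import pandas as pd

from .sssom_io import MappingSet
from .xref_matcher import CurieError, normalize_curie

__all__ = [
    "GwasAssociation",
    "TranslatedAnnotation",
    "parse_gwas_associations",
    "translate_annotations",
    "detect_unmapped_terms",
    "write_annotations",
    "EXACT_ONLY",
]

logger = logging.getLogger(__name__)

#: Default predicate filter for translation — conservative exact-only.
EXACT_ONLY = frozenset({"skos:exactMatch"})

#: All predicates the mapping layer can produce.
ALL_PREDICATES = frozenset(
    {"skos:exactMatch", "skos:broadMatch", "skos:narrowMatch", "skos:relatedMatch"}
)

# accepted header spellings, checked in order
_SNP_COLUMNS = ("SNPS", "SNP_ID_CURRENT", "snp_id")
_TRAIT_LABEL_COLUMNS = ("DISEASE/TRAIT", "DISEASE_TRAIT", "MAPPED_TRAIT", "trait_label")
_TRAIT_URI_COLUMNS = ("MAPPED_TRAIT_URI", "trait_uri")
_BACKGROUND_COLUMNS = (
    "BACKGROUND TRAIT URIS",
    "MAPPED_BACKGROUND_TRAIT_URI",
    "BACKGROUND_TRAIT_URI",
    "background_trait_uri",
)
_PVALUE_COLUMNS = ("P-VALUE", "P_VALUE", "PVALUE_MLOG", "p_value")
_QTL_COLUMNS = ("QTL_NAME", "qtl_name")


@dataclass
class GwasAssociation:
    """One SNP↔trait association row, minted as a QTL-like record."""

    snp_id: str
    qtl_name: str
    trait_label: str
    trait_ids: list[str]
    background_trait_ids: list[str] = field(default_factory=list)
    p_value: str = ""


@dataclass(frozen=True)
class TranslatedAnnotation:
    """A target-ontology annotation on a QTL with provenance to its trait term."""

    qtl_name: str
    term_id: str
    term_label: str
    source_term_id: str
    mapping_predicate: str
    background: bool = False


def _pick_column(columns: Sequence[str], options: Sequence[str]) -> str | None:
    for option in options:
        if option in columns:
            return option
    return None


def _split_uris(cell: str) -> list[str]:
    out = []
    for chunk in str(cell).replace(", ", "|").split("|"):
        chunk = chunk.strip()
        if chunk and chunk.lower() not in ("nan", "na"):
            out.append(chunk)
    return out


def _normalize_uris(raw_uris: Iterable[str], context: str) -> list[str]:
    out = []
    for raw in raw_uris:
        try:
            curie = normalize_curie(raw)
        except CurieError:
            logger.warning("skipping un-parseable trait URI %r on %s", raw, context)
            continue
        if curie not in out:
            out.append(curie)
    return out


def parse_gwas_associations(source: IO[str] | str) -> list[GwasAssociation]:
    """Parse a GWAS-catalog-style association TSV.

    Required columns (GWAS catalog spellings accepted): a SNP identifier,
    a trait label, and pipe- or comma-delimited mapped-trait URIs.
    Optional: background-trait URIs, p-value, and an explicit QTL name;
    when the latter is absent names are minted as ``GWAS<row>_H``.

    Rows whose trait-URI cell yields no parseable CURIE are skipped with a
    logged warning and counted in the log.
    """
    frame = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    columns = list(frame.columns)

    snp_col = _pick_column(columns, _SNP_COLUMNS)
    label_col = _pick_column(columns, _TRAIT_LABEL_COLUMNS)
    uri_col = _pick_column(columns, _TRAIT_URI_COLUMNS)
    missing = [
        name
        for name, col in (
            ("SNP id (e.g. SNPS)", snp_col),
            ("trait label (e.g. DISEASE/TRAIT)", label_col),
            ("mapped-trait URI (e.g. MAPPED_TRAIT_URI)", uri_col),
        )
        if col is None
    ]
    if missing:
        raise ValueError(f"GWAS table missing required columns: {'; '.join(missing)}")

    background_col = _pick_column(columns, _BACKGROUND_COLUMNS)
    pvalue_col = _pick_column(columns, _PVALUE_COLUMNS)
    qtl_col = _pick_column(columns, _QTL_COLUMNS)

    associations: list[GwasAssociation] = []
    skipped = 0
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        record = dict(zip(columns, row))
        snp_id = record[snp_col].strip()
        trait_ids = _normalize_uris(_split_uris(record[uri_col]), snp_id or f"row {i}")
        if not trait_ids:
            logger.warning("row %d (%s): no parseable trait URI; skipped", i, snp_id)
            skipped += 1
            continue
        background_ids = (
            _normalize_uris(_split_uris(record[background_col]), snp_id)
            if background_col
            else []
        )
        qtl_name = record[qtl_col].strip() if qtl_col else ""
        associations.append(
            GwasAssociation(
                snp_id=snp_id,
                qtl_name=qtl_name or f"GWAS{i}_H",
                trait_label=record[label_col].strip(),
                trait_ids=trait_ids,
                background_trait_ids=background_ids,
                p_value=record[pvalue_col].strip() if pvalue_col else "",
            )
        )
    if skipped:
        logger.warning("skipped %d association rows with no parseable trait URI", skipped)
    return associations


def translate_annotations(
    associations: Iterable[GwasAssociation],
    accepted_mappings: MappingSet,
    target_prefix: str,
    allowed_predicates: frozenset[str] | set[str] = EXACT_ONLY,
) -> list[TranslatedAnnotation]:
    """Propagate trait annotations into one target ontology through mappings.

    For every association, every trait id (background traits flagged) and
    every ACCEPTED mapping whose subject is that trait, whose object is in
    ``target_prefix`` and whose predicate is allowed, one annotation is
    emitted.  Output is deduplicated on (qtl_name, term_id, source_term_id)
    — a trait appearing both as primary and background keeps its primary
    annotation — and sorted for determinism.
    """
    target_prefix = target_prefix.upper().rstrip(":")
    by_subject: dict[str, list] = {}
    for record in accepted_mappings.accepted():
        if record.predicate not in allowed_predicates:
            continue
        if record.object_id.partition(":")[0].upper() != target_prefix:
            continue
        by_subject.setdefault(record.subject_id, []).append(record)

    out: dict[tuple[str, str, str], TranslatedAnnotation] = {}
    for assoc in associations:
        trait_stream = [(tid, False) for tid in assoc.trait_ids] + [
            (tid, True) for tid in assoc.background_trait_ids
        ]
        for trait_id, background in trait_stream:
            for record in by_subject.get(trait_id, ()):
                key = (assoc.qtl_name, record.object_id, trait_id)
                if key not in out:
                    out[key] = TranslatedAnnotation(
                        qtl_name=assoc.qtl_name,
                        term_id=record.object_id,
                        term_label=record.object_label,
                        source_term_id=trait_id,
                        mapping_predicate=record.predicate,
                        background=background,
                    )
    return sorted(
        out.values(), key=lambda a: (a.qtl_name, a.term_id, a.source_term_id)
    )


def detect_unmapped_terms(
    associations: Iterable[GwasAssociation],
    accepted_mappings: MappingSet,
) -> list[str]:
    """Trait ids (primary or background) with no accepted mapping at all.

    The returned sorted list feeds the new-term log that curators monitor
    as fresh GWAS records arrive.
    """
    mapped_subjects = {r.subject_id for r in accepted_mappings.accepted()}
    seen: set[str] = set()
    for assoc in associations:
        seen.update(assoc.trait_ids)
        seen.update(assoc.background_trait_ids)
    return sorted(seen - mapped_subjects)


_ANNOTATION_COLUMNS = [
    "qtl_name",
    "term_id",
    "term_label",
    "source_term_id",
    "predicate",
    "background",
]


def write_annotations(annotations: Iterable[TranslatedAnnotation], stream: IO[str]) -> int:
    """Write translated annotations as TSV; returns the row count."""
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(_ANNOTATION_COLUMNS)
    n = 0
    for a in annotations:
        writer.writerow(
            [
                a.qtl_name,
                a.term_id,
                a.term_label,
                a.source_term_id,
                a.mapping_predicate,
                str(a.background).lower(),
            ]
        )
        n += 1
    return n
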