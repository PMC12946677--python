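"""Mapping statistics by target ontology and provenance.

For each target ontology prefix the report counts distinct *subject* terms
(not mapping rows) with at least one accepted mapping into that prefix,
split by how the mapping was found: automated (lexical/xref matching,
curator-confirmed) versus manual curation only.  A subject with both an
automated and a manual accepted mapping into a prefix counts as automated —
automation found it.  Percentages are rounded half-up to whole percent.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import IO

from .mapping_store import Justification
from .sssom_io import MappingSet

__all__ = ["PrefixStats", "mapping_stats", "render_stats_table"]


@dataclass(frozen=True)
class PrefixStats:
    """Mapping tallies for one target ontology prefix."""

    total_mapped: int
    automated: int
    manual: int

    @property
    def pct_automated(self) -> int:
        if self.total_mapped == 0:
            return 0
        return _round_half_up(100 * self.automated / self.total_mapped)


def _round_half_up(x: float) -> int:
    from math import floor

    return int(floor(x + 0.5))


def mapping_stats(mapping_set: MappingSet) -> dict[str, PrefixStats]:
    """Per-prefix counts of distinct mapped subjects, by provenance.

    Only ACCEPTED records count.  The grouping key is the object term's
    CURIE prefix; the counting unit is the distinct subject id.
    """
    automated: dict[str, set[str]] = {}
    subjects: dict[str, set[str]] = {}
    for record in mapping_set.accepted():
        prefix = record.object_id.partition(":")[0]
        subjects.setdefault(prefix, set()).add(record.subject_id)
        if record.justification is Justification.LEXICAL_AUTOMATED:
            automated.setdefault(prefix, set()).add(record.subject_id)
    stats = {}
    for prefix, subject_ids in subjects.items():
        n_auto = len(automated.get(prefix, set()))
        stats[prefix] = PrefixStats(
            total_mapped=len(subject_ids),
            automated=n_auto,
            manual=len(subject_ids) - n_auto,
        )
    return stats


def render_stats_table(stats: dict[str, PrefixStats], stream: IO[str]) -> int:
    """Write the stats as TSV, one row per prefix (sorted); returns row count."""
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(["prefix", "total_mapped", "automated", "manual", "pct_automated"])
    for prefix in sorted(stats):
        s = stats[prefix]
        writer.writerow([prefix, s.total_mapped, s.automated, s.manual, s.pct_automated])
    return len(stats)
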