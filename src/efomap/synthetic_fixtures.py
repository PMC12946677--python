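"""Synthetic ontology pairs and GWAS tables with planted ground truth.

Real inputs to the mapping pipeline — an EFO subset, target ontologies,
GWAS-catalog association dumps — are large downloads whose content shifts
between releases.  This module generates small stand-ins with *planted*
matches, so every stage of the pipeline can be exercised against an exact
known answer:

* ``exact-label`` pairs share an identical label;
* ``permuted`` pairs' labels are word permutations of each other;
* ``punct`` pairs differ only in case and punctuation;
* ``synonym-only`` pairs match only through a synonym on the target;
* ``xref-only`` pairs share a third-party MESH xref and nothing lexical;
* distractor terms on either side match nothing.

Every planted pair is built from a distinct word combination out of a
fixed biomedical word bank, so planted keywords never collide with one
another; distractor labels use per-side synthetic token namespaces
(``srcnoise*`` / ``tgtnoise*``) disjoint from the word bank, so distractor
keywords cannot collide with anything by construction.  Generation is
fully deterministic given the seed.
"""

from __future__ import annotations

import csv
import io
import itertools
import random
from dataclasses import dataclass

from .ontology_io import Ontology, OntologyTerm, Synonym, SynonymScope

__all__ = ["FixtureSpec", "gen_ontology_pair", "gen_associations", "write_truth"]

#: Fixed biomedical-flavoured word bank; no external resources.
WORD_BANK = (
    "systolic diastolic blood pressure diabetes mellitus heart attack "
    "myocardial infarction renal failure serum glucose level body weight "
    "cholesterol insulin kidney disease artery coronary hypertension bone "
    "density mass index urine protein cardiac output stroke volume liver "
    "enzyme thyroid hormone plasma triglyceride asthma obesity anemia"
).split()

SOURCE_PREFIX = "EFO"
TARGET_PREFIX = "TGT"

#: local-id block for minted trait CURIEs guaranteed absent from fixtures
UNMAPPED_LOCAL_BASE = 9_000_000


@dataclass(frozen=True)
class FixtureSpec:
    """Counts of planted match classes and distractors for one fixture pair."""

    n_exact_label: int = 0
    n_permuted: int = 0
    n_punct: int = 0
    n_synonym_only: int = 0
    n_xref_only: int = 0
    n_distractor_source: int = 0
    n_distractor_target: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_exact_label", "n_permuted", "n_punct", "n_synonym_only",
            "n_xref_only", "n_distractor_source", "n_distractor_target",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_dict(cls, data: dict) -> "FixtureSpec":
        return cls(**data)


def _round_half_up(x: float) -> int:
    from math import floor

    return int(floor(x + 0.5))


def _draw_combos(rng: random.Random, n: int, size: int = 3) -> list[tuple[str, ...]]:
    """``n`` distinct word combinations; distinct multisets ⇒ distinct keywords."""
    combos = list(itertools.combinations(WORD_BANK, size))
    if n > len(combos):
        raise ValueError(f"word bank supports at most {len(combos)} planted pairs")
    rng.shuffle(combos)
    return combos[:n]


def _phrase(rng: random.Random, words: tuple[str, ...]) -> str:
    order = list(words)
    rng.shuffle(order)
    return " ".join(order)


def _permute_differently(rng: random.Random, label: str) -> str:
    words = label.split()
    other = " ".join(reversed(words))
    if other == label:  # cannot happen for >=2 distinct words, but stay safe
        rng.shuffle(words)
        other = " ".join(words)
    return other


def _punct_variant(label: str) -> str:
    words = label.split()
    head, tail = words[-1], words[:-1]
    return f"{head.capitalize()} {' '.join(tail)},".replace(" ,", ",") if tail else head.upper()


def gen_ontology_pair(
    spec: FixtureSpec,
) -> tuple[Ontology, Ontology, set[tuple[str, str, str]]]:
    """Build a (source, target, truth) triple per the fixture spec.

    ``truth`` holds every planted pair as (source id, target id, method)
    with method ``LEXICAL`` or ``XREF``.  Deterministic given ``spec.seed``.
    """
    rng = random.Random(spec.seed)
    source = Ontology(prefix=SOURCE_PREFIX)
    target = Ontology(prefix=TARGET_PREFIX)
    truth: set[tuple[str, str, str]] = set()

    n_combos = (
        spec.n_exact_label
        + spec.n_permuted
        + spec.n_punct
        + 2 * spec.n_synonym_only
        + 2 * spec.n_xref_only
    )
    combos = iter(_draw_combos(rng, n_combos))
    counter = itertools.count(1)

    def mint(ontology: Ontology, prefix: str, label: str) -> OntologyTerm:
        term = OntologyTerm(id=f"{prefix}:{next(counter):07d}", label=label)
        ontology.add(term)
        return term

    for _ in range(spec.n_exact_label):
        label = _phrase(rng, next(combos))
        s = mint(source, SOURCE_PREFIX, label)
        t = mint(target, TARGET_PREFIX, label)
        truth.add((s.id, t.id, "LEXICAL"))

    for _ in range(spec.n_permuted):
        label = _phrase(rng, next(combos))
        s = mint(source, SOURCE_PREFIX, label)
        t = mint(target, TARGET_PREFIX, _permute_differently(rng, label))
        truth.add((s.id, t.id, "LEXICAL"))

    for _ in range(spec.n_punct):
        label = _phrase(rng, next(combos))
        s = mint(source, SOURCE_PREFIX, label)
        t = mint(target, TARGET_PREFIX, _punct_variant(label))
        truth.add((s.id, t.id, "LEXICAL"))

    for _ in range(spec.n_synonym_only):
        source_label = _phrase(rng, next(combos))
        target_label = _phrase(rng, next(combos))
        s = mint(source, SOURCE_PREFIX, source_label)
        t = mint(target, TARGET_PREFIX, target_label)
        t.synonyms.append(
            Synonym(_permute_differently(rng, source_label), SynonymScope.EXACT)
        )
        truth.add((s.id, t.id, "LEXICAL"))

    for i in range(spec.n_xref_only):
        s = mint(source, SOURCE_PREFIX, _phrase(rng, next(combos)))
        t = mint(target, TARGET_PREFIX, _phrase(rng, next(combos)))
        mesh = f"MESH:D{100000 + i:06d}"
        s.add_xref(mesh)
        t.add_xref(mesh)
        truth.add((s.id, t.id, "XREF"))

    for j in range(spec.n_distractor_source):
        term = mint(source, SOURCE_PREFIX, f"srcnoise{j}a srcnoise{j}b")
        term.add_xref(f"MESH:D{500000 + j:06d}")

    for j in range(spec.n_distractor_target):
        term = mint(target, TARGET_PREFIX, f"tgtnoise{j}a tgtnoise{j}b")
        term.add_xref(f"MESH:D{700000 + j:06d}")

    return source, target, truth


def write_truth(truth: set[tuple[str, str, str]], stream) -> int:
    """Write the planted-truth table as TSV, sorted; returns row count."""
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(["source_id", "target_id", "expected_method"])
    rows = sorted(truth)
    writer.writerows(rows)
    return len(rows)


def _curie_to_uri(curie: str) -> str:
    prefix, _, local = curie.partition(":")
    if prefix.upper() == "EFO":
        return f"http://www.ebi.ac.uk/efo/EFO_{local}"
    return f"http://purl.obolibrary.org/obo/{prefix.upper()}_{local}"


def gen_associations(
    source: Ontology,
    n_assoc: int,
    frac_unmapped: float = 0.0,
    frac_background: float = 0.0,
    seed: int = 0,
) -> str:
    """Generate a GWAS-catalog-style association TSV as text.

    ``round(frac_unmapped * n_assoc)`` rows (half-up) carry a minted trait
    URI absent from the source ontology — these are the planted "new"
    terms an unmapped-term scan must find; ``round(frac_background *
    n_assoc)`` rows carry a background trait drawn from the source.
    Byte-identical output for a fixed seed.
    """
    if n_assoc > 0 and len(source) == 0:
        raise ValueError("cannot generate associations from an empty source ontology")
    rng = random.Random(seed)
    term_ids = sorted(t.id for t in source.active_terms())

    n_unmapped = _round_half_up(frac_unmapped * n_assoc)
    n_background = _round_half_up(frac_background * n_assoc)
    unmapped_rows = set(rng.sample(range(n_assoc), n_unmapped)) if n_assoc else set()
    background_rows = set(rng.sample(range(n_assoc), n_background)) if n_assoc else set()

    buffer = io.StringIO()
    writer = csv.writer(buffer, delimiter="\t", lineterminator="\n")
    writer.writerow(
        ["SNPS", "DISEASE/TRAIT", "MAPPED_TRAIT_URI", "BACKGROUND TRAIT URIS", "P-VALUE"]
    )
    prefix = source.prefix or SOURCE_PREFIX
    for i in range(n_assoc):
        if i in unmapped_rows:
            trait_id = f"{prefix}:{UNMAPPED_LOCAL_BASE + i:07d}"
            trait_label = f"novel trait {i}"
        else:
            trait_id = rng.choice(term_ids)
            trait_label = source[trait_id].label
        background = (
            _curie_to_uri(rng.choice(term_ids)) if i in background_rows else ""
        )
        snp = f"rs{rng.randint(1_000_000, 99_999_999)}"
        p_value = f"{rng.randint(1, 9)}e-{rng.randint(8, 30)}"
        writer.writerow(
            [snp, trait_label, _curie_to_uri(trait_id), background, p_value]
        )
    return buffer.getvalue()
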