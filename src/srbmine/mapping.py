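"""Mapping mined gene symbols onto the target genome.

Implements the literature funnel: mined symbols are looked up in the
organism dictionary (unmapped symbols stand in for genes with no homolog
in the target genus), duplicates are collapsed (same locus tag, or same
normalized product within the same symbol family), the retained genes are
partitioned by pathway, and GO-term frequencies are tabulated per aspect.

Deduplication deliberately does NOT merge records that share only a
product string: annotation tables sometimes print the same product name
for distinct genes (e.g. several sulfur-metabolism genes all labelled
"Cysteine synthase A"), so product equality collapses entries only when
the symbol family (casefolded symbol with trailing digits stripped) also
matches.  The first occurrence is always the representative kept.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .annotate import GeneDictionary, GeneRecord

__all__ = [
    "MappedRecord",
    "MappingFunnel",
    "GoFrequencyTable",
    "map_to_genome",
    "deduplicate",
    "categorize_pathways",
    "go_term_frequency",
    "normalize_product",
    "symbol_family",
]

GO_ASPECTS = ("molecular_function", "biological_process", "cellular_component")


@dataclass(frozen=True)
class MappedRecord:
    symbol: str
    locus_tag: str
    product: str
    pathway: str


@dataclass
class MappingFunnel:
    """The symbol → genome mapping funnel with full accounting.

    Invariants: ``len(input_symbols) == len(mapped) + len(unmapped)`` and
    ``len(mapped) == len(removed) + len(retained)`` once deduplicated.
    """

    input_symbols: list[str] = field(default_factory=list)
    mapped: list[MappedRecord] = field(default_factory=list)
    unmapped: list[str] = field(default_factory=list)
    removed: list[tuple[MappedRecord, str]] = field(default_factory=list)
    retained: list[MappedRecord] = field(default_factory=list)


def normalize_product(product: str) -> str:
    """Case-fold and collapse whitespace."""
    return " ".join(product.casefold().split())


def symbol_family(symbol: str) -> str:
    """Casefolded symbol with trailing digits stripped (dsrA2 → dsra)."""
    return re.sub(r"\d+$", "", symbol.casefold())


def map_to_genome(
    symbols: Sequence[str], dictionary: GeneDictionary
) -> MappingFunnel:
    """Resolve each mined symbol against the organism dictionary.

    A symbol maps iff its normalized form is a dictionary surface form;
    everything else lands verbatim in ``unmapped`` (the stand-in for
    symbols with no homolog in the target genus).  Order is preserved.
    """
    funnel = MappingFunnel(input_symbols=list(symbols))
    for symbol in symbols:
        tag = dictionary.resolve(symbol)
        if tag is None:
            funnel.unmapped.append(symbol)
        else:
            rec = dictionary.records[tag]
            funnel.mapped.append(
                MappedRecord(
                    symbol=symbol,
                    locus_tag=tag,
                    product=rec.product,
                    pathway=rec.pathway,
                )
            )
    return funnel


def deduplicate(funnel: MappingFunnel) -> MappingFunnel:
    """Collapse duplicate mapped entries, keeping the first occurrence.

    An entry is removed with reason ``duplicate-locus`` if its locus tag
    was already seen, or ``duplicate-product`` if an earlier entry shares
    both its normalized product name and its symbol family.  Idempotent.
    """
    out = replace(
        funnel,
        input_symbols=list(funnel.input_symbols),
        mapped=list(funnel.mapped),
        unmapped=list(funnel.unmapped),
        removed=[],
        retained=[],
    )
    seen_locus: set[str] = set()
    seen_product: set[tuple[str, str]] = set()
    for rec in funnel.mapped:
        key = (normalize_product(rec.product), symbol_family(rec.symbol))
        if rec.locus_tag in seen_locus:
            out.removed.append((rec, "duplicate-locus"))
        elif rec.product and key in seen_product:
            out.removed.append((rec, "duplicate-product"))
        else:
            seen_locus.add(rec.locus_tag)
            seen_product.add(key)
            out.retained.append(rec)
    return out


def categorize_pathways(
    retained: Iterable[MappedRecord | GeneRecord],
) -> dict[str, list]:
    """Partition records by pathway; missing labels go to "uncategorized"."""
    census: dict[str, list] = {}
    for rec in retained:
        pathway = rec.pathway or "uncategorized"
        census.setdefault(pathway, []).append(rec)
    return census


@dataclass
class GoFrequencyTable:
    """Per-aspect GO term → gene count, with the top term per aspect."""

    counts: dict[str, Counter] = field(
        default_factory=lambda: {a: Counter() for a in GO_ASPECTS}
    )

    def top_terms(self) -> dict[str, tuple[str, int] | None]:
        return {
            aspect: (c.most_common(1)[0] if c else None)
            for aspect, c in self.counts.items()
        }


def go_term_frequency(genes: Iterable[GeneRecord]) -> GoFrequencyTable:
    """Count genes per GO term, split by aspect.

    A gene with k GO terms contributes to exactly k cells.  An unknown
    aspect string raises ``ValueError`` naming the offending record.
    """
    table = GoFrequencyTable()
    for rec in genes:
        for go_id, aspect in rec.go_terms:
            if aspect not in table.counts:
                raise ValueError(
                    f"unknown GO aspect {aspect!r} on record {rec.locus_tag}"
                )
            table.counts[aspect][go_id] += 1
    return table
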