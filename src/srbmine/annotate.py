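"""Dictionary-based gene mention annotation ("microbe annotator").

Builds an organism-specific gene dictionary from an annotation table,
splits long documents into overlapping windows, and tags gene mentions
deterministically with a longest-match-leftmost dictionary matcher at
token boundaries.  The matcher is a deterministic stand-in for a trained
NER model: it is exactly reproducible and serves as the reference
recognizer for the evaluation harness, which accepts any recognizer that
emits character-offset mentions.

Offsets are 0-based half-open character positions; token boundaries are
transitions between word characters (``[A-Za-z0-9_]``) and anything else,
so locus tags such as ``dde_2265`` tokenize intact.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GeneRecord",
    "GeneDictionary",
    "Mention",
    "AnnotatedDocument",
    "AmbiguousSurfaceError",
    "build_dictionary",
    "granularize",
    "annotate_document",
    "annotate_text_granular",
    "annotate_corpus",
    "recognize",
]

_WORD = re.compile(r"[A-Za-z0-9_]")


class AmbiguousSurfaceError(ValueError):
    """Two distinct locus tags share a normalized surface form."""


def normalize_surface(surface: str) -> str:
    """Case-fold a surface form for lookup."""
    return surface.casefold()


@dataclass(frozen=True)
class GeneRecord:
    """One gene of the target organism.

    ``go_terms`` is a sequence of ``(go_id, aspect)`` pairs where aspect is
    one of ``molecular_function``, ``biological_process``,
    ``cellular_component``.
    """

    locus_tag: str
    symbol: str
    synonyms: tuple[str, ...] = ()
    product: str = ""
    pathway: str = ""
    go_terms: tuple[tuple[str, str], ...] = ()

    def surfaces(self) -> tuple[str, ...]:
        return (self.symbol, *self.synonyms, self.locus_tag)


@dataclass
class GeneDictionary:
    """Locus-tag-keyed gene records plus a normalized surface-form lookup."""

    records: dict[str, GeneRecord]
    lookup: dict[str, str]  # normalized surface -> locus tag
    _pattern: re.Pattern | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, surface: str) -> bool:
        return normalize_surface(surface) in self.lookup

    def resolve(self, surface: str) -> str | None:
        """Locus tag for a surface form, or None."""
        return self.lookup.get(normalize_surface(surface))

    def pattern(self) -> re.Pattern | None:
        """Compiled alternation over all surfaces, longest first.

        Longest-first ordering makes Python's leftmost-first-alternative
        semantics behave as leftmost-longest.  None for an empty dictionary.
        """
        if self._pattern is None and self.lookup:
            surfaces = sorted(self.lookup, key=lambda s: (-len(s), s))
            alt = "|".join(re.escape(s) for s in surfaces)
            self._pattern = re.compile(
                rf"(?<![A-Za-z0-9_])(?:{alt})(?![A-Za-z0-9_])", re.IGNORECASE
            )
        return self._pattern


@dataclass(frozen=True, order=True)
class Mention:
    """A gene mention as a 0-based half-open character span."""

    start: int
    end: int
    text: str
    locus_tag: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")


@dataclass
class AnnotatedDocument:
    """A document with sorted, non-overlapping gene mentions."""

    doc_id: str
    text: str
    mentions: list[Mention] = field(default_factory=list)

    def __post_init__(self) -> None:
        for m in self.mentions:
            if m.end > len(self.text):
                raise ValueError(f"mention {m} exceeds document length")
            if self.text[m.start : m.end] != m.text:
                raise ValueError(
                    f"mention text {m.text!r} does not match slice "
                    f"{self.text[m.start:m.end]!r}"
                )
        self.mentions.sort()
        for a, b in zip(self.mentions, self.mentions[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping mentions {a} / {b}")

    def locus_tags(self) -> list[str]:
        """Deduplicated locus tags, first-seen order."""
        return list(dict.fromkeys(m.locus_tag for m in self.mentions))


def build_dictionary(records: Iterable[GeneRecord]) -> GeneDictionary:
    """Build the surface-form lookup from gene records.

    Every normalized surface form (primary symbol, each synonym, and the
    locus tag itself) must map to exactly one locus tag.

    Raises
    ------
    ValueError
        On duplicate locus tags.
    AmbiguousSurfaceError
        If two locus tags collide on a normalized surface form; the message
        lists every collision.
    """
    recs: dict[str, GeneRecord] = {}
    lookup: dict[str, str] = {}
    collisions: list[str] = []
    for rec in records:
        if rec.locus_tag in recs:
            raise ValueError(f"duplicate locus tag {rec.locus_tag}")
        recs[rec.locus_tag] = rec
        for surface in rec.surfaces():
            key = normalize_surface(surface)
            if not key:
                continue
            owner = lookup.get(key)
            if owner is not None and owner != rec.locus_tag:
                collisions.append(f"{surface!r}: {owner} vs {rec.locus_tag}")
            else:
                lookup[key] = rec.locus_tag
    if collisions:
        raise AmbiguousSurfaceError(
            "ambiguous surface forms: " + "; ".join(collisions)
        )
    return GeneDictionary(records=recs, lookup=lookup)


def granularize(
    text: str, window: int, overlap: int
) -> list[tuple[str, int]]:
    """Split text into overlapping windows with source offsets.

    Returns ``(segment_text, source_offset)`` pairs; consecutive segments
    overlap by ``overlap`` characters and jointly cover the text.  A text
    shorter than ``window`` yields one segment; empty text yields none.
    """
    if not 0 <= overlap < window:
        raise ValueError(f"need 0 <= overlap < window, got {overlap} / {window}")
    if not text:
        return []
    step = window - overlap
    segments = []
    pos = 0
    while True:
        segments.append((text[pos : pos + window], pos))
        if pos + window >= len(text):
            break
        pos += step
    return segments


def _candidates(
    pattern: re.Pattern, text: str, offset: int = 0
) -> list[tuple[int, int, str]]:
    """All dictionary matches in text, including overlapping starts.

    After a match at position ``s`` the scan resumes at ``s + 1`` so that
    every starting position gets its longest match recorded.
    """
    out = []
    pos = 0
    while True:
        m = pattern.search(text, pos)
        if m is None:
            break
        out.append((m.start() + offset, m.end() + offset, m.group(0)))
        pos = m.start() + 1
    return out


def _resolve(
    candidates: Sequence[tuple[int, int, str]], dictionary: GeneDictionary
) -> list[Mention]:
    """Greedy longest-match-leftmost resolution over candidate spans."""
    ordered = sorted(set(candidates), key=lambda c: (c[0], c[0] - c[1]))
    mentions = []
    cursor = 0
    for start, end, surf in ordered:
        if start >= cursor:
            tag = dictionary.resolve(surf)
            if tag is None:  # cannot happen for matcher-produced candidates
                continue
            mentions.append(Mention(start, end, surf, tag))
            cursor = end
    return mentions


def annotate_document(
    doc_id: str, text: str, dictionary: GeneDictionary
) -> AnnotatedDocument:
    """Tag all dictionary gene mentions in a document.

    Matches are found at token boundaries only, resolved deterministically
    longest-first then leftmost.  An empty text or dictionary yields zero
    mentions.
    """
    pattern = dictionary.pattern()
    if pattern is None or not text:
        return AnnotatedDocument(doc_id=doc_id, text=text, mentions=[])
    cands = _candidates(pattern, text)
    return AnnotatedDocument(doc_id=doc_id, text=text, mentions=_resolve(cands, dictionary))


def annotate_text_granular(
    doc_id: str,
    text: str,
    dictionary: GeneDictionary,
    window: int,
    overlap: int,
) -> AnnotatedDocument:
    """Annotate via overlapping windows, reconciling offsets globally.

    Candidates found inside each window are mapped back to source
    coordinates, re-validated against the full text's token boundaries
    (discarding matches created by a window cutting through a token),
    deduplicated, and resolved with the same longest-match-leftmost rule as
    :func:`annotate_document`.  Provided ``overlap`` is at least the length
    of the longest surface form, the result equals whole-text annotation.
    """
    pattern = dictionary.pattern()
    if pattern is None or not text:
        return AnnotatedDocument(doc_id=doc_id, text=text, mentions=[])
    cands: list[tuple[int, int, str]] = []
    for segment, offset in granularize(text, window, overlap):
        for start, end, surf in _candidates(pattern, segment, offset):
            # re-check boundaries in the full text: a window edge can fake one
            if start > 0 and _WORD.match(text[start - 1]):
                continue
            if end < len(text) and _WORD.match(text[end]):
                continue
            cands.append((start, end, surf))
    return AnnotatedDocument(doc_id=doc_id, text=text, mentions=_resolve(cands, dictionary))


def annotate_corpus(
    docs: Iterable[AnnotatedDocument | tuple[str, str]],
    dictionary: GeneDictionary,
    window: int | None = None,
    overlap: int = 0,
) -> list[AnnotatedDocument]:
    """Annotate a corpus; items are documents or ``(doc_id, text)`` pairs."""
    out = []
    for doc in docs:
        doc_id, text = (doc.doc_id, doc.text) if isinstance(doc, AnnotatedDocument) else doc
        if window is None:
            out.append(annotate_document(doc_id, text, dictionary))
        else:
            out.append(annotate_text_granular(doc_id, text, dictionary, window, overlap))
    return out


def recognize(
    corpus: Iterable[AnnotatedDocument],
) -> tuple[dict[str, list[str]], dict[str, int]]:
    """Per-document unique locus tags plus the corpus-level mention funnel.

    Returns ``(per_doc, funnel)`` where ``per_doc`` maps doc_id to its
    deduplicated locus tags and ``funnel`` reports
    ``{"mentions": total mentions with duplicates, "unique_genes": distinct
    locus tags corpus-wide}`` — the mined-mentions → unique-genes funnel.
    """
    per_doc: dict[str, list[str]] = {}
    total = 0
    universe: set[str] = set()
    for doc in corpus:
        tags = doc.locus_tags()
        per_doc[doc.doc_id] = tags
        total += len(doc.mentions)
        universe.update(tags)
    return per_doc, {"mentions": total, "unique_genes": len(universe)}
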