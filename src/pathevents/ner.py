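"""Pathway mention recognition and the disguise bridge to a gene-only extractor.

Two complementary recognizers are provided:

* :func:`soft_match` — soft dictionary matching of text windows against
  pathway-database synonyms, scored by token-set Jaccard similarity after
  lowercasing, compound splitting, and removal of pathway head terms
  ("pathway", "signaling", "cascade", ...).
* :func:`rule_detect` — a head-term rule: any occurrence of a pathway head
  term extends leftwards over contiguous entity-like tokens (capitalized
  words, hyphen/slash compounds, Greek-letter tokens) to form a mention.

Gene mentions nested inside pathway names ("Notch" in "Notch pathway") are
absorbed by :func:`merge_overlaps`, which collapses every connected component
of overlapping spans into a single mention over the union of boundaries.

Because GENIA-style event extractors only accept protein entities, pathway
mentions are *disguised* as proteins before extraction and *undisguised*
afterwards via a sidecar that remembers their true class.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .standoff import (
    Argument,
    Document,
    EntityClass,
    Event,
    IntegrityError,
    Mention,
    PathwayDB,
    UsageError,
    a1_lines,
)

__all__ = [
    "SoftMatchConfig",
    "DisguiseSidecar",
    "DEFAULT_HEAD_TERMS",
    "normalize_tokens",
    "token_set_similarity",
    "soft_match",
    "rule_detect",
    "merge_overlaps",
    "resolve_pathway_overlaps",
    "disguise",
    "undisguise",
]

#: Pathway trigger tokens; multi-word terms are matched as token sequences.
DEFAULT_HEAD_TERMS = frozenset(
    {"pathway", "pathways", "signaling", "signalling", "cascade", "signal transduction"}
)


@dataclass(frozen=True)
class SoftMatchConfig:
    similarity_threshold: float = 0.8
    head_terms: frozenset[str] = DEFAULT_HEAD_TERMS
    max_entity_tokens: int = 5

    def __post_init__(self) -> None:
        if not (0.0 <= self.similarity_threshold <= 1.0):
            raise UsageError("similarity_threshold must lie in [0, 1]")
        if not self.head_terms:
            raise UsageError("head_terms must be non-empty")
        if self.max_entity_tokens < 1:
            raise UsageError("max_entity_tokens must be positive")


@dataclass
class DisguiseSidecar:
    """Maps extractor-facing mention IDs back to their original class/span."""

    entries: dict[str, tuple[EntityClass, int, int]] = field(default_factory=dict)

    def pathway_ids(self) -> set[str]:
        return {tid for tid, (cls, _s, _e) in self.entries.items() if cls is EntityClass.PATHWAY}


# ---------------------------------------------------------------------------
# Tokenization and similarity
# ---------------------------------------------------------------------------

_WS_TOKEN = re.compile(r"\S+")
_EDGE_PUNCT = ".,;:!?()[]{}\"'"


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Whitespace tokens with character spans, edge punctuation stripped."""
    out = []
    for m in _WS_TOKEN.finditer(text):
        tok, start, end = m.group(), m.start(), m.end()
        while tok and tok[0] in _EDGE_PUNCT:
            tok, start = tok[1:], start + 1
        while tok and tok[-1] in _EDGE_PUNCT:
            tok, end = tok[:-1], end - 1
        if tok:
            out.append((tok, start, end))
    return out


def _head_token_set(head_terms: Iterable[str]) -> frozenset[str]:
    toks: set[str] = set()
    for term in head_terms:
        toks.update(term.lower().split())
    return frozenset(toks)


def normalize_tokens(text: str, head_terms: Iterable[str] = DEFAULT_HEAD_TERMS) -> frozenset[str]:
    """Lowercase, split on whitespace/slash/hyphen, drop head-term tokens."""
    head = _head_token_set(head_terms)
    toks = set()
    for raw in re.split(r"[\s/\-]+", text.lower()):
        raw = raw.strip(_EDGE_PUNCT)
        if raw and raw not in head:
            toks.add(raw)
    return frozenset(toks)


def token_set_similarity(a: frozenset[str], b: frozenset[str]) -> float:
    """Jaccard index of two token sets; 0 when either is empty."""
    if not a or not b:
        return 0.0
    return len(a & b) / len(a | b)


def _has_greek(tok: str) -> bool:
    return any("GREEK" in unicodedata.name(c, "") for c in tok)


def _entity_like(tok: str) -> bool:
    """Tokens that plausibly name a molecule or pathway component."""
    if any(c.isupper() for c in tok):
        return True
    if "/" in tok or "-" in tok:
        return True
    if any(c.isdigit() for c in tok):
        return True
    return _has_greek(tok)


# ---------------------------------------------------------------------------
# Recognizers
# ---------------------------------------------------------------------------

def _head_term_spans(
    tokens: list[tuple[str, int, int]], head_terms: Iterable[str]
) -> list[tuple[int, int]]:
    """(first_token_index, last_token_index) of each head-term occurrence."""
    seqs = sorted((term.lower().split() for term in head_terms), key=len, reverse=True)
    hits: list[tuple[int, int]] = []
    lowered = [t[0].lower() for t in tokens]
    i = 0
    while i < len(tokens):
        matched = False
        for seq in seqs:
            j = i + len(seq)
            if lowered[i:j] == seq:
                hits.append((i, j - 1))
                i = j
                matched = True
                break
        if not matched:
            i += 1
    return hits


def _fresh_ids(mentions: list[Mention], prefix: str = "P") -> list[Mention]:
    return [replace(m, mention_id=f"{prefix}{i + 1}") for i, m in enumerate(mentions)]


def resolve_pathway_overlaps(candidates: list[Mention]) -> list[Mention]:
    """Keep the longer span among overlapping candidates (tie: smaller start).

    Pathway mentions must never overlap one another, so overlapping
    candidates from the two recognizers are resolved greedily.
    """
    ranked = sorted(candidates, key=lambda m: (-(m.end - m.start), m.start, m.mention_id))
    kept: list[Mention] = []
    for cand in ranked:
        if not any(cand.overlaps(k) for k in kept):
            kept.append(cand)
    return sorted(kept, key=lambda m: m.start)


def soft_match(doc: Document, db: PathwayDB, cfg: SoftMatchConfig) -> list[Mention]:
    """Soft dictionary matching of token windows against pathway synonyms.

    A window qualifies when its normalized token set reaches the similarity
    threshold against some synonym (or canonical name). The longest
    qualifying window wins per position.
    """
    tokens = tokenize(doc.text)
    syn_sets = [
        (normalize_tokens(name, cfg.head_terms), name) for name, _rec in db.synonym_names()
    ]
    syn_sets = [(s, name) for s, name in syn_sets if s]
    if not syn_sets:
        return []

    max_window = cfg.max_entity_tokens + 2  # room for trailing head terms
    candidates: list[Mention] = []
    for i in range(len(tokens)):
        for j in range(i + 1, min(i + 1 + max_window, len(tokens) + 1)):
            start, end = tokens[i][1], tokens[j - 1][2]
            window_text = doc.text[start:end]
            cand_set = normalize_tokens(window_text, cfg.head_terms)
            if not cand_set or len(cand_set) > cfg.max_entity_tokens:
                continue
            best = max(token_set_similarity(cand_set, s) for s, _ in syn_sets)
            if best >= cfg.similarity_threshold:
                candidates.append(
                    Mention(
                        mention_id=f"S{i}_{j}",
                        doc_id=doc.doc_id,
                        start=start,
                        end=end,
                        surface=window_text,
                        entity_class=EntityClass.PATHWAY,
                    )
                )
    return _fresh_ids(resolve_pathway_overlaps(candidates))


def rule_detect(doc: Document, cfg: SoftMatchConfig) -> list[Mention]:
    """Head-term rule: extend left over entity-like tokens.

    A head-term occurrence ("pathway", "signaling", ...) absorbs up to
    ``max_entity_tokens`` contiguous entity-like tokens to its left; spans
    with no entity-like token are dropped. Returned spans never overlap.
    """
    tokens = tokenize(doc.text)
    candidates: list[Mention] = []
    for first, last in _head_term_spans(tokens, cfg.head_terms):
        k = first - 1
        taken = 0
        while k >= 0 and taken < cfg.max_entity_tokens and _entity_like(tokens[k][0]):
            k -= 1
            taken += 1
        if taken == 0:
            continue
        start, end = tokens[k + 1][1], tokens[last][2]
        candidates.append(
            Mention(
                mention_id=f"R{first}",
                doc_id=doc.doc_id,
                start=start,
                end=end,
                surface=doc.text[start:end],
                entity_class=EntityClass.PATHWAY,
            )
        )
    return _fresh_ids(resolve_pathway_overlaps(candidates))


# ---------------------------------------------------------------------------
# Overlap merging
# ---------------------------------------------------------------------------

def merge_overlaps(genes: list[Mention], pathways: list[Mention]) -> list[Mention]:
    """Absorb gene mentions overlapping pathway mentions (union of boundaries).

    Overlap is transitive: each connected component of overlapping spans
    collapses to a single mention whose span is the interval union. A
    component containing at least one pathway mention becomes a PATHWAY
    mention; gene-only components stay GENE. Disjoint mentions pass through
    unchanged. The output is sorted by start offset and overlap-free.
    """
    mentions = list(genes) + list(pathways)
    if not mentions:
        return []
    doc_ids = {m.doc_id for m in mentions}
    if len(doc_ids) > 1:
        raise UsageError(f"mentions span multiple documents: {sorted(doc_ids)}")

    ordered = sorted(mentions, key=lambda m: (m.start, m.end, m.mention_id))
    components: list[list[Mention]] = []
    cur: list[Mention] = []
    cur_end = -1
    for m in ordered:
        if cur and m.start < cur_end:
            cur.append(m)
            cur_end = max(cur_end, m.end)
        else:
            if cur:
                components.append(cur)
            cur, cur_end = [m], m.end
    components.append(cur)

    out: list[Mention] = []
    for comp in components:
        if len(comp) == 1:
            out.append(comp[0])
            continue
        start = min(m.start for m in comp)
        end = max(m.end for m in comp)
        cls = (
            EntityClass.PATHWAY
            if any(m.entity_class is EntityClass.PATHWAY for m in comp)
            else EntityClass.GENE
        )
        # Stitch the union surface from overlapping member surfaces.
        surface_chars: list[str | None] = [None] * (end - start)
        for m in comp:
            for i, ch in enumerate(m.surface):
                surface_chars[m.start - start + i] = ch
        if any(c is None for c in surface_chars):  # pragma: no cover - by construction
            raise IntegrityError("merged component does not tile its union span")
        out.append(
            Mention(
                mention_id=comp[0].mention_id,
                doc_id=comp[0].doc_id,
                start=start,
                end=end,
                surface="".join(surface_chars),  # type: ignore[arg-type]
                entity_class=cls,
            )
        )
    return sorted(out, key=lambda m: m.start)


# ---------------------------------------------------------------------------
# Disguise / undisguise
# ---------------------------------------------------------------------------

def disguise(mentions: list[Mention]) -> tuple[str, list[Mention], DisguiseSidecar]:
    """Renumber mentions T1..Tn and write them all with entity type Protein.

    Returns the .a1 content, the renumbered mentions, and a sidecar
    recording which IDs are really pathways.
    """
    ordered = sorted(mentions, key=lambda m: (m.start, m.end))
    for a, b in zip(ordered, ordered[1:]):
        if a.overlaps(b):
            raise UsageError(
                f"disguise requires non-overlapping mentions; {a.mention_id} "
                f"overlaps {b.mention_id}"
            )
    renumbered = [replace(m, mention_id=f"T{i + 1}") for i, m in enumerate(ordered)]
    sidecar = DisguiseSidecar(
        entries={
            m.mention_id: (m.entity_class, m.start, m.end)
            for m in renumbered
            if m.entity_class is EntityClass.PATHWAY
        }
    )
    return a1_lines(renumbered, disguise_as_protein=True), renumbered, sidecar


def _restore_mention(m: Mention, sidecar: DisguiseSidecar) -> Mention:
    entry = sidecar.entries.get(m.mention_id)
    if entry is None:
        return m
    cls, start, end = entry
    if (start, end) != (m.start, m.end):
        raise IntegrityError(
            f"sidecar span ({start}, {end}) for {m.mention_id} disagrees with "
            f"mention span ({m.start}, {m.end})"
        )
    return replace(m, entity_class=cls)


def _restore_arg(arg: Argument, sidecar: DisguiseSidecar, cache: dict[int, Argument]) -> Argument:
    key = id(arg)
    if key in cache:
        return cache[key]
    if isinstance(arg, Mention):
        out: Argument = _restore_mention(arg, sidecar)
    else:
        out = replace(
            arg,
            themes=tuple(_restore_arg(t, sidecar, cache) for t in arg.themes),
            cause=None if arg.cause is None else _restore_arg(arg.cause, sidecar, cache),
        )
    cache[key] = out
    return out


def undisguise(events: list[Event], sidecar: DisguiseSidecar) -> list[Event]:
    """Restore the PATHWAY class on flagged mentions throughout nested events.

    Idempotent: re-applying with the same sidecar is a no-op, since restored
    mentions keep their IDs and spans.
    """
    cache: dict[int, Argument] = {}
    return [_restore_arg(e, sidecar, cache) for e in events]  # type: ignore[misc]


def undisguise_mentions(mentions: list[Mention], sidecar: DisguiseSidecar) -> list[Mention]:
    return [_restore_mention(m, sidecar) for m in mentions]
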