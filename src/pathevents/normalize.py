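"""Entity normalization: gene mentions to Entrez IDs, pathway mentions to
canonical pathway-database records, and the discard rule for events whose
participants cannot be normalized.

Gene lookup is exact after case folding — a deliberate contrast with the
fuzzy pathway matching, since unmapped gene mentions are treated as likely
NER false positives and fuzzy gene matching would re-admit them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .ner import SoftMatchConfig, normalize_tokens, token_set_similarity
from .standoff import (
    Argument,
    EntityClass,
    Event,
    GeneLexicon,
    Mention,
    PathwayDB,
    PathwayRecord,
    UsageError,
)

__all__ = [
    "NormalizedEntity",
    "DiscardRecord",
    "Normalizer",
    "normalize_gene",
    "normalize_pathway",
    "filter_normalizable",
    "write_discard_log",
]

#: Node key types: ("GENE", entrez_id) or ("PATHWAY", canonical_id).
NodeKey = tuple[str, object]


@dataclass(frozen=True)
class NormalizedEntity:
    kind: EntityClass
    gene_id: int | None
    pathway_id: str | None
    source_mention: Mention

    def __post_init__(self) -> None:
        if (self.gene_id is None) == (self.pathway_id is None):
            raise UsageError("exactly one of gene_id / pathway_id must be set")

    @property
    def key(self) -> NodeKey:
        if self.kind is EntityClass.GENE:
            return ("GENE", self.gene_id)
        return ("PATHWAY", self.pathway_id)


@dataclass(frozen=True)
class DiscardRecord:
    doc_id: str
    event_id: str
    reason: str
    surface: str


def normalize_gene(m: Mention, lex: GeneLexicon) -> NormalizedEntity | None:
    """Case-folded exact lookup; None when the surface is absent."""
    if m.entity_class is not EntityClass.GENE:
        raise UsageError(f"normalize_gene requires a GENE mention, got {m.entity_class}")
    gene_id = lex.lookup(m.surface)
    if gene_id is None:
        return None
    return NormalizedEntity(
        kind=EntityClass.GENE, gene_id=gene_id, pathway_id=None, source_mention=m
    )


def normalize_pathway(
    m: Mention, db: PathwayDB, cfg: SoftMatchConfig
) -> NormalizedEntity | None:
    """Best-similarity synonym at or above the threshold wins.

    Similarity is the same normalized token-set Jaccard used by the soft
    matcher, so recognition and normalization agree on what "close" means.
    Ties are broken by lexicographically smallest canonical_id.
    """
    if m.entity_class is not EntityClass.PATHWAY:
        raise UsageError(f"normalize_pathway requires a PATHWAY mention, got {m.entity_class}")
    cand = normalize_tokens(m.surface, cfg.head_terms)
    best: tuple[float, str] | None = None  # (score, canonical_id); max score, min id
    for name, rec in db.synonym_names():
        score = token_set_similarity(cand, normalize_tokens(name, cfg.head_terms))
        if score < cfg.similarity_threshold:
            continue
        if best is None or score > best[0] or (score == best[0] and rec.canonical_id < best[1]):
            best = (score, rec.canonical_id)
    if best is None:
        return None
    return NormalizedEntity(
        kind=EntityClass.PATHWAY, gene_id=None, pathway_id=best[1], source_mention=m
    )


class Normalizer:
    """Caching facade over gene and pathway normalization.

    Exposes ``key(mention) -> NodeKey | None`` for use by the pair
    extraction stage.
    """

    def __init__(self, lex: GeneLexicon, db: PathwayDB, cfg: SoftMatchConfig | None = None):
        self.lex = lex
        self.db = db
        self.cfg = cfg or SoftMatchConfig()
        self._cache: dict[tuple[EntityClass, str], NormalizedEntity | None] = {}

    def normalize(self, m: Mention) -> NormalizedEntity | None:
        cache_key = (m.entity_class, m.surface)
        if cache_key not in self._cache:
            if m.entity_class is EntityClass.GENE:
                ent = normalize_gene(m, self.lex)
            else:
                ent = normalize_pathway(m, self.db, self.cfg)
            self._cache[cache_key] = ent
        ent = self._cache[cache_key]
        if ent is None:
            return None
        # Re-anchor the cached entity to this mention.
        return NormalizedEntity(
            kind=ent.kind, gene_id=ent.gene_id, pathway_id=ent.pathway_id, source_mention=m
        )

    def key(self, m: Mention) -> NodeKey | None:
        ent = self.normalize(m)
        return None if ent is None else ent.key

    def pathway_record(self, canonical_id: str) -> PathwayRecord | None:
        return self.db.get(canonical_id)


def _mention_participants(arg: Argument) -> Iterable[Mention]:
    """Every mention reachable in the argument subtree (themes and cause)."""
    if isinstance(arg, Mention):
        yield arg
        return
    for theme in arg.themes:
        yield from _mention_participants(theme)
    if arg.cause is not None:
        yield from _mention_participants(arg.cause)


def filter_normalizable(
    events: list[Event],
    lex: GeneLexicon,
    db: PathwayDB,
    cfg: SoftMatchConfig | None = None,
) -> tuple[list[Event], list[DiscardRecord]]:
    """Keep only events whose every mention participant normalizes.

    Discarding is all-or-nothing per event: one unmappable mention anywhere
    in the nested structure discards the whole event. Kept events are
    returned unaltered; |kept| + |discarded| == |input|.
    """
    normalizer = Normalizer(lex, db, cfg)
    kept: list[Event] = []
    discards: list[DiscardRecord] = []
    for ev in events:
        offender: Mention | None = None
        for m in _mention_participants(ev):
            if normalizer.key(m) is None:
                offender = m
                break
        if offender is None:
            kept.append(ev)
        else:
            reason = (
                "unmappable_gene"
                if offender.entity_class is EntityClass.GENE
                else "unmappable_pathway"
            )
            discards.append(
                DiscardRecord(
                    doc_id=ev.doc_id,
                    event_id=ev.event_id,
                    reason=reason,
                    surface=offender.surface,
                )
            )
    return kept, discards


def write_discard_log(discards: Iterable[DiscardRecord], path: str | Path) -> Path:
    out = Path(path)
    lines = [f"{d.doc_id}\t{d.event_id}\t{d.reason}\t{d.surface}" for d in discards]
    out.write_text("".join(line + "\n" for line in lines), encoding="utf-8")
    return out
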