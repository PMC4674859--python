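"""Event post-processing: pathway event-type validity, recursive expansion of
nested arguments, and enumeration of unique undirected interaction pairs.

An event contributes pairs in one of two ways:

* regulation events (``Regulation``, ``Positive_regulation``,
  ``Negative_regulation``) with both a cause and a theme yield the cross
  product of the participant sets of the two sides, ``<Cause, Theme>``;
* binding events with *n* ≥ 2 distinct themes yield all *n*-choose-2
  co-participant pairs.

Nested event arguments are expanded recursively to their participating
entities, and directionality is ignored: pairs are unordered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Callable, Iterable

from .normalize import NodeKey
from .standoff import (
    Argument,
    EntityClass,
    Event,
    EventType,
    Mention,
    REGULATION_TYPES,
    StandoffError,
)

__all__ = [
    "Category",
    "InteractionPair",
    "make_pair",
    "is_valid_pathway_event",
    "filter_valid_pathway_events",
    "expand_participants",
    "pairs_from_event",
    "extract_unique_pairs",
    "is_pathway_pair",
    "write_pairs_tsv",
]


class StructureError(StandoffError):
    """Cyclic or otherwise malformed event argument structure."""


Category = EventType  # pair categories reuse the regulation/binding event types

_CATEGORY_FROM_TYPE = {
    EventType.REGULATION: EventType.REGULATION,
    EventType.POSITIVE_REGULATION: EventType.POSITIVE_REGULATION,
    EventType.NEGATIVE_REGULATION: EventType.NEGATIVE_REGULATION,
    EventType.BINDING: EventType.BINDING,
}

#: SIF relation names per pair category.
CATEGORY_RELATION = {
    EventType.REGULATION: "reg",
    EventType.POSITIVE_REGULATION: "pos_reg",
    EventType.NEGATIVE_REGULATION: "neg_reg",
    EventType.BINDING: "binding",
}


def _canonical_order(a: NodeKey, b: NodeKey) -> tuple[NodeKey, NodeKey]:
    return (a, b) if (a[0], str(a[1])) <= (b[0], str(b[1])) else (b, a)


@dataclass(frozen=True)
class InteractionPair:
    """An undirected, normalized interaction with provenance.

    Equality and hashing ignore provenance and endpoint order, so pairs
    deduplicate corpus-wide on (unordered node pair, category).
    """

    node_a: NodeKey
    node_b: NodeKey
    category: EventType
    provenance: frozenset[tuple[str, str]] = field(default_factory=frozenset, compare=False)

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise StructureError(f"self-pair is not a valid interaction: {self.node_a}")

    @property
    def nodes(self) -> frozenset[NodeKey]:
        return frozenset((self.node_a, self.node_b))


def make_pair(
    a: NodeKey,
    b: NodeKey,
    category: EventType,
    provenance: Iterable[tuple[str, str]] = (),
) -> InteractionPair:
    na, nb = _canonical_order(a, b)
    return InteractionPair(na, nb, category, frozenset(provenance))


def is_pathway_pair(pair: InteractionPair) -> bool:
    """A pathway interaction needs only one endpoint to be a pathway."""
    return pair.node_a[0] == "PATHWAY" or pair.node_b[0] == "PATHWAY"


# ---------------------------------------------------------------------------
# Pathway event-type validity
# ---------------------------------------------------------------------------

def _contains_pathway(arg: Argument) -> bool:
    if isinstance(arg, Mention):
        return arg.entity_class is EntityClass.PATHWAY
    if any(_contains_pathway(t) for t in arg.themes):
        return True
    return arg.cause is not None and _contains_pathway(arg.cause)


def is_valid_pathway_event(e: Event) -> bool:
    """Pathways may only participate in the three regulation event types.

    Gene expression, transcription, protein catabolism, phosphorylation,
    localization and binding cannot take a pathway participant. The check
    applies at every nesting level on the path to a pathway mention: an
    event is valid iff it has no pathway participant at all, or its own
    type and that of every sub-event containing a pathway are regulatory.
    """
    if not _contains_pathway(e):
        return True
    if e.event_type not in REGULATION_TYPES:
        return False
    sub_events = [a for a in (*e.themes, e.cause) if isinstance(a, Event)]
    return all(is_valid_pathway_event(sub) for sub in sub_events)


def filter_valid_pathway_events(events: list[Event]) -> tuple[list[Event], list[Event]]:
    kept = [e for e in events if is_valid_pathway_event(e)]
    dropped = [e for e in events if not is_valid_pathway_event(e)]
    return kept, dropped


# ---------------------------------------------------------------------------
# Recursive participant expansion
# ---------------------------------------------------------------------------

KeyFn = Callable[[Mention], "NodeKey | None"]


def mention_key(m: Mention) -> NodeKey:
    """Surface-based key; useful default when no normalizer is in play."""
    return (m.entity_class.value, m.surface)


def expand_participants(arg: Argument, key_fn: KeyFn = mention_key) -> frozenset[NodeKey]:
    """All participating entity keys of an argument subtree.

    A mention expands to a singleton (or the empty set when ``key_fn``
    returns None, i.e. the mention does not normalize); an event expands to
    the union over its themes and cause. Cycles raise ``StructureError``.
    """

    def walk(a: Argument, stack: tuple[int, ...]) -> frozenset[NodeKey]:
        if isinstance(a, Mention):
            k = key_fn(a)
            return frozenset() if k is None else frozenset({k})
        if id(a) in stack:
            raise StructureError(f"cycle detected through event {a.event_id}")
        stack = stack + (id(a),)
        out: frozenset[NodeKey] = frozenset()
        for theme in a.themes:
            out |= walk(theme, stack)
        if a.cause is not None:
            out |= walk(a.cause, stack)
        return out

    return walk(arg, ())


# ---------------------------------------------------------------------------
# Pair enumeration
# ---------------------------------------------------------------------------

def pairs_from_event(e: Event, key_fn: KeyFn = mention_key) -> list[InteractionPair]:
    """Interaction pairs asserted by one event.

    Regulation with a cause: cross product of the cause-side and theme-side
    participant sets (self-pairs removed). Regulation without a cause:
    nothing. Binding: all unordered pairs over the distinct theme
    participants (< 2 distinct themes: nothing). Other event types carry no
    cause argument in the GE inventory and yield nothing.
    """
    category = _CATEGORY_FROM_TYPE.get(e.event_type)
    if category is None:
        return []
    prov = ((e.doc_id, e.event_id),)
    pairs: list[InteractionPair] = []
    if category is EventType.BINDING:
        participants: set[NodeKey] = set()
        for theme in e.themes:
            participants |= expand_participants(theme, key_fn)
        for a, b in combinations(sorted(participants, key=lambda k: (k[0], str(k[1]))), 2):
            pairs.append(make_pair(a, b, EventType.BINDING, prov))
        return pairs
    if e.cause is None:
        return []
    cause_side = expand_participants(e.cause, key_fn)
    theme_side: frozenset[NodeKey] = frozenset()
    for theme in e.themes:
        theme_side |= expand_participants(theme, key_fn)
    for c in sorted(cause_side, key=lambda k: (k[0], str(k[1]))):
        for t in sorted(theme_side, key=lambda k: (k[0], str(k[1]))):
            if c == t:
                continue
            pairs.append(make_pair(c, t, category, prov))
    return pairs


def extract_unique_pairs(
    events: Iterable[Event],
    key_fn: KeyFn = mention_key,
    key_includes_category: bool = True,
) -> set[InteractionPair]:
    """Deduplicate pairs corpus-wide, merging provenance sets.

    By default the uniqueness key is (unordered node pair, category); with
    ``key_includes_category=False`` pairs collapse on the node pair alone
    and the category of the first occurrence (in sorted order) is kept.
    """
    merged: dict[tuple, InteractionPair] = {}
    for ev in events:
        for pair in pairs_from_event(ev, key_fn):
            dk: tuple
            if key_includes_category:
                dk = (pair.node_a, pair.node_b, pair.category)
            else:
                dk = (pair.node_a, pair.node_b)
            if dk in merged:
                old = merged[dk]
                merged[dk] = InteractionPair(
                    old.node_a, old.node_b, old.category, old.provenance | pair.provenance
                )
            else:
                merged[dk] = pair
    return set(merged.values())


def write_pairs_tsv(pairs: Iterable[InteractionPair], path: str | Path) -> Path:
    """Export pairs as ``node_a  node_b  category  n_docs  doc_ids``."""
    from .standoff import node_label

    rows = []
    for p in sorted(pairs, key=lambda p: (str(p.node_a), str(p.node_b), p.category.value)):
        docs = sorted({doc for doc, _ev in p.provenance})
        rows.append(
            f"{node_label(p.node_a)}\t{node_label(p.node_b)}\t{p.category.value}"
            f"\t{len(docs)}\t{';'.join(docs)}"
        )
    out = Path(path)
    out.write_text("".join(r + "\n" for r in rows), encoding="utf-8")
    return out
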