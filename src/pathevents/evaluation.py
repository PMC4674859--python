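"""Precision / pseudo-recall / F1 evaluation and candidate-pair sampling.

Genuine recall over the full event space is not computable at literature
scale, so recall is estimated on a sampled candidate set: all same-document
<pathway, gene> mention pairs lying within a character-distance threshold
(default 100). Pseudo-recall is then TP/(TP+FN) over that sample.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import networkx as nx

from .events import expand_participants, KeyFn, mention_key
from .standoff import Document, EntityClass, Event, Mention, StandoffError

__all__ = [
    "UndefinedMetricError",
    "EvalCounts",
    "CandidatePair",
    "precision",
    "pseudo_recall",
    "f1_score",
    "char_distance",
    "sample_candidate_pairs",
    "events_equivalent",
    "score_events",
]


class UndefinedMetricError(StandoffError):
    """Raised when a ratio metric has a zero denominator."""


@dataclass(frozen=True)
class EvalCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def precision(c: EvalCounts) -> float:
    """TP / (TP + FP)."""
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: tp + fp == 0")
    return c.tp / (c.tp + c.fp)


def pseudo_recall(c: EvalCounts) -> float:
    """TP / (TP + FN), estimated on the sampled candidate set."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("pseudo-recall undefined: tp + fn == 0")
    return c.tp / (c.tp + c.fn)


def f1_score(p: float, r: float) -> float:
    """Harmonic mean 2pr/(p+r) of unrounded precision and recall."""
    if p + r == 0:
        raise UndefinedMetricError("F1 undefined: p + r == 0")
    return 2 * p * r / (p + r)


# ---------------------------------------------------------------------------
# Candidate-pair sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidatePair:
    doc_id: str
    pathway_mention: Mention
    gene_mention: Mention
    char_distance: int


def char_distance(a: Mention, b: Mention) -> int:
    """Characters strictly between the nearer span boundaries (0 if overlapping)."""
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def sample_candidate_pairs(
    docs: Sequence[Document],
    mentions: Iterable[Mention],
    n: int,
    seed: int,
    max_dist: int = 100,
) -> list[CandidatePair]:
    """Sample n <pathway, gene> pairs from the qualifying candidates.

    Qualifying pairs lie in the same document at character distance
    strictly below ``max_dist``. Enumeration order is deterministic, the
    draw is uniform without replacement under ``seed``, and when fewer than
    n pairs qualify they are all returned with a warning.
    """
    if n < 0:
        raise ValueError("sample size must be non-negative")
    doc_ids = {d.doc_id for d in docs}
    by_doc: dict[str, tuple[list[Mention], list[Mention]]] = {}
    for m in mentions:
        if m.doc_id not in doc_ids:
            continue
        genes, pathways = by_doc.setdefault(m.doc_id, ([], []))
        (genes if m.entity_class is EntityClass.GENE else pathways).append(m)

    universe: list[CandidatePair] = []
    for doc_id in sorted(by_doc):
        genes, pathways = by_doc[doc_id]
        for pw in sorted(pathways, key=lambda m: (m.start, m.end, m.mention_id)):
            for g in sorted(genes, key=lambda m: (m.start, m.end, m.mention_id)):
                dist = char_distance(pw, g)
                if dist < max_dist:
                    universe.append(CandidatePair(doc_id, pw, g, dist))

    if len(universe) <= n:
        if len(universe) < n:
            warnings.warn(
                f"only {len(universe)} candidate pairs qualify (requested {n})",
                stacklevel=2,
            )
        return universe
    rng = random.Random(seed)
    picked = sorted(rng.sample(range(len(universe)), n))
    return [universe[i] for i in picked]


# ---------------------------------------------------------------------------
# Event-level scoring
# ---------------------------------------------------------------------------

MatcherFn = Callable[[Event, Event], bool]


def events_equivalent(a: Event, b: Event, key_fn: KeyFn = mention_key) -> bool:
    """Same event type and identical per-role participant sets.

    Theme-side and cause-side participants are compared after recursive
    nested expansion — an event is correct only when the event and its
    arguments both are.
    """
    if a.event_type is not b.event_type:
        return False

    def side_sets(e: Event) -> tuple[frozenset, frozenset]:
        themes: frozenset = frozenset()
        for t in e.themes:
            themes |= expand_participants(t, key_fn)
        cause = (
            frozenset() if e.cause is None else expand_participants(e.cause, key_fn)
        )
        return themes, cause

    return side_sets(a) == side_sets(b)


def score_events(
    gold: Sequence[Event],
    predicted: Sequence[Event],
    matcher: MatcherFn | None = None,
    n_candidates: int | None = None,
) -> EvalCounts:
    """Confusion counts via maximum bipartite matching under ``matcher``.

    TP is the size of a maximum matching between predicted and gold events;
    unmatched predicted events are FP, unmatched gold events FN. TN (only
    meaningful for candidate-set evaluation) is the remainder of
    ``n_candidates`` when given, else 0.
    """
    if matcher is None:
        matcher = events_equivalent
    g = nx.Graph()
    pred_nodes = [("P", i) for i in range(len(predicted))]
    gold_nodes = [("G", j) for j in range(len(gold))]
    g.add_nodes_from(pred_nodes, bipartite=0)
    g.add_nodes_from(gold_nodes, bipartite=1)
    for i, p in enumerate(predicted):
        for j, q in enumerate(gold):
            if matcher(p, q):
                g.add_edge(("P", i), ("G", j))
    matching = nx.algorithms.bipartite.maximum_matching(g, top_nodes=pred_nodes)
    tp = sum(1 for node in matching if node[0] == "P")
    fp = len(predicted) - tp
    fn = len(gold) - tp
    tn = 0
    if n_candidates is not None:
        tn = max(0, n_candidates - tp - fp - fn)
    return EvalCounts(tp=tp, fp=fp, tn=tn, fn=fn)
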