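"""Synthetic corpora with planted ground-truth interactions.

The generator emits documents built from a small template grammar
("GEN3 activates PWX1 signaling.", "Overexpression of GEN7 inhibits
GEN2.", ...) together with the matching standoff annotations, a gene
lexicon and a pathway database, so every downstream stage — normalization,
event filtering, pair extraction, network construction — can be tested
end to end without external data.

Planted events follow the same restrictions the pipeline enforces:
pathway participants appear only in regulation-type events, binding events
have gene themes only. A configurable fraction of mentions is deliberately
given surfaces absent from the lexicons to exercise the discard rule; the
realized discard count is recorded in the ground truth.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .events import InteractionPair, make_pair, write_pairs_tsv
from .network import InteractionNetwork
from .normalize import NodeKey
from .standoff import (
    Document,
    EntityClass,
    Event,
    EventType,
    GeneLexicon,
    Mention,
    PathwayDB,
    PathwayRecord,
    Trigger,
    UsageError,
    write_a1,
    write_a2,
    write_document,
)

__all__ = [
    "FixtureConfig",
    "GroundTruth",
    "FixtureCorpus",
    "generate_corpus",
    "write_corpus",
    "expected_network",
]


@dataclass(frozen=True)
class FixtureConfig:
    n_docs: int = 100
    n_genes: int = 30
    n_pathways: int = 10
    min_events_per_doc: int = 1
    max_events_per_doc: int = 4
    nesting_probability: float = 0.2
    binding_fraction: float = 0.2
    pathway_theme_probability: float = 0.35
    pathway_cause_probability: float = 0.15
    membership_probability: float = 0.2
    unmappable_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "nesting_probability",
            "binding_fraction",
            "pathway_theme_probability",
            "pathway_cause_probability",
            "membership_probability",
            "unmappable_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise UsageError(f"{name} must lie in [0, 1], got {v}")
        if min(self.n_docs, self.n_genes, self.n_pathways) < 0:
            raise UsageError("counts must be non-negative")
        if not (1 <= self.min_events_per_doc <= self.max_events_per_doc):
            raise UsageError("need 1 <= min_events_per_doc <= max_events_per_doc")
        if self.n_docs > 0 and self.n_genes < 2:
            raise UsageError("at least 2 genes are needed to plant distinct pairs")


@dataclass
class GroundTruth:
    planted_pairs: set[InteractionPair]
    n_events: int
    discard_count: int
    #: mean over events of 1 - (1-u)^m, m = number of mention participants
    analytic_discard_expectation: float

    @property
    def discard_fraction(self) -> float:
        return self.discard_count / self.n_events if self.n_events else 0.0


@dataclass
class FixtureCorpus:
    documents: list[Document]
    mentions: dict[str, list[Mention]] = field(default_factory=dict)
    events: dict[str, list[Event]] = field(default_factory=dict)
    lexicon: GeneLexicon = field(default_factory=lambda: GeneLexicon({}))
    pathway_db: PathwayDB = field(default_factory=lambda: PathwayDB({}))
    ground_truth: GroundTruth = field(
        default_factory=lambda: GroundTruth(set(), 0, 0, 0.0)
    )


# ---------------------------------------------------------------------------
# Entity universes
# ---------------------------------------------------------------------------

def _gene_universe(n: int) -> dict[str, int]:
    """Gene symbols GEN1..GENn mapped to Entrez-style IDs 1001..1000+n."""
    return {f"GEN{i + 1}": 1001 + i for i in range(n)}


def _pathway_universe(n: int, genes: dict[str, int], rng: random.Random, p_member: float):
    """Pathways PWX1..PWXn with multi-source synonyms and random members."""
    records = {}
    surfaces = {}
    for i in range(n):
        stem = f"PWX{i + 1}"
        cid = f"pw{i + 1:03d}"
        members = frozenset(gid for gid in genes.values() if rng.random() < p_member)
        records[cid] = PathwayRecord(
            canonical_id=cid,
            canonical_name=f"{stem} signaling pathway",
            synonyms=frozenset(
                {
                    ("KEGG", f"{stem} signaling pathway"),
                    ("WikiPathways", f"{stem} pathway"),
                    ("Reactome", f"{stem} cascade"),
                }
            ),
            members=members,
        )
        surfaces[cid] = f"{stem} signaling"
    return PathwayDB(records), surfaces


# ---------------------------------------------------------------------------
# Document assembly
# ---------------------------------------------------------------------------

class _DocBuilder:
    def __init__(self, doc_id: str):
        self.doc_id = doc_id
        self.parts: list[str] = []
        self.pos = 0
        self.mentions: list[Mention] = []
        self.events: list[Event] = []
        self._tid = 0
        self._eid = 0

    def add(self, s: str) -> tuple[int, int]:
        start = self.pos
        self.parts.append(s)
        self.pos += len(s)
        return start, self.pos

    def mention(self, surface: str, cls: EntityClass) -> Mention:
        start, end = self.add(surface)
        self._tid += 1
        m = Mention(f"T{self._tid}", self.doc_id, start, end, surface, cls)
        self.mentions.append(m)
        return m

    def trigger(self, word: str, etype: EventType) -> Trigger:
        start, end = self.add(word)
        self._tid += 1
        return Trigger(f"T{self._tid}", etype, start, end, word)

    def event(self, etype: EventType, trig: Trigger, themes, cause=None) -> Event:
        self._eid += 1
        return Event(
            event_id=f"E{self._eid}",
            doc_id=self.doc_id,
            event_type=etype,
            trigger=trig,
            themes=tuple(themes),
            cause=cause,
        )

    def text(self) -> str:
        return "".join(self.parts)


@dataclass
class _Participant:
    surface: str
    cls: EntityClass
    key: NodeKey | None  # None when deliberately unmappable


_REG_VERBS = {
    EventType.POSITIVE_REGULATION: "activates",
    EventType.NEGATIVE_REGULATION: "inhibits",
    EventType.REGULATION: "regulates",
}


def generate_corpus(cfg: FixtureConfig) -> FixtureCorpus:
    """Generate a deterministic corpus with planted interactions.

    The same config (including seed) always produces byte-identical
    documents, annotations and tables.
    """
    rng = random.Random(cfg.seed)
    genes = _gene_universe(cfg.n_genes)
    db, pw_surfaces = _pathway_universe(cfg.n_pathways, genes, rng, cfg.membership_probability)
    lexicon = GeneLexicon({sym.casefold(): gid for sym, gid in genes.items()})
    gene_symbols = sorted(genes)
    pathway_ids = sorted(pw_surfaces)
    unk_counter = 0

    def sample_gene() -> _Participant:
        nonlocal unk_counter
        if cfg.unmappable_fraction and rng.random() < cfg.unmappable_fraction:
            unk_counter += 1
            return _Participant(f"XUNK{unk_counter}", EntityClass.GENE, None)
        sym = rng.choice(gene_symbols)
        return _Participant(sym, EntityClass.GENE, ("GENE", genes[sym]))

    def sample_pathway() -> _Participant:
        nonlocal unk_counter
        if cfg.unmappable_fraction and rng.random() < cfg.unmappable_fraction:
            unk_counter += 1
            return _Participant(f"QUNK{unk_counter} signaling", EntityClass.PATHWAY, None)
        cid = rng.choice(pathway_ids)
        return _Participant(pw_surfaces[cid], EntityClass.PATHWAY, ("PATHWAY", cid))

    documents: list[Document] = []
    mentions: dict[str, list[Mention]] = {}
    events: dict[str, list[Event]] = {}
    planted: dict[tuple, InteractionPair] = {}
    n_events = 0
    discard_count = 0
    expectation_sum = 0.0

    def plant(a: NodeKey, b: NodeKey, category: EventType, doc_id: str, eid: str) -> None:
        key = (*sorted((a, b), key=lambda k: (k[0], str(k[1]))), category)
        prov = frozenset({(doc_id, eid)})
        if key in planted:
            old = planted[key]
            planted[key] = InteractionPair(
                old.node_a, old.node_b, old.category, old.provenance | prov
            )
        else:
            planted[key] = make_pair(a, b, category, prov)

    for d in range(cfg.n_docs):
        doc_id = f"DOC{d + 1:05d}"
        b = _DocBuilder(doc_id)
        n_here = rng.randint(cfg.min_events_per_doc, cfg.max_events_per_doc)
        for _ in range(n_here):
            n_events += 1
            if rng.random() < cfg.binding_fraction:
                # Binding: 2 or 3 distinct gene themes, no pathway allowed.
                n_themes = 3 if rng.random() < 0.3 else 2
                parts = []
                seen: set[str] = set()
                while len(parts) < n_themes:
                    p = sample_gene()
                    if p.surface in seen:
                        continue
                    seen.add(p.surface)
                    parts.append(p)
                m_count = len(parts)
                theme_mentions = [b.mention(parts[0].surface, parts[0].cls)]
                b.add(" ")
                trig = b.trigger("interacts", EventType.BINDING)
                b.add(" with ")
                theme_mentions.append(b.mention(parts[1].surface, parts[1].cls))
                if n_themes == 3:
                    b.add(" and ")
                    theme_mentions.append(b.mention(parts[2].surface, parts[2].cls))
                b.add(". ")
                ev = b.event(EventType.BINDING, trig, theme_mentions)
                b.events.append(ev)
                clean = all(p.key is not None for p in parts)
                if clean:
                    keys = sorted({p.key for p in parts}, key=lambda k: (k[0], str(k[1])))
                    for i in range(len(keys)):
                        for j in range(i + 1, len(keys)):
                            plant(keys[i], keys[j], EventType.BINDING, doc_id, ev.event_id)
                else:
                    discard_count += 1
            else:
                etype = rng.choice(
                    (
                        EventType.POSITIVE_REGULATION,
                        EventType.NEGATIVE_REGULATION,
                        EventType.REGULATION,
                    )
                )
                theme = (
                    sample_pathway()
                    if rng.random() < cfg.pathway_theme_probability
                    else sample_gene()
                )
                while True:
                    cause = (
                        sample_pathway()
                        if rng.random() < cfg.pathway_cause_probability
                        else sample_gene()
                    )
                    if cause.surface != theme.surface:
                        break
                nested = (
                    cause.cls is EntityClass.GENE and rng.random() < cfg.nesting_probability
                )
                m_count = 2
                if nested:
                    # "Overexpression of C <verb> T. "
                    trig_inner = b.trigger("Overexpression", EventType.GENE_EXPRESSION)
                    b.add(" of ")
                    cause_m = b.mention(cause.surface, cause.cls)
                    b.add(" ")
                    trig_outer = b.trigger(_REG_VERBS[etype], etype)
                    b.add(" ")
                    theme_m = b.mention(theme.surface, theme.cls)
                    b.add(". ")
                    inner = b.event(EventType.GENE_EXPRESSION, trig_inner, [cause_m])
                    outer = b.event(etype, trig_outer, [theme_m], cause=inner)
                    b.events.append(outer)
                    ev_id = outer.event_id
                else:
                    cause_m = b.mention(cause.surface, cause.cls)
                    b.add(" ")
                    trig_outer = b.trigger(_REG_VERBS[etype], etype)
                    b.add(" ")
                    theme_m = b.mention(theme.surface, theme.cls)
                    b.add(". ")
                    ev = b.event(etype, trig_outer, [theme_m], cause=cause_m)
                    b.events.append(ev)
                    ev_id = ev.event_id
                if cause.key is not None and theme.key is not None:
                    plant(cause.key, theme.key, etype, doc_id, ev_id)
                else:
                    discard_count += 1
            u = cfg.unmappable_fraction
            expectation_sum += 1.0 - (1.0 - u) ** m_count
        documents.append(Document(doc_id, b.text()))
        mentions[doc_id] = b.mentions
        events[doc_id] = b.events

    gt = GroundTruth(
        planted_pairs=set(planted.values()),
        n_events=n_events,
        discard_count=discard_count,
        analytic_discard_expectation=(expectation_sum / n_events if n_events else 0.0),
    )
    return FixtureCorpus(
        documents=documents,
        mentions=mentions,
        events=events,
        lexicon=lexicon,
        pathway_db=db,
        ground_truth=gt,
    )


def write_corpus(corpus: FixtureCorpus, out_dir: str | Path) -> Path:
    """Write the corpus directory: txt/a1/a2 per document plus the tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for doc in corpus.documents:
        write_document(doc, out)
        write_a1(corpus.mentions[doc.doc_id], out / f"{doc.doc_id}.a1")
        write_a2(corpus.events[doc.doc_id], out / f"{doc.doc_id}.a2")
    lex_lines = [
        f"{surface}\t{gid}" for surface, gid in sorted(corpus.lexicon.mapping.items())
    ]
    (out / "gene_lexicon.tsv").write_text(
        "".join(line + "\n" for line in lex_lines), encoding="utf-8"
    )
    db_lines = []
    for cid in sorted(corpus.pathway_db.records):
        rec = corpus.pathway_db.records[cid]
        members = ";".join(str(g) for g in sorted(rec.members))
        for source, name in sorted(rec.synonyms):
            db_lines.append(f"{cid}\t{rec.canonical_name}\t{source}\t{name}\t{members}")
    (out / "pathway_db.tsv").write_text(
        "".join(line + "\n" for line in db_lines), encoding="utf-8"
    )
    write_pairs_tsv(corpus.ground_truth.planted_pairs, out / "planted_pairs.tsv")
    return out


def expected_network(
    gt: GroundTruth, db: PathwayDB, expand_members: bool = False
) -> InteractionNetwork:
    """Naive reference construction of the merged network.

    Applies the two edge rules (text-mined pairs, curated membership) with
    plain nested loops; used as the independent oracle for the network
    builder.
    """
    from .events import CATEGORY_RELATION

    net = InteractionNetwork()
    for pair in sorted(
        gt.planted_pairs, key=lambda p: (str(p.node_a), str(p.node_b), p.category.value)
    ):
        net.add_edge(
            pair.node_a, pair.node_b, relation=CATEGORY_RELATION[pair.category], origin="TEXT_MINED"
        )
    gene_nodes = [n for n in sorted(net.nodes(), key=str) if n[0] == "GENE"]
    pathway_nodes = [n for n in sorted(net.nodes(), key=str) if n[0] == "PATHWAY"]
    for pw in pathway_nodes:
        rec = db.get(pw[1])  # type: ignore[arg-type]
        if rec is None:
            continue
        if expand_members:
            for gid in sorted(rec.members):
                net.add_edge(("GENE", gid), pw, relation="member_of", origin="CURATED")
        else:
            for gene in gene_nodes:
                if gene[1] in rec.members:
                    net.add_edge(gene, pw, relation="member_of", origin="CURATED")
    return net
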