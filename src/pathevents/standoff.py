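"""BioNLP-ST standoff I/O: documents, mentions, events, lexicons, and SIF.

The standoff dialect is the one used by GENIA-style event extractors:
``<doc>.txt`` holds the raw text, ``<doc>.a1`` the entity mentions
(``Tid<TAB>Type start end<TAB>surface``), and ``<doc>.a2`` the event
triggers plus event lines (``Eid<TAB>Type:Ttrig Theme:X Cause:Y``).
Offsets are 0-based, half-open, and measured in characters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Union

__all__ = [
    "StandoffError",
    "FormatError",
    "ParseError",
    "IntegrityError",
    "LoadError",
    "UsageError",
    "EntityClass",
    "EventType",
    "REGULATION_TYPES",
    "Document",
    "Mention",
    "Trigger",
    "Event",
    "Argument",
    "GeneLexicon",
    "PathwayRecord",
    "PathwayDB",
    "read_document",
    "write_document",
    "read_a1",
    "write_a1",
    "read_a2",
    "write_a2",
    "read_gene_lexicon",
    "read_pathway_db",
    "read_sif",
    "write_sif",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class StandoffError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(StandoffError):
    """A file could not be decoded or does not exist."""


class ParseError(StandoffError):
    """A line does not match the expected standoff / TSV syntax."""


class IntegrityError(StandoffError):
    """Parsed content contradicts the document it annotates."""


class LoadError(StandoffError):
    """A mapping table contains conflicting or invalid rows."""


class UsageError(StandoffError):
    """An operation was called with arguments violating its contract."""


# ---------------------------------------------------------------------------
# Enums and domain types
# ---------------------------------------------------------------------------

class EntityClass(str, Enum):
    GENE = "GENE"
    PATHWAY = "PATHWAY"


class EventType(str, Enum):
    """The nine GENIA GE event types."""

    GENE_EXPRESSION = "Gene_expression"
    TRANSCRIPTION = "Transcription"
    PROTEIN_CATABOLISM = "Protein_catabolism"
    PHOSPHORYLATION = "Phosphorylation"
    LOCALIZATION = "Localization"
    BINDING = "Binding"
    REGULATION = "Regulation"
    POSITIVE_REGULATION = "Positive_regulation"
    NEGATIVE_REGULATION = "Negative_regulation"


#: Event types a pathway entity may legitimately participate in.
REGULATION_TYPES = frozenset(
    {EventType.REGULATION, EventType.POSITIVE_REGULATION, EventType.NEGATIVE_REGULATION}
)


@dataclass(frozen=True)
class Document:
    doc_id: str
    text: str

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise UsageError("doc_id must be non-empty")


@dataclass(frozen=True)
class Mention:
    """A typed text span (gene/protein or pathway) in one document."""

    mention_id: str
    doc_id: str
    start: int
    end: int
    surface: str
    entity_class: EntityClass

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise UsageError(
                f"invalid span [{self.start}, {self.end}) for mention {self.mention_id}"
            )

    def overlaps(self, other: "Mention") -> bool:
        """True when the two spans share at least one character."""
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class Trigger:
    """Keyword span signalling an event's presence (e.g. "activates")."""

    trigger_id: str
    event_type: EventType
    start: int
    end: int
    text: str


Argument = Union[Mention, "Event"]


@dataclass(frozen=True)
class Event:
    """A typed relation with Theme and optional Cause arguments.

    Arguments may be mentions or nested events; the reference structure is
    cycle-free by construction (the parser rejects cycles).
    """

    event_id: str
    doc_id: str
    event_type: EventType
    trigger: Trigger
    themes: tuple[Argument, ...] = ()
    cause: Argument | None = None
    # Roles parsed but not interpreted (e.g. Site of a phosphorylation);
    # kept as raw (role, reference-id) pairs so writing round-trips.
    extra_args: tuple[tuple[str, str], ...] = ()


# ---------------------------------------------------------------------------
# Lexicon and pathway database tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneLexicon:
    """Surface form -> Entrez Gene ID mapping (lookup is case-folded)."""

    mapping: Mapping[str, int]

    def lookup(self, surface: str) -> int | None:
        return self.mapping.get(surface.casefold())

    def __len__(self) -> int:
        return len(self.mapping)

    def __contains__(self, surface: str) -> bool:
        return surface.casefold() in self.mapping


@dataclass(frozen=True)
class PathwayRecord:
    canonical_id: str
    canonical_name: str
    synonyms: frozenset[tuple[str, str]]  # (source_db, name)
    members: frozenset[int]  # Entrez Gene IDs, unioned across sources


@dataclass(frozen=True)
class PathwayDB:
    records: Mapping[str, PathwayRecord]

    def __len__(self) -> int:
        return len(self.records)

    def get(self, canonical_id: str) -> PathwayRecord | None:
        return self.records.get(canonical_id)

    def synonym_names(self) -> Iterable[tuple[str, PathwayRecord]]:
        """Yield every (synonym name, record) pair, canonical names included."""
        for rec in self.records.values():
            yield rec.canonical_name, rec
            for _src, name in sorted(rec.synonyms):
                yield name, rec


# ---------------------------------------------------------------------------
# Documents
# ---------------------------------------------------------------------------

def read_document(txt_path: str | Path) -> Document:
    """Read ``<doc_id>.txt``; the doc_id is the filename stem."""
    path = Path(txt_path)
    if not path.exists():
        raise FormatError(f"document file not found: {path}")
    try:
        text = path.read_text(encoding="utf-8")
    except UnicodeDecodeError as exc:
        raise FormatError(f"not valid UTF-8: {path}") from exc
    return Document(doc_id=path.stem, text=text)


def write_document(doc: Document, out_dir: str | Path) -> Path:
    path = Path(out_dir) / f"{doc.doc_id}.txt"
    path.write_text(doc.text, encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# .a1 entity files
# ---------------------------------------------------------------------------

_A1_TYPES = {"Protein": EntityClass.GENE, "Pathway": EntityClass.PATHWAY}
_A1_LINE = re.compile(r"^(T\S*)\t(\S+) (\d+) (\d+)\t(.*)$")


def read_a1(a1_path: str | Path, doc: Document, strict_types: bool = True) -> list[Mention]:
    """Parse entity mentions, validating spans against the document text.

    ``Protein`` lines map to :class:`EntityClass.GENE`, ``Pathway`` lines to
    :class:`EntityClass.PATHWAY`. Unknown entity types raise when
    ``strict_types`` is set and are skipped (flagged via the return of
    :func:`read_a1_flagged`) otherwise.
    """
    mentions, _ = read_a1_flagged(a1_path, doc, strict_types=strict_types)
    return mentions


def read_a1_flagged(
    a1_path: str | Path, doc: Document, strict_types: bool = True
) -> tuple[list[Mention], list[str]]:
    path = Path(a1_path)
    if not path.exists():
        raise FormatError(f"a1 file not found: {path}")
    mentions: list[Mention] = []
    flagged: list[str] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        m = _A1_LINE.match(line)
        if m is None:
            raise ParseError(f"{path}:{lineno}: malformed a1 line: {line!r}")
        tid, etype, start_s, end_s, surface = m.groups()
        start, end = int(start_s), int(end_s)
        if etype not in _A1_TYPES:
            flagged.append(line)
            if strict_types:
                raise ParseError(f"{path}:{lineno}: unknown entity type {etype!r}")
            continue
        if not (0 <= start < end <= len(doc.text)):
            raise IntegrityError(
                f"{path}:{lineno}: span [{start}, {end}) outside document "
                f"{doc.doc_id!r} of length {len(doc.text)}"
            )
        if doc.text[start:end] != surface:
            raise IntegrityError(
                f"{path}:{lineno}: surface {surface!r} does not match document "
                f"text {doc.text[start:end]!r}"
            )
        mentions.append(
            Mention(
                mention_id=tid,
                doc_id=doc.doc_id,
                start=start,
                end=end,
                surface=surface,
                entity_class=_A1_TYPES[etype],
            )
        )
    return mentions, flagged


_CLASS_TO_A1 = {EntityClass.GENE: "Protein", EntityClass.PATHWAY: "Pathway"}


def a1_lines(mentions: Iterable[Mention], disguise_as_protein: bool = False) -> str:
    """Serialize mentions to .a1 content (deterministic, input order)."""
    lines = []
    for m in mentions:
        etype = "Protein" if disguise_as_protein else _CLASS_TO_A1[m.entity_class]
        lines.append(f"{m.mention_id}\t{etype} {m.start} {m.end}\t{m.surface}")
    return "\n".join(lines) + ("\n" if lines else "")


def write_a1(mentions: Iterable[Mention], a1_path: str | Path) -> Path:
    path = Path(a1_path)
    path.write_text(a1_lines(mentions), encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# .a2 trigger + event files
# ---------------------------------------------------------------------------

_A2_TRIGGER = re.compile(r"^(T\S*)\t(\S+) (\d+) (\d+)\t(.*)$")
_A2_EVENT = re.compile(r"^(E\S*)\t(\S+):(\S+)((?: \S+:\S+)*)$")
_THEME_ROLE = re.compile(r"^Theme\d*$")


def read_a2(a2_path: str | Path, mentions: list[Mention], doc_id: str | None = None) -> list[Event]:
    """Parse triggers and events, resolving nested references.

    Returns every event declared in the file (nested sub-events included),
    in file order. Dangling references and reference cycles are rejected.
    """
    path = Path(a2_path)
    if not path.exists():
        raise FormatError(f"a2 file not found: {path}")
    if doc_id is None:
        doc_id = mentions[0].doc_id if mentions else path.stem
    mention_by_id = {m.mention_id: m for m in mentions}

    triggers: dict[str, Trigger] = {}
    raw_events: dict[str, tuple[EventType, str, list[tuple[str, str]]]] = {}
    order: list[str] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        if line.startswith("T"):
            m = _A2_TRIGGER.match(line)
            if m is None:
                raise ParseError(f"{path}:{lineno}: malformed trigger line: {line!r}")
            tid, etype_s, start_s, end_s, text = m.groups()
            try:
                etype = EventType(etype_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: unknown event type {etype_s!r}") from exc
            triggers[tid] = Trigger(tid, etype, int(start_s), int(end_s), text)
        elif line.startswith("E"):
            m = _A2_EVENT.match(line)
            if m is None:
                raise ParseError(f"{path}:{lineno}: malformed event line: {line!r}")
            eid, etype_s, trig_id, rest = m.groups()
            try:
                etype = EventType(etype_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: unknown event type {etype_s!r}") from exc
            args = [tuple(a.split(":", 1)) for a in rest.split()] if rest.strip() else []
            if eid in raw_events:
                raise ParseError(f"{path}:{lineno}: duplicate event id {eid}")
            raw_events[eid] = (etype, trig_id, args)  # type: ignore[assignment]
            order.append(eid)
        else:
            raise ParseError(f"{path}:{lineno}: unrecognized a2 line: {line!r}")

    resolved: dict[str, Event] = {}

    def resolve(eid: str, stack: tuple[str, ...]) -> Event:
        if eid in resolved:
            return resolved[eid]
        if eid in stack:
            raise IntegrityError(f"{path}: cyclic event reference through {eid}")
        if eid not in raw_events:
            raise IntegrityError(f"{path}: dangling event reference {eid}")
        etype, trig_id, args = raw_events[eid]
        if trig_id not in triggers:
            raise IntegrityError(f"{path}: event {eid} references undeclared trigger {trig_id}")
        if triggers[trig_id].event_type is not etype:
            raise IntegrityError(
                f"{path}: event {eid} type {etype.value} disagrees with trigger {trig_id}"
            )
        themes: list[Argument] = []
        cause: Argument | None = None
        extra: list[tuple[str, str]] = []

        def resolve_ref(ref: str) -> Argument:
            if ref.startswith("E"):
                return resolve(ref, stack + (eid,))
            if ref in mention_by_id:
                return mention_by_id[ref]
            raise IntegrityError(f"{path}: event {eid} references undeclared entity {ref}")

        for role, ref in args:
            if _THEME_ROLE.match(role):
                themes.append(resolve_ref(ref))
            elif role == "Cause":
                if cause is not None:
                    raise ParseError(f"{path}: event {eid} has multiple Cause arguments")
                cause = resolve_ref(ref)
            else:
                extra.append((role, ref))
        ev = Event(
            event_id=eid,
            doc_id=doc_id,
            event_type=etype,
            trigger=triggers[trig_id],
            themes=tuple(themes),
            cause=cause,
            extra_args=tuple(extra),
        )
        resolved[eid] = ev
        return ev

    return [resolve(eid, ()) for eid in order]


def a2_lines(events: Iterable[Event]) -> str:
    """Serialize events (with their nested sub-events and triggers) to .a2."""
    triggers: dict[str, Trigger] = {}
    event_lines: dict[str, str] = {}
    order: list[str] = []

    def emit(ev: Event) -> None:
        if ev.event_id in event_lines:
            return
        triggers[ev.trigger.trigger_id] = ev.trigger
        parts = [f"{ev.event_id}\t{ev.event_type.value}:{ev.trigger.trigger_id}"]
        args = []
        for i, theme in enumerate(ev.themes):
            role = "Theme" if i == 0 else f"Theme{i + 1}"
            ref = theme.event_id if isinstance(theme, Event) else theme.mention_id
            args.append(f"{role}:{ref}")
            if isinstance(theme, Event):
                emit(theme)
        if ev.cause is not None:
            ref = ev.cause.event_id if isinstance(ev.cause, Event) else ev.cause.mention_id
            args.append(f"Cause:{ref}")
            if isinstance(ev.cause, Event):
                emit(ev.cause)
        for role, ref in ev.extra_args:
            args.append(f"{role}:{ref}")
        event_lines[ev.event_id] = parts[0] + (" " + " ".join(args) if args else "")
        order.append(ev.event_id)

    for ev in events:
        emit(ev)

    lines = [
        f"{t.trigger_id}\t{t.event_type.value} {t.start} {t.end}\t{t.text}"
        for t in sorted(triggers.values(), key=lambda t: (t.start, t.trigger_id))
    ]
    lines += [event_lines[eid] for eid in sorted(order)]
    return "\n".join(lines) + ("\n" if lines else "")


def write_a2(events: Iterable[Event], a2_path: str | Path) -> Path:
    path = Path(a2_path)
    path.write_text(a2_lines(events), encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Gene lexicon and pathway database TSVs
# ---------------------------------------------------------------------------

def read_gene_lexicon(tsv_path: str | Path) -> GeneLexicon:
    """Load ``surface<TAB>entrez_id`` rows.

    Duplicate rows with identical mapping are tolerated; the same
    (case-folded) surface mapping to two different IDs is a hard error.
    """
    path = Path(tsv_path)
    if not path.exists():
        raise FormatError(f"gene lexicon not found: {path}")
    mapping: dict[str, int] = {}
    conflicts: list[str] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        surface, id_s = parts
        try:
            gene_id = int(id_s)
        except ValueError as exc:
            raise LoadError(f"{path}:{lineno}: non-integer gene ID {id_s!r}") from exc
        if gene_id <= 0:
            raise LoadError(f"{path}:{lineno}: gene ID must be positive, got {gene_id}")
        key = surface.casefold()
        if key in mapping and mapping[key] != gene_id:
            conflicts.append(f"{surface!r} -> {mapping[key]} vs {gene_id}")
        else:
            mapping[key] = gene_id
    if conflicts:
        raise LoadError(f"{path}: conflicting gene mappings: " + "; ".join(conflicts))
    return GeneLexicon(mapping=mapping)


def read_pathway_db(tsv_path: str | Path) -> PathwayDB:
    """Load pathway records, unioning synonym and member sets per canonical_id.

    Columns: ``canonical_id  canonical_name  source_db  synonym  member_ids``
    (member_ids semicolon-separated Entrez IDs).
    """
    path = Path(tsv_path)
    if not path.exists():
        raise FormatError(f"pathway db not found: {path}")
    names: dict[str, str] = {}
    synonyms: dict[str, set[tuple[str, str]]] = {}
    members: dict[str, set[int]] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ParseError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
        cid, cname, source, synonym, member_s = parts
        names.setdefault(cid, cname)
        synonyms.setdefault(cid, set()).add((source, synonym))
        for tok in member_s.split(";"):
            tok = tok.strip()
            if not tok:
                continue
            try:
                gid = int(tok)
            except ValueError as exc:
                raise LoadError(f"{path}:{lineno}: non-integer member ID {tok!r}") from exc
            if gid <= 0:
                raise LoadError(f"{path}:{lineno}: member ID must be positive, got {gid}")
            members.setdefault(cid, set()).add(gid)
    records = {
        cid: PathwayRecord(
            canonical_id=cid,
            canonical_name=names[cid],
            synonyms=frozenset(synonyms.get(cid, set())),
            members=frozenset(members.get(cid, set())),
        )
        for cid in names
    }
    return PathwayDB(records=records)


# ---------------------------------------------------------------------------
# SIF (Simple Interaction Format)
# ---------------------------------------------------------------------------

# Gene nodes print as bare Entrez integers; pathway nodes carry a "PW:" prefix
# so the two namespaces can never collide.

SIF_RELATIONS = ("reg", "pos_reg", "neg_reg", "binding", "member_of")


def node_label(key: tuple[str, object]) -> str:
    kind, ident = key
    if kind == "GENE":
        return str(ident)
    return f"PW:{ident}"


def parse_node_label(label: str) -> tuple[str, object]:
    if label.startswith("PW:"):
        return ("PATHWAY", label[3:])
    try:
        return ("GENE", int(label))
    except ValueError as exc:
        raise ParseError(f"unparseable SIF node label {label!r}") from exc


def write_sif(network: "InteractionNetwork", path: str | Path) -> Path:  # noqa: F821
    """Write one tab-separated triple per edge, sorted lexicographically."""
    lines = []
    for a, b, relation in network.edge_triples():
        if relation == "member_of":
            # member_of is printed gene-first so the triple reads "A member_of C"
            gene, pw = (a, b) if a[0] == "GENE" else (b, a)
            lines.append(f"{node_label(gene)}\t{relation}\t{node_label(pw)}")
        else:
            la, lb = sorted((node_label(a), node_label(b)))
            lines.append(f"{la}\t{relation}\t{lb}")
    out = Path(path)
    out.write_text("".join(line + "\n" for line in sorted(lines)), encoding="utf-8")
    return out


def read_sif(path: str | Path) -> "InteractionNetwork":  # noqa: F821
    """Read a SIF file back into a network.

    Edge origin is recovered from the relation: ``member_of`` edges are
    curated, all others text-mined.
    """
    from .network import InteractionNetwork  # local import avoids a cycle

    p = Path(path)
    if not p.exists():
        raise FormatError(f"SIF file not found: {p}")
    net = InteractionNetwork()
    for lineno, line in enumerate(p.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ParseError(f"{p}:{lineno}: expected 3 columns, got {len(parts)}")
        la, relation, lb = parts
        if relation not in SIF_RELATIONS:
            raise ParseError(f"{p}:{lineno}: unknown relation {relation!r}")
        a, b = parse_node_label(la), parse_node_label(lb)
        origin = "CURATED" if relation == "member_of" else "TEXT_MINED"
        net.add_edge(a, b, relation=relation, origin=origin)
    return net


def mentions_equal_modulo_id(a: Mention, b: Mention) -> bool:
    return replace(a, mention_id="x") == replace(b, mention_id="x")
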