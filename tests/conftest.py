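import random

import pytest
from hypothesis import settings

from pathevents.standoff import (
    Document,
    EntityClass,
    Event,
    EventType,
    Mention,
    PathwayDB,
    PathwayRecord,
    Trigger,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# Hand-built worked examples
# ---------------------------------------------------------------------------

@pytest.fixture
def nested_regulation_event():
    """Depth-2 event: deficiency of HIPK2 (cause) drives Gal-3 overexpression."""
    doc_id = "21698151"
    hipk2 = Mention("T1", doc_id, 0, 5, "HIPK2", EntityClass.GENE)
    gal3 = Mention("T2", doc_id, 59, 64, "Gal-3", EntityClass.GENE)
    theme_ev = Event(
        "E1",
        doc_id,
        EventType.GENE_EXPRESSION,
        Trigger("T3", EventType.GENE_EXPRESSION, 65, 79, "overexpression"),
        themes=(gal3,),
    )
    cause_ev = Event(
        "E2",
        doc_id,
        EventType.NEGATIVE_REGULATION,
        Trigger("T4", EventType.NEGATIVE_REGULATION, 6, 16, "deficiency"),
        themes=(hipk2,),
    )
    return Event(
        "E3",
        doc_id,
        EventType.POSITIVE_REGULATION,
        Trigger("T5", EventType.POSITIVE_REGULATION, 26, 37, "responsible"),
        themes=(theme_ev,),
        cause=cause_ev,
    )


@pytest.fixture
def pathway_theme_event():
    """Downregulation of uPAR inhibits FAK/PI3K/Akt signaling (pathway theme)."""
    doc_id = "21191179"
    text = "Downregulation of uPAR inhibits migration, invasion, proliferation, FAK/PI3K/Akt signaling"
    upar = Mention("T1", doc_id, 18, 22, "uPAR", EntityClass.GENE)
    pw = Mention("T2", doc_id, 68, 90, "FAK/PI3K/Akt signaling", EntityClass.PATHWAY)
    assert text[18:22] == "uPAR" and text[68:90] == "FAK/PI3K/Akt signaling"
    cause_ev = Event(
        "E1",
        doc_id,
        EventType.NEGATIVE_REGULATION,
        Trigger("T3", EventType.NEGATIVE_REGULATION, 0, 14, "Downregulation"),
        themes=(upar,),
    )
    return Event(
        "E2",
        doc_id,
        EventType.NEGATIVE_REGULATION,
        Trigger("T4", EventType.NEGATIVE_REGULATION, 23, 31, "inhibits"),
        themes=(pw,),
        cause=cause_ev,
    )


@pytest.fixture
def tiny_pathway_db():
    return PathwayDB(
        {
            "wnt": PathwayRecord(
                "wnt",
                "Wnt signaling pathway",
                frozenset(
                    {
                        ("KEGG", "Wnt signaling pathway"),
                        ("WikiPathways", "Wnt signaling"),
                        ("PID", "Wnt pathway"),
                        ("BioCarta", "Wnt cascade"),
                    }
                ),
                frozenset({1, 2, 3}),
            ),
            "camp": PathwayRecord(
                "camp",
                "cAMP cascade",
                frozenset({("KEGG", "cAMP cascade")}),
                frozenset({10, 11}),
            ),
            "pi3k": PathwayRecord(
                "pi3k",
                "PI3K/Akt pathway",
                frozenset({("KEGG", "PI3K-Akt signaling pathway")}),
                frozenset({207, 5979}),
            ),
        }
    )


# ---------------------------------------------------------------------------
# Random structure generators (seeded)
# ---------------------------------------------------------------------------

def random_document(rng: random.Random, n_words: int = 30) -> Document:
    words = [rng.choice(["alpha", "BRAF", "kinase", "cell", "Wnt", "growth"]) for _ in range(n_words)]
    return Document(f"D{rng.randrange(10**6)}", " ".join(words))


def random_mentions(rng: random.Random, doc: Document, n: int) -> list[Mention]:
    """Non-overlapping valid mentions over the document."""
    out = []
    pos = 0
    i = 0
    while len(out) < n and pos < len(doc.text) - 2:
        start = pos + rng.randrange(0, 3)
        length = rng.randrange(1, 6)
        end = min(start + length, len(doc.text))
        if start >= end:
            break
        i += 1
        out.append(
            Mention(
                f"T{i}",
                doc.doc_id,
                start,
                end,
                doc.text[start:end],
                rng.choice([EntityClass.GENE, EntityClass.PATHWAY]),
            )
        )
        pos = end + rng.randrange(1, 4)
    return out


def random_event_forest(
    rng: random.Random, mentions: list[Mention], n_events: int, max_depth: int = 3
) -> list[Event]:
    """Cycle-free events over the given mentions; nested with some probability."""
    doc_id = mentions[0].doc_id
    counter = {"e": 0, "t": 100}

    def new_event(depth: int) -> Event:
        counter["e"] += 1
        counter["t"] += 1
        eid = f"E{counter['e']}"
        etype = rng.choice(list(EventType))
        trig_start = rng.randrange(0, 20)
        trig = Trigger(f"T{counter['t']}", etype, trig_start, trig_start + 4, "trig")

        def arg(d):
            if d < max_depth and rng.random() < 0.35:
                return new_event(d + 1)
            return rng.choice(mentions)

        if etype is EventType.BINDING:
            themes = tuple(rng.choice(mentions) for _ in range(rng.randrange(1, 4)))
            return Event(eid, doc_id, etype, trig, themes=themes)
        themes = (arg(depth),)
        cause = arg(depth) if rng.random() < 0.6 else None
        return Event(eid, doc_id, etype, trig, themes=themes, cause=cause)

    return [new_event(0) for _ in range(n_events)]
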