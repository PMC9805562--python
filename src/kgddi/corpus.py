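"""Relation-extraction corpus handling: DDIExtraction-2013-style XML and a
normalized JSON dialect, candidate-pair enumeration, target-pair masking, and
mention-to-KG linking with coverage statistics.

A sentence with n drug mentions yields C(n,2) classification instances.  For
each instance the target pair is rewritten as DRUG1/DRUG2 (in sentence
order) and every other mention as DRUGOTHER, e.g.

    Exposure to oral DRUG1 is unaffected by DRUG2 but greatly increased by
    DRUGOTHER.

Mentions are linked to KG entities by normalized exact string match over
names and synonyms; GROUP-type mentions match category/ATC vocabulary, all
others match drug vocabulary.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

from .kg_store import EntityType, KnowledgeGraph

__all__ = [
    "Mention",
    "Sentence",
    "Document",
    "RelationInstance",
    "LabelSet",
    "DDI_LABELS",
    "LinkingTable",
    "read_corpus",
    "read_corpus_json",
    "write_corpus_json",
    "enumerate_pairs",
    "mask_sentence",
    "make_instances",
    "build_linking_table",
    "link_mention",
    "coverage",
    "write_instances_jsonl",
    "read_instances_jsonl",
]

MASK1, MASK2, MASK_OTHER = "DRUG1", "DRUG2", "DRUGOTHER"


@dataclass(frozen=True)
class Mention:
    id: str
    start: int  # 0-based, half-open
    end: int
    text: str
    mention_type: str = "DRUG"

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class Sentence:
    id: str
    text: str
    mentions: list[Mention] = field(default_factory=list)
    pairs: list[tuple[str, str, str]] = field(default_factory=list)  # (m1, m2, label)


@dataclass
class Document:
    id: str
    sentences: list[Sentence] = field(default_factory=list)


@dataclass
class RelationInstance:
    sentence_masked: str
    m1: Mention
    m2: Mention
    label: str
    kg1: str | None = None
    kg2: str | None = None
    provenance: dict = field(default_factory=dict)


@dataclass(frozen=True)
class LabelSet:
    positives: tuple[str, ...]
    negative_label: str = "negative"

    def __post_init__(self) -> None:
        if self.negative_label in self.positives:
            raise ValueError("negative label must not be a positive class")

    @property
    def all_labels(self) -> tuple[str, ...]:
        return self.positives + (self.negative_label,)

    @property
    def c(self) -> int:
        return len(self.positives) + 1

    def canonicalize(self, raw: str) -> str:
        low = raw.strip().lower()
        for lab in self.all_labels:
            if lab.lower() == low:
                return lab
        # shared-task spelling variants
        aliases = {"int.": "Int", "interaction": "Int", "advise": "Advice"}
        if low in aliases and aliases[low] in self.all_labels:
            return aliases[low]
        if low in ("false", "none", "no", "neg"):
            return self.negative_label
        raise KeyError(f"label {raw!r} not in label set {self.all_labels}")


#: The DDIExtraction-2013 label set: four positive interaction types plus the
#: negative (no-interaction) class, c = 5.
DDI_LABELS = LabelSet(positives=("Mechanism", "Effect", "Advice", "Int"))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _parse_char_offset(raw: str) -> tuple[int, int]:
    """Shared-task offsets are inclusive 'start-end', possibly discontinuous
    ('a-b;c-d'); we keep the first contiguous segment and convert to 0-based
    half-open."""
    first = raw.split(";")[0]
    m = re.fullmatch(r"(\d+)-(\d+)", first.strip())
    if not m:
        raise ValueError(f"malformed charOffset {raw!r}")
    start, end_inclusive = int(m.group(1)), int(m.group(2))
    return start, end_inclusive + 1


def read_corpus(xml_path: str | Path, labelset: LabelSet = DDI_LABELS) -> list[Document]:
    """Parse DDIExtraction-2013-dialect XML (document/sentence/entity/pair)."""
    tree = etree.parse(str(xml_path))
    docs: list[Document] = []
    for dnode in tree.getroot().iter("document"):
        doc = Document(id=dnode.get("id", f"d{len(docs)}"))
        for snode in dnode.iter("sentence"):
            sent = Sentence(id=snode.get("id", ""), text=snode.get("text", ""))
            seen_spans: set[tuple[int, int]] = set()
            for enode in snode.iter("entity"):
                eid = enode.get("id", "")
                start, end = _parse_char_offset(enode.get("charOffset", ""))
                if end > len(sent.text) or start < 0:
                    raise ValueError(
                        f"entity {eid!r}: offset {start}-{end} outside sentence "
                        f"(length {len(sent.text)})"
                    )
                if (start, end) in seen_spans:  # duplicate annotation
                    continue
                seen_spans.add((start, end))
                sent.mentions.append(
                    Mention(
                        id=eid,
                        start=start,
                        end=end,
                        text=sent.text[start:end],
                        mention_type=enode.get("type", "DRUG").upper(),
                    )
                )
            for pnode in snode.iter("pair"):
                ddi = pnode.get("ddi", "false").lower() == "true"
                raw = pnode.get("type") if ddi else labelset.negative_label
                label = labelset.canonicalize(raw or labelset.negative_label)
                sent.pairs.append((pnode.get("e1"), pnode.get("e2"), label))
            doc.sentences.append(sent)
        docs.append(doc)
    return docs


def read_corpus_json(path: str | Path) -> list[Document]:
    """Normalized JSON dialect: {"documents": [{"id", "sentences": [{"id",
    "text", "mentions": [{"id","start","end","type","text"}], "pairs":
    [{"m1","m2","label"}]}]}]}."""
    payload = json.loads(Path(path).read_text())
    docs = []
    for d in payload["documents"]:
        doc = Document(id=d["id"])
        for s in d["sentences"]:
            sent = Sentence(id=s["id"], text=s["text"])
            for m in s.get("mentions", []):
                text = sent.text[m["start"] : m["end"]]
                if "text" in m and m["text"] != text:
                    raise ValueError(
                        f"mention {m['id']!r}: stored text {m['text']!r} does not "
                        f"match span {text!r}"
                    )
                if m["end"] > len(sent.text):
                    raise ValueError(f"mention {m['id']!r}: span outside sentence")
                sent.mentions.append(
                    Mention(
                        id=m["id"],
                        start=m["start"],
                        end=m["end"],
                        text=text,
                        mention_type=m.get("type", "DRUG").upper(),
                    )
                )
            for p in s.get("pairs", []):
                sent.pairs.append((p["m1"], p["m2"], p["label"]))
            doc.sentences.append(sent)
        docs.append(doc)
    return docs


def write_corpus_json(docs: list[Document], path: str | Path) -> None:
    payload = {
        "documents": [
            {
                "id": d.id,
                "sentences": [
                    {
                        "id": s.id,
                        "text": s.text,
                        "mentions": [
                            {
                                "id": m.id,
                                "start": m.start,
                                "end": m.end,
                                "type": m.mention_type,
                                "text": m.text,
                            }
                            for m in s.mentions
                        ],
                        "pairs": [
                            {"m1": a, "m2": b, "label": lab} for a, b, lab in s.pairs
                        ],
                    }
                    for s in d.sentences
                ],
            }
            for d in docs
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# Pair enumeration and masking
# ---------------------------------------------------------------------------


def enumerate_pairs(mentions: list[Mention]) -> list[tuple[Mention, Mention]]:
    """All C(n,2) mention pairs, each ordered by position in the sentence."""
    ms = sorted(mentions, key=lambda m: (m.start, m.end))
    return [(ms[i], ms[j]) for i in range(len(ms)) for j in range(i + 1, len(ms))]


def mask_sentence(
    sentence: str, mentions: list[Mention], pair: tuple[Mention, Mention]
) -> str:
    """Replace the target pair by DRUG1/DRUG2 (sentence order) and every
    other mention by DRUGOTHER; non-mention text is untouched."""
    m1, m2 = sorted(pair, key=lambda m: (m.start, m.end))
    if m1.end > m2.start:
        raise ValueError(f"target mentions overlap: {m1.span} vs {m2.span}")
    repl = {m1.span: MASK1, m2.span: MASK2}
    for m in mentions:
        repl.setdefault(m.span, MASK_OTHER)
    out = sentence
    for (start, end), token in sorted(repl.items(), reverse=True):
        out = out[:start] + token + out[end:]
    return out


def make_instances(
    docs: list[Document],
    labelset: LabelSet = DDI_LABELS,
    linking_table: "LinkingTable | None" = None,
) -> list[RelationInstance]:
    """Enumerate, mask and (optionally) link every gold pair in a corpus.

    Pairs annotated in the corpus are used as-is; the label of an annotated
    pair is its gold label, and mention pairs without an annotation are
    skipped (the shared task annotates every candidate pair, so nothing is
    lost there).
    """
    instances: list[RelationInstance] = []
    for doc in docs:
        for sent in doc.sentences:
            by_id = {m.id: m for m in sent.mentions}
            for a, b, label in sent.pairs:
                m1, m2 = sorted((by_id[a], by_id[b]), key=lambda m: (m.start, m.end))
                inst = RelationInstance(
                    sentence_masked=mask_sentence(sent.text, sent.mentions, (m1, m2)),
                    m1=m1,
                    m2=m2,
                    label=labelset.canonicalize(label),
                    provenance={
                        "doc": doc.id,
                        "sentence": sent.id,
                        "mentions": [m1.id, m2.id],
                    },
                )
                if linking_table is not None:
                    inst.kg1 = link_mention(linking_table, m1)
                    inst.kg2 = link_mention(linking_table, m2)
                instances.append(inst)
    return instances


# ---------------------------------------------------------------------------
# Mention -> KG linking
# ---------------------------------------------------------------------------


def _normalize(surface: str) -> str:
    return re.sub(r"\s+", " ", surface.strip().lower())


@dataclass
class LinkingTable:
    """Normalized surface -> entity-ID maps.  ``drug_map`` serves DRUG/BRAND/
    DRUG_N mentions, ``group_map`` (category + ATC names) serves GROUP
    mentions."""

    drug_map: dict[str, str] = field(default_factory=dict)
    group_map: dict[str, str] = field(default_factory=dict)

    def lookup(self, surface: str, mention_type: str = "DRUG") -> str | None:
        key = _normalize(surface)
        if mention_type.upper() == "GROUP":
            return self.group_map.get(key) or self.drug_map.get(key)
        return self.drug_map.get(key) or self.group_map.get(key)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for key, eid in sorted(self.drug_map.items()):
                fh.write(f"{key}\t{eid}\n")
            for key, eid in sorted(self.group_map.items()):
                fh.write(f"{key}\t{eid}\n")


def build_linking_table(kg: KnowledgeGraph) -> LinkingTable:
    """Index every name and synonym of drug and category/ATC entities."""
    table = LinkingTable()
    for e in kg.entities.values():
        if e.type == EntityType.drug:
            target = table.drug_map
        elif e.type in (EntityType.category, EntityType.atc):
            target = table.group_map
        else:
            continue
        for name in e.names:
            target.setdefault(_normalize(name), e.id)
    return table


def link_mention(table: LinkingTable, mention: Mention) -> str | None:
    """Normalized exact-match linking; a miss returns None (downstream uses a
    learned unknown-entity vector)."""
    return table.lookup(mention.text, mention.mention_type)


def coverage(instances: list[RelationInstance]) -> dict:
    """Instance-level coverage (both mentions linked) and mention-level
    coverage over unique normalized surfaces."""
    if not instances:
        raise ValueError("no instances")
    both = sum(1 for i in instances if i.kg1 is not None and i.kg2 is not None)
    unique: dict[str, bool] = {}
    for inst in instances:
        for m, kid in ((inst.m1, inst.kg1), (inst.m2, inst.kg2)):
            key = _normalize(m.text)
            unique[key] = unique.get(key, False) or kid is not None
    return {
        "instance_coverage": both / len(instances),
        "mention_coverage": sum(unique.values()) / len(unique),
        "n_instances": len(instances),
        "n_unique_mentions": len(unique),
    }


# ---------------------------------------------------------------------------
# Instance JSON-lines I/O
# ---------------------------------------------------------------------------


def write_instances_jsonl(instances: list[RelationInstance], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for inst in instances:
            fh.write(
                json.dumps(
                    {
                        "sentence_masked": inst.sentence_masked,
                        "label": inst.label,
                        "kg1": inst.kg1,
                        "kg2": inst.kg2,
                        "m1": {
                            "id": inst.m1.id,
                            "start": inst.m1.start,
                            "end": inst.m1.end,
                            "text": inst.m1.text,
                            "type": inst.m1.mention_type,
                        },
                        "m2": {
                            "id": inst.m2.id,
                            "start": inst.m2.start,
                            "end": inst.m2.end,
                            "text": inst.m2.text,
                            "type": inst.m2.mention_type,
                        },
                        "provenance": inst.provenance,
                    }
                )
                + "\n"
            )


def read_instances_jsonl(path: str | Path) -> list[RelationInstance]:
    instances = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            instances.append(
                RelationInstance(
                    sentence_masked=rec["sentence_masked"],
                    m1=Mention(
                        id=rec["m1"]["id"],
                        start=rec["m1"]["start"],
                        end=rec["m1"]["end"],
                        text=rec["m1"]["text"],
                        mention_type=rec["m1"].get("type", "DRUG"),
                    ),
                    m2=Mention(
                        id=rec["m2"]["id"],
                        start=rec["m2"]["start"],
                        end=rec["m2"]["end"],
                        text=rec["m2"]["text"],
                        mention_type=rec["m2"].get("type", "DRUG"),
                    ),
                    label=rec["label"],
                    kg1=rec.get("kg1"),
                    kg2=rec.get("kg2"),
                    provenance=rec.get("provenance", {}),
                )
            )
    return instances
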