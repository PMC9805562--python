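"""Typed heterogeneous pharmaceutical knowledge graph: data model, I/O,
pseudo-node augmentation, splits, and node-type filtering.

The graph mixes five kinds of "actual" nodes — drugs, proteins, pathways,
MeSH-style category terms and ATC codes — connected by the eight relation
kinds found in pharmaceutical resources (``category``, ``atc``, ``pathway``,
the symmetric ``interact``, and the four drug-protein roles ``target``,
``enzyme``, ``carrier``, ``transporter``).  Two "pseudo" node kinds carry
side information: ``textual`` nodes hold a synonym or a description string,
``structural`` nodes hold a SMILES string.  Pseudo nodes are attached via the
``synonym``/``description``/``structure`` relations and live only in the
train split, so they enrich embeddings without contaminating evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd

__all__ = [
    "EntityType",
    "Entity",
    "RelationType",
    "Triple",
    "KnowledgeGraph",
    "DEFAULT_RELATIONS",
    "load_triples",
    "save_kg",
    "load_kg",
    "add_textual_nodes",
    "add_structural_nodes",
    "remove_node_type",
    "candidates_of_type",
]

SPLITS = ("train", "valid", "test")


class EntityType(str, Enum):
    drug = "drug"
    protein = "protein"
    pathway = "pathway"
    category = "category"
    atc = "atc"
    textual = "textual"
    structural = "structural"

    @property
    def is_pseudo(self) -> bool:
        return self in (EntityType.textual, EntityType.structural)


ACTUAL_TYPES = tuple(t for t in EntityType if not t.is_pseudo)
PSEUDO_TYPES = (EntityType.textual, EntityType.structural)


@dataclass
class Entity:
    id: str
    type: EntityType
    names: list[str] = field(default_factory=list)
    smiles: str | None = None
    description: str | None = None

    def __post_init__(self) -> None:
        self.type = EntityType(self.type)
        if not self.type.is_pseudo and not self.names:
            raise ValueError(f"actual entity {self.id!r} must have a name")
        if self.smiles is not None and self.type not in (
            EntityType.drug,
            EntityType.structural,
        ):
            raise ValueError(
                f"entity {self.id!r}: smiles only allowed on drug/structural nodes"
            )


@dataclass(frozen=True)
class RelationType:
    name: str
    symmetric: bool
    domain: frozenset[EntityType]
    range: frozenset[EntityType]


def _rel(name, dom, rng, symmetric=False) -> RelationType:
    return RelationType(
        name=name,
        symmetric=symmetric,
        domain=frozenset(EntityType(d) for d in dom),
        range=frozenset(EntityType(r) for r in rng),
    )


#: Domain/range schema for the standard relation vocabulary.  ``interact`` is
#: the only symmetric relation; structure/synonym/description point at pseudo
#: nodes and are generated by augmentation, never read from triple files with
#: actual endpoints.
DEFAULT_RELATIONS: dict[str, RelationType] = {
    r.name: r
    for r in [
        _rel("category", ["drug"], ["category"]),
        _rel("atc", ["drug"], ["atc"]),
        _rel("pathway", ["drug", "protein"], ["pathway"]),
        _rel("interact", ["drug"], ["drug"], symmetric=True),
        _rel("target", ["drug"], ["protein"]),
        _rel("enzyme", ["drug"], ["protein"]),
        _rel("carrier", ["drug"], ["protein"]),
        _rel("transporter", ["drug"], ["protein"]),
        _rel("structure", ["drug"], ["structural"]),
        _rel("synonym", [t.value for t in ACTUAL_TYPES], ["textual"]),
        _rel("description", [t.value for t in ACTUAL_TYPES], ["textual"]),
    ]
}


class Triple(NamedTuple):
    h: str
    r: str
    t: str


@dataclass
class KnowledgeGraph:
    """Entity registry + relation schema + split-partitioned triples."""

    entities: dict[str, Entity]
    relations: dict[str, RelationType] = field(
        default_factory=lambda: dict(DEFAULT_RELATIONS)
    )
    splits: dict[str, list[Triple]] = field(
        default_factory=lambda: {s: [] for s in SPLITS}
    )

    def __post_init__(self) -> None:
        for s in SPLITS:
            self.splits.setdefault(s, [])
        self.validate()

    # -- queries ---------------------------------------------------------
    @property
    def triples(self) -> list[Triple]:
        return [t for s in SPLITS for t in self.splits[s]]

    def entities_of_type(self, kind: EntityType) -> list[Entity]:
        kind = EntityType(kind)
        return [e for e in self.entities.values() if e.type == kind]

    def triple_set(self, splits: Iterable[str] = SPLITS) -> set[Triple]:
        return {t for s in splits for t in self.splits[s]}

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        for split, triples in self.splits.items():
            if split not in SPLITS:
                raise ValueError(f"unknown split {split!r}")
            for tr in triples:
                self._check_triple(tr)

    def _check_triple(self, tr: Triple) -> None:
        if tr.h not in self.entities:
            raise KeyError(f"triple head {tr.h!r} not a registered entity")
        if tr.t not in self.entities:
            raise KeyError(f"triple tail {tr.t!r} not a registered entity")
        rel = self.relations.get(tr.r)
        if rel is None:
            raise KeyError(f"unknown relation {tr.r!r}")
        ht, tt = self.entities[tr.h].type, self.entities[tr.t].type
        if ht not in rel.domain:
            raise ValueError(
                f"triple {tr}: head type {ht.value} outside domain of {tr.r}"
            )
        if tt not in rel.range:
            raise ValueError(
                f"triple {tr}: tail type {tt.value} outside range of {tr.r}"
            )

    def copy(self) -> "KnowledgeGraph":
        return KnowledgeGraph(
            entities={k: replace(v, names=list(v.names)) for k, v in self.entities.items()},
            relations=dict(self.relations),
            splits={s: list(ts) for s, ts in self.splits.items()},
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_META_COLS = ["id", "type", "names", "smiles", "description"]


def _read_metadata(metadata_path: str | Path) -> dict[str, Entity]:
    df = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("id", "type") if c not in df.columns]
    if missing:
        raise ValueError(f"metadata lacks required columns {missing}")
    entities: dict[str, Entity] = {}
    for row in df.itertuples(index=False):
        eid = row.id
        if eid in entities:
            raise ValueError(f"duplicate entity id {eid!r} in metadata")
        names = [n for n in getattr(row, "names", "").split("|") if n]
        entities[eid] = Entity(
            id=eid,
            type=EntityType(row.type),
            names=names,
            smiles=getattr(row, "smiles", "") or None,
            description=getattr(row, "description", "") or None,
        )
    return entities


def _read_triple_tsv(path: str | Path) -> list[Triple]:
    triples: list[Triple] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if parts[:3] == ["head", "relation", "tail"]:
                continue  # optional header
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            triples.append(Triple(parts[0], parts[1], parts[2]))
    return triples


def load_triples(
    tsv_path: str | Path,
    metadata_path: str | Path,
    relations: dict[str, RelationType] | None = None,
    split: str = "train",
) -> KnowledgeGraph:
    """Load a KG from a 3-column triple TSV plus an entity metadata TSV.

    Every triple endpoint must be registered in the metadata; metadata rows
    never referenced by a triple become isolated entities.
    """
    entities = _read_metadata(metadata_path)
    triples = _read_triple_tsv(tsv_path)
    splits = {s: [] for s in SPLITS}
    splits[split] = triples
    return KnowledgeGraph(
        entities=entities,
        relations=dict(relations or DEFAULT_RELATIONS),
        splits=splits,
    )


def save_kg(kg: KnowledgeGraph, out_dir: str | Path) -> None:
    """Serialize a KG to a directory: entities.tsv, triples_<split>.tsv, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "id": e.id,
            "type": e.type.value,
            "names": "|".join(e.names),
            "smiles": e.smiles or "",
            "description": e.description or "",
        }
        for e in kg.entities.values()
    ]
    pd.DataFrame(rows, columns=_META_COLS).to_csv(
        out / "entities.tsv", sep="\t", index=False
    )
    for s in SPLITS:
        with open(out / f"triples_{s}.tsv", "w", encoding="utf-8") as fh:
            for tr in kg.splits[s]:
                fh.write(f"{tr.h}\t{tr.r}\t{tr.t}\n")
    manifest = {
        "format": "kgddi-kg/1",
        "n_entities": len(kg.entities),
        "n_triples": {s: len(kg.splits[s]) for s in SPLITS},
        "relations": {
            name: {
                "symmetric": r.symmetric,
                "domain": sorted(t.value for t in r.domain),
                "range": sorted(t.value for t in r.range),
            }
            for name, r in kg.relations.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_kg(kg_dir: str | Path) -> KnowledgeGraph:
    kg_dir = Path(kg_dir)
    manifest = json.loads((kg_dir / "manifest.json").read_text())
    relations = {
        name: _rel(name, spec["domain"], spec["range"], spec["symmetric"])
        for name, spec in manifest["relations"].items()
    }
    entities = _read_metadata(kg_dir / "entities.tsv")
    splits = {s: _read_triple_tsv(kg_dir / f"triples_{s}.tsv") for s in SPLITS}
    return KnowledgeGraph(entities=entities, relations=relations, splits=splits)


# ---------------------------------------------------------------------------
# Pseudo-node augmentation
# ---------------------------------------------------------------------------


def add_textual_nodes(kg: KnowledgeGraph) -> KnowledgeGraph:
    """Attach one textual pseudo-node per synonym and per description.

    The first entry of ``names`` is the primary name; every further entry is
    a synonym and gets its own textual node linked by the ``synonym``
    relation.  A non-empty ``description`` gets one node via ``description``.
    New triples go to the train split only.  Idempotent.
    """
    kg = kg.copy()
    train = kg.splits["train"]
    existing = set(train)
    for e in list(kg.entities.values()):
        if e.type.is_pseudo:
            continue
        for i, syn in enumerate(e.names[1:], start=1):
            nid = f"TXT|{e.id}|syn{i}"
            if nid not in kg.entities:
                kg.entities[nid] = Entity(nid, EntityType.textual, names=[syn])
            tr = Triple(e.id, "synonym", nid)
            if tr not in existing:
                train.append(tr)
                existing.add(tr)
        if e.description:
            nid = f"TXT|{e.id}|desc"
            if nid not in kg.entities:
                kg.entities[nid] = Entity(
                    nid, EntityType.textual, names=[e.description]
                )
            tr = Triple(e.id, "description", nid)
            if tr not in existing:
                train.append(tr)
                existing.add(tr)
    kg.validate()
    return kg


def add_structural_nodes(kg: KnowledgeGraph) -> KnowledgeGraph:
    """Attach one structural pseudo-node per unique drug SMILES string.

    Drugs sharing a SMILES string share the node: the structure is a property
    of the molecule, not of the database entry.  Train split only; idempotent.
    """
    kg = kg.copy()
    train = kg.splits["train"]
    existing = set(train)
    by_smiles: dict[str, str] = {
        e.smiles: e.id
        for e in kg.entities.values()
        if e.type == EntityType.structural and e.smiles
    }
    n_new = len(by_smiles)
    for e in list(kg.entities.values()):
        if e.type != EntityType.drug or not e.smiles:
            continue
        nid = by_smiles.get(e.smiles)
        if nid is None:
            nid = f"STR|{n_new}"
            n_new += 1
            by_smiles[e.smiles] = nid
            kg.entities[nid] = Entity(
                nid, EntityType.structural, names=[], smiles=e.smiles
            )
        tr = Triple(e.id, "structure", nid)
        if tr not in existing:
            train.append(tr)
            existing.add(tr)
    kg.validate()
    return kg


def remove_node_type(kg: KnowledgeGraph, kind: EntityType) -> KnowledgeGraph:
    """Drop all entities of one kind and every triple touching them.

    Used for node-type ablations; drugs are the subjects of the task and
    cannot be removed.  Split membership of surviving triples is preserved.
    """
    kind = EntityType(kind)
    if kind == EntityType.drug:
        raise ValueError("refusing to remove drug nodes: drugs are the task subjects")
    keep = {eid for eid, e in kg.entities.items() if e.type != kind}
    return KnowledgeGraph(
        entities={eid: replace(e, names=list(e.names)) for eid, e in kg.entities.items() if eid in keep},
        relations=dict(kg.relations),
        splits={
            s: [tr for tr in ts if tr.h in keep and tr.t in keep]
            for s, ts in kg.splits.items()
        },
    )


def candidates_of_type(kg: KnowledgeGraph, kind: EntityType) -> list[str]:
    """All entity IDs of a given type, sorted for determinism."""
    kind = EntityType(kind)
    return sorted(e.id for e in kg.entities.values() if e.type == kind)
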