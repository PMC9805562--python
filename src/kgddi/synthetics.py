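"""Synthetic data: planted-structure heterogeneous KGs and templated
relation-extraction corpora whose labels depend on KG neighborhoods.

The KG generator samples a hidden low-rank embedding for every entity and
emits, per relation, the top-scoring admissible pairs under a planted score
function (DistMult by default).  ``interact`` — the dominant relation, as in
real pharmaceutical KGs — is symmetric and emitted in both directions.  The
taxonomy relations ``category`` and ``atc`` attach every drug to its single
top-scoring parent, so each drug acquires a discrete *grade* (which category
node it belongs to) that embedding training can recover from the graph.

The corpus generator writes templated sentences over drug mentions and
labels each mention pair by a rule over KG features of the pair.  The
default rule maps the pair's grade sum (0..4) onto the five DDI classes, so
the label is decodable from the knowledge graph but *not* from the text —
templates are chosen independently of the label.  This is what makes the
KG-marker ablation informative: a classifier without KG markers can only
learn the label prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import (
    DDI_LABELS,
    Document,
    LabelSet,
    LinkingTable,
    Mention,
    Sentence,
    build_linking_table,
)
from .kg_store import DEFAULT_RELATIONS, Entity, EntityType, KnowledgeGraph, Triple

__all__ = [
    "SyntheticKGSpec",
    "SyntheticCorpusSpec",
    "KGGroundTruth",
    "generate_kg",
    "generate_corpus",
    "drug_grades",
    "pair_features",
    "grade_sum_label",
]


@dataclass
class SyntheticKGSpec:
    counts: dict[str, int] = field(
        default_factory=lambda: {
            "drug": 80,
            "protein": 20,
            "pathway": 6,
            "category": 3,
            "atc": 6,
        }
    )
    score_kind: str = "distmult"
    #: dimension of the hidden planted vectors; kept small so the edge sets
    #: carry genuinely low-rank, recoverable structure (a model fitted with
    #: d >= this rank can represent the planted scores exactly)
    d: int = 4
    #: absolute planted-score cutoff; None selects by per-relation density
    threshold: float | None = None
    #: fraction of admissible pairs kept per quantile relation
    densities: dict[str, float] = field(
        default_factory=lambda: {
            "interact": 0.10,
            "target": 0.05,
            "enzyme": 0.03,
            "carrier": 0.015,
            "transporter": 0.02,
            "pathway": 0.05,
        }
    )
    #: relations attaching each head to its single best tail (taxonomies)
    top1_relations: tuple[str, ...] = ("category", "atc")
    #: which relations to emit (e.g. ("interact",) for a KG whose only
    #: relation is the symmetric one)
    relations: tuple[str, ...] = (
        "category", "atc", "pathway", "interact", "target",
        "enzyme", "carrier", "transporter",
    )
    #: drugs are planted in as many communities as there are category nodes;
    #: this weight mixes the community center into each drug vector, so
    #: interact edges concentrate within communities and category membership
    #: reflects the same structure (0 = no community structure)
    cluster_weight: float = 0.85
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    smiles_fraction: float = 0.8
    synonyms_per_drug: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        for kind, n in self.counts.items():
            if n < 2:
                raise ValueError(f"need >= 2 entities of type {kind}")


@dataclass
class KGGroundTruth:
    vectors: dict[str, np.ndarray]
    relation_vectors: dict[str, np.ndarray]
    drug_grades: dict[str, int]


_SYLLABLES = ["va", "lor", "mi", "den", "zu", "pra", "tex", "ol", "fen", "cab",
              "ri", "mab", "tin", "xa", "nor", "pil", "dro", "ket", "sul", "ame"]
_SMILES_FRAGS = ["C", "CC", "N", "O", "c1ccccc1", "C(=O)", "S", "Cl", "F",
                 "C(N)", "OC", "C1CC1"]


def _pseudo_name(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        name = "".join(rng.choice(_SYLLABLES, size=3)) + rng.choice(
            ["ine", "ol", "ide", "an", "il"]
        )
        if name not in used:
            used.add(name)
            return name


def _fake_smiles(rng: np.random.Generator) -> str:
    return "".join(rng.choice(_SMILES_FRAGS, size=int(rng.integers(3, 7))))


def _planted_scores(kind, vec, rvec, heads, tails, h_idx, t_idx):
    H = np.stack([vec[heads[i]] for i in h_idx])
    T = np.stack([vec[tails[i]] for i in t_idx])
    if kind == "distmult":
        return np.einsum("ij,j,ij->i", H, rvec, T)
    if kind == "transe":
        return -np.linalg.norm(H + rvec - T, axis=1)
    raise ValueError(f"unsupported planted score kind {kind!r}")


def generate_kg(spec: SyntheticKGSpec) -> tuple[KnowledgeGraph, KGGroundTruth]:
    """Sample a typed KG with planted low-rank structure.

    Returns the graph (entities carry generated names, synonyms, fake SMILES
    and descriptions so the augmentation operations have something to do)
    plus the hidden ground truth used to plant it.
    """
    rng = np.random.default_rng(spec.seed)
    used_names: set[str] = set()
    entities: dict[str, Entity] = {}
    ids_by_type: dict[str, list[str]] = {}
    prefixes = {"drug": "DB", "protein": "P", "pathway": "SMP",
                "category": "D", "atc": "ATC"}
    for kind, n in spec.counts.items():
        ids = [f"{prefixes[kind]}{i:04d}" for i in range(n)]
        ids_by_type[kind] = ids
        for eid in ids:
            names = [_pseudo_name(rng, used_names)]
            smiles = None
            description = None
            if kind == "drug":
                names += [_pseudo_name(rng, used_names)
                          for _ in range(spec.synonyms_per_drug)]
                if rng.random() < spec.smiles_fraction:
                    smiles = _fake_smiles(rng)
                if rng.random() < 0.5:
                    description = f"{names[0]} is a small molecule agent."
            entities[eid] = Entity(eid, EntityType(kind), names=names,
                                   smiles=smiles, description=description)

    vectors = {eid: rng.standard_normal(spec.d) for eid in entities}
    # plant drug communities: one center per category node; a drug's vector
    # leans toward its community center and the category node sits on it
    n_com = spec.counts["category"]
    centers = rng.standard_normal((n_com, spec.d))
    centers *= np.sqrt(spec.d) / np.linalg.norm(centers, axis=1, keepdims=True)
    w = spec.cluster_weight
    for i, eid in enumerate(ids_by_type["drug"]):
        com = i % n_com
        vectors[eid] = w * centers[com] + np.sqrt(1 - w**2) * rng.standard_normal(spec.d)
    for g, eid in enumerate(ids_by_type["category"]):
        vectors[eid] = centers[g]
    relation_vectors: dict[str, np.ndarray] = {}

    triples: list[Triple] = []
    schema = DEFAULT_RELATIONS
    for rel_name in spec.relations:
        rel = schema[rel_name]
        # identity relation for the symmetric and taxonomy relations keeps
        # their planted scores as plain inner products, so community and
        # category structure survive; the other relations get random
        # diagonal weights
        if rel.symmetric or rel_name in spec.top1_relations:
            rvec = np.ones(spec.d)
        else:
            rvec = rng.standard_normal(spec.d)
        relation_vectors[rel_name] = rvec
        heads = [e for k in spec.counts if EntityType(k) in rel.domain
                 for e in ids_by_type[k]]
        tails = [e for k in spec.counts if EntityType(k) in rel.range
                 for e in ids_by_type[k]]
        if rel_name in spec.top1_relations:
            t_mat = np.stack([vectors[t] for t in tails])
            for h in heads:
                scores = t_mat @ (rvec * vectors[h])
                triples.append(Triple(h, rel_name, tails[int(scores.argmax())]))
            continue
        if rel.symmetric:
            pairs = [(i, j) for i in range(len(heads)) for j in range(i + 1, len(heads))]
        else:
            pairs = [(i, j) for i in range(len(heads)) for j in range(len(tails))]
        h_idx = np.array([p[0] for p in pairs])
        t_idx = np.array([p[1] for p in pairs])
        scores = _planted_scores(spec.score_kind, vectors, rvec, heads, tails,
                                 h_idx, t_idx)
        if spec.threshold is not None:
            keep = np.flatnonzero(scores > spec.threshold)
        else:
            density = spec.densities.get(rel_name, 0.05)
            n_keep = max(1, int(round(density * len(pairs))))
            keep = np.argsort(scores)[::-1][:n_keep]
        if keep.size == 0:
            raise ValueError(
                f"relation {rel_name!r}: threshold {spec.threshold} yields 0 "
                f"triples (score range {scores.min():.3f}..{scores.max():.3f})"
            )
        for i in keep:
            h, t = heads[h_idx[i]], tails[t_idx[i]]
            triples.append(Triple(h, rel_name, t))
            if rel.symmetric:
                triples.append(Triple(t, rel_name, h))

    # split assignment: symmetric pairs stay together so no evaluation triple
    # is the mirror image of a train triple
    groups: dict[tuple, list[Triple]] = {}
    for tr in triples:
        key = (tr.r, *sorted((tr.h, tr.t))) if schema[tr.r].symmetric \
            else (tr.r, tr.h, tr.t)
        groups.setdefault(key, []).append(tr)
    keys = sorted(groups)
    rng.shuffle(keys)
    n = len(keys)
    n_train = int(round(spec.fractions[0] * n))
    n_valid = int(round(spec.fractions[1] * n))
    splits = {"train": [], "valid": [], "test": []}
    for i, key in enumerate(keys):
        split = "train" if i < n_train else "valid" if i < n_train + n_valid else "test"
        splits[split].extend(groups[key])

    kg = KnowledgeGraph(entities=entities, relations=dict(schema), splits=splits)
    grades = drug_grades(kg)
    return kg, KGGroundTruth(vectors=vectors, relation_vectors=relation_vectors,
                             drug_grades=grades)


# ---------------------------------------------------------------------------
# KG features for corpus labeling
# ---------------------------------------------------------------------------


def drug_grades(kg: KnowledgeGraph) -> dict[str, int]:
    """Grade of a drug = index (in sorted order) of the category node it
    links to; drugs without a category edge get the middle grade."""
    cats = sorted(e.id for e in kg.entities.values()
                  if e.type == EntityType.category)
    cat_index = {c: i for i, c in enumerate(cats)}
    grades: dict[str, int] = {}
    for tr in kg.triples:
        if tr.r == "category" and tr.t in cat_index:
            grades.setdefault(tr.h, cat_index[tr.t])
    mid = len(cats) // 2
    for e in kg.entities.values():
        if e.type == EntityType.drug:
            grades.setdefault(e.id, mid)
    return grades


def pair_features(kg: KnowledgeGraph, grades: dict[str, int],
                  interact: set[frozenset], d1: str, d2: str) -> dict:
    return {
        "grade1": grades[d1],
        "grade2": grades[d2],
        "grade_sum": grades[d1] + grades[d2],
        "interact_edge": frozenset((d1, d2)) in interact,
        "shared_category": grades[d1] == grades[d2],
    }


def grade_sum_label(features: dict, labelset: LabelSet = DDI_LABELS) -> str:
    """Default deterministic rule: grade sum 0..4 -> [negative, Mechanism,
    Effect, Advice, Int] (an ordinal mapping, linearly decodable from any
    embedding direction that encodes the grade)."""
    order = (labelset.negative_label,) + labelset.positives
    s = min(features["grade_sum"], len(order) - 1)
    return order[s]


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

_TEMPLATES_2 = [
    "Coadministration of {A} with {B} was evaluated in a randomized study .",
    "Patients receiving {A} were also given {B} during the trial .",
    "The pharmacokinetics of {A} were measured after administration of {B} .",
    "{A} and {B} were prescribed together in the cohort .",
    "Clinicians observed the combination of {A} and {B} in practice .",
]
_TEMPLATES_3 = [
    "Subjects took {A} together with {B} and {C} for two weeks .",
    "Plasma levels of {A} were monitored during treatment with {B} and {C} .",
    "A regimen of {A} , {B} and {C} was administered to the volunteers .",
]


@dataclass
class SyntheticCorpusSpec:
    n_sentences: int = 400
    #: probability of 2 vs 3 mentions per sentence
    p_three_mentions: float = 0.3
    label_noise: float = 0.1
    labelset: LabelSet = field(default_factory=lambda: DDI_LABELS)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.label_noise < 1:
            raise ValueError("label_noise must be in [0, 1)")


def generate_corpus(
    spec: SyntheticCorpusSpec, kg: KnowledgeGraph
) -> tuple[list[Document], LinkingTable]:
    """Templated sentences over drug mentions; every mention pair is labeled
    by the grade-sum rule over KG features, with a ``label_noise`` fraction
    flipped to a uniformly random label."""
    drugs = sorted(e.id for e in kg.entities.values() if e.type == EntityType.drug)
    if len(drugs) < 2:
        raise ValueError("corpus generation needs >= 2 drugs in the KG")
    rng = np.random.default_rng(spec.seed)
    grades = drug_grades(kg)
    interact = {frozenset((tr.h, tr.t)) for tr in kg.triples if tr.r == "interact"}
    labels = spec.labelset.all_labels

    doc = Document(id="synthetic-0")
    for s_idx in range(spec.n_sentences):
        n_mentions = 3 if rng.random() < spec.p_three_mentions else 2
        if n_mentions == 3 and len(drugs) < 3:
            n_mentions = 2
        template = (
            rng.choice(_TEMPLATES_3) if n_mentions == 3 else rng.choice(_TEMPLATES_2)
        )
        chosen = list(rng.choice(drugs, size=n_mentions, replace=False))
        surfaces = [
            str(rng.choice(kg.entities[d].names)) for d in chosen
        ]
        text = ""
        cursor = 0
        mentions: list[Mention] = []
        remaining = template
        for slot, (d, surf) in zip("ABC", zip(chosen, surfaces)):
            pre, _, remaining = remaining.partition("{" + slot + "}")
            text += pre
            start = len(text)
            text += surf
            mentions.append(
                Mention(
                    id=f"s{s_idx}.m{len(mentions)}",
                    start=start,
                    end=len(text),
                    text=surf,
                    mention_type="DRUG",
                )
            )
            cursor = len(text)
        text += remaining
        sent = Sentence(id=f"s{s_idx}", text=text, mentions=mentions)
        order = sorted(range(n_mentions), key=lambda i: mentions[i].start)
        for a in range(n_mentions):
            for b in range(a + 1, n_mentions):
                i, j = order[a], order[b]
                feats = pair_features(kg, grades, interact, chosen[i], chosen[j])
                label = grade_sum_label(feats, spec.labelset)
                if rng.random() < spec.label_noise:
                    label = str(rng.choice(labels))
                sent.pairs.append((mentions[i].id, mentions[j].id, label))
        doc.sentences.append(sent)

    return [doc], build_linking_table(kg)
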