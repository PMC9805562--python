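import numpy as np
import pytest

from kgddi.corpus import make_instances
from kgddi.kg_embed import KGTrainConfig, fit
from kgddi.kg_store import Entity, EntityType, KnowledgeGraph, Triple
from kgddi.synthetics import (
    SyntheticCorpusSpec,
    SyntheticKGSpec,
    generate_corpus,
    generate_kg,
)

# A worked preprocessing example: one sentence, three drug mentions, three
# candidate pairs (standard shared-task XML dialect).
WORKED_SENTENCE = (
    "Exposure to oral S-ketamine is unaffected by itraconazole "
    "but greatly increased by ticlopidine."
)
WORKED_XML = f"""<?xml version="1.0" encoding="UTF-8"?>
<corpus>
 <document id="d1">
  <sentence id="d1.s0" text="{WORKED_SENTENCE}">
   <entity id="d1.s0.e0" charOffset="17-26" type="drug" text="S-ketamine"/>
   <entity id="d1.s0.e1" charOffset="45-56" type="drug" text="itraconazole"/>
   <entity id="d1.s0.e2" charOffset="83-93" type="drug" text="ticlopidine"/>
   <pair id="d1.s0.p0" e1="d1.s0.e0" e2="d1.s0.e1" ddi="false"/>
   <pair id="d1.s0.p1" e1="d1.s0.e0" e2="d1.s0.e2" ddi="true" type="mechanism"/>
   <pair id="d1.s0.p2" e1="d1.s0.e1" e2="d1.s0.e2" ddi="true" type="effect"/>
  </sentence>
 </document>
</corpus>
"""

WORKED_MASKS = [
    "Exposure to oral DRUG1 is unaffected by DRUG2 but greatly increased by DRUGOTHER.",
    "Exposure to oral DRUG1 is unaffected by DRUGOTHER but greatly increased by DRUG2.",
    "Exposure to oral DRUGOTHER is unaffected by DRUG1 but greatly increased by DRUG2.",
]


@pytest.fixture(scope="session")
def worked_xml_path(tmp_path_factory):
    path = tmp_path_factory.mktemp("xml") / "worked.xml"
    path.write_text(WORKED_XML)
    return path


@pytest.fixture
def toy_kg() -> KnowledgeGraph:
    """Hand-built 6-entity KG: 3 drugs, 1 protein, 1 category, 1 pathway."""
    entities = {
        "d1": Entity("d1", EntityType.drug, ["aspirin", "acetylsalicylic acid"],
                     smiles="CC(=O)Oc1ccccc1C(=O)O",
                     description="a common analgesic"),
        "d2": Entity("d2", EntityType.drug, ["warfarin"], smiles="CC(=O)CC"),
        "d3": Entity("d3", EntityType.drug, ["heparin"]),
        "p1": Entity("p1", EntityType.protein, ["COX-1"]),
        "c1": Entity("c1", EntityType.category, ["anticoagulants"]),
        "w1": Entity("w1", EntityType.pathway, ["hemostasis"]),
    }
    splits = {
        "train": [
            Triple("d1", "interact", "d2"),
            Triple("d2", "interact", "d1"),
            Triple("d1", "target", "p1"),
            Triple("d2", "category", "c1"),
            Triple("d3", "category", "c1"),
            Triple("d1", "pathway", "w1"),
        ],
        "valid": [Triple("d2", "interact", "d3")],
        "test": [Triple("d3", "interact", "d2")],
    }
    return KnowledgeGraph(entities=entities, splits=splits)


@pytest.fixture(scope="session")
def planted():
    """Planted synthetic KG plus a fitted DistMult model (shared: fitting is
    the expensive step)."""
    kg, truth = generate_kg(SyntheticKGSpec(seed=1))
    model = fit(kg, "distmult", KGTrainConfig(seed=1))
    return kg, truth, model


@pytest.fixture(scope="session")
def synth_corpus(planted):
    """Train/test instance sets over the planted KG, with linking."""
    kg, _truth, _model = planted
    docs_tr, table = generate_corpus(SyntheticCorpusSpec(n_sentences=300, seed=11), kg)
    docs_te, _ = generate_corpus(SyntheticCorpusSpec(n_sentences=150, seed=12), kg)
    train = make_instances(docs_tr, linking_table=table)
    test = make_instances(docs_te, linking_table=table)
    return train, test, table


@pytest.fixture
def rng():
    return np.random.default_rng(0)
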