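"""Ranking-based link-prediction evaluation with same-type replacement.

For each evaluated triple the head (and, separately, the tail) is replaced by
every other entity of the same type; the true triple's score is ranked among
the corrupted scores.  Rank uses mean-rank tie handling:

    rank = 1 + #{strictly higher} + 0.5 * #{equal}

so the metric is invariant to candidate ordering.  ``raw`` ranking keeps all
corruptions; ``filtered`` drops corruptions that are themselves known
positives anywhere in the KG.  MRR is the mean reciprocal rank; Hits@k the
fraction of ranks <= k.  Pseudo-node triples live only in the train split and
never enter evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kg_embed import KGEmbeddingModel, _indices, _raw_scores
from .kg_store import KnowledgeGraph, Triple, candidates_of_type

__all__ = ["RankResult", "rank_triple", "evaluate", "random_baseline_mrr"]


@dataclass(frozen=True)
class RankResult:
    triple: Triple
    side: str  # "head" | "tail"
    rank: float
    n_candidates: int


def _candidate_ids(kg: KnowledgeGraph, true_endpoint: str) -> list[str]:
    kind = kg.entities[true_endpoint].type
    return [c for c in candidates_of_type(kg, kind) if c != true_endpoint]


def rank_triple(
    model: KGEmbeddingModel,
    kg: KnowledgeGraph,
    triple: Triple,
    side: str,
    filtered: bool = False,
    known: set[Triple] | None = None,
) -> RankResult:
    """Rank the true triple against same-type corruptions of one endpoint."""
    if side not in ("head", "tail"):
        raise ValueError(f"side must be 'head' or 'tail', got {side!r}")
    true_ep = triple.h if side == "head" else triple.t
    cands = _candidate_ids(kg, true_ep)
    if filtered:
        if known is None:
            known = kg.triple_set()
        if side == "head":
            cands = [c for c in cands if Triple(c, triple.r, triple.t) not in known]
        else:
            cands = [c for c in cands if Triple(triple.h, triple.r, c) not in known]
    if not cands:
        raise ValueError(
            f"no same-type candidate to corrupt the {side} of {triple}"
        )
    if side == "head":
        corrupted = [Triple(c, triple.r, triple.t) for c in cands]
    else:
        corrupted = [Triple(triple.h, triple.r, c) for c in cands]
    h, r, t = _indices(model, [triple] + corrupted)
    scores = _raw_scores(model.score_kind, model.E, model.R, h, r, t)
    true_score, cand_scores = scores[0], scores[1:]
    higher = int(np.sum(cand_scores > true_score))
    equal = int(np.sum(cand_scores == true_score))
    return RankResult(
        triple=triple,
        side=side,
        rank=1.0 + higher + 0.5 * equal,
        n_candidates=len(cands),
    )


def summarize_ranks(ranks: np.ndarray, ks: tuple[int, ...] = (1, 3, 10)) -> dict:
    ranks = np.asarray(ranks, dtype=float)
    out = {"mrr": float(np.mean(1.0 / ranks)), "n": int(ranks.size)}
    for k in ks:
        out[f"hits@{k}"] = float(np.mean(ranks <= k))
    return out


def evaluate(
    model: KGEmbeddingModel,
    kg: KnowledgeGraph,
    split: str = "test",
    filtered: bool = False,
) -> dict:
    """MRR and Hits@{1,3,10} over a split, one head- and one tail-replacement
    rank per triple."""
    triples = kg.splits[split]
    if not triples:
        raise ValueError(f"split {split!r} is empty")
    known = kg.triple_set() if filtered else None
    ranks = []
    for tr in triples:
        for side in ("head", "tail"):
            ranks.append(
                rank_triple(model, kg, tr, side, filtered=filtered, known=known).rank
            )
    return summarize_ranks(np.array(ranks))


def random_baseline_mrr(n_candidates: int) -> float:
    """Expected MRR of a uniformly random ranking among n_candidates + the
    true triple: the mean of 1/i over i = 1..n_candidates+1 (harmonic sum)."""
    n = n_candidates + 1
    return float(np.sum(1.0 / np.arange(1, n + 1)) / n)
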