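"""Knowledge-graph embedding: score functions, logistic loss, type-constrained
negative sampling, and mini-batch Adagrad training.

Four score functions are supported, all under the similarity convention
(higher score = more plausible triple):

* ``transe``    f(h,r,t) = -|| e_h + w_r - e_t ||_2
* ``distmult``  f(h,r,t) = <e_h, w_r, e_t>  (trilinear, diagonal relation)
* ``complex``   f(h,r,t) = Re <e_h, w_r, conj(e_t)>  with complex-valued
  vectors stored as d/2 real + d/2 imaginary components
* ``simple``    f(h,r,t) = (<h_head, r_fwd, t_tail> + <t_head, r_inv, h_tail>)/2
  with separate head/tail entity halves and forward/inverse relation halves

Parameter budgets are matched: every score kind stores exactly ``d`` real
numbers per entity and per relation, so kinds are comparable at fixed ``d``.

Training minimizes the logistic loss
``sum log(1 + exp(-y * f(h,r,t))) + lambda * ||Theta||^2`` with y=+1 on
observed triples and y=-1 on type-constrained corruptions, using Adagrad
with hand-derived sparse gradients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kg_store import KnowledgeGraph, Triple, candidates_of_type

__all__ = [
    "SCORE_KINDS",
    "KGEmbeddingModel",
    "KGTrainConfig",
    "TripleBatch",
    "score",
    "score_batch",
    "logistic_loss",
    "sample_negatives",
    "init_from_vectors",
    "fit",
    "save_model",
    "load_model",
]

SCORE_KINDS = ("transe", "distmult", "complex", "simple")


@dataclass
class KGEmbeddingModel:
    """Entity/relation embedding tables plus the score-function kind."""

    entity_ids: list[str]
    relation_names: list[str]
    score_kind: str
    d: int
    E: np.ndarray  # (n_entities, d)
    R: np.ndarray  # (n_relations, d)
    history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.score_kind not in SCORE_KINDS:
            raise ValueError(f"unknown score kind {self.score_kind!r}")
        if self.score_kind in ("complex", "simple") and self.d % 2:
            raise ValueError(f"{self.score_kind} requires an even dimension")
        self.entity_index = {e: i for i, e in enumerate(self.entity_ids)}
        self.relation_index = {r: i for i, r in enumerate(self.relation_names)}

    @classmethod
    def create(
        cls,
        entity_ids: list[str],
        relation_names: list[str],
        score_kind: str,
        d: int,
        seed: int = 0,
        init_scale: float = 0.1,
    ) -> "KGEmbeddingModel":
        rng = np.random.default_rng(seed)
        E = rng.uniform(-init_scale, init_scale, size=(len(entity_ids), d))
        R = rng.uniform(-init_scale, init_scale, size=(len(relation_names), d))
        return cls(list(entity_ids), list(relation_names), score_kind, d, E, R)

    def entity_vector(self, entity_id: str) -> np.ndarray:
        return self.E[self.entity_index[entity_id]]


@dataclass
class KGTrainConfig:
    d: int = 16
    lambda_l2: float = 1e-2
    negatives_per_positive: int = 20
    learning_rate: float = 0.05
    batch_size: int = 256
    epochs: int = 30
    seed: int = 0
    init_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.lambda_l2 < 0:
            raise ValueError("lambda_l2 must be nonnegative")
        for name in ("negatives_per_positive", "learning_rate", "batch_size", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TripleBatch:
    positives: list[Triple]
    negatives: list[Triple]

    @property
    def labels(self) -> np.ndarray:
        return np.concatenate(
            [np.ones(len(self.positives)), -np.ones(len(self.negatives))]
        )

    @property
    def all_triples(self) -> list[Triple]:
        return self.positives + self.negatives


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def _raw_scores(
    kind: str, E: np.ndarray, R: np.ndarray, h: np.ndarray, r: np.ndarray, t: np.ndarray
) -> np.ndarray:
    eh, wr, et = E[h], R[r], E[t]
    if kind == "transe":
        return -np.linalg.norm(eh + wr - et, axis=-1)
    if kind == "distmult":
        return np.einsum("ij,ij,ij->i", eh, wr, et)
    if kind == "complex":
        k = E.shape[1] // 2
        hr, hi = eh[:, :k], eh[:, k:]
        rr, ri = wr[:, :k], wr[:, k:]
        tr_, ti = et[:, :k], et[:, k:]
        # Re(sum h * r * conj(t))
        return np.sum(hr * rr * tr_ + hi * rr * ti + hr * ri * ti - hi * ri * tr_, axis=-1)
    if kind == "simple":
        k = E.shape[1] // 2
        h_head, h_tail = eh[:, :k], eh[:, k:]
        t_head, t_tail = et[:, :k], et[:, k:]
        fwd, inv = wr[:, :k], wr[:, k:]
        return 0.5 * (
            np.sum(h_head * fwd * t_tail, axis=-1)
            + np.sum(t_head * inv * h_tail, axis=-1)
        )
    raise ValueError(f"unknown score kind {kind!r}")


def _raw_grads(
    kind: str,
    E: np.ndarray,
    R: np.ndarray,
    h: np.ndarray,
    r: np.ndarray,
    t: np.ndarray,
    df: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of ``sum(df * f)`` w.r.t. the h-rows, r-rows and t-rows."""
    eh, wr, et = E[h], R[r], E[t]
    df = df[:, None]
    if kind == "transe":
        u = eh + wr - et
        nrm = np.linalg.norm(u, axis=-1, keepdims=True)
        g = -u / np.maximum(nrm, 1e-12)
        return df * g, df * g, -df * g
    if kind == "distmult":
        return df * wr * et, df * eh * et, df * eh * wr
    if kind == "complex":
        k = E.shape[1] // 2
        hr, hi = eh[:, :k], eh[:, k:]
        rr, ri = wr[:, :k], wr[:, k:]
        tr_, ti = et[:, :k], et[:, k:]
        gh = np.concatenate([rr * tr_ + ri * ti, rr * ti - ri * tr_], axis=1)
        gr = np.concatenate([hr * tr_ + hi * ti, hr * ti - hi * tr_], axis=1)
        gt = np.concatenate([hr * rr - hi * ri, hi * rr + hr * ri], axis=1)
        return df * gh, df * gr, df * gt
    if kind == "simple":
        k = E.shape[1] // 2
        h_head, h_tail = eh[:, :k], eh[:, k:]
        t_head, t_tail = et[:, :k], et[:, k:]
        fwd, inv = wr[:, :k], wr[:, k:]
        gh = 0.5 * np.concatenate([fwd * t_tail, t_head * inv], axis=1)
        gr = 0.5 * np.concatenate([h_head * t_tail, t_head * h_tail], axis=1)
        gt = 0.5 * np.concatenate([inv * h_tail, h_head * fwd], axis=1)
        return df * gh, df * gr, df * gt
    raise ValueError(f"unknown score kind {kind!r}")


def _indices(model: KGEmbeddingModel, triples: list[Triple]):
    try:
        h = np.array([model.entity_index[tr.h] for tr in triples], dtype=np.intp)
        t = np.array([model.entity_index[tr.t] for tr in triples], dtype=np.intp)
        r = np.array([model.relation_index[tr.r] for tr in triples], dtype=np.intp)
    except KeyError as exc:
        raise KeyError(f"triple component not in model: {exc.args[0]!r}") from None
    return h, r, t


def score_batch(model: KGEmbeddingModel, triples: list[Triple]) -> np.ndarray:
    h, r, t = _indices(model, triples)
    return _raw_scores(model.score_kind, model.E, model.R, h, r, t)


def score(model: KGEmbeddingModel, triple: Triple) -> float:
    """f(h, r, t) under the similarity convention (higher = more plausible)."""
    return float(score_batch(model, [triple])[0])


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------


def logistic_loss(
    model: KGEmbeddingModel, batch: TripleBatch, config: KGTrainConfig
) -> float:
    """``sum log(1+exp(-y f)) + lambda * ||Theta_touched||^2``.

    Theta is restricted to the entity and relation rows the batch touches;
    the full-table norm is recovered in expectation over batches.
    """
    triples = batch.all_triples
    if not triples:
        raise ValueError("empty batch")
    y = batch.labels
    f = score_batch(model, triples)
    loss = float(np.sum(np.logaddexp(0.0, -y * f)))
    if config.lambda_l2 > 0:
        h, r, t = _indices(model, triples)
        e_rows = np.unique(np.concatenate([h, t]))
        r_rows = np.unique(r)
        loss += config.lambda_l2 * (
            float(np.sum(model.E[e_rows] ** 2)) + float(np.sum(model.R[r_rows] ** 2))
        )
    return loss


# ---------------------------------------------------------------------------
# Negative sampling
# ---------------------------------------------------------------------------


def sample_negatives(
    kg: KnowledgeGraph,
    positives: list[Triple],
    k: int,
    seed: int,
    known: set[Triple] | None = None,
    max_tries: int = 50,
) -> TripleBatch:
    """Type-constrained filtered corruption: each positive yields ``k``
    negatives, each replacing one endpoint (side chosen uniformly) with a
    uniformly drawn entity of the same type, never the original, and
    resampled when the corruption is a known train triple.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    if known is None:
        known = set(kg.splits["train"])
    pools: dict[str, list[str]] = {}

    def pool_for(eid: str) -> list[str]:
        kind = kg.entities[eid].type.value
        if kind not in pools:
            pools[kind] = candidates_of_type(kg, kind)
        return pools[kind]

    negatives: list[Triple] = []
    for pos in positives:
        for _ in range(k):
            side = "head" if rng.integers(2) == 0 else "tail"
            orig = pos.h if side == "head" else pos.t
            pool = pool_for(orig)
            if len(pool) < 2:  # corruption impossible on this side
                side = "tail" if side == "head" else "head"
                orig = pos.h if side == "head" else pos.t
                pool = pool_for(orig)
                if len(pool) < 2:
                    raise ValueError(
                        f"cannot corrupt {pos}: no alternative entity on either side"
                    )
            neg = None
            for _try in range(max_tries):
                cand = pool[rng.integers(len(pool))]
                if cand == orig:
                    continue
                neg = (
                    Triple(cand, pos.r, pos.t)
                    if side == "head"
                    else Triple(pos.h, pos.r, cand)
                )
                if neg not in known:
                    break
            if neg is None:  # every draw hit the original; pick deterministically
                cand = next(c for c in pool if c != orig)
                neg = (
                    Triple(cand, pos.r, pos.t)
                    if side == "head"
                    else Triple(pos.h, pos.r, cand)
                )
            negatives.append(neg)
    return TripleBatch(positives=list(positives), negatives=negatives)


# ---------------------------------------------------------------------------
# Initialization from external vector providers
# ---------------------------------------------------------------------------


def init_from_vectors(
    model: KGEmbeddingModel,
    provider: dict[str, np.ndarray],
    projection_seed: int | None = None,
) -> KGEmbeddingModel:
    """Overwrite entity rows with externally provided vectors.

    Providers with a source dimension different from the model's ``d`` need
    ``projection_seed``: a fixed-seed Gaussian linear map (source_dim x d,
    scaled by 1/sqrt(source_dim)) is applied so the same input always yields
    the same row.  Entities absent from the provider keep their current rows.
    """
    proj_cache: dict[int, np.ndarray] = {}
    for eid, vec in provider.items():
        if eid not in model.entity_index:
            continue
        vec = np.asarray(vec, dtype=float)
        if vec.shape == (model.d,):
            row = vec
        else:
            if projection_seed is None:
                raise ValueError(
                    f"provider vector for {eid!r} has dimension {vec.shape[0]}, "
                    f"model d={model.d}, and no projection is configured"
                )
            src = vec.shape[0]
            if src not in proj_cache:
                prng = np.random.default_rng(projection_seed)
                proj_cache[src] = prng.standard_normal((src, model.d)) / np.sqrt(src)
            row = vec @ proj_cache[src]
        model.E[model.entity_index[eid]] = row
    return model


def load_vector_file(path: str | Path) -> dict[str, np.ndarray]:
    """Read a whitespace-separated ``id v1 v2 ...`` vector file."""
    provider: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 2:
                continue
            provider[parts[0]] = np.array([float(x) for x in parts[1:]])
    return provider


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def fit(
    kg: KnowledgeGraph,
    score_kind: str,
    config: KGTrainConfig,
    init_vectors: dict[str, np.ndarray] | None = None,
    projection_seed: int | None = None,
) -> KGEmbeddingModel:
    """Mini-batch Adagrad training of the logistic link-prediction loss.

    Reproducible under ``config.seed``; per-epoch mean loss is recorded in
    ``model.history``.
    """
    train = kg.splits["train"]
    if not train:
        raise ValueError("train split is empty")
    entity_ids = sorted(kg.entities)
    relation_names = sorted(kg.relations)
    model = KGEmbeddingModel.create(
        entity_ids,
        relation_names,
        score_kind,
        d=config.d,
        seed=config.seed,
        init_scale=config.init_scale,
    )
    if init_vectors:
        init_from_vectors(model, init_vectors, projection_seed=projection_seed)

    rng = np.random.default_rng(config.seed + 1)
    known = set(train)
    gE = np.zeros_like(model.E)
    gR = np.zeros_like(model.R)
    eps = 1e-10
    lam = config.lambda_l2

    for epoch in range(config.epochs):
        order = rng.permutation(len(train))
        epoch_loss, n_terms = 0.0, 0
        for start in range(0, len(train), config.batch_size):
            pos = [train[i] for i in order[start : start + config.batch_size]]
            batch = sample_negatives(
                kg,
                pos,
                config.negatives_per_positive,
                seed=int(rng.integers(2**31 - 1)),
                known=known,
            )
            triples = batch.all_triples
            y = batch.labels
            h, r, t = _indices(model, triples)
            f = _raw_scores(model.score_kind, model.E, model.R, h, r, t)
            epoch_loss += float(np.sum(np.logaddexp(0.0, -y * f)))
            n_terms += len(triples)
            # dL/df = -y * sigmoid(-y f)
            z = -y * f
            df = -y / (1.0 + np.exp(-z))
            dh, dr, dt = _raw_grads(model.score_kind, model.E, model.R, h, r, t, df)
            dE = np.zeros_like(model.E)
            dR = np.zeros_like(model.R)
            np.add.at(dE, h, dh)
            np.add.at(dE, t, dt)
            np.add.at(dR, r, dr)
            if lam > 0:  # L2 on the rows this batch touches
                e_rows = np.unique(np.concatenate([h, t]))
                r_rows = np.unique(r)
                dE[e_rows] += 2 * lam * model.E[e_rows]
                dR[r_rows] += 2 * lam * model.R[r_rows]
            gE += dE**2
            gR += dR**2
            model.E -= config.learning_rate * dE / (np.sqrt(gE) + eps)
            model.R -= config.learning_rate * dR / (np.sqrt(gR) + eps)
        model.history.append(epoch_loss / max(n_terms, 1))
    return model


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_model(model: KGEmbeddingModel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "entities.txt").write_text("\n".join(model.entity_ids) + "\n")
    (out / "relations.txt").write_text("\n".join(model.relation_names) + "\n")
    np.savetxt(out / "entity_table.tsv", model.E, delimiter="\t")
    np.savetxt(out / "relation_table.tsv", model.R, delimiter="\t")
    (out / "manifest.json").write_text(
        json.dumps(
            {
                "format": "kgddi-kge/1",
                "score_kind": model.score_kind,
                "d": model.d,
                "history": model.history,
            },
            indent=2,
        )
    )


def load_model(model_dir: str | Path) -> KGEmbeddingModel:
    p = Path(model_dir)
    manifest = json.loads((p / "manifest.json").read_text())
    E = np.loadtxt(p / "entity_table.tsv", delimiter="\t", ndmin=2)
    R = np.loadtxt(p / "relation_table.tsv", delimiter="\t", ndmin=2)
    return KGEmbeddingModel(
        entity_ids=(p / "entities.txt").read_text().splitlines(),
        relation_names=(p / "relations.txt").read_text().splitlines(),
        score_kind=manifest["score_kind"],
        d=manifest["d"],
        E=E,
        R=R,
        history=list(manifest.get("history", [])),
    )
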