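"""Marker-augmented transformer relation classifier.

The input layout appends two entity-marker slots after the sentence:

    [CLS] w_1 ... DRUG1 ... DRUG2 ... [SEP] [KG1] [KG2]

Ordinary tokens are looked up in the word-embedding table; the two marker
slots are looked up in the knowledge-graph entity table (or a learned
unknown-entity vector when a mention could not be linked).  Each marker
shares its position ID with its in-sentence mention, so self-attention treats
marker and mention as co-located; with sharing disabled the markers take the
position IDs following the SEP token.  The classification head concatenates
the final-layer states of CLS and the two mention tokens, applies a middle
linear layer and an output linear layer, and softmaxes over the c classes.

Training freezes the word and KG embedding tables by default (the attention
and head parameters train), and maintains a running arithmetic mean of every
trainable parameter after each optimizer update; prediction can use either
the current or the averaged parameters.  The encoder is a contract: the
shipped default is a small randomly initialized transformer, and anything
mapping an embedded batch to same-length hidden states can be substituted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .corpus import DDI_LABELS, LabelSet, RelationInstance
from .kg_embed import KGEmbeddingModel
from .nn import Tensor, concat, gather, layer_norm, softmax

__all__ = [
    "Vocabulary",
    "EncodedInput",
    "EncoderConfig",
    "AblationConfig",
    "DDIETrainConfig",
    "DDIEModel",
    "TrainingState",
    "build_input",
    "tokenize",
    "train",
    "predict",
]

RESERVED = ("[PAD]", "[UNK]", "[CLS]", "[SEP]", "DRUG1", "DRUG2", "DRUGOTHER",
            "[KG1]", "[KG2]")
PAD, UNK, CLS, SEP, DRUG1, DRUG2, DRUGOTHER, KG1, KG2 = range(9)

_TOKEN_RE = re.compile(r"\w+|[^\w\s]")


def tokenize(text: str) -> list[str]:
    """Whitespace + punctuation splitting; reserved tokens stay atomic."""
    return _TOKEN_RE.findall(text)


@dataclass
class Vocabulary:
    token_to_id: dict[str, int]

    def __post_init__(self) -> None:
        for i, tok in enumerate(RESERVED):
            if self.token_to_id.get(tok) != i:
                raise ValueError(f"reserved token {tok!r} must map to id {i}")

    @classmethod
    def build(cls, texts: list[str]) -> "Vocabulary":
        mapping = {tok: i for i, tok in enumerate(RESERVED)}
        for text in texts:
            for tok in tokenize(text):
                if tok not in mapping:
                    mapping[tok] = len(mapping)
        return cls(mapping)

    def __len__(self) -> int:
        return len(self.token_to_id)

    def encode(self, tokens: list[str]) -> list[int]:
        return [self.token_to_id.get(t, UNK) for t in tokens]


@dataclass
class EncodedInput:
    token_ids: list[int]
    position_ids: list[int]
    kg_entity_ids: tuple[str | None, str | None]
    m1_index: int
    m2_index: int
    label_id: int
    has_markers: bool = True

    def __post_init__(self) -> None:
        if len(self.token_ids) != len(self.position_ids):
            raise ValueError("token_ids and position_ids must have equal length")


@dataclass
class EncoderConfig:
    L: int = 1
    d: int = 32
    heads: int = 2
    d_ff: int = 64
    d_m: int = 32  # middle-layer dimension of the classification head
    max_len: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.d % self.heads:
            raise ValueError("d must be divisible by heads")


@dataclass
class AblationConfig:
    share_position_ids: bool = True
    freeze_embeddings: bool = True
    use_cls: bool = True
    use_mentions: bool = True
    use_kg: bool = True

    def __post_init__(self) -> None:
        if not (self.use_cls or self.use_mentions):
            raise ValueError("the head needs CLS or mention representations")


@dataclass
class DDIETrainConfig:
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 2e-3
    weight_decay: float = 0.01
    seed: int = 0


# ---------------------------------------------------------------------------
# Input construction
# ---------------------------------------------------------------------------


def build_input(
    instance: RelationInstance,
    vocab: Vocabulary,
    ablation: AblationConfig,
    labelset: LabelSet = DDI_LABELS,
    max_len: int = 128,
) -> EncodedInput:
    """Tokenize a masked sentence into the marker layout.

    Position IDs run 0,1,2,... over CLS..SEP.  With ``use_kg`` the two marker
    slots are appended last; with position sharing their position IDs copy
    the DRUG1/DRUG2 token positions (the first mention at position 1 puts its
    marker at position 1), otherwise they continue after SEP's.
    """
    tokens = tokenize(instance.sentence_masked)
    if tokens.count("DRUG1") != 1 or tokens.count("DRUG2") != 1:
        raise ValueError(
            f"masked sentence must contain DRUG1 and DRUG2 exactly once: "
            f"{instance.sentence_masked!r}"
        )
    token_ids = [CLS] + vocab.encode(tokens) + [SEP]
    m1_index = 1 + tokens.index("DRUG1")
    m2_index = 1 + tokens.index("DRUG2")
    sep_pos = len(token_ids) - 1
    position_ids = list(range(len(token_ids)))
    if ablation.use_kg:
        token_ids = token_ids + [KG1, KG2]
        if ablation.share_position_ids:
            position_ids += [position_ids[m1_index], position_ids[m2_index]]
        else:
            position_ids += [sep_pos + 1, sep_pos + 2]
    if len(token_ids) > max_len:
        raise ValueError(
            f"sequence of length {len(token_ids)} exceeds max_len={max_len} "
            f"(instance {instance.provenance})"
        )
    return EncodedInput(
        token_ids=token_ids,
        position_ids=position_ids,
        kg_entity_ids=(instance.kg1, instance.kg2),
        m1_index=m1_index,
        m2_index=m2_index,
        label_id=labelset.all_labels.index(instance.label),
        has_markers=ablation.use_kg,
    )


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


class DDIEModel:
    """Embedding tables + L-layer self-attention encoder + CLS/mention head."""

    def __init__(
        self,
        vocab: Vocabulary,
        kg_model: KGEmbeddingModel,
        config: EncoderConfig,
        ablation: AblationConfig | None = None,
        labelset: LabelSet = DDI_LABELS,
    ):
        self.vocab = vocab
        self.config = config
        self.ablation = ablation or AblationConfig()
        self.labelset = labelset
        self.kg_entity_index = dict(kg_model.entity_index)
        self.kg_lookup_count = 0  # instrumentation: KG-table reads in forward

        rng = np.random.default_rng(config.seed)
        d, dm, c = config.d, config.d_m, labelset.c
        scale = 0.02

        def init(*shape):
            return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)

        kg_rows = kg_model.E
        if kg_model.d != d:  # fixed-seed projection into the encoder space
            proj = rng.standard_normal((kg_model.d, d)) / np.sqrt(kg_model.d)
            kg_rows = kg_rows @ proj
        freeze = self.ablation.freeze_embeddings
        p: dict[str, Tensor] = {
            "word_table": Tensor(
                rng.normal(0.0, scale, size=(len(vocab), d)), requires_grad=not freeze
            ),
            "kg_table": Tensor(np.array(kg_rows), requires_grad=not freeze),
            "unk_entity": init(d),
            "pos_table": init(config.max_len + 2, d),
            "W_mid": init(3 * d, dm),
            "b_mid": Tensor(np.zeros(dm), requires_grad=True),
            "W_fc": init(dm, c),
            "b_fc": Tensor(np.zeros(c), requires_grad=True),
        }
        for l in range(config.L):
            for name in ("Wq", "Wk", "Wv", "Wo"):
                p[f"L{l}.{name}"] = init(d, d)
                p[f"L{l}.{name.replace('W', 'b')}"] = Tensor(
                    np.zeros(d), requires_grad=True
                )
            p[f"L{l}.ln1_g"] = Tensor(np.ones(d), requires_grad=True)
            p[f"L{l}.ln1_b"] = Tensor(np.zeros(d), requires_grad=True)
            p[f"L{l}.W1"] = init(d, config.d_ff)
            p[f"L{l}.b1"] = Tensor(np.zeros(config.d_ff), requires_grad=True)
            p[f"L{l}.W2"] = init(config.d_ff, d)
            p[f"L{l}.b2"] = Tensor(np.zeros(d), requires_grad=True)
            p[f"L{l}.ln2_g"] = Tensor(np.ones(d), requires_grad=True)
            p[f"L{l}.ln2_b"] = Tensor(np.zeros(d), requires_grad=True)
        self.params = p

    # -- batching --------------------------------------------------------
    def _collate(self, inputs: list[EncodedInput]):
        B = len(inputs)
        T = max(len(i.token_ids) for i in inputs)
        tok = np.full((B, T), PAD, dtype=np.intp)
        pos = np.zeros((B, T), dtype=np.intp)
        mask = np.zeros((B, T))
        marker_pos = np.full((B, 2), -1, dtype=np.intp)
        kg_rows = np.zeros((B, 2), dtype=np.intp)
        kg_known = np.zeros((B, 2))
        m_idx = np.zeros((B, 2), dtype=np.intp)
        labels = np.zeros(B, dtype=np.intp)
        for b, inp in enumerate(inputs):
            n = len(inp.token_ids)
            tok[b, :n] = inp.token_ids
            pos[b, :n] = inp.position_ids
            mask[b, :n] = 1.0
            m_idx[b] = (inp.m1_index, inp.m2_index)
            labels[b] = inp.label_id
            if inp.has_markers:
                marker_pos[b] = (n - 2, n - 1)
                for j, eid in enumerate(inp.kg_entity_ids):
                    if eid is not None and eid in self.kg_entity_index:
                        kg_rows[b, j] = self.kg_entity_index[eid]
                        kg_known[b, j] = 1.0
        return tok, pos, mask, marker_pos, kg_rows, kg_known, m_idx, labels

    # -- forward ---------------------------------------------------------
    def embed(self, tok, pos, marker_pos, kg_rows, kg_known) -> Tensor:
        """Embedding lookup: words from the word table, marker slots from the
        KG table (or the learned unknown-entity vector), plus positions."""
        B, T = tok.shape
        x = gather(self.params["word_table"], tok)
        has_markers = bool((marker_pos >= 0).any())
        if has_markers:
            self.kg_lookup_count += 1
            content = gather(self.params["kg_table"], kg_rows)  # (B,2,d)
            known = Tensor(kg_known[:, :, None])
            content = content * known + self.params["unk_entity"] * (1.0 - known)
            scatter = np.zeros((B, T, 2))
            slot_mask = np.zeros((B, T, 1))
            for b in range(B):
                for j in range(2):
                    scatter[b, marker_pos[b, j], j] = 1.0
                    slot_mask[b, marker_pos[b, j], 0] = 1.0
            x = x * Tensor(1.0 - slot_mask) + Tensor(scatter) @ content
        return x + gather(self.params["pos_table"], pos)

    def encode(self, x: Tensor, mask: np.ndarray) -> Tensor:
        """L layers of masked multi-head self-attention with post-norm
        residual blocks (Transformer encoder convention)."""
        B, T, d = x.shape
        H = self.config.heads
        dh = d // H
        bias = np.where(mask[:, None, None, :] > 0, 0.0, -1e9)
        p = self.params
        for l in range(self.config.L):
            q = (x @ p[f"L{l}.Wq"] + p[f"L{l}.bq"]).reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            k = (x @ p[f"L{l}.Wk"] + p[f"L{l}.bk"]).reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            v = (x @ p[f"L{l}.Wv"] + p[f"L{l}.bv"]).reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh)) + Tensor(bias)
            ctx = softmax(scores, axis=-1) @ v
            ctx = ctx.transpose(0, 2, 1, 3).reshape(B, T, d)
            att = ctx @ p[f"L{l}.Wo"] + p[f"L{l}.bo"]
            x = layer_norm(x + att, p[f"L{l}.ln1_g"], p[f"L{l}.ln1_b"])
            ff = nn.gelu(x @ p[f"L{l}.W1"] + p[f"L{l}.b1"]) @ p[f"L{l}.W2"] + p[f"L{l}.b2"]
            x = layer_norm(x + ff, p[f"L{l}.ln2_g"], p[f"L{l}.ln2_b"])
        return x

    def classify(self, hidden: Tensor, m_idx: np.ndarray) -> Tensor:
        """Concatenate [h_CLS; h_m1; h_m2] (ablated parts zeroed so shapes
        stay stable), apply the middle and output layers; returns logits."""
        B, T, d = hidden.shape
        flat = hidden.reshape(B * T, d)
        off = np.arange(B) * T
        h_cls = gather_rows(flat, off)  # CLS sits at index 0
        h_m1 = gather_rows(flat, off + m_idx[:, 0])
        h_m2 = gather_rows(flat, off + m_idx[:, 1])
        a = self.ablation
        cls_w = 1.0 if a.use_cls else 0.0
        men_w = 1.0 if a.use_mentions else 0.0
        h_all = concat([h_cls * cls_w, h_m1 * men_w, h_m2 * men_w], axis=-1)
        h_mid = h_all @ self.params["W_mid"] + self.params["b_mid"]
        return h_mid @ self.params["W_fc"] + self.params["b_fc"]

    def forward(self, inputs: list[EncodedInput]) -> tuple[Tensor, np.ndarray]:
        tok, pos, mask, marker_pos, kg_rows, kg_known, m_idx, labels = self._collate(
            inputs
        )
        x = self.embed(tok, pos, marker_pos, kg_rows, kg_known)
        hidden = self.encode(x, mask)
        return self.classify(hidden, m_idx), labels

    def probabilities(self, inputs: list[EncodedInput]) -> np.ndarray:
        logits, _ = self.forward(inputs)
        return softmax(logits, axis=-1).data


def gather_rows(flat: Tensor, idx: np.ndarray) -> Tensor:
    return gather(flat, np.asarray(idx, dtype=np.intp))


# ---------------------------------------------------------------------------
# Training with weight averaging
# ---------------------------------------------------------------------------


@dataclass
class TrainingState:
    model: DDIEModel
    averaged: dict[str, np.ndarray]
    update_count: int = 0
    epoch_losses: list[float] = field(default_factory=list)

    def average_update(self) -> None:
        """Fold the current trainable parameters into the running mean."""
        self.update_count += 1
        k = self.update_count
        for name, p in self.model.params.items():
            if not p.requires_grad:
                continue
            if name not in self.averaged:
                self.averaged[name] = np.array(p.data)
            else:
                self.averaged[name] += (p.data - self.averaged[name]) / k


def train(
    instances: list[RelationInstance],
    model: DDIEModel,
    config: DDIETrainConfig,
) -> TrainingState:
    """Mini-batch AdamW training of the cross-entropy loss with running
    weight averaging; frozen tables are excluded from the optimizer."""
    if not instances:
        raise ValueError("empty training set")
    ablation = model.ablation
    encoded = [
        build_input(i, model.vocab, ablation, model.labelset, model.config.max_len)
        for i in instances
    ]
    opt = nn.AdamW(
        model.params,
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
    )
    state = TrainingState(model=model, averaged={})
    rng = np.random.default_rng(config.seed)
    for _epoch in range(config.epochs):
        order = rng.permutation(len(encoded))
        total, nb = 0.0, 0
        for start in range(0, len(encoded), config.batch_size):
            batch = [encoded[i] for i in order[start : start + config.batch_size]]
            logits, labels = model.forward(batch)
            loss = nn.cross_entropy(logits, labels)
            opt.zero_grad()
            loss.backward()
            opt.step()
            state.average_update()
            total += float(loss.data)
            nb += 1
        state.epoch_losses.append(total / max(nb, 1))
    return state


def predict(
    state: TrainingState,
    instances: list[RelationInstance],
    use_average: bool = True,
    batch_size: int = 64,
) -> tuple[list[str], np.ndarray]:
    """Predicted labels and class probabilities; with ``use_average`` the
    running parameter mean is swapped in for the forward pass."""
    model = state.model
    encoded = [
        build_input(i, model.vocab, model.ablation, model.labelset, model.config.max_len)
        for i in instances
    ]
    stash: dict[str, np.ndarray] = {}
    if use_average and state.averaged:
        for name, avg in state.averaged.items():
            stash[name] = model.params[name].data
            model.params[name].data = avg
    try:
        probs = np.concatenate(
            [
                model.probabilities(encoded[s : s + batch_size])
                for s in range(0, len(encoded), batch_size)
            ]
        )
    finally:
        for name, data in stash.items():
            model.params[name].data = data
    labels = [model.labelset.all_labels[i] for i in probs.argmax(axis=1)]
    return labels, probs
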