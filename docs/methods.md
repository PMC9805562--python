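# Methods

## The model

`kgddi` treats DDI extraction as sentence-level relation classification over
a given drug-mention pair, enriched with background knowledge from a typed
pharmaceutical knowledge graph (KG).  The two stages are independent
artifacts connected by one object: the entity-embedding table.

### Stage 1 — knowledge-graph embedding

The KG has five "actual" node kinds (drug, protein, pathway, category, ATC)
and eleven relations: the eight observed in pharmaceutical resources
(category, atc, pathway, interact, target, enzyme, carrier, transporter) and
three augmentation relations (synonym, description, structure) that attach
pseudo-nodes.  `interact` is declared symmetric; it dominates real
pharmaceutical graphs by orders of magnitude, which is why score functions
that can represent symmetry (DistMult, ComplEx, SimplE) outperform pure
translation (TransE) here — the package reproduces that qualitative fact on
synthetic data.

All four score functions use the similarity convention (higher = more
plausible); TransE is the negated Euclidean distance.  Parameter budgets are
matched at d real numbers per entity and relation for every kind (ComplEx
splits d into real/imaginary halves; SimplE into head/tail and
forward/inverse halves), so kinds are comparable at fixed d.

Training minimizes the logistic loss with L2 regularization,

    L = Σ log(1 + exp(−y·f(h,r,t))) + λ‖Θ‖²,

y = +1 on observed triples and −1 on corruptions.  A printed form of this
loss sometimes appears with exp(+y·f); that sign convention would penalize
high-scoring positives, so the standard form above is used.  Negative
sampling is type-constrained (an endpoint is replaced only by an entity of
the same type, never the original) and filtered against known train triples
to avoid false negatives.  The regularizer is applied batch-locally to the
parameter rows each batch touches, which recovers the global penalty in
expectation while keeping updates sparse.  The optimizer is Adagrad with
hand-derived gradients (verified against finite differences in the test
suite).

Defaults: d = 16, λ = 1e-2, 20 negatives per positive, learning rate 0.05,
batch 256, 30 epochs.  These were chosen on the synthetic validation split:
the embedding generalizes best in this regime, and longer or hotter training
overfits the train incidence matrix (held-out edges then become
indistinguishable from non-edges).

### Link-prediction evaluation

Each evaluated triple contributes one head- and one tail-replacement rank
against all same-type candidates.  Ties take the mean rank
(1 + #higher + ½·#equal), making the metric invariant to candidate order.
Raw ranking (no candidate removed) is the default because the evaluation
protocol is described over *all* created corruptions; a filtered mode
(corruptions that are known positives elsewhere in the KG are dropped) is
available by flag.  For *recovery* measurements on dense synthetic graphs
the filtered mode is the informative one: with a symmetric dominant relation
most strong candidates are themselves true edges, so raw MRR is bounded by
neighbor exchangeability no matter how good the model is, while filtered MRR
isolates "can the model tell held-out edges from true non-edges".  The
random-ranking baseline used for comparison is the closed-form harmonic sum
E[1/rank] = (1/n)·Σ_{i≤n} 1/i with n the actual (filtered) candidate count
per case.

### Stage 2 — marker-augmented classification

Sentences are masked per target pair (DRUG1/DRUG2/DRUGOTHER), tokenized by
whitespace+punctuation with the mask tokens atomic, and laid out as
[CLS] … [SEP] [KG1] [KG2].  The marker slots are looked up in the KG entity
table (row of the linked entity, or a learned unknown-entity vector when
linking missed); every other token is looked up in the word table.  Position
IDs run 0,1,2,… over CLS…SEP; with position sharing on, each marker takes
its mention's position ID, otherwise the two IDs after SEP.  Segment
embeddings are omitted: the task is single-sentence, so they would add a
constant.

The encoder is a contract — anything that maps the embedded batch to
same-length hidden states.  The shipped default is a small randomly
initialized post-norm transformer (default L = 1 layer, d = 32, 2 heads,
feed-forward 64) built on the package's own autodiff engine; a pretrained
encoder can be substituted without interface change.  The head concatenates
[h_CLS; h_m1; h_m2] (mention states are the DRUG1/DRUG2 token states —
atomic tokens, so no sub-word pooling rule is needed), applies the middle
layer (3d×d_m) and output layer (d_m×c), and softmaxes.  The middle layer
is linear, matching the defining equations, which state no nonlinearity; d_m
defaults to 32 (it is never specified upstream).  Ablation flags zero the
disabled head inputs rather than dropping them so one W_mid shape serves all
ablations, and with KG markers disabled the marker slots are omitted
entirely (the KG table is then provably never read; a lookup counter is
asserted in tests).

Training: AdamW on cross-entropy, plain (no class re-weighting), with the
word and KG embedding tables frozen by default — position embeddings and
all attention/head parameters train; freezing only the two lookup tables is
the literal reading of "embeddings are frozen", and it is also the variant
that generalizes to entities seen only at test time.  After every optimizer
update the running arithmetic mean of all trainable parameters is folded in
(no burn-in); prediction uses the averaged parameters by default.

### Metrics and significance

Micro precision/recall/F pool TP/FP/FN over the four positive classes only
(the DDI shared-task convention; the negative class is excluded).  Note that
micro-F is the mediant of the per-class count ratios and therefore always
lies within [min, max] of the per-class Fs — though it is *not* their
support-weighted mean.  System comparison uses the approximate-randomization
shuffle test: predictions of systems A and B are swapped per instance with
probability ½, 10 000 times by default; p = (1 + #{|Δ| ≥ |Δ_obs|}) /
(1 + 10 000), two-sided, with +1 smoothing so p > 0 at finite shuffles.
Instance-level swapping (rather than full label-sequence permutation) is the
standard approximate-randomization form.

## Synthetic data

The generator defines the study conditions for every test.

**KG.**  Defaults: 80 drugs, 20 proteins, 6 pathways, 3 categories, 6 ATC
codes (115 entities).  Every entity gets a hidden planted vector of rank 4.
Drugs belong to one of three *communities* (one per category node): a drug's
vector is 0.85·(community center) + √(1−0.85²)·noise, and the category
nodes sit on the centers.  Edges per relation are the top-scoring admissible
pairs under the planted score function (DistMult by default): taxonomy
relations (category, atc) take each head's single best tail, so every drug
has exactly one category and one ATC parent; the other relations keep a
density quantile of pairs (interact 10%, target 5%, enzyme 3%, transporter
2%, carrier 1.5%, pathway 5%) — an absolute score threshold can be set
instead, and a threshold yielding zero edges is an error.  `interact` is
emitted in both directions and split jointly (an unordered pair never
straddles train/test).  Splits are 80/10/10.  Entities carry generated
names, two synonyms per drug, fake SMILES strings (syntactically plausible,
chemically meaningless — nothing in scope reads chemistry) and occasional
descriptions, so the augmentation operations and entity linking have real
work to do.

The low planted rank and the community structure are what make link
prediction *learnable* at this scale: held-out interact edges are implied by
the communities plus a rank-4 residual, both representable by a d = 16
refit.  Under the defaults a DistMult refit reaches filtered held-out MRR
6–9× the random baseline across seeds.

**Corpus.**  Sentences are instantiated from a small template bank (2- or
3-mention templates, the third mention becoming DRUGOTHER), with surfaces
drawn from each drug's names/synonyms, and exact character spans recorded.
Crucially, the template choice is independent of the label: the label of a
pair is a function of KG features only.  The default rule reads each drug's
*grade* (the index of its category parent, 0–2) and maps the pair's grade
sum 0–4 onto [negative, Mechanism, Effect, Advice, Int]; a noise fraction
(default 10%) of labels is resampled uniformly.  Because the grade sum is
ordinal and each drug's grade is encoded in its KG neighborhood, the label
is linearly decodable from the pair's KG embeddings but *not* from the text.
This is the designed separation behind the KG-marker comparison: the
marker-less model can only learn the label prior (micro-F ≈ 0.3 on the
defaults), while the marker model decodes the grades through attention
(micro-F ≈ 0.55–0.75 depending on seed and training length).

What the synthetic corpus does **not** emulate: the heavy negative-class
imbalance of real DDI corpora (≈85% negative), lexical variety, discourse
phenomena, linking ambiguity (coverage is 100% by construction) and any
text-label correlation.  Passing tests therefore demonstrate the mechanics
and the information flow from KG to classifier, not clinical-text
performance.

## Problem sizes

Tests and the acceptance script run the full pipeline at desk scale, chosen
so the whole suite completes in a few minutes on one CPU: planted KG of 115
entities (≈1000 triples), embedding d = 16; corpora of 300 train / 150 test
sentences (≈500/250 instances); encoder L = 1, d = 32, 2 heads, 25 epochs;
5 paired seeds for the marker-vs-no-marker comparison; 10 000 shuffles for
significance.

## Known limitations

- The shipped encoder is randomly initialized; absolute extraction quality
  on real corpora requires substituting a pretrained encoder through the
  encoder contract.
- Entity linking is normalized exact string matching; no fuzzy matching,
  abbreviation handling or context disambiguation.
- Discontinuous mentions (semicolon offsets) are truncated to their first
  segment; masking needs one contiguous span.
- Mixed-precision training and ensembling are out of scope; neither changes
  any defined computation.
- The head is linear on top of the encoder states; tasks whose labels are
  not (approximately) linearly decodable from [h_CLS; h_m1; h_m2] need a
  deeper head or encoder.
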