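# Methods

## The extraction problem

Clinical notes written in the TCM tradition compress several findings into
one compound phrase: a single span may name two body parts, one severity
adverb and one symptom ("head, trunk, heavily, hurt"), where the faithful
reading is two separate localized symptoms sharing one severity.  Treating
such *mixture symptom mentions* as atomic entities loses exactly the
structure an efficacy analysis needs.  This package disassembles them by
joint entity-relation extraction over three entity types — `symptom`,
`body_part`, `severity` — and two directed relation labels:

* `located_at`: symptom → body_part
* `is_a_description_of`: severity → symptom

The defining difficulty is **relation overlap**: in a large annotation
project with this schema, roughly one entity in six participates in two or
more relations (a symptom located at two body parts, a severity shared by
two symptoms).  Pairwise pipeline classifiers handle this poorly; the joint
model here is built around it.

## The joint model

Sentences are sequences of single characters (`S_char = [char_1..char_n]`);
there is no word segmentation.  Five components:

1. **Character embedding.**  Either a trainable lookup table (default,
   `d_emb = 64`, UNK row for unseen characters) or fixed per-sentence
   contextual vectors loaded from a text file (`external_contextual` mode) —
   the hook for any pretrained contextual encoder.  Computing such vectors
   is out of scope.
2. **bi-LSTM encoder.**  One layer per direction, 64 units each, so
   `h_i ∈ R^128`.  Dropout (p = 0.5) is applied to the encoder output in
   training mode only.
3. **Linear-chain CRF tagger.**  A linear map gives per-token emission
   scores over the 7 BIO tags ({B-,I-}×3 types ∪ O); learned transition,
   start and stop scores complete the path score.  The NER loss `L_ner` is
   the negative conditional log-likelihood of the gold path, with the
   log-partition computed by the forward recursion in log space (O(nK²), no
   overflow for emissions up to 1e3).  Decoding is exact Viterbi; ties break
   toward the lowest tag index.  Transition constraints are soft (learned),
   the common bi-LSTM-CRF choice.
4. **Label embedding.**  Each entity tag has a learned vector `g_i`
   (`d_g = 25`); the relation input is `z_i = [h_i, g_i]`.  Gold tags feed
   this lookup during training (a stability choice; feeding CRF-predicted
   tags is a config switch), Viterbi tags at inference.  Disabling the label
   embedding (`z_i = h_i`) is the ablation axis.
5. **Multihead sigmoid relation scorer.**  For each relation label `r` with
   parameters `U_r, W_r ∈ R^{d_z×d_r}`, `b_r ∈ R^{d_r}`, `V_r ∈ R^{d_r}`
   (`d_r = 64`, activation f = tanh):

       s_r(z_j, z_i) = V_r · tanh(U_r z_j + W_r z_i + b_r)
       P(head = j, label = r | i)  =  σ(s_r(z_j, z_i))

   Probabilities are independent per (i, j, r) cell — deliberately *not*
   normalized over heads — so one token can select several heads: that is
   what makes overlapping relations representable.  Arcs live at the token
   level: the last token of the dependent entity points at the last token of
   the head entity; every token with no outgoing relation carries one
   reserved `none` self-arc, so each token contributes gold terms.

At decode time, every cell with probability ≥ threshold whose dependent
token is the last token of a predicted entity becomes an arc; arcs convert
to span-level triples against the predicted entities, and an optional
strict-schema filter (on by default) drops type-inconsistent triples.  The
threshold defaults to 0.5 and is tuned on the dev split by grid search over
{0.1, …, 0.9} maximizing relation micro-F1.

### The relation loss

The per-gold-arc objective `Σ_i Σ_{gold arcs of i} −log P(head, label | i)`
is exposed as `relation_loss` and anchors the unit fixtures (single arc with
probability p costs exactly −log p).  As a *training* objective over
independent sigmoids, gold-only terms leave all non-gold cells without
gradient — at initialization every cell sits near σ(0) = 0.5 and threshold
decoding would keep everything.  Training therefore minimizes the full
binary cross-entropy over all (i, j, label) cells (`relation_bce`, computed
stably from raw scores), whose gold terms coincide with `relation_loss` and
which additionally drives non-gold probabilities toward 0.  This is the
standard loss of the multihead-selection formulation this model follows.
The joint objective is `L_ner + L_re`, optimized in one pass with Adam
(lr = 0.001 for all RNN layers), gradient-norm clipping at 5, batch 16,
up to 30 epochs with patience 5 on dev relation F1 (best checkpoint kept)
and an unconditional stop once dev entity and relation F1 reach 0.999.

## The pipeline baseline

Stage 1 is the same bi-LSTM-CRF tagger trained on tags alone.  Stage 2
classifies each ordered pair of entities with a bi-GRU: entity-position
indicator embeddings (outside / in-source / in-target, 8 dims) are
concatenated to the character embeddings, the bi-GRU output is pooled over
time (smooth max via log-sum-exp) and a linear softmax chooses among
{located_at, is_a_description_of, none}.  Stage 2 trains on gold entities
(negative pairs subsampled at 3:1 per positive; all pairs are scored at
inference) and is applied to stage-1 predictions at inference, so tagging
errors propagate — the effect the joint model avoids.  Both estimators share
one `TrainConfig` so budgets can be matched exactly.

## Numerical core

No deep-learning framework is used: the package carries a small reverse-mode
autodiff engine on numpy float64 (`mixsym.nn`), with broadcast-aware
arithmetic, matmul, pointwise nonlinearities, log-sum-exp, concatenation,
numpy-style indexing with scatter-add gradients, masked batch-first LSTM/GRU
cells and Adam.  Gradient correctness is enforced by central
finite-difference tests at relative tolerance 1e-4 over every parameter of a
small joint network, and the CRF forward/Viterbi/loss are tested against
exhaustive enumeration of all K^n paths (n ≤ 6, K ≤ 5, 100 random draws,
tolerance 1e-6).  Sequences are right-padded and masked; hidden states carry
through masked steps unchanged, so padding never affects real tokens.
Everything is seeded through `numpy.random.default_rng`; with a fixed seed,
training is bit-reproducible single-threaded.

## Synthetic corpus generator

Real corpora with this schema are licensed and unavailable, so the package
generates its own.  Sentences are concatenations of 1–3 *mention groups*
drawn from a template inventory: a lone symptom; a symptom located at k
body parts (k ≤ 7) with or without a severity; a body part shared by two
symptoms; a severity shared by two symptoms (with or without body parts).
Each template contributes a fixed count vector of entity types, relation
labels and entity degrees, so template frequencies can be **calibrated** to
any requested target distributions by non-negative least squares
(`scipy.optimize.lsq_linear`), with degree rows weighted hardest and
templates containing a zero-probability degree excluded outright.  For the
default targets —

| distribution | default |
|---|---|
| entity types | symptom 56.26%, body_part 36.8%, severity 6.94% |
| relation labels | located_at 86.81%, is_a_description_of 13.19% |
| entity relation-degree | 0: 6.456, 1: 76.886, 2: 14.249, 3: 1.975, 4: 0.331, 5: 0.089, 6: 0.010, 7: 0.004 (%) |

— the moment problem is solved exactly (machine precision), and empirical
deviations at 50,000+ entities stay well under one percentage point per
cell.  The degree-0 mass consists of lone symptoms; a separate `noise` knob
(default 0, since degree 0 is already in the target) can add extra
relation-free distractor sentences.  The degree-≥2 mass (16.658%) is the
overlap statistic that motivates the multihead design.  One published
summary of such an annotation project contains two internal inconsistencies
worth noting: a "706 entities in no relation" figure that is actually 4,706
(11.48% of symptoms), and degree counts summing to one more entity than the
type table; the generator follows the degree table, whose percentages are
self-consistent.

Surface forms are pseudo-Chinese: three disjoint CJK character blocks (body,
symptom, severity words of fixed lengths 2/2/1) plus full-width punctuation.
Boundaries, types and arcs are therefore a *deterministic* function of the
surface string, which is what makes the learnability criteria meaningful: a
correct implementation can reach near-perfect F1, so a shortfall indicates a
defect, not noise.  This is also what the generator does **not** emulate:
real clinical text has ambiguous segmentations, shared characters across
types, discontinuous mentions and annotation noise.  Passing here
demonstrates that the machinery optimizes and decodes correctly, not that
these F1 levels transfer to real notes.

## Study conditions and what the checks show

Problem sizes are chosen for a single CPU:

* **Learnability**: default corpus, 2,000 train / 250 dev sentences, ≤ 30
  epochs.  The joint model reaches dev entity and relation micro-F1 of 1.0
  around epoch 6 (~1.5 min).
* **Joint vs pipeline**: an overlap-rich corpus (degree mix {0: 5, 1: 60,
  2: 30, 3: 5}%, ~35% of entities in ≥ 2 relations), 800/100/100 split, both
  models trained with an identical budget (15 epochs, same seed, same
  early-stop rule).  Both saturate on this fully learnable corpus, so the
  published direction — joint relation recall ≥ pipeline relation recall —
  holds with equality at convergence; at sub-convergence budgets the
  ordering fluctuates and no claim is made there.
* **Label-embedding ablation**: identical budgets with the label embedding
  on vs off; the direction (recall with ≥ recall without) again holds, as a
  tie at saturation.
* **Generator fidelity**: 13,000 sentences (> 50,000 entities), every
  distribution cell within 1 percentage point of its target.

Strict-match evaluation is used throughout: an entity counts only if type
and both offsets match exactly; a relation only if its label, direction and
both endpoint spans match (an undirected mode exists for schemas with
uncertain direction).  Relation metrics can be stratified by the gold degree
of the endpoints (buckets 0 / 1 / 2+), isolating overlapping-relation
recall.  Boundary conventions: P = 1 when there are no predictions, R = 1
when there is no gold, F1 = 0 when tp = 0 with nonzero fp or fn.

## Degenerate inputs and edge rules

* Ill-formed BIO sequences from the decoder are repaired deterministically
  (leading/dangling `I-x` opens a span like `B-x`).
* Sentences above `max_seq_len` (default 480) are truncated with a warning;
  annotations that no longer fit are dropped.
* Relation direction is configurable off (undirected matching) because the
  schema direction is a convention; strict validation enforces
  symptom→body_part and severity→symptom.
* Entities in no relation are legal; in strict mode a relation-free
  body_part or severity triggers a warning (the guidelines reserve
  relation-free mentions for symptoms), never a rejection.
* Degree > 7 is unsupported by the generator (matches the published support).

## Known limitations

* The encoder is desk-scale; absolute F1 on licensed clinical corpora with a
  fine-tuned transformer is out of reach here and is not claimed.
* The pipeline baseline's stage-2 input encoding is one reasonable reading
  of a two-stage bi-GRU classifier; other encodings exist.
* The generator's difficulty is a design choice (deterministic surface-to-
  annotation mapping); conclusions about relative model quality on harder,
  noisier text require real data.
* Reassembling the disassembled parts into complete symptom mentions is a
  separate downstream task, out of scope.
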