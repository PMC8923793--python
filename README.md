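# mixsym

Joint entity–relation extraction for disassembling **mixture symptom
mentions** in Traditional Chinese Medicine (TCM) clinical notes.

TCM notes compress several clinical findings into single compound phrases: a
span like "头身强痛" (*head, trunk, heavily, hurt*) really describes two
symptoms — head pain and trunk pain — sharing one severity modifier.
Structuring such text for efficacy analysis requires *disassembling* these
mentions into entities and the relations between them.  This package is for
clinical-NLP researchers and corpus builders working with that schema:

* entity types `symptom`, `body_part`, `severity`;
* directed relations `located_at` (symptom → body_part) and
  `is_a_description_of` (severity → symptom).

The core estimator is a **joint multihead-selection model**: a character
embedding feeds a bi-LSTM whose states drive both a linear-chain CRF entity
tagger (loss `L_ner`, the path negative log-likelihood) and a per-pair,
per-label sigmoid relation scorer over `z_i = [h_i, g_i]` (hidden state plus
a learned embedding of the entity tag).  For each relation label *r*,

    s_r(z_j, z_i) = V_r · tanh(U_r z_j + W_r z_i + b_r)
    P(head = char_j, label = r | char_i) = σ(s_r(z_j, z_i))

Each token independently selects any number of heads (the last token of a
target entity), so one entity can participate in several relations — the
"relation overlap" that defeats pairwise pipelines (about one entity in six
in real corpora of this schema).  The joint objective is `L_ner + L_re`,
optimized in one pass; a threshold tuned on the dev split turns
probabilities into relation arcs.  A two-stage **pipeline baseline**
(bi-LSTM-CRF tagger, then a bi-GRU classifier over candidate entity pairs)
is included for controlled comparisons.

Because corpora with this schema are licensed, the package ships a
**calibrated synthetic-corpus generator**: template frequencies are fitted
by non-negative least squares so the generated entity-type, relation-label
and relation-degree distributions match the published statistics of a large
annotation project (56.26 / 36.8 / 6.94 % entity types; 86.81 / 13.19 %
relation labels; 16.658 % of entities in ≥ 2 relations).  Everything —
training, ablations, evaluation — runs from a seed, with no downloads.
The neural layers (autodiff, LSTM/GRU, CRF, Adam) are implemented on numpy
inside the package; see `docs/methods.md` for the full model description.

## Worked example

```python
from mixsym import (default_config, generate_corpus, train_dev_test_split,
                    TrainConfig, JointExtractorModel, relation_prf)

docs = generate_corpus(default_config(n_sentences=1000, seed=13))
train, dev, test = train_dev_test_split(docs, seed=13)

model = JointExtractorModel(train, dev, TrainConfig(epochs=15, seed=13))
results = model.fit()
print(results.summary())

pred = results.predict([d.sentence for d in test])
m = relation_prf(test, pred)["micro"]
print(f"relation micro: P={m.precision:.3f} R={m.recall:.3f} F1={m.f1:.3f}")
```

Output (abridged):

```
JointResults
================================================================
mode: joint   label embedding: True   seed: 13
optimizer: Adam(lr=0.001)   dropout: 0.5   batch: 16
decision threshold: 0.50   best epoch: 15
----------------------------------------------------------------
epoch       L_ner        L_re  dev entF1  dev relF1
    1    13933.12    57031.70     0.4722     0.0000
    2     9804.45    24460.72     0.6575     0.3284
  ...
    9      320.33     1529.44     1.0000     0.9901
  ...
   15       39.48      304.92     1.0000     0.9980
relation micro: P=1.000 R=1.000 F1=1.000
```

The per-epoch rows show both loss components falling and dev F1 rising to
saturation (the synthetic corpus is deterministically learnable by design —
see `docs/methods.md` for what that does and does not demonstrate); the
final line is strict-match relation precision/recall/F1 on held-out test
sentences, where a relation counts only if its label, direction and both
endpoint spans are exact.

The same workflow is available from the shell:

```bash
mixsym generate --n 1000 --seed 13 --out corpus/
mixsym stats corpus/train.json
mixsym train --train corpus/train.json --dev corpus/dev.json \
             --mode joint --seed 13 --out ckpt/
mixsym predict --checkpoint ckpt/ --input corpus/test.json --out pred.json
mixsym evaluate --gold corpus/test.json --pred pred.json
```

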