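# promptsyn

Few-shot drug-pair synergy classification for rare cancer tissues.

## The problem

High-throughput drug-combination screens report, for each (drug 1, drug 2,
cell line) triple, the two single-drug sensitivities (relative inhibition,
RI) and a **Loewe synergy score** — the excess over the response expected if
the two drugs were one compound, on a scale from −100 (antagonism) to 75
(strong synergy). A pair is called *synergistic* when

```
y = 1  if Loewe > 5,   else 0.
```

Most screened rows come from a handful of common tissues; tissues with fewer
than 4000 rows (pancreas, endometrium, liver, soft tissue, stomach, urinary
tract, bone) are **rare**, and models must adapt to them from only
k ∈ {0, 2, 4, …, 128} labeled examples.

`promptsyn` implements a language-model route to this problem and the
data-driven comparators it is measured against:

* **Tabular-to-text serialization.** Each row
  `x = {d1, d2, c, t, ri1, ri2}` becomes a fixed six-sentence text block
  ("The first drug is …") wrapped in a task instruction that ends with the
  answer cue `Synergy:`.
* **Causal-LM classifier.** A decoder-only transformer encodes the prompt
  with left padding (so the last token is always the cue); an affine head
  maps the final hidden state to two logits, trained with cross-entropy.
  Fine-tuning is either *full* (backbone + head) or *head-only* (backbone
  frozen bit-exactly). At k = 0 the model scores the continuations
  `" Positive"` vs `" Not positive"` by likelihood instead of using a head.
* **Common-tissue warm-up.** Before per-tissue adaptation the classifier is
  fine-tuned on common-tissue rows (80/20 stratified split, epoch checkpoint
  selected by validation AUPRC).
* **Nested k-shot protocol.** Each rare tissue is split 80/20 with labels
  stratified; shot sets are nested (S_k ⊂ S_2k), follow the tissue's label
  proportion, always contain both classes, and the test split is
  byte-identical across all k.
* **Baselines.** Logistic matrix factorization (collaborative filtering),
  XGBoost over one-hot drug/cell features, and a TabTransformer-style
  attention model — all without the tissue feature.
* **Metrics.** AUPRC (average precision with tie-group handling) and AUROC
  (Mann–Whitney), both verified against brute-force oracles.
* **Synthetic screens.** A latent-factor generator produces DrugComb-shaped
  tables with controllable interaction strength, noise, label prevalence and
  per-tissue distribution shift (a rotation of the tissue's cell-line
  latents), so the whole pipeline runs without any download.

The transformer backbone, its byte-level tokenizer, and the reverse-mode
autodiff engine underneath are implemented in NumPy inside this package;
the shipped trainable instance is a small random-initialized model
(H = 32, 2 layers) — the artifact is the training and evaluation protocol,
not pretrained weights.

## Worked example

```python
from promptsyn import (SimConfig, TissueSpec, generate, label_records,
                       partition_tissues, tissue_counts, serialize_record,
                       build_prompt, auroc, auprc)
from promptsyn.baselines import fit_cf
from promptsyn.kshot import SplitSpec, split_tissue

config = SimConfig(
    n_drugs=20, alpha=2.5, sigma=0.1, mechanism="additive",
    tissues={"lung": TissueSpec(6, 3000), "breast": TissueSpec(6, 3000),
             "bone": TissueSpec(3, 400)},
    seed=7,
)
records = generate(config)
examples = label_records(records)

counts = tissue_counts(records)
print("rows per tissue:", counts)
print("rare tissues:", sorted(partition_tissues(counts, threshold=1000).rare))

print(build_prompt(serialize_record(records[0])))

bone = [ex for ex in examples if ex.record.tissue == "bone"]
common = [ex for ex in examples if ex.record.tissue != "bone"]
train, test = split_tissue(bone, SplitSpec(test_fraction=0.2, seed=7))
cf = fit_cf(common, d=16, seed=7, epochs=300)
scores = cf.predict_proba([ex.record for ex in test])
labels = [ex.y for ex in test]
print(f"bone test set: n={len(test)}, positives={sum(labels)}")
print(f"common-tissue CF on held-out bone: AUROC={auroc(labels, scores):.3f} "
      f"AUPRC={auprc(labels, scores):.3f}")
```

Output:

```
rows per tissue: {'lung': 3000, 'breast': 3000, 'bone': 400}
rare tissues: ['bone']
Decide in a single word if the synergy of the drug combination in the cell line is positive or not. The first drug is DRUG-012. The second drug is DRUG-003. The cell line is CELL-001. Tissue is lung. The first drug's sensitivity using relative inhibition is 44.791. The second drug's sensitivity using relative inhibition is 54.561. Synergy:
bone test set: n=80, positives=27
common-tissue CF on held-out bone: AUROC=0.992 AUPRC=0.983
```

The 400-row "bone" tissue was never used to fit the collaborative filter,
yet because this screen's latent mechanism is shared across tissues
(`mechanism="additive"`, no shift), relational information learned on the
6000 common-tissue rows extrapolates almost perfectly. Adding a large
`shift_deg` to the rare tissue breaks exactly this transfer — see
`promptsyn.experiments.distribution_shift`.

A `promptsyn` console command exposes the same pipeline from the shell:
`promptsyn simulate`, `warmup`, `train`, `predict`, `zero-shot`, and
`kshot` (grid runs from a YAML config). Run `promptsyn --help` for options.

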