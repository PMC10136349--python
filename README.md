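# triagekit

Tools for turning **multilabel clinical text** — records that pair a
free-text chief complaint with one or more diagnosis names — into
trainable single-label classification problems, and for diagnosing and
mitigating the two failure modes such corpora exhibit: **class
overlapping** (identical complaints filed under different labels) and
**class imbalance** (diagnosis frequencies spanning orders of magnitude).

It is written for people building department-triage or
diagnosis-prediction models from hospital record dumps, where the raw
data cannot be shared: every stage is exercised end to end on a seeded
synthetic corpus generator that emulates the statistical shape of a
neurosurgery chief-complaint corpus.

## What is in the box

**Problem transformations** (`triagekit.transforms`). A record with text
*x* and label set *Y* ⊆ {1..L} can be made single-label by:

- **DM** (dictionary mapping): emit one row (*x*, ℓ) per ℓ ∈ *Y*;
- **LP** (label powerset): each distinct *Y* becomes its own class;
- **TP** (triage priority): map each label through an expert-ranked
  urgency scheme π: label → rank and keep the most urgent,
  *y* = min{π(ℓ) : ℓ ∈ *Y*};
- **integration-DM / integration-LP**: coarsen *Y* to its rank set
  {π(ℓ)} first, then apply DM or LP;
- **BR / CC**: one binary task per label (binary relevance), optionally
  chained so each task reads the earlier labels' values (classifier
  chain).

TP is the interesting one: a head-trauma + subarachnoid-hemorrhage
record is simply a trauma case, because trauma outranks hemorrhage. The
built-in 10-class scheme covers 28 frequent neurosurgical diagnoses
(`triagekit.builtin_scheme()`); custom schemes load from YAML/JSON.

**Overlap diagnostics** (`triagekit.overlap`). A row *overlaps* when its
exact text occurs in another row with a different class id — the rows no
classifier can get entirely right. `compute_overlap` counts them;
coarsening labels (TP) provably never increases the count.

**Cost-sensitive losses** (`triagekit.losses`), on an N×C probability
matrix p̂ with one-hot targets y:

- cross-entropy: mean over rows of −log p̂(true);
- focal: −α(1 − p̂)^γ log p̂ (α = 1, γ = 2 defaults);
- class-balanced focal: focal × effective-number class weight
  (1 − β)/(1 − β^{n_c});
- Tversky / focal Tversky: per class, TI_c = TP_c/(TP_c + α·FP_c +
  β·FN_c) in soft counts (α = 0.7, β = 0.3), loss Σ_c (1 − TI_c)^{1/γ}
  with γ = 4/3;
- **composite**: λ·focal + (1 − λ)·focal-Tversky with λ = 0.7 — the
  objective that trades a little headline accuracy for minority-class
  recall.

Every loss ships with its analytic gradient (`loss_gradient`), validated
against finite differences, so the suite plugs into any
probability-producing trainer.

**Reference classifier** (`triagekit.classifier`): hashed character
1–3-gram features into a linear softmax head trained by full-batch
gradient descent under any of the losses. Deterministic given a seed. A
transformer encoder can be slotted behind the same contract (see
`docs/methods.md`).

**Evaluation** (`triagekit.metrics`): confusion matrix; per-class and
macro/weighted precision, recall, F1 (macro-F1 = harmonic mean of macro
precision and macro recall); top-1 accuracy plus the one-vs-rest
averaged binary accuracy reported separately.

**Synthetic corpora** (`triagekit.synthetic`): Zipf-imbalanced diagnosis
draws over a priority scheme, ~1.27 labels per record with extra labels
biased toward the primary's priority class, and a controllable rate of
verbatim text reuse under different label sets.

## Worked example

```python
import triagekit as tk

corpus, truth = tk.generate_corpus(
    tk.GeneratorConfig(n_records=2000, overlap_rate=0.15, seed=7)
)
data = tk.MultiLabelDataset.from_corpus(corpus)
scheme = tk.builtin_scheme()

print("mean labels/record:", round(truth.mean_labels_empirical, 3))
print("method\ttotal\toverlapping\tproportion")
datasets = {
    "LP": tk.lp_transform(data),
    "integration-LP": tk.integrated_transform(data, scheme, "LP"),
    "TP": tk.tp_transform(data, scheme),
}
for ds in datasets.values():
    print(tk.compute_overlap(ds))

before = tk.compute_overlap(datasets["LP"]).proportion_pct
after = tk.compute_overlap(datasets["TP"]).proportion_pct
print("relative change LP -> TP:", tk.relative_change(before, after), "%")

train_set, test_set = tk.split_dataset(datasets["TP"], 0.2, seed=7)
model = tk.train(
    train_set,
    tk.TrainConfig(epochs=200, learning_rate=0.5, loss_id="composite", seed=0),
    spec=tk.FeatureSpec(hash_dim=2**14),
)
pred = tk.predict(model, test_set.texts())
cm = tk.confusion_matrix(test_set.class_ids(), pred, k=datasets["TP"].n_classes)
report = tk.evaluate(cm)
print("accuracy %.4f  F1-macro %.4f  F1-weighted %.4f"
      % (report.accuracy_top1, report.f1_macro, report.f1_weighted))
```

prints

```
mean labels/record: 1.258
method	total	overlapping	proportion
LP	2000	541	27.05%
integration-LP	2000	180	9.00%
TP	2000	154	7.70%
relative change LP -> TP: -71.53 %
accuracy 0.8803  F1-macro 0.0936  F1-weighted 0.8243
```

Reading it: with 15 % of records reusing an earlier complaint under a
different diagnosis set, 27 % of label-powerset rows are ambiguous;
priority coarsening collapses most of those combinations into a common
class, cutting the overlap to 7.7 % (a 71.5 % relative reduction) —
which is precisely why the TP-trained classifier reaches 88 % test
accuracy on ten imbalanced classes. The wide gap between weighted and
macro F1 is the imbalance speaking: the Zipf tail classes have very few
test rows.

The same workflow is available from the shell:

```sh
triagekit simulate --n 2000 --overlap-rate 0.15 --seed 7 --out corpus.jsonl
triagekit transform corpus.jsonl --method TP --out tp.tsv
triagekit overlap tp.tsv
triagekit train tp.tsv --loss composite --out model.npz
triagekit evaluate model.npz tp.tsv
triagekit run --method TP --loss composite --seed 7 --out-dir run/
```

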