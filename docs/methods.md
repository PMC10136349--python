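# Methods

This note records the model choices, parameter conventions and numerical
decisions behind triagekit, and what the synthetic-data experiments do
and do not demonstrate.

## The problem setting

A corpus is a list of records (chief complaint text, set of diagnosis
names). Predicting a diagnosis from the complaint is a multilabel text
classification problem with two structural pathologies typical of real
hospital dumps:

* **Class overlapping.** The complaint is a short, lossy summary; the
  diagnosis also depends on examination and history. Identical
  complaints therefore legitimately occur under different diagnosis
  sets. Rows whose exact text appears under ≥ 2 distinct classes are
  irreducibly ambiguous for any classifier, and their gradient
  contributions pull the model in opposite directions, producing
  oscillating, non-convergent training loss.
* **Class imbalance.** Diagnosis frequencies are roughly power-law; a
  handful of diagnoses dominate and the tail is thin.

## Preprocessing

Cleaning normalises complaints with Unicode NFKC, removes punctuation
runs at string edges (any length) and internal runs of length ≥ 2
(replaced by a space — single internal marks such as a clause comma are
information and are kept), collapses whitespace, and drops records
lacking either a complaint or a diagnosis. The punctuation rule is a
deterministic, documented stand-in: real-world cleaning specs are rarely
written down precisely, so the rule here is fixed by the property that
matters — idempotence (cleaning twice equals cleaning once), which the
test suite checks on arbitrary strings.

Diagnostic screening removes diagnoses occurring in fewer than
`min_count` records (records containing the diagnosis, not multiplicity,
since a record's diagnoses form a set), then drops records left with no
diagnosis. The default `min_count = 101` keeps diagnoses with strictly
more than 100 occurrences, the conventional cut for this corpus family.

De-identification is by field selection: only the complaint and
diagnosis fields are ever read; name, id and demographic columns are
ignored at parse time. No hashing layer is needed because nothing
sensitive enters the data model.

## The priority scheme

A `PriorityScheme` is an ordered list of classes, rank 1 most urgent,
each owning a set of diagnosis names; validation requires consecutive
ranks and a single class per diagnosis. The built-in 10-class
neurosurgery scheme places the 13 traumatic diagnoses at rank 1,
cerebral hemorrhage at rank 2, epilepsy at 3, and so on down to
dizziness at rank 10. One membership is genuinely ambiguous in the
source material: "subarachnoid hemorrhage" appears both among the
traumatic diagnoses and in the cerebral-hemorrhage class. The built-in
scheme resolves it to cerebral hemorrhage (rank 2) — consistent with
the worked integration example, where head trauma + subarachnoid
hemorrhage integrates to {trauma, cerebral hemorrhage} — and names the
rank-1 entry "Traumatic subarachnoid hemorrhage", the variant that
co-occurs with head trauma. Whether the rank-1 entry is the traumatic
variant is an inference, not a stated fact; config files must resolve
any duplicate membership explicitly (`resolve: {diagnosis: rank}`), so
user schemes cannot smuggle the ambiguity back in.

Lookup is exact string matching after NFKC + casefold + whitespace
normalisation. No fuzzy matching: predictability beats recall for an
expert-auditable scheme. Unknown diagnoses follow a policy — `error`,
`drop_record` (default, mirroring the restriction of modelling to the
frequent screened diagnoses) or `other_class` (a synthetic rank K+1).

## Transformations

* **DM** emits one row per (record, label), record order then label
  order. Row count is Σ|Y_r|. DM *manufactures* overlap: every
  multi-label record contributes identical texts under different
  classes.
* **LP** assigns a class per distinct label set, numbered by first
  appearance (1-based). First-appearance numbering is stable and
  order-dependent; class descriptors join the sorted member names with
  `+` so identical sets always share a descriptor regardless of
  numbering.
* **TP** coarsens each record's label set through the scheme and keeps
  the minimum rank. Tie-breaking is vacuous (min of a set); equal-rank
  duplicates collapse before the min. Records whose labels are all
  unknown under `drop_record` are omitted and listed in
  `dataset.dropped`, so row-count discrepancies between methods are
  auditable.
* **integration-DM/LP** replace each label set by its rank set first,
  then apply DM or LP — the half-way points between raw and fully
  collapsed labelling.
* **BR/CC** build per-label binary tasks. CC tasks carry the gold 0/1
  values of all earlier chain labels at train time and the chain's own
  predictions at inference (chain order defaults to vocabulary order).
  Decision threshold is 0.5 and the headline multilabel metric is
  subset (exact-match) accuracy — the strictest of the usual choices,
  fixed here because set-valued predictions need a single headline
  number.

DM evaluation scores each expanded row independently (prediction correct
iff it equals the row's own label). The laxer convention — correct if
the prediction lies anywhere in the source record's true set — is
available as a flag-style alternative by evaluating against the
multilabel view, but is not the default because it inflates DM's
apparent accuracy relative to the other single-label methods.

Splitting is stratified per class (classes with a single row go to
train), deterministic given the seed.

## Overlap statistic

A row overlaps iff its exact (already normalised) text occurs in another
row with a different class id. Rows are counted, not distinct texts —
the magnitudes of row-level totals make instance counting the right
reading — but the distinct-text count is reported alongside. Percentages
are rounded half-up to two decimals, matching printed-report precision;
relative changes are signed, 100·(after − before)/before.

The key structural fact, tested by brute force: for a fixed multiset of
texts, any many-to-one relabelling can only merge a text's class set,
never split it, so label coarsening never increases the overlapping-row
count. This is the mechanism by which TP (the coarsest labelling)
minimises overlap, integration-LP sits between TP and LP, and DM
maximises it.

## Loss suite

All losses act on an N×C matrix of predicted class probabilities p̂ and
one-hot targets y; probabilities are clipped to [1e−12, 1 − 1e−12]
before any logarithm; logs are natural.

* Cross-entropy and the focal family are **means over rows**; the
  Tversky family is a **sum over classes** of batch-level indices.
  Reductions are a convention that the source formulas leave open; these
  were fixed once so that (a) CE matches the standard library
  definition (verified against scikit-learn's `log_loss`) and (b) the
  Tversky term gives every class equal vote regardless of size — which
  is exactly the property that makes it useful under imbalance.
* Focal: −α(1 − p̂)^γ log p̂ on the true class, defaults α = 1, γ = 2
  (the standard values; the tuned values for the original corpus were
  never reported). γ = 0, α = 1 reduces exactly to cross-entropy.
* Class-balanced focal is named in the experimental lineage but never
  defined there; this package adopts the effective-number weighting
  (1 − β)/(1 − β^{n_c}), normalised to mean 1 so the loss scale is
  comparable to plain focal, with β = 0.999 by default. β = 0 or equal
  class counts reduce exactly to focal.
* Focal Tversky: per class, soft counts TP_c = Σᵢ p̂·y,
  FP_c = Σᵢ p̂·(1 − y), FN_c = Σᵢ (1 − p̂)·y;
  TI_c = (TP_c + ε)/(TP_c + α·FP_c + β·FN_c + ε) with α = 0.7, β = 0.3,
  ε = 1e−6 (ε in numerator and denominator so a class absent from a
  batch has TI = 1 and contributes zero loss); the loss is
  Σ_c (1 − TI_c)^{1/γ} with γ = 4/3, and γ = 1 recovers plain Tversky.
  The exponent is implemented exactly as printed in the source formula,
  (1 − TI)^{1/γ}. The surrounding prose is self-contradictory about
  whether γ < 1 or γ > 1 "increases focusing"; with the printed 1/γ
  exponent and γ = 4/3 > 1, exponent 3/4 < 1 amplifies near-perfect
  classes' residuals — the formula is followed and the contradiction
  noted here rather than resolved silently. The foreground/background
  semantics of the original segmentation loss are mapped onto
  classification as one-vs-rest per class, which is the only reading
  under which the per-class sum is well defined.
* Composite: λ·focal + (1 − λ)·focal-Tversky, λ = 0.7. Endpoints reduce
  exactly to the components, and the value always lies between them.

`loss_gradient` provides analytic ∂L/∂p̂ for all six losses; every
gradient is validated against central finite differences (step 1e−5,
relative tolerance 1e−6) on 100 random small batches. The trainer
composes it with the softmax Jacobian,
∂L/∂z_j = p_j (g_j − Σ_k p_k g_k).

## Reference classifier

The encoder is hashed character 1–3-gram counts, L2-normalised, hashed
with BLAKE2b into 2¹⁶ buckets by default (a fixed, versioned hash so
featurisation is identical across platforms and Python builds). This is
a deliberate choice of test surface: the subject under study is the
transformation + loss machinery acting on the probability head, which is
encoder-agnostic. A transformer backend slots in behind the adapter
contract: tokenize → embed → the same linear softmax head, the same
losses on probabilities, with the conventional fine-tuning defaults
(learning rate 2e−5, embedding dropout 0.1) applying to that backend
only. The linear reference model instead uses plain full-batch gradient
descent with a fixed learning rate (0.1 default) and no dropout —
regularisation and optimiser schedules are encoder concerns, not part of
the studied machinery.

Prediction takes the highest-probability class, ties broken toward the
lowest class id (numpy argmax's first-maximum rule, stated as contract).
Training is deterministic given the seed, including the recorded
per-epoch loss trajectory.

## Synthetic generator

Per record: a primary diagnosis is drawn from a Zipf(s = 1.2)
distribution over the scheme's diagnoses (ordered by priority rank, so
the head of the distribution is the trauma class, as in the real
frequency table); the number of labels is 1 + Poisson(mean_labels − 1)
truncated to the available labels, targeting a mean of 1.27
labels/record; extra labels prefer the primary's priority class with
probability 0.7 (this companion bias is what makes priority coarsening
collapse label combinations, mirroring the head-trauma+scalp-laceration
style of frequent combination). The complaint is a token template —
class-specific symptom token, shared duration token, optionally a shared
extra token — plus a per-record uniqueness token, so no two texts
collide by accident. With probability `overlap_rate` a record instead
copies the complaint of a uniformly chosen earlier record whose label
set differs, verbatim; injected record ids are listed in the ground
truth. Verbatim copying matches the exact-equality overlap definition;
near-duplicates would not register and are out of scope.

What the generator does **not** emulate: natural language (no syntax,
no lexical variation between synonymous complaints), label noise,
temporal drift, and near-duplicate texts. Consequently, passing the
synthetic experiments demonstrates that the machinery behaves as
designed under controlled overlap and imbalance — not that any
particular accuracy level transfers to real clinical text, where the
encoder and annotation quality dominate.

## Experiment sizes and the qualitative reproduction

The absolute headline numbers of the original study (≈ 87–88 % accuracy
on a ~25k-record hospital corpus) are functions of private data and a
transformer encoder, and are not reproduction targets. What is
reproduced, on seeded synthetic corpora, is every ordering the method
claims:

* overlap(TP) ≤ overlap(integration-LP) ≤ overlap(LP) on a 5,000-record
  corpus with overlap_rate 0.15, zipf_s 1.2;
* TP test accuracy ≥ LP test accuracy on that corpus (stratified 80/20
  split, 200 epochs, learning rate 0.5, 2¹⁴ hash buckets — desk-scale
  settings chosen so the full suite runs in well under a minute of
  training time);
* composite-loss minority recall ≥ cross-entropy minority recall on a
  ~9:1 two-class corpus (600 records, ten equiprobable diagnoses of
  which nine share the majority class, overlap_rate 0.15) in a majority
  of 5 seeds — a stochastic property asserted by majority direction, not
  by margin.

## Numerical choices and degenerate inputs

* Probability clip 1e−12 before logs; Tversky smoothing ε = 1e−6;
  rounding of printed percentages half-up to 2 decimals via decimal
  arithmetic (not banker's rounding).
* Zero-denominator precision/recall (class never predicted / never
  present) is reported as 0 and flagged in the report rather than NaN.
* Headline accuracy is top-1 (trace/N). The one-vs-rest averaged binary
  accuracy Σ(TP_i+TN_i)/Σ(TP_i+TN_i+FP_i+FN_i) is reported separately
  as `accuracy_ovr`; for single-label data it equals 1 − 2(1 − top1)/K
  (each top-1 error contributes one FP and one FN among 2·errors + ...
  bookkeeping verified exhaustively in tests), so it is redundant but
  kept for comparability with reports that print it.
* Weighted precision/recall are Σ w_i·metric_i with w_i = n_i/N (weights
  summing to 1, so a perfect classifier scores exactly 1); a printed
  formula that additionally divides by the class count is treated as a
  typographical slip, since under it no classifier could score 1.
* Empty corpora, single-class training data, empty texts, empty label
  sets and non-consecutive scheme ranks all raise typed errors rather
  than propagating garbage.

## Known limitations

* Exact-string overlap misses near-duplicates; an embedding-based soft
  overlap is out of scope.
* The linear reference classifier underfits relative to a transformer;
  macro indices on Zipf-tailed synthetic corpora are accordingly low.
  The package's claims are about orderings, not absolute levels.
* LP class ids depend on record order (first appearance); shuffling the
  corpus renumbers classes (descriptors, being sorted name joins, are
  stable).
* The scheme is expert-provided by design; no automatic priority
  learning.
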