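# Methods

## Problem setting

Curated biomedical databases (the running example is the catalog of
genome-wide association studies, GWAS) record *what* a paper reported —
its target phenotype, the ancestry groups of its study samples — but not
*where* in the text that information appears, and the curated wording
rarely matches the text verbatim. `weakext` turns such records into
training data for text extractors by treating curation-to-text matching
as classification with noisy labels:

1. **Passage extraction (A).** A term dictionary tags candidate entity
   mentions in each article; every mention becomes a candidate passage
   with up to 10 context tokens per side.
2. **Feature creation (B).** Passages become sparse vectors (n-gram
   TF-IDF blocks, positional signals).
3. **Committee voting (C).** Simple weak classifiers — matching rules,
   cue-word lexicons, a logistic-regression base learner — each cast a
   hard yes/no vote on whether a passage supports the curated datum,
   producing an I×J binary matrix M.
4. **Label estimation (D).** An EM estimator turns M into per-passage
   positive probabilities p̂ᵢ and per-classifier error rates êⱼ.
5. **Cost-sensitive learning (E).** p̂ is hardened into labels
   yᵢ = round(p̂ᵢ) and converted into importance-reweighting costs cᵢ;
   an L2-regularised hinge-loss linear SVM is trained with per-example
   weights cᵢ.

Two extraction tasks are wired end to end: ranking a document's target
phenotypes (scored by the precision-at-k of its top-k candidates), and
extracting ⟨stage, ethnicity⟩ tuples describing study samples (scored by
tuple-level micro/macro precision, recall and F1, under article-based
cross-validation).

## The label model (step D)

All variants share the smoothed error-rate (M-step) form

    e_j = ( Σ_i [ p_i (1 − M_ij) + (1 − p_i) M_ij ] + k′ ) / (I + K′)

i.e. the expected disagreement between classifier j's votes and the
current soft labels, with a Beta-style pseudo-count k′/K′ (defaults
k′ = 1, K′ = 2; likewise k = 1, K = 2 on the passage side).

Three p-updates are implemented:

* **`posterior` (default).** The maximum-likelihood E-step of the
  one-coin model (one scalar error rate per classifier, conditionally
  independent votes): p_i is the Bayes posterior
  p_i ∝ π · Π_j (1−e_j)^{M_ij} e_j^{1−M_ij}, with the mixing weight π
  re-estimated as mean(p) each iteration and p initialised to the
  smoothed vote fraction. This is the classical single-parameter
  annotator model, deliberately *not* the full confusion-matrix version
  (two error rates per classifier), which is out of scope.
* **`disagreement`.** The score-style update
  p_i = (Σ_j (1−e_j) M_ij + k)/(J + K): a reliability-weighted vote
  fraction. Fixed points are exact and analytically checkable (e.g. on
  M = [[1,1],[0,0]] with the default priors the fixed point is
  p̂ = (15/28, 1/4), ê = (3/7, 3/7)).
* **`paper_literal`.** As `disagreement` but with the error-rate update
  e_j = (Σ_i p_i M_ij + k′)/(I + K′), under which a classifier's "error"
  grows by agreeing with probable positives.

**Why `posterior` is the default.** The score-style p is compressed into
[k/(J+K), (J+k)/(J+K)] and is not a calibrated probability. Two
consequences are provable and were measured: (i) the disagreement
e-update, fed soft scores around 0.2–0.75 instead of near-0/1
posteriors, overestimates error rates badly (measured mean |ê − e| ≈
0.16 on simulated 1000×7 committees with true errors in [0.1, 0.35],
against ≈ 0.011 for `posterior`); and (ii) since round(p̂) = 1 requires
Σ_j (1−e_j) M_ij ≥ (J+K)/2 − k — the same absolute threshold as
majority vote but with shrunk per-vote weights — the score-style hard
labels are always a subset of the majority-vote positives and can only
lose accuracy when the committee is better than chance. The maximum-
likelihood E-step removes both defects; the two score-style variants are
retained because their fixed points are part of the package's
contractual surface and useful for fidelity experiments. The class
prior term matters: without it the posterior is miscalibrated whenever
the true positive rate differs from ½ (measured: EM beat majority vote
in 20/20 simulated committees with the prior vs 16/20 without).

Convergence is declared when max_i |Δp_i| < tol (default 1e−6), capped
at 100 synchronous iterations; non-convergence is reported on the
result, not raised. Hardening rounds half-up (p̂ = 0.5 → 1).

The estimator is also exposed in the model/results idiom
(`CommitteeLabelModel(M).fit()` → results with `p_hat`, `e_hat`,
`summary()`), which is the natural shape for the one genuinely fitted
model in the pipeline.

## Costs and the weighted SVM (step E)

With pos_fraction = Σ y_i / I:

    y_i = 1:  c_i = p̂_i / pos_fraction
    y_i = 0:  c_i = (1 − p̂_i) / (1 − pos_fraction)   (lemma_consistent, default)
              c_i = p̂_i / (1 − pos_fraction)          (paper_literal)

The default uses the estimated probability *of the assigned label* in
the numerator, which is what the density-ratio reading of importance
reweighting (cost ≈ p(y|x)/p_ρ(y|x)) implies; the `paper_literal`
numerator — which rewards likely-positive examples mislabelled
negative — is kept as a switch. An empty class's denominator is
conventionally 1, and costs are floored at 1e−9 so they stay strictly
positive in the p̂ = 0 corner. A useful identity for auditing: the mean
cost of the positive class equals mean(p̂ | y=1)/pos_fraction.

Training minimises reg·‖w‖²/2 + Σ_i c_i·hinge(y_i, f(x_i)) via
liblinear (dual coordinate descent, tol 1e−4, ≤ 10 000 iterations, seed
0); scaling all costs and `reg` together leaves the solution unchanged,
and integer costs are equivalent to example replication — both are
tested. The regularisation constant and optimizer are this package's
choices. Prediction thresholds the margin at 0 with ties going
positive; a training fold whose labels collapse to one class yields a
constant predictor rather than an error (relevant only for very small
folds).

## Committees

*Phenotype task* (5 rules, fixed order): mention in title/abstract;
exact match to a curated term; substring match in either direction;
exact-or-partial match to a synonym of the curated term (a pluggable
concept-grouped TSV stands in for a terminology service); compound
(multi-token) mention. Matching case-folds, normalises typography and
treats hyphens and spaces as equivalent. The title/abstract rule reads
only the text, not the curated record.

*Stage/ethnicity task* (two stacked 3-member committees): a logistic-
regression base learner trained on the curated weak labels — voting on
training rows only via 5-fold out-of-fold prediction so it never votes
on its own training data —, a cue-word rule (sample-description terms
for the positive/negative committee; stage-cue terms for the
initial/replication committee, defaulting to "initial" when no cue or
both cues fire, since the initial stage is obligatory in a GWAS), and
the curated weak label itself (ethnicity present in either stage;
for the stage committee, "initial" wins when an ethnicity is curated
under both stages). The bundled 65-term sample-description and 4+4-term
stage-cue lexicons are reconstructions of the *kind* of list a curator
would write, not anyone's exact lists, and are user-replaceable files.

## Features

Phenotype task: character 2–4-grams of the mention, word (1,2)-grams and
character 2–4-grams of the context window — each block TF-IDF weighted
(smoothed IDF log((1+N)/(1+df)) + 1) and L2-normalised per block — plus
binary in-title/in-abstract flags and a per-section-title flag bag.
N-gram ranges are this package's choice of standard small ranges.
Context windows may cross sentence boundaries for this task; document-
frequency statistics are fitted over training passages.

Stage/ethnicity task: a one-hot canonical-entity indicator, Porter-
stemmed context (1,2)-gram TF-IDF, section-title TF-IDF, the mention's
normalised character offset from the article start and from its section
start, and the entity's same-article mention count; the assembled
vector is standardised to zero mean and unit variance per dimension
with training statistics (this produces dense matrices; at the corpus
sizes this package targets that is the simpler and faster route).
Windows never cross sentence boundaries here. The Porter stemmer is the
classic 1980 algorithm, implemented in-package and verified against the
published example set.

## Synthetic study conditions

The generators produce everything the pipeline consumes, in the same
file formats the real readers parse.

*Committee matrices*: true labels drawn with a configurable positive
prior (default 0.4), J classifiers flipping independently with
per-classifier error rates (< 0.5 enforced).

*Phenotype corpora*: each document plants one gold phenotype (two with
probability 0.5, matching the ~1.5 targets per paper typical of curated
GWAS records) in the title with probability 0.9 (otherwise the
abstract), echoes it in the body, and adds 2–3 distractor phenotypes in
body sentences. The curated term is the canonical name, a synonym
(probability 0.3) or a single-character typo (probability 0.1) —
emulating the standardised-terminology mismatch that makes curated data
noisy. The bundled vocabulary is ~40 phenotypes with synonyms.

*Stage/ethnicity corpora*: documents draw 1–2 initial-stage ancestry
groups and, with probability 0.6, a replication group; every true tuple
is supported by 1–2 sample-description sentences whose stage cue appears
with probability 0.7, sometimes echoed by an unlinked mention; 1–2
bystander groups appear only in background sentences without sample
vocabulary. With probability `label_noise` a curated tuple names a
bystander group instead of the true one — corrupting the weak labels in
both directions while the returned evaluation gold stays clean. The
bundled dictionary maps ~60 surface terms (country adjectivals and
demonyms) to 14 top-level ancestry groups, so dictionary coverage of the
generated corpora is complete by construction (which is what makes the
assign-all baseline's recall exactly 1.0 — mirroring the qualitative
behaviour of that baseline on real data).

What the generators do *not* emulate: real discourse (sentences are
templated), abbreviations, tables, cross-sentence coreference, tribal or
fine-grained ancestry terms, and curation errors other than the modelled
synonym/typo/tuple-swap channels. Passing tests therefore demonstrate
that the machinery is correct and that the cost-sensitive route beats
the cost-insensitive one *under these planted conditions*; they do not
certify real-corpus accuracy figures.

## Evaluation protocol

P@k counts a document as correct when any of its top-k ranked
phenotypes matches any curated term (case-insensitive); documents with
empty gold are excluded from the denominator, documents without
predictions count as misses. Tuple metrics: micro pools TP/FP/FN over
documents; macro averages per-document precision and recall first and
takes the harmonic mean of the two macro averages (not the mean of
per-document F1s). A document with empty gold and empty prediction
contributes precision = recall = 1 to the macro average; one with gold
but no predictions contributes precision 0 (the convention had to be
chosen; recall is unaffected). Cross-validation shuffles articles with
the run seed and splits at article granularity; predictions are pooled
over folds before the final metric computation.

## Problem sizes and determinism

Default benchmark sizes — 200-document corpora, 10 replicate seeds for
the noisy-label ordering experiment, 1000×7 committees with 20
replicates for label-model recovery, 100-document corpora with 3
replicates for phenotype ranking — were chosen so the whole suite and
the reproduction script each run in minutes on one CPU while keeping
sampling error well inside the margins being asserted. All randomness
flows from a single root seed per run (simulation, fold shuffling,
solver seeding); repeating any CLI run with the same manifest reproduces
its output tree byte for byte, which the test suite asserts.

## Known limitations

* The extractors assume dictionary-based mention detection; entities
  absent from the dictionary are invisible (sequence-tagging detectors
  are explicitly out of scope).
* The label model assumes conditionally independent committee members;
  strongly correlated rules (e.g. exact match ⊆ substring match) violate
  this, which inflates confidence but in practice still orders passages
  usefully.
* The cost formula inherits EM's calibration: under the score-style
  variants the hardened labels are systematically conservative (see
  above), so those variants are for fidelity experiments, not production
  use.
* The cost-sensitive route's advantage over direct weak-label training
  is an average-and-stability effect: across replicate corpus draws its
  macro F1 is nearly constant while the cost-insensitive route's varies
  widely with how the label noise happens to fall, so on an individual
  draw direct training can match or exceed it.
* Macro-averaged metrics are sensitive to the zero-prediction convention
  documented above.
* XML support is a minimal title/abstract/section dialect; full-text
  journal XML must be converted upstream.
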