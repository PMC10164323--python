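# Methods

## Model

The classifier is a linear scorer over binary substructure features.
Training consists of counting. For each class $C_i$ (odor descriptor) and
feature $F_j$ (SMARTS pattern):

* **weight** $G_{j,i} = \Pr(F_j \mid C_i)$, the fraction of training
  molecules of class $i$ containing pattern $j$. Multilabel molecules
  contribute to every class they carry.
* **idf** $\mathrm{idf}_j = \log\!\big(|C| / \#\{\text{classes with} \ge 1
  \text{ member containing } F_j\}\big)$. Zero iff the feature occurs in
  every class.
* **influence** $I_{i,j} = a_{i,j} G_{j,i}$, where the weighting factor
  $a$ defines the model variant:

  | variant | $a_{i,j}$ | resulting $I_{i,j}$ |
  |---|---|---|
  | `same_weighted` | $1$ | $G$ |
  | `tfidf_weighted` | $\text{tf-idf}$ | $G^2\,\mathrm{idf}$ |
  | `tfidf_over_prfc` | $\text{tf-idf}/G$ | $\text{tf-idf}$ |
  | `tfidf_over_prfc_times_prcf` | $\text{tf-idf}\cdot\Pr(C_i\mid F_j)/G$ | $\text{tf-idf}\cdot\Pr(C_i\mid F_j)$ |

  Because occurrence is binary, the term-frequency factor
  $\#(F_j,C_i)/\mathrm{len}(C_i)$ *is* $G$, so
  $\text{tf-idf} = G \cdot \mathrm{idf}$ — an identity the test suite
  checks on random instances.

Prediction: a molecule's per-class score is the sum of the influences of
its present, selected, trained features; the argmax set is predicted. A
molecule with no usable features, or whose argmax set spans all classes,
is *unpredictable* — it is neither correct nor incorrect but stays in the
overall-accuracy denominator.

### Numerical choices

* **Log base.** The idf log base is natural log by default and
  configurable. Changing base multiplies every tf-idf influence by the
  constant $1/\ln b$, so no argmax prediction can change; the suite
  verifies prediction invariance between base $e$ and base 10.
* **Division variants at $G=0$.** `tfidf_over_prfc` divides the weighting
  factor by $G$; where $G = 0$ the influence is defined as 0, the limit of
  $\text{tf-idf}\cdot(1/G)\cdot G$. This removes the singularity without
  changing any defined value. Likewise for the $\Pr(C|F)$ variant, and
  $\Pr(C_i|F_j)$ is 0 where the feature never occurs.
* **Ties.** All classes attaining the maximal score are predicted (score
  comparison is exact float equality; tied sums arise from identical
  influence sums, which are computed in identical order). A tie over the
  *full* class set means unpredictable; a proper-subset tie is a
  multilabel prediction.
* **Untrained features.** Features absent from every training molecule
  have no defined idf; they are flagged untrained and ignored at
  prediction, mirroring what happens when a held-out molecule carries
  substructures never seen in training.
* **Feature selection** drops features with idf = 0 (present in every
  class). Under tf-idf weighting this is provably a no-op for the
  predicted sets, since such features carry zero influence either way;
  under same-weighting it changes results and is the recommended setting.

## Feature extraction

Catalogs of SMARTS features are built by computing the maximum common
substructure (RDKit `rdFMCS`, element-level atom comparison) over every
unordered pair of a reference corpus, keeping each distinct MCS with at
least `min_atoms` atoms (default 2). Patterns are de-duplicated via a
round-trip through the toolkit's canonical SMARTS writer; output order is
first-appearance order over pairs in corpus order, so identical inputs
yield byte-identical catalogs. A per-pair timeout (default 5 s) skips
pathological pairs with a warning instead of stalling the build. The
hierarchical relationship between fragments (a larger fragment implies
its sub-fragments) is not stored; every pattern is matched directly
against every molecule, which yields the same binary presence
information. The repository bundles a 20-odorant corpus (all MW < 200) so
catalog construction is exercised end to end; the algorithm accepts any
corpus size, and a precomputed catalog can be loaded from a plain-text
SMARTS file for large-scale feature spaces whose pairwise MCS is
computed elsewhere.

## Descriptor overlap and panel preprocessing

$\mathrm{overlap}(d_1,d_2) = \#M_{d_1\cap d_2} / \min(\#M_{d_1},
\#M_{d_2})$: 1 when one descriptor's molecule set contains the other's,
0 when disjoint, undefined (an error) for descriptors without molecules.

Raw panel tables (molecules × descriptors, percent applicability) are
reduced in five ordered stages: (1) a descriptor applies to a molecule iff
applicability ≥ 25 % (inclusive); (2) descriptors need ≥ 10 molecules
(inclusive); (3) descriptors whose mean overlap with the other survivors
is > 0.49 (strict) are dropped — computed once on the post-stage-2 set,
with an iterative worst-offender mode behind a flag; (4) manually listed
descriptors are dropped (for the classic atlas recipe: *heavy* and
*light*, which panelists use inconsistently); (5) molecules left without
descriptors are removed. Every stage's surviving counts are recorded in a
report. Threshold directionality (inclusive vs strict) follows the
literal wording of the recipe the defaults encode.

## Validation protocol

* **Correctness.** A prediction is correct iff it is a non-empty subset
  of the molecule's true labels. Overall accuracy divides by all tested
  molecules, predicted accuracy by those where a prediction was made.
* **Cross-validation.** Objects are shuffled with an explicit seed and
  split into k (default 5) near-equal unstratified folds; idf, feature
  selection and all counts are recomputed per training split. The
  feature catalog itself is fixed across folds — only counts are refit —
  consistent with how untrained features are handled. Metrics are pooled
  over all held-out predictions, then averaged across classes. `k=None`
  trains and tests on the full dataset (training accuracy).
* **Under-/over-estimated one-vs-rest metrics.** The classifier predicts
  an argmax set but molecules can carry several true labels. For a focus
  class, a multilabel molecule whose prediction hit a *different* true
  label is scored either as a miss (true 1 / predicted 0 —
  *underestimated*, a lower bound) or reassigned to the rest class
  (true 0 / predicted 0 — *overestimated*, an upper bound; at least one
  true label genuinely is in the rest class). ROC AUC uses the hard 0/1
  predictions as scores; a class with constant truth has undefined AUC
  and is excluded from the class mean with a log note. MCC follows the
  convention that two all-zero vectors score 1 (the classifier correctly
  put every molecule in the rest class; occurs only in overestimated
  mode); other degenerate one-class tables score 0. Means are reported to
  two decimals, percentages to one.

## Synthetic data

The generator emulates the qualitative structure-odor findings the method
is designed to surface — esters ↔ fruity, sulfur ↔ sickening, chain
hydroxyl ↔ medicinal, C=C ↔ floral, quaternary alkyl ↔ woody, benzene
↔ perfumery — by assembling each molecule from its class's core fragment
plus 0–3 random linear-alkyl decoys, then corrupting labels: with
probability `noise` the label is replaced by a random other class, with
probability `multilabel` a second label is added. The motif SMARTS are
mutually exclusive under alkyl decoration, so the structural signal is
exact and label corruption is the only noise source. Defaults are
6 classes × 10 molecules — small enough that every study in the test
suite and acceptance script runs in seconds, large enough that every
class survives five-fold splitting. The noisy study uses noise 0.1 and
multilabel 0.28 (≈ 1.28 labels per molecule, the multilabel density of
the classic 64-molecule odor dataset).

What passing synthetic tests do **not** show: real odorants are not
motif-plus-alkyl assemblies, real descriptor noise is not uniform over
classes, and real feature spaces (tens of thousands of MCS fragments)
are vastly larger than the 9-pattern synthetic catalog. Results on the
synthetic studies validate the *mechanics* (counting, weighting,
selection, evaluation conventions), not chemical generality.

## Known limitations

* Pairwise MCS scales quadratically in corpus size; corpora beyond a few
  hundred molecules should precompute catalogs offline.
* The classifier outputs argmax label sets only — no calibrated
  probabilities or thresholded multilabel scores.
* Influence values are reported unnormalized as defined above; their
  absolute scale depends on class counts and idf and is comparable
  within a model, not across datasets.
* Descriptor labels compare by exact normalized string; no fuzzy or
  semantic matching.
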