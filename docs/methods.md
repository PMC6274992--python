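# Methods

## Model

The unit of analysis is the ordering, not the level, of expression.
For gene set *G* and control cohort *C*, every unordered member pair
*(i, j)* (genes sorted lexicographically, pairs in canonical
combination order) gets a template bit: `true` iff `x_i < x_j` in a
strict majority of control samples. A tie within a sample counts as
"not less than"; an exact 50/50 split across the cohort resolves to the
lexicographically first gene ranking lower, so template construction is
deterministic. Pair support — the fraction of controls agreeing with
the majority — is retained and always lies in [0.5, 1].

A sample's GSR index for *G* is the fraction of template bits its own
values reproduce, with a tied sample pair counting as a mismatch of a
strict template bit. Consequences used by the tests: the index is
invariant to the input order of set members and to any monotone
transform of the expression scale; for a tie-free sample, negating the
values maps the index to one minus itself; and the majority template is
the maximizer of the cohort-mean index over all 2^P pair assignments
(verified exhaustively on small fixtures).

This is a single-template reading of differential rank conservation
(DIRAC): one template, built from controls only, scores both arms.
There is no case-phenotype template and no template-based classifier;
classification is done separately on the functionome profiles.

## Control scoring and why it matters

How control samples are scored against a control-derived template
determines whether the per-set case/control comparison is calibrated:

* **insample** — template from all controls, controls scored against
  it. Each control takes part in the majority vote that scores it, so
  control scores are optimistic (on the default synthetic preset this
  inflates the null false-positive rate of the per-set Mann-Whitney
  test to roughly 0.15 at p < 0.05). Kept for descriptive summaries.
* **loo** — template from all controls, each control rescored against
  the majority of the other n−1. The mean bias vanishes, but cases and
  controls now face slightly different templates, and the per-set
  difference in conditional means overdisperses; the measured null
  false-positive rate stays near 0.10.
* **split** (default) — controls in even positions (of the given
  column order) build the template, controls in odd positions are
  scored, and cases are scored against the same template. Conditional
  on the template, both arms are i.i.d. draws from the same score
  distribution under the null, so the Mann-Whitney test is calibrated
  (measured 0.045–0.05). The cost is that half the controls serve only
  the template; the reported control functionome covers the scored
  half.

The public `build_rank_template` / `gsr_index` operations always use
the full cohort handed to them; the split happens inside
`reconstruct_functionome`.

## Group correction

Stage groups can be scored against control pools restricted to
different gene universes (multi-platform pairing), which shifts each
group's control baseline. The correction multiplies each raw case mean
by `mean(control means) / (group's control mean)`. This multiplicative
form reproduces a published four-stage corrected-mean table from its
printed raw means to within 1e-3 and degenerates to the identity when
all control means coincide; it is a reconstruction — the source
analysis states only that case means were "corrected by the averages of
the control groups" — and is documented as such.

## Staged inference

* Mann-Whitney U, two-sided, exact null for tie-free arms of at most 8
  observations, otherwise normal approximation with tie and continuity
  correction (scipy); NA observations drop out per arm.
* Benjamini-Hochberg step-up within each stage; NA p-values propagate
  and do not count toward m (statsmodels; an independent hand-rolled
  step-up serves as the test oracle).
* Ranking: ascending p, ties broken by larger |1 − ratio|, then set id
  — fully deterministic.
* Intersection: membership-signature counting over the four top-k
  lists (k = 75 by default); region sizes sum to the union size.
* Progressive filter: q < α (default 0.05) in **all** four stages and
  strictly decreasing case/control ratio (tolerance ε, default 0).
  All-stage significance is the strictest reading of "statistically
  significant"; both choices are parameters.
* Core/auxiliary: terms of the common and progressive lists with
  ontology depth < 3 are excluded as non-specific upper-level terms
  (depth = shortest parent path to any root, following is_a and
  part_of). Cross-list matches are exact identity or ancestor-closure
  Jaccard ≥ τ (default 0.5); matched terms merge into single-linkage
  clusters (connected components of the thresholded similarity graph) —
  the core elements. Surviving unmatched terms of either list are the
  auxiliary elements. The similarity measure, τ, and the depth cutoff
  are stand-ins for an informally described merging step and are all
  configurable; ancestor-closure Jaccard was chosen because it is
  deterministic and needs nothing beyond the DAG (no corpus
  information content).

## Classification

RBF-kernel SVM (scikit-learn SVC), C = 1, bandwidth from the median
heuristic (γ = 1 / (2 · median squared pairwise distance)) — an
explicit, deterministic stand-in for kernlab-style automatic sigma
estimation. Stratified k-fold CV, reshuffled each of the (default 10)
repeats from a seed sequence, so reports are bit-reproducible given the
seed. Binary tasks report sensitivity, specificity, accuracy and AUC
from pooled decision values; the 4-class task uses one-vs-one voting
and reports macro recall/specificity, accuracy, and per-class
one-vs-rest AUCs built from summed pairwise margins — the latter are
labeled non-comparable to a binary AUC, and no single multiclass AUC
is reported. Group-profile clustering is Euclidean average linkage with
optimal leaf ordering; the dendrogram serializes to Newick with branch
lengths derived from merge heights.

## Synthetic cohorts

The generator emulates a staged tumor study with a shared control pool:

* Every gene has a baseline log-scale level (N(7, 1)); a sample is the
  baseline plus i.i.d. Gaussian jitter with `noise_sd` (default 0.5
  baseline-SD units). The default leaves the control cohort conserving
  roughly 85% of within-set orderings; lighter jitter pushes scores
  toward 1, heavier jitter toward the random floor.
* Deregulation = within-set value permutation: in each case sample, a
  fraction π of a planted set's member genes (rounded, at least 2 when
  π > 0) have their values permuted among themselves. The GSR index
  responds only to ordering, so this is the minimal faithful
  perturbation; mean planted-set GSR is non-increasing in π, reaching
  the ~0.5 random-match floor at π = 1 with vanishing jitter.
* Default preset: 1000 genes, 200 sets of 10 genes, 40 controls, 40
  cases per stage; 10 "common" sets at π = 0.5 in every stage and 10
  "progressive" sets at π = (0.4, 0.6, 0.8, 1.0) across stages I–IV —
  severities bracketing the common level, with the weakest stage still
  detectable at this cohort size and the strongest a complete
  scramble. A `paper_scale()` preset carries the full-size stage
  layout (34/39/695/131 cases, 136 controls).
* Planted sets receive genes reserved exclusively for them. Without
  this, gene sharing lets planted perturbations leak into nominally
  null sets and both null calibration and ranking recovery are
  unattainable by construction. Real gene-set collections do share
  genes — that leakage (a known false-positive source in set-level
  analyses) is deliberately absent from the simulation, so passing
  recovery tests demonstrate the inference machinery, not robustness
  to set overlap.
* An accompanying random ontology supplies a single root, the two
  immune ancestor terms at depth 1 (reusing their real accessions so
  downstream defaults apply), hub terms, and one gene set per term
  with a name-consistent term mapping; roughly 40% of terms fall under
  the immune ancestors.
* Everything is byte-reproducible from the config seed.

What the simulation does **not** model: platform/batch effects,
probe-level structure, correlated gene-gene noise, gene sharing between
sets, and survival outcomes.

## Problem sizes and numerical choices

The test suite and the acceptance script run the default preset over
ten seeds (about 20 simulated cohorts of 200 samples × 1000 genes) plus
brute-force oracle checks on fixtures of at most 4 genes and 6 samples,
where exhaustive enumeration over all 2^P templates and all
Mann-Whitney reassignments is feasible; the whole suite completes in
well under a minute on one CPU. Degenerate inputs are handled
explicitly: sets with fewer than two genes in the common universe
become NA columns with a skip reason (never zero-filled), empty
Mann-Whitney arms yield NA p-values with a warning, a zero control mean
yields an NA ratio, and ties everywhere resolve by the deterministic
rules above.

## Known limitations

* The split control scoring halves the control sample available to the
  statistical comparison; with very small control cohorts (< ~10) the
  loo or insample modes may be preferable for description, at the cost
  of calibration.
* Depth < 3 is a crude proxy for "non-specific upper-level term" and
  interacts with ontology granularity.
* The name-based set-to-term mapping assumes GMT-style names derived
  from term names; collections with other naming conventions need an
  explicit mapping file.
* Multi-dataset pairing averages each control's per-set score over the
  pairings of a stage group; with heterogeneous platforms this blends
  gene universes rather than stratifying by them.
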