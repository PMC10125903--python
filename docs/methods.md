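# Methods

## The prediction problem

Given a panel of cancer models (cell lines or PDX models), the package
predicts a quantitative synergy score for a pair of drugs in a model.
Positive scores denote synergy (the combination outperforms the expectation
from the monotherapies), negative scores antagonism.  The design constraint
inherited from the Cancer Drug Atlas lineage is that predictors must be
derivable from routinely available data only: monotherapy sensitivity
(AUC-like summaries), drug–target annotations and binary mutation calls —
no gene expression or chemical structure.

## Drug–drug distance (step 1)

Let `X` be the n × m monotherapy matrix (drugs × models).

1. **Cosine similarity.** `A[i, j] = cos(x_i, x_j)` over the models
   observed in *both* drugs' rows (raw, uncentered values; no z-scoring).
   Pairs sharing fewer than `min_overlap = 3` models, or with a zero-norm
   restricted vector, are marked missing and later imputed with the minimum
   observed off-diagonal similarity — i.e. treated as maximally dissimilar
   without inventing structure.  A drug whose entire observed vector is
   zero has no direction and is rejected.
2. **Profile distance.** `M[i, j] = ||A[i, ·] − A[j, ·]||₂`: two drugs are
   close when they relate to the whole panel in the same way.  The phrase
   "Euclidean similarity of A" in the lineage is deliberately implemented
   as a Euclidean *distance* between rows of `A`, since Ward linkage
   requires a distance; this is the one place the package takes an
   interpretive stance, and it is the standard one.
3. **Ward cophenetic distance.** `M` is clustered with Ward linkage
   (`scipy.cluster.hierarchy`); the drug–drug distance used as a feature is
   the cophenetic distance — the merge height at which two drugs first
   join a cluster.  It is ultrametric by construction
   (`d(i,k) ≤ max(d(i,j), d(j,k))` for all triples), which the test suite
   asserts exhaustively on small panels against an independent
   Lance–Williams agglomeration oracle.  SciPy's tie-breaking (earliest
   cluster index) makes the linkage deterministic.

## Features and symmetry (step 2)

Each (drug A, drug B, model) record is described by exactly four
predictors:

| feature            | meaning                                           |
|--------------------|---------------------------------------------------|
| `sens_a`, `sens_b` | monotherapy sensitivity of each drug in the model |
| `target_indicator` | 1 iff either drug targets a gene mutated in the model |
| `coph_dist`        | cophenetic drug–drug distance                     |

No tissue or model covariates are added, keeping the comparison with the
name-encoding baseline fair.  Missing sensitivity is an error by default
(silent imputation distorts benchmarks); per-drug median imputation is
available behind a flag.  Unordered pairs are canonicalized
(`drug_a ≤ drug_b`) at ingest; training tables are *symmetry augmented* —
both orientations emitted, swapping `sens_a`/`sens_b` — so a model cannot
learn the arbitrary orientation of the pair.  Test tables are never
augmented.

## Predictors

* **ACDA** — `RandomForestRegressor` on the four features.  Hyperparameters
  are chosen by random search: candidates are sampled from
  {trees 100/200/500, depth ∞/5/10/20, min leaf 1/2/5/10, features
  all/√p}, scored by mean R² over k shuffled folds, and the *default*
  configuration is always evaluated as candidate 0 — so the selected
  configuration never scores below the untuned one on the same folds.
  Defaults: `n_iter = 20`, `k = 5` (`TuningConfig()`); repeated benchmarks
  use a reduced search (`TuningConfig.fast()`: `n_iter = 5`, `k = 3`,
  trees ≤ 200) as their default, which changes wall-clock cost far more
  than accuracy on the planted data.
* **CDA** — the predecessor baseline on the same four features: logistic
  regression when the target takes exactly two values (probability-scale
  predictions), ordinary least squares otherwise.
* **EN** — random forest on one-hot encoded names only: one indicator per
  drug (1 if the drug is either member of the pair) and per model.
  Vocabularies freeze at fit; unseen names encode to all-zero blocks
  silently.  This is what makes EN collapse when train and test studies
  share no identifiers.
* **EN-ACDA** — the four features concatenated with the one-hot design,
  tuned like ACDA.
* **ACDA-EN-ACDA** — the exact elementwise mean of ACDA and EN-ACDA
  predictions.

A single master seed derives the tuning-sampler, fold and forest seeds
(`numpy.random.SeedSequence`), so every fit and benchmark is bitwise
reproducible.

## Benchmarking

**MCCV.** Records are split 2/3 : 1/3 *by unordered drug pair*: all records
of a pair — every model and both orientations — land on one side, so a
trained combination can never leak into evaluation.  Per repeat the pooled
test predictions are correlated (Pearson) with measured scores; 10 repeats
give mean ± SEM (sample n−1 standard deviation over √repeats).  All methods
are evaluated on identical split plans (paired comparison).  Per-pair
prediction averaging is *off* inside benchmarks and applied only in
candidate ranking.  Unstratified (record-level) splitting exists for
comparison but is not the default.

**Down-sampling.** Per repeat, the test set is fixed and training subsets
of increasing size are nested prefixes of one seeded permutation of the
training pool, reducing between-size variance; size `None` denotes the full
pool and reproduces the plain benchmark for the same seed.

**3-1-1 fold rotation.** Pairs are split into five folds; in each rotation
hyperparameters are selected by training candidates on three folds and
scoring on a fourth, then both tuned and default forests are refit on all
four and evaluated on the held-out fifth.

**Cross-study transfer.** `cross_study_evaluation` trains on one study and
tests on another, each with its own cophenetic matrix.  A predictor that
outputs an exact constant on the test study (EN with fully disjoint
identifiers: its whole design is zero) has an undefined Pearson
correlation; the function reports r = 0 for it by convention, since a
constant carries no ranking information.  `pearson_and_sem` itself raises
on zero-variance inputs.

## PDX workflow

Categorical tumor responses map to scores as CR = 0.75, PR = 0.5,
SD = 0.25, PD = 0.0; only the CR anchor is canonical, the rest are a
documented, fully configurable package default in 0.25 steps.
`rank_candidates` trains every method on all measured combinations, scores
the unmeasured pair × model universe (both orientations, requiring observed
sensitivity for both drugs), and optionally collapses mirrored rows by
averaging.  Between-method agreement on above-threshold hit sets is scored
with the exact upper-tail hypergeometric probability
`hypergeom.sf(k − 1, N, K, n)`.

## Synthetic data

The generator plants the structure the method assumes rather than imitating
any real screen's marginals:

* **Monotherapy**: drugs belong to one of 6 latent clusters;
  `sens = clip(0.5 + 0.3·cluster_profile + 0.05·model_effect +
  0.05·noise, 0, 1)`.  Clustering monotherapy therefore recovers the latent
  groups and the cophenetic distance is informative by construction.
* **Mutations**: i.i.d. Bernoulli(0.2) over 60 genes × 30 models; each drug
  targets 2 genes.  This yields a target-hit indicator rate near 0.6.
* **Scores**: records are drawn without replacement from all pair × model
  combinations; with proximity `q = 1 − coph/max(coph)`,

  * linear: `0.5·ind + 0.3·q + 0.1·(sens_a + sens_b) + ε`,
  * nonlinear: `0.15·ind + 0.1·q + 0.1·(sens_a + sens_b) + 0.6·ind·q + ε`,

  with `ε ~ N(0, 0.05)`.  The nonlinear interaction is representable by a
  forest but not by a linear model, separating ACDA from the CDA baseline
  by design.
* **Two-study variant**: an independent second draw from the same process,
  with a chosen fraction of drug/model identifiers renamed, so features
  transfer but names do not.
* **PDX variant**: continuous scores discretized at (0.125, 0.375, 0.625)
  — the midpoints of the default category scores, so category ↔ score
  round-trips.

Defaults are 40 drugs × 30 models, 600 records, noise 0.05.  What passing
tests on this data shows: the pipeline recovers planted signal without
leakage, the methods order as their designs predict, and everything is
reproducible.  What it does not show: performance on real screens, whose
noise is heteroscedastic and structured, whose mutations are correlated,
and whose synergy is not a clean function of these four features.

## Numerical and design notes

* Canonical lexicographic sorting on write gives byte-identical CSV
  round-trips (reads use pandas' `float_precision="round_trip"`).
* Negative "no synergy" sampling draws unmeasured unordered pairs
  uniformly without replacement, assigns score 0 and a uniformly drawn
  model (records need a model id); repeated negative sets are realized by
  distinct seeds.
* Random-search ties resolve to the earliest candidate; split and fold
  shuffles are `default_rng(seed)` permutations.
* Dendrogram figures cut the tree into `min(10, n − 1)` flat clusters; arc
  color is a monotone light-to-dark ramp in cophenetic distance, and the
  figure model (`DendrogramArcFigure`) exposes leaf order, cluster labels
  and per-arc color values for programmatic inspection.  Heatmaps sort
  labels before clustering so the rendered order is independent of input
  row order.
* Adding an exact duplicate drug merges with its twin at height 0 but can
  shift *other* cophenetic values (the similarity matrix gains a column
  and Ward's weights change); this perturbation is regression-tested on a
  frozen fixture rather than bounded in closed form.

## Problem sizes

The shipped tests and the acceptance script run the full benchmark at the
default generator scale (600 records, 10 MCCV repeats, reduced search),
the cross-study comparison at the same scale, and the ranking/overlap
analysis on a 16-drug × 10-model study — sizes chosen so the complete
pipeline, not a shortcut, is exercised on a single CPU.

## Known limitations

* The generator's planted function shares the model's feature set, so
  absolute correlations here are optimistic; only *contrasts* between
  methods are meaningful evidence.
* CDA's logistic mode emits probability-scale scores that are compared
  directly with continuous measurements when correlated; this is a
  convention, not a calibration.
* No handling of dose–response surfaces, raw tumor-volume time series, or
  synergy-metric harmonization; inputs are assumed already summarized.
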