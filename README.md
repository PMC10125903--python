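# acda

Drug-combination synergy prediction for cancer models, using only data that
routine pharmacogenomic screens already produce: monotherapy drug
sensitivity (AUC-like summaries), drug–target annotations, and binary
mutation calls.  The package is aimed at computational pharmacologists who
want to prioritize drug pairs for combination testing in cell-line panels
or patient-derived xenograft (PDX) collections without gene-expression or
chemical-structure inputs.

## The method

For a drug pair (A, B) in model *m*, the synergy score *s* is regressed on
four features:

```
s(A, B, m) ≈ f( sens_A(m), sens_B(m), I[targets(A) ∪ targets(B) hit a mutated gene in m], d_coph(A, B) )
```

where `d_coph` is the **cophenetic drug–drug distance**: drug response
vectors are projected to pairwise cosine similarity **A**, the Euclidean
distance between rows of **A** gives **M**, and Ward hierarchical
clustering of **M** yields a dendrogram whose first-join merge heights
define an ultrametric distance between drugs.  The regressor *f* is a
random forest tuned by random search over k-fold cross-validation (the
**ACDA** method).  For benchmarking, the package also implements the
predecessor **CDA** (logistic/linear regression on the same features), the
DREAM-challenge-style **EN** (random forest on one-hot encoded drug and
model names), **EN-ACDA** (both designs concatenated), and the
**ACDA-EN-ACDA** consensus (exact mean of ACDA and EN-ACDA predictions).

Evaluation uses Monte Carlo cross-validation with leave-pair-out
stratification: 2/3 of the *unordered drug pairs* (never individual
records) train, 1/3 test, repeated 10 times; Pearson correlation of
predicted versus measured synergy is reported as mean ± SEM.  Training
tables are symmetry-augmented — both (A, B) and (B, A) orientations — and a
per-pair averaging function collapses mirrored predictions downstream.

## Worked example

Everything runs on synthetic data with planted synergy structure — no
downloads:

```
$ acda synth -o demo --n-drugs 20 --n-models 12 --n-records 200 --seed 1
wrote dataset + ground_truth.csv to demo
$ acda validate demo
OK: 20 drugs, 12 models, 60 genes, 200 synergy records, 129 unique pairs
$ acda benchmark demo --methods acda,cda,en,en-acda,consensus --repeats 5 --seed 1 -o results.csv
ACDA: r = 0.976 +/- 0.001
CDA: r = 0.983 +/- 0.001
EN: r = 0.392 +/- 0.041
EN-ACDA: r = 0.978 +/- 0.002
ACDA-EN-ACDA: r = 0.978 +/- 0.001
wrote results.csv
```

Each line is the mean ± SEM Pearson correlation between predicted and
measured synergy over 5 leave-pair-out MCCV repeats.  The feature-based
methods (ACDA, CDA, EN-ACDA) recover the planted signal almost fully —
this generator's default scoring function is linear, so the CDA baseline
is not handicapped here (use `--synergy-function nonlinear` to plant an
interaction only the forest captures).  EN, which sees only drug/model
*names*, scores far lower because held-out pairs are unseen combinations.

Ranking unmeasured combinations:

```
$ acda rank demo --methods acda,cda --seed 1 -o candidates.csv
wrote candidates.csv (2080 candidates)
$ head -3 candidates.csv
drug_a,drug_b,model,sens_a,sens_b,target_indicator,coph_dist,ACDA,CDA,averaged
D001,D004,M008,0.787...,0.767...,1.0,0.0476...,0.9488...,0.9398...,True
D000,D013,M005,0.794...,0.741...,1.0,0.0588...,0.9473...,0.9366...,True
```

The top candidates are pairs of mutually close drugs (small `coph_dist`)
whose targets hit a mutated gene (`target_indicator = 1`) — exactly the
planted synergy profile.  `averaged=True` marks per-pair averaged scores.

Also available: `acda distance` (cophenetic matrix export),
`acda features`, `acda fit` / `acda predict` (model persistence),
`acda plot dendrogram|heatmap` (synergy-arc dendrogram; clustered
prediction heatmap).

As a library:

```python
from acda import GeneratorSpec, generate_dataset, run_mccv_benchmark

dataset, truth = generate_dataset(GeneratorSpec(seed=1))
results = run_mccv_benchmark(dataset, methods=["acda", "cda"], repeats=10)
for r in results:
    print(r.method_tag, r.mean_r, r.sem)
```

## Input formats

A dataset directory contains four UTF-8, comma-separated files with header
rows:

| file              | layout                                              |
|-------------------|-----------------------------------------------------|
| `monotherapy.csv` | rows = drugs, columns = models, first column `drug_id`; empty cell = missing |
| `mutations.csv`   | rows = genes, columns = models, cells ∈ {0, 1}, first column `gene_id` |
| `targets.csv`     | columns `drug_id,gene_id`, one row per target gene  |
| `synergy.csv`     | columns `drug_a,drug_b,model,score,source`          |

Tables hand-exported from public resources (GDSC, DrugComb, NIBR PDXE) in
this layout work directly; the package ships no downloaders.

See `docs/methods.md` for the model, its assumptions, parameter defaults
and known limitations.
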