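"""Deterministic synthetic datasets with planted synergy structure.

The generator emulates the statistical premise of the method: drug synergy
is predictable from the two monotherapy sensitivities, a drug-target /
mutation hit indicator, and the cophenetic drug-drug distance.  Drugs are
assigned to latent sensitivity clusters, so the Ward clustering of the
generated monotherapy matrix recovers meaningful distances; the synergy
score is then an explicit function of the four features (computed through
the package's own distance pipeline) plus Gaussian noise.

Two planted forms are provided:

* ``linear``   -- score = 0.5*indicator + 0.3*(1 - coph/max) +
  0.1*(sens_a + sens_b) + eps
* ``nonlinear`` -- adds a strong indicator x proximity interaction that a
  linear model cannot represent, separating the forest-based methods from
  the linear baseline by design.

A single seed governs every draw through documented sub-seed derivation;
identical specs give byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import (
    CapacityError,
    Dataset,
    DrugTargetMap,
    MonotherapyMatrix,
    MutationMatrix,
    SynergyRecord,
)
from .drug_distance import drug_drug_distance
from .features import target_mutation_indicator

__all__ = [
    "GeneratorSpec",
    "DEFAULT_CATEGORY_THRESHOLDS",
    "generate_dataset",
    "generate_two_study_dataset",
    "generate_pdx_dataset",
]

LINEAR_COEFFICIENTS = {
    "indicator": 0.5,
    "proximity": 0.3,
    "sensitivity": 0.1,
    "interaction": 0.0,
}

NONLINEAR_COEFFICIENTS = {
    "indicator": 0.15,
    "proximity": 0.1,
    "sensitivity": 0.1,
    "interaction": 0.6,
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic study.

    Defaults describe a mid-sized screen: 40 drugs in 6 latent sensitivity
    clusters across 30 models, 60 candidate genes mutated independently at
    rate 0.2, 2 annotated targets per drug, 600 measured pair-model records
    and Gaussian measurement noise with standard deviation 0.05 on the
    synergy score.
    """

    n_drugs: int = 40
    n_models: int = 30
    n_genes: int = 60
    n_drug_clusters: int = 6
    targets_per_drug: int = 2
    mutation_rate: float = 0.2
    synergy_function: str = "linear"  # or "nonlinear"
    coefficients: dict = field(default_factory=dict)
    noise_sd: float = 0.05
    n_records: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("n_drugs", "n_models", "n_genes", "n_drug_clusters"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.synergy_function not in ("linear", "nonlinear"):
            raise ValueError(
                f"unknown synergy_function {self.synergy_function!r}"
            )

    def resolved_coefficients(self) -> dict:
        base = (
            LINEAR_COEFFICIENTS
            if self.synergy_function == "linear"
            else NONLINEAR_COEFFICIENTS
        )
        return dict(base, **self.coefficients)


def _sub_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _planted_score(
    coeff: dict, sens_a: float, sens_b: float, indicator: int, proximity: float
) -> float:
    return (
        coeff["indicator"] * indicator
        + coeff["proximity"] * proximity
        + coeff["sensitivity"] * (sens_a + sens_b)
        + coeff["interaction"] * indicator * proximity
    )


def generate_dataset(spec: GeneratorSpec) -> tuple[Dataset, pd.DataFrame]:
    """Generate the four tables plus a ground-truth feature/score table.

    Monotherapy sensitivity of drug d in model m is
    ``0.5 + 0.3*cluster_profile[c(d), m] + 0.05*model_effect[m] + 0.05*eps``
    clipped to [0, 1], so drugs in one latent cluster share a response
    profile and the cophenetic distance is informative.  Records are drawn
    without replacement from all unordered pairs x models; stored scores are
    the planted function of the *realized* features plus noise.

    Returns ``(dataset, ground_truth)`` where ``ground_truth`` carries the
    noiseless score ``true_score`` alongside the four realized features.
    """
    rng_mono, rng_mut, rng_tgt, rng_rec, rng_noise = _sub_rngs(spec.seed, 5)
    drugs = [f"D{i:03d}" for i in range(spec.n_drugs)]
    models = [f"M{i:03d}" for i in range(spec.n_models)]
    genes = [f"G{i:03d}" for i in range(spec.n_genes)]

    cluster = rng_mono.integers(spec.n_drug_clusters, size=spec.n_drugs)
    profiles = rng_mono.normal(size=(spec.n_drug_clusters, spec.n_models))
    model_effect = rng_mono.normal(size=spec.n_models)
    mono_values = np.clip(
        0.5
        + 0.3 * profiles[cluster]
        + 0.05 * model_effect
        + 0.05 * rng_mono.normal(size=(spec.n_drugs, spec.n_models)),
        0.0,
        1.0,
    )
    monotherapy = MonotherapyMatrix(
        pd.DataFrame(mono_values, index=pd.Index(drugs, name="drug_id"),
                     columns=models)
    )

    mut_values = (
        rng_mut.random(size=(spec.n_genes, spec.n_models)) < spec.mutation_rate
    ).astype(int)
    mutations = MutationMatrix(
        pd.DataFrame(mut_values, index=pd.Index(genes, name="gene_id"),
                     columns=models)
    )
    targets = DrugTargetMap(
        {
            d: frozenset(
                rng_tgt.choice(genes, size=spec.targets_per_drug, replace=False)
            )
            for d in drugs
        }
    )

    coph = drug_drug_distance(monotherapy)
    max_coph = float(coph.to_numpy().max())

    all_triples = [
        (a, b, m)
        for i, a in enumerate(drugs)
        for b in drugs[i + 1 :]
        for m in models
    ]
    if spec.n_records > len(all_triples):
        raise CapacityError(
            f"n_records={spec.n_records} exceeds the {len(all_triples)} "
            "available pair-model combinations"
        )
    chosen = rng_rec.choice(len(all_triples), size=spec.n_records, replace=False)
    coeff = spec.resolved_coefficients()

    records, truth_rows = [], []
    for idx in sorted(chosen):
        a, b, m = all_triples[idx]
        sens_a = monotherapy.sensitivity(a, m)
        sens_b = monotherapy.sensitivity(b, m)
        indicator = target_mutation_indicator(a, b, m, targets, mutations)
        coph_ab = float(coph.at[a, b])
        proximity = 1.0 - coph_ab / max_coph if max_coph > 0 else 1.0
        true = _planted_score(coeff, sens_a, sens_b, indicator, proximity)
        score = true + (
            float(rng_noise.normal(scale=spec.noise_sd)) if spec.noise_sd else 0.0
        )
        records.append(SynergyRecord(a, b, m, score, "synthetic"))
        truth_rows.append(
            {
                "drug_a": a, "drug_b": b, "model": m,
                "sens_a": sens_a, "sens_b": sens_b,
                "target_indicator": indicator, "coph_dist": coph_ab,
                "proximity": proximity, "true_score": true, "score": score,
            }
        )
    dataset = Dataset(monotherapy, mutations, targets, records)
    dataset.validate()
    return dataset, pd.DataFrame(truth_rows)


def _rename_dataset(dataset: Dataset, fraction: float, prefix: str,
                    seed: int) -> Dataset:
    rng = np.random.default_rng(seed)
    drugs = list(dataset.monotherapy.drug_ids)
    models = list(dataset.monotherapy.model_ids)
    n_d = int(round(fraction * len(drugs)))
    n_m = int(round(fraction * len(models)))
    renamed_drugs = {drugs[i] for i in rng.choice(len(drugs), n_d, replace=False)}
    renamed_models = {models[i] for i in rng.choice(len(models), n_m, replace=False)}
    dmap = {d: (f"{prefix}{d}" if d in renamed_drugs else d) for d in drugs}
    mmap = {m: (f"{prefix}{m}" if m in renamed_models else m) for m in models}

    mono = dataset.monotherapy.df.rename(index=dmap, columns=mmap)
    mut = dataset.mutations.df.rename(columns=mmap)
    targets = DrugTargetMap(
        {dmap[d]: genes for d, genes in dataset.targets.mapping.items()}
    )
    synergy = [
        SynergyRecord(dmap[r.drug_a], dmap[r.drug_b], mmap[r.model], r.score,
                      r.source).canonicalized()
        for r in dataset.synergy
    ]
    return Dataset(MonotherapyMatrix(mono), MutationMatrix(mut), targets, synergy)


def generate_two_study_dataset(
    spec: GeneratorSpec, rename_fraction: float = 1.0
) -> tuple[tuple[Dataset, pd.DataFrame], tuple[Dataset, pd.DataFrame]]:
    """Two independently sampled studies sharing one planted score function.

    Study B follows the same generative process with fresh draws, then the
    stated fraction of its drug and model identifiers is renamed so they do
    not occur in study A.  Feature-based methods transfer between the
    studies; name-based (one-hot) methods lose exactly the renamed fraction
    of their vocabulary.
    """
    if not 0 < rename_fraction <= 1:
        raise ValueError("rename_fraction must be in (0, 1]")
    seed_b, seed_rename = (
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(spec.seed).spawn(2)
    )
    study_a = generate_dataset(spec)
    ds_b, truth_b = generate_dataset(replace(spec, seed=seed_b))
    ds_b = _rename_dataset(ds_b, rename_fraction, "B-", seed_rename)
    # keep the truth table's keys aligned with the renamed dataset
    key_frame = pd.DataFrame(
        [(r.drug_a, r.drug_b, r.model) for r in ds_b.synergy],
        columns=["drug_a", "drug_b", "model"],
    )
    truth_b = pd.concat(
        [key_frame, truth_b.drop(columns=["drug_a", "drug_b", "model"])], axis=1
    )
    return study_a, (ds_b, truth_b)


DEFAULT_CATEGORY_THRESHOLDS = (0.125, 0.375, 0.625)
"""Score cut points separating PD | SD | PR | CR.

These are the midpoints between the default category scores
(PD=0, SD=0.25, PR=0.5, CR=0.75), so mapping a category back to its score
and re-thresholding round-trips.
"""


def generate_pdx_dataset(
    spec: GeneratorSpec,
    category_thresholds: tuple[float, float, float] = DEFAULT_CATEGORY_THRESHOLDS,
) -> tuple[Dataset, pd.DataFrame]:
    """A categorically scored study shaped like a PDX tumor-response screen.

    Continuous planted scores are discretized into PD / SD / PR / CR by the
    strictly increasing ``category_thresholds``.  Returns the dataset (with
    continuous scores, standing in for tumor-volume-derived sensitivity) and
    a response table with one categorical label per combination record.
    """
    thresholds = tuple(category_thresholds)
    if list(thresholds) != sorted(thresholds) or len(set(thresholds)) != len(
        thresholds
    ):
        raise ValueError(
            f"category thresholds must be strictly increasing, got {thresholds}"
        )
    dataset, truth = generate_dataset(spec)
    labels = np.array(["PD", "SD", "PR", "CR"])
    idx = np.searchsorted(np.array(thresholds), truth["score"].to_numpy(),
                          side="right")
    responses = truth[["drug_a", "drug_b", "model", "score"]].copy()
    responses["response"] = labels[idx]
    return dataset, responses
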