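"""Feature construction for (drug A, drug B, model) synergy records.

Each record is described by exactly four predictors:

* ``sens_a``, ``sens_b`` -- monotherapy sensitivity of the two drugs in the
  record's model,
* ``target_indicator`` -- 1 if either drug targets a gene mutated in the
  model, else 0,
* ``coph_dist`` -- the cophenetic drug-drug distance.

Symmetry augmentation emits both orientations (A, B) and (B, A) of every
pair so that trained models cannot latch onto the arbitrary column order of
the two sensitivities; the indicator and the cophenetic distance are
orientation-invariant by construction.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .data_model import (
    DrugTargetMap,
    MonotherapyMatrix,
    MutationMatrix,
    SynergyRecord,
    ValidationError,
)

__all__ = [
    "FEATURE_COLUMNS",
    "KEY_COLUMNS",
    "MissingFeatureError",
    "target_mutation_indicator",
    "build_feature_table",
]

KEY_COLUMNS = ["drug_a", "drug_b", "model"]
FEATURE_COLUMNS = ["sens_a", "sens_b", "target_indicator", "coph_dist"]


class MissingFeatureError(ValidationError):
    """A record needs a monotherapy sensitivity that is not observed."""


def target_mutation_indicator(
    drug_a: str,
    drug_b: str,
    model: str,
    targets: DrugTargetMap,
    mutations: MutationMatrix,
) -> int:
    """1 iff any target gene of either drug is mutated in the model.

    The union of the two drugs' target sets is intersected with the model's
    mutated genes, so a shared mutated target counts once.  Models absent
    from the mutation matrix yield 0.
    """
    genes = targets.targets_of(drug_a) | targets.targets_of(drug_b)
    if not genes:
        return 0
    return int(bool(genes & mutations.mutated_genes(model)))


def build_feature_table(
    records: Sequence[SynergyRecord],
    monotherapy: MonotherapyMatrix,
    cophenetic: pd.DataFrame,
    targets: DrugTargetMap,
    mutations: MutationMatrix,
    augment_symmetry: bool = False,
    impute_missing: bool = False,
    include_score: bool = True,
) -> pd.DataFrame:
    """Assemble the four-feature design table for a list of records.

    One row per record; two with ``augment_symmetry`` (the mirrored row swaps
    ``sens_a``/``sens_b`` and the drug names, keeping indicator and distance
    identical).  A pure function: identical inputs give an identical table.

    Missing monotherapy sensitivity raises :class:`MissingFeatureError`
    listing the offending records; with ``impute_missing`` the per-drug
    median sensitivity is substituted instead.
    """
    medians = monotherapy.df.median(axis=1) if impute_missing else None
    rows: list[dict] = []
    missing: list[tuple[str, str, str]] = []

    def sens(drug: str, model: str, key: tuple[str, str, str]) -> float:
        value = monotherapy.sensitivity(drug, model)
        if pd.isna(value):
            if impute_missing and medians is not None and drug in medians.index:
                return float(medians[drug])
            missing.append(key)
            return float("nan")
        return value

    for rec in records:
        a, b = rec.pair
        key = (a, b, rec.model)
        sa, sb = sens(a, rec.model, key), sens(b, rec.model, key)
        indicator = target_mutation_indicator(a, b, rec.model, targets, mutations)
        coph = float(cophenetic.at[a, b])
        base = {
            "drug_a": a,
            "drug_b": b,
            "model": rec.model,
            "sens_a": sa,
            "sens_b": sb,
            "target_indicator": indicator,
            "coph_dist": coph,
        }
        if include_score:
            base["score"] = rec.score
        rows.append(base)
        if augment_symmetry:
            mirror = dict(base)
            mirror["drug_a"], mirror["drug_b"] = b, a
            mirror["sens_a"], mirror["sens_b"] = sb, sa
            rows.append(mirror)

    if missing:
        unique = sorted(set(missing))
        raise MissingFeatureError(
            f"missing monotherapy sensitivity for {len(unique)} record(s): "
            f"{unique[:10]}"
        )
    columns = KEY_COLUMNS + FEATURE_COLUMNS + (["score"] if include_score else [])
    return pd.DataFrame(rows, columns=columns)
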