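"""Core domain types, CSV input/output, dataset filters and negative-pair sampling.

The package works with four tables:

* a monotherapy sensitivity matrix (drugs x models, AUC-like scores),
* a binary mutation matrix (genes x models),
* a drug -> target-gene mapping,
* a list of measured synergy records (drug A, drug B, model, score).

Drug pairs are unordered; every record is canonicalized at ingest so that
``drug_a <= drug_b`` lexicographically.  The ordered (B, A) duplicates needed
for symmetry-augmented training are produced downstream by the features
module, never stored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "FormatError",
    "CapacityError",
    "MonotherapyMatrix",
    "MutationMatrix",
    "DrugTargetMap",
    "SynergyRecord",
    "Dataset",
    "canonical_pair",
    "read_dataset",
    "write_dataset",
    "synergy_to_frame",
    "synergy_from_frame",
    "filter_min_entries",
    "sample_no_synergy_pairs",
]


class ValidationError(ValueError):
    """A table or record violates a structural invariant."""


class FormatError(ValueError):
    """An input file does not follow the documented CSV layout."""


class CapacityError(ValueError):
    """A request exceeds what the data can supply (e.g. too many pairs)."""


def canonical_pair(drug_a: str, drug_b: str) -> tuple[str, str]:
    """Return the unordered pair as a lexicographically sorted tuple."""
    return (drug_a, drug_b) if drug_a <= drug_b else (drug_b, drug_a)


@dataclass(frozen=True)
class MonotherapyMatrix:
    """Drugs x models sensitivity table (AUC-like, missing values allowed).

    ``df`` is indexed by drug id with model ids as columns.  Missing
    sensitivities are ``NaN`` -- never 0, which is a valid AUC.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if df.index.duplicated().any():
            raise ValidationError("duplicate drug identifiers in monotherapy matrix")
        if df.columns.duplicated().any():
            raise ValidationError("duplicate model identifiers in monotherapy matrix")
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise ValidationError(
                f"monotherapy matrix needs >=2 drugs and >=2 models, got {df.shape}"
            )
        empty = df.index[df.isna().all(axis=1)]
        if len(empty):
            raise ValidationError(
                f"drugs with no observed sensitivity: {sorted(empty)}"
            )

    @property
    def drug_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def model_ids(self) -> list[str]:
        return list(self.df.columns)

    def sensitivity(self, drug: str, model: str) -> float:
        """Scalar lookup; NaN when the cell is missing or unknown."""
        if drug not in self.df.index or model not in self.df.columns:
            return float("nan")
        return float(self.df.at[drug, model])


@dataclass(frozen=True)
class MutationMatrix:
    """Binary genes x models matrix; 1 means the gene is mutated in the model."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if df.index.duplicated().any():
            raise ValidationError("duplicate gene identifiers in mutation matrix")
        if df.columns.duplicated().any():
            raise ValidationError("duplicate model identifiers in mutation matrix")
        vals = df.to_numpy()
        if vals.size and not np.isin(vals[~pd.isna(vals)], [0, 1]).all():
            raise ValidationError("mutation matrix cells must be 0 or 1")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def model_ids(self) -> list[str]:
        return list(self.df.columns)

    def mutated_genes(self, model: str) -> frozenset[str]:
        """Genes mutated in ``model``; empty set for unknown models."""
        if model not in self.df.columns:
            return frozenset()
        col = self.df[model]
        return frozenset(col.index[col == 1])


@dataclass(frozen=True)
class DrugTargetMap:
    """Mapping drug id -> set of target gene ids (possibly empty)."""

    mapping: Mapping[str, frozenset[str]]

    def targets_of(self, drug: str) -> frozenset[str]:
        return self.mapping.get(drug, frozenset())

    @property
    def drug_ids(self) -> list[str]:
        return list(self.mapping)


@dataclass(frozen=True)
class SynergyRecord:
    """One (drug A, drug B, model, score) observation.

    Positive scores denote synergy, negative antagonism.  ``source`` is a
    free-text study/tissue label used for grouping filters.
    """

    drug_a: str
    drug_b: str
    model: str
    score: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.drug_a == self.drug_b:
            raise ValidationError(
                f"synergy record pairs a drug with itself: {self.drug_a}"
            )
        if not np.isfinite(self.score):
            raise ValidationError(
                f"non-finite synergy score for ({self.drug_a}, {self.drug_b}, {self.model})"
            )

    @property
    def pair(self) -> tuple[str, str]:
        return canonical_pair(self.drug_a, self.drug_b)

    def canonicalized(self) -> "SynergyRecord":
        a, b = self.pair
        if (a, b) == (self.drug_a, self.drug_b):
            return self
        return replace(self, drug_a=a, drug_b=b)


SYNERGY_COLUMNS = ["drug_a", "drug_b", "model", "score", "source"]


def synergy_to_frame(records: Sequence[SynergyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.drug_a, r.drug_b, r.model, r.score, r.source) for r in records],
        columns=SYNERGY_COLUMNS,
    )


def synergy_from_frame(frame: pd.DataFrame) -> list[SynergyRecord]:
    missing = [c for c in SYNERGY_COLUMNS[:4] if c not in frame.columns]
    if missing:
        raise FormatError(f"synergy table missing required column(s): {missing}")
    source = frame["source"] if "source" in frame.columns else [""] * len(frame)
    return [
        SynergyRecord(str(a), str(b), str(m), float(s), str(src)).canonicalized()
        for a, b, m, s, src in zip(
            frame["drug_a"], frame["drug_b"], frame["model"], frame["score"], source
        )
    ]


@dataclass
class Dataset:
    """The four tables bundled together, with cross-reference validation."""

    monotherapy: MonotherapyMatrix
    mutations: MutationMatrix
    targets: DrugTargetMap
    synergy: list[SynergyRecord] = field(default_factory=list)

    def validate(self) -> list[str]:
        """Raise :class:`ValidationError` on broken invariants.

        Returns a list of non-fatal warnings (e.g. mutation-matrix models
        never referenced by the monotherapy table, which are retained --
        their target-indicator features simply default to 0).
        """
        drugs = set(self.monotherapy.drug_ids)
        models = set(self.monotherapy.model_ids)
        bad_drugs = sorted(
            {d for r in self.synergy for d in (r.drug_a, r.drug_b) if d not in drugs}
        )
        if bad_drugs:
            raise ValidationError(
                f"synergy records reference drugs absent from monotherapy: {bad_drugs}"
            )
        bad_models = sorted({r.model for r in self.synergy if r.model not in models})
        if bad_models:
            raise ValidationError(
                f"synergy records reference models absent from monotherapy: {bad_models}"
            )
        notes = []
        extra = sorted(set(self.mutations.model_ids) - models)
        if extra:
            notes.append(
                f"mutation matrix has {len(extra)} model(s) not in monotherapy "
                f"(retained): {extra[:5]}"
            )
        unmut = sorted(models - set(self.mutations.model_ids))
        if unmut:
            notes.append(
                f"{len(unmut)} model(s) lack mutation data; target indicator "
                f"defaults to 0 for them"
            )
        return notes

    @property
    def known_pairs(self) -> set[tuple[str, str]]:
        return {r.pair for r in self.synergy}


# ---------------------------------------------------------------------------
# CSV input/output
#
# Layout (UTF-8, comma separated, header required, minimal quoting):
#   monotherapy.csv  rows = drugs, columns = models, first column `drug_id`
#   mutations.csv    rows = genes, columns = models, first column `gene_id`
#   targets.csv      columns `drug_id,gene_id`, one row per target gene
#   synergy.csv      columns `drug_a,drug_b,model,score,source`
# ---------------------------------------------------------------------------

FILE_NAMES = {
    "monotherapy": "monotherapy.csv",
    "mutations": "mutations.csv",
    "targets": "targets.csv",
    "synergy": "synergy.csv",
}


def _resolve_paths(source: str | Path | Mapping[str, str | Path]) -> dict[str, Path]:
    if isinstance(source, (str, Path)):
        base = Path(source)
        return {key: base / name for key, name in FILE_NAMES.items()}
    return {key: Path(p) for key, p in source.items()}


def _read_matrix(path: Path, index_col: str) -> pd.DataFrame:
    # round_trip parsing so write(read(x)) is byte-identical
    df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    if df.columns[0] != index_col:
        raise FormatError(
            f"{path.name}: first column must be '{index_col}', found '{df.columns[0]}'"
        )
    return df.set_index(index_col).rename_axis(index=index_col)


def read_dataset(source: str | Path | Mapping[str, str | Path]) -> Dataset:
    """Load a :class:`Dataset` from a directory (or explicit path mapping).

    Raises :class:`FormatError` for missing columns and
    :class:`ValidationError` when cross-references fail.  Non-fatal issues
    (e.g. extra mutation-matrix models) are emitted as warnings.
    """
    paths = _resolve_paths(source)
    mono = MonotherapyMatrix(_read_matrix(paths["monotherapy"], "drug_id"))
    mut = MutationMatrix(_read_matrix(paths["mutations"], "gene_id"))

    tg = pd.read_csv(paths["targets"], dtype=str)
    for col in ("drug_id", "gene_id"):
        if col not in tg.columns:
            raise FormatError(f"targets.csv missing required column '{col}'")
    mapping: dict[str, frozenset[str]] = {
        drug: frozenset(group["gene_id"]) for drug, group in tg.groupby("drug_id")
    }
    # drugs screened but with no annotated target keep an empty set
    for drug in mono.drug_ids:
        mapping.setdefault(drug, frozenset())
    targets = DrugTargetMap(mapping)

    syn_frame = pd.read_csv(
        paths["synergy"],
        dtype={"drug_a": str, "drug_b": str, "model": str},
        float_precision="round_trip",
    )
    synergy = synergy_from_frame(syn_frame)

    ds = Dataset(mono, mut, targets, synergy)
    for note in ds.validate():
        warnings.warn(note, stacklevel=2)
    return ds


def write_dataset(dataset: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the four CSVs with canonical (lexicographic) sorting.

    ``write_dataset(read_dataset(p))`` reproduces byte-identical tables once
    both sides are canonically sorted.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {key: out / name for key, name in FILE_NAMES.items()}

    mono = dataset.monotherapy.df.sort_index().sort_index(axis=1)
    mono.to_csv(paths["monotherapy"], index_label="drug_id")

    mut = dataset.mutations.df.sort_index().sort_index(axis=1)
    mut.to_csv(paths["mutations"], index_label="gene_id", float_format="%g")

    rows = [
        (drug, gene)
        for drug in sorted(dataset.targets.mapping)
        for gene in sorted(dataset.targets.mapping[drug])
    ]
    pd.DataFrame(rows, columns=["drug_id", "gene_id"]).to_csv(
        paths["targets"], index=False
    )

    frame = synergy_to_frame(dataset.synergy)
    frame = frame.sort_values(SYNERGY_COLUMNS[:4] + ["source"], kind="mergesort")
    frame.to_csv(paths["synergy"], index=False)
    return paths


# ---------------------------------------------------------------------------
# Filters and negative-pair sampling
# ---------------------------------------------------------------------------

def filter_min_entries(
    records: Sequence[SynergyRecord],
    threshold: int,
    group_key: Callable[[SynergyRecord], object] | None = None,
) -> list[SynergyRecord]:
    """Keep only records whose group has at least ``threshold`` members.

    The default group key is the record's ``source`` label (study/tissue);
    the canonical screening filter keeps groups with >= 1000 drug-drug-model
    entries.  Relative record order is preserved and the operation is
    idempotent.
    """
    if threshold < 1:
        raise ValueError(f"threshold must be >= 1, got {threshold}")
    key = group_key or (lambda r: r.source)
    counts: dict[object, int] = {}
    for r in records:
        counts[key(r)] = counts.get(key(r), 0) + 1
    return [r for r in records if counts[key(r)] >= threshold]


def sample_no_synergy_pairs(
    dataset: Dataset, n_pairs: int, seed: int, source: str = "no_synergy"
) -> list[SynergyRecord]:
    """Draw ``n_pairs`` unmeasured drug pairs and label them as non-synergistic.

    Pairs are sampled uniformly without replacement over unordered pairs of
    drugs present in the monotherapy matrix, excluding every known synergy
    pair; each sampled pair gets score 0 and a model drawn uniformly from the
    monotherapy models.  Deterministic given ``seed``; repeated draws of
    "no synergy" sets are realized by distinct seeds.
    """
    if n_pairs < 0:
        raise ValueError("n_pairs must be non-negative")
    drugs = sorted(dataset.monotherapy.drug_ids)
    known = dataset.known_pairs
    candidates = [
        (a, b)
        for i, a in enumerate(drugs)
        for b in drugs[i + 1 :]
        if (a, b) not in known
    ]
    if n_pairs > len(candidates):
        raise CapacityError(
            f"requested {n_pairs} unknown pairs but only {len(candidates)} exist"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n_pairs, replace=False)
    models = dataset.monotherapy.model_ids
    out = []
    for i in sorted(idx):
        a, b = candidates[i]
        model = models[int(rng.integers(len(models)))]
        out.append(SynergyRecord(a, b, model, 0.0, source))
    return out
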