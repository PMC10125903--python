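import numpy as np
import pandas as pd
import pytest

from acda.data_model import (
    Dataset,
    DrugTargetMap,
    MonotherapyMatrix,
    MutationMatrix,
    SynergyRecord,
)
from acda.synthetic import GeneratorSpec, generate_dataset


@pytest.fixture(scope="session")
def tiny_spec() -> GeneratorSpec:
    """A small planted study used across test modules."""
    return GeneratorSpec(
        n_drugs=12, n_models=8, n_genes=15, n_drug_clusters=3,
        n_records=80, seed=42,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec):
    return generate_dataset(tiny_spec)


@pytest.fixture()
def toy_dataset() -> Dataset:
    """A fully hand-written 3-drug, 2-model dataset for exact assertions."""
    mono = MonotherapyMatrix(
        pd.DataFrame(
            [[0.8, 0.2], [0.7, 0.3], [0.1, 0.9]],
            index=pd.Index(["A", "B", "C"], name="drug_id"),
            columns=["M1", "M2"],
        )
    )
    mut = MutationMatrix(
        pd.DataFrame(
            [[1, 0], [0, 1], [0, 0]],
            index=pd.Index(["EGFR", "TP53", "KRAS"], name="gene_id"),
            columns=["M1", "M2"],
        )
    )
    targets = DrugTargetMap(
        {"A": frozenset({"EGFR"}), "B": frozenset({"KRAS"}), "C": frozenset()}
    )
    synergy = [
        SynergyRecord("A", "B", "M1", 0.5, "toy"),
        SynergyRecord("A", "C", "M2", -0.2, "toy"),
    ]
    return Dataset(mono, mut, targets, synergy)


def random_distance_matrix(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """A valid Euclidean distance matrix over random points (no ties w.p. 1)."""
    points = rng.normal(size=(n, 4))
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    ids = [f"D{i}" for i in range(n)]
    return pd.DataFrame(d, index=ids, columns=ids)
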