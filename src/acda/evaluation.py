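"""Benchmarking and downstream analysis.

The central procedure is Monte Carlo cross-validation (MCCV): repeatedly
split the synergy records 2/3 : 1/3, train on one side, evaluate Pearson
correlation of predicted versus measured synergy on the other, and report
mean +/- SEM over the repeats.  Splitting is stratified at the level of the
unordered drug pair -- every record of a pair lands on one side -- so that a
combination seen in training can never leak into the test set through its
mirror orientation or another model.

Also here: the training-set down-sampling experiment, the rotating 3-1-1
fold hyperparameter-tuning experiment, per-pair prediction averaging,
categorical PDX response mapping, candidate ranking for unmeasured
combinations, and the hypergeometric test of between-method agreement on
above-threshold hits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import Dataset, SynergyRecord, ValidationError
from .drug_distance import drug_drug_distance
from .features import FEATURE_COLUMNS, KEY_COLUMNS, build_feature_table
from .models import (
    DEFAULT_RF_PARAMS,
    AlignmentError,
    FittedModel,
    TuningConfig,
    consensus_average,
    fit_acda,
    fit_cda,
    fit_en,
    fit_en_acda,
    predict,
)

__all__ = [
    "UndefinedCorrelationError",
    "SplitPlan",
    "BenchmarkResult",
    "DEFAULT_PDX_MAPPING",
    "METHOD_TAGS",
    "mccv_split",
    "pearson_and_sem",
    "run_mccv_benchmark",
    "cross_study_evaluation",
    "benchmark_results_to_frame",
    "downsample_experiment",
    "rotating_fold_tuning",
    "average_pair_predictions",
    "map_pdx_response",
    "rank_candidates",
    "method_overlap_significance",
]


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined (a zero-variance vector)."""


#: canonical method names; "consensus" is accepted as an alias
METHOD_TAGS = ("ACDA", "CDA", "EN", "EN-ACDA", "ACDA-EN-ACDA")

_ALIASES = {
    "acda": "ACDA",
    "cda": "CDA",
    "en": "EN",
    "en-acda": "EN-ACDA",
    "en_acda": "EN-ACDA",
    "acda-en-acda": "ACDA-EN-ACDA",
    "consensus": "ACDA-EN-ACDA",
}


def normalize_method(name: str) -> str:
    tag = _ALIASES.get(name.lower().strip())
    if tag is None:
        raise ValueError(f"unknown method {name!r}; choose from {METHOD_TAGS}")
    return tag


@dataclass(frozen=True)
class SplitPlan:
    """Positional train/test record indices for one MCCV repeat."""

    train_idx: tuple[int, ...]
    test_idx: tuple[int, ...]
    seed: int
    stratified: bool = True


@dataclass(frozen=True)
class BenchmarkResult:
    """Per-repeat Pearson r with mean and standard error across repeats."""

    method_tag: str
    per_repeat_r: tuple[float, ...]

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.per_repeat_r))

    @property
    def sem(self) -> float:
        """Sample (n-1) standard deviation over sqrt(repeats); NaN for n < 2."""
        n = len(self.per_repeat_r)
        if n < 2:
            return float("nan")
        return float(np.std(self.per_repeat_r, ddof=1) / np.sqrt(n))


def mccv_split(
    records: list[SynergyRecord],
    train_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    stratified: bool = True,
) -> SplitPlan:
    """One random train/test partition of the synergy records.

    With ``stratified`` (the default) the unordered drug pairs -- not the
    individual records -- are partitioned, so roughly ``train_fraction`` of
    the pairs (and all their records, across models and orientations) go to
    training.  Unstratified splitting partitions records directly and is
    kept only for comparison.
    """
    rng = np.random.default_rng(seed)
    if stratified:
        pairs = sorted({r.pair for r in records})
        if len(pairs) < 3:
            raise ValidationError(
                f"need >= 3 distinct drug pairs to split, got {len(pairs)}"
            )
        order = rng.permutation(len(pairs))
        n_train = int(round(train_fraction * len(pairs)))
        n_train = min(max(n_train, 1), len(pairs) - 1)
        train_pairs = {pairs[i] for i in order[:n_train]}
        train = tuple(i for i, r in enumerate(records) if r.pair in train_pairs)
        test = tuple(i for i, r in enumerate(records) if r.pair not in train_pairs)
    else:
        if len(records) < 3:
            raise ValidationError("need >= 3 records to split")
        order = rng.permutation(len(records))
        n_train = int(round(train_fraction * len(records)))
        n_train = min(max(n_train, 1), len(records) - 1)
        train = tuple(sorted(int(i) for i in order[:n_train]))
        test = tuple(sorted(int(i) for i in order[n_train:]))
    return SplitPlan(train_idx=train, test_idx=test, seed=seed, stratified=stratified)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValidationError(f"need >= 3 points per repeat, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "a prediction or measurement vector has zero variance"
        )
    return float(stats.pearsonr(x, y).statistic)


def pearson_and_sem(
    per_repeat_pairs: list[tuple[np.ndarray, np.ndarray]], method_tag: str = ""
) -> BenchmarkResult:
    """Per-repeat Pearson r of (predicted, measured), with mean and SEM."""
    rs = tuple(_pearson(pred, meas) for pred, meas in per_repeat_pairs)
    return BenchmarkResult(method_tag=method_tag, per_repeat_r=rs)


def _repeat_seeds(master_seed: int, repeats: int) -> list[int]:
    state = np.random.SeedSequence(master_seed).generate_state(repeats)
    return [int(s % (2**31)) for s in state]


def _fit_method(
    tag: str,
    train_features: pd.DataFrame,
    tuning: TuningConfig,
    seed: int,
    cda_mode: str = "auto",
) -> FittedModel:
    if tag == "ACDA":
        return fit_acda(train_features, tuning=tuning, seed=seed)
    if tag == "CDA":
        return fit_cda(train_features, mode=cda_mode)
    if tag == "EN":
        return fit_en(train_features, seed=seed)
    if tag == "EN-ACDA":
        return fit_en_acda(train_features, tuning=tuning, seed=seed)
    raise ValueError(f"no direct fit for method {tag!r}")


def run_mccv_benchmark(
    dataset: Dataset,
    methods: list[str] | None = None,
    repeats: int = 10,
    master_seed: int = 0,
    tuning: TuningConfig | None = None,
    train_fraction: float = 2.0 / 3.0,
    stratified: bool = True,
    cda_mode: str = "auto",
) -> list[BenchmarkResult]:
    """MCCV benchmark of the requested methods on identical split plans.

    Per repeat: split the records (pair-stratified by default), build the
    training table with symmetry augmentation and the test table without,
    fit every method, and correlate pooled test predictions with the
    measured scores.  Per-pair prediction averaging is *not* applied here;
    it is reserved for downstream candidate ranking.  The consensus
    (ACDA-EN-ACDA) is the mean of its two components' test predictions.

    Everything is reproducible end-to-end from ``master_seed``; ``tuning``
    defaults to the reduced :meth:`TuningConfig.fast` search to keep
    repeated benchmarks affordable.
    """
    if not methods:
        methods = list(METHOD_TAGS)
    tags = [normalize_method(m) for m in methods]
    tuning = tuning or TuningConfig.fast()
    records = dataset.synergy
    coph = drug_drug_distance(dataset.monotherapy)

    needed = set(tags)
    if "ACDA-EN-ACDA" in needed:
        needed |= {"ACDA", "EN-ACDA"}
    fit_tags = [t for t in METHOD_TAGS if t in needed and t != "ACDA-EN-ACDA"]

    per_method: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {t: [] for t in tags}
    for rep_seed in _repeat_seeds(master_seed, repeats):
        plan = mccv_split(
            records, train_fraction=train_fraction, seed=rep_seed, stratified=stratified
        )
        train_recs = [records[i] for i in plan.train_idx]
        test_recs = [records[i] for i in plan.test_idx]
        train_feats = build_feature_table(
            train_recs, dataset.monotherapy, coph, dataset.targets, dataset.mutations,
            augment_symmetry=True,
        )
        test_feats = build_feature_table(
            test_recs, dataset.monotherapy, coph, dataset.targets, dataset.mutations,
            augment_symmetry=False,
        )
        measured = test_feats["score"].to_numpy(dtype=float)
        preds: dict[str, np.ndarray] = {}
        for tag in fit_tags:
            model = _fit_method(tag, train_feats, tuning, rep_seed, cda_mode)
            preds[tag] = predict(model, test_feats)
        if "ACDA-EN-ACDA" in needed:
            preds["ACDA-EN-ACDA"] = consensus_average(
                preds["ACDA"], preds["EN-ACDA"]
            )
        for tag in tags:
            per_method[tag].append((preds[tag], measured))

    return [pearson_and_sem(per_method[tag], method_tag=tag) for tag in tags]


def cross_study_evaluation(
    train_dataset: Dataset,
    test_dataset: Dataset,
    methods: list[str] | None = None,
    seed: int = 0,
    tuning: TuningConfig | None = None,
    cda_mode: str = "auto",
) -> dict[str, float]:
    """Train every method on one study and correlate on another.

    Features are aligned record-by-record; each study's cophenetic distances
    come from its own monotherapy matrix.  A method that predicts a constant
    (e.g. the EN one-hot forest when no test-study name was seen in
    training, so its whole design is zero) carries no ranking information,
    and its correlation is reported as 0 by convention rather than raising.
    """
    if not methods:
        methods = ["ACDA", "CDA", "EN", "EN-ACDA"]
    tags = [normalize_method(m) for m in methods]
    tuning = tuning or TuningConfig.fast()

    def feats(ds: Dataset, augment: bool) -> pd.DataFrame:
        coph = drug_drug_distance(ds.monotherapy)
        return build_feature_table(
            ds.synergy, ds.monotherapy, coph, ds.targets, ds.mutations,
            augment_symmetry=augment,
        )

    train_feats = feats(train_dataset, True)
    test_feats = feats(test_dataset, False)
    measured = test_feats["score"].to_numpy(dtype=float)

    needed = set(tags)
    if "ACDA-EN-ACDA" in needed:
        needed |= {"ACDA", "EN-ACDA"}
    preds: dict[str, np.ndarray] = {}
    for tag in [t for t in METHOD_TAGS if t in needed and t != "ACDA-EN-ACDA"]:
        model = _fit_method(tag, train_feats, tuning, seed, cda_mode)
        preds[tag] = predict(model, test_feats)
    if "ACDA-EN-ACDA" in needed:
        preds["ACDA-EN-ACDA"] = consensus_average(preds["ACDA"], preds["EN-ACDA"])

    out = {}
    for tag in tags:
        p = preds[tag]
        out[tag] = 0.0 if np.ptp(p) == 0 else _pearson(p, measured)
    return out


def benchmark_results_to_frame(results: list[BenchmarkResult]) -> pd.DataFrame:
    """Long table (method, repeat, pearson_r) plus a summary block (mean, SEM)."""
    rows = []
    for res in results:
        for i, r in enumerate(res.per_repeat_r):
            rows.append(
                {"method": res.method_tag, "repeat": i, "pearson_r": r,
                 "mean_r": np.nan, "sem": np.nan}
            )
    for res in results:
        rows.append(
            {"method": res.method_tag, "repeat": pd.NA, "pearson_r": np.nan,
             "mean_r": res.mean_r, "sem": res.sem}
        )
    return pd.DataFrame(rows, columns=["method", "repeat", "pearson_r", "mean_r", "sem"])


def downsample_experiment(
    dataset: Dataset,
    train_sizes: list[int],
    fixed_test_size: int | None = None,
    repeats: int = 3,
    master_seed: int = 0,
    method: str = "ACDA",
    tuning: TuningConfig | None = None,
    train_fraction: float = 2.0 / 3.0,
) -> dict[int, BenchmarkResult]:
    """Benchmark one method at shrinking training-set sizes.

    Per repeat the test set is held constant across sizes, and the training
    subsets are nested (each smaller subset is a prefix of a seeded
    permutation of the full training pool) to reduce between-size variance.
    A size of ``None`` means the repeat's full training pool, which
    reproduces :func:`run_mccv_benchmark` for the same seed.
    """
    tag = normalize_method(method)
    tuning = tuning or TuningConfig.fast()
    records = dataset.synergy
    coph = drug_drug_distance(dataset.monotherapy)
    seeds = _repeat_seeds(master_seed, repeats)

    per_size: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {
        s: [] for s in train_sizes
    }
    for rep_seed in seeds:
        plan = mccv_split(records, train_fraction=train_fraction, seed=rep_seed)
        rng = np.random.default_rng(rep_seed)
        pool = list(plan.train_idx)
        explicit = [s for s in train_sizes if s is not None]
        if explicit and max(explicit) > len(pool):
            raise ValidationError(
                f"requested training size {max(explicit)} exceeds the "
                f"available pool of {len(pool)} records"
            )
        order = rng.permutation(len(pool))
        test_idx = list(plan.test_idx)
        if fixed_test_size is not None:
            if fixed_test_size > len(test_idx):
                raise ValidationError(
                    f"fixed_test_size {fixed_test_size} exceeds the test set "
                    f"of {len(test_idx)} records"
                )
            keep = rng.permutation(len(test_idx))[:fixed_test_size]
            test_idx = [test_idx[i] for i in sorted(keep)]
        test_feats = build_feature_table(
            [records[i] for i in test_idx],
            dataset.monotherapy, coph, dataset.targets, dataset.mutations,
        )
        measured = test_feats["score"].to_numpy(dtype=float)
        for size in train_sizes:
            n_take = len(pool) if size is None else size
            chosen = sorted(pool[i] for i in order[:n_take])
            train_feats = build_feature_table(
                [records[i] for i in chosen],
                dataset.monotherapy, coph, dataset.targets, dataset.mutations,
                augment_symmetry=True,
            )
            model = _fit_method(tag, train_feats, tuning, rep_seed)
            per_size[size].append((predict(model, test_feats), measured))

    return {
        size: pearson_and_sem(pairs, method_tag=tag)
        for size, pairs in per_size.items()
    }


def rotating_fold_tuning(
    dataset: Dataset,
    master_seed: int = 0,
    tuning: TuningConfig | None = None,
    n_folds: int = 5,
) -> pd.DataFrame:
    """3-1-1 fold-rotation experiment: tuned versus untuned forest.

    Drug pairs are partitioned into ``n_folds`` folds.  In each rotation one
    fold is held out for validation; hyperparameters are selected on the
    remaining four (three folds train each candidate, the fourth scores it),
    then both the tuned and the default-configuration forest are refitted on
    all four and evaluated on the validation fold.  Returns one row per
    rotation with ``base_r`` and ``tuned_r``.
    """
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.model_selection import ParameterSampler

    tuning = tuning or TuningConfig.fast()
    records = dataset.synergy
    pairs = sorted({r.pair for r in records})
    if len(pairs) < n_folds:
        raise ValidationError(
            f"need >= {n_folds} distinct pairs for {n_folds}-fold rotation"
        )
    coph = drug_drug_distance(dataset.monotherapy)
    rng = np.random.default_rng(master_seed)
    fold_of_pair = {}
    for fold, chunk in enumerate(np.array_split(rng.permutation(len(pairs)), n_folds)):
        for i in chunk:
            fold_of_pair[pairs[i]] = fold
    fold_idx = [
        [i for i, r in enumerate(records) if fold_of_pair[r.pair] == f]
        for f in range(n_folds)
    ]

    def table(idx: list[int], augment: bool) -> pd.DataFrame:
        return build_feature_table(
            [records[i] for i in idx],
            dataset.monotherapy, coph, dataset.targets, dataset.mutations,
            augment_symmetry=augment,
        )

    seeds = _repeat_seeds(master_seed, n_folds)
    rows = []
    for rotation in range(n_folds):
        val = fold_idx[rotation]
        tune = fold_idx[(rotation + 1) % n_folds]
        train = [
            i
            for f in range(n_folds)
            if f not in (rotation, (rotation + 1) % n_folds)
            for i in fold_idx[f]
        ]
        train_t, tune_t = table(train, True), table(tune, False)
        all4_t = table(sorted(train + tune), True)
        val_t = table(val, False)
        y_train = train_t["score"].to_numpy(dtype=float)
        X_train = train_t[FEATURE_COLUMNS].to_numpy(dtype=float)
        X_tune = tune_t[FEATURE_COLUMNS].to_numpy(dtype=float)
        y_tune = tune_t["score"].to_numpy(dtype=float)
        forest_seed = seeds[rotation]
        candidates = [dict(DEFAULT_RF_PARAMS)] + [
            dict(p)
            for p in ParameterSampler(
                tuning.search_space, n_iter=tuning.n_iter, random_state=forest_seed
            )
        ]
        scores = []
        for params in candidates:
            forest = RandomForestRegressor(random_state=forest_seed, **params)
            forest.fit(X_train, y_train)
            scores.append(forest.score(X_tune, y_tune))
        best = candidates[int(np.argmax(scores))]

        X_all4 = all4_t[FEATURE_COLUMNS].to_numpy(dtype=float)
        y_all4 = all4_t["score"].to_numpy(dtype=float)
        X_val = val_t[FEATURE_COLUMNS].to_numpy(dtype=float)
        y_val = val_t["score"].to_numpy(dtype=float)
        base = RandomForestRegressor(random_state=forest_seed, **DEFAULT_RF_PARAMS)
        base.fit(X_all4, y_all4)
        tuned = RandomForestRegressor(random_state=forest_seed, **best)
        tuned.fit(X_all4, y_all4)
        rows.append(
            {
                "rotation": rotation,
                "base_r": _pearson(base.predict(X_val), y_val),
                "tuned_r": _pearson(tuned.predict(X_val), y_val),
                "chosen_params": best,
            }
        )
    return pd.DataFrame(rows)


def average_pair_predictions(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse mirrored (A, B) / (B, A) predictions to one canonical row.

    Numeric columns are averaged over the canonical (unordered pair, model)
    key; singletons pass through unchanged.  Output order follows the first
    appearance of each canonical key, so the result is invariant to the
    relative order of the two mirrored rows.
    """
    missing = [c for c in KEY_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"prediction table missing key column(s): {missing}")
    work = table.copy()
    swap = work["drug_a"] > work["drug_b"]
    work.loc[swap, ["drug_a", "drug_b"]] = work.loc[
        swap, ["drug_b", "drug_a"]
    ].to_numpy()
    if {"sens_a", "sens_b"} <= set(work.columns):
        work.loc[swap, ["sens_a", "sens_b"]] = work.loc[
            swap, ["sens_b", "sens_a"]
        ].to_numpy()
    grouped = work.groupby(KEY_COLUMNS, sort=False, as_index=False).mean(
        numeric_only=True
    )
    return grouped


DEFAULT_PDX_MAPPING = {"CR": 0.75, "PR": 0.5, "SD": 0.25, "PD": 0.0}
"""Response category -> synergy score.

CR (complete response) maps to 0.75; the remaining categories descend in
0.25 steps to PD (progressive disease) at 0.  The non-CR values are a
documented package default and fully configurable.
"""


def map_pdx_response(
    categories: list[str], mapping: dict[str, float] | None = None
) -> np.ndarray:
    """Elementwise lookup of categorical PDX responses as synergy scores."""
    mapping = DEFAULT_PDX_MAPPING if mapping is None else mapping
    unmapped = sorted({c for c in categories if c not in mapping})
    if unmapped:
        raise ValidationError(f"response categories without a mapping: {unmapped}")
    return np.array([mapping[c] for c in categories], dtype=float)


def rank_candidates(
    dataset: Dataset,
    methods: list[str] | None = None,
    sort_by: str | None = None,
    apply_pair_averaging: bool = True,
    seed: int = 0,
    tuning: TuningConfig | None = None,
    cda_mode: str = "auto",
) -> pd.DataFrame:
    """Rank unmeasured drug-pair x model combinations by predicted synergy.

    Every method is trained on *all* measured records (with symmetry
    augmentation); the candidate universe is all unordered drug pairs x
    models without a measured record and with observed monotherapy
    sensitivity for both drugs.  Both orientations of each candidate are
    scored; with ``apply_pair_averaging`` the mirrored rows are collapsed to
    one canonical row (the ``averaged`` column records which variant a row
    is).  Rows are sorted descending by ``sort_by`` (default: the first
    requested method).
    """
    if not methods:
        methods = list(METHOD_TAGS)
    tags = [normalize_method(m) for m in methods]
    tuning = tuning or TuningConfig.fast()
    records = dataset.synergy
    coph = drug_drug_distance(dataset.monotherapy)
    train_feats = build_feature_table(
        records, dataset.monotherapy, coph, dataset.targets, dataset.mutations,
        augment_symmetry=True,
    )

    measured = {(r.pair[0], r.pair[1], r.model) for r in records}
    drugs = sorted(dataset.monotherapy.drug_ids)
    mono = dataset.monotherapy
    candidates = [
        SynergyRecord(a, b, m, 0.0, "candidate")
        for i, a in enumerate(drugs)
        for b in drugs[i + 1 :]
        for m in mono.model_ids
        if (a, b, m) not in measured
        and not pd.isna(mono.sensitivity(a, m))
        and not pd.isna(mono.sensitivity(b, m))
    ]
    columns = KEY_COLUMNS + FEATURE_COLUMNS + tags + ["averaged"]
    if not candidates:
        return pd.DataFrame(columns=columns)
    cand_feats = build_feature_table(
        candidates, mono, coph, dataset.targets, dataset.mutations,
        augment_symmetry=True, include_score=False,
    )

    needed = set(tags)
    if "ACDA-EN-ACDA" in needed:
        needed |= {"ACDA", "EN-ACDA"}
    preds: dict[str, np.ndarray] = {}
    for tag in [t for t in METHOD_TAGS if t in needed and t != "ACDA-EN-ACDA"]:
        model = _fit_method(tag, train_feats, tuning, seed, cda_mode)
        preds[tag] = predict(model, cand_feats)
    if "ACDA-EN-ACDA" in needed:
        preds["ACDA-EN-ACDA"] = consensus_average(preds["ACDA"], preds["EN-ACDA"])

    out = cand_feats.copy()
    for tag in tags:
        out[tag] = preds[tag]
    if apply_pair_averaging:
        out = average_pair_predictions(out)
        out["averaged"] = True
    else:
        out["averaged"] = False
    key = normalize_method(sort_by) if sort_by else tags[0]
    return out.sort_values(key, ascending=False, kind="mergesort").reset_index(
        drop=True
    )


def method_overlap_significance(
    score_table: pd.DataFrame, threshold: float = 0.75
) -> pd.DataFrame:
    """Pairwise hypergeometric test of agreement on above-threshold hits.

    Over a shared candidate universe of size N, each method defines a hit
    set (predicted score >= ``threshold``).  For methods with K and n hits
    overlapping in k candidates, the upper-tail probability of an overlap
    >= k under random draws is ``hypergeom.sf(k - 1, N, K, n)``.  Small
    p-values mean the methods agree far more than chance.
    """
    if isinstance(score_table, dict):
        series = list(score_table.values())
        first = series[0].index
        if not all(s.index.equals(first) for s in series[1:]):
            raise AlignmentError("methods must share one candidate universe")
        score_table = pd.DataFrame(score_table)
    if score_table.isna().to_numpy().any():
        raise AlignmentError("candidate universes differ (NaN scores present)")
    n_total = len(score_table)
    methods = list(score_table.columns)
    hits = {m: score_table.index[score_table[m] >= threshold] for m in methods}
    pvals = pd.DataFrame(index=methods, columns=methods, dtype=float)
    for m1 in methods:
        for m2 in methods:
            big_k, small_n = len(hits[m1]), len(hits[m2])
            overlap = len(hits[m1].intersection(hits[m2]))
            pvals.loc[m1, m2] = float(
                stats.hypergeom.sf(overlap - 1, n_total, big_k, small_n)
            )
    return pvals
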