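import numpy as np
import pandas as pd
import pytest

from acda.data_model import SynergyRecord, ValidationError
from acda.evaluation import (
    DEFAULT_PDX_MAPPING,
    AlignmentError,
    UndefinedCorrelationError,
    average_pair_predictions,
    downsample_experiment,
    map_pdx_response,
    mccv_split,
    method_overlap_significance,
    pearson_and_sem,
    rank_candidates,
    rotating_fold_tuning,
    run_mccv_benchmark,
)
from acda.models import TuningConfig
from acda.synthetic import GeneratorSpec, generate_dataset

from .oracles import hypergeom_upper_tail, two_pass_pearson

TINY_TUNING = TuningConfig(
    search_space={"n_estimators": [30], "max_depth": [None, 5]}, n_iter=2, k=3
)


def make_records(n_pairs: int, n_models: int = 3, mirrored: bool = False):
    records = []
    for p in range(n_pairs):
        a, b = f"D{p:02d}", f"D{p:02d}x"
        for m in range(n_models):
            records.append(SynergyRecord(a, b, f"M{m}", 0.1 * p, "fix"))
            if mirrored:
                records.append(SynergyRecord(b, a, f"M{m}", 0.1 * p, "fix"))
    return records


class TestMccvSplit:
    def test_exact_small_case(self):
        records = make_records(3)
        plan = mccv_split(records, seed=0)
        assert len(plan.train_idx) == 6 and len(plan.test_idx) == 3
        assert not set(plan.train_idx) & set(plan.test_idx)

    def test_no_pair_crosses_the_boundary_over_seeds(self):
        records = make_records(20, n_models=2)
        for seed in range(100):
            plan = mccv_split(records, seed=seed)
            train_pairs = {records[i].pair for i in plan.train_idx}
            test_pairs = {records[i].pair for i in plan.test_idx}
            assert not train_pairs & test_pairs
            assert len(plan.train_idx) + len(plan.test_idx) == len(records)

    def test_ordered_mirrors_co_located(self):
        rng = np.random.default_rng(0)
        records = make_records(10, n_models=2, mirrored=True)
        for seed in rng.integers(0, 10_000, size=20):
            plan = mccv_split(records, seed=int(seed))
            sides = {}
            for i in plan.train_idx:
                sides[records[i].pair] = "train"
            for i in plan.test_idx:
                assert sides.get(records[i].pair, "test") == "test"

    def test_deterministic_per_seed(self):
        records = make_records(8)
        assert mccv_split(records, seed=5) == mccv_split(records, seed=5)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError, match="3"):
            mccv_split(make_records(2))


class TestPearsonAndSem:
    def test_perfect_and_anti_correlation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = pearson_and_sem([(x, x), (2 * x, x)], method_tag="t")
        assert res.mean_r == pytest.approx(1.0)
        assert res.sem == pytest.approx(0.0)
        res2 = pearson_and_sem([(-x, x)])
        assert res2.per_repeat_r[0] == pytest.approx(-1.0)

    def test_hand_computed_mean_and_sem(self):
        # three repeats engineered to r = 1.0, 0.5, 0.0
        x = np.array([1.0, 2.0, 3.0])
        y_half = np.array([0.0, 1.0, 0.5])  # r = 0.5 with x
        y_zero = np.array([1.0, 0.0, 1.0])  # r = 0 with x (zero cross-moment)
        assert two_pass_pearson(x, y_half) == pytest.approx(0.5)
        assert two_pass_pearson(x, y_zero) == pytest.approx(0.0)
        res = pearson_and_sem([(x, x), (x, y_half), (x, y_zero)])
        assert res.per_repeat_r == pytest.approx((1.0, 0.5, 0.0))
        assert res.mean_r == pytest.approx(0.5)
        assert res.sem == pytest.approx(0.5 / np.sqrt(3), abs=1e-9)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x, y = rng.normal(size=30), rng.normal(size=30)
            res = pearson_and_sem([(x, y)])
            assert res.per_repeat_r[0] == pytest.approx(
                two_pass_pearson(x, y), abs=1e-12
            )

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_and_sem([(np.ones(5), np.arange(5.0))])

    def test_short_vectors_rejected(self):
        with pytest.raises(ValidationError):
            pearson_and_sem([(np.array([1.0, 2.0]), np.array([1.0, 2.0]))])


@pytest.fixture(scope="module")
def bench_dataset():
    ds, _ = generate_dataset(
        GeneratorSpec(n_drugs=14, n_models=8, n_genes=20, n_drug_clusters=3,
                      n_records=90, seed=11)
    )
    return ds


class TestBenchmark:
    def test_smoke_contract_and_determinism(self, bench_dataset):
        res1 = run_mccv_benchmark(
            bench_dataset, methods=["acda", "cda", "consensus"], repeats=2,
            master_seed=3, tuning=TINY_TUNING,
        )
        res2 = run_mccv_benchmark(
            bench_dataset, methods=["acda", "cda", "consensus"], repeats=2,
            master_seed=3, tuning=TINY_TUNING,
        )
        assert [r.method_tag for r in res1] == ["ACDA", "CDA", "ACDA-EN-ACDA"]
        assert all(len(r.per_repeat_r) == 2 for r in res1)
        assert res1 == res2  # bitwise reproducible end to end
        assert all(-1 <= r <= 1 for res in res1 for r in res.per_repeat_r)

    def test_consensus_is_exact_mean_of_components(self, bench_dataset):
        # run with all three tags on the same master seed: the consensus
        # per-repeat r must equal recomputing pearson on averaged predictions;
        # here we check the weaker but exact end-to-end contract that the
        # consensus result is deterministic and bounded by its components'
        # spread only through the averaging identity (verified directly in
        # test_models); this test pins that all three tags run jointly.
        res = run_mccv_benchmark(
            bench_dataset, methods=["acda", "en-acda", "acda-en-acda"],
            repeats=2, master_seed=9, tuning=TINY_TUNING,
        )
        tags = {r.method_tag for r in res}
        assert tags == {"ACDA", "EN-ACDA", "ACDA-EN-ACDA"}


class TestDownsample:
    def test_full_size_reproduces_benchmark(self, bench_dataset):
        full = run_mccv_benchmark(
            bench_dataset, methods=["acda"], repeats=2, master_seed=4,
            tuning=TINY_TUNING,
        )[0]
        sizes_result = downsample_experiment(
            bench_dataset, train_sizes=[None], repeats=2, master_seed=4,
            tuning=TINY_TUNING,
        )
        assert sizes_result[None].per_repeat_r == full.per_repeat_r

    def test_trend_on_low_noise_data(self):
        ds, _ = generate_dataset(
            GeneratorSpec(n_drugs=14, n_models=8, n_genes=20, n_drug_clusters=3,
                          n_records=120, noise_sd=0.0, seed=21)
        )
        res = downsample_experiment(
            ds, train_sizes=[20, 60], repeats=2, master_seed=6,
            tuning=TINY_TUNING,
        )
        assert res[20].mean_r <= res[60].mean_r + 0.05

    def test_nested_subsets_and_constant_test_set(self, bench_dataset):
        res = downsample_experiment(
            bench_dataset, train_sizes=[20, 40], fixed_test_size=15, repeats=2,
            master_seed=5, tuning=TINY_TUNING,
        )
        assert set(res) == {20, 40}
        for r in res.values():
            assert len(r.per_repeat_r) == 2

    def test_infeasible_size_rejected(self, bench_dataset):
        with pytest.raises(ValidationError, match="exceeds"):
            downsample_experiment(
                bench_dataset, train_sizes=[10_000], repeats=1, master_seed=0,
                tuning=TINY_TUNING,
            )


class TestRotatingFolds:
    def test_coverage_and_disjointness(self, bench_dataset):
        table = rotating_fold_tuning(
            bench_dataset, master_seed=2, tuning=TINY_TUNING
        )
        assert list(table["rotation"]) == [0, 1, 2, 3, 4]
        assert np.isfinite(table["base_r"]).all()
        assert np.isfinite(table["tuned_r"]).all()

    def test_too_few_pairs_rejected(self):
        ds, _ = generate_dataset(
            GeneratorSpec(n_drugs=4, n_models=4, n_genes=5, n_drug_clusters=2,
                          n_records=6, seed=0)
        )
        pairs = {r.pair for r in ds.synergy}
        if len(pairs) >= 5:
            pytest.skip("fixture produced too many pairs")
        with pytest.raises(ValidationError):
            rotating_fold_tuning(ds, master_seed=0, tuning=TINY_TUNING)


class TestPairAveraging:
    def test_mirrored_rows_average(self):
        table = pd.DataFrame(
            {"drug_a": ["A", "B"], "drug_b": ["B", "A"], "model": ["M", "M"],
             "pred": [0.8, 0.6]}
        )
        out = average_pair_predictions(table)
        assert len(out) == 1
        assert out.iloc[0]["pred"] == pytest.approx(0.7)
        assert (out.iloc[0]["drug_a"], out.iloc[0]["drug_b"]) == ("A", "B")

    def test_singleton_passes_through(self):
        table = pd.DataFrame(
            {"drug_a": ["B"], "drug_b": ["A"], "model": ["M"], "pred": [0.4]}
        )
        out = average_pair_predictions(table)
        assert len(out) == 1
        assert out.iloc[0]["pred"] == pytest.approx(0.4)

    def test_invariant_to_row_order(self):
        t1 = pd.DataFrame(
            {"drug_a": ["A", "B"], "drug_b": ["B", "A"], "model": ["M", "M"],
             "pred": [0.8, 0.6]}
        )
        t2 = t1.iloc[::-1].reset_index(drop=True)
        pd.testing.assert_frame_equal(
            average_pair_predictions(t1), average_pair_predictions(t2)
        )


class TestPdxMapping:
    def test_default_mapping_values(self):
        out = map_pdx_response(["CR", "PR", "SD", "PD"])
        assert list(out) == [0.75, 0.5, 0.25, 0.0]
        assert DEFAULT_PDX_MAPPING["CR"] == 0.75

    def test_custom_mapping(self):
        assert map_pdx_response(["X"], {"X": 0.1})[0] == pytest.approx(0.1)

    def test_unmapped_label_listed(self):
        with pytest.raises(ValidationError, match="MR"):
            map_pdx_response(["CR", "MR"])


class TestRankCandidates:
    def test_universe_excludes_measured_and_collapses_mirrors(self, bench_dataset):
        ranked = rank_candidates(
            bench_dataset, methods=["acda", "cda"], apply_pair_averaging=True,
            seed=1, tuning=TINY_TUNING,
        )
        measured = {(r.pair[0], r.pair[1], r.model) for r in bench_dataset.synergy}
        produced = set(zip(ranked["drug_a"], ranked["drug_b"], ranked["model"]))
        assert not produced & measured
        assert len(produced) == len(ranked)  # mirrors collapsed
        assert (ranked["drug_a"] <= ranked["drug_b"]).all()
        assert ranked["averaged"].all()
        # descending sort by first method
        assert (np.diff(ranked["ACDA"].to_numpy()) <= 1e-12).all()

    def test_non_averaged_keeps_both_orientations(self, bench_dataset):
        ranked = rank_candidates(
            bench_dataset, methods=["cda"], apply_pair_averaging=False,
            seed=1, tuning=TINY_TUNING,
        )
        assert not ranked["averaged"].any()
        keys = set(zip(ranked["drug_a"], ranked["drug_b"], ranked["model"]))
        mirrored = {(b, a, m) for a, b, m in keys}
        assert keys == mirrored

    def test_stable_under_same_seed(self, bench_dataset):
        r1 = rank_candidates(bench_dataset, methods=["acda"], seed=2,
                             tuning=TINY_TUNING)
        r2 = rank_candidates(bench_dataset, methods=["acda"], seed=2,
                             tuning=TINY_TUNING)
        pd.testing.assert_frame_equal(r1, r2)


class TestOverlapSignificance:
    def test_worked_enumeration_case(self):
        # N=10, K=5, n=4, overlap 3 -> (C(5,3)C(5,1)+C(5,4)C(5,0))/C(10,4)
        scores = pd.DataFrame(
            {
                "m1": [1, 1, 1, 1, 1, 0, 0, 0, 0, 0],
                "m2": [1, 1, 1, 0, 0, 1, 0, 0, 0, 0],
            },
            dtype=float,
        )
        p = method_overlap_significance(scores, threshold=1.0)
        assert p.loc["m1", "m2"] == pytest.approx(55 / 210, abs=1e-12)
        assert p.loc["m2", "m1"] == pytest.approx(55 / 210, abs=1e-12)

    def test_identical_sets_hit_the_nested_minimum(self):
        scores = pd.DataFrame({"m1": [1, 1, 0, 0], "m2": [1, 1, 0, 0]}, dtype=float)
        p = method_overlap_significance(scores, threshold=1.0)
        assert p.loc["m1", "m2"] == pytest.approx(
            hypergeom_upper_tail(2, 4, 2, 2), abs=1e-12
        )

    def test_disjoint_sets_give_one(self):
        scores = pd.DataFrame({"m1": [1, 0, 0, 0], "m2": [0, 1, 0, 0]}, dtype=float)
        p = method_overlap_significance(scores, threshold=1.0)
        assert p.loc["m1", "m2"] == pytest.approx(1.0)

    def test_matches_exact_enumeration_for_small_universes(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n_total = int(rng.integers(4, 21))
            s1 = (rng.random(n_total) < rng.random()).astype(float)
            s2 = (rng.random(n_total) < rng.random()).astype(float)
            scores = pd.DataFrame({"m1": s1, "m2": s2})
            p = method_overlap_significance(scores, threshold=1.0)
            k = int(((s1 == 1) & (s2 == 1)).sum())
            expected = hypergeom_upper_tail(
                k, n_total, int(s1.sum()), int(s2.sum())
            )
            assert p.loc["m1", "m2"] == pytest.approx(expected, abs=1e-12)

    def test_mismatched_universes_rejected(self):
        s1 = pd.Series([1.0, 0.0], index=["a", "b"])
        s2 = pd.Series([1.0, 0.0], index=["a", "c"])
        with pytest.raises(AlignmentError):
            method_overlap_significance({"m1": s1, "m2": s2})
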