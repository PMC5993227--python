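import numpy as np
import pandas as pd
import pytest

from hdallom.evaluation import (
    best_tally,
    mean_difference_ci,
    rmse,
    run_size_experiment,
    run_strategy_experiment,
    split_train_test,
)
from hdallom.plot_data import eligible_plots


class TestRmse:
    def test_perfect_prediction(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_constant_offset(self):
        assert rmse([2.0, 3.0, 4.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_arithmetic(self):
        assert rmse([13.0, 16.0], [10.0, 20.0]) == pytest.approx(np.sqrt(12.5))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            rmse([], [])


class TestSplitTrainTest:
    def test_cardinality_and_disjointness(self):
        tr, te = split_train_test(200, 10, seed=3)
        assert len(tr) == 10 and len(te) == 50
        assert not set(tr) & set(te)

    def test_boundary(self):
        tr, te = split_train_test(150, 100, seed=3)
        assert len(tr) == 100 and len(te) == 50
        with pytest.raises(ValueError):
            split_train_test(150, 101, seed=3)

    def test_deterministic(self):
        a = split_train_test(120, 30, seed=5)
        b = split_train_test(120, 30, seed=5)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_tree_sequence_mode(self):
        trees = list("abcdefghij")
        tr, te = split_train_test(trees, 3, seed=1, test_size=4)
        assert len(tr) == 3 and len(te) == 4
        assert not set(tr) & set(te)
        assert set(tr) | set(te) <= set(trees)


@pytest.fixture(scope="module")
def tiny_size_records(small_plots_module):
    plots = eligible_plots(small_plots_module, 150)
    return run_size_experiment(
        plots[:2], sizes=(10, 30, 50), iterations=4, seed=9
    )


@pytest.fixture(scope="module")
def small_plots_module(request):
    from hdallom.synthetic import GeneratorConfig, generate_dataset

    plots, _ = generate_dataset(
        GeneratorConfig(n_plots=3, trees_per_plot=(200, 240), master_seed=77)
    )
    return plots


class TestRunSizeExperiment:
    def test_record_cardinality(self, tiny_size_records):
        # 2 plots x 3 sizes x 4 iterations x 7 competitors
        assert len(tiny_size_records) == 2 * 3 * 4 * 7

    def test_all_models_share_the_split(self, small_plots_module):
        # identical test trees within a cell: reference rmse must agree
        # between two runs that differ only in model list order
        plots = eligible_plots(small_plots_module, 150)[:1]
        a = run_size_experiment(plots, sizes=(20,), iterations=3, seed=4)
        b = run_size_experiment(
            plots, sizes=(20,), iterations=3, seed=4,
            models=("loglog", "weibull", "michaelis_menten", "weibull_weighted", "mm_weighted"),
        )
        ka = a[a.model == "regional"].sort_values("iteration")["rmse"].to_numpy()
        kb = b[b.model == "regional"].sort_values("iteration")["rmse"].to_numpy()
        np.testing.assert_allclose(ka, kb)

    def test_reference_rmse_flat_in_n(self, tiny_size_records):
        # references are never refit, so within a plot their mean rmse is
        # n-invariant apart from which test trees are drawn
        reg = tiny_size_records[tiny_size_records.model == "regional"]
        spread = reg.groupby(["plot_id", "n_train"])["rmse"].mean().groupby("plot_id").std()
        overall = reg["rmse"].std()
        assert (spread < overall + 1e-9).all()

    def test_reproducible_bit_for_bit(self, small_plots_module, tmp_path):
        plots = eligible_plots(small_plots_module, 150)[:2]
        a = run_size_experiment(plots, sizes=(10, 20), iterations=2, seed=123)
        b = run_size_experiment(plots, sizes=(10, 20), iterations=2, seed=123)
        fa, fb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.to_csv(fa, index=False)
        b.to_csv(fb, index=False)
        assert fa.read_bytes() == fb.read_bytes()

    def test_local_beats_pooled_regional_at_large_n(self, small_plots_module):
        plots = eligible_plots(small_plots_module, 150)
        rec = run_size_experiment(plots, sizes=(100,), iterations=8, seed=2)
        m = rec[rec.converged].groupby("model")["rmse"].mean()
        assert m["weibull"] < m["regional"]


class TestRunStrategyExperiment:
    def test_cardinality_and_labels(self, small_plots_module):
        plots = eligible_plots(small_plots_module, 150)[:1]
        rec = run_strategy_experiment(plots, sizes=(20, 50), iterations=3, seed=5)
        # 1 plot x 5 strategies x 2 sizes x 3 iters x 2 models
        assert len(rec) == 5 * 2 * 3 * 2
        assert set(rec.strategy.unique()) == {"Rand", "Strat", "Big", "BigRand", "BigStrat"}

    def test_big_deterministic_across_iterations(self, small_plots_module):
        plots = eligible_plots(small_plots_module, 150)[:1]
        rec = run_strategy_experiment(
            plots, strategies=("Big",), sizes=(30,), iterations=4, seed=6
        )
        per_iter = rec[rec.model == "weibull"].groupby("iteration")["rmse"].first()
        assert per_iter.nunique() == 1


def _records(rows):
    return pd.DataFrame(
        rows, columns=["plot_id", "n_train", "iteration", "model", "strategy",
                       "rmse", "agb_error", "converged"]
    )


class TestBestTally:
    def test_dominant_model_probability_one(self):
        rows = []
        for it in range(5):
            for n in (10, 20):
                rows.append(("p1", n, it, "A", None, 1.0, 0.0, True))
                rows.append(("p1", n, it, "B", None, 2.0, 0.0, True))
        curves = {c.competitor: c for c in best_tally(_records(rows), smooth=False)}
        assert np.allclose(curves["A"].probability_best, 1.0)
        assert np.allclose(curves["B"].probability_best, 0.0)

    def test_never_converged_never_wins(self):
        rows = []
        for it in range(5):
            rows.append(("p1", 10, it, "A", None, 5.0, 0.0, True))
            rows.append(("p1", 10, it, "B", None, np.nan, np.nan, False))
        curves = {c.competitor: c for c in best_tally(_records(rows), smooth=False)}
        assert np.allclose(curves["B"].probability_best, 0.0)

    def test_exact_ties_split_evenly_in_expectation(self):
        rows = []
        for it in range(400):
            rows.append(("p1", 10, it, "A", None, 1.0, 0.0, True))
            rows.append(("p1", 10, it, "B", None, 1.0, 0.0, True))
        curves = {c.competitor: c for c in best_tally(_records(rows), seed=0, smooth=False)}
        pa = curves["A"].probability_best[0]
        assert 0.4 < pa < 0.6  # binomial(400, 1/2) within ~4 sd
        again = {c.competitor: c for c in best_tally(_records(rows), seed=0, smooth=False)}
        assert again["A"].probability_best[0] == pa  # deterministic tie-break

    def test_strategy_grouping_takes_best_form(self):
        rows = [
            ("p1", 10, 1, "weibull", "Rand", 3.0, 0.0, True),
            ("p1", 10, 1, "michaelis_menten", "Rand", 1.0, 0.0, True),
            ("p1", 10, 1, "weibull", "Big", 2.0, 0.0, True),
            ("p1", 10, 1, "michaelis_menten", "Big", 2.5, 0.0, True),
        ]
        curves = {c.competitor: c for c in
                  best_tally(_records(rows), group="strategy", smooth=False)}
        assert curves["Rand"].probability_best[0] == 1.0  # its MM form scores 1.0
        assert curves["Big"].probability_best[0] == 0.0


class TestMeanDifferenceCI:
    def test_identical_predictors_give_zero(self):
        rows = []
        rng = np.random.default_rng(0)
        for p in ("p1", "p2", "p3"):
            for it in range(10):
                v = rng.uniform(2, 3)
                rows.append((p, 10, it, "A", None, v, 0.0, True))
                rows.append((p, 10, it, "ref", None, v, 0.0, True))
        mean, lo, hi = mean_difference_ci(_records(rows), "A", "ref", seed=1)
        assert mean == pytest.approx(0.0, abs=1e-12)
        assert lo <= 0.0 <= hi

    def test_constant_shift_degenerate_ci(self):
        rows = []
        for p in ("p1", "p2"):
            for it in range(5):
                rows.append((p, 10, it, "A", None, 2.0, 0.0, True))
                rows.append((p, 10, it, "ref", None, 3.0, 0.0, True))
        mean, lo, hi = mean_difference_ci(_records(rows), "A", "ref", seed=1)
        assert mean == pytest.approx(-1.0)
        assert lo == pytest.approx(-1.0) and hi == pytest.approx(-1.0)

    def test_missing_pairing_raises(self):
        rows = [("p1", 10, 1, "A", None, 2.0, 0.0, True)]
        with pytest.raises(ValueError):
            mean_difference_ci(_records(rows), "A", "ref")

    def test_separates_local_from_regional_with_plot_variation(self):
        from hdallom.synthetic import GeneratorConfig, generate_dataset

        # enough plots with diverse true allometries that the pooled
        # baseline is clearly worse than a 20-tree local fit in each
        plots, _ = generate_dataset(
            GeneratorConfig(n_plots=8, trees_per_plot=(200, 240), master_seed=17)
        )
        rec = run_size_experiment(
            eligible_plots(plots), sizes=(20,), iterations=6, seed=11,
            models=("weibull",),
        )
        mean, lo, hi = mean_difference_ci(rec, "weibull", "regional", seed=2)
        assert mean < 0  # local fit beats the pooled baseline
        assert hi < 0  # interval excludes zero on the negative side
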