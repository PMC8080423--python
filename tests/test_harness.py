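"""Cross-validation harness: folds, tuning, experiments, model comparison."""

import numpy as np
import pytest
from scipy import stats

from ordicell.harness import (
    ExperimentResult,
    TrainConfig,
    build_head,
    build_model,
    compare_models,
    paired_t_pvalue,
    run_experiment,
    stratified_folds,
    tune_lambda,
    win_counts,
)
from ordicell.metrics import MetricReport
from ordicell.synthetic import OrdinalDatasetSpec, sample_ordinal_features


def _dataset(K=4, total=160, separation=6.0, seed=0, dim=2):
    spec = OrdinalDatasetSpec(K=K, total=total, class_separation=separation,
                              feature_dim=dim, seed=seed)
    df = sample_ordinal_features(spec)
    X = df[[c for c in df.columns if c.startswith("feature_")]].to_numpy()
    return X, df["label"].to_numpy()


class TestBuildHead:
    @pytest.mark.parametrize(
        "K,loss,width",
        [(7, "ce", 7), (7, "co2", 7), (7, "ho2", 7), (7, "oe", 6),
         (4, "bu", 1), (5, "pu", 1)],
    )
    def test_output_width_per_loss(self, K, loss, width):
        assert build_head(K, loss).out_width == width

    def test_layer_stack_description(self):
        desc = build_head(7, "ce").describe()
        assert desc == ["dropout(p=0.2)", "dense(512)", "relu",
                        "dropout(p=0.2)", "dense(256)", "relu", "dense(7)"]

    def test_instantiated_stack_maps_embedding_to_output(self):
        rng = np.random.default_rng(0)
        layers = build_head(7, "oe").instantiate(32, rng)
        from ordicell.nn import Sequential

        z = Sequential(layers).forward(rng.normal(size=(3, 32)))
        assert z.shape == (3, 6)

    def test_unknown_loss_rejected(self):
        with pytest.raises(ValueError):
            build_head(7, "hinge")


class TestStratifiedFolds:
    def test_balanced_seven_class_ten_fold(self):
        labels = np.repeat(np.arange(1, 8), 10)
        folds = stratified_folds(labels, 10, seed=0)
        for f in range(10):
            classes, counts = np.unique(labels[folds == f], return_counts=True)
            assert classes.tolist() == list(range(1, 8))
            assert np.all(counts == 1)

    def test_partition_and_stratification_bound(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(1, 5, 200)
        folds = stratified_folds(labels, 5, seed=3)
        assert np.bincount(folds).sum() == 200
        for k in range(1, 5):
            per_fold = [np.sum((folds == f) & (labels == k)) for f in range(5)]
            assert max(per_fold) - min(per_fold) <= 1

    def test_leave_one_out(self):
        labels = np.arange(1, 6)
        folds = stratified_folds(labels, 5, seed=0)
        assert sorted(folds.tolist()) == [0, 1, 2, 3, 4]

    def test_deterministic_under_seed(self):
        labels = np.repeat([1, 2, 3], 20)
        np.testing.assert_array_equal(
            stratified_folds(labels, 4, seed=7), stratified_folds(labels, 4, seed=7)
        )


class TestTuneLambda:
    def test_single_value_grid_short_circuits(self):
        X, y = _dataset(total=40)
        cfg = TrainConfig(loss_name="co2", lambda_grid=(0.5,), epochs=1)
        assert tune_lambda(X, y, 4, cfg, seed=0) == 0.5

    def test_empty_grid_is_an_error(self):
        with pytest.raises(ValueError):
            TrainConfig(loss_name="co2", lambda_grid=())

    def test_destructive_lambda_rejected_in_favor_of_zero(self):
        # with an enormous penalty weight the model collapses; inner CV must
        # prefer lambda = 0 (plain CE behaviour) on separable data
        X, y = _dataset(K=3, total=90, separation=8.0)
        cfg = TrainConfig(loss_name="co2", lambda_grid=(0.0, 1e4), epochs=30,
                          initial_step_size=1e-2, inner_folds=3,
                          head_widths=(16,), backbone_name="identity")
        assert tune_lambda(X, y, 3, cfg, seed=0) == 0.0

    def test_deterministic_under_seed(self):
        X, y = _dataset(K=3, total=60, separation=4.0)
        cfg = TrainConfig(loss_name="co2", lambda_grid=(0.1, 1.0), epochs=5,
                          inner_folds=3, head_widths=(8,),
                          backbone_name="identity")
        assert tune_lambda(X, y, 3, cfg, seed=4) == tune_lambda(X, y, 3, cfg, seed=4)


class TestRunExperiment:
    def test_separable_data_all_folds_accurate(self):
        X, y = _dataset(K=3, total=120, separation=10.0)
        cfg = TrainConfig(loss_name="ce", lambda_grid=(0.0,), epochs=80,
                          initial_step_size=1e-2, outer_folds=3,
                          head_widths=(32,), seed=0)
        result = run_experiment(X, y, cfg)
        for report in result.fold_reports:
            assert report.accuracy > 0.95

    def test_rerun_is_identical(self):
        X, y = _dataset(K=3, total=60, separation=4.0)
        cfg = TrainConfig(loss_name="co2", lambda_grid=(1.0,), epochs=5,
                          outer_folds=3, head_widths=(8,),
                          backbone_name="identity", seed=2)
        a = run_experiment(X, y, cfg)
        b = run_experiment(X, y, cfg)
        from dataclasses import asdict

        for ra, rb in zip(a.fold_reports, b.fold_reports):
            for field, va in asdict(ra).items():
                vb = asdict(rb)[field]
                assert va == vb or (np.isnan(va) and np.isnan(vb))

    def test_missing_class_in_training_split_is_an_error(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        y = np.array([1, 1, 1, 1, 1, 2])  # one sample of class 2
        cfg = TrainConfig(loss_name="ce", epochs=1, outer_folds=2,
                          head_widths=(4,))
        with pytest.raises(ValueError, match="absent"):
            run_experiment(X, y, cfg)

    def test_result_aggregates_and_frame(self):
        X, y = _dataset(K=3, total=60, separation=4.0)
        cfg = TrainConfig(loss_name="ce", epochs=3, outer_folds=3,
                          head_widths=(8,), backbone_name="identity")
        result = run_experiment(X, y, cfg)
        assert len(result.fold_reports) == 3
        assert set(result.means) == {"accuracy", "mae", "uoc", "kendall_tau",
                                     "macro_auroc", "mean_gini"}
        frame = result.to_frame()
        assert len(frame) == 3 and "chosen_lambda" in frame.columns

    def test_lr_trace_recorded_per_fold(self):
        X, y = _dataset(K=3, total=60, separation=4.0)
        cfg = TrainConfig(loss_name="ce", epochs=4, outer_folds=3,
                          head_widths=(8,), backbone_name="identity")
        result = run_experiment(X, y, cfg)
        for log in result.fold_logs:
            assert len(log["lr_trace"]) == 4
            assert np.all(np.diff(log["lr_trace"]) <= 1e-15)


class TestCompareModels:
    def _fake_result(self, values_by_metric):
        n = len(next(iter(values_by_metric.values())))
        reports = []
        for i in range(n):
            fields = dict(accuracy=0.5, mae=1.0, uoc=50.0, kendall_tau=0.5,
                          macro_auroc=0.5, mean_gini=0.5)
            for metric, vals in values_by_metric.items():
                fields[metric] = vals[i]
            reports.append(MetricReport(**fields))
        cfg = TrainConfig(loss_name="ce")
        return ExperimentResult(config=cfg, fold_reports=reports,
                                chosen_lambdas=[None] * n)

    def test_identical_results_marked_similar(self):
        a = self._fake_result({"mae": [0.5, 0.6, 0.7]})
        b = self._fake_result({"mae": [0.5, 0.6, 0.7]})
        table = compare_models({"a": a, "b": b}, "mae")
        assert table["p_vs_best"].min() == 1.0
        assert table["similar_to_best"].all()

    def test_constant_nonzero_difference_is_dissimilar(self):
        a = self._fake_result({"mae": [1, 2, 3, 4, 5]})
        b = self._fake_result({"mae": [2, 3, 4, 5, 6]})
        table = compare_models({"a": a, "b": b}, "mae")
        assert table.loc["a", "best"]
        assert table.loc["b", "p_vs_best"] == 0.0
        assert not table.loc["b", "similar_to_best"]

    def test_pvalue_matches_textbook_t_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            a = rng.normal(size=10)
            b = a + rng.normal(0.3, 0.5, size=10)
            d = a - b
            t = d.mean() / (d.std(ddof=1) / np.sqrt(10))
            p_oracle = 2 * stats.t.sf(abs(t), df=9)
            assert paired_t_pvalue(a, b) == pytest.approx(p_oracle, abs=1e-6)

    def test_direction_respected_per_metric(self):
        good = self._fake_result({"accuracy": [0.9, 0.8, 0.9],
                                  "mae": [0.1, 0.2, 0.1]})
        bad = self._fake_result({"accuracy": [0.5, 0.4, 0.5],
                                 "mae": [0.9, 1.0, 0.9]})
        assert compare_models({"g": good, "b": bad}, "accuracy").loc["g", "best"]
        assert compare_models({"g": good, "b": bad}, "mae").loc["g", "best"]

    def test_win_counts(self):
        a = self._fake_result({"mae": [0.1, 0.1, 0.1]})
        b = self._fake_result({"mae": [0.9, 0.9, 0.9]})
        tables = [compare_models({"a": a, "b": b}, "mae"),
                  compare_models({"a": a, "b": b}, "uoc")]
        wins = win_counts(tables)
        assert wins["a"] + wins["b"] == 2


class TestTrainConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = TrainConfig(loss_name="ho2", lambda_grid=(0.1, 1.0), epochs=7)
        path = tmp_path / "config.yaml"
        cfg.to_yaml(path)
        assert TrainConfig.from_yaml(path) == cfg

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(loss_name="nope")
        with pytest.raises(ValueError):
            TrainConfig(outer_folds=1)
        with pytest.raises(ValueError):
            TrainConfig(plateau_factor=1.5)
        with pytest.raises(ValueError):
            TrainConfig(inference_rule="median")

    def test_unknown_backbone_rejected(self):
        cfg = TrainConfig(backbone_name="resnet18")
        with pytest.raises(ValueError, match="backbone"):
            build_model(cfg, 4, (2,), np.random.default_rng(0))
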