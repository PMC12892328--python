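"""Losses, metrics, null model, quantiles, CV mechanics and grid search."""

import numpy as np
import pandas as pd
import pytest

from pkagraph.gnn_models import ModelConfig
from pkagraph.training_eval import (
    PkaGNN,
    compute_metrics,
    cross_validate,
    evaluate_predictions,
    grid_search,
    loss_value,
    null_model_predict,
    quantile_report,
    shift_correlation,
    train_model,
)

FAST = dict(max_epochs=40, patience=10)
SMALL_CFG = ModelConfig(
    architecture="GCN", hidden_channels=8, dropout_rate=0.0, loss="mse",
    learning_rate=0.01, batch_size=16, seed=0,
)


class TestLossValue:
    def test_perfect_predictions_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        for kind in ("mse", "l1", "smooth_l1"):
            assert loss_value(y, y, kind) == 0.0

    def test_smooth_l1_quadratic_branch(self):
        # |e| = 0.25 < beta: e^2 / (2 beta) = 0.0625
        assert loss_value([0.25], [0.0], "smooth_l1") == pytest.approx(0.0625)

    def test_closed_forms_large_error(self):
        # e = 2: l1 = 2, mse = 4, smooth_l1 = |e| - beta/2 = 1.75
        assert loss_value([2.0], [0.0], "l1") == 2.0
        assert loss_value([2.0], [0.0], "mse") == 4.0
        assert loss_value([2.0], [0.0], "smooth_l1") == 1.75

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            loss_value([], [], "mse")


class TestComputeMetrics:
    def test_perfect(self):
        assert compute_metrics([(1.0, 1.0), (2.0, 2.0)]) == (0.0, 0.0)

    def test_symmetric_unit_errors(self):
        mae, rmse = compute_metrics([(1.0, 0.0), (-1.0, 0.0)])
        assert (mae, rmse) == (1.0, 1.0)

    def test_uneven_errors(self):
        mae, rmse = compute_metrics([(0.0, 0.0), (2.0, 0.0)])
        assert mae == 1.0
        assert rmse == pytest.approx(np.sqrt(2))

    def test_mae_never_exceeds_rmse(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pairs = rng.normal(size=(10, 2))
            mae, rmse = compute_metrics(pairs)
            assert mae <= rmse + 1e-12


class TestNullModel:
    @pytest.mark.parametrize("rtype,ref", [
        ("ASP", 3.7), ("GLU", 4.2), ("HIS", 6.5), ("LYS", 10.4),
    ])
    def test_reference_values(self, rtype, ref):
        assert null_model_predict(rtype) == ref

    def test_unsupported_type(self):
        with pytest.raises(ValueError):
            null_model_predict("CYS")

    def test_zero_mae_on_reference_labels(self, toy_graphs):
        pairs = [
            (null_model_predict(g.key.residue_name), g.label)
            for g in toy_graphs
        ]
        mae, rmse = compute_metrics(pairs)
        assert mae == 0.0 and rmse == 0.0


class TestQuantileReport:
    # 8 constructed pairs: ASP reference 3.7, |shift| spread over 4 bins
    PAIRS = [
        (3.7, 3.7), (3.8, 3.75),          # |shift| 0.00, 0.05 -> Q1
        (4.0, 3.95), (3.4, 3.3),          # 0.25, 0.40 -> Q2
        (4.5, 4.3), (2.9, 2.8),           # 0.60, 0.90 -> Q3
        (5.5, 5.2), (9.0, 8.6),           # 1.50, 4.90 -> Q4
    ]
    TYPES = ["ASP"] * 8

    def test_hand_bucketing(self):
        report = quantile_report(self.PAIRS, self.TYPES, [0.2, 0.5, 1.0])
        assert [q["count"] for q in report] == [2, 2, 2, 2]

    def test_counts_sum_to_n(self):
        report = quantile_report(self.PAIRS, self.TYPES, [0.1, 0.3])
        assert sum(q["count"] for q in report) == len(self.PAIRS)

    def test_all_zero_shifts_in_first_bin(self):
        pairs = [(4.0, 3.7)] * 5
        report = quantile_report(pairs, ["ASP"] * 5)
        assert report[0]["count"] == 5
        assert all(q["count"] == 0 for q in report[1:])

    def test_above_last_boundary_kept(self):
        pairs = [(10.0, 9.9)]  # |shift| = 6.2 for ASP
        report = quantile_report(pairs, ["ASP"])
        assert report[-1]["count"] == 1

    def test_non_increasing_boundaries_rejected(self):
        with pytest.raises(ValueError):
            quantile_report(self.PAIRS, self.TYPES, [0.5, 0.2])


class TestShiftCorrelation:
    def test_perfect_agreement(self):
        pairs = [(3.9, 3.9), (4.5, 4.5), (3.0, 3.0)]
        assert shift_correlation(pairs, ["ASP"] * 3) == pytest.approx(1.0)

    def test_anticorrelated(self):
        exp = [3.9, 4.5, 3.0]
        pred = [3.7 - (e - 3.7) for e in exp]
        pairs = list(zip(pred, exp))
        assert shift_correlation(pairs, ["ASP"] * 3) == pytest.approx(-1.0)

    def test_matches_textbook_pearson(self):
        from scipy.stats import pearsonr

        rng = np.random.default_rng(5)
        exp = 3.7 + rng.normal(size=30)
        pred = 3.7 + rng.normal(size=30)
        pairs = list(zip(pred, exp))
        r = shift_correlation(pairs, ["ASP"] * 30)
        assert r == pytest.approx(pearsonr(pred - 3.7, exp - 3.7)[0],
                                  abs=1e-12)

    def test_zero_variance_undefined(self):
        pairs = [(3.7, 4.0), (3.7, 4.5), (3.7, 3.0)]
        with pytest.raises(ValueError):
            shift_correlation(pairs, ["ASP"] * 3)


class TestTraining:
    def test_recovers_planted_linear_signal(self, planted_small):
        graphs, record = planted_small
        res = train_model(graphs[:100], graphs[100:], SMALL_CFG,
                          max_epochs=200, patience=25)
        pred = res.predict(graphs[100:])
        exp = np.array([g.label for g in graphs[100:]])
        mae = np.mean(np.abs(pred - exp))
        assert mae < record["noise_sd"] + 0.1

    def test_same_seed_identical_history(self, planted_small):
        graphs, _ = planted_small
        r1 = train_model(graphs[:40], graphs[40:50], SMALL_CFG, **FAST)
        r2 = train_model(graphs[:40], graphs[40:50], SMALL_CFG, **FAST)
        assert r1.history == r2.history
        for k in r1.params:
            np.testing.assert_array_equal(r1.params[k], r2.params[k])

    def test_early_stopping_respects_patience(self, planted_small):
        graphs, _ = planted_small
        res = train_model(graphs[:40], graphs[40:50], SMALL_CFG,
                          max_epochs=300, patience=10)
        assert res.epochs_run <= res.best_epoch + 10

    def test_empty_sets_rejected(self, planted_small):
        graphs, _ = planted_small
        with pytest.raises(ValueError):
            train_model([], graphs[:5], SMALL_CFG)

    def test_summary_mentions_config(self, planted_small):
        graphs, _ = planted_small
        res = PkaGNN(graphs[:30], SMALL_CFG).fit(**FAST)
        text = res.summary()
        assert "GCN" in text and "best epoch" in text

    def test_checkpoint_roundtrip(self, planted_small, tmp_path):
        from pkagraph.training_eval import PkaGNNResults

        graphs, _ = planted_small
        res = PkaGNN(graphs[:30], SMALL_CFG).fit(**FAST)
        res.save(tmp_path / "m.json")
        back = PkaGNNResults.load(tmp_path / "m.json")
        np.testing.assert_allclose(
            back.predict(graphs[:5]), res.predict(graphs[:5]), atol=1e-12
        )


@pytest.fixture(scope="module")
def cv(planted_small):
    graphs, _ = planted_small
    graphs = graphs[:60]
    return cross_validate(graphs, SMALL_CFG, k=5, seed=3, **FAST), graphs


class TestCrossValidation:
    def test_fold_sizes_near_equal(self, cv):
        result, graphs = cv
        sizes = [len(fr.predictions) for fr in result.fold_results]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == len(graphs)

    def test_every_graph_validated_once(self, cv):
        # labels are continuous draws, so the multiset of held-out labels
        # matching the dataset's labels means each graph appears exactly once
        result, graphs = cv
        held_out = sorted(
            e for fr in result.fold_results for _k, _p, e in fr.predictions
        )
        assert held_out == sorted(g.label for g in graphs)

    def test_pooled_mae_is_arithmetic_mean(self, cv):
        result, _graphs = cv
        pairs = result.pooled_pairs
        mae = np.mean([abs(p - e) for p, e in pairs])
        assert result.report.mae == pytest.approx(mae, abs=1e-12)

    def test_mae_le_rmse(self, cv):
        result, _ = cv
        assert result.report.mae <= result.report.rmse + 1e-12

    def test_k_exceeding_n_rejected(self, planted_small):
        graphs, _ = planted_small
        with pytest.raises(ValueError):
            cross_validate(graphs[:5], SMALL_CFG, k=10)


class TestGridSearch:
    def test_two_point_grid(self, planted_small):
        graphs, _ = planted_small
        grid = {"architecture": ["GCN"], "hidden_channels": [4, 8],
                "dropout_rate": [0.0], "loss": ["mse"],
                "learning_rate": [0.01], "batch_size": [16]}
        table = grid_search(graphs[:40], grid, k=3, seed=1, **FAST)
        assert len(table) == 2
        assert table["best"].sum() == 1
        best = table[table["best"]].iloc[0]
        assert best["mae"] == table["mae"].min()

    def test_rerun_reproduces_table(self, planted_small):
        graphs, _ = planted_small
        grid = {"architecture": ["GCN"], "hidden_channels": [4],
                "dropout_rate": [0.0], "loss": ["mse"],
                "learning_rate": [0.01], "batch_size": [16]}
        t1 = grid_search(graphs[:30], grid, k=3, seed=2, **FAST)
        t2 = grid_search(graphs[:30], grid, k=3, seed=2, **FAST)
        pd.testing.assert_frame_equal(t1, t2)

    def test_empty_grid_rejected(self, planted_small):
        graphs, _ = planted_small
        with pytest.raises(ValueError):
            grid_search(graphs, {}, k=3)


class TestEvaluatePredictions:
    def test_report_consistency(self, planted_small):
        graphs, _ = planted_small
        rng = np.random.default_rng(0)
        pairs = [(g.label + rng.normal(scale=0.3), g.label) for g in graphs]
        types = [g.key.residue_name for g in graphs]
        report = evaluate_predictions(pairs, types)
        assert report.n == len(pairs)
        assert report.mae <= report.rmse
        assert sum(q["count"] for q in report.quantiles) == report.n
        assert set(report.per_type) <= {"ASP", "GLU", "HIS", "LYS"}
        assert "MAE" in report.summary()
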