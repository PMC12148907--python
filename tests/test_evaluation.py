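import numpy as np
import pandas as pd
import pytest

from attenurank.evaluation import (
    EvalResult,
    GridSpec,
    PhaseConfig,
    PoolExhaustedError,
    audit_leakage,
    benchmark_real,
    classification_scores,
    effect_size,
    phase1_hybrid,
    phase2_pure_synthetic,
    render_reports,
    results_frame,
    select_optima,
)
from conftest import STRONG_SIGNAL, features_and_targets

SMALL = GridSpec.small()


class TestScores:
    def test_perfect_predictions(self):
        assert classification_scores([0, 1, 0, 1], [0, 1, 0, 1]) == (1.0, 1.0, 1.0, 1.0)

    def test_hand_confusion_matrix(self):
        acc, prec, rec, f1 = classification_scores((0, 0, 1, 1), (0, 1, 1, 1))
        assert acc == 0.75
        assert prec == pytest.approx((1.0 + 2 / 3) / 2, abs=1e-9)  # macro over classes
        assert rec == pytest.approx(0.75)
        f1_0 = 2 * 1.0 * 0.5 / (1.0 + 0.5)
        f1_1 = 2 * (2 / 3) * 1.0 / (2 / 3 + 1.0)
        assert f1 == pytest.approx((f1_0 + f1_1) / 2)

    def test_one_class_predictions_on_balanced_truth(self):
        acc, *_ = classification_scores([0, 1, 0, 1], [1, 1, 1, 1])
        assert acc == 0.5

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            classification_scores([0, 1], [0])


class TestEffectSize:
    def test_relative_improvement(self):
        assert effect_size(0.54, 0.81) == 50.0
        assert effect_size(0.72, 0.72) == 0.0
        assert effect_size(0.37, 0.37) == 0.0

    def test_zero_benchmark_undefined(self):
        with pytest.raises(ValueError):
            effect_size(0.0, 0.5)


class TestSelectOptima:
    def make(self, target, model, prop, acc, f1):
        return EvalResult(
            target=target, model=model, phase="hybrid", synthetic_proportion=prop,
            best_params={}, accuracy=acc, precision=acc, recall=acc, f1=f1,
            cv_accuracy=acc,
        )

    def test_single_candidate(self):
        r = self.make("cmj", "xgboost", 10, 0.8, 0.8)
        assert select_optima([r])["cmj"] is r

    def test_known_argmax_matches_exhaustive_scan(self):
        rng = np.random.default_rng(0)
        results = [
            self.make("cmj", "random_forest", p, rng.random(), rng.random())
            for p in range(10, 101, 10)
        ]
        best = select_optima(results)["cmj"]
        exhaustive = max(results, key=lambda r: r.accuracy)
        assert best.accuracy == exhaustive.accuracy

    def test_accuracy_tie_broken_by_f1_then_proportion(self):
        a = self.make("pr", "adaboost", 50, 0.8, 0.70)
        b = self.make("pr", "adaboost", 30, 0.8, 0.75)
        assert select_optima([a, b])["pr"] is b
        c = self.make("pr", "adaboost", 20, 0.8, 0.75)
        assert select_optima([a, b, c])["pr"] is c


class TestBenchmark:
    def test_degenerate_labels_rejected(self, small_features_targets):
        features, targets = small_features_targets
        constant = targets.copy()
        constant["cmj"] = 0
        with pytest.raises(ValueError, match="degenerate"):
            benchmark_real(features, constant, SMALL, targets=["cmj"])

    def test_deterministic_given_seed(self, small_features_targets):
        features, targets = small_features_targets
        cfg = PhaseConfig(phase="benchmark", seed=5)
        a = benchmark_real(features, targets, SMALL, cfg, targets=["cmj", "pr"])
        b = benchmark_real(features, targets, SMALL, cfg, targets=["cmj", "pr"])
        assert {k: v.accuracy for k, v in a.items()} == {k: v.accuracy for k, v in b.items()}
        assert a["cmj"].best_params == b["cmj"].best_params

    def test_planted_signal_is_learnable_above_chance(self):
        """With a strong planted attenuation signal, the best model beats
        the 0.5 majority baseline for most targets when averaged over seeds."""
        means = {}
        for target in ("cmj", "dj"):
            accs = []
            for seed in range(6):
                features, targets = features_and_targets(seed=seed, **STRONG_SIGNAL)
                bench = benchmark_real(
                    features, targets, SMALL,
                    PhaseConfig(phase="benchmark", seed=seed), targets=[target],
                )
                accs.append(bench[target].accuracy)
            means[target] = np.mean(accs)
        assert all(m > 0.5 for m in means.values()), means


@pytest.fixture(scope="module")
def data():
    real_X, real_y = features_and_targets(seed=1, **STRONG_SIGNAL)
    synth_X, synth_y = features_and_targets(seed=77, n=200, **STRONG_SIGNAL)
    return real_X, real_y, synth_X, synth_y


class TestPhases:
    def test_phase1_composition_audit(self, data):
        real_X, real_y, synth_X, synth_y = data
        results = phase1_hybrid(
            real_X, real_y, synth_X, synth_y, SMALL,
            PhaseConfig(phase="hybrid", seed=2, proportions=(50,)), targets=["cmj"],
        )
        res = results[0]
        assert len(res.train_real_indices) == 30  # 75% of 41 rows
        assert len(res.test_indices) == 11
        assert len(res.train_synth_indices) == 15  # round(0.5 * 30)

    def test_phase1_zero_proportion_reduces_to_benchmark(self, data):
        real_X, real_y, synth_X, synth_y = data
        cfg_b = PhaseConfig(phase="benchmark", seed=3)
        bench = benchmark_real(real_X, real_y, SMALL, cfg_b, targets=["cmj"])
        results = phase1_hybrid(
            real_X, real_y, synth_X, synth_y, SMALL,
            PhaseConfig(phase="hybrid", seed=3, proportions=(0,)), targets=["cmj"],
        )
        assert results[0].accuracy == bench["cmj"].accuracy
        assert results[0].train_synth_indices == ()

    def test_phase1_pool_exhaustion(self, data):
        real_X, real_y, *_ = data
        tiny_pool_X, tiny_pool_y = features_and_targets(seed=78, n=5, **STRONG_SIGNAL)
        with pytest.raises(PoolExhaustedError):
            phase1_hybrid(
                real_X, real_y, tiny_pool_X, tiny_pool_y, SMALL,
                PhaseConfig(phase="hybrid", seed=2, proportions=(100,)), targets=["cmj"],
            )

    def test_phase2_uses_full_pool_and_no_real_rows(self, data):
        real_X, real_y, synth_X, synth_y = data
        results = phase2_pure_synthetic(
            real_X, real_y, synth_X, synth_y, SMALL,
            PhaseConfig(phase="pure_synthetic", seed=2, proportions=(100,)),
            targets=["cmj"],
        )
        res = results[0]
        assert len(res.train_synth_indices) == 200
        assert res.train_real_indices == ()
        assert len(res.test_indices) == len(real_X)

    def test_phase2_rejects_sub_forty_proportions(self):
        with pytest.raises(ValueError, match=">= 40"):
            PhaseConfig(phase="pure_synthetic", proportions=(20,))

    def test_leakage_audit(self, data):
        real_X, real_y, synth_X, synth_y = data
        bench = benchmark_real(real_X, real_y, SMALL,
                               PhaseConfig(phase="benchmark", seed=4), targets=["cmj"])
        p1 = phase1_hybrid(real_X, real_y, synth_X, synth_y, SMALL,
                           PhaseConfig(phase="hybrid", seed=4, proportions=(50,)),
                           targets=["cmj"])
        p2 = phase2_pure_synthetic(real_X, real_y, synth_X, synth_y, SMALL,
                                   PhaseConfig(phase="pure_synthetic", seed=4,
                                               proportions=(50,)), targets=["cmj"])
        assert audit_leakage(list(bench.values()) + p1 + p2)
        leaky = EvalResult(
            target="cmj", model="random_forest", phase="hybrid",
            synthetic_proportion=0, best_params={}, accuracy=1, precision=1,
            recall=1, f1=1, cv_accuracy=1,
            train_real_indices=(1, 2), test_indices=(2, 3),
        )
        assert not audit_leakage([leaky])


class TestRenderReports:
    def test_empty_results_write_tables(self, tmp_path):
        files = render_reports([], tmp_path)
        assert (tmp_path / "results.csv").exists()
        assert (tmp_path / "optima.csv").exists()
        assert not list(tmp_path.glob("*.png"))

    def test_two_target_run_counts_and_determinism(self, tmp_path):
        rng = np.random.default_rng(0)
        results = [
            EvalResult(target=t, model="random_forest", phase="hybrid",
                       synthetic_proportion=p, best_params={"n_estimators": 50},
                       accuracy=float(rng.random()), precision=0.5, recall=0.5,
                       f1=0.5, cv_accuracy=0.5)
            for t in ("cmj", "pr") for p in (10, 20)
        ]
        render_reports(results, tmp_path / "a")
        render_reports(results, tmp_path / "b")
        assert len(list((tmp_path / "a").glob("accuracy_*.png"))) == 2
        assert (tmp_path / "a" / "results.csv").read_bytes() == (
            tmp_path / "b" / "results.csv"
        ).read_bytes()

    def test_results_frame_one_row_per_cell(self):
        frame = results_frame([])
        assert list(frame.columns)[:4] == ["target", "model", "phase", "synthetic_proportion"]
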