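"""Two-phase machine-learning evaluation of synthetic-data utility.

The harness answers two questions about a synthetic table generated from a
small real cohort:

* **Phase 1 (hybrid augmentation)** — does adding synthetic rows to the
  real training split (at 10%–100% of the real training size, in steps of
  10) improve held-out accuracy on real data?
* **Phase 2 (train-synthetic, test-real)** — can models trained *only* on
  synthetic rows (40%–100% of the synthetic pool) predict the real
  cohort?  Below ~40% of a 200-row pool training becomes too unstable to
  interpret, hence the phase's lower bound.

Both phases are benchmarked against the best model per target trained
exclusively on real data.  Four classifier families are tuned by grid
search with stratified 5-fold cross-validation: random forest, XGBoost,
AdaBoost (depth-1 tree base learners) and a linear SVM (standardized
features).  Model selection uses CV accuracy with F1 as tie-break and a
fixed simplicity order as the final tie-break.  Every result row records
the exact train/test row indices used, so leakage-freedom is auditable
after the fact.

The per-comparison *effect size* is the relative accuracy change against
the benchmark, ``100 · (acc_new − acc_bench) / acc_bench`` percent.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from ._seeds import child_seed

__all__ = [
    "GridSpec",
    "PhaseConfig",
    "EvalResult",
    "PoolExhaustedError",
    "MODEL_FAMILIES",
    "classification_scores",
    "effect_size",
    "benchmark_real",
    "phase1_hybrid",
    "phase2_pure_synthetic",
    "select_optima",
    "audit_leakage",
    "results_frame",
    "render_reports",
]

# Simplicity order used as the final tie-break (simplest first).
MODEL_FAMILIES: tuple[str, ...] = ("linear_svm", "adaboost", "random_forest", "xgboost")

PHASE1_PROPORTIONS: tuple[int, ...] = tuple(range(10, 101, 10))
PHASE2_PROPORTIONS: tuple[int, ...] = tuple(range(40, 101, 10))


class PoolExhaustedError(ValueError):
    """More synthetic rows were requested than the pool holds."""


@dataclasses.dataclass
class GridSpec:
    """Hyperparameter grids per model family."""

    grids: dict[str, dict[str, list]] = dataclasses.field(
        default_factory=lambda: {
            "random_forest": {
                "n_estimators": [50, 100, 200],
                "max_depth": [None, 10, 20, 30],
            },
            "xgboost": {
                "n_estimators": [50, 100, 200],
                "learning_rate": [0.01, 0.1, 0.2],
                "max_depth": [3, 6, 9],
            },
            "adaboost": {
                "n_estimators": [50, 100, 200],
                "learning_rate": [0.01, 0.1, 1.0],
            },
            "linear_svm": {
                "clf__C": [0.01, 0.1, 1.0, 10.0],
                "clf__max_iter": [1000, 2000],
            },
        }
    )

    def __post_init__(self) -> None:
        for family, grid in self.grids.items():
            if family not in MODEL_FAMILIES:
                raise ValueError(f"unknown model family {family!r}")
            if not grid or any(len(v) == 0 for v in grid.values()):
                raise ValueError(f"empty grid for family {family!r}")

    @classmethod
    def small(cls) -> "GridSpec":
        """A deliberately tiny grid for control experiments and smoke runs."""
        return cls(
            grids={
                "random_forest": {"n_estimators": [100], "max_depth": [None]},
            }
        )


@dataclasses.dataclass
class PhaseConfig:
    """Configuration of one evaluation phase."""

    phase: str = "benchmark"  # benchmark | hybrid | pure_synthetic
    train_fraction: float = 0.75
    proportions: tuple[int, ...] = ()
    seed: int = 0
    score_averaging: str = "macro"  # macro | weighted

    def __post_init__(self) -> None:
        if self.phase not in ("benchmark", "hybrid", "pure_synthetic"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.score_averaging not in ("macro", "weighted"):
            raise ValueError(f"unknown averaging {self.score_averaging!r}")
        if not self.proportions:
            if self.phase == "hybrid":
                self.proportions = PHASE1_PROPORTIONS
            elif self.phase == "pure_synthetic":
                self.proportions = PHASE2_PROPORTIONS
        if self.phase == "pure_synthetic" and any(p < 40 for p in self.proportions):
            raise ValueError("pure-synthetic proportions must be >= 40%")
        if any(not 0 <= p <= 100 for p in self.proportions):
            raise ValueError("proportions must lie in [0, 100]")


@dataclasses.dataclass
class EvalResult:
    """One evaluated (target, model, phase, proportion) cell."""

    target: str
    model: str
    phase: str
    synthetic_proportion: int
    best_params: dict
    accuracy: float
    precision: float
    recall: float
    f1: float
    cv_accuracy: float
    effect_size_pct: float | None = None
    train_real_indices: tuple[int, ...] = ()
    train_synth_indices: tuple[int, ...] = ()
    test_indices: tuple[int, ...] = ()


def classification_scores(
    y_true, y_pred, averaging: str = "macro"
) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, F1) with the configured class averaging."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    return (
        float(accuracy_score(y_true, y_pred)),
        float(precision_score(y_true, y_pred, average=averaging, zero_division=0)),
        float(recall_score(y_true, y_pred, average=averaging, zero_division=0)),
        float(f1_score(y_true, y_pred, average=averaging, zero_division=0)),
    )


def effect_size(benchmark_accuracy: float, new_accuracy: float) -> float:
    """Relative accuracy change vs. the benchmark, in percent (1 decimal)."""
    if benchmark_accuracy <= 0:
        raise ValueError("effect size is undefined for a zero benchmark accuracy")
    return round(100.0 * (new_accuracy - benchmark_accuracy) / benchmark_accuracy, 1)


def _make_estimator(family: str, seed: int):
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if family == "xgboost":
        return XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss", verbosity=0,
            tree_method="hist",
        )
    if family == "adaboost":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1), random_state=seed
        )
    if family == "linear_svm":
        return Pipeline(
            [("scale", StandardScaler()), ("clf", LinearSVC(random_state=seed))]
        )
    raise ValueError(f"unknown model family {family!r}")


def _grid_search(X, y, family: str, grid: dict, seed: int):
    """Stratified 5-fold grid search; returns (best, params, cv_acc, cv_f1)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate labels: training data holds a single class")
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    search = GridSearchCV(
        _make_estimator(family, seed),
        grid,
        scoring={"accuracy": "accuracy", "f1": "f1_macro"},
        refit="accuracy",
        cv=cv,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(np.asarray(X, dtype=float), y)
    idx = search.best_index_
    cv_acc = float(search.cv_results_["mean_test_accuracy"][idx])
    cv_f1 = float(search.cv_results_["mean_test_f1"][idx])
    params = {k.replace("clf__", ""): v for k, v in search.best_params_.items()}
    return search.best_estimator_, params, cv_acc, cv_f1


def _evaluate_families(
    X_train,
    y_train,
    X_test,
    y_test,
    grids: GridSpec,
    seed: int,
    averaging: str,
    target: str,
    phase: str,
    proportion: int,
    train_real_idx,
    train_synth_idx,
    test_idx,
) -> list[EvalResult]:
    results = []
    for family in MODEL_FAMILIES:
        if family not in grids.grids:
            continue
        model, params, cv_acc, _cv_f1 = _grid_search(
            X_train, y_train, family, grids.grids[family],
            child_seed(seed, "grid", target, family, phase, proportion),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            y_pred = model.predict(np.asarray(X_test, dtype=float))
        acc, prec, rec, f1 = classification_scores(y_test, y_pred, averaging)
        results.append(
            EvalResult(
                target=target,
                model=family,
                phase=phase,
                synthetic_proportion=proportion,
                best_params=params,
                accuracy=acc,
                precision=prec,
                recall=rec,
                f1=f1,
                cv_accuracy=cv_acc,
                train_real_indices=tuple(int(i) for i in train_real_idx),
                train_synth_indices=tuple(int(i) for i in train_synth_idx),
                test_indices=tuple(int(i) for i in test_idx),
            )
        )
    return results


def _split(features: pd.DataFrame, y: np.ndarray, target: str, config: PhaseConfig):
    """The real-data 75/25 stratified split, shared by benchmark and Phase 1."""
    idx = np.arange(len(features))
    train_idx, test_idx = train_test_split(
        idx,
        test_size=1.0 - config.train_fraction,
        stratify=y,
        random_state=child_seed(config.seed, "split", target),
    )
    return np.sort(train_idx), np.sort(test_idx)


def benchmark_real(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    grids: GridSpec | None = None,
    config: PhaseConfig | None = None,
    targets: Sequence[str] | None = None,
) -> dict[str, EvalResult]:
    """Best real-data-only model per target.

    ``labels`` holds one 0/1 column per target, row-aligned with
    ``features``.  For each target every model family is grid-searched with
    stratified 5-fold CV on the 75% training split; the family with the
    best CV accuracy (ties: CV F1, then the fixed simplicity order) is
    scored on the held-out 25% split.
    """
    grids = grids or GridSpec()
    config = config or PhaseConfig(phase="benchmark")
    winners: dict[str, EvalResult] = {}
    for target in targets or labels.columns:
        y = np.asarray(labels[target])
        if len(np.unique(y)) < 2:
            raise ValueError(f"degenerate labels for target {target!r}")
        train_idx, test_idx = _split(features, y, target, config)
        candidates: list[tuple[float, float, int, EvalResult]] = []
        X_train = features.iloc[train_idx]
        X_test = features.iloc[test_idx]
        per_family = _evaluate_families(
            X_train, y[train_idx], X_test, y[test_idx], grids,
            config.seed, config.score_averaging, target, "benchmark", 0,
            train_idx, (), test_idx,
        )
        for res in per_family:
            simplicity = MODEL_FAMILIES.index(res.model)
            candidates.append((-res.cv_accuracy, -res.f1, simplicity, res))
        candidates.sort(key=lambda c: c[:3])
        winners[target] = candidates[0][3]
    return winners


def phase1_hybrid(
    real_features: pd.DataFrame,
    real_labels: pd.DataFrame,
    synth_features: pd.DataFrame,
    synth_labels: pd.DataFrame,
    grids: GridSpec | None = None,
    config: PhaseConfig | None = None,
    benchmark: Mapping[str, EvalResult] | None = None,
    targets: Sequence[str] | None = None,
) -> list[EvalResult]:
    """Hybrid augmentation sweep: real training split + synthetic rows.

    At proportion ``p`` exactly ``round(p/100 × n_real_train)`` synthetic
    rows (a seeded draw without replacement from the pool) are appended to
    the real training rows; every model is then scored on the untouched
    real test split.  ``p = 0`` reduces exactly to the benchmark.
    """
    grids = grids or GridSpec()
    config = config or PhaseConfig(phase="hybrid")
    results: list[EvalResult] = []
    for target in targets or real_labels.columns:
        y = np.asarray(real_labels[target])
        y_synth = np.asarray(synth_labels[target])
        train_idx, test_idx = _split(real_features, y, target, config)
        for p in config.proportions:
            n_syn = int(round(p / 100.0 * len(train_idx)))
            if n_syn > len(synth_features):
                raise PoolExhaustedError(
                    f"proportion {p}% needs {n_syn} synthetic rows, "
                    f"pool holds {len(synth_features)}"
                )
            rng = np.random.default_rng(child_seed(config.seed, "phase1", target, p))
            synth_idx = np.sort(rng.choice(len(synth_features), n_syn, replace=False))
            X_train = pd.concat(
                [real_features.iloc[train_idx], synth_features.iloc[synth_idx]],
                ignore_index=True,
            )
            y_train = np.concatenate([y[train_idx], y_synth[synth_idx]])
            per_family = _evaluate_families(
                X_train, y_train, real_features.iloc[test_idx], y[test_idx],
                grids, config.seed, config.score_averaging, target, "hybrid", p,
                train_idx, synth_idx, test_idx,
            )
            if benchmark and target in benchmark:
                bench_acc = benchmark[target].accuracy
                for res in per_family:
                    res.effect_size_pct = effect_size(bench_acc, res.accuracy)
            results.extend(per_family)
    return results


def phase2_pure_synthetic(
    real_features: pd.DataFrame,
    real_labels: pd.DataFrame,
    synth_features: pd.DataFrame,
    synth_labels: pd.DataFrame,
    grids: GridSpec | None = None,
    config: PhaseConfig | None = None,
    benchmark: Mapping[str, EvalResult] | None = None,
    targets: Sequence[str] | None = None,
) -> list[EvalResult]:
    """Train-synthetic-test-real sweep: no real row ever enters training.

    At proportion ``p`` the model trains on ``round(p/100 × n_synth)``
    synthetic rows (a seeded permutation prefix of the pool) and is
    evaluated on the complete real dataset.
    """
    grids = grids or GridSpec()
    config = config or PhaseConfig(phase="pure_synthetic")
    results: list[EvalResult] = []
    all_real = np.arange(len(real_features))
    for target in targets or real_labels.columns:
        y = np.asarray(real_labels[target])
        y_synth = np.asarray(synth_labels[target])
        for p in config.proportions:
            n = int(round(p / 100.0 * len(synth_features)))
            if n > len(synth_features):
                raise PoolExhaustedError(
                    f"proportion {p}% needs {n} rows, pool holds {len(synth_features)}"
                )
            rng = np.random.default_rng(child_seed(config.seed, "phase2", target, p))
            synth_idx = np.sort(rng.permutation(len(synth_features))[:n])
            per_family = _evaluate_families(
                synth_features.iloc[synth_idx], y_synth[synth_idx],
                real_features, y, grids, config.seed, config.score_averaging,
                target, "pure_synthetic", p, (), synth_idx, all_real,
            )
            if benchmark and target in benchmark:
                bench_acc = benchmark[target].accuracy
                for res in per_family:
                    res.effect_size_pct = effect_size(bench_acc, res.accuracy)
            results.extend(per_family)
    return results


def audit_leakage(results: Sequence[EvalResult]) -> bool:
    """True iff no result row shares real rows between training and test.

    Benchmark/hybrid rows must keep real-train and test indices disjoint;
    pure-synthetic rows must contain no real training rows at all.
    """
    for res in results:
        if set(res.train_real_indices) & set(res.test_indices):
            return False
        if res.phase == "pure_synthetic" and res.train_real_indices:
            return False
    return True


def select_optima(results: Sequence[EvalResult]) -> dict[str, EvalResult]:
    """Per target, the (model, proportion) with the best test accuracy.

    Ties break by F1, then by the smaller synthetic proportion, then by
    the fixed model simplicity order.
    """
    if not results:
        raise ValueError("no results to select from")
    optima: dict[str, EvalResult] = {}
    for res in results:
        cur = optima.get(res.target)
        if cur is None:
            optima[res.target] = res
            continue
        key = (-res.accuracy, -res.f1, res.synthetic_proportion,
               MODEL_FAMILIES.index(res.model))
        cur_key = (-cur.accuracy, -cur.f1, cur.synthetic_proportion,
                   MODEL_FAMILIES.index(cur.model))
        if key < cur_key:
            optima[res.target] = res
    return optima


def results_frame(results: Sequence[EvalResult]) -> pd.DataFrame:
    """Tidy frame: one row per target × model × proportion."""
    rows = [
        {
            "target": r.target,
            "model": r.model,
            "phase": r.phase,
            "synthetic_proportion": r.synthetic_proportion,
            "accuracy": r.accuracy,
            "f1": r.f1,
            "precision": r.precision,
            "recall": r.recall,
            "cv_accuracy": r.cv_accuracy,
            "effect_size_pct": r.effect_size_pct,
            "best_params": repr(r.best_params),
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "target", "model", "phase", "synthetic_proportion", "accuracy",
            "f1", "precision", "recall", "cv_accuracy", "effect_size_pct",
            "best_params",
        ],
    )


def render_reports(
    results: Sequence[EvalResult],
    out_dir,
    benchmark: Mapping[str, EvalResult] | None = None,
) -> list[Path]:
    """Write tidy CSVs and accuracy-vs-proportion figures per target."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    frame = results_frame(results)
    path = out / "results.csv"
    frame.to_csv(path, index=False)
    written.append(path)

    optima_path = out / "optima.csv"
    if results:
        optima = select_optima(results)
        results_frame(list(optima.values())).to_csv(optima_path, index=False)
        written.append(optima_path)
    else:
        results_frame([]).to_csv(optima_path, index=False)
        written.append(optima_path)
        return written

    for target, group in frame.groupby("target"):
        fig, (ax_top, ax_bot) = plt.subplots(
            2, 1, figsize=(7, 6), sharex=True,
            gridspec_kw={"height_ratios": [2, 1]},
        )
        bench_acc = benchmark[target].accuracy if benchmark and target in benchmark else None
        for model, sub in group.groupby("model"):
            sub = sub.sort_values("synthetic_proportion")
            ax_top.plot(sub["synthetic_proportion"], sub["accuracy"],
                        marker="o", label=model)
            if bench_acc is not None:
                ax_bot.plot(sub["synthetic_proportion"],
                            sub["accuracy"] - bench_acc, marker="o", label=model)
        if bench_acc is not None:
            ax_top.axhline(bench_acc, color="k", ls="--", lw=1, label="benchmark")
            ax_bot.axhline(0.0, color="k", ls="--", lw=1)
        ax_top.set_ylabel("test accuracy")
        ax_top.set_title(f"{target}: accuracy vs synthetic proportion")
        ax_top.legend(fontsize=8)
        ax_bot.set_xlabel("synthetic data proportion (%)")
        ax_bot.set_ylabel("Δ vs benchmark")
        fig.tight_layout()
        fig_path = out / f"accuracy_{target}.png"
        fig.savefig(fig_path, dpi=100)
        plt.close(fig)
        written.append(fig_path)
    return written
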