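"""Distributional-fidelity metrics for real-vs-synthetic comparison.

All metrics live on [0, 1] with 1 meaning identical summaries:

* *KS-complement* — 1 minus the maximum empirical-CDF gap between two
  numeric samples (column shapes, numeric columns);
* *TV-complement* — 1 minus the total-variation distance between two
  categorical frequency vectors (column shapes, categorical columns);
* *correlation similarity* — ``1 − |ρ_real − ρ_synth| / 2`` with Pearson ρ
  (pair trends, numeric-numeric pairs);
* *contingency similarity* — 1 minus half the L1 distance between the two
  joint contingency tables (pair trends, categorical-categorical pairs;
  numeric-categorical pairs are discretized first);
* *Hellinger distance* — ``√(½ Σ (√q − √p)²)`` between binned
  distributions; 0 for identical, 1 for disjoint support.

:func:`quality_report` aggregates these into a column-shapes score, a
column-pair-trends score and their mean (the overall score), plus
per-column Hellinger distances and fidelity tiers (high > 0.85, moderate
0.80–0.85, lower < 0.80 on the shape score).
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .tvae.transforms import ColumnMetadata, infer_metadata

__all__ = [
    "DiscreteDistribution",
    "DistributionError",
    "FidelityReport",
    "hellinger",
    "discretize_pair",
    "ks_complement",
    "tv_complement",
    "correlation_similarity",
    "contingency_similarity",
    "mixed_pair_similarity",
    "quality_report",
    "plot_marginals",
]

DEFAULT_BINS = 20
TIER_HIGH = 0.85
TIER_MODERATE = 0.80


class DistributionError(ValueError):
    """Input is not a valid probability distribution or sample."""


@dataclasses.dataclass(frozen=True)
class DiscreteDistribution:
    """Probabilities over a shared finite support."""

    support: tuple
    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if len(self.support) != len(p):
            raise DistributionError("support and probabilities differ in length")
        if np.any(p < 0):
            raise DistributionError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise DistributionError(f"probabilities must sum to 1, got {p.sum()!r}")


def hellinger(p: DiscreteDistribution, q: DiscreteDistribution) -> float:
    """Hellinger distance between two distributions on the same support."""
    if p.support != q.support:
        raise DistributionError("distributions must share a support")
    pa = np.asarray(p.probabilities, dtype=float)
    qa = np.asarray(q.probabilities, dtype=float)
    return float(np.sqrt(0.5 * np.sum((np.sqrt(qa) - np.sqrt(pa)) ** 2)))


def discretize_pair(
    real_col, synth_col, n_bins: int = DEFAULT_BINS
) -> tuple[DiscreteDistribution, DiscreteDistribution]:
    """Bin two numeric columns onto shared equal-width bins.

    Bins span the pooled min–max of both columns; empty bins carry
    probability 0.  A zero pooled range degenerates to a single bin.
    """
    r = np.asarray(real_col, dtype=float)
    s = np.asarray(synth_col, dtype=float)
    if r.size == 0 or s.size == 0:
        raise DistributionError("cannot discretize an empty column")
    lo = min(r.min(), s.min())
    hi = max(r.max(), s.max())
    if hi == lo:
        support = ((lo, hi),)
        return (
            DiscreteDistribution(support, (1.0,)),
            DiscreteDistribution(support, (1.0,)),
        )
    edges = np.linspace(lo, hi, n_bins + 1)
    support = tuple((float(a), float(b)) for a, b in zip(edges[:-1], edges[1:]))
    pr, _ = np.histogram(r, bins=edges)
    ps, _ = np.histogram(s, bins=edges)
    return (
        DiscreteDistribution(support, tuple(pr / pr.sum())),
        DiscreteDistribution(support, tuple(ps / ps.sum())),
    )


def ks_complement(real_col, synth_col) -> float:
    """1 − sup |F_real − F_synth| over the empirical CDFs."""
    r = np.sort(np.asarray(real_col, dtype=float))
    s = np.sort(np.asarray(synth_col, dtype=float))
    if r.size == 0 or s.size == 0:
        raise DistributionError("ks_complement needs non-empty columns")
    pooled = np.concatenate([r, s])
    f_r = np.searchsorted(r, pooled, side="right") / r.size
    f_s = np.searchsorted(s, pooled, side="right") / s.size
    return float(1.0 - np.max(np.abs(f_r - f_s)))


def tv_complement(real_col, synth_col) -> float:
    """1 − total-variation distance over the union of categories."""
    r = pd.Series(list(real_col))
    s = pd.Series(list(synth_col))
    if r.empty or s.empty:
        raise DistributionError("tv_complement needs non-empty columns")
    cats = sorted(set(r) | set(s), key=repr)
    pr = r.value_counts(normalize=True).reindex(cats, fill_value=0.0)
    ps = s.value_counts(normalize=True).reindex(cats, fill_value=0.0)
    return float(1.0 - 0.5 * np.abs(pr.to_numpy() - ps.to_numpy()).sum())


def correlation_similarity(real_pair, synth_pair) -> float:
    """1 − |ρ_real − ρ_synth| / 2 with Pearson correlations."""
    def rho(pair) -> float:
        a = np.asarray(pair[0], dtype=float)
        b = np.asarray(pair[1], dtype=float)
        if np.std(a) == 0 or np.std(b) == 0:
            raise DistributionError("correlation undefined for a zero-variance column")
        return float(np.corrcoef(a, b)[0, 1])

    return float(1.0 - abs(rho(real_pair) - rho(synth_pair)) / 2.0)


def contingency_similarity(real_pair, synth_pair) -> float:
    """1 − ½ Σ |p_real(a,b) − p_synth(a,b)| over joint contingency cells."""
    def joint(pair) -> pd.Series:
        a, b = pair
        frame = pd.DataFrame({"a": list(a), "b": list(b)})
        if frame.empty:
            raise DistributionError("contingency_similarity needs non-empty columns")
        return frame.value_counts(normalize=True)

    pr, ps = joint(real_pair), joint(synth_pair)
    cells = pr.index.union(ps.index)
    diff = pr.reindex(cells, fill_value=0.0) - ps.reindex(cells, fill_value=0.0)
    return float(1.0 - 0.5 * np.abs(diff.to_numpy()).sum())


def _bin_column(real_num, synth_num, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    r = np.asarray(real_num, dtype=float)
    s = np.asarray(synth_num, dtype=float)
    lo = min(r.min(), s.min())
    hi = max(r.max(), s.max())
    if hi == lo:
        return np.zeros(r.size, dtype=int), np.zeros(s.size, dtype=int)
    edges = np.linspace(lo, hi, n_bins + 1)
    return (
        np.clip(np.digitize(r, edges[1:-1]), 0, n_bins - 1),
        np.clip(np.digitize(s, edges[1:-1]), 0, n_bins - 1),
    )


def mixed_pair_similarity(real_pair, synth_pair, n_bins: int = DEFAULT_BINS) -> float:
    """Contingency similarity after discretizing the numeric member.

    ``real_pair`` and ``synth_pair`` are (numeric_column, categorical_column)
    tuples; the numeric columns are binned onto shared equal-width bins.
    """
    r_num, r_cat = real_pair
    s_num, s_cat = synth_pair
    r_bins, s_bins = _bin_column(r_num, s_num, n_bins)
    return contingency_similarity((r_bins, list(r_cat)), (s_bins, list(s_cat)))


def _tier(shape_score: float) -> str:
    if shape_score > TIER_HIGH:
        return "high"
    if shape_score >= TIER_MODERATE:
        return "moderate"
    return "lower"


@dataclasses.dataclass
class FidelityReport:
    """Aggregated real-vs-synthetic similarity scores."""

    column_shapes: dict[str, dict]          # name -> {score, metric, hellinger, tier}
    column_pair_trends: dict[str, dict]     # "a|b" -> {score, metric}
    column_shapes_score: float
    column_pair_trends_score: float
    overall_score: float
    aggregate_hellinger: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    def to_markdown(self) -> str:
        lines = [
            "| column | metric | shape score | Hellinger | tier |",
            "| --- | --- | --- | --- | --- |",
        ]
        for name, row in self.column_shapes.items():
            lines.append(
                f"| {name} | {row['metric']} | {row['score']:.4f} "
                f"| {row['hellinger']:.4f} | {row['tier']} |"
            )
        lines += [
            "",
            f"Column shapes score: {self.column_shapes_score:.4f}",
            f"Column pair trends score: {self.column_pair_trends_score:.4f}",
            f"Overall score: {self.overall_score:.4f}",
            f"Aggregate Hellinger distance: {self.aggregate_hellinger:.4f}",
        ]
        return "\n".join(lines)


def quality_report(
    real: pd.DataFrame,
    synth: pd.DataFrame,
    metadata: Sequence[ColumnMetadata] | None = None,
    n_bins: int = DEFAULT_BINS,
) -> FidelityReport:
    """Single-table quality report over marginals and pairwise trends.

    Column shapes use KS-complement for numeric and TV-complement for
    categorical columns; pair trends use correlation similarity
    (numeric-numeric), contingency similarity (categorical-categorical) or
    discretized contingency similarity (mixed).  The two aggregate scores
    are unweighted means over columns / unordered pairs, and the overall
    score is their mean.  Per-column Hellinger distances (shared
    ``n_bins``-bin equal-width histograms for numeric columns, category
    frequencies for categorical ones) and shape-score tiers are included.
    """
    if list(real.columns) != list(synth.columns):
        only_real = [c for c in real.columns if c not in synth.columns]
        only_synth = [c for c in synth.columns if c not in real.columns]
        raise ValueError(
            f"schema mismatch: only in real {only_real}, only in synthetic {only_synth}"
        )
    if metadata is None:
        metadata = infer_metadata(real)
    kinds = {m.name: m.kind for m in metadata}

    shapes: dict[str, dict] = {}
    hellingers: list[float] = []
    for name in real.columns:
        if kinds[name] == "continuous":
            score = ks_complement(real[name], synth[name])
            metric = "ks_complement"
            p, q = discretize_pair(real[name], synth[name], n_bins)
        else:
            score = tv_complement(real[name], synth[name])
            metric = "tv_complement"
            cats = tuple(sorted(set(real[name]) | set(synth[name]), key=repr))
            pr = pd.Series(list(real[name])).value_counts(normalize=True)
            ps = pd.Series(list(synth[name])).value_counts(normalize=True)
            p = DiscreteDistribution(cats, tuple(pr.reindex(cats, fill_value=0.0)))
            q = DiscreteDistribution(cats, tuple(ps.reindex(cats, fill_value=0.0)))
        h = hellinger(p, q)
        hellingers.append(h)
        shapes[name] = {
            "score": score,
            "metric": metric,
            "hellinger": h,
            "tier": _tier(score),
        }

    trends: dict[str, dict] = {}
    for a, b in itertools.combinations(real.columns, 2):
        ka, kb = kinds[a], kinds[b]
        try:
            if ka == "continuous" and kb == "continuous":
                score = correlation_similarity(
                    (real[a], real[b]), (synth[a], synth[b])
                )
                metric = "correlation_similarity"
            elif ka == "categorical" and kb == "categorical":
                score = contingency_similarity(
                    (real[a], real[b]), (synth[a], synth[b])
                )
                metric = "contingency_similarity"
            else:
                num, cat = (a, b) if ka == "continuous" else (b, a)
                score = mixed_pair_similarity(
                    (real[num], real[cat]), (synth[num], synth[cat]), n_bins
                )
                metric = "mixed_pair_similarity"
        except DistributionError:
            continue  # zero-variance pairs carry no trend information
        trends[f"{a}|{b}"] = {"score": score, "metric": metric}

    shape_score = float(np.mean([s["score"] for s in shapes.values()]))
    trend_score = float(np.mean([t["score"] for t in trends.values()])) if trends else 1.0
    return FidelityReport(
        column_shapes=shapes,
        column_pair_trends=trends,
        column_shapes_score=shape_score,
        column_pair_trends_score=trend_score,
        overall_score=float((shape_score + trend_score) / 2.0),
        aggregate_hellinger=float(np.mean(hellingers)),
    )


def plot_marginals(
    real: pd.DataFrame,
    synth: pd.DataFrame,
    report: FidelityReport,
    out_dir,
    max_cols_per_fig: int = 12,
) -> list[Path]:
    """Overlaid real/synthetic marginal plots per column, saved as PNGs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = list(real.columns)
    paths = []
    for fig_idx in range(0, len(names), max_cols_per_fig):
        chunk = names[fig_idx : fig_idx + max_cols_per_fig]
        ncols = 3
        nrows = -(-len(chunk) // ncols)
        fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows))
        axes = np.atleast_1d(axes).ravel()
        for ax, name in zip(axes, chunk):
            info = report.column_shapes[name]
            if info["metric"] == "ks_complement":
                bins = np.histogram_bin_edges(
                    np.concatenate([real[name], synth[name]]).astype(float), bins=20
                )
                ax.hist(real[name], bins=bins, density=True, alpha=0.5,
                        color="gray", label="real")
                ax.hist(synth[name], bins=bins, density=True, alpha=0.5,
                        color="green", label="synthetic")
            else:
                cats = sorted(set(real[name]) | set(synth[name]), key=repr)
                xs = np.arange(len(cats))
                pr = pd.Series(list(real[name])).value_counts(normalize=True).reindex(cats, fill_value=0)
                ps = pd.Series(list(synth[name])).value_counts(normalize=True).reindex(cats, fill_value=0)
                ax.bar(xs - 0.2, pr, width=0.4, color="gray", label="real")
                ax.bar(xs + 0.2, ps, width=0.4, color="green", label="synthetic")
                ax.set_xticks(xs, [str(c) for c in cats])
            ax.set_title(f"{name} ({info['score']:.2f}, {info['tier']})", fontsize=9)
            ax.legend(fontsize=7)
        for ax in axes[len(chunk):]:
            ax.axis("off")
        fig.tight_layout()
        path = out / f"marginals_{fig_idx // max_cols_per_fig}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths.append(path)
    return paths
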