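"""Column transforms for tabular VAE training.

Continuous columns use *mode-specific normalization*: a Gaussian mixture
(up to ``max_modes`` components, the count selected by BIC) is fitted per
column; each value is then encoded as a bounded scalar offset within its
(sampled) mode — ``(x − μ_k) / (4 σ_k)``, clipped to (−1, 1) — plus a
one-hot mode indicator.  This is the standard preprocessing for VAE/GAN
synthesis of tabular data: it lets the network model multi-modal marginals
as a categorical choice plus a near-Gaussian residual.

Categorical columns are one-hot encoded.  Both transforms are invertible
on their training domain.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

__all__ = ["ColumnMetadata", "DataTransformer", "infer_metadata", "TransformError"]

_MODE_WEIGHT_THRESHOLD = 0.005
_MAX_PRECISION = 8


class TransformError(ValueError):
    """A column cannot be fitted or transformed."""


@dataclasses.dataclass
class ColumnMetadata:
    """What the synthesizer needs to know about one column."""

    name: str
    kind: str  # "continuous" | "categorical"
    observed_min: float | None = None
    observed_max: float | None = None
    precision: int | None = None  # decimal places to round to
    integer: bool = False
    categories: tuple | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise TransformError(f"unknown column kind {self.kind!r}")
        if (
            self.observed_min is not None
            and self.observed_max is not None
            and self.observed_min > self.observed_max
        ):
            raise TransformError(f"min > max for column {self.name!r}")
        if self.precision is not None and self.precision < 0:
            raise TransformError(f"negative precision for column {self.name!r}")


def _inferred_precision(values: np.ndarray) -> int:
    """Smallest number of decimals that represents every value exactly."""
    for d in range(_MAX_PRECISION + 1):
        if np.allclose(values, np.round(values, d), rtol=0, atol=1e-12):
            return d
    return _MAX_PRECISION


def infer_metadata(
    table: pd.DataFrame,
    categorical_columns: Sequence[str] | None = None,
    max_categories: int = 10,
) -> list[ColumnMetadata]:
    """Infer per-column metadata from a training table.

    A column is categorical if explicitly listed, non-numeric, or an
    integer column with at most ``max_categories`` distinct values (Likert
    scores and binary group labels fall out of this rule).  Everything else
    is continuous, with observed min/max and rounding precision recorded
    for constrained sampling.
    """
    declared = set(categorical_columns or ())
    unknown = declared - set(table.columns)
    if unknown:
        raise TransformError(f"categorical column(s) not in table: {sorted(unknown)}")
    metadata = []
    for name in table.columns:
        col = table[name]
        values = col.to_numpy()
        is_numeric = pd.api.types.is_numeric_dtype(col)
        integral = is_numeric and bool(
            np.all(np.asarray(values, dtype=float) == np.rint(np.asarray(values, dtype=float)))
        )
        if (
            name in declared
            or not is_numeric
            or (integral and col.nunique() <= max_categories)
        ):
            cats = tuple(pd.unique(col))
            metadata.append(ColumnMetadata(name=name, kind="categorical", categories=cats))
        else:
            fv = np.asarray(values, dtype=float)
            metadata.append(
                ColumnMetadata(
                    name=name,
                    kind="continuous",
                    observed_min=float(np.min(fv)),
                    observed_max=float(np.max(fv)),
                    precision=_inferred_precision(fv),
                    integer=integral,
                )
            )
    return metadata


class _ContinuousTransform:
    """Mode-specific normalizer for a single continuous column."""

    def __init__(self, meta: ColumnMetadata, max_modes: int, seed: int) -> None:
        self.meta = meta
        self.max_modes = max_modes
        self.seed = seed
        self.means: np.ndarray | None = None
        self.stds: np.ndarray | None = None
        self.weights: np.ndarray | None = None

    @property
    def n_modes(self) -> int:
        return len(self.means)

    @property
    def output_dim(self) -> int:
        return 1 + self.n_modes

    def fit(self, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if np.any(~np.isfinite(values)):
            raise TransformError(f"non-finite values in column {self.meta.name!r}")
        if np.ptp(values) == 0.0:
            # Constant column: a single degenerate mode; offsets are 0 and
            # the inverse returns the constant exactly.
            self.means = np.array([values[0]])
            self.stds = np.array([1.0])
            self.weights = np.array([1.0])
            return
        # Number of modes selected by BIC: unimodal columns get exactly one
        # mode, clearly multi-modal columns get one mode per cluster.
        max_k = int(min(self.max_modes, len(np.unique(values))))
        x = values.reshape(-1, 1)
        best = None
        for k in range(1, max_k + 1):
            gm = GaussianMixture(
                n_components=k,
                n_init=1,
                max_iter=200,
                random_state=self.seed % (2**31),
            ).fit(x)
            bic = gm.bic(x)
            if best is None or bic < best[0]:
                best = (bic, gm)
        gm = best[1]
        keep = gm.weights_ > _MODE_WEIGHT_THRESHOLD
        if not np.any(keep):
            keep = gm.weights_ == gm.weights_.max()
        self.means = gm.means_.ravel()[keep]
        self.stds = np.maximum(np.sqrt(gm.covariances_.ravel()[keep]), 1e-12)
        self.weights = gm.weights_[keep] / gm.weights_[keep].sum()

    def _posterior(self, values: np.ndarray) -> np.ndarray:
        z = (values[:, None] - self.means[None, :]) / self.stds[None, :]
        log_p = -0.5 * z**2 - np.log(self.stds)[None, :] + np.log(self.weights)[None, :]
        log_p -= log_p.max(axis=1, keepdims=True)
        p = np.exp(log_p)
        return p / p.sum(axis=1, keepdims=True)

    def transform(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        n = len(values)
        if self.n_modes == 1:
            modes = np.zeros(n, dtype=int)
        else:
            post = self._posterior(values)
            cum = np.cumsum(post, axis=1)
            u = rng.random((n, 1))
            modes = (u > cum).sum(axis=1).clip(0, self.n_modes - 1)
        alpha = (values - self.means[modes]) / (4.0 * self.stds[modes])
        alpha = np.clip(alpha, -0.99, 0.99)
        out = np.zeros((n, self.output_dim))
        out[:, 0] = alpha
        out[np.arange(n), 1 + modes] = 1.0
        return out

    def inverse(self, block: np.ndarray) -> np.ndarray:
        alpha = np.clip(block[:, 0], -1.0, 1.0)
        modes = np.argmax(block[:, 1:], axis=1)
        return alpha * 4.0 * self.stds[modes] + self.means[modes]


class _CategoricalTransform:
    """One-hot encoder for a single categorical column."""

    def __init__(self, meta: ColumnMetadata) -> None:
        self.meta = meta
        self.categories = list(meta.categories or ())

    def fit(self, values: np.ndarray) -> None:
        if not self.categories:
            self.categories = list(pd.unique(pd.Series(values)))
        observed = set(pd.unique(pd.Series(values)))
        missing = observed - set(self.categories)
        if missing:
            raise TransformError(
                f"column {self.meta.name!r} holds categories outside metadata: {sorted(map(str, missing))}"
            )

    @property
    def output_dim(self) -> int:
        return len(self.categories)

    def transform(self, values: np.ndarray) -> np.ndarray:
        index = {c: i for i, c in enumerate(self.categories)}
        idx = np.array([index[v] for v in values])
        out = np.zeros((len(values), self.output_dim))
        out[np.arange(len(values)), idx] = 1.0
        return out

    def inverse(self, block: np.ndarray, rng: np.random.Generator | None) -> np.ndarray:
        if rng is None:
            idx = np.argmax(block, axis=1)
        else:
            p = block / block.sum(axis=1, keepdims=True)
            cum = np.cumsum(p, axis=1)
            u = rng.random((len(block), 1))
            idx = (u > cum).sum(axis=1).clip(0, self.output_dim - 1)
        cats = np.asarray(self.categories)
        return cats[idx]


@dataclasses.dataclass
class ColumnSpan:
    """Location of one column's encoding inside the transformed matrix."""

    name: str
    kind: str
    start: int
    width: int  # total width (continuous: 1 alpha + n_modes indicator)


class DataTransformer:
    """Fitted, invertible transform from a mixed table to a float matrix."""

    def __init__(self, max_modes: int = 10, seed: int = 0) -> None:
        self.max_modes = max_modes
        self.seed = seed
        self.metadata: list[ColumnMetadata] = []
        self.transforms: dict[str, object] = {}
        self.spans: list[ColumnSpan] = []
        self.output_dim = 0

    def fit(self, table: pd.DataFrame, metadata: list[ColumnMetadata] | None = None) -> "DataTransformer":
        if len(table) < 1:
            raise TransformError("cannot fit transforms on an empty table")
        if table.isna().any().any():
            bad = [c for c in table.columns if table[c].isna().any()]
            raise TransformError(f"missing values in column(s): {bad}")
        self.metadata = metadata or infer_metadata(table)
        by_name = {m.name: m for m in self.metadata}
        if set(by_name) != set(table.columns):
            raise TransformError("metadata columns do not match table columns")
        start = 0
        for name in table.columns:
            meta = by_name[name]
            if meta.kind == "continuous":
                tr = _ContinuousTransform(meta, self.max_modes, self.seed + start)
                tr.fit(table[name].to_numpy())
            else:
                tr = _CategoricalTransform(meta)
                tr.fit(table[name].to_numpy())
            self.transforms[name] = tr
            self.spans.append(ColumnSpan(name, meta.kind, start, tr.output_dim))
            start += tr.output_dim
        self.output_dim = start
        return self

    def transform(self, table: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
        blocks = []
        for span in self.spans:
            tr = self.transforms[span.name]
            values = table[span.name].to_numpy()
            if span.kind == "continuous":
                blocks.append(tr.transform(values, rng))
            else:
                blocks.append(tr.transform(values))
        return np.concatenate(blocks, axis=1)

    def inverse_transform(
        self,
        matrix: np.ndarray,
        rng: np.random.Generator | None = None,
        sample_categoricals: bool = True,
    ) -> pd.DataFrame:
        """Map a transformed matrix back to a table.

        Continuous columns decode via the mode indicated by the argmax of
        their indicator block; categorical columns are sampled from the
        (softmax-normalized) block probabilities when ``sample_categoricals``
        is set, otherwise taken as the argmax.
        """
        data = {}
        for span in self.spans:
            tr = self.transforms[span.name]
            block = matrix[:, span.start : span.start + span.width]
            if span.kind == "continuous":
                data[span.name] = tr.inverse(block)
            else:
                use_rng = rng if sample_categoricals else None
                data[span.name] = tr.inverse(block, use_rng)
        return pd.DataFrame(data)

    def activation_spans(self) -> list[tuple[str, int, int]]:
        """(type, start, width) segments of the network output layer.

        ``"alpha"`` segments (width 1) take a tanh activation and a Gaussian
        reconstruction loss; ``"softmax"`` segments take cross-entropy.
        """
        segments: list[tuple[str, int, int]] = []
        for span in self.spans:
            if span.kind == "continuous":
                segments.append(("alpha", span.start, 1))
                if span.width > 1:
                    segments.append(("softmax", span.start + 1, span.width - 1))
            else:
                segments.append(("softmax", span.start, span.width))
        return segments
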