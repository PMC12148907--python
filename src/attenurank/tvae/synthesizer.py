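"""Training and constrained sampling for the tabular VAE.

The default configuration matches the setup used throughout this package's
reference experiments: 128-dimensional latent space, (128, 128) hidden
layers on both sides, L2 weight decay 1e-3, batch size 500, 500 epochs,
reconstruction weighting factor 2, and Adam at learning rate 1e-3.  With a
41-row training table and batch size 500, every epoch is a single
full-batch step — the configuration stays well-defined at any scale.

Sampling draws latent vectors from the standard-normal prior, decodes, and
inverts the column transforms.  Two constraint switches keep samples inside
the training envelope: ``enforce_min_max_values`` clips each continuous
column to its observed training range, and ``enforce_rounding`` rounds to
the precision inferred from the training column.  Categorical outputs are
sampled from the decoder's softmax probabilities and can therefore never
leave the training category set.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .._seeds import child_seed
from .network import TvaeNetwork
from .transforms import ColumnMetadata, DataTransformer, infer_metadata

__all__ = ["TVAEConfig", "TVAESynthesizer", "TrainingDivergedError"]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, epoch: int) -> None:
        super().__init__(f"training loss became non-finite at epoch {epoch}")
        self.epoch = epoch


@dataclasses.dataclass
class TVAEConfig:
    """Synthesizer architecture and training configuration."""

    embedding_dim: int = 128
    compress_dims: tuple[int, ...] = (128, 128)
    decompress_dims: tuple[int, ...] = (128, 128)
    l2scale: float = 1e-3
    batch_size: int = 500
    epochs: int = 500
    loss_factor: float = 2.0
    learning_rate: float = 1e-3
    enforce_min_max_values: bool = True
    enforce_rounding: bool = True
    max_modes: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        dims = (self.embedding_dim, *self.compress_dims, *self.decompress_dims)
        if any(d < 1 for d in dims):
            raise ValueError("all layer dimensions must be positive")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.l2scale < 0 or self.learning_rate <= 0:
            raise ValueError("l2scale must be >= 0 and learning_rate > 0")
        self.compress_dims = tuple(self.compress_dims)
        self.decompress_dims = tuple(self.decompress_dims)


class TVAESynthesizer:
    """Fit a tabular VAE on a training table and sample synthetic rows."""

    def __init__(self, config: TVAEConfig | None = None) -> None:
        self.config = config or TVAEConfig()
        self.transformer: DataTransformer | None = None
        self.network: TvaeNetwork | None = None
        self.loss_trace: list[float] = []
        self._columns: list[str] = []
        self._dtypes: dict[str, np.dtype] | None = None

    # ------------------------------------------------------------------ fit
    def fit(
        self,
        table: pd.DataFrame,
        metadata: list[ColumnMetadata] | None = None,
        categorical_columns: Sequence[str] | None = None,
    ) -> "TVAESynthesizer":
        if len(table) < 2:
            raise ValueError("need at least 2 training rows")
        cfg = self.config
        if metadata is None:
            metadata = infer_metadata(table, categorical_columns)
        self._columns = list(table.columns)
        self._dtypes = {c: table[c].dtype for c in table.columns}

        self.transformer = DataTransformer(
            max_modes=cfg.max_modes, seed=child_seed(cfg.seed, "transform")
        ).fit(table, metadata)
        rng = np.random.default_rng(child_seed(cfg.seed, "train"))
        x = self.transformer.transform(table, rng)

        self.network = TvaeNetwork(
            data_dim=self.transformer.output_dim,
            compress_dims=cfg.compress_dims,
            decompress_dims=cfg.decompress_dims,
            embedding_dim=cfg.embedding_dim,
            segments=self.transformer.activation_spans(),
            rng=rng,
        )

        n = x.shape[0]
        self.loss_trace = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, cfg.batch_size):
                batch = x[order[start : start + cfg.batch_size]]
                eps = rng.standard_normal((batch.shape[0], cfg.embedding_dim))
                loss, _, _, grads = self.network.loss_and_grads(
                    batch, eps, cfg.loss_factor
                )
                if not np.isfinite(loss):
                    raise TrainingDivergedError(epoch)
                self.network.adam_step(
                    grads, lr=cfg.learning_rate, weight_decay=cfg.l2scale
                )
                epoch_losses.append(loss)
            self.loss_trace.append(float(np.mean(epoch_losses)))
        return self

    # --------------------------------------------------------------- sample
    def sample(self, n: int, seed: int | None = None) -> pd.DataFrame:
        """Draw ``n`` synthetic rows from the fitted model."""
        if self.network is None or self.transformer is None:
            raise RuntimeError("synthesizer is not fitted")
        if n < 0:
            raise ValueError(f"n must be >= 0, got {n}")
        cfg = self.config
        rng = np.random.default_rng(
            child_seed(cfg.seed if seed is None else seed, "sample")
        )
        if n == 0:
            empty = pd.DataFrame({c: pd.Series(dtype=self._dtypes[c]) for c in self._columns})
            return empty

        z = rng.standard_normal((n, cfg.embedding_dim))
        rec = self.network.decode(z)
        out = rec.copy()
        sigma = self.network.params["sigma"]
        for kind, st, width in self.transformer.activation_spans():
            if kind == "alpha":
                # The continuous output model is Gaussian with a learned
                # per-dimension scale; sampling draws from it, not its mean.
                out[:, st] = np.tanh(rec[:, st]) + sigma[st] * rng.standard_normal(n)
            else:
                logits = rec[:, st : st + width]
                e = np.exp(logits - logits.max(axis=1, keepdims=True))
                out[:, st : st + width] = e / e.sum(axis=1, keepdims=True)

        table = self.transformer.inverse_transform(out, rng, sample_categoricals=True)

        for meta in self.transformer.metadata:
            if meta.kind != "continuous":
                continue
            col = table[meta.name].astype(float)
            if cfg.enforce_rounding and meta.precision is not None:
                col = col.round(meta.precision)
            # clip last: rounding must never push a value outside the envelope
            if cfg.enforce_min_max_values:
                col = col.clip(meta.observed_min, meta.observed_max)
            if meta.integer:
                col = col.round().astype(np.int64)
            table[meta.name] = col
        for name, dtype in self._dtypes.items():
            if name in table.columns and table[name].dtype != dtype:
                try:
                    table[name] = table[name].astype(dtype)
                except (TypeError, ValueError):
                    pass
        return table[self._columns]

    # ----------------------------------------------------------- save/load
    def save(self, directory) -> None:
        """Persist the fitted model: metadata JSON + parameter arrays."""
        if self.network is None or self.transformer is None:
            raise RuntimeError("synthesizer is not fitted")
        out = Path(directory)
        out.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": dataclasses.asdict(self.config),
            "columns": self._columns,
            "dtypes": {c: str(d) for c, d in self._dtypes.items()},
            "loss_trace": self.loss_trace,
            "metadata": [dataclasses.asdict(m) for m in self.transformer.metadata],
            "continuous_params": {
                s.name: {
                    "means": self.transformer.transforms[s.name].means.tolist(),
                    "stds": self.transformer.transforms[s.name].stds.tolist(),
                    "weights": self.transformer.transforms[s.name].weights.tolist(),
                }
                for s in self.transformer.spans
                if s.kind == "continuous"
            },
        }
        with open(out / "model.json", "w") as fh:
            json.dump(meta, fh, indent=2,
                      default=lambda o: o.item() if hasattr(o, "item") else str(o))
        np.savez(out / "params.npz", **self.network.params)

    @classmethod
    def load(cls, directory) -> "TVAESynthesizer":
        src = Path(directory)
        with open(src / "model.json") as fh:
            meta = json.load(fh)
        raw_cfg = dict(meta["config"])
        raw_cfg["compress_dims"] = tuple(raw_cfg["compress_dims"])
        raw_cfg["decompress_dims"] = tuple(raw_cfg["decompress_dims"])
        self = cls(TVAEConfig(**raw_cfg))
        self._columns = meta["columns"]
        self._dtypes = {c: np.dtype(d) for c, d in meta["dtypes"].items()}
        self.loss_trace = meta["loss_trace"]

        metadata = []
        for m in meta["metadata"]:
            m = dict(m)
            if m.get("categories") is not None:
                m["categories"] = tuple(m["categories"])
            metadata.append(ColumnMetadata(**m))
        tr = DataTransformer(max_modes=self.config.max_modes)
        tr.metadata = metadata
        from .transforms import ColumnSpan, _CategoricalTransform, _ContinuousTransform

        start = 0
        for m in metadata:
            if m.kind == "continuous":
                ct = _ContinuousTransform(m, self.config.max_modes, 0)
                params = meta["continuous_params"][m.name]
                ct.means = np.asarray(params["means"])
                ct.stds = np.asarray(params["stds"])
                ct.weights = np.asarray(params["weights"])
                width = ct.output_dim
            else:
                ct = _CategoricalTransform(m)
                ct.fit(np.asarray(list(m.categories)))
                width = ct.output_dim
            tr.transforms[m.name] = ct
            tr.spans.append(ColumnSpan(m.name, m.kind, start, width))
            start += width
        tr.output_dim = start
        self.transformer = tr

        params = np.load(src / "params.npz")
        rng = np.random.default_rng(0)
        self.network = TvaeNetwork(
            data_dim=tr.output_dim,
            compress_dims=self.config.compress_dims,
            decompress_dims=self.config.decompress_dims,
            embedding_dim=self.config.embedding_dim,
            segments=tr.activation_spans(),
            rng=rng,
        )
        for key in self.network.params:
            self.network.params[key] = params[key]
        return self
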