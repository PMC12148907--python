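import numpy as np
import pandas as pd
import pytest

from attenurank.tvae import (
    ColumnMetadata,
    DataTransformer,
    TVAEConfig,
    TVAESynthesizer,
    infer_metadata,
)
from attenurank.tvae.network import TvaeNetwork
from attenurank.fidelity import ks_complement, tv_complement


def tiny_mixed_table(n=200, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "x": rng.normal(10.0, 2.0, n).round(3),
            "y": rng.normal(-5.0, 1.0, n).round(3),
            "label": rng.integers(0, 2, n),
        }
    )


class TestTransforms:
    def test_metadata_inference(self):
        table = tiny_mixed_table()
        meta = {m.name: m for m in infer_metadata(table)}
        assert meta["x"].kind == "continuous"
        assert meta["x"].precision == 3
        assert meta["label"].kind == "categorical"
        assert set(meta["label"].categories) == {0, 1}

    def test_single_mode_offsets_match_direct_formula(self):
        """Oracle: with one fitted mode, the encoded offset is exactly
        (x - mu) / (4 sd) for the fitted mode parameters."""
        rng = np.random.default_rng(1)
        table = pd.DataFrame({"x": rng.standard_normal(5000)})
        tr = DataTransformer(seed=0).fit(table)
        ct = tr.transforms["x"]
        assert ct.n_modes == 1
        values = np.linspace(-2, 2, 20)
        block = ct.transform(values, np.random.default_rng(0))
        expected = np.clip((values - ct.means[0]) / (4.0 * ct.stds[0]), -0.99, 0.99)
        np.testing.assert_allclose(block[:, 0], expected, rtol=1e-12)
        # and the fitted mode tracks the true standard normal
        assert abs(ct.means[0]) < 0.1 and abs(ct.stds[0] - 1.0) < 0.1

    def test_two_mode_column_uses_two_modes(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(-5, 0.3, 500), rng.normal(5, 0.3, 500)])
        tr = DataTransformer(seed=0).fit(pd.DataFrame({"x": x}))
        assert tr.transforms["x"].n_modes == 2

    def test_categorical_roundtrip(self):
        table = pd.DataFrame({"label": [0, 1, 1, 0, 1]})
        tr = DataTransformer(seed=0).fit(table)
        rng = np.random.default_rng(0)
        matrix = tr.transform(table, rng)
        back = tr.inverse_transform(matrix, sample_categoricals=False)
        np.testing.assert_array_equal(back["label"], table["label"])

    def test_constant_column_single_mode_zero_offsets(self):
        table = pd.DataFrame({"x": [5.5] * 10, "y": np.arange(10.0) + 0.25})
        tr = DataTransformer(seed=0).fit(table)
        ct = tr.transforms["x"]
        assert ct.n_modes == 1
        rng = np.random.default_rng(0)
        block = ct.transform(table["x"].to_numpy(), rng)
        np.testing.assert_array_equal(block[:, 0], 0.0)
        np.testing.assert_allclose(ct.inverse(block), 5.5)

    def test_continuous_roundtrip_within_mode_resolution(self):
        table = tiny_mixed_table()
        tr = DataTransformer(seed=0).fit(table)
        rng = np.random.default_rng(3)
        back = tr.inverse_transform(tr.transform(table, rng), sample_categoricals=False)
        # offsets are clipped at +/-0.99 so reconstruction is near-exact
        np.testing.assert_allclose(back["x"], table["x"], atol=0.5)


class TestNetworkGradients:
    def test_analytic_gradients_match_numerical(self):
        """The hand-written backward pass against central differences."""
        rng = np.random.default_rng(0)
        segments = [("alpha", 0, 1), ("softmax", 1, 3), ("alpha", 4, 1), ("softmax", 5, 2)]
        net = TvaeNetwork(
            data_dim=7, compress_dims=(6, 5), decompress_dims=(5, 6),
            embedding_dim=3, segments=segments, rng=rng,
        )
        x = rng.standard_normal((8, 7)) * 0.5
        for start, width in ((1, 3), (5, 2)):
            x[:, start : start + width] = 0.0
            x[np.arange(8), start + rng.integers(0, width, 8)] = 1.0
        eps = rng.standard_normal((8, 3))
        _, _, _, grads = net.loss_and_grads(x, eps, loss_factor=2.0)
        h = 1e-6
        for key, p in net.params.items():
            flat = p.reshape(-1)
            for idx in rng.choice(flat.size, size=min(8, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + h
                lp, *_ = net.loss_and_grads(x, eps, 2.0)
                flat[idx] = orig - h
                lm, *_ = net.loss_and_grads(x, eps, 2.0)
                flat[idx] = orig
                numeric = (lp - lm) / (2 * h)
                assert grads[key].reshape(-1)[idx] == pytest.approx(numeric, abs=1e-5), key


class TestTraining:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            TVAEConfig(epochs=0)
        with pytest.raises(ValueError):
            TVAEConfig(embedding_dim=0)

    def test_defaults_match_reference_configuration(self):
        cfg = TVAEConfig()
        assert cfg.embedding_dim == 128
        assert cfg.compress_dims == (128, 128)
        assert cfg.decompress_dims == (128, 128)
        assert cfg.l2scale == pytest.approx(1e-3)
        assert cfg.batch_size == 500
        assert cfg.epochs == 500
        assert cfg.loss_factor == 2
        assert cfg.learning_rate == pytest.approx(1e-3)
        assert cfg.enforce_min_max_values and cfg.enforce_rounding

    def test_deterministic_loss_trace(self):
        table = tiny_mixed_table(100)
        cfg = TVAEConfig(seed=3, epochs=20)
        a = TVAESynthesizer(cfg).fit(table)
        b = TVAESynthesizer(cfg).fit(table)
        assert a.loss_trace == b.loss_trace
        assert len(a.loss_trace) == 20

    @pytest.mark.parametrize("seed", range(5))
    def test_loss_decreases_over_training(self, seed):
        table = tiny_mixed_table(100, seed=seed)
        syn = TVAESynthesizer(TVAEConfig(seed=seed, epochs=50)).fit(table)
        assert syn.loss_trace[-1] < syn.loss_trace[0]


@pytest.fixture(scope="module")
def fitted():
    table = tiny_mixed_table(150, seed=5)
    return table, TVAESynthesizer(TVAEConfig(seed=5, epochs=60)).fit(table)


class TestSampling:
    def test_zero_samples_keep_schema(self, fitted):
        table, syn = fitted
        out = syn.sample(0)
        assert list(out.columns) == list(table.columns)
        assert len(out) == 0

    def test_samples_respect_training_envelope(self, fitted):
        table, syn = fitted
        out = syn.sample(500)
        for col in ("x", "y"):
            assert out[col].min() >= table[col].min()
            assert out[col].max() <= table[col].max()
        assert set(out["label"].unique()) <= set(table["label"].unique())

    def test_rounding_enforced(self, fitted):
        table, syn = fitted
        out = syn.sample(200)
        np.testing.assert_allclose(out["x"], out["x"].round(3))

    def test_constant_column_sampled_exactly(self):
        table = pd.DataFrame({"c": [5.0] * 50, "x": np.random.default_rng(0).normal(size=50)})
        syn = TVAESynthesizer(TVAEConfig(seed=1, epochs=10)).fit(table)
        assert (syn.sample(100)["c"] == 5.0).all()

    def test_sampling_deterministic_given_seed(self, fitted):
        _, syn = fitted
        pd.testing.assert_frame_equal(syn.sample(50, seed=9), syn.sample(50, seed=9))

    def test_save_load_roundtrip(self, fitted, tmp_path):
        _, syn = fitted
        syn.save(tmp_path / "model")
        loaded = TVAESynthesizer.load(tmp_path / "model")
        pd.testing.assert_frame_equal(syn.sample(40, seed=3), loaded.sample(40, seed=3))


class TestFidelityRecovery:
    def test_two_mode_mixture_marginal_recovered(self):
        """Train on draws from a known two-mode Gaussian mixture; the sampled
        marginal should be close (KS complement > 0.85) to a fresh draw."""
        rng = np.random.default_rng(7)

        def draw(n):
            comp = rng.random(n) < 0.4
            return np.where(comp, rng.normal(-3, 0.5, n), rng.normal(2, 1.0, n))

        train = pd.DataFrame({"x": draw(2000)})
        syn = TVAESynthesizer(TVAEConfig(seed=11, epochs=150)).fit(train)
        sampled = syn.sample(2000)
        assert ks_complement(draw(2000), sampled["x"]) > 0.85

    def test_balanced_binary_column_preserved(self):
        rng = np.random.default_rng(13)
        table = pd.DataFrame(
            {"x": rng.normal(size=400), "group": rng.integers(0, 2, 400)}
        )
        syn = TVAESynthesizer(TVAEConfig(seed=13, epochs=150)).fit(
            table, categorical_columns=["group"]
        )
        sampled = syn.sample(400)
        assert tv_complement(table["group"], sampled["group"]) > 0.85
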