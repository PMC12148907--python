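"""NumPy encoder/decoder network for the tabular VAE.

A small pair of MLPs with analytically derived gradients and an Adam
optimizer.  At the scale this model runs at (tens to thousands of rows,
a few hundred transformed dimensions, two 128-unit hidden layers) dense
NumPy linear algebra is more than fast enough, and keeping the backward
pass explicit makes it directly checkable against numerical gradients.

Loss (minimized): ``loss_factor * reconstruction + KL`` where

* reconstruction sums, per batch row, a Gaussian negative log-likelihood
  on each continuous offset dimension — ``(x − tanh(x̂))² / (2 σ_d²)
  + log σ_d`` with a learned per-dimension output scale ``σ_d`` clamped to
  [0.01, 1] — and a cross-entropy on each softmax segment (mode indicators
  and one-hot categoricals);
* KL is the divergence of the diagonal-Gaussian posterior from the
  standard-normal prior, ``−½ Σ (1 + log σ² − μ² − σ²)``;
* both terms are averaged over the batch; the weighting factor multiplies
  the reconstruction term only.
"""

from __future__ import annotations

import numpy as np

__all__ = ["TvaeNetwork"]


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def _init_linear(rng: np.random.Generator, fan_out: int, fan_in: int):
    # Uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)), the standard MLP default.
    bound = 1.0 / np.sqrt(fan_in)
    w = rng.uniform(-bound, bound, size=(fan_out, fan_in))
    b = rng.uniform(-bound, bound, size=fan_out)
    return w, b


class TvaeNetwork:
    """Encoder/decoder pair with manual backprop and Adam updates."""

    def __init__(
        self,
        data_dim: int,
        compress_dims: tuple[int, ...],
        decompress_dims: tuple[int, ...],
        embedding_dim: int,
        segments: list[tuple[str, int, int]],
        rng: np.random.Generator,
    ) -> None:
        if data_dim < 1:
            raise ValueError("transformed data must have at least one dimension")
        self.data_dim = data_dim
        self.embedding_dim = embedding_dim
        self.segments = segments

        self.params: dict[str, np.ndarray] = {}
        dims = [data_dim, *compress_dims]
        for i in range(len(compress_dims)):
            w, b = _init_linear(rng, dims[i + 1], dims[i])
            self.params[f"enc_w{i}"], self.params[f"enc_b{i}"] = w, b
        w, b = _init_linear(rng, embedding_dim, dims[-1])
        self.params["enc_wmu"], self.params["enc_bmu"] = w, b
        w, b = _init_linear(rng, embedding_dim, dims[-1])
        self.params["enc_wlv"], self.params["enc_blv"] = w, b

        ddims = [embedding_dim, *decompress_dims]
        for i in range(len(decompress_dims)):
            w, b = _init_linear(rng, ddims[i + 1], ddims[i])
            self.params[f"dec_w{i}"], self.params[f"dec_b{i}"] = w, b
        w, b = _init_linear(rng, data_dim, ddims[-1])
        self.params["dec_wout"], self.params["dec_bout"] = w, b
        # Learned output scales for the Gaussian reconstruction terms.
        self.params["sigma"] = np.full(data_dim, 0.1)

        self.n_enc = len(compress_dims)
        self.n_dec = len(decompress_dims)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # ------------------------------------------------------------------ fwd
    def _encode(self, x: np.ndarray):
        hs = [x]
        h = x
        for i in range(self.n_enc):
            h = _relu(h @ self.params[f"enc_w{i}"].T + self.params[f"enc_b{i}"])
            hs.append(h)
        mu = h @ self.params["enc_wmu"].T + self.params["enc_bmu"]
        lv = h @ self.params["enc_wlv"].T + self.params["enc_blv"]
        return hs, mu, lv

    def _decode(self, z: np.ndarray):
        gs = [z]
        g = z
        for i in range(self.n_dec):
            g = _relu(g @ self.params[f"dec_w{i}"].T + self.params[f"dec_b{i}"])
            gs.append(g)
        rec = g @ self.params["dec_wout"].T + self.params["dec_bout"]
        return gs, rec

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Raw decoder output (pre-activation) for sampling."""
        return self._decode(z)[1]

    # ----------------------------------------------------------- loss+grads
    def loss_and_grads(self, x: np.ndarray, eps: np.ndarray, loss_factor: float):
        """Forward pass, loss, and gradients w.r.t. every parameter.

        ``eps`` is the standard-normal reparameterization noise, supplied by
        the caller so that training is a pure function of its seed.
        """
        n = x.shape[0]
        hs, mu, lv_pre = self._encode(x)
        lv = np.clip(lv_pre, -20.0, 20.0)  # guard exp() overflow early in training
        lv_mask = (lv_pre > -20.0) & (lv_pre < 20.0)
        std = np.exp(0.5 * lv)
        z = mu + std * eps
        gs, rec = self._decode(z)
        sigma = self.params["sigma"]

        drec = np.zeros_like(rec)
        recon = 0.0
        dsigma = np.zeros_like(sigma)
        for kind, st, width in self.segments:
            if kind == "alpha":
                s = sigma[st]
                t = np.tanh(rec[:, st])
                eq = x[:, st] - t
                recon += float(np.sum(eq**2) / (2.0 * s**2) + n * np.log(s))
                drec[:, st] = -(eq * (1.0 - t**2)) / s**2
                dsigma[st] = -float(np.sum(eq**2)) / s**3 + n / s
            else:
                logits = rec[:, st : st + width]
                p = _softmax(logits)
                target = x[:, st : st + width]
                recon += float(-np.sum(target * np.log(np.clip(p, 1e-12, None))))
                drec[:, st : st + width] = p - target

        scale = loss_factor / n
        recon_loss = recon * scale
        drec *= scale
        dsigma *= scale

        kl = float(-0.5 * np.sum(1.0 + lv - mu**2 - np.exp(lv)) / n)
        loss = recon_loss + kl

        grads: dict[str, np.ndarray] = {"sigma": dsigma}

        # Decoder backward.
        g_last = gs[-1]
        grads["dec_wout"] = drec.T @ g_last
        grads["dec_bout"] = drec.sum(axis=0)
        dg = drec @ self.params["dec_wout"]
        for i in range(self.n_dec - 1, -1, -1):
            dg = dg * (gs[i + 1] > 0)
            grads[f"dec_w{i}"] = dg.T @ gs[i]
            grads[f"dec_b{i}"] = dg.sum(axis=0)
            dg = dg @ self.params[f"dec_w{i}"]
        dz = dg

        # Through the reparameterization, plus the KL term's own gradients.
        dmu = dz + mu / n
        dlv = (dz * 0.5 * std * eps + (-0.5 * (1.0 - np.exp(lv))) / n) * lv_mask

        # Encoder backward.
        h_last = hs[-1]
        grads["enc_wmu"] = dmu.T @ h_last
        grads["enc_bmu"] = dmu.sum(axis=0)
        grads["enc_wlv"] = dlv.T @ h_last
        grads["enc_blv"] = dlv.sum(axis=0)
        dh = dmu @ self.params["enc_wmu"] + dlv @ self.params["enc_wlv"]
        for i in range(self.n_enc - 1, -1, -1):
            dh = dh * (hs[i + 1] > 0)
            grads[f"enc_w{i}"] = dh.T @ hs[i]
            grads[f"enc_b{i}"] = dh.sum(axis=0)
            dh = dh @ self.params[f"enc_w{i}"]

        return loss, recon_loss, kl, grads

    # ----------------------------------------------------------------- adam
    def adam_step(
        self,
        grads: dict[str, np.ndarray],
        lr: float,
        weight_decay: float = 0.0,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self._adam_t += 1
        b1, b2 = betas
        t = self._adam_t
        for key, p in self.params.items():
            g = grads[key]
            if weight_decay:
                g = g + weight_decay * p
            m = self._adam_m[key] = b1 * self._adam_m[key] + (1 - b1) * g
            v = self._adam_v[key] = b2 * self._adam_v[key] + (1 - b2) * g**2
            m_hat = m / (1 - b1**t)
            v_hat = v / (1 - b2**t)
            p -= lr * m_hat / (np.sqrt(v_hat) + eps)
        np.clip(self.params["sigma"], 0.01, 1.0, out=self.params["sigma"])
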