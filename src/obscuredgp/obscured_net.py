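"""The obscured base model: a small 1-D convolutional regression network.

The network maps (obscured vector, reference phenotype) to a predicted
partner phenotype. Its shape follows the DeepGS extractor motif: the binary
agreement vector is treated as a 1-D signal in marker order and passed
through one convolution stage (a small filter bank), max pooling, dropout
and one fully connected reduction, producing a low-dimensional embedding of
the differences between the two genotypes. The embedding is concatenated
with the scalar reference phenotype and fed to a two-layer fully connected
estimator ending in a single linear output. Training minimizes mean squared
error with mini-batch Adam, end to end, for a fixed number of epochs
(default 20).

The implementation is plain numpy with explicit backpropagation: the model
is a few thousand parameters, and a self-contained forward/backward keeps
training bit-reproducible from (data, config, seed) with no framework in
the loop. Dropout and batch shuffling draw from a generator derived from
the config seed; inference disables dropout and is a pure function of the
learned parameters and the inputs.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError, DivergenceError, ShapeError
from .obscuring import ObscuredVector, PairDataset


@dataclass
class NetConfig:
    """Architecture and training hyperparameters.

    Kernel and pool widths are clipped to the input length at build time so
    very small marker sets (down to 8 features) remain valid configurations.
    """

    n_features: int
    n_conv_filters: int = 8
    conv_width: int = 18
    pool_width: int = 4
    dropout_conv: float = 0.2
    dropout_fc: float = 0.1
    extractor_width: int = 32
    estimator_width: int = 32
    epochs: int = 20
    batch_size: int = 64
    step_size: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ConfigurationError("n_features must be ≥ 1")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be ≥ 1")
        for w in (self.n_conv_filters, self.conv_width, self.pool_width,
                  self.extractor_width, self.estimator_width, self.batch_size):
            if w < 1:
                raise ConfigurationError("all widths must be ≥ 1")
        for p in (self.dropout_conv, self.dropout_fc):
            if not 0.0 <= p < 1.0:
                raise ConfigurationError("dropout rates must be in [0, 1)")

    @property
    def effective_conv_width(self) -> int:
        return min(self.conv_width, self.n_features)

    @property
    def conv_out_len(self) -> int:
        return self.n_features - self.effective_conv_width + 1

    @property
    def effective_pool_width(self) -> int:
        return min(self.pool_width, self.conv_out_len)

    @property
    def pooled_len(self) -> int:
        return self.conv_out_len // self.effective_pool_width


class ObscuredNet:
    """Trainable obscured base model; see the module docstring for topology."""

    _PARAM_NAMES = ("Wc", "bc", "W1", "b1", "W2", "b2", "W3", "b3")

    def __init__(self, config: NetConfig):
        self.config = config
        self.training_log: list[float] = []
        rng = np.random.default_rng(config.seed)
        k = config.effective_conv_width
        F = config.n_conv_filters
        d_flat = config.pooled_len * F
        d1, d2 = config.extractor_width, config.estimator_width

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params = {
            "Wc": he((F, k), k),
            "bc": np.zeros(F),
            "W1": he((d_flat, d1), d_flat),
            "b1": np.zeros(d1),
            "W2": he((d1 + 1, d2), d1 + 1),
            "b2": np.zeros(d2),
            "W3": he((d2, 1), d2),
            "b3": np.zeros(1),
        }

    # ---------------------------------------------------------------- forward

    def _forward(self, X: np.ndarray, y_ref: np.ndarray, train: bool, rng=None):
        cfg = self.config
        if X.shape[1] != cfg.n_features:
            raise ShapeError(f"expected {cfg.n_features} features, got {X.shape[1]}")
        p = self.params
        k, pw, L2 = cfg.effective_conv_width, cfg.effective_pool_width, cfg.pooled_len
        B = X.shape[0]

        cols = sliding_window_view(X, k, axis=1)          # (B, L, k)
        pre = cols @ p["Wc"].T + p["bc"]                  # (B, L, F)
        h = np.maximum(pre, 0.0)

        pooled_in = h[:, : L2 * pw, :].reshape(B, L2, pw, -1)
        arg = np.argmax(pooled_in, axis=2)                # (B, L2, F)
        pooled = np.take_along_axis(pooled_in, arg[:, :, None, :], axis=2)[:, :, 0, :]

        flat = pooled.reshape(B, -1)
        if train and cfg.dropout_conv > 0:
            mask1 = (rng.random(flat.shape) >= cfg.dropout_conv) / (1 - cfg.dropout_conv)
        else:
            mask1 = 1.0
        flat_d = flat * mask1

        z1 = flat_d @ p["W1"] + p["b1"]
        a1 = np.maximum(z1, 0.0)
        if train and cfg.dropout_fc > 0:
            mask2 = (rng.random(a1.shape) >= cfg.dropout_fc) / (1 - cfg.dropout_fc)
        else:
            mask2 = 1.0
        a1_d = a1 * mask2

        cat = np.hstack([a1_d, np.asarray(y_ref, dtype=float)[:, None]])
        z2 = cat @ p["W2"] + p["b2"]
        a2 = np.maximum(z2, 0.0)
        out = (a2 @ p["W3"])[:, 0] + p["b3"][0]

        cache = (X, cols, pre, pooled_in, arg, flat, mask1, flat_d, z1, a1, mask2, cat, z2, a2)
        return out, cache

    def _backward(self, dout: np.ndarray, cache) -> dict[str, np.ndarray]:
        cfg = self.config
        p = self.params
        (X, cols, pre, pooled_in, arg, flat, mask1, flat_d, z1, a1, mask2, cat, z2, a2) = cache
        B = X.shape[0]
        pw, L2 = cfg.effective_pool_width, cfg.pooled_len
        F = cfg.n_conv_filters

        g = {}
        g["W3"] = a2.T @ dout[:, None]
        g["b3"] = np.array([dout.sum()])
        da2 = dout[:, None] @ p["W3"].T
        dz2 = da2 * (z2 > 0)
        g["W2"] = cat.T @ dz2
        g["b2"] = dz2.sum(axis=0)
        dcat = dz2 @ p["W2"].T
        da1 = dcat[:, :-1] * mask2
        dz1 = da1 * (z1 > 0)
        g["W1"] = flat_d.T @ dz1
        g["b1"] = dz1.sum(axis=0)
        dflat = (dz1 @ p["W1"].T) * mask1

        dpooled = dflat.reshape(B, L2, F)
        dpooled_in = np.zeros_like(pooled_in)
        np.put_along_axis(dpooled_in, arg[:, :, None, :], dpooled[:, :, None, :], axis=2)
        dh = np.zeros_like(pre)
        dh[:, : L2 * pw, :] = dpooled_in.reshape(B, L2 * pw, F)
        dpre = dh * (pre > 0)

        g["Wc"] = np.einsum("blf,blk->fk", dpre, cols)
        g["bc"] = dpre.sum(axis=(0, 1))
        return g

    # ---------------------------------------------------------------- training

    def train(self, pairs: PairDataset) -> "ObscuredNet":
        """Mini-batch Adam on MSE over the pair rows for exactly config.epochs."""
        cfg = self.config
        if pairs.n_pairs == 0:
            raise ShapeError("empty pair dataset")
        if pairs.n_features != cfg.n_features:
            raise ShapeError(
                f"pair dataset has {pairs.n_features} features, config expects {cfg.n_features}"
            )
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x0B5C]))
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(val) for k, val in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        for epoch in range(cfg.epochs):
            order = rng.permutation(pairs.n_pairs)
            losses = []
            for start in range(0, pairs.n_pairs, cfg.batch_size):
                rows = order[start : start + cfg.batch_size]
                X, y_ref, y_query = pairs.batch(rows)
                out, cache = self._forward(X, y_ref, train=True, rng=rng)
                resid = out - y_query
                loss = float(np.mean(resid**2))
                if not np.isfinite(loss):
                    raise DivergenceError(f"non-finite loss at epoch {epoch + 1}")
                losses.append(loss)
                grads = self._backward(2.0 * resid / rows.size, cache)
                t += 1
                for name in self._PARAM_NAMES:
                    gname = grads[name]
                    m[name] = beta1 * m[name] + (1 - beta1) * gname
                    v[name] = beta2 * v[name] + (1 - beta2) * gname**2
                    mhat = m[name] / (1 - beta1**t)
                    vhat = v[name] / (1 - beta2**t)
                    self.params[name] -= cfg.step_size * mhat / (np.sqrt(vhat) + eps)
            self.training_log.append(float(np.mean(losses)))
        return self

    # --------------------------------------------------------------- inference

    def predict_batch(self, bits: np.ndarray, y_ref: np.ndarray) -> np.ndarray:
        """Deterministic predictions for a batch of (obscured bits, y_ref) rows."""
        bits = np.atleast_2d(np.asarray(bits, dtype=float))
        out, _ = self._forward(bits, np.atleast_1d(y_ref), train=False)
        return out

    def predict_pair(self, v: ObscuredVector | np.ndarray, y_ref: float) -> float:
        bits = v.bits if isinstance(v, ObscuredVector) else np.asarray(v, dtype=float)
        if bits.shape != (self.config.n_features,):
            raise ShapeError(f"obscured vector length {bits.shape} != {self.config.n_features}")
        return float(self.predict_batch(bits[None, :], np.array([y_ref]))[0])

    # ------------------------------------------------------------- persistence

    def save(self, path) -> None:
        meta = json.dumps({"config": asdict(self.config), "training_log": self.training_log})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path) -> "ObscuredNet":
        with np.load(path if isinstance(path, io.IOBase) else str(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            model = cls(NetConfig(**meta["config"]))
            model.training_log = meta["training_log"]
            for name in cls._PARAM_NAMES:
                model.params[name] = data[name]
        return model


def build_model(config: NetConfig) -> ObscuredNet:
    """Construct an untrained obscured model with seeded initialization."""
    return ObscuredNet(config)


def train(model: ObscuredNet, pairs: PairDataset) -> ObscuredNet:
    """Train ``model`` in place on the pair dataset; returns the model."""
    return model.train(pairs)
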