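"""GRU posterior classifier over raw filtered 10 x 100 signal windows.

A single-layer gated recurrent unit network implemented directly in numpy:
per-channel z-score input normalization -> GRU -> dropout -> ReLU -> fully
connected -> softmax, trained with Adam and a step learning-rate schedule.
The output of every 50 ms inference step is the posterior probability of
the seven classes (rest c0 and grasps c1..c6).

Gate convention (documented because the parameter count depends on it):
dual-bias gates in order (r, z, n),

    r_t = sigmoid(x W_ir + b_ir + h U_hr + b_hr)
    z_t = sigmoid(x W_iz + b_iz + h U_hz + b_hz)
    n_t = tanh(x W_in + b_in + r_t * (h U_hn + b_hn))
    h_t = (1 - z_t) * n_t + z_t * h_{t-1}

so the GRU layer holds 3 * (H * (I + H) + 2H) parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import WindowSpec, segment

__all__ = [
    "GruConfig",
    "GruPosteriorNet",
    "PosteriorSequence",
    "build_model",
    "train_model",
    "predict_posteriors",
    "gru_param_count",
    "select_hidden_units",
]

HIDDEN_CHOICES = (100, 150, 200, 250, 300)


@dataclass(frozen=True)
class GruConfig:
    hidden_units: int = 150
    dropout: float = 0.2
    grad_clip: float = 5.0  # global-norm clip; 0 disables
    n_classes: int = 7
    input_channels: int = 10
    window_samples: int = 100
    batch_size: int = 128
    epochs: int = 30
    learning_rate: float = 1e-3
    lr_drop_factor: float = 0.1
    lr_drop_period: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.n_classes != 7:
            raise ValueError("the decoder is defined over 7 classes (c0..c6)")
        if self.hidden_units not in HIDDEN_CHOICES:
            warnings.warn(
                f"hidden_units={self.hidden_units} is outside the studied set "
                f"{HIDDEN_CHOICES}", stacklevel=2,
            )


@dataclass
class PosteriorSequence:
    """Time-ordered class-probability frames emitted every inference step."""

    frames: np.ndarray        # (n_frames, 7), rows on the simplex
    step_ms: float = 50.0
    timestamps_ms: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if self.timestamps_ms.size == 0:
            self.timestamps_ms = np.arange(self.frames.shape[0]) * self.step_ms

    def __len__(self) -> int:
        return self.frames.shape[0]


def gru_param_count(config: GruConfig, include_head: bool = False) -> int:
    """Closed-form parameter count of the GRU layer (optionally + FC head)."""
    h, i = config.hidden_units, config.input_channels
    count = 3 * (h * (i + h) + 2 * h)
    if include_head:
        count += h * config.n_classes + config.n_classes
    return count


def _softmax(logits: np.ndarray) -> np.ndarray:
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


class GruPosteriorNet:
    """Numpy GRU classifier with manual backprop and Adam."""

    def __init__(self, config: GruConfig, dtype=np.float32):
        self.config = config
        self.dtype = np.dtype(dtype)  # float32 default; float64 for checks
        rng = np.random.default_rng(config.seed)
        i, h, c = config.input_channels, config.hidden_units, config.n_classes

        def glorot(fan_in: int, fan_out: int, shape: tuple) -> np.ndarray:
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, shape).astype(self.dtype)

        def orthogonal(size: int, n_blocks: int) -> np.ndarray:
            # per-gate orthogonal recurrent blocks: stable short-schedule BPTT
            blocks = []
            for _ in range(n_blocks):
                a = rng.standard_normal((size, size))
                q, r = np.linalg.qr(a)
                blocks.append(q * np.sign(np.diag(r)))
            return np.hstack(blocks).astype(self.dtype)

        self.params = {
            "Wx": glorot(i, h, (i, 3 * h)),
            "Uh": orthogonal(h, 3),
            "bx": np.zeros(3 * h, dtype=self.dtype),
            "bh": np.zeros(3 * h, dtype=self.dtype),
            "Wf": glorot(h, c, (h, c)),
            "bf": np.zeros(c, dtype=self.dtype),
        }
        # bias the update gate toward carrying state: the window statistic is
        # an amplitude integrated over 100 steps, so long memory helps early
        self.params["bx"][h : 2 * h] = 1.0
        # per-channel normalization statistics, set from the training set
        self.mu = np.zeros(i)
        self.sd = np.ones(i)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # ------------------------------------------------------------------ core
    @property
    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())

    def set_normalization(self, windows: np.ndarray) -> None:
        """Per-channel z-score statistics over the training windows."""
        self.mu = windows.mean(axis=(0, 2))
        self.sd = windows.std(axis=(0, 2))
        self.sd[self.sd == 0] = 1.0

    def _normalize(self, x: np.ndarray) -> np.ndarray:
        out = (x - self.mu[None, :, None]) / self.sd[None, :, None]
        return out.astype(self.dtype, copy=False)

    def _forward(self, x: np.ndarray, dropout_rng=None):
        """x: (B, C, T) raw windows. Returns (probs, cache)."""
        cfg = self.config
        p = self.params
        h_dim = cfg.hidden_units
        xs = self._normalize(x).transpose(2, 0, 1)  # (T, B, C)
        T, B, _ = xs.shape
        gx = xs @ p["Wx"] + p["bx"]  # (T, B, 3H)
        h = np.zeros((B, h_dim), dtype=self.dtype)
        hs = np.empty((T, B, h_dim), dtype=self.dtype)
        rs = np.empty((T, B, h_dim), dtype=self.dtype)
        zs = np.empty((T, B, h_dim), dtype=self.dtype)
        ns = np.empty((T, B, h_dim), dtype=self.dtype)
        qs = np.empty((T, B, h_dim), dtype=self.dtype)
        for t in range(T):
            gh = h @ p["Uh"] + p["bh"]
            r = _sigmoid(gx[t, :, :h_dim] + gh[:, :h_dim])
            z = _sigmoid(gx[t, :, h_dim : 2 * h_dim] + gh[:, h_dim : 2 * h_dim])
            q = gh[:, 2 * h_dim :]
            n = np.tanh(gx[t, :, 2 * h_dim :] + r * q)
            h = (1.0 - z) * n + z * h
            rs[t], zs[t], ns[t], qs[t], hs[t] = r, z, n, q, h
        if dropout_rng is not None and cfg.dropout > 0:
            keep = dropout_rng.random(h.shape) >= cfg.dropout
            mask = keep.astype(self.dtype) / self.dtype.type(1.0 - cfg.dropout)
        else:
            mask = np.ones_like(h)
        hd = h * mask
        relu = np.maximum(hd, 0.0)
        logits = relu @ p["Wf"] + p["bf"]
        probs = _softmax(logits)
        cache = (xs, rs, zs, ns, qs, hs, mask, hd, relu)
        return probs, cache

    def _backward(self, probs: np.ndarray, labels: np.ndarray, cache) -> dict:
        p = self.params
        h_dim = self.config.hidden_units
        xs, rs, zs, ns, qs, hs, mask, hd, relu = cache
        T, B, _ = xs.shape
        dlogits = probs.copy()
        dlogits[np.arange(B), labels] -= 1.0
        dlogits /= B
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["Wf"] = relu.T @ dlogits
        grads["bf"] = dlogits.sum(axis=0)
        dhd = (dlogits @ p["Wf"].T).astype(self.dtype) * (hd > 0)
        dh = dhd * mask
        dgates = np.empty((T, B, 3 * h_dim), dtype=self.dtype)   # input side
        dgates_h = np.empty((T, B, 3 * h_dim), dtype=self.dtype)  # hidden side
        UhT = p["Uh"].T
        buf = np.empty((B, 3 * h_dim), dtype=self.dtype)
        for t in range(T - 1, -1, -1):
            r, z, n, q = rs[t], zs[t], ns[t], qs[t]
            h_prev = hs[t - 1] if t > 0 else np.zeros_like(hs[0])
            dn_pre = dh * (1.0 - z) * (1.0 - n**2)
            dz_pre = dh * (h_prev - n) * z * (1.0 - z)
            dr_pre = dn_pre * q * r * (1.0 - r)
            dgates[t, :, :h_dim] = dr_pre
            dgates[t, :, h_dim : 2 * h_dim] = dz_pre
            dgates[t, :, 2 * h_dim :] = dn_pre  # candidate grad, input side
            # hidden-side candidate pre-activation carries the reset gate
            buf[:, :h_dim] = dr_pre
            buf[:, h_dim : 2 * h_dim] = dz_pre
            buf[:, 2 * h_dim :] = dn_pre * r
            dgates_h[t] = buf
            dh = dh * z + buf @ UhT
        flat_x = xs.reshape(T * B, -1)
        flat_g = dgates.reshape(T * B, -1)
        grads["Wx"] = flat_x.T @ flat_g
        grads["bx"] = flat_g.sum(axis=0)
        h_prevs = np.concatenate([np.zeros((1, B, h_dim)), hs[:-1]], axis=0)
        flat_h = h_prevs.reshape(T * B, -1)
        flat_gh = dgates_h.reshape(T * B, -1)
        grads["Uh"] = flat_h.T @ flat_gh
        grads["bh"] = flat_gh.sum(axis=0)
        return grads

    def _adam_step(self, grads: dict, lr: float, b1=0.9, b2=0.999, eps=1e-8) -> None:
        clip = self.config.grad_clip
        if clip > 0:
            norm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
            if norm > clip:
                grads = {k: g * (clip / norm) for k, g in grads.items()}
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k]
            v = self._adam_v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g**2
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # ------------------------------------------------------------------- API
    def fit(self, windows: np.ndarray, labels: np.ndarray) -> dict:
        """Train with Adam; returns per-epoch loss/accuracy history."""
        cfg = self.config
        windows = np.asarray(windows, dtype=float)
        labels = np.asarray(labels, dtype=int)
        if windows.ndim != 3 or windows.shape[1:] != (cfg.input_channels, cfg.window_samples):
            raise ValueError(
                f"expected windows of shape (n, {cfg.input_channels}, "
                f"{cfg.window_samples}), got {windows.shape}"
            )
        if np.unique(labels).size < 2:
            raise ValueError("training labels must cover at least two classes")
        self.set_normalization(windows)
        rng = np.random.default_rng(cfg.seed + 1)
        history = {"loss": [], "accuracy": [], "lr": []}
        n = windows.shape[0]
        for epoch in range(cfg.epochs):
            lr = cfg.learning_rate * cfg.lr_drop_factor ** (epoch // cfg.lr_drop_period)
            order = rng.permutation(n)
            losses, correct = [], 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = windows[idx], labels[idx]
                probs, cache = self._forward(xb, dropout_rng=rng)
                eps = 1e-12
                losses.append(-np.log(probs[np.arange(len(yb)), yb] + eps).mean() * len(yb))
                correct += int((probs.argmax(axis=1) == yb).sum())
                grads = self._backward(probs, yb, cache)
                self._adam_step(grads, lr)
            history["loss"].append(float(np.sum(losses) / n))
            history["accuracy"].append(correct / n)
            history["lr"].append(lr)
        return history

    def predict_proba(self, windows: np.ndarray, batch_size: int = 512) -> np.ndarray:
        windows = np.asarray(windows, dtype=float)
        out = np.empty((windows.shape[0], self.config.n_classes))
        for start in range(0, windows.shape[0], batch_size):
            probs, _ = self._forward(windows[start : start + batch_size])
            out[start : start + probs.shape[0]] = probs
        return out

    def predict(self, windows: np.ndarray) -> np.ndarray:
        return self.predict_proba(windows).argmax(axis=1)

    # ------------------------------------------------------------ persistence
    def save(self, path) -> None:
        from dataclasses import asdict

        np.savez(
            path,
            mu=self.mu,
            sd=self.sd,
            **{f"param_{k}": v for k, v in self.params.items()},
            **{f"cfg_{k}": v for k, v in asdict(self.config).items()},
        )

    @classmethod
    def load(cls, path) -> "GruPosteriorNet":
        data = np.load(path)
        cfg_kwargs = {
            k[4:]: data[k].item() for k in data.files if k.startswith("cfg_")
        }
        cfg_kwargs = {
            k: (
                float(v)
                if k in ("dropout", "learning_rate", "lr_drop_factor", "grad_clip")
                else int(v)
            )
            for k, v in cfg_kwargs.items()
        }
        net = cls(GruConfig(**cfg_kwargs))
        for k in net.params:
            net.params[k] = data[f"param_{k}"]
        net.mu, net.sd = data["mu"], data["sd"]
        return net


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def build_model(config: GruConfig) -> GruPosteriorNet:
    """Construct an untrained network; weights are a pure function of the seed."""
    return GruPosteriorNet(config)


def train_model(
    model: GruPosteriorNet, windows: np.ndarray, labels: np.ndarray, config: GruConfig | None = None
) -> tuple[GruPosteriorNet, dict]:
    """Train in place and return (model, history)."""
    if config is not None and config != model.config:
        raise ValueError("config mismatch: build the model from the same config")
    history = model.fit(windows, labels)
    return model, history


def predict_posteriors(
    model: GruPosteriorNet, recording, spec: WindowSpec = WindowSpec(100.0, 50.0)
) -> PosteriorSequence:
    """Posterior frames for a (filtered) recording: 100 ms windows every 50 ms."""
    windows, timestamps, _ = segment(recording, spec)
    return PosteriorSequence(
        frames=model.predict_proba(windows),
        step_ms=spec.step_ms,
        timestamps_ms=timestamps,
    )


def select_hidden_units(evaluate_fn, candidates=HIDDEN_CHOICES):
    """Hyperparameter sweep: return (best_hidden_units, score table).

    ``evaluate_fn(hidden_units) -> float`` should report mean accuracy over
    subjects; ties break toward the smaller model.
    """
    scores = {h: float(evaluate_fn(h)) for h in candidates}
    best = max(sorted(scores), key=lambda h: scores[h])
    return best, scores
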