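"""LSTM autoencoder for paired-time-point feature extraction.

A sequence-to-sequence autoencoder over the two clinical time points:
an LSTM encoder (standard cell: forget, input, and output gates) reads
the (H0, H1) measurement vectors, its final hidden state is projected
linearly to a low-dimensional latent code, and an LSTM decoder driven by
that code reconstructs both time points under mean-squared error.  The
latent code is what gets appended to the dataset as the ``deep`` feature
family.

Implemented directly in numpy (forward + analytic backprop + Adam) so
the package has no deep-learning framework dependency; gradients are
validated against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AutoencoderSpec", "TrainedAutoencoder", "fit_autoencoder", "encode"]


@dataclass
class AutoencoderSpec:
    latent_dim: int = 8
    hidden_units: int = 32
    epochs: int = 200
    learning_rate: float = 0.01
    seed: int = 0

    def validate(self, n_features: int) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.latent_dim > n_features:
            raise ValueError(
                f"latent_dim ({self.latent_dim}) exceeds number of paired "
                f"features ({n_features})"
            )
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


class _LSTM:
    """Batched single-layer LSTM cell.

    Weights ``W`` have shape (4H, din + H) with gate row blocks ordered
    (input, forget, cell-candidate, output); bias ``b`` has shape (4H,)
    with the forget block initialized to +1.
    """

    def __init__(self, din: int, hidden: int, rng: np.random.Generator):
        self.din = din
        self.hidden = hidden
        scale = np.sqrt(6.0 / (din + 2 * hidden))
        self.W = rng.uniform(-scale, scale, size=(4 * hidden, din + hidden))
        self.b = np.zeros(4 * hidden)
        self.b[hidden : 2 * hidden] = 1.0

    def step(self, x, h_prev, c_prev):
        """One timestep; returns (h, c, cache). x: (n, din)."""
        H = self.hidden
        z = np.concatenate([x, h_prev], axis=1)
        a = z @ self.W.T + self.b
        i = _sigmoid(a[:, :H])
        f = _sigmoid(a[:, H : 2 * H])
        g = np.tanh(a[:, 2 * H : 3 * H])
        o = _sigmoid(a[:, 3 * H :])
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h = o * tc
        cache = (z, i, f, g, o, c_prev, tc)
        return h, c, cache

    def backward_step(self, dh, dc_next, cache, dW, db):
        """Backprop one timestep; returns (dx, dh_prev, dc_prev).

        Accumulates weight gradients into dW/db in place.
        """
        H = self.hidden
        z, i, f, g, o, c_prev, tc = cache
        do = dh * tc
        dc = dc_next + dh * o * (1.0 - tc**2)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_prev = dc * f
        da = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g**2),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dW += da.T @ z
        db += da.sum(axis=0)
        dz = da @ self.W
        return dz[:, : self.din], dz[:, self.din :], dc_prev


@dataclass
class TrainedAutoencoder:
    """Fitted parameters, the training-loss trace, and the feature
    ordering the model was trained on."""

    spec: AutoencoderSpec
    params: dict[str, np.ndarray]
    loss_trace: list[float]
    feature_names: list[str] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.params["enc_W"].shape[1] - self.spec.hidden_units


def _build(spec: AutoencoderSpec, d: int, rng: np.random.Generator):
    H, L = spec.hidden_units, spec.latent_dim
    enc = _LSTM(d, H, rng)
    dec = _LSTM(L, H, rng)
    scale_z = np.sqrt(6.0 / (H + L))
    scale_o = np.sqrt(6.0 / (H + d))
    params = {
        "enc_W": enc.W,
        "enc_b": enc.b,
        "Wz": rng.uniform(-scale_z, scale_z, size=(L, H)),
        "bz": np.zeros(L),
        "dec_W": dec.W,
        "dec_b": dec.b,
        "Wo": rng.uniform(-scale_o, scale_o, size=(d, H)),
        "bo": np.zeros(d),
    }
    return enc, dec, params


def _attach(enc: _LSTM, dec: _LSTM, params: dict[str, np.ndarray]) -> None:
    enc.W, enc.b = params["enc_W"], params["enc_b"]
    dec.W, dec.b = params["dec_W"], params["dec_b"]


def _forward(enc, dec, params, X):
    """Full forward pass.  X: (n, T, d).  Returns (loss, recon, caches)."""
    n, T, d = X.shape
    H = enc.hidden
    h = np.zeros((n, H))
    c = np.zeros((n, H))
    enc_caches = []
    for t in range(T):
        h, c, cache = enc.step(X[:, t, :], h, c)
        enc_caches.append(cache)
    z = h @ params["Wz"].T + params["bz"]

    hd = np.zeros((n, H))
    cd = np.zeros((n, H))
    dec_caches = []
    recon = np.empty_like(X)
    for t in range(T):
        hd, cd, cache = dec.step(z, hd, cd)
        dec_caches.append(cache)
        recon[:, t, :] = hd @ params["Wo"].T + params["bo"]
    loss = float(((recon - X) ** 2).mean())
    return loss, recon, (enc_caches, dec_caches, h, z)


def _gradients(enc, dec, params, X):
    """Analytic gradients of the MSE loss w.r.t. every parameter."""
    n, T, d = X.shape
    H = enc.hidden
    loss, recon, (enc_caches, dec_caches, h_enc, z) = _forward(enc, dec, params, X)
    grads = {k: np.zeros_like(v) for k, v in params.items()}

    dout = 2.0 * (recon - X) / recon.size  # (n, T, d)
    dz = np.zeros_like(z)
    dh = np.zeros((n, H))
    dc = np.zeros((n, H))
    for t in reversed(range(T)):
        dh_t = dh + dout[:, t, :] @ params["Wo"]
        grads["Wo"] += dout[:, t, :].T @ (
            dec_caches[t][6] * dec_caches[t][4]  # h_t = o * tanh(c)
        )
        grads["bo"] += dout[:, t, :].sum(axis=0)
        dx, dh, dc = dec.backward_step(dh_t, dc, dec_caches[t], grads["dec_W"], grads["dec_b"])
        dz += dx

    grads["Wz"] += dz.T @ h_enc
    grads["bz"] += dz.sum(axis=0)
    dh = dz @ params["Wz"]
    dc = np.zeros((n, H))
    for t in reversed(range(T)):
        _, dh, dc = enc.backward_step(dh, dc, enc_caches[t], grads["enc_W"], grads["enc_b"])
    return loss, grads


def fit_autoencoder(sequences: np.ndarray, spec: AutoencoderSpec) -> TrainedAutoencoder:
    """Train on ``sequences`` of shape (n, T, d) with full-batch Adam.

    Deterministic under ``spec.seed``; the loss trace has exactly
    ``spec.epochs`` entries (loss evaluated before each update).
    """
    X = np.asarray(sequences, dtype=float)
    if X.ndim != 3:
        raise ValueError(f"sequences must be 3-D (n, T, d), got shape {X.shape}")
    if not np.isfinite(X).all():
        raise ValueError("sequences contain non-finite values")
    n, T, d = X.shape
    spec.validate(d)

    rng = np.random.default_rng(spec.seed)
    enc, dec, params = _build(spec, d, rng)

    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v_) for k, v_ in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    trace: list[float] = []
    for step in range(1, spec.epochs + 1):
        loss, grads = _gradients(enc, dec, params, X)
        trace.append(loss)
        lr = spec.learning_rate
        for k in params:
            m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
            v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
            mhat = m[k] / (1 - beta1**step)
            vhat = v[k] / (1 - beta2**step)
            params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
    return TrainedAutoencoder(spec=spec, params=params, loss_trace=trace)


def encode(model: TrainedAutoencoder, sequences: np.ndarray) -> np.ndarray:
    """Latent codes (n, latent_dim) for new sequences."""
    X = np.asarray(sequences, dtype=float)
    if X.ndim != 3 or X.shape[2] != model.n_features or X.shape[1] != 2:
        raise ValueError(
            f"expected sequences of shape (n, 2, {model.n_features}), got {X.shape}"
        )
    spec = model.spec
    rng = np.random.default_rng(0)
    enc = _LSTM(model.n_features, spec.hidden_units, rng)
    dec = _LSTM(spec.latent_dim, spec.hidden_units, rng)
    _attach(enc, dec, model.params)
    n = X.shape[0]
    h = np.zeros((n, spec.hidden_units))
    c = np.zeros((n, spec.hidden_units))
    for t in range(X.shape[1]):
        h, c, _ = enc.step(X[:, t, :], h, c)
    return h @ model.params["Wz"].T + model.params["bz"]


def reconstruction_mse(model: TrainedAutoencoder, sequences: np.ndarray) -> float:
    X = np.asarray(sequences, dtype=float)
    spec = model.spec
    rng = np.random.default_rng(0)
    enc = _LSTM(X.shape[2], spec.hidden_units, rng)
    dec = _LSTM(spec.latent_dim, spec.hidden_units, rng)
    _attach(enc, dec, model.params)
    loss, _, _ = _forward(enc, dec, model.params, X)
    return loss
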