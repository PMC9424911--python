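"""Decoding steps A-C: screening thresholds, ON detection, 9-class decoding.

Step A rejects windows whose high-band (55-95 Hz) temporal energy on any
frontal/temporal reference channel exceeds a per-channel threshold set to
105% of the largest energy seen across the slight-expression training
windows -- regular-amplitude expressions carry far more EMG energy there
and are excluded immediately.

Step B turns the interface on: common-spatial-pattern (CSP, 2 filter
pairs) log-variance features of the 5-50 Hz window feed a Gaussian-kernel
SVM whose scale is gamma = 1 / (n_feature * var(X)), detecting the
designated state-switching expression (s-RB) against everything else.

Step C decodes 9 targets (8 slight expressions + NON) with a small
temporal Conv1D -> max-pool -> Conv1D -> GRU -> dense network trained with
RMSprop on categorical cross-entropy.  The network is implemented here in
numpy (forward and backward passes), so training is deterministic given a
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .signal_core import (
    ALL_LABELS,
    NON_LABEL,
    REFERENCE_CHANNELS,
    SCREENING_BAND,
    SFE_CLASSES,
    WINDOW_SAMPLES,
)

LABEL_INDEX: dict[str, int] = {name: i for i, name in enumerate(ALL_LABELS)}


def one_hot(labels: list[str] | np.ndarray) -> np.ndarray:
    """One-hot encode labels in the canonical 9-way order."""
    idx = np.array([LABEL_INDEX[l] for l in labels])
    out = np.zeros((idx.size, len(ALL_LABELS)))
    out[np.arange(idx.size), idx] = 1.0
    return out


# ---------------------------------------------------------------------------
# Step A: obvious non-sFE exclusion by temporal-energy thresholds
# ---------------------------------------------------------------------------

@dataclass
class ThresholdBank:
    """Per-reference-channel energy thresholds (uV^2) in the screening band."""

    thresholds: dict[str, float]
    channels: list[str]
    band: tuple[float, float] = SCREENING_BAND

    def __post_init__(self) -> None:
        missing = [c for c in REFERENCE_CHANNELS if c not in self.thresholds]
        if missing:
            raise ValueError(f"thresholds missing reference channels {missing}")

    @property
    def reference_indices(self) -> list[int]:
        return [self.channels.index(c) for c in REFERENCE_CHANNELS]


def fit_step_a(training_windows: np.ndarray, channels: list[str],
               margin: float = 1.05) -> ThresholdBank:
    """Thresholds = margin x the highest per-channel temporal energy over
    all slight-expression training windows (already in the screening band).

    ``training_windows``: n x channels x samples.
    """
    windows = np.asarray(training_windows, dtype=float)
    if windows.ndim != 3 or windows.shape[0] < 1:
        raise ValueError("need a n x channels x samples stack of windows")
    for name in REFERENCE_CHANNELS:
        if name not in channels:
            from .signal_core import MontageMismatchError
            raise MontageMismatchError(f"reference channel {name} absent")
    energies = np.sum(windows * windows, axis=2)        # n x channels
    peak = energies.max(axis=0)
    thresholds = {name: float(margin * peak[channels.index(name)])
                  for name in REFERENCE_CHANNELS}
    return ThresholdBank(thresholds=thresholds, channels=list(channels))


def step_a_screen(window: np.ndarray, bank: ThresholdBank) -> bool:
    """True = accept (probably an sFE window); False = reject as obvious NON.

    ``window`` must already be filtered to the screening band.  A window is
    rejected iff any reference channel's temporal energy exceeds its own
    threshold.
    """
    w = np.asarray(window, dtype=float)
    for name in REFERENCE_CHANNELS:
        i = bank.channels.index(name)
        if float(np.sum(w[i] * w[i])) > bank.thresholds[name]:
            return False
    return True


def step_a_screen_batch(windows: np.ndarray, bank: ThresholdBank) -> np.ndarray:
    """Vectorized :func:`step_a_screen` over an n x channels x samples stack."""
    w = np.asarray(windows, dtype=float)
    idx = bank.reference_indices
    energies = np.sum(w[:, idx] * w[:, idx], axis=2)
    thr = np.array([bank.thresholds[c] for c in REFERENCE_CHANNELS])
    return np.all(energies <= thr[None, :], axis=1)


def threshold_method_score(ar: float, rr: float, ts: float) -> float:
    """Composite comparison score 100 / (1/AR + 1/RR + Ts).

    AR and RR are fractions in (0, 1]; Ts is the per-window timespan in ms.
    The factor 100 puts the score on the percent-like scale of the
    method-comparison table.
    """
    if not (0.0 < ar <= 1.0 and 0.0 < rr <= 1.0):
        raise ValueError("AR and RR must be fractions in (0, 1]")
    if ts < 0:
        raise ValueError("Ts must be >= 0")
    return 100.0 / (1.0 / ar + 1.0 / rr + ts)


# ---------------------------------------------------------------------------
# Step B: CSP features + scaled-Gaussian SVM ON detection
# ---------------------------------------------------------------------------

@dataclass
class CSPModel:
    """2m spatial filters (rows) fitted on two window classes."""

    filters: np.ndarray               # 2m x channels
    class_covs: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def n_filters(self) -> int:
        return self.filters.shape[0]


def _mean_normalized_cov(windows: np.ndarray) -> np.ndarray:
    covs = np.einsum("ncs,nds->ncd", windows, windows)
    traces = np.trace(covs, axis1=1, axis2=2)
    return (covs / traces[:, None, None]).mean(axis=0)


def fit_csp(class_a: np.ndarray, class_b: np.ndarray, pairs: int = 2) -> CSPModel:
    """Common spatial patterns from two stacks of (5-50 Hz) windows.

    Per-window channel covariances are trace-normalized and averaged per
    class; the generalized eigenproblem C_a w = l (C_a + C_b) w yields the
    filters, keeping the ``pairs`` most discriminative from each end.
    """
    from scipy.linalg import eigh

    a = np.asarray(class_a, dtype=float)
    b = np.asarray(class_b, dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 windows per class")
    ca = _mean_normalized_cov(a)
    cb = _mean_normalized_cov(b)
    evals, evecs = eigh(ca, ca + cb)
    order = np.argsort(evals)
    keep = np.concatenate([order[::-1][:pairs], order[:pairs]])
    return CSPModel(filters=evecs[:, keep].T, class_covs=(ca, cb))


def csp_features(model: CSPModel, window: np.ndarray,
                 classical: bool = False) -> np.ndarray:
    """Log-variance CSP feature vector of one window.

    Default normalizes each log variance by the sum of log variances, so
    the 2m features sum to exactly 1; ``classical=True`` uses the
    log(var / sum var) variant instead.
    """
    y = model.filters @ np.asarray(window, dtype=float)
    v = y.var(axis=1)
    if np.any(v <= 0):
        raise ValueError("degenerate window: zero variance under a filter")
    if classical:
        return np.log(v / v.sum())
    logv = np.log(v)
    denom = logv.sum()
    if abs(denom) < 1e-9:
        raise ValueError("degenerate features: sum of log variances ~ 0")
    return logv / denom


def csp_features_batch(model: CSPModel, windows: np.ndarray,
                       classical: bool = False) -> np.ndarray:
    return np.stack([csp_features(model, w, classical) for w in windows])


def kernel_scale(features: np.ndarray) -> float:
    """Scaled-Gaussian kernel hyperparameter gamma = 1 / (n_feature * var(X)),
    with var(X) pooled over every entry of the feature matrix."""
    x = np.asarray(features, dtype=float)
    n_feature = x.shape[1]
    v = float(x.var())
    if v == 0:
        raise ValueError("zero feature variance; gamma undefined")
    return 1.0 / (n_feature * v)


@dataclass
class OnDetector:
    """Binary interface-ON detector: CSP features + scaled-Gaussian SVM."""

    csp: CSPModel
    gamma: float
    svc: object

    def predict_window(self, window: np.ndarray) -> str:
        f = csp_features(self.csp, window)
        return str(self.svc.predict(f[None, :])[0])

    def predict(self, windows: np.ndarray) -> np.ndarray:
        f = csp_features_batch(self.csp, windows)
        return self.svc.predict(f)


def train_on_detector(on_windows: np.ndarray, else_windows: np.ndarray,
                      pairs: int = 2, box_constraint: float = 1.0) -> OnDetector:
    """Fit the CSP + scaled-Gaussian-SVM pipeline on 5-50 Hz windows.

    ``on_windows`` are state-switching (s-RB) windows; ``else_windows`` is
    everything else (rest, relax, other sFEs, regular-amplitude FEs).
    """
    from sklearn.svm import SVC

    csp = fit_csp(on_windows, else_windows, pairs=pairs)
    x = np.vstack([csp_features_batch(csp, on_windows),
                   csp_features_batch(csp, else_windows)])
    y = np.array(["ON"] * len(on_windows) + ["else"] * len(else_windows))
    gamma = kernel_scale(x)
    svc = SVC(C=box_constraint, kernel="rbf", gamma=gamma)
    svc.fit(x, y)
    return OnDetector(csp=csp, gamma=gamma, svc=svc)


# ---------------------------------------------------------------------------
# Step C: the Conv1D-GRU window classifier (sFE-Net)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SFENetSpec:
    """Architecture hyperparameters of the 9-class window network."""

    n_steps: int = WINDOW_SAMPLES     # input time steps
    n_channels: int = 30              # input features per step
    conv1_filters: int = 64
    conv2_filters: int = 128
    kernel: int = 3
    pool: int = 3
    gru_units: int = 128
    dense1: int = 64
    dense2: int = 32
    n_classes: int = len(ALL_LABELS)
    dropout: float = 0.1
    recurrent_dropout: float = 0.1
    learning_rate: float = 0.001
    batch_size: int = 128

    def layer_shapes(self) -> list[tuple[int, ...]]:
        """Output shape after each stage (shape-audit utility)."""
        t1 = self.n_steps - self.kernel + 1                       # conv1, valid
        t2 = (t1 - self.pool) // self.pool + 1                    # max-pool
        t3 = t2 - self.kernel + 1                                 # conv2, valid
        return [
            (self.n_steps, self.n_channels),
            (t1, self.conv1_filters),
            (t2, self.conv1_filters),
            (t3, self.conv2_filters),
            (self.gru_units,),
            (self.dense1,),
            (self.dense2,),
            (self.n_classes,),
        ]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(n, n)))
    return q


class SFENet:
    """Numpy implementation of the Conv1D -> max-pool -> Conv1D -> GRU ->
    dense 9-class window classifier, trained with RMSprop on categorical
    cross-entropy.

    The convolutions run along the temporal dimension with linear
    activation (as specified); the GRU uses tanh/sigmoid activations and
    returns its last state.  Inputs are standardized with statistics frozen
    at training time.
    """

    def __init__(self, spec: SFENetSpec = SFENetSpec(), seed: int = 0):
        self.spec = spec
        self.rng = np.random.default_rng(seed)
        s, r = spec, self.rng
        k, c_in = s.kernel, s.n_channels
        self.params: dict[str, np.ndarray] = {}
        p = self.params
        p["W1"] = _glorot(r, k * c_in, s.conv1_filters, (k * c_in, s.conv1_filters))
        p["b1"] = np.zeros(s.conv1_filters)
        p["W2"] = _glorot(r, k * s.conv1_filters, s.conv2_filters,
                          (k * s.conv1_filters, s.conv2_filters))
        p["b2"] = np.zeros(s.conv2_filters)
        u, ci = s.gru_units, s.conv2_filters
        for gate in ("z", "r", "h"):
            p[f"Wx{gate}"] = _glorot(r, ci, u, (ci, u))
            p[f"Wh{gate}"] = _orthogonal(r, u)
            p[f"b{gate}"] = np.zeros(u)
        p["W3"] = _glorot(r, u, s.dense1, (u, s.dense1))
        p["b3"] = np.zeros(s.dense1)
        p["W4"] = _glorot(r, s.dense1, s.dense2, (s.dense1, s.dense2))
        p["b4"] = np.zeros(s.dense2)
        p["W5"] = _glorot(r, s.dense2, s.n_classes, (s.dense2, s.n_classes))
        p["b5"] = np.zeros(s.n_classes)
        self._rms: dict[str, np.ndarray] = {k_: np.zeros_like(v)
                                            for k_, v in p.items()}
        self.input_mean = 0.0
        self.input_std = 1.0

    # -- forward -----------------------------------------------------------

    @staticmethod
    def _unfold(x: np.ndarray, k: int) -> np.ndarray:
        """(B, T, C) -> (B, T-k+1, k*C) sliding patches along time."""
        b, t, c = x.shape
        view = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
        # view: (B, T-k+1, C, k) -> (B, T-k+1, k, C)
        return view.transpose(0, 1, 3, 2).reshape(b, t - k + 1, k * c)

    def forward(self, x: np.ndarray, train: bool = False,
                dropout_rng: np.random.Generator | None = None) -> dict:
        """Full forward pass; returns the cache used by :meth:`backward`.

        ``x``: (B, n_steps, n_channels), already standardized.
        """
        s, p = self.spec, self.params
        cache: dict = {"x": x, "train": train}
        u1 = self._unfold(x, s.kernel)
        z1 = u1 @ p["W1"] + p["b1"]                       # (B, 98, 64)
        t1 = z1.shape[1]
        t_pool = (t1 - s.pool) // s.pool + 1
        z1c = z1[:, :t_pool * s.pool].reshape(z1.shape[0], t_pool, s.pool, -1)
        arg = z1c.argmax(axis=2)
        pool = z1c.max(axis=2)                             # (B, 32, 64)
        u2 = self._unfold(pool, s.kernel)
        z2 = u2 @ p["W2"] + p["b2"]                       # (B, 30, 128)

        b = x.shape[0]
        if train:
            rng = dropout_rng or self.rng
            mx = (rng.random((b, s.conv2_filters)) >= s.dropout) / (1 - s.dropout)
            mh = (rng.random((b, s.gru_units)) >= s.recurrent_dropout) \
                / (1 - s.recurrent_dropout)
        else:
            mx = np.ones((b, s.conv2_filters))
            mh = np.ones((b, s.gru_units))

        h = np.zeros((b, s.gru_units))
        gru_cache = []
        for t in range(z2.shape[1]):
            xt = z2[:, t] * mx
            hd = h * mh
            zg = _sigmoid(xt @ p["Wxz"] + hd @ p["Whz"] + p["bz"])
            rg = _sigmoid(xt @ p["Wxr"] + hd @ p["Whr"] + p["br"])
            hbar = np.tanh(xt @ p["Wxh"] + (rg * hd) @ p["Whh"] + p["bh"])
            h_new = zg * h + (1 - zg) * hbar
            gru_cache.append((xt, h, hd, zg, rg, hbar))
            h = h_new

        d1 = h @ p["W3"] + p["b3"]
        a1 = np.maximum(d1, 0.0)
        d2 = a1 @ p["W4"] + p["b4"]
        a2 = np.maximum(d2, 0.0)
        logits = a2 @ p["W5"] + p["b5"]
        shifted = logits - logits.max(axis=1, keepdims=True)
        expv = np.exp(shifted)
        probs = expv / expv.sum(axis=1, keepdims=True)

        cache.update(u1=u1, z1=z1, arg=arg, pool=pool, u2=u2, z2=z2,
                     mx=mx, mh=mh, gru=gru_cache, h=h, a1=a1, a2=a2,
                     d1=d1, d2=d2, probs=probs, t_pool=t_pool)
        return cache

    # -- backward ----------------------------------------------------------

    def backward(self, cache: dict, y_onehot: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of mean categorical cross-entropy wrt all parameters."""
        s, p = self.spec, self.params
        b = y_onehot.shape[0]
        g: dict[str, np.ndarray] = {}

        dlogits = (cache["probs"] - y_onehot) / b
        g["W5"] = cache["a2"].T @ dlogits
        g["b5"] = dlogits.sum(axis=0)
        da2 = dlogits @ p["W5"].T
        dd2 = da2 * (cache["d2"] > 0)
        g["W4"] = cache["a1"].T @ dd2
        g["b4"] = dd2.sum(axis=0)
        da1 = dd2 @ p["W4"].T
        dd1 = da1 * (cache["d1"] > 0)
        g["W3"] = cache["h"].T @ dd1
        g["b3"] = dd1.sum(axis=0)
        dh = dd1 @ p["W3"].T

        for name in ("Wxz", "Wxr", "Wxh", "Whz", "Whr", "Whh",
                     "bz", "br", "bh"):
            g[name] = np.zeros_like(p[name])
        dz2 = np.zeros_like(cache["z2"])
        mx, mh = cache["mx"], cache["mh"]
        for t in range(len(cache["gru"]) - 1, -1, -1):
            xt, h_prev, hd, zg, rg, hbar = cache["gru"][t]
            dzg = dh * (h_prev - hbar)
            dhbar = dh * (1 - zg)
            dh_prev = dh * zg
            dah = dhbar * (1 - hbar * hbar)
            g["Wxh"] += xt.T @ dah
            g["Whh"] += (rg * hd).T @ dah
            g["bh"] += dah.sum(axis=0)
            dxt = dah @ p["Wxh"].T
            drh = dah @ p["Whh"].T
            drg = drh * hd
            dhd = drh * rg
            daz = dzg * zg * (1 - zg)
            dar = drg * rg * (1 - rg)
            g["Wxz"] += xt.T @ daz
            g["Whz"] += hd.T @ daz
            g["bz"] += daz.sum(axis=0)
            g["Wxr"] += xt.T @ dar
            g["Whr"] += hd.T @ dar
            g["br"] += dar.sum(axis=0)
            dxt += daz @ p["Wxz"].T + dar @ p["Wxr"].T
            dhd += daz @ p["Whz"].T + dar @ p["Whr"].T
            dh = dh_prev + dhd * mh
            dz2[:, t] = dxt * mx

        du2 = dz2 @ p["W2"].T                              # (B, 30, 3*64)
        g["W2"] = np.einsum("btk,btf->kf", cache["u2"], dz2)
        g["b2"] = dz2.sum(axis=(0, 1))
        dpool = self._fold(du2, s.kernel, cache["pool"].shape[1])
        # un-pool: route gradients to argmax positions
        bsz, t_pool = dpool.shape[0], cache["t_pool"]
        dz1 = np.zeros_like(cache["z1"])
        arg = cache["arg"]                                 # (B, 32, 64)
        bi = np.arange(bsz)[:, None, None]
        ti = np.arange(t_pool)[None, :, None]
        fi = np.arange(s.conv1_filters)[None, None, :]
        flat_t = ti * s.pool + arg
        np.add.at(dz1, (bi, flat_t, fi), dpool)
        g["W1"] = np.einsum("btk,btf->kf", cache["u1"], dz1)
        g["b1"] = dz1.sum(axis=(0, 1))
        return g

    @staticmethod
    def _fold(dpatches: np.ndarray, k: int, t_in: int) -> np.ndarray:
        """Adjoint of :meth:`_unfold`: scatter (B, T-k+1, k*C) back to (B, T, C)."""
        b, t_out, kc = dpatches.shape
        c = kc // k
        out = np.zeros((b, t_in, c))
        dp = dpatches.reshape(b, t_out, k, c)
        for j in range(k):
            out[:, j:j + t_out] += dp[:, :, j]
        return out

    # -- training ----------------------------------------------------------

    def loss(self, probs: np.ndarray, y_onehot: np.ndarray) -> float:
        eps = 1e-12
        return float(-(y_onehot * np.log(probs + eps)).sum(axis=1).mean())

    def _rmsprop_step(self, grads: dict[str, np.ndarray],
                      rho: float = 0.9, eps: float = 1e-7) -> None:
        lr = self.spec.learning_rate
        for k, gk in grads.items():
            c = self._rms[k]
            c *= rho
            c += (1 - rho) * gk * gk
            self.params[k] -= lr * gk / (np.sqrt(c) + eps)

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.input_mean) / self.input_std

    def fit(self, windows: np.ndarray, labels: list[str] | np.ndarray,
            epochs: int = 30, validation_fraction: float = 0.1,
            seed: int | None = None, verbose: bool = False) -> dict:
        """Train on (n, channels, samples) windows in the decoding band.

        Inputs are transposed time-major and standardized; the best
        validation-accuracy parameter set is kept.  Returns a history dict.
        """
        s = self.spec
        labels = list(labels)
        present = set(labels)
        missing = [l for l in ALL_LABELS if l not in present]
        if missing:
            raise ValueError(f"classes absent from training set: {missing}")
        x = np.asarray(windows, dtype=float).transpose(0, 2, 1)  # (n, T, C)
        y = one_hot(labels)
        self.input_mean = float(x.mean())
        self.input_std = float(x.std()) or 1.0
        x = self.standardize(x)

        rng = np.random.default_rng(self.rng.integers(2 ** 31)
                                    if seed is None else seed)
        n = x.shape[0]
        perm = rng.permutation(n)
        n_val = max(1, int(round(validation_fraction * n)))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        xv, yv = x[val_idx], y[val_idx]
        xt, yt = x[tr_idx], y[tr_idx]

        best_acc, best_params = -1.0, None
        history = {"loss": [], "val_accuracy": []}
        for _ in range(epochs):
            order = rng.permutation(xt.shape[0])
            losses = []
            for i0 in range(0, xt.shape[0], s.batch_size):
                idx = order[i0:i0 + s.batch_size]
                cache = self.forward(xt[idx], train=True, dropout_rng=rng)
                losses.append(self.loss(cache["probs"], yt[idx]))
                grads = self.backward(cache, yt[idx])
                self._rmsprop_step(grads)
            val_pred = self._predict_std(xv)
            acc = float((val_pred == yv.argmax(axis=1)).mean())
            history["loss"].append(float(np.mean(losses)))
            history["val_accuracy"].append(acc)
            if acc > best_acc:
                best_acc = acc
                best_params = {k: v.copy() for k, v in self.params.items()}
            if verbose:
                print(f"epoch loss={history['loss'][-1]:.4f} val_acc={acc:.4f}")
        if best_params is not None:
            self.params = best_params
        history["best_val_accuracy"] = best_acc
        return history

    def _predict_std(self, x_std: np.ndarray, batch: int = 512) -> np.ndarray:
        preds = []
        for i0 in range(0, x_std.shape[0], batch):
            cache = self.forward(x_std[i0:i0 + batch], train=False)
            preds.append(cache["probs"].argmax(axis=1))
        return np.concatenate(preds)

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        """9-way distributions for (n, channels, samples) windows."""
        x = self.standardize(np.asarray(windows, dtype=float)
                             .transpose(0, 2, 1))
        out = []
        for i0 in range(0, x.shape[0], 512):
            out.append(self.forward(x[i0:i0 + 512], train=False)["probs"])
        return np.vstack(out)

    def predict(self, windows: np.ndarray) -> np.ndarray:
        idx = self.predict_proba(windows).argmax(axis=1)
        return np.array([ALL_LABELS[i] for i in idx])

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        np.savez(path, input_mean=self.input_mean, input_std=self.input_std,
                 **self.params)

    @classmethod
    def load(cls, path: str | Path, spec: SFENetSpec = SFENetSpec()) -> "SFENet":
        net = cls(spec, seed=0)
        data = np.load(path)
        for k in net.params:
            net.params[k] = data[k]
        net.input_mean = float(data["input_mean"])
        net.input_std = float(data["input_std"])
        return net


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))


def step_c_decode(net: SFENet, window: np.ndarray) -> tuple[str, np.ndarray]:
    """Decode one (channels x samples) 5-50 Hz window: (label, distribution).

    Argmax ties break toward the lowest one-hot index.
    """
    probs = net.predict_proba(window[None, ...])[0]
    return ALL_LABELS[int(probs.argmax())], probs


def train_sfe_net(windows: np.ndarray, labels: list[str],
                  spec: SFENetSpec = SFENetSpec(), seed: int = 0,
                  epochs: int = 30, **kwargs) -> tuple[SFENet, dict]:
    """Train the 9-class window network; returns (net, history)."""
    net = SFENet(spec, seed=seed)
    history = net.fit(windows, labels, epochs=epochs, seed=seed + 1, **kwargs)
    return net, history


# ---------------------------------------------------------------------------
# Dataset balancing (overlap slicing) and evaluation
# ---------------------------------------------------------------------------

def balance_by_overlap(segments_by_class: dict[str, list[np.ndarray]],
                       length: int = WINDOW_SAMPLES,
                       target: int | None = None) -> dict[str, np.ndarray]:
    """Slice per-class segments into windows, shrinking the stride (50%
    overlap, then 75%, ...) for minority classes until counts match.

    ``segments_by_class``: label -> list of channels x samples arrays.
    Returns label -> n x channels x length stacks, all of equal count.
    """
    def slice_all(segs: list[np.ndarray], stride: int) -> list[np.ndarray]:
        out = []
        for seg in segs:
            for s0 in range(0, seg.shape[1] - length + 1, stride):
                out.append(seg[:, s0:s0 + length])
        return out

    counts = {lab: slice_all(segs, length)
              for lab, segs in segments_by_class.items()}
    if target is None:
        target = max(len(v) for v in counts.values())
    balanced: dict[str, np.ndarray] = {}
    for lab, segs in segments_by_class.items():
        stride = length
        windows = counts[lab]
        while len(windows) < target and stride > 1:
            stride = max(1, stride // 2)
            windows = slice_all(segs, stride)
        balanced[lab] = np.stack(windows[:target])
    return balanced


@dataclass
class EvaluationReport:
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    confusion: np.ndarray
    labels: list[str]

    def per_class_accuracy(self) -> np.ndarray:
        totals = self.confusion.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, np.diag(self.confusion) / totals, 0.0)


def confusion_metrics(confusion: np.ndarray,
                      labels: list[str]) -> EvaluationReport:
    """Accuracy / precision / recall / F1 derived from a confusion matrix."""
    confusion = np.asarray(confusion, dtype=float)
    total = confusion.sum()
    acc = float(np.trace(confusion) / total) if total else 0.0
    col = confusion.sum(axis=0)
    row = confusion.sum(axis=1)
    diag = np.diag(confusion)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(col > 0, diag / col, 0.0)
        rec = np.where(row > 0, diag / row, 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    return EvaluationReport(accuracy=acc, precision=prec, recall=rec, f1=f1,
                            confusion=confusion, labels=list(labels))


def evaluate(model_factory, windows: np.ndarray, labels: list[str],
             k_folds: int = 10, seed: int = 0,
             label_order: list[str] | None = None) -> EvaluationReport:
    """Stratified k-fold evaluation of any fit/predict window classifier.

    ``model_factory()`` must return a fresh estimator with ``fit(windows,
    labels)`` and ``predict(windows)``.  The summed out-of-fold confusion
    matrix drives all metrics; its rows sum to the per-class counts.
    """
    from sklearn.metrics import confusion_matrix
    from sklearn.model_selection import StratifiedKFold

    labels = np.asarray(labels)
    order = label_order or [l for l in ALL_LABELS if l in set(labels)]
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    conf = np.zeros((len(order), len(order)))
    for tr, te in skf.split(windows, labels):
        model = model_factory()
        model.fit(windows[tr], labels[tr])
        pred = model.predict(windows[te])
        conf += confusion_matrix(labels[te], pred, labels=order)
    return confusion_metrics(conf, order)


# ---------------------------------------------------------------------------
# Model bundle persistence
# ---------------------------------------------------------------------------

def save_bundle(directory: str | Path, bank: ThresholdBank,
                detector: OnDetector, net: SFENet,
                extra_metadata: dict | None = None) -> None:
    """Serialize the trained decoder to a directory: YAML metadata
    (montage, bands, thresholds, gamma) + portable weight files."""
    import joblib
    import yaml

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "channels": list(bank.channels),
        "screening_band": list(bank.band),
        "thresholds": {k: float(v) for k, v in bank.thresholds.items()},
        "gamma": float(detector.gamma),
        "spec": {k: getattr(net.spec, k) for k in
                 ("n_steps", "n_channels", "conv1_filters", "conv2_filters",
                  "kernel", "pool", "gru_units", "dense1", "dense2",
                  "n_classes", "dropout", "recurrent_dropout",
                  "learning_rate", "batch_size")},
    }
    if extra_metadata:
        meta.update(extra_metadata)
    (directory / "metadata.yaml").write_text(yaml.safe_dump(meta))
    net.save(directory / "sfenet.npz")
    joblib.dump(detector, directory / "on_detector.joblib")


def load_bundle(directory: str | Path) -> tuple[ThresholdBank, OnDetector, SFENet, dict]:
    import joblib
    import yaml

    directory = Path(directory)
    meta_path = directory / "metadata.yaml"
    if not meta_path.exists():
        raise FileNotFoundError(
            f"no model bundle at {directory}; run the 'train' command first"
        )
    meta = yaml.safe_load(meta_path.read_text())
    bank = ThresholdBank(thresholds=meta["thresholds"],
                         channels=meta["channels"],
                         band=tuple(meta["screening_band"]))
    detector = joblib.load(directory / "on_detector.joblib")
    spec = SFENetSpec(**meta["spec"])
    net = SFENet.load(directory / "sfenet.npz", spec=spec)
    return bank, detector, net, meta


def assign_instructions(report: EvaluationReport,
                        instructions_by_vitality: list[str]) -> dict[str, str]:
    """Map device instructions (most vital first) to the most accurately
    decoded non-state-switching classes.

    s-RB stays reserved for switching and NON for hold-on.
    """
    acc = report.per_class_accuracy()
    candidates = [(lab, a) for lab, a in zip(report.labels, acc)
                  if lab in SFE_CLASSES and lab != "s-RB"]
    candidates.sort(key=lambda t: -t[1])
    return {lab: instr for (lab, _), instr
            in zip(candidates, instructions_by_vitality)}
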