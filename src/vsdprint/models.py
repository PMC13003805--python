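"""Two-stage neural estimation of CBV and VSD from GESFIDE contrast ratios.

Two fully connected networks are chained: the CBV estimator (CBVE) maps the
18-echo post/pre signal ratio to the blood volume fraction, and the VSD
estimator (VSDE) maps the same 18 ratios plus the predicted CBV (19 inputs)
to the 40-bin vessel size distribution.  Hidden layers (CBVE:
2048-1024-512-256-128-64-16-8, VSDE: 2048-1024-512-256-128-64) use ReLU; the
CBVE output is rectified (CBV ≥ 0) and the VSDE output is a sigmoid per bin
(values in (0, 1), matching the max-normalized VSD).  Both stages minimize
mean squared error with Adam (β1 = 0.5, β2 = 0.9, learning rate 1e-4) from
He-initialized weights; stage two trains with the CBVE frozen.

The implementation is plain numpy: forward/backward passes, Adam and early
stopping are written out explicitly, which keeps training bit-reproducible
for a fixed seed on a given platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

CBV_BOUNDS = (0.01, 0.40)


# ---------------------------------------------------------------------------
# minimal fully connected network
# ---------------------------------------------------------------------------


class MLP:
    """Fully connected network with ReLU hidden layers, trained by Adam on MSE.

    ``out_activation`` is ``"relu"`` or ``"sigmoid"``.  Weights are stored in
    float32; He (fan-in) initialization.
    """

    def __init__(self, sizes, out_activation: str = "relu", seed: int = 0):
        if out_activation not in ("relu", "sigmoid"):
            raise ValueError(f"unsupported output activation {out_activation!r}")
        self.sizes = list(int(s) for s in sizes)
        self.out_activation = out_activation
        rng = np.random.default_rng(seed)
        self.W = [
            (rng.standard_normal((a, b)) * np.sqrt(2.0 / a)).astype(np.float32)
            for a, b in zip(self.sizes[:-1], self.sizes[1:])
        ]
        self.b = [np.zeros(b, dtype=np.float32) for b in self.sizes[1:]]
        self._adam_state = None

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, cache: bool = False):
        a = np.asarray(x, dtype=np.float32)
        if a.ndim == 1:
            a = a[None, :]
        acts = [a]
        n_layers = len(self.W)
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            z = a @ w + b
            if i < n_layers - 1:
                a = np.maximum(z, 0.0)
            elif self.out_activation == "relu":
                a = np.maximum(z, 0.0)
            else:
                a = 1.0 / (1.0 + np.exp(-z))
            acts.append(a)
        return (acts[-1], acts) if cache else acts[-1]

    predict = forward

    def _pre_activation(self, x: np.ndarray) -> np.ndarray:
        """Pre-activation of the output layer."""
        a = np.asarray(x, dtype=np.float32)
        for w, b in zip(self.W[:-1], self.b[:-1]):
            a = np.maximum(a @ w + b, 0.0)
        return a @ self.W[-1] + self.b[-1]

    def _backward(self, acts, y):
        """Gradients of mean-over-batch-and-outputs squared error."""
        y = np.asarray(y, dtype=np.float32)
        out = acts[-1]
        n = out.size
        delta = 2.0 * (out - y) / np.float32(n)
        if self.out_activation == "sigmoid":
            delta = delta * out * (1.0 - out)
        else:
            delta = delta * (out > 0)
        gW, gb = [None] * len(self.W), [None] * len(self.b)
        for i in range(len(self.W) - 1, -1, -1):
            gW[i] = acts[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.W[i].T) * (acts[i] > 0)
        return gW, gb

    # -- optimization -------------------------------------------------------

    def _adam_step(self, grads, lr, beta1, beta2, eps=1e-8):
        gW, gb = grads
        if self._adam_state is None:
            self._adam_state = {
                "t": 0,
                "mW": [np.zeros_like(w) for w in self.W],
                "vW": [np.zeros_like(w) for w in self.W],
                "mb": [np.zeros_like(b) for b in self.b],
                "vb": [np.zeros_like(b) for b in self.b],
            }
        st = self._adam_state
        st["t"] += 1
        t = st["t"]
        c1 = 1.0 - beta1**t
        c2 = 1.0 - beta2**t
        for i in range(len(self.W)):
            for params, grads_i, mkey, vkey in (
                (self.W, gW, "mW", "vW"),
                (self.b, gb, "mb", "vb"),
            ):
                m = st[mkey][i]
                v = st[vkey][i]
                m *= beta1
                m += (1 - beta1) * grads_i[i]
                v *= beta2
                v += (1 - beta2) * grads_i[i] ** 2
                params[i] -= (lr * (m / c1) / (np.sqrt(v / c2) + eps)).astype(np.float32)

    def fit(
        self,
        x,
        y,
        x_val=None,
        y_val=None,
        *,
        lr: float = 1e-4,
        beta1: float = 0.5,
        beta2: float = 0.9,
        batch_size: int = 256,
        max_epochs: int = 500,
        patience: int = 20,
        seed: int = 0,
    ) -> dict:
        """Mini-batch Adam with early stopping on validation loss.

        Returns a history dict with per-epoch train/val losses; the weights
        are restored to the best validation epoch.  Raises on divergent
        (NaN) loss.
        """
        x = np.asarray(x, dtype=np.float32)
        y = np.atleast_2d(np.asarray(y, dtype=np.float32))
        if y.shape[0] != x.shape[0]:
            y = y.T
        rng = np.random.default_rng(seed)
        if self.out_activation == "relu":
            # Alive-start recentering: inputs here are strongly correlated
            # across samples, so the rectified output's pre-activation is
            # nearly constant — one unlucky init sign would zero the gradient
            # for every sample.  Shift the output bias so the median
            # pre-activation matches the median target (deterministic).
            probe = x[: min(len(x), 512)]
            z = self._pre_activation(probe)
            self.b[-1] += (np.median(y[: len(probe)], axis=0) - np.median(z, axis=0)).astype(
                np.float32
            )
        history = {"train_loss": [], "val_loss": []}
        best_val = np.inf
        best_weights = None
        stall = 0
        for epoch in range(max_epochs):
            perm = rng.permutation(len(x))
            losses = []
            for start in range(0, len(x), batch_size):
                idx = perm[start : start + batch_size]
                out, acts = self.forward(x[idx], cache=True)
                loss = float(np.mean((out - y[idx]) ** 2))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged (loss={loss}) at epoch {epoch}"
                    )
                losses.append(loss)
                self._adam_step(self._backward(acts, y[idx]), lr, beta1, beta2)
            history["train_loss"].append(float(np.mean(losses)))
            if x_val is not None:
                val = float(np.mean((self.forward(x_val) - np.atleast_2d(y_val).reshape(len(x_val), -1)) ** 2))
                history["val_loss"].append(val)
                if val < best_val - 1e-12:
                    best_val = val
                    best_weights = ([w.copy() for w in self.W], [b.copy() for b in self.b])
                    stall = 0
                else:
                    stall += 1
                    if stall >= patience:
                        break
        if best_weights is not None:
            self.W, self.b = best_weights
        return history

    def state(self) -> dict:
        return {
            "sizes": self.sizes,
            "out_activation": self.out_activation,
            "weights": [w.copy() for w in self.W],
            "biases": [b.copy() for b in self.b],
        }

    def load_state(self, state: dict) -> None:
        self.sizes = list(state["sizes"])
        self.out_activation = state["out_activation"]
        self.W = [np.asarray(w, dtype=np.float32) for w in state["weights"]]
        self.b = [np.asarray(b, dtype=np.float32) for b in state["biases"]]


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


@dataclass
class SignalDataset:
    """Filtered, shuffled and partitioned signal/label collection.

    ``partition`` holds "train" / "val" / "test" per record; ``provenance``
    carries the generator and simulator configuration plus the seed.
    """

    signals: np.ndarray  # (N, 18) post/pre ratio curves
    cbv_labels: np.ndarray  # (N,)
    vsd_labels: np.ndarray  # (N, 40)
    partition: np.ndarray  # (N,) str
    provenance: dict = field(default_factory=dict)

    def split(self, name: str):
        sel = self.partition == name
        return self.signals[sel], self.cbv_labels[sel], self.vsd_labels[sel]

    def counts(self) -> dict:
        return {k: int((self.partition == k).sum()) for k in ("train", "val", "test")}


def filter_and_split(
    signals: np.ndarray,
    cbv_labels: np.ndarray,
    vsd_labels: np.ndarray,
    bounds: tuple = CBV_BOUNDS,
    ratios: tuple = (8, 1, 1),
    seed: int = 0,
    provenance: dict | None = None,
) -> SignalDataset:
    """Remove out-of-bounds-CBV records and split the rest 8:1:1.

    Records with CBV below ``bounds[0]`` or above ``bounds[1]`` are dropped
    (they correspond to background or implausibly dense sampling volumes).
    The remainder is shuffled with ``seed``; split sizes are
    floor(N·8/10) / floor(N/10) / remainder, so 31,320 in-bounds records
    partition into 25,056 / 3,132 / 3,132.
    """
    signals = np.asarray(signals)
    cbv_labels = np.asarray(cbv_labels, dtype=float)
    vsd_labels = np.asarray(vsd_labels)
    keep = (cbv_labels >= bounds[0]) & (cbv_labels <= bounds[1])
    if not keep.any():
        raise ValueError("filter_and_split: no records remain after the CBV filter")
    signals, cbv_labels, vsd_labels = signals[keep], cbv_labels[keep], vsd_labels[keep]

    n = len(cbv_labels)
    total = sum(ratios)
    n_train = n * ratios[0] // total
    n_val = n * ratios[1] // total
    perm = np.random.default_rng(seed).permutation(n)
    partition = np.empty(n, dtype=object)
    partition[perm[:n_train]] = "train"
    partition[perm[n_train : n_train + n_val]] = "val"
    partition[perm[n_train + n_val :]] = "test"
    return SignalDataset(
        signals, cbv_labels, vsd_labels, partition.astype(str),
        provenance=dict(provenance or {}, split_seed=seed, filter_bounds=bounds),
    )


# ---------------------------------------------------------------------------
# model pair: specification, training, prediction, persistence
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """Architecture and optimization hyper-parameters of the CBVE/VSDE pair."""

    cbve_hidden: tuple = (2048, 1024, 512, 256, 128, 64, 16, 8)
    vsde_hidden: tuple = (2048, 1024, 512, 256, 128, 64)
    n_echoes: int = 18
    n_bins: int = 40
    learning_rate: float = 1e-4
    beta1: float = 0.5
    beta2: float = 0.9
    batch_size: int = 256
    max_epochs: int = 500
    patience: int = 20
    teacher_forcing: bool = False  # True: feed the true CBV as the VSDE's 19th input while training

    @property
    def cbve_sizes(self):
        return (self.n_echoes, *self.cbve_hidden, 1)

    @property
    def vsde_sizes(self):
        return (self.n_echoes + 1, *self.vsde_hidden, self.n_bins)


@dataclass
class TrainedModelPair:
    """Frozen CBVE + VSDE with training provenance."""

    cbve: MLP
    vsde: MLP
    spec: ModelSpec
    history: dict
    seed: int


def train_two_stage(ds: SignalDataset, spec: ModelSpec | None = None, seed: int = 0) -> TrainedModelPair:
    """Stage 1 trains the CBVE; stage 2 freezes it and trains the VSDE.

    The VSDE's 19th input is the frozen CBVE's prediction (or the true CBV
    under ``spec.teacher_forcing``); at inference it is always the CBVE
    prediction.
    """
    spec = spec or ModelSpec()
    xs, cbv_tr, vsd_tr = ds.split("train")
    xv, cbv_va, vsd_va = ds.split("val")

    cbve = MLP(spec.cbve_sizes, out_activation="relu", seed=seed)
    hist1 = cbve.fit(
        xs, cbv_tr[:, None], xv, cbv_va[:, None],
        lr=spec.learning_rate, beta1=spec.beta1, beta2=spec.beta2,
        batch_size=spec.batch_size, max_epochs=spec.max_epochs,
        patience=spec.patience, seed=seed + 1,
    )
    frozen = cbve.state()  # stage 2 must leave these untouched

    if spec.teacher_forcing:
        aux_tr, aux_va = cbv_tr[:, None], cbv_va[:, None]
    else:
        aux_tr, aux_va = cbve.predict(xs), cbve.predict(xv)
    vsde = MLP(spec.vsde_sizes, out_activation="sigmoid", seed=seed + 1000)
    hist2 = vsde.fit(
        np.hstack([xs, aux_tr]), vsd_tr, np.hstack([xv, aux_va]), vsd_va,
        lr=spec.learning_rate, beta1=spec.beta1, beta2=spec.beta2,
        batch_size=spec.batch_size, max_epochs=spec.max_epochs,
        patience=spec.patience, seed=seed + 2,
    )
    cbve.load_state(frozen)
    return TrainedModelPair(
        cbve, vsde, spec, {"cbve": hist1, "vsde": hist2}, seed,
    )


def predict(models: TrainedModelPair, signals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted (CBV, VSD) for one signal or a batch.

    CBV is non-negative (rectified output); VSD bins lie in (0, 1)
    (sigmoid output).
    """
    x = np.atleast_2d(np.asarray(signals, dtype=np.float32))
    if x.shape[1] != models.spec.n_echoes:
        raise ValueError(f"expected {models.spec.n_echoes}-echo signals, got {x.shape[1]}")
    cbv = models.cbve.predict(x)
    vsd = models.vsde.predict(np.hstack([x, cbv]))
    if np.asarray(signals).ndim == 1:
        return float(cbv[0, 0]), vsd[0]
    return cbv[:, 0], vsd


def save_model_pair(models: TrainedModelPair, path: str) -> None:
    """Persist both networks and their config as a portable .npz checkpoint."""
    payload = {}
    for name, net in (("cbve", models.cbve), ("vsde", models.vsde)):
        for i, (w, b) in enumerate(zip(net.W, net.b)):
            payload[f"{name}_W{i}"] = w
            payload[f"{name}_b{i}"] = b
    meta = {
        "spec": {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(models.spec).items()},
        "seed": models.seed,
        "cbve_sizes": list(models.cbve.sizes),
        "vsde_sizes": list(models.vsde.sizes),
    }
    payload["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_model_pair(path: str) -> TrainedModelPair:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        spec_kw = dict(meta["spec"])
        for key in ("cbve_hidden", "vsde_hidden"):
            spec_kw[key] = tuple(spec_kw[key])
        spec = ModelSpec(**spec_kw)
        pair = {}
        for name, sizes, act in (
            ("cbve", meta["cbve_sizes"], "relu"),
            ("vsde", meta["vsde_sizes"], "sigmoid"),
        ):
            net = MLP(sizes, out_activation=act, seed=0)
            net.W = [np.asarray(data[f"{name}_W{i}"]) for i in range(len(sizes) - 1)]
            net.b = [np.asarray(data[f"{name}_b{i}"]) for i in range(len(sizes) - 1)]
            pair[name] = net
    return TrainedModelPair(pair["cbve"], pair["vsde"], spec, {}, meta["seed"])
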