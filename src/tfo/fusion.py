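"""Information-fusion MLP for binary hypoxemia detection.

The network has two heads.  The *representation head* maps the ten
pulsation ratios (five detectors x two wavelengths) — the "signature" of a
round's measurement geometry — through a single 10 -> 16 linear layer with
ReLU.  The *classification head* concatenates that 16-dim representation
with the five per-detector modulation ratios and passes the 21-dim vector
through hidden layers 128 -> 64 -> 32 -> 16 (ReLU after each) to a single
sigmoid output: the probability that the sample is hypoxemic.

Feature scaling follows the two roles: pulsation ratios are standardized
across rounds (one mean/sd per feature over the whole training set), while
modulation ratios are standardized per round (each round's own mean/sd per
detector), because their sensitivity to saturation is strongly
subject-specific.

Training minimizes class-weighted binary cross-entropy (weight
``N_total / (2 * N_c)`` per class) with Adam (lr 1e-4, weight decay 1e-4),
at most 300 epochs, early-stopping when the validation loss has not
improved for 25 epochs and restoring the best weights.  Weights are
initialized from a normal distribution, biases at zero.

Implemented directly on NumPy: the model is a few small dense layers, and
a self-contained implementation keeps initialization, the optimizer update
and the training loop exactly reproducible under a seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "Standardizer",
    "FusionMLP",
    "build_network",
    "class_weights",
    "train",
    "predict",
    "PULSATION_COLUMNS",
    "MODULATION_COLUMNS",
]

PULSATION_COLUMNS = tuple(
    f"pr_d{d}_{lam}" for d in range(1, 6) for lam in (740, 850)
)
MODULATION_COLUMNS = tuple(f"phi_d{d}" for d in range(1, 6))


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of the two-head fusion network."""

    n_pulsation: int = 10
    representation_width: int = 16
    n_modulation: int = 5
    hidden_widths: tuple[int, ...] = (128, 64, 32, 16)
    #: weight init: normal with this std, or None for He scaling
    #: (std = sqrt(2/fan_in), the standard choice for ReLU stacks — a fixed
    #: small std starves the deeper layers of gradient).
    init_std: float | None = None

    def __post_init__(self) -> None:
        if self.n_pulsation < 1 or self.n_modulation < 1:
            raise ValueError("feature counts must be positive")
        if any(w < 1 for w in self.hidden_widths) or self.representation_width < 1:
            raise ValueError("layer widths must be positive")
        for a, b in zip(self.hidden_widths, self.hidden_widths[1:]):
            if b * 2 != a:
                raise ValueError("hidden widths must halve at each layer")

    @property
    def classification_input(self) -> int:
        return self.representation_width + self.n_modulation

    def layer_shapes(self) -> list[tuple[int, int]]:
        """Weight-matrix shapes: representation layer, then classification path."""
        shapes = [(self.n_pulsation, self.representation_width)]
        widths = (self.classification_input,) + self.hidden_widths + (1,)
        shapes += list(zip(widths[:-1], widths[1:]))
        return shapes


@dataclass
class TrainConfig:
    """Optimization settings for the fusion network."""

    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    max_epochs: int = 300
    patience: int = 25
    batch_size: int = 64
    seed: int = 0
    use_class_weights: bool = True

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.max_epochs, self.patience, self.batch_size) <= 0:
            raise ValueError("all training parameters must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight decay must be non-negative")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


class Standardizer:
    """Zero-mean/unit-variance scaling, across rounds or per round.

    ``across_rounds`` fits one mean/sd per feature over all provided rows
    (population sd).  ``per_round`` fits a mean/sd per (round, feature),
    each round scaled by its own statistics.
    """

    def __init__(self, mode: str):
        if mode not in ("across_rounds", "per_round"):
            raise ValueError(f"unknown standardizer mode {mode!r}")
        self.mode = mode
        self.columns: tuple[str, ...] | None = None
        self.stats: dict = {}

    def fit(
        self,
        df: pd.DataFrame,
        columns: tuple[str, ...],
        round_ids: np.ndarray | None = None,
    ) -> "Standardizer":
        self.columns = tuple(columns)
        x = df.loc[:, list(columns)].to_numpy(float)
        if self.mode == "across_rounds":
            if x.shape[0] < 2:
                raise ValueError("need at least 2 samples to fit a standardizer")
            mean = x.mean(axis=0)
            sd = x.std(axis=0)
            for c, s in zip(columns, sd):
                if s <= 0:
                    raise ValueError(f"zero variance in feature {c!r}")
            self.stats = {"mean": mean, "sd": sd}
        else:
            if round_ids is None:
                raise ValueError("per_round mode requires round_ids")
            round_ids = np.asarray(round_ids)
            self.stats = {}
            for r in np.unique(round_ids):
                xr = x[round_ids == r]
                if xr.shape[0] < 2:
                    raise ValueError(f"need at least 2 samples in round {r}")
                mean = xr.mean(axis=0)
                sd = xr.std(axis=0)
                for c, s in zip(columns, sd):
                    if s <= 0:
                        raise ValueError(f"zero variance in feature {c!r} of round {r}")
                self.stats[r] = {"mean": mean, "sd": sd}
        return self

    def _round_stats(self, round_ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        means = np.empty((round_ids.size, len(self.columns)))
        sds = np.empty_like(means)
        for r in np.unique(round_ids):
            if r not in self.stats:
                raise KeyError(f"round {r} was not seen during fit")
            sel = round_ids == r
            means[sel] = self.stats[r]["mean"]
            sds[sel] = self.stats[r]["sd"]
        return means, sds

    def transform(
        self, df: pd.DataFrame, round_ids: np.ndarray | None = None
    ) -> np.ndarray:
        if self.columns is None:
            raise RuntimeError("standardizer is not fitted")
        x = df.loc[:, list(self.columns)].to_numpy(float)
        if self.mode == "across_rounds":
            return (x - self.stats["mean"]) / self.stats["sd"]
        if round_ids is None:
            raise ValueError("per_round mode requires round_ids")
        means, sds = self._round_stats(np.asarray(round_ids))
        return (x - means) / sds

    def inverse_transform(
        self, z: np.ndarray, round_ids: np.ndarray | None = None
    ) -> np.ndarray:
        if self.mode == "across_rounds":
            return z * self.stats["sd"] + self.stats["mean"]
        means, sds = self._round_stats(np.asarray(round_ids))
        return z * sds + means

    def to_dict(self) -> dict:
        if self.mode == "across_rounds":
            stats = {
                "mean": self.stats["mean"].tolist(),
                "sd": self.stats["sd"].tolist(),
            }
        else:
            stats = {
                str(r): {"mean": s["mean"].tolist(), "sd": s["sd"].tolist()}
                for r, s in self.stats.items()
            }
        return {"mode": self.mode, "columns": list(self.columns), "stats": stats}


class FusionMLP:
    """The two-head network, parameters held as plain NumPy arrays."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for n_in, n_out in spec.layer_shapes():
            std = spec.init_std if spec.init_std is not None else np.sqrt(2.0 / n_in)
            self.weights.append(rng.normal(0.0, std, size=(n_in, n_out)))
            self.biases.append(np.zeros(n_out))

    # -- architecture audit helpers -------------------------------------
    @property
    def layer_shapes(self) -> list[tuple[int, int]]:
        return [w.shape for w in self.weights]

    @property
    def n_relu(self) -> int:
        # one after the representation layer, one after each hidden layer
        return 1 + len(self.spec.hidden_widths)

    def parameters(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def set_parameters(self, params: list[np.ndarray]) -> None:
        n = len(self.weights)
        self.weights = [p.copy() for p in params[:n]]
        self.biases = [p.copy() for p in params[n:]]

    # -- forward / backward ---------------------------------------------
    def _forward(
        self, x_pulsation: np.ndarray, x_modulation: np.ndarray
    ) -> tuple[np.ndarray, list]:
        cache = []
        h = x_pulsation @ self.weights[0] + self.biases[0]
        a = np.maximum(h, 0.0)
        cache.append((x_pulsation, h))
        z = np.concatenate([a, x_modulation], axis=1)
        for k in range(1, len(self.weights) - 1):
            h = z @ self.weights[k] + self.biases[k]
            cache.append((z, h))
            z = np.maximum(h, 0.0)
        logits = z @ self.weights[-1] + self.biases[-1]
        cache.append((z, logits))
        prob = 1.0 / (1.0 + np.exp(-logits))
        return prob.ravel(), cache

    def predict_proba(
        self, x_pulsation: np.ndarray, x_modulation: np.ndarray
    ) -> np.ndarray:
        prob, _ = self._forward(
            np.asarray(x_pulsation, float), np.asarray(x_modulation, float)
        )
        return prob

    def _backward(
        self,
        cache: list,
        prob: np.ndarray,
        y: np.ndarray,
        sample_weight: np.ndarray,
    ) -> tuple[list[np.ndarray], list[np.ndarray]]:
        n = y.size
        rep_width = self.spec.representation_width
        d_logit = (sample_weight * (prob - y) / n)[:, None]
        grads_w = [np.empty(0)] * len(self.weights)
        grads_b = [np.empty(0)] * len(self.biases)

        z_last, _ = cache[-1]
        grads_w[-1] = z_last.T @ d_logit
        grads_b[-1] = d_logit.sum(axis=0)
        dz = d_logit @ self.weights[-1].T

        for k in range(len(self.weights) - 2, 0, -1):
            z_in, h = cache[k]
            dh = dz * (h > 0)
            grads_w[k] = z_in.T @ dh
            grads_b[k] = dh.sum(axis=0)
            dz = dh @ self.weights[k].T

        # dz is the gradient w.r.t. concat(representation, modulation)
        xp, h0 = cache[0]
        da = dz[:, :rep_width]
        dh0 = da * (h0 > 0)
        grads_w[0] = xp.T @ dh0
        grads_b[0] = dh0.sum(axis=0)
        return grads_w, grads_b


def build_network(spec: NetworkSpec | None = None, seed: int = 0) -> FusionMLP:
    """Construct a fusion network with seeded normal-init weights, zero biases."""
    return FusionMLP(spec or NetworkSpec(), seed=seed)


def class_weights(y: np.ndarray) -> dict[int, float]:
    """Inverse-frequency class weights: w_c = N_total / (2 * N_c)."""
    y = np.asarray(y).astype(int)
    n = y.size
    counts = {c: int(np.sum(y == c)) for c in (0, 1)}
    if counts[0] == 0 or counts[1] == 0:
        raise ValueError("both classes must be present in the training set")
    return {c: n / (2.0 * counts[c]) for c in (0, 1)}


def _bce(prob: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None = None) -> float:
    eps = 1e-12
    p = np.clip(prob, eps, 1.0 - eps)
    losses = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    if sample_weight is not None:
        losses = losses * sample_weight
    return float(losses.mean())


class _Adam:
    """Adam with L2-coupled weight decay (decay added to the gradient)."""

    def __init__(self, params: list[np.ndarray], lr: float, weight_decay: float):
        self.lr = lr
        self.wd = weight_decay
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            g = g + self.wd * p
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def train(
    model: FusionMLP,
    train_data: tuple[np.ndarray, np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray, np.ndarray],
    config: TrainConfig,
) -> pd.DataFrame:
    """Fit the network in place; returns the per-epoch loss history.

    ``train_data``/``val_data`` are ``(x_pulsation, x_modulation, y)``
    triples of already-standardized features.  Training stops early when
    the validation BCE has not improved for ``config.patience`` epochs; the
    best-on-validation parameters are restored before returning.
    """
    xp_tr, xm_tr, y_tr = (np.asarray(a, float) for a in train_data)
    xp_va, xm_va, y_va = (np.asarray(a, float) for a in val_data)
    y_tr = y_tr.astype(float)
    y_va = y_va.astype(float)

    weights = class_weights(y_tr)
    if config.use_class_weights:
        sw_tr = np.where(y_tr > 0.5, weights[1], weights[0])
        # the stopping criterion mirrors the training objective; an
        # unweighted criterion would undo the weighting by favoring
        # majority-class-calibrated checkpoints
        sw_va = np.where(y_va > 0.5, weights[1], weights[0])
    else:
        sw_tr = np.ones_like(y_tr)
        sw_va = np.ones_like(y_va)

    rng = np.random.default_rng(config.seed)
    optimizer = _Adam(model.parameters(), config.learning_rate, config.weight_decay)

    best_loss = np.inf
    best_params = [p.copy() for p in model.parameters()]
    best_epoch = -1
    history = []
    n = y_tr.size
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            prob, cache = model._forward(xp_tr[idx], xm_tr[idx])
            gw, gb = model._backward(cache, prob, y_tr[idx], sw_tr[idx])
            optimizer.step(model.parameters(), gw + gb)
            epoch_loss += _bce(prob, y_tr[idx], sw_tr[idx]) * idx.size
        train_loss = epoch_loss / n
        val_prob = model.predict_proba(xp_va, xm_va)
        val_loss = _bce(val_prob, y_va, sw_va)
        history.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss}
        )
        if val_loss < best_loss - 1e-12:
            best_loss = val_loss
            best_epoch = epoch
            best_params = [p.copy() for p in model.parameters()]
        elif epoch - best_epoch >= config.patience:
            break
    model.set_parameters(best_params)
    hist = pd.DataFrame(history)
    hist.attrs["best_epoch"] = best_epoch
    return hist


def predict(
    model: FusionMLP,
    x_pulsation: np.ndarray,
    x_modulation: np.ndarray,
    threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and thresholded labels (positive iff p >= threshold)."""
    xp = np.asarray(x_pulsation, float)
    xm = np.asarray(x_modulation, float)
    col_means = np.concatenate([xp.mean(axis=0), xm.mean(axis=0)])
    if np.any(np.abs(col_means) > 3.0):
        warnings.warn(
            "input features look unstandardized (|column mean| > 3); "
            "apply the fitted standardizers before predicting"
        )
    prob = model.predict_proba(xp, xm)
    return prob, prob >= threshold


def save_model(
    model: FusionMLP,
    path: str | Path,
    standardizers: dict[str, Standardizer] | None = None,
) -> None:
    """NPZ of the parameters plus a portable JSON of shapes and scalers."""
    path = Path(path)
    arrays = {f"w{i}": w for i, w in enumerate(model.weights)}
    arrays.update({f"b{i}": b for i, b in enumerate(model.biases)})
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {
        "spec": {
            "n_pulsation": model.spec.n_pulsation,
            "representation_width": model.spec.representation_width,
            "n_modulation": model.spec.n_modulation,
            "hidden_widths": list(model.spec.hidden_widths),
            "init_std": model.spec.init_std,
        },
        "layer_shapes": [list(s) for s in model.layer_shapes],
        "standardizers": {
            name: s.to_dict() for name, s in (standardizers or {}).items()
        },
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> FusionMLP:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec = NetworkSpec(
        n_pulsation=meta["spec"]["n_pulsation"],
        representation_width=meta["spec"]["representation_width"],
        n_modulation=meta["spec"]["n_modulation"],
        hidden_widths=tuple(meta["spec"]["hidden_widths"]),
        init_std=meta["spec"]["init_std"],
    )
    model = FusionMLP(spec, seed=0)
    with np.load(path.with_suffix(".npz")) as data:
        model.weights = [data[f"w{i}"] for i in range(len(model.weights))]
        model.biases = [data[f"b{i}"] for i in range(len(model.biases))]
    return model
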