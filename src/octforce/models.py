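"""Force-regression models: 1D ResNets mapping one scan to one force value.

The central class is :class:`ResNetForceRegressor`, a scikit-learn style
estimator (``fit`` / ``predict`` / ``get_params``) wrapping the numpy network
core in :mod:`octforce.nn`.  It accepts either representation of the optical
signal as its input matrix: raw interferograms (n_scans, 1024) or
reconstructed depth profiles (n_scans, 512).  Inputs are standardized with a
global scalar mean/scale fitted on the training split only; targets are
plain forces in newtons.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .signal_model import N_SPECTRAL_SAMPLES
from .reconstruction import N_DEPTH_BINS

ARCHITECTURES = ("resnet6", "resnet18", "resnet34")
INPUT_MODES = ("raw", "recon")
_SCALE_FLOOR = 1e-8

__all__ = [
    "ARCHITECTURES",
    "INPUT_MODES",
    "ModelSpec",
    "NormalizationStats",
    "build_model",
    "fit_normalization",
    "predict_force",
    "ResNetForceRegressor",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture + input-representation choice for one model.

    ``input_length`` is 1024 for raw interferograms and 512 for reconstructed
    depth profiles.  ``width`` is the stem channel count; 64 matches the
    canonical ResNet stem, smaller values give desk-scale models.
    """

    architecture: str = "resnet6"
    input_mode: str = "recon"
    width: int = 64

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}")
        if self.input_mode not in INPUT_MODES:
            raise ValueError(f"input_mode must be one of {INPUT_MODES}")
        if self.width < 1:
            raise ValueError("width must be a positive integer")

    @property
    def input_length(self) -> int:
        return N_SPECTRAL_SAMPLES if self.input_mode == "raw" else N_DEPTH_BINS


@dataclass(frozen=True)
class NormalizationStats:
    """Global standardization constants, fitted on the training split only."""

    mean: float
    scale: float
    n_features: int
    fitted_on: str = "train"

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be strictly positive")

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale


def build_model(spec: ModelSpec, seed: int) -> nn.ResNet1D:
    """Instantiate the 1D ResNet for a model spec, deterministically from ``seed``."""
    return nn.ResNet1D(spec.architecture, width=spec.width, seed=seed)


def fit_normalization(train_inputs: np.ndarray, fitted_on: str = "train") -> NormalizationStats:
    """Global scalar mean/std over all entries of the training inputs."""
    X = np.asarray(train_inputs, dtype=np.float64)
    if X.size == 0:
        raise ValueError("training set must be non-empty")
    mean = float(X.mean())
    scale = float(X.std())
    if scale < _SCALE_FLOOR:
        warnings.warn(
            "training inputs have (near-)zero variance; flooring scale",
            RuntimeWarning,
            stacklevel=2,
        )
        scale = _SCALE_FLOOR
    return NormalizationStats(
        mean=mean, scale=scale, n_features=X.shape[-1], fitted_on=fitted_on
    )


def predict_force(
    model: nn.ResNet1D,
    stats: NormalizationStats,
    scan: np.ndarray,
    *,
    batch_size: int = 1024,
) -> float | np.ndarray:
    """Predict force (N) for one scan or a batch of scans, in evaluation mode."""
    X = np.asarray(scan, dtype=np.float64)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != stats.n_features:
        raise ValueError(
            f"scan length {X.shape[1]} does not match fitted input length {stats.n_features}"
        )
    Xs = stats.apply(X)
    parts = [
        model.forward(Xs[i : i + batch_size], train=False)
        for i in range(0, Xs.shape[0], batch_size)
    ]
    preds = np.concatenate(parts).astype(np.float64)
    return float(preds[0]) if single else preds


def _recalibrate_batchnorm(
    net: nn.ResNet1D, X: np.ndarray, batch_size: int, max_batches: int = 256
) -> None:
    """Replace BN running statistics with equal-weight averages over the
    training set (one deterministic forward pass in training mode).

    Exponential running averages lag the final weights when the optimizer is
    still moving at its fixed learning rate; recomputing the inference
    statistics against the last-epoch weights removes that train/eval
    mismatch.
    """
    bns = net._batchnorms()
    saved_momentum = [bn.momentum for bn in bns]
    for bn in bns:
        bn.running_mean[...] = 0.0
        bn.running_var[...] = 0.0
    n_batches = min(max_batches, max(1, int(np.ceil(X.shape[0] / batch_size))))
    for i in range(n_batches):
        for bn in bns:
            bn.momentum = 1.0 / (i + 1)  # cumulative (equal-weight) average
        net.forward(X[i * batch_size : (i + 1) * batch_size], train=True)
    for bn, mom in zip(bns, saved_momentum):
        bn.momentum = mom


class ResNetForceRegressor(RegressorMixin, BaseEstimator):
    """1D-convolutional ResNet regression of needle-tip force from one scan.

    Trains with Adam on the batch mean squared error for a fixed number of
    epochs; the fitted model is the last-epoch model (no early stopping).
    All randomness — weight initialization and epoch shuffling — derives from
    ``random_state``, so identical data and seed reproduce the fit exactly.

    Parameters
    ----------
    architecture : {"resnet6", "resnet18", "resnet34"}
        Network depth variant.
    width : int
        Stem channel count (64 = canonical ResNet stem).
    epochs, batch_size, learning_rate : training protocol constants.
    shuffle : bool
        Reshuffle the training order every epoch.
    bn_recalibrate : bool
        After the last epoch, recompute BatchNorm inference statistics over
        the training set against the final weights (removes the lag of the
        exponential running averages behind a still-moving optimizer).
    average_final_epoch : bool
        Replace the final weights by their Polyak (tail) average over the
        last epoch's optimizer steps.  At a fixed learning rate Adam never
        anneals, so the iterates orbit the optimum with non-vanishing
        variance; averaging the final epoch removes that stationary noise
        without any validation-based model selection.
    random_state : int
        Seed for initialization and shuffling.

    Attributes
    ----------
    net_ : the trained :class:`octforce.nn.ResNet1D`.
    norm_stats_ : :class:`NormalizationStats` fitted on the training inputs.
    history_ : dict with per-epoch ``train_loss`` and, when validation data
        was supplied to ``fit``, ``val_mae_mN``.
    n_features_in_ : input length seen during fit.
    """

    def __init__(
        self,
        architecture: str = "resnet6",
        width: int = 64,
        epochs: int = 150,
        batch_size: int = 128,
        learning_rate: float = 0.005,
        shuffle: bool = True,
        bn_recalibrate: bool = True,
        average_final_epoch: bool = True,
        random_state: int = 0,
    ) -> None:
        self.architecture = architecture
        self.width = width
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.shuffle = shuffle
        self.bn_recalibrate = bn_recalibrate
        self.average_final_epoch = average_final_epoch
        self.random_state = random_state

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        validation_data: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> "ResNetForceRegressor":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_samples, length) aligned with y")
        if X.shape[0] < 1:
            raise ValueError("training set must be non-empty")

        self.n_features_in_ = X.shape[1]
        self.norm_stats_ = fit_normalization(X)
        Xs = self.norm_stats_.apply(X).astype(np.float32)
        yt = y.astype(np.float64)

        net = nn.ResNet1D(self.architecture, width=self.width, seed=self.random_state)
        opt = nn.Adam(net.params(), lr=self.learning_rate)
        rng = np.random.default_rng(self.random_state + 1)

        n = Xs.shape[0]
        order = np.arange(n)
        history: dict[str, list[float]] = {"train_loss": []}
        if validation_data is not None:
            history["val_mae_mN"] = []
        tail_avg: list[np.ndarray] | None = None
        for epoch in range(self.epochs):
            if self.shuffle:
                order = rng.permutation(n)
            in_tail = self.average_final_epoch and epoch == self.epochs - 1
            if in_tail:
                tail_avg = [np.zeros_like(p.data, dtype=np.float64) for p in net.params()]
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                pred = net.forward(Xs[idx], train=True)
                loss, gpred = nn.mse_and_grad(pred, yt[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged: non-finite loss at epoch {epoch}, "
                        f"batch {n_batches} (lr={self.learning_rate})"
                    )
                net.zero_grad()
                net.backward(gpred)
                opt.step()
                epoch_loss += loss
                n_batches += 1
                if in_tail:
                    for acc, p in zip(tail_avg, net.params()):
                        acc += (p.data - acc) / n_batches  # running mean of iterates
            history["train_loss"].append(epoch_loss / max(n_batches, 1))
            if validation_data is not None:
                Xv, yv = validation_data
                pv = predict_force(net, self.norm_stats_, np.asarray(Xv, float))
                history["val_mae_mN"].append(
                    float(np.mean(np.abs(pv - np.asarray(yv, float)))) * 1000.0
                )
        if tail_avg is not None:
            for acc, p in zip(tail_avg, net.params()):
                p.data[...] = acc.astype(p.data.dtype)
        if self.bn_recalibrate or tail_avg is not None:
            _recalibrate_batchnorm(net, Xs, self.batch_size)
            if validation_data is not None:
                Xv, yv = validation_data
                pv = predict_force(net, self.norm_stats_, np.asarray(Xv, float))
                history["val_mae_mN"][-1] = (
                    float(np.mean(np.abs(pv - np.asarray(yv, float)))) * 1000.0
                )
        self.net_ = net
        self.history_ = history
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "net_")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be (n_samples, length)")
        return predict_force(self.net_, self.norm_stats_, X)


def save_checkpoint(path: str | Path, regressor: ResNetForceRegressor) -> None:
    """Write model weights (npz) plus a JSON sidecar with config and stats."""
    check_is_fitted(regressor, "net_")
    path = Path(path)
    np.savez(path, **regressor.net_.state_arrays())
    sidecar = {
        "params": regressor.get_params(),
        "normalization": asdict(regressor.norm_stats_),
        "n_features_in": int(regressor.n_features_in_),
    }
    npz_path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    npz_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> ResNetForceRegressor:
    """Rebuild a fitted regressor from :func:`save_checkpoint` output."""
    path = Path(path)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    sidecar = json.loads(npz_path.with_suffix(".json").read_text())
    reg = ResNetForceRegressor(**sidecar["params"])
    reg.norm_stats_ = NormalizationStats(**sidecar["normalization"])
    reg.n_features_in_ = sidecar["n_features_in"]
    net = nn.ResNet1D(reg.architecture, width=reg.width, seed=reg.random_state)
    with np.load(npz_path) as arrays:
        net.load_state_arrays(dict(arrays))
    reg.net_ = net
    return reg
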