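"""Training protocol and the raw-vs-reconstructed comparison harness.

The calibration question the harness answers: given paired (scan, force)
records, does a network learn force better from the raw interferogram or from
the reconstructed depth profile?  For each architecture, input representation
and seed it trains a model under one shared protocol (Adam, MSE loss, fixed
epochs/batch size/learning rate, 20% hold-out) and reports the validation
mean absolute error in millinewtons, aggregated as mean +/- std over seeds.

The hold-out split defaults to the final contiguous 20% of the time series
("block"): M-scan records are strongly autocorrelated in time, so a random
split would leak near-duplicate neighbours between train and validation.
A random split remains available for parity experiments.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .models import ModelSpec, ResNetForceRegressor, predict_force
from .reconstruction import AScanReconstructor
from .signal_model import CalibrationDataset

__all__ = [
    "TrainConfig",
    "EvalReport",
    "split_dataset",
    "mse_loss",
    "prepare_representations",
    "train_model",
    "evaluate_mae",
    "naive_mae",
    "run_comparison",
    "measure_inference_time",
]


@dataclass(frozen=True)
class TrainConfig:
    """Shared training protocol for every model in a comparison.

    Defaults are the full-scale protocol (150 epochs, batch 128, lr 0.005,
    Adam, 20% hold-out, five seeds); desk-scale experiments override epochs,
    width and seeds explicitly.
    """

    epochs: int = 150
    batch_size: int = 128
    learning_rate: float = 0.005
    val_fraction: float = 0.20
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    split_strategy: str = "block"
    width: int = 64

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")
        if len(self.seeds) == 0 or len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seeds must be non-empty and distinct")
        if self.split_strategy not in ("random", "block"):
            raise ValueError("split_strategy must be 'random' or 'block'")
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training constants")
        object.__setattr__(self, "seeds", tuple(int(s) for s in self.seeds))


@dataclass
class EvalReport:
    """Per-run MAEs and their per-cell aggregation, Table-style.

    ``runs`` has one row per (needle_id, arch, input_mode, seed) with
    ``mae_mN``; ``aggregate`` has one row per (needle_id, arch, input_mode)
    with ``mean_mae_mN``, ``std_mae_mN`` and ``rel_diff`` — the relative
    raw-vs-recon difference (MAE_raw - MAE_recon) / MAE_recon for that
    architecture (same value on both rows of a pair).  Inference timings in
    ms per scan are informational.
    """

    runs: pd.DataFrame
    aggregate: pd.DataFrame
    inference_ms: dict[str, float] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "runs": self.runs.to_dict(orient="records"),
            "aggregate": self.aggregate.to_dict(orient="records"),
            "inference_ms": self.inference_ms,
            "provenance": self.provenance,
        }


def split_dataset(
    n_samples: int,
    config: TrainConfig,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/validation index split.

    ``random`` shuffles indices with the seed and holds out the last
    ``val_fraction`` of the shuffled order; ``block`` holds out the final
    contiguous fraction of the time series regardless of the seed.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples to split")
    n_val = int(round(n_samples * config.val_fraction))
    n_val = min(max(n_val, 1), n_samples - 1)
    if config.split_strategy == "block":
        idx = np.arange(n_samples)
        return idx[: n_samples - n_val], idx[n_samples - n_val :]
    order = np.random.default_rng(seed).permutation(n_samples)
    return np.sort(order[: n_samples - n_val]), np.sort(order[n_samples - n_val :])


def mse_loss(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Batch mean squared error (1/N) * sum (y - yhat)^2."""
    yt = np.asarray(y_true, dtype=np.float64)
    yp = np.asarray(y_pred, dtype=np.float64)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal shapes")
    if yt.size == 0:
        raise ValueError("empty batch")
    return float(np.mean((yt - yp) ** 2))


def prepare_representations(
    dataset: CalibrationDataset,
    reconstructor: AScanReconstructor | None = None,
    *,
    log_compress: bool = True,
) -> dict[str, np.ndarray]:
    """Build aligned (scan, force) training arrays for both representations.

    Reconstructs the M-scan (unless already attached to the dataset), then
    drops the EMA burn-in rows from raw, recon and forces alike so both arms
    train on identical samples.  The recon arm is log-compressed
    (``log(1 + magnitude)``) by default — the conventional dynamic-range
    compression for OCT intensity profiles, which also conditions the input
    for gradient training.  Returns ``{"raw": (n, 1024), "recon": (n, 512),
    "force": (n,)}``.
    """
    if reconstructor is None:
        reconstructor = AScanReconstructor(chirp=dataset.mscan.chirp)
    reconstructor.fit(dataset.mscan)
    X_raw = dataset.mscan.spectra.T
    if dataset.recon is not None:
        X_recon = np.asarray(dataset.recon).T
    else:
        X_recon = reconstructor.transform(dataset.mscan)
    keep = reconstructor.valid_slice()
    X_recon = X_recon[keep]
    if log_compress:
        X_recon = np.log1p(X_recon)
    return {
        "raw": X_raw[keep],
        "recon": X_recon,
        "force": dataset.force_trace.forces[keep],
    }


def train_model(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    config: TrainConfig,
    seed: int,
) -> tuple[ResNetForceRegressor, dict]:
    """Split, train and log one model under the shared protocol.

    Returns the fitted regressor and its history (per-epoch training loss and
    validation MAE).  The returned model is the last-epoch model; there is no
    early stopping or validation-based selection.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.shape[1] != spec.input_length:
        raise ValueError(
            f"input length {X.shape[1]} does not match spec "
            f"({spec.input_mode} expects {spec.input_length})"
        )
    train_idx, val_idx = split_dataset(X.shape[0], config, seed=seed)
    reg = ResNetForceRegressor(
        architecture=spec.architecture,
        width=spec.width,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        random_state=seed,
    )
    reg.fit(X[train_idx], y[train_idx], validation_data=(X[val_idx], y[val_idx]))
    history = dict(reg.history_)
    history["train_idx"] = train_idx
    history["val_idx"] = val_idx
    return reg, history


def evaluate_mae(model, stats_or_X, X_val=None, y_val=None) -> float:
    """Validation mean absolute error, in millinewtons.

    Two call forms: ``evaluate_mae(regressor, X_val, y_val)`` with a fitted
    :class:`ResNetForceRegressor`, or ``evaluate_mae(net, stats, X_val,
    y_val)`` with a bare network plus its normalization stats.
    """
    if y_val is None:
        X_val, y_val = stats_or_X, X_val
        preds = model.predict(np.asarray(X_val, dtype=np.float64))
    else:
        preds = predict_force(model, stats_or_X, np.asarray(X_val, dtype=np.float64))
    y = np.asarray(y_val, dtype=np.float64)
    if y.size == 0:
        raise ValueError("empty validation set")
    return float(np.mean(np.abs(y - preds))) * 1000.0


def naive_mae(y_train: np.ndarray, y_val: np.ndarray) -> float:
    """MAE (mN) of the constant predictor equal to the training-mean force."""
    y_val = np.asarray(y_val, dtype=np.float64)
    if y_val.size == 0:
        raise ValueError("empty validation set")
    return float(np.mean(np.abs(y_val - np.mean(y_train)))) * 1000.0


def run_comparison(
    representations: dict[str, np.ndarray],
    architectures: list[str],
    config: TrainConfig,
    *,
    needle_id: str = "synthetic-0",
    input_modes: tuple[str, ...] = ("raw", "recon"),
    measure_timing: bool = False,
    provenance: dict | None = None,
) -> EvalReport:
    """Train every architecture x input-mode x seed cell and tabulate MAEs.

    ``representations`` is the output of :func:`prepare_representations`
    (burn-in already discarded).  Every cell shares the training protocol;
    per-cell relative difference is (MAE_raw - MAE_recon) / MAE_recon.
    """
    for mode in input_modes:
        if mode not in representations:
            raise ValueError(f"representations lack the {mode!r} input arrays")
    y = representations["force"]
    rows = []
    timing: dict[str, float] = {}
    for arch in architectures:
        for mode in input_modes:
            X = representations[mode]
            spec = ModelSpec(architecture=arch, input_mode=mode, width=config.width)
            for seed in config.seeds:
                reg, history = train_model(X, y, spec, config, seed)
                val_idx = history["val_idx"]
                mae = evaluate_mae(reg, X[val_idx], y[val_idx])
                rows.append(
                    {
                        "needle_id": needle_id,
                        "arch": arch,
                        "input_mode": mode,
                        "seed": seed,
                        "mae_mN": mae,
                    }
                )
                if measure_timing and f"{arch}/{mode}" not in timing:
                    timing[f"{arch}/{mode}"] = measure_inference_time(
                        reg, X[val_idx][: min(256, len(val_idx))]
                    )[0]
    runs = pd.DataFrame(rows)
    aggregate = aggregate_runs(runs)
    return EvalReport(
        runs=runs,
        aggregate=aggregate,
        inference_ms=timing,
        provenance={"config": asdict(config), **(provenance or {})},
    )


def aggregate_runs(runs: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- std over seeds per cell, plus the raw-vs-recon relative difference."""
    grouped = (
        runs.groupby(["needle_id", "arch", "input_mode"])["mae_mN"]
        .agg(mean_mae_mN="mean", std_mae_mN="std")
        .reset_index()
        .fillna({"std_mae_mN": 0.0})
    )
    rel = {}
    for (needle, arch), cell in grouped.groupby(["needle_id", "arch"]):
        modes = dict(zip(cell["input_mode"], cell["mean_mae_mN"]))
        if "raw" in modes and "recon" in modes and modes["recon"] > 0:
            rel[(needle, arch)] = (modes["raw"] - modes["recon"]) / modes["recon"]
    grouped["rel_diff"] = [
        rel.get((needle, arch), np.nan)
        for needle, arch in zip(grouped["needle_id"], grouped["arch"])
    ]
    return grouped


def measure_inference_time(
    model: ResNetForceRegressor,
    batch: np.ndarray,
    *,
    n_repeats: int = 10,
) -> tuple[float, float]:
    """Median and interquartile spread of per-scan latency in milliseconds.

    Wall-clock, informational only; a warm-up pass precedes the timed loop.
    """
    batch = np.asarray(batch, dtype=np.float64)
    model.predict(batch)  # warm-up
    times = []
    for _ in range(n_repeats):
        start = time.perf_counter()
        model.predict(batch)
        times.append((time.perf_counter() - start) * 1000.0 / batch.shape[0])
    times = np.asarray(times)
    q25, q75 = np.percentile(times, [25, 75])
    return float(np.median(times)), float(q75 - q25)
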