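"""Training, fine-tuning, prediction and evaluation for the CCS regressors."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..evidence_io import CuratedRecord, PeptideIon
from .encoding import EncodingError, encode, encode_matrix, n_features
from .losses import (
    baseline_sum_loss_grad,
    mae_loss_grad,
    multiconf_loss_grad,
)
from .network import Adam, CCSModel, ModelSpec

logger = logging.getLogger(__name__)

LOSS_KINDS = ("multiconf", "baseline_sum", "single")


@dataclass(frozen=True)
class TrainConfig:
    """Split fractions, optimization settings and loss selection."""

    train_frac: float = 0.81
    val_frac: float = 0.09
    test_frac: float = 0.10
    max_epochs: int = 500
    patience: int = 10
    seed: int = 0
    learning_rate: float = 1e-3
    batch_size: int = 64
    loss_kind: str = "multiconf"
    loss_form: str = "sorted"  # multiconf only: "sorted" | "assignment"

    def __post_init__(self) -> None:
        total = self.train_frac + self.val_frac + self.test_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.loss_kind not in LOSS_KINDS:
            raise ValueError(f"loss_kind must be one of {LOSS_KINDS}")


@dataclass(frozen=True)
class PredictionPair:
    """Sorted pair of conformer CCS predictions."""

    ccs_small: float
    ccs_large: float

    def __post_init__(self) -> None:
        if self.ccs_small > self.ccs_large:
            raise ValueError("ccs_small must be <= ccs_large")


def two_conformer_records(
    records: Sequence[CuratedRecord],
) -> list[CuratedRecord]:
    """Keep only records with exactly two conformer CCS values."""
    return [r for r in records if len(r.ccs_values) == 2]


def split_dataset(
    records: Sequence[CuratedRecord], cfg: TrainConfig
) -> dict[str, list[CuratedRecord]]:
    """Seeded disjoint train/val/test partition at the ion level."""
    n = len(records)
    if n < 10:
        raise ValueError("need at least 10 records to split")
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    n_train = int(math.floor(cfg.train_frac * n))
    n_val = int(math.floor(cfg.val_frac * n))
    idx = {
        "train": perm[:n_train],
        "val": perm[n_train : n_train + n_val],
        "test": perm[n_train + n_val :],
    }
    return {k: [records[i] for i in v] for k, v in idx.items()}


def _targets(
    records: Sequence[CuratedRecord], cfg: TrainConfig
) -> tuple[np.ndarray, np.ndarray | None]:
    """Target array for the configured loss; also the baseline selections."""
    if cfg.loss_kind == "multiconf":
        for r in records:
            if len(r.ccs_values) != 2:
                raise ValueError(
                    "multiconf loss requires exactly two conformer values "
                    f"(got {len(r.ccs_values)} for {r.ion.peptidoform})"
                )
        return np.array([r.ccs_values for r in records], dtype=float), None
    if cfg.loss_kind == "baseline_sum":
        rng = np.random.default_rng(cfg.seed)
        picks = np.array(
            [rng.integers(len(r.ccs_values)) for r in records], dtype=int
        )
        y = np.array(
            [r.ccs_values[k] for r, k in zip(records, picks)], dtype=float
        )
        return y, picks
    # single
    y = np.array([r.ccs_values[0] for r in records], dtype=float)
    return y, None


def _loss_grad(cfg: TrainConfig, out: np.ndarray, yb: np.ndarray):
    if cfg.loss_kind == "multiconf":
        return multiconf_loss_grad(out, yb, form=cfg.loss_form)
    if cfg.loss_kind == "baseline_sum":
        return baseline_sum_loss_grad(out, yb)
    return mae_loss_grad(out, yb)


def train(
    records: Sequence[CuratedRecord],
    spec: ModelSpec,
    cfg: TrainConfig,
    model: CCSModel | None = None,
    refit_scalers: bool = True,
) -> tuple[CCSModel, dict]:
    """Train a CCS regressor with early stopping on the validation split.

    Returns the model (best-validation weights restored) and a history
    dict with per-epoch train/val losses (in Å², CCS scale).
    """
    if cfg.loss_kind == "single" and spec.n_outputs != 1:
        raise ValueError("single loss requires a single-output spec")
    if cfg.loss_kind in ("multiconf", "baseline_sum") and spec.n_outputs != 2:
        raise ValueError(f"{cfg.loss_kind} loss requires a two-output spec")

    splits = split_dataset(records, cfg)
    arrays = {}
    history: dict = {"train_loss": [], "val_loss": []}
    for name, recs in splits.items():
        X = encode_matrix([r.ion for r in recs], spec.max_len)
        y, picks = _targets(recs, cfg)
        arrays[name] = (X, y)
        if picks is not None and name == "train":
            history["random_selection"] = picks.tolist()

    X_train, y_train = arrays["train"]
    X_val, y_val = arrays["val"]

    if model is None:
        model = CCSModel(spec, n_features(spec.max_len), seed=cfg.seed)
    if refit_scalers:
        model.set_scalers(X_train, y_train)
    yn_train = (y_train - model.y_mean) / model.y_std
    yn_val = (y_val - model.y_mean) / model.y_std

    opt = Adam(model.params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    best_val = math.inf
    best_params = model.copy_params()
    best_epoch = -1
    stale = 0
    n = len(y_train)

    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            batch = perm[start : start + cfg.batch_size]
            cache: dict = {}
            out = model.forward(X_train[batch], cache)
            if not np.isfinite(out).all():
                raise RuntimeError(
                    f"training diverged: non-finite outputs at epoch {epoch}"
                )
            loss, dout = _loss_grad(cfg, out, yn_train[batch])
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            grads = model.backward(cache, dout)
            opt.step(model.params, grads)
            epoch_loss += loss * len(batch)
        val_out = model.forward(X_val)
        if not np.isfinite(val_out).all():
            raise RuntimeError(
                f"training diverged: non-finite outputs at epoch {epoch}"
            )
        val_loss, _ = _loss_grad(cfg, val_out, yn_val)
        history["train_loss"].append(epoch_loss / n * model.y_std)
        history["val_loss"].append(val_loss * model.y_std)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_params = model.copy_params()
            best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break

    model.load_params(best_params)
    history["best_epoch"] = best_epoch
    history["stopped_epoch"] = len(history["train_loss"]) - 1
    history["splits"] = {k: len(v) for k, v in splits.items()}
    return model, history


SHARED_PREFIX = "shared_"


def fine_tune(
    pretrained: CCSModel,
    records: Sequence[CuratedRecord],
    spec2: ModelSpec,
    cfg: TrainConfig,
) -> tuple[CCSModel, dict]:
    """Fine-tune a two-output model from a pretrained single-output trunk.

    Shared-layer weights (and the input/target scalers) are copied from
    the pretrained model; branch heads are freshly initialized; every
    parameter remains trainable.
    """
    if spec2.n_outputs != 2:
        raise ValueError("fine_tune target spec must have two outputs")
    if spec2.shared_layers != pretrained.spec.shared_layers:
        raise ValueError(
            "shared layer sizes differ: "
            f"{pretrained.spec.shared_layers} vs {spec2.shared_layers}"
        )
    model = CCSModel(spec2, pretrained.n_features, seed=cfg.seed)
    mismatched = [
        k
        for k in model.params
        if k.startswith(SHARED_PREFIX)
        and model.params[k].shape != pretrained.params[k].shape
    ]
    if mismatched:
        raise ValueError(f"shared-layer shape mismatch for: {mismatched}")
    for k in model.params:
        if k.startswith(SHARED_PREFIX):
            model.params[k] = pretrained.params[k].copy()
    model.x_mean = pretrained.x_mean.copy()
    model.x_std = pretrained.x_std.copy()
    model.y_mean = pretrained.y_mean
    model.y_std = pretrained.y_std
    return train(records, spec2, cfg, model=model, refit_scalers=False)


def predict(
    model: CCSModel, ions: Sequence[PeptideIon]
) -> tuple[list[PredictionPair | float | None], dict[int, str]]:
    """Predict CCS for a batch of ions.

    Returns one entry per ion: a :class:`PredictionPair` (two-output
    models, sorted so ccs_small <= ccs_large), a float (single-output), or
    None with a message in the error dict for unencodable ions.
    """
    results: list[PredictionPair | float | None] = []
    errors: dict[int, str] = {}
    ok_idx = []
    rows = []
    for i, ion in enumerate(ions):
        try:
            rows.append(encode(ion, model.spec.max_len).flat)
            ok_idx.append(i)
            results.append(None)
        except EncodingError as exc:
            errors[i] = str(exc)
            results.append(None)
    if rows:
        out = model.predict_raw(np.stack(rows))
        for j, i in enumerate(ok_idx):
            if model.spec.n_outputs == 1:
                results[i] = float(out[j, 0])
            else:
                lo, hi = sorted(out[j])
                results[i] = PredictionPair(float(lo), float(hi))
    return results, errors


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) < 1e-15 or np.std(b) < 1e-15:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def evaluate(
    predictions: Sequence[PredictionPair],
    records: Sequence[CuratedRecord],
    mode: str = "paired",
) -> dict:
    """Score predictions against curated records.

    ``paired`` mode needs two-conformer records and reports per-output
    MAE, median relative error, Pearson r, and the fraction of predictions
    whose error is below the median inter-conformer CCS gap.  ``closest``
    mode scores each single observed CCS against the nearer of the two
    predictions.
    """
    if not predictions or len(predictions) != len(records):
        raise ValueError("predictions and records must be non-empty and equal length")
    pred = np.array(
        [[p.ccs_small, p.ccs_large] for p in predictions], dtype=float
    )
    if mode == "paired":
        targ = np.array(
            [sorted(r.ccs_values[:2]) for r in records], dtype=float
        )
        if any(len(r.ccs_values) < 2 for r in records):
            raise ValueError("paired mode requires two-conformer records")
        gaps = targ[:, 1] - targ[:, 0]
        median_gap = float(np.median(gaps))
        metrics = {"median_conformer_gap": median_gap, "outputs": {}}
        names = ("small", "large")
        for k in range(2):
            err = np.abs(pred[:, k] - targ[:, k])
            metrics["outputs"][names[k]] = {
                "mae": float(err.mean()),
                "median_relative_error": float(
                    np.median(err / targ[:, k])
                ),
                "pearson_r": _pearson(pred[:, k], targ[:, k]),
                "frac_error_below_median_gap": float(
                    np.mean(err < median_gap)
                ),
            }
        return metrics
    if mode == "closest":
        targ = np.array([r.ccs_values[0] for r in records], dtype=float)
        err_both = np.abs(pred - targ[:, None])
        closest = np.argmin(err_both, axis=1)
        err = err_both[np.arange(len(targ)), closest]
        chosen = pred[np.arange(len(targ)), closest]
        return {
            "mae": float(err.mean()),
            "median_relative_error": float(np.median(err / targ)),
            "pearson_r": _pearson(chosen, targ),
        }
    raise ValueError(f"unknown mode {mode!r}")
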