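"""A small fully-connected regressor with a branched multi-output head.

Implemented directly on numpy so that training is reproducible and light
enough for a single CPU.  The network has a shared dense trunk over the
flattened atomic-composition features and, for the two-output variant, two
branch heads of two dense layers each ending in a single output node.
Models serialize to a single ``.npz`` archive carrying the architecture,
scaler statistics and weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description.

    ``shared_layers`` are the trunk widths; each branch head is
    ``branch_hidden`` wide followed by a single output node.
    """

    shared_layers: tuple[int, ...] = (256, 128, 64)
    branch_hidden: int = 32
    n_outputs: int = 2
    max_len: int = 40

    def __post_init__(self) -> None:
        if self.n_outputs not in (1, 2):
            raise ValueError("n_outputs must be 1 or 2")
        if not self.shared_layers:
            raise ValueError("at least one shared layer required")


def _he_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))


class CCSModel:
    """Trunk + branch-head regressor with standardized inputs/targets."""

    def __init__(self, spec: ModelSpec, n_features: int, seed: int = 0):
        self.spec = spec
        self.n_features = n_features
        self.params: dict[str, np.ndarray] = {}
        self.x_mean = np.zeros(n_features)
        self.x_std = np.ones(n_features)
        self.y_mean = 0.0
        self.y_std = 1.0
        rng = np.random.default_rng(seed)
        fan = n_features
        for i, width in enumerate(spec.shared_layers):
            self.params[f"shared_W{i}"] = _he_init(rng, fan, width)
            self.params[f"shared_b{i}"] = np.zeros(width)
            fan = width
        for h in range(spec.n_outputs):
            self.params[f"head{h}_W0"] = _he_init(rng, fan, spec.branch_hidden)
            self.params[f"head{h}_b0"] = np.zeros(spec.branch_hidden)
            self.params[f"head{h}_W1"] = _he_init(rng, spec.branch_hidden, 1)
            self.params[f"head{h}_b1"] = np.zeros(1)

    # ------------------------------------------------------------------ math
    def set_scalers(self, X: np.ndarray, y: np.ndarray) -> None:
        """Fit input/target standardization on the training arrays."""
        self.x_mean = X.mean(axis=0)
        self.x_std = X.std(axis=0)
        self.x_std[self.x_std < 1e-12] = 1.0
        self.y_mean = float(np.mean(y))
        self.y_std = float(np.std(y)) or 1.0

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean) / self.x_std

    def forward(
        self, X: np.ndarray, cache: dict | None = None
    ) -> np.ndarray:
        """Raw branch outputs in standardized target units, shape (n, k)."""
        h = self._standardize(np.asarray(X, dtype=float))
        if cache is not None:
            cache["shared_in"] = []
        for i in range(len(self.spec.shared_layers)):
            z = h @ self.params[f"shared_W{i}"] + self.params[f"shared_b{i}"]
            if cache is not None:
                cache["shared_in"].append(h)
                cache.setdefault("shared_z", []).append(z)
            h = np.maximum(z, 0.0)
        outs = []
        if cache is not None:
            cache["trunk_out"] = h
        for k in range(self.spec.n_outputs):
            z0 = h @ self.params[f"head{k}_W0"] + self.params[f"head{k}_b0"]
            a0 = np.maximum(z0, 0.0)
            z1 = a0 @ self.params[f"head{k}_W1"] + self.params[f"head{k}_b1"]
            if cache is not None:
                cache[f"head{k}_z0"] = z0
                cache[f"head{k}_a0"] = a0
            outs.append(z1[:, 0])
        return np.stack(outs, axis=1)

    def backward(
        self, cache: dict, dout: np.ndarray
    ) -> dict[str, np.ndarray]:
        """Gradients of the loss for every parameter given d(loss)/d(outputs)."""
        grads: dict[str, np.ndarray] = {}
        h = cache["trunk_out"]
        dtrunk = np.zeros_like(h)
        for k in range(self.spec.n_outputs):
            dz1 = dout[:, k : k + 1]
            grads[f"head{k}_W1"] = cache[f"head{k}_a0"].T @ dz1
            grads[f"head{k}_b1"] = dz1.sum(axis=0)
            da0 = dz1 @ self.params[f"head{k}_W1"].T
            dz0 = da0 * (cache[f"head{k}_z0"] > 0)
            grads[f"head{k}_W0"] = h.T @ dz0
            grads[f"head{k}_b0"] = dz0.sum(axis=0)
            dtrunk += dz0 @ self.params[f"head{k}_W0"].T
        dh = dtrunk
        for i in range(len(self.spec.shared_layers) - 1, -1, -1):
            dz = dh * (cache["shared_z"][i] > 0)
            grads[f"shared_W{i}"] = cache["shared_in"][i].T @ dz
            grads[f"shared_b{i}"] = dz.sum(axis=0)
            dh = dz @ self.params[f"shared_W{i}"].T
        return grads

    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        """Outputs on the CCS scale (unsorted branch order), shape (n, k)."""
        return self.forward(X) * self.y_std + self.y_mean

    # ------------------------------------------------------------------ io
    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_params(self, params: dict[str, np.ndarray]) -> None:
        for k, v in params.items():
            if k not in self.params:
                raise KeyError(f"unexpected parameter {k}")
            if self.params[k].shape != v.shape:
                raise ValueError(
                    f"shape mismatch for {k}: "
                    f"{self.params[k].shape} vs {v.shape}"
                )
            self.params[k] = v.copy()

    def save(self, path: str | Path) -> None:
        meta = {
            "spec": {
                "shared_layers": list(self.spec.shared_layers),
                "branch_hidden": self.spec.branch_hidden,
                "n_outputs": self.spec.n_outputs,
                "max_len": self.spec.max_len,
            },
            "n_features": self.n_features,
            "y_mean": self.y_mean,
            "y_std": self.y_std,
        }
        np.savez(
            path,
            _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            x_mean=self.x_mean,
            x_std=self.x_std,
            **self.params,
        )

    @classmethod
    def load(cls, path: str | Path) -> "CCSModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["_meta"]).decode())
            spec = ModelSpec(
                shared_layers=tuple(meta["spec"]["shared_layers"]),
                branch_hidden=meta["spec"]["branch_hidden"],
                n_outputs=meta["spec"]["n_outputs"],
                max_len=meta["spec"]["max_len"],
            )
            model = cls(spec, meta["n_features"], seed=0)
            model.x_mean = data["x_mean"]
            model.x_std = data["x_std"]
            model.y_mean = meta["y_mean"]
            model.y_std = meta["y_std"]
            for k in model.params:
                model.params[k] = data[k]
        return model


class Adam:
    """Adaptive-moment optimizer over a parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )
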