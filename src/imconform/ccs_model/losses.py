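"""Loss functions for one- and two-output CCS regression.

The two-output conformer loss ties each branch to a distinct target.  The
default form sorts the targets and charges branch 1 with the smaller and
branch 2 with the larger conformer; the alternative ``assignment`` form
takes the minimum over both pairings.  Both are invariant to the order in
which the targets are supplied.
"""

from __future__ import annotations

import numpy as np


def _check_finite(*arrays: np.ndarray) -> None:
    for a in arrays:
        if not np.isfinite(a).all():
            raise ValueError("loss inputs must be finite")


def multiconf_loss(
    predictions: np.ndarray,
    targets: np.ndarray,
    form: str = "sorted",
) -> float:
    """Two-output conformer loss, averaged over samples.

    Parameters
    ----------
    predictions : (n, 2) or (2,) array — branch outputs (branch order kept).
    targets : (n, 2) or (2,) array — the two conformer CCS values, in any
        order.
    form : "sorted" (default) pairs branch 1 with the smaller target and
        branch 2 with the larger; "assignment" takes the cheaper of the two
        pairings per sample.  Both are permutation-invariant in targets.
    """
    loss, _ = multiconf_loss_grad(predictions, targets, form)
    return loss


def multiconf_loss_grad(
    predictions: np.ndarray,
    targets: np.ndarray,
    form: str = "sorted",
) -> tuple[float, np.ndarray]:
    """Loss plus gradient with respect to the predictions."""
    p = np.atleast_2d(np.asarray(predictions, dtype=float))
    t = np.atleast_2d(np.asarray(targets, dtype=float))
    _check_finite(p, t)
    if p.shape[1] != 2 or t.shape[1] != 2 or p.shape[0] != t.shape[0]:
        raise ValueError("predictions and targets must both be (n, 2)")
    n = p.shape[0]
    ts = np.sort(t, axis=1)
    if form == "sorted":
        resid = p - ts
        loss = float(np.abs(resid).mean())
        grad = np.sign(resid) / (2.0 * n)
        return loss, grad
    if form == "assignment":
        direct = np.abs(p - ts).sum(axis=1)
        swapped = np.abs(p - ts[:, ::-1]).sum(axis=1)
        use_swap = swapped < direct
        matched = np.where(use_swap[:, None], ts[:, ::-1], ts)
        resid = p - matched
        loss = float(np.minimum(direct, swapped).mean()) / 2.0
        grad = np.sign(resid) / (2.0 * n)
        return loss, grad
    raise ValueError(f"unknown loss form {form!r}")


def baseline_sum_loss(
    predictions: np.ndarray, target: np.ndarray
) -> float:
    """Sum of absolute errors of both branches against one target CCS."""
    loss, _ = baseline_sum_loss_grad(predictions, target)
    return loss


def baseline_sum_loss_grad(
    predictions: np.ndarray, target: np.ndarray
) -> tuple[float, np.ndarray]:
    """Baseline loss plus gradient with respect to the predictions."""
    p = np.atleast_2d(np.asarray(predictions, dtype=float))
    t = np.asarray(target, dtype=float).reshape(-1, 1)
    _check_finite(p, t)
    if p.shape[1] != 2 or p.shape[0] != t.shape[0]:
        raise ValueError("predictions must be (n, 2) with one target per row")
    n = p.shape[0]
    resid = p - t
    loss = float(np.abs(resid).sum(axis=1).mean())
    grad = np.sign(resid) / n
    return loss, grad


def mae_loss_grad(
    predictions: np.ndarray, target: np.ndarray
) -> tuple[float, np.ndarray]:
    """Plain single-output mean absolute error with gradient."""
    p = np.asarray(predictions, dtype=float).reshape(-1, 1)
    t = np.asarray(target, dtype=float).reshape(-1, 1)
    _check_finite(p, t)
    resid = p - t
    loss = float(np.abs(resid).mean())
    grad = np.sign(resid) / p.shape[0]
    return loss, grad
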