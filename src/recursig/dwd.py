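"""Distance-weighted discrimination (DWD) batch adjustment.

DWD finds the direction separating two batches by minimizing the sum of
inverse margins (plus a linear penalty on slack) over unit-norm directions;
systematic batch bias is removed by projecting every sample onto that
direction and translating each batch so the projected batch means coincide
with the pooled projected mean. Expression outside the span of the
direction is untouched, so the adjustment is a rank-1 translation per
batch.

The convex program

    minimize   sum_i 1/r_i + C * sum_i xi_i
    subject to r_i = y_i (w.x_i + b) + xi_i,  r_i > 0,  xi_i >= 0,  |w| <= 1

is solved in its smooth reduced form: eliminating the slack variables
analytically gives the C^1 loss  V(r) = 1/r  for r >= 1/sqrt(C)  and
V(r) = 2*sqrt(C) - C r  below, minimized over the unit ball with SLSQP in
the span of the data (an SVD-reduced coordinate system, so dimensionality
is at most the number of samples).

Genes are mean-centered and scaled to unit SD before direction finding and
the adjustment is mapped back to the original scale, the standard practice
preventing high-variance genes from dominating the direction. More than
two batches are merged successively in descending size order, each merge
adjusting the pooled set and the incoming batch onto their common mean.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

logger = logging.getLogger(__name__)


@dataclass
class DWDAdjustment:
    """One pairwise merge: direction and projected means (standardized space)."""

    direction: np.ndarray           # unit vector in standardized gene space
    batch_means: dict[str, float]   # projected means before adjustment
    pooled_mean: float              # common projected mean after adjustment


def _dwd_loss(theta: np.ndarray, Z: np.ndarray, y: np.ndarray, C: float):
    """Smooth DWD objective and gradient in reduced coordinates."""
    w, b = theta[:-1], theta[-1]
    r = y * (Z @ w + b)
    rc = 1.0 / np.sqrt(C)
    below = r < rc
    loss = np.empty_like(r)
    np.divide(1.0, np.where(below, 1.0, r), out=loss)
    loss[below] = 2.0 * np.sqrt(C) - C * r[below]
    dV = np.where(below, -C, -1.0 / np.maximum(r, rc) ** 2)
    gy = dV * y
    grad = np.concatenate([Z.T @ gy, [gy.sum()]])
    return float(loss.sum()), grad


def dwd_direction(X_a: np.ndarray, X_b: np.ndarray,
                  penalty: float | None = None) -> np.ndarray:
    """Unit DWD direction separating two batches (samples x genes inputs).

    ``penalty`` is the slack penalty C; the default is 100 / d^2 with d the
    median cross-batch pairwise distance (the convention of the method's
    reference implementation).
    """
    X_a = np.atleast_2d(np.asarray(X_a, dtype=float))
    X_b = np.atleast_2d(np.asarray(X_b, dtype=float))
    if X_a.shape[0] < 2 or X_b.shape[0] < 2:
        raise ValueError("each batch needs at least 2 samples")
    if X_a.shape[1] != X_b.shape[1]:
        raise ValueError("batches must share a common gene panel")
    X = np.vstack([X_a, X_b])
    y = np.concatenate([-np.ones(len(X_a)), np.ones(len(X_b))])
    if penalty is None:
        d2 = ((X_a[:, None, :] - X_b[None, :, :]) ** 2).sum(axis=2)
        med = np.sqrt(np.median(d2))
        penalty = 100.0 / max(med, 1e-12) ** 2
    center = X.mean(axis=0)
    Xc = X - center
    # reduce to the span of the data: at most n - 1 coordinates
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    keep = s > max(s[0], 1e-300) * 1e-12
    Vt = Vt[keep]
    Z = Xc @ Vt.T
    r = Z.shape[1]
    mu_diff = Z[y > 0].mean(axis=0) - Z[y < 0].mean(axis=0)
    nrm = np.linalg.norm(mu_diff)
    w0 = (mu_diff / nrm * 0.9) if nrm > 0 else np.zeros(r)
    theta0 = np.concatenate([w0, [0.0]])
    ball = optimize.NonlinearConstraint(
        lambda th: th[:-1] @ th[:-1], -np.inf, 1.0,
        jac=lambda th: np.concatenate([2.0 * th[:-1], [0.0]])[None, :])
    with warnings.catch_warnings():
        # the objective is linear below the critical margin; the quasi-Newton
        # Hessian update warns harmlessly there
        warnings.filterwarnings("ignore", message="delta_grad == 0.0")
        res = optimize.minimize(
            _dwd_loss, theta0, args=(Z, y, penalty), jac=True,
            method="trust-constr", constraints=[ball],
            options={"maxiter": 2000, "gtol": 1e-12, "xtol": 1e-14})
    if res.status not in (1, 2):  # gradient/step convergence
        raise RuntimeError(f"DWD solver failed: {res.message}")
    w = res.x[:-1]
    nw = np.linalg.norm(w)
    if nw == 0:
        raise RuntimeError("DWD solver returned a zero direction")
    w_full = Vt.T @ (w / nw)
    return w_full / np.linalg.norm(w_full)


def dwd_adjust(dataset, penalty: float | None = None,
               merge_order: list[str] | None = None,
               return_details: bool = False):
    """Remove additive batch bias from a multi-batch dataset.

    Batches are merged pairwise (largest first, or per ``merge_order``): at
    each merge the DWD direction between the pooled set and the incoming
    batch is computed on standardized expression, and both sides are
    translated along it so their projected means meet at the pooled mean.
    Survival columns pass through untouched.
    """
    if dataset.batch is None:
        raise ValueError("dataset has no batch labels")
    labels, counts = np.unique(dataset.batch.astype(str), return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 batches to adjust")
    small = labels[counts < 2]
    if len(small):
        raise ValueError(f"batch(es) with fewer than 2 samples: {list(small)}")
    if merge_order is None:
        merge_order = list(labels[np.argsort(-counts, kind="stable")])
    else:
        if set(merge_order) != set(labels):
            raise ValueError("merge_order must list every batch exactly once")

    mean = dataset.expr.mean(axis=1, keepdims=True)
    sd = dataset.expr.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = ((dataset.expr - mean) / sd).T        # samples x genes, standardized

    batch_str = dataset.batch.astype(str)
    pooled = np.flatnonzero(batch_str == merge_order[0])
    details = []
    for lab in merge_order[1:]:
        incoming = np.flatnonzero(batch_str == lab)
        w = dwd_direction(Z[pooled], Z[incoming], penalty=penalty)
        proj_a = Z[pooled] @ w
        proj_b = Z[incoming] @ w
        target = (proj_a.sum() + proj_b.sum()) / (len(pooled) + len(incoming))
        details.append(DWDAdjustment(
            direction=w,
            batch_means={"pooled": float(proj_a.mean()), lab: float(proj_b.mean())},
            pooled_mean=float(target)))
        Z[pooled] -= np.outer(np.full(len(pooled), proj_a.mean() - target), w)
        Z[incoming] -= np.outer(np.full(len(incoming), proj_b.mean() - target), w)
        pooled = np.concatenate([pooled, incoming])

    adjusted = Z.T * sd + mean
    out = replace(dataset, expr=adjusted)
    return (out, details) if return_details else out
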