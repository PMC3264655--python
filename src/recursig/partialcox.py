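"""Partial Cox regression: a partial-least-squares analogue for censored
outcomes.

Predictive components are built sequentially from mean-centered expression:
component k's gene weights are proportional to the per-gene univariate Cox
coefficients fitted on the current residual matrix, with the linear
predictor of the previously extracted components entering each fit as an
offset; the residual matrix is then deflated by ordinary least squares
projection off the new component. A final multivariate Cox model on the K
components, composed with the (unit-norm) weight vectors, yields one
coefficient beta_i per gene, so the risk score of sample j is the centered
linear form

    score_j = sum_i beta_i (x_ij - xbar_i)

with xbar_i the per-gene training mean. Training scores therefore have mean
zero, and samples are classified high-risk (score > 0) or low-risk
(score < 0); a score of exactly zero is assigned to the low-risk group.

The number of components K is chosen to maximize |Dxy| of the training risk
scores (smallest K attaining the maximum); a fixed K can be requested
instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import coxph
from .metrics import somers_dxy

logger = logging.getLogger(__name__)


@dataclass
class PartialCoxModel:
    """Fitted partial Cox regression: per-gene coefficients and means."""

    gene_ids: np.ndarray
    beta: np.ndarray             # per-gene coefficient, centered-expression scale
    train_means: np.ndarray      # per-gene training mean
    K: int                       # components actually used
    gamma: np.ndarray            # component-level Cox coefficients
    weights: np.ndarray          # (p, K) unit-norm weight vectors per component
    n: int
    dxy: float                   # training Dxy of the returned model
    dxy_trace: np.ndarray = field(default=None, repr=False)  # |Dxy| for K=1..

    def to_table(self):
        import pandas as pd
        return pd.DataFrame({"gene_id": self.gene_ids, "beta": self.beta,
                             "train_mean": self.train_means})

    def write(self, path) -> None:
        """Tab-delimited serialization with a metadata header."""
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"# K={self.K}\tn={self.n}\tdxy={self.dxy:.6f}\n")
            self.to_table().to_csv(fh, sep="\t", index=False,
                                   lineterminator="\n")


@dataclass
class RiskScoreSet:
    """Per-sample risk scores and sign-based two-group classification."""

    scores: np.ndarray
    groups: np.ndarray           # "high" (score > 0) / "low" (score <= 0)

    @property
    def high_mask(self) -> np.ndarray:
        return self.groups == "high"


def _build(X: np.ndarray, time, event, K: int, tol: float = 1e-9):
    """Sequential component construction; returns per-K model snapshots."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    means = X.mean(axis=0)
    Xc = X - means
    R = Xc.copy()
    Bt = np.eye(p)                       # centered X -> residual map
    comps = np.empty((n, 0))
    M = np.empty((p, 0))                 # centered X -> components
    strata_info = coxph._prepare_strata(time, event, None)
    snapshots = []                       # (beta_genes, gamma) per K
    gamma = np.empty(0)
    for _ in range(K):
        offset = comps @ gamma if comps.shape[1] else None
        res = coxph.batch_cox(R.T, time, event, offset=offset,
                              strata_info=strata_info)
        gvec = np.where(np.isfinite(res["coef"]), res["coef"], 0.0)
        norm = np.linalg.norm(gvec)
        if norm < 1e-10:
            break
        w = gvec / norm
        c = R @ w
        c_ss = float(c @ c)
        if c_ss < 1e-12:
            break
        m = Bt @ w
        comps = np.column_stack([comps, c])
        M = np.column_stack([M, m])
        # component-level Cox fit, warm-started from the previous gamma
        init = np.append(gamma, 0.0)[None, :]
        g_new, _, _, conv, _, _ = coxph._newton_batch(
            comps[None], strata_info, init=init, tol=tol)
        if not conv[0]:
            logger.warning("component-level Cox fit did not converge at K=%d",
                           comps.shape[1])
        gamma = g_new[0]
        snapshots.append((M @ gamma, gamma.copy()))
        q = (R.T @ c) / c_ss
        R = R - np.outer(c, q)
        Bt = Bt - np.outer(m, q)
    return means, M, snapshots


def fit_partial_cox(X: np.ndarray, time, event, K: int,
                    gene_ids=None) -> PartialCoxModel:
    """Fit with exactly K components (error if the data cannot support K)."""
    if K < 1:
        raise ValueError("K must be >= 1")
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.asarray(event).sum() < 1:
        raise ValueError("no events")
    means, M, snapshots = _build(X, time, event, K)
    if len(snapshots) < K:
        raise ValueError(f"only {len(snapshots)} informative components "
                         f"available (requested K={K})")
    return _model_from_snapshot(X, time, event, means, M, snapshots,
                                len(snapshots), gene_ids)


def _model_from_snapshot(X, time, event, means, M, snapshots, k, gene_ids,
                         trace=None) -> PartialCoxModel:
    beta, gamma = snapshots[k - 1]
    scores = (X - means) @ beta
    try:
        dxy = somers_dxy(scores, time, event).dxy
    except ValueError:
        dxy = np.nan
    if gene_ids is None:
        gene_ids = np.array([f"g{i}" for i in range(X.shape[1])], dtype=object)
    return PartialCoxModel(gene_ids=np.asarray(gene_ids, dtype=object),
                           beta=beta, train_means=means, K=k, gamma=gamma,
                           weights=M[:, :k], n=X.shape[0], dxy=float(dxy),
                           dxy_trace=trace)


def select_K(X: np.ndarray, time, event, K_max: int = 20,
             gene_ids=None) -> tuple[int, np.ndarray, PartialCoxModel]:
    """Choose K maximizing training |Dxy|; returns (K*, trace, fitted model).

    Fits components 1..K_max (stopping early if the residual matrix is
    exhausted), evaluates |Dxy| of the training risk scores at every K, and
    returns the smallest K attaining the maximum.
    """
    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    X = np.asarray(X, dtype=float)
    means, M, snapshots = _build(X, time, event, K_max)
    if not snapshots:
        raise ValueError("no informative component could be extracted")
    Xc = X - means
    trace = np.full(K_max, np.nan)
    for k, (beta, _) in enumerate(snapshots, start=1):
        scores = Xc @ beta
        try:
            trace[k - 1] = abs(somers_dxy(scores, time, event).dxy)
        except ValueError:
            trace[k - 1] = np.nan
    k_star = int(np.nanargmax(trace)) + 1
    model = _model_from_snapshot(X, time, event, means, M, snapshots, k_star,
                                 gene_ids, trace=trace)
    return k_star, trace, model


def fit_auto(X: np.ndarray, time, event, k_policy="select", K_max: int = 20,
             gene_ids=None) -> PartialCoxModel:
    """Fit under a K policy: ``"select"`` (maximize |Dxy|) or a fixed int."""
    if k_policy == "select":
        _, _, model = select_K(X, time, event, K_max=K_max, gene_ids=gene_ids)
        return model
    k = int(k_policy)
    # a fixed K is capped by what the data supports
    means, M, snapshots = _build(X, time, event, k)
    if not snapshots:
        raise ValueError("no informative component could be extracted")
    return _model_from_snapshot(X, time, event, means, M, snapshots,
                                min(k, len(snapshots)), gene_ids)


def risk_scores(model: PartialCoxModel, X_new: np.ndarray,
                gene_ids=None) -> RiskScoreSet:
    """Score new samples (samples x genes) with the trained centered form.

    The gene panel must equal the model's panel; pass ``gene_ids`` to align
    (and to get an error listing any missing genes).
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if gene_ids is not None:
        gene_ids = np.asarray(gene_ids, dtype=object)
        pos = {g: i for i, g in enumerate(gene_ids)}
        missing = [g for g in model.gene_ids if g not in pos]
        if missing:
            raise ValueError(f"gene panel mismatch; missing genes: {missing[:10]}")
        X_new = X_new[:, [pos[g] for g in model.gene_ids]]
    if X_new.shape[1] != len(model.beta):
        raise ValueError("gene panel mismatch: wrong number of genes")
    scores = (X_new - model.train_means) @ model.beta
    n_zero = int(np.sum(scores == 0.0))
    if n_zero:
        logger.info("%d sample(s) with risk score exactly 0 assigned to the "
                    "low-risk group", n_zero)
    groups = np.where(scores > 0, "high", "low").astype(object)
    return RiskScoreSet(scores=scores, groups=groups)
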