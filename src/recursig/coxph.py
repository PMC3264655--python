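"""Censored-survival primitives: stratified Cox regression, Schoenfeld
proportional-hazards diagnostics, Kaplan-Meier estimation, and the
Mantel-Haenszel log-rank test.

The Cox fitter maximizes the stratified partial likelihood by Newton's
method with the Efron correction for tied event times (Breslow available).
It is written as a *batched* solver: a whole panel of small models that
share the same outcome but differ in one covariate column (one model per
gene) is fitted simultaneously with vectorized risk-set accumulation. The
per-gene bootstrap screen performs on the order of 10^5 such fits, which is
why the engine is array-based rather than per-model.

Monotone partial likelihood (a perfectly separating covariate) is detected
by coefficient divergence; the affected models are refitted with a small
L2 penalty (1e-6 * n) and flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

_DIVERGE = 15.0  # |beta| beyond this is treated as monotone-likelihood divergence


# ---------------------------------------------------------------------------
# outcome pre-processing


class _SurvStratum:
    """Sorted order and Efron tie-group bookkeeping for one stratum."""

    __slots__ = ("order", "ev_pos", "grp_first_pos", "grp_starts",
                 "slot_grp", "slot_frac", "n_events")

    def __init__(self, idx: np.ndarray, time: np.ndarray, event: np.ndarray):
        t = time[idx]
        order_local = np.argsort(t, kind="stable")
        self.order = idx[order_local]
        ts = t[order_local]
        ev = event[idx][order_local].astype(bool)
        self.ev_pos = np.flatnonzero(ev)
        self.n_events = len(self.ev_pos)
        ev_times = ts[self.ev_pos]
        # tie groups: runs of equal event times
        new_grp = np.ones(self.n_events, dtype=bool)
        new_grp[1:] = ev_times[1:] != ev_times[:-1]
        self.grp_starts = np.flatnonzero(new_grp)
        grp_times = ev_times[self.grp_starts]
        # risk set at an event time t = all sorted positions with time >= t
        self.grp_first_pos = np.searchsorted(ts, grp_times, side="left")
        d = np.diff(np.append(self.grp_starts, self.n_events))
        self.slot_grp = np.repeat(np.arange(len(d)), d)
        self.slot_frac = np.concatenate([np.arange(di) / di for di in d])


def _prepare_strata(time: np.ndarray, event: np.ndarray,
                    strata: np.ndarray | None) -> list[_SurvStratum]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if strata is None:
        groups = [np.arange(len(time))]
    else:
        strata = np.asarray(strata).astype(str)
        groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    out = []
    for idx in groups:
        st = _SurvStratum(idx, time, event)
        if st.n_events == 0:
            logger.warning("dropping stratum with %d samples and no events", len(idx))
            continue
        out.append(st)
    if not out:
        raise ValueError("no events in any stratum")
    return out


def _revcumsum(a: np.ndarray, axis: int = 1) -> np.ndarray:
    return np.flip(np.cumsum(np.flip(a, axis), axis), axis)


# ---------------------------------------------------------------------------
# batched partial-likelihood evaluation


def _eval_batch(beta: np.ndarray, Xs_list, off_list, strata_info,
                breslow: bool, want_derivs: bool):
    """Penalized-free partial log-likelihood (and optionally derivatives).

    beta: (G, p); Xs_list[s]: (G, m_s, p) covariates gathered per stratum in
    time order; off_list[s]: (G, m_s) offsets or None.
    """
    G, p = beta.shape
    ll = np.zeros(G)
    grad = np.zeros((G, p)) if want_derivs else None
    info = np.zeros((G, p, p)) if want_derivs else None
    for st, Xs, off in zip(strata_info, Xs_list, off_list):
        eta = np.einsum("gmp,gp->gm", Xs, beta)
        if off is not None:
            eta = eta + off
        shift = eta.max(axis=1, keepdims=True)
        r = np.exp(eta - shift)
        rc = _revcumsum(r)
        frac = st.slot_frac if not breslow else np.zeros_like(st.slot_frac)
        R = rc[:, st.grp_first_pos]
        r_ev = r[:, st.ev_pos]
        D = np.add.reduceat(r_ev, st.grp_starts, axis=1)
        phi = R[:, st.slot_grp] - frac * D[:, st.slot_grp]
        ll += (eta[:, st.ev_pos] - shift).sum(axis=1) - np.log(phi).sum(axis=1)
        if not want_derivs:
            continue
        rx = r[:, :, None] * Xs
        rxc = _revcumsum(rx)
        Rx = rxc[:, st.grp_first_pos, :]
        Dx = np.add.reduceat(rx[:, st.ev_pos, :], st.grp_starts, axis=1)
        phix = Rx[:, st.slot_grp, :] - frac[None, :, None] * Dx[:, st.slot_grp, :]
        mu = phix / phi[:, :, None]
        grad += Xs[:, st.ev_pos, :].sum(axis=1) - mu.sum(axis=1)
        rxx = rx[:, :, :, None] * Xs[:, :, None, :]
        rxxc = _revcumsum(rxx)
        Rxx = rxxc[:, st.grp_first_pos]
        Dxx = np.add.reduceat(rxx[:, st.ev_pos], st.grp_starts, axis=1)
        phixx = Rxx[:, st.slot_grp] - frac[None, :, None, None] * Dxx[:, st.slot_grp]
        info += (phixx / phi[:, :, None, None]).sum(axis=1)
        info -= np.einsum("gsp,gsq->gpq", mu, mu)
    return ll, grad, info


def _gather(X: np.ndarray, offset: np.ndarray | None, strata_info):
    Xs_list = [X[:, st.order, :] for st in strata_info]
    off_list = [None if offset is None else offset[..., st.order]
                for st in strata_info]
    return Xs_list, off_list


def _newton_batch(X: np.ndarray, strata_info, offset=None, init=None,
                  penalty: float = 0.0, ties: str = "efron",
                  tol: float = 1e-9, max_iter: int = 60):
    """Newton-Raphson on a batch of Cox models.

    X: (G, n, p). Returns beta, info, ll, converged, n_iter, separable.
    """
    G, n, p = X.shape
    breslow = ties == "breslow"
    Xs_list, off_list = _gather(X, offset, strata_info)
    beta = np.zeros((G, p)) if init is None else np.array(init, dtype=float)
    ll, grad, info = _eval_batch(beta, Xs_list, off_list, strata_info, breslow, True)
    ll = ll - 0.5 * penalty * (beta ** 2).sum(axis=1)
    converged = np.zeros(G, dtype=bool)
    n_iter = 0
    eye = np.eye(p)
    active = np.arange(G)          # models still iterating
    for n_iter in range(1, max_iter + 1):
        sub_Xs = [Xs[active] for Xs in Xs_list]
        sub_off = [None if o is None else (o if o.shape[0] == 1 else o[active])
                   for o in off_list]
        H = info[active] + (penalty + 1e-12) * eye
        g = grad[active] - penalty * beta[active]
        try:
            step = np.linalg.solve(H, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H + 1e-8 * eye, g[..., None])[..., 0]
        np.clip(step, -2.0, 2.0, out=step)
        new_beta = beta[active] + step
        # evaluate derivatives at the candidate so accepted steps reuse them
        for _ in range(12):  # vectorized step-halving (rarely triggered)
            ll_new, grad_new, info_new = _eval_batch(
                new_beta, sub_Xs, sub_off, strata_info, breslow, True)
            ll_new = ll_new - 0.5 * penalty * (new_beta ** 2).sum(axis=1)
            bad = ~np.isfinite(ll_new) | (ll_new < ll[active] - 1e-10)
            if not bad.any():
                break
            new_beta[bad] = 0.5 * (beta[active][bad] + new_beta[bad])
        # rows where no acceptable step exists have stalled at a numerical
        # optimum (typically extreme coefficients underflowing exp); revert
        # them and stop iterating
        stalled = bad
        if stalled.any():
            new_beta[stalled] = beta[active][stalled]
            ll_new[stalled] = ll[active][stalled]
            grad_new[stalled] = grad[active][stalled]
            info_new[stalled] = info[active][stalled]
        just = (np.abs(ll_new - ll[active])
                < tol * (np.abs(ll_new) + 0.1)) | stalled
        beta[active], ll[active] = new_beta, ll_new
        grad[active], info[active] = grad_new, info_new
        converged[active[just & ~stalled]] = True
        # rows drifting beyond the divergence bound are monotone-likelihood
        # cases: stop iterating them here, the ridge refit below handles them
        diverging = np.abs(new_beta).max(axis=1) > _DIVERGE
        active = active[~just & ~diverging]
        if active.size == 0:
            break
    separable = np.abs(beta).max(axis=1) > _DIVERGE
    if separable.any() and penalty == 0.0:
        logger.warning("monotone likelihood in %d model(s); refitting with small "
                       "L2 penalty", int(separable.sum()))
        off_sub = None if offset is None else (
            offset if offset.shape[0] == 1 else offset[separable])
        sub = _newton_batch(X[separable], strata_info, off_sub, None,
                            1e-6 * n, ties, tol, max_iter)
        b2, i2, l2, c2, _, _ = sub
        beta[separable], ll[separable], converged[separable] = b2, l2, c2
        # refresh derivatives at the (partly refitted) optimum for SEs
        _, grad, info = _eval_batch(beta, Xs_list, off_list, strata_info, breslow, True)
    return beta, info, ll, converged, n_iter, separable


# ---------------------------------------------------------------------------
# public single-model interface


@dataclass
class CoxFit:
    """A fitted (optionally stratified) Cox proportional-hazards model."""

    coef: np.ndarray
    se: np.ndarray
    p: np.ndarray
    loglik: float
    cov: np.ndarray
    converged: bool
    n_iter: int
    n: int
    n_events: int
    names: list[str] = field(default_factory=list)
    ties: str = "efron"
    strata: np.ndarray | None = None
    separable: bool = False
    penalty: float = 0.0

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)


def fit_cox(X: np.ndarray, time: np.ndarray, event: np.ndarray,
            strata: np.ndarray | None = None, ties: str = "efron",
            tol: float = 1e-12, max_iter: int = 60, penalty: float = 0.0,
            offset: np.ndarray | None = None,
            names: list[str] | None = None) -> CoxFit:
    """Fit a Cox model by Newton-Raphson on the stratified partial likelihood.

    ``X`` is samples x covariates. Efron's correction is applied to tied
    event times by default. Wald standard errors and p-values come from the
    inverse observed information at the optimum.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim != 2:
        raise ValueError("X must be samples x covariates")
    n, p = X.shape
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("no events in the data")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant covariate column(s) in X")
    strata_info = _prepare_strata(time, event, strata)
    off = None if offset is None else np.asarray(offset, float)[None, :]
    beta, info, ll, conv, n_iter, sep = _newton_batch(
        X[None], strata_info, off, None, penalty, ties, tol, max_iter)
    if not conv[0]:
        logger.warning("Cox fit did not converge in %d iterations", max_iter)
    cov = _safe_inv(info[0])
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta[0] / se, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return CoxFit(coef=beta[0], se=se, p=pvals, loglik=float(ll[0]), cov=cov,
                  converged=bool(conv[0]), n_iter=n_iter, n=n,
                  n_events=int(event.sum()),
                  names=names or [f"x{i}" for i in range(p)], ties=ties,
                  strata=strata, separable=bool(sep[0]),
                  penalty=penalty if not sep[0] else 1e-6 * n)


def _safe_inv(a: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(a)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(a)


def cox_loglik(X: np.ndarray, time: np.ndarray, event: np.ndarray,
               beta: np.ndarray, strata: np.ndarray | None = None,
               ties: str = "efron", offset: np.ndarray | None = None):
    """Partial log-likelihood and score at ``beta`` (no fitting)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    strata_info = _prepare_strata(time, event, strata)
    Xs_list, off_list = _gather(X[None],
                                None if offset is None else np.asarray(offset)[None],
                                strata_info)
    ll, grad, info = _eval_batch(np.atleast_2d(np.asarray(beta, float)),
                                 Xs_list, off_list, strata_info,
                                 ties == "breslow", True)
    return float(ll[0]), grad[0], info[0]


def batch_cox(gene_expr: np.ndarray, time: np.ndarray, event: np.ndarray,
              shared: np.ndarray | None = None,
              strata: np.ndarray | None = None,
              offset: np.ndarray | None = None, ties: str = "efron",
              tol: float = 1e-9, max_iter: int = 60,
              init: np.ndarray | None = None, strata_info=None):
    """Fit G Cox models that differ only in their first covariate column.

    ``gene_expr`` is (G, n); ``shared`` (n, k) columns are appended to every
    model. Returns a dict with per-model coefficient, SE and Wald p-value of
    the gene term, plus full coefficient arrays for warm starts.
    """
    gene_expr = np.asarray(gene_expr, dtype=float)
    G, n = gene_expr.shape
    if strata_info is None:
        strata_info = _prepare_strata(time, event, strata)
    cols = [gene_expr[:, :, None]]
    if shared is not None:
        shared = np.atleast_2d(np.asarray(shared, dtype=float))
        if shared.shape[0] != n:
            shared = shared.T
        cols.append(np.broadcast_to(shared[None], (G, n, shared.shape[1])))
    X = np.concatenate(cols, axis=2) if len(cols) > 1 else cols[0]
    off = None
    if offset is not None:
        offset = np.asarray(offset, dtype=float)
        off = offset[None, :] if offset.ndim == 1 else offset
    beta, info, ll, conv, n_iter, sep = _newton_batch(
        np.ascontiguousarray(X), strata_info, off, init, 0.0, ties, tol, max_iter)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.array([_safe_inv(i) for i in info])
    var0 = cov[:, 0, 0]
    se0 = np.sqrt(np.maximum(var0, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se0 > 0, beta[:, 0] / se0, 0.0)
    p0 = 2.0 * stats.norm.sf(np.abs(z))
    return {"coef": beta[:, 0], "se": se0, "p": p0, "beta_full": beta,
            "loglik": ll, "converged": conv, "separable": sep,
            "strata_info": strata_info}


# ---------------------------------------------------------------------------
# Schoenfeld proportional-hazards diagnostics


def schoenfeld_residuals(fit: CoxFit, X: np.ndarray, time: np.ndarray,
                         event: np.ndarray):
    """Schoenfeld residuals (Efron tie handling) per event, in event-time order.

    Returns (event_times, residuals) with residuals summing to the score at
    the optimum (zero) per covariate.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    strata_info = _prepare_strata(time, event, fit.strata)
    breslow = fit.ties == "breslow"
    res, ev_times = [], []
    for st in strata_info:
        Xs = X[st.order]
        eta = Xs @ fit.coef
        shift = eta.max()
        r = np.exp(eta - shift)
        rc = _revcumsum(r[None])[0]
        rx = r[:, None] * Xs
        rxc = _revcumsum(rx[None])[0]
        frac = st.slot_frac if not breslow else np.zeros_like(st.slot_frac)
        R = rc[st.grp_first_pos]
        Rx = rxc[st.grp_first_pos]
        D = np.add.reduceat(r[st.ev_pos], st.grp_starts)
        Dx = np.add.reduceat(rx[st.ev_pos], st.grp_starts, axis=0)
        phi = R[st.slot_grp] - frac * D[st.slot_grp]
        mu = (Rx[st.slot_grp] - frac[:, None] * Dx[st.slot_grp]) / phi[:, None]
        # average the Efron risk-set means within each tie group
        d = np.diff(np.append(st.grp_starts, st.n_events))
        mu_bar = np.add.reduceat(mu, st.grp_starts, axis=0) / d[:, None]
        grp_of_event = np.repeat(np.arange(len(d)), d)
        res.append(Xs[st.ev_pos] - mu_bar[grp_of_event])
        t_sorted = np.asarray(time, float)[st.order]
        ev_times.append(t_sorted[st.ev_pos])
    res = np.vstack(res)
    ev_times = np.concatenate(ev_times)
    order = np.argsort(ev_times, kind="stable")
    return ev_times[order], res[order]


def schoenfeld_ph_test(fit: CoxFit, X: np.ndarray, time: np.ndarray,
                       event: np.ndarray, transform: str = "km"):
    """Grambsch-Therneau test of proportional hazards per covariate.

    Scaled Schoenfeld residuals are correlated with a transform of event
    time (Kaplan-Meier transform by default; ``identity`` and ``rank``
    selectable); the statistic is chi-square on 1 df per covariate.
    """
    if not fit.converged:
        raise ValueError("PH test requires a converged fit")
    event = np.asarray(event, dtype=int)
    d = int(event.sum())
    if d < 3:
        raise ValueError("PH test requires at least 3 events")
    ev_times, s = schoenfeld_residuals(fit, X, time, event)
    if transform == "km":
        km = km_estimate(time, event)
        g = 1.0 - km.survival_at(ev_times)
    elif transform == "identity":
        g = ev_times.astype(float)
    elif transform == "rank":
        g = stats.rankdata(ev_times)
    else:
        raise ValueError(f"unknown time transform {transform!r}")
    gc = g - g.mean()
    V = fit.cov
    sstar = fit.coef[None, :] + d * (s @ V.T)
    num = (gc[:, None] * sstar).sum(axis=0) ** 2
    den = d * np.diag(V) * (gc ** 2).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(den > 0, num / den, 0.0)
    return stats.chi2.sf(chi2, df=1)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


@dataclass
class KMCurve:
    """Product-limit estimate of the survivor function."""

    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # risk-set size at each event time
    n_events: np.ndarray       # events at each event time
    censor_times: np.ndarray   # censoring times (marks)

    def survival_at(self, t) -> np.ndarray:
        """Step-function evaluation (right-continuous): S(t)."""
        idx = np.searchsorted(self.times, np.atleast_1d(t), side="right")
        s = np.concatenate([[1.0], self.survival])
        out = s[idx]
        return out if np.ndim(t) else float(out[0])

    def to_table(self):
        import pandas as pd
        return pd.DataFrame({"time": self.times, "survival": self.survival,
                             "at_risk": self.at_risk, "n_events": self.n_events})


def km_estimate(time: np.ndarray, event: np.ndarray) -> KMCurve:
    """Kaplan-Meier estimator; at a tied time, events precede censorings."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise ValueError("empty input")
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    ev_times = np.unique(t[e == 1])
    n = len(t)
    at_risk = n - np.searchsorted(t, ev_times, side="left")
    d = np.array([np.sum((t == u) & (e == 1)) for u in ev_times])
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(1.0 - d / at_risk)
    return KMCurve(times=ev_times, survival=surv, at_risk=at_risk, n_events=d,
                   censor_times=np.sort(t[e == 0]))


def logrank_test(time: np.ndarray, event: np.ndarray,
                 group: np.ndarray) -> tuple[float, float]:
    """Two-group Mantel-Haenszel log-rank test (chi-square on 1 df)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) != 2:
        raise ValueError(f"log-rank test requires exactly 2 non-empty groups, "
                         f"got {len(labels)}")
    if event.sum() == 0:
        raise ValueError("no events")
    g1 = group == labels[1]
    ev_times = np.unique(time[event == 1])
    o_minus_e = 0.0
    var = 0.0
    for u in ev_times:
        at_risk = time >= u
        nj = int(at_risk.sum())
        n1j = int((at_risk & g1).sum())
        dj = int(((time == u) & (event == 1)).sum())
        d1j = int(((time == u) & (event == 1) & g1).sum())
        o_minus_e += d1j - dj * n1j / nj
        if nj > 1:
            var += dj * (n1j / nj) * (1 - n1j / nj) * (nj - dj) / (nj - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))
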