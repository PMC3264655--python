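"""Censored-outcome prediction metrics.

Harrell's concordance index C and Somers' Dxy for a continuous risk score
against right-censored survival, and time-dependent ROC / AUC(t) with the
nearest-neighbor bivariate estimator of the joint law of (marker, survival).

Sign convention (important): ``c_index`` is Harrell's C in the *risk*
direction — the probability over usable pairs that the sample with the
higher score fails earlier — so a good risk score pushes C toward 1.
``dxy`` is the rank correlation of the score with survival *time*,
Dxy = 2(C_time - 0.5) = -2(C - 0.5): a good risk score yields a *negative*
Dxy (e.g. a strong training signature gives Dxy near -0.8).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ConcordanceResult:
    """Pairwise concordance between a risk score and censored survival."""

    c_index: float      # Harrell C, risk direction (good model -> 1)
    dxy: float          # score-vs-time Somers' Dxy = -2 (C - 0.5)
    n_pairs: int        # usable (comparable) pairs under censoring


def somers_dxy(scores, time, event) -> ConcordanceResult:
    """Harrell-style pair counting under right censoring.

    A pair is usable iff the sample with the shorter follow-up has an event
    and the two times differ. A usable pair is concordant when the sample
    failing earlier carries the higher score; tied scores count 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(scores)
    if n < 2:
        raise ValueError("need at least 2 samples")
    # usable[i, j]: t_i < t_j and event_i == 1
    earlier = time[:, None] < time[None, :]
    usable = earlier & (event[:, None] == 1)
    conc = usable & (scores[:, None] > scores[None, :])
    ties = usable & (scores[:, None] == scores[None, :])
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ValueError("no usable pairs (all censored or all times tied)")
    c = (conc.sum() + 0.5 * ties.sum()) / n_usable
    return ConcordanceResult(c_index=float(c), dxy=float(-2.0 * (c - 0.5)),
                             n_pairs=n_usable)


@dataclass
class TimeROC:
    """ROC curve for marker X against event status at horizon t."""

    t: float
    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    span: float

    def to_table(self):
        import pandas as pd
        return pd.DataFrame({"cutoff": self.cutoffs,
                             "sensitivity": self.sensitivity,
                             "specificity": self.specificity})


def default_span(n: int) -> float:
    """Nearest-neighbor bandwidth 0.25 * n^(-1/5) (standard smoothing rate)."""
    return 0.25 * n ** (-0.2)


def _conditional_survival(marker: np.ndarray, time: np.ndarray,
                          event: np.ndarray, t: float, span: float) -> np.ndarray:
    """S(t | X = x_i) by Kaplan-Meier within a nearest-neighbor window.

    Neighborhoods are symmetric windows in the empirical percentile of the
    marker: j is a neighbor of i iff |F(x_j) - F(x_i)| <= span. The
    smoothing exists solely to borrow strength across the marker axis under
    censoring; when no observation is censored at or before t the
    conditional survival is the exact empirical indicator 1{T_i > t} (the
    span -> 0 limit), keeping the uncensored case free of boundary blur.
    """
    n = len(marker)
    if not np.any((event == 0) & (time <= t)):
        return (time > t).astype(float)
    order = np.argsort(marker, kind="stable")
    pct = np.empty(n)
    pct[order] = (np.arange(n) + 0.5) / n
    s = np.empty(n)
    t_o = time[order]
    e_o = event[order]
    pct_o = pct[order]
    for k in range(n):
        lo = np.searchsorted(pct_o, pct_o[k] - span, side="left")
        hi = np.searchsorted(pct_o, pct_o[k] + span, side="right")
        tt, ee = t_o[lo:hi], e_o[lo:hi]
        sub = np.argsort(tt, kind="stable")
        tt, ee = tt[sub], ee[sub]
        ev_mask = (ee == 1) & (tt <= t)
        if not ev_mask.any():
            s[order[k]] = 1.0
            continue
        m = len(tt)
        ev_t, d = np.unique(tt[ev_mask], return_counts=True)
        at_risk = m - np.searchsorted(tt, ev_t, side="left")
        s[order[k]] = np.prod(1.0 - d / at_risk)
    return s


def time_dependent_roc(marker, time, event, t: float,
                       span: float | None = None) -> TimeROC:
    """Time-dependent ROC at horizon t under right censoring.

    Cases are subjects with an event by t, controls those surviving beyond
    t; both probabilities are estimated through the nearest-neighbor
    bivariate law: sens(c,t) = [P(X>c) - S(c,t)] / [1 - S(t)] and
    spec(c,t) = 1 - S(c,t)/S(t), with S(c,t) = mean_i 1{x_i>c} S(t|x_i).
    AUC(t) is the trapezoid area after monotone cleanup of the curve.
    """
    marker = np.asarray(marker, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(marker)
    if span is None:
        span = default_span(n)
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if not np.any((time <= t) & (event == 1)):
        raise ValueError(f"no cases (events) by t={t}")
    if not np.any(time > t):
        raise ValueError(f"no controls (survivors) beyond t={t}")

    s_cond = _conditional_survival(marker, time, event, t, span)
    order = np.argsort(marker, kind="stable")
    x_sorted = marker[order]
    s_sorted = s_cond[order]
    # S_joint(c) = (1/n) sum_{x_i > c} S(t|x_i), evaluated at each cutoff;
    # cutoffs are the distinct marker values (plus -inf for the full curve).
    # Sums stay unnormalized and are divided once, so the uncensored case
    # (integer-valued sums) reduces to exact empirical proportions.
    suffix = np.concatenate([np.cumsum(s_sorted[::-1])[::-1], [0.0]])
    uniq = np.unique(x_sorted)
    pos = np.concatenate([[0], np.searchsorted(x_sorted, uniq, side="right")])
    cutoffs = np.concatenate([[-np.inf], uniq])
    tail_count = (n - pos).astype(float)    # #{X > c}
    tail_s = suffix[pos]                    # sum_{x_i > c} S(t | x_i)
    s_total = suffix[0]
    if s_total <= 0 or s_total >= n:
        raise ValueError("degenerate survival estimate at t")
    sens = np.clip((tail_count - tail_s) / (n - s_total), 0.0, 1.0)
    spec = np.clip(1.0 - tail_s / s_total, 0.0, 1.0)
    fpr = 1.0 - spec
    # monotone cleanup: sort by fpr, enforce non-decreasing sensitivity
    idx = np.lexsort((sens, fpr))
    fpr_m = np.concatenate([[0.0], fpr[idx], [1.0]])
    sens_m = np.concatenate([[0.0], np.maximum.accumulate(sens[idx]), [1.0]])
    auc = float(np.trapezoid(sens_m, fpr_m))
    return TimeROC(t=float(t), cutoffs=cutoffs, sensitivity=sens,
                   specificity=spec, auc=auc, span=float(span))


def auc_curve(marker, time, event, t_grid, span: float | None = None) -> np.ndarray:
    """AUC(t) over a grid; grid points failing preconditions yield NaN."""
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    out = np.full(len(t_grid), np.nan)
    for i, t in enumerate(t_grid):
        try:
            out[i] = time_dependent_roc(marker, time, event, t, span=span).auc
        except ValueError as exc:
            logger.warning("AUC(t=%.3g) undefined: %s", t, exc)
    if np.isnan(out).all():
        raise ValueError("AUC undefined at every grid point")
    return out
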