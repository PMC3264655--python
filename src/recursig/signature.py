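"""Signature discovery: rank-ordered forward selection under partial Cox
regression maximizing |Dxy|, wrapped in leave-one-out cross-validation with
a gene-frequency criterion, plus transfer evaluation on independent
datasets.

Forward selection walks prefixes of the ranked gene list: for each prefix
length m it fits a partial Cox model on the first m genes, records the
training |Dxy| of the resulting risk scores, and keeps the smallest prefix
attaining the maximum. LOOCV repeats the whole selection with each sample
withheld once; genes occurring in more than ``freq_threshold`` (default
50%) of the folds form the final signature. A fold never sees the withheld
sample's outcome — with ``rerank_per_fold=True`` even the bootstrap
screening is recomputed inside the fold (slower; the cheaper variant reuses
the global ranking).

Transfer evaluation follows the refit protocol: the signature is
intersected with the test platform's gene panel, the partial Cox model is
*refit on the test set* restricted to those genes (per-gene coefficients
are platform-specific), and discrimination is reported as Dxy, an AUC(t)
curve, and a log-rank comparison of the sign-based risk groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import coxph, metrics, partialcox, ranking as ranking_mod
from .datasets import SurvivalDataset

logger = logging.getLogger(__name__)


@dataclass
class Signature:
    """Final gene list with LOOCV occurrence frequencies and audit trail."""

    genes: list[str]
    frequencies: dict[str, float]        # per-gene LOOCV occurrence frequency
    freq_threshold: float
    fold_subsets: list[list[str]] = field(repr=False, default_factory=list)
    config: dict = field(default_factory=dict)

    def write(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"gene_id": self.genes,
                      "loocv_frequency": [self.frequencies[g] for g in self.genes]
                      }).to_csv(path, sep="\t", index=False, lineterminator="\n")


@dataclass
class TransferReport:
    """Performance of a signature refit on an independent dataset."""

    name: str
    genes_present: int
    signature_size: int
    dxy: float
    auc_times: np.ndarray
    auc: np.ndarray
    mean_auc: float
    logrank_chi2: float | None
    logrank_p: float | None
    scores: np.ndarray = field(repr=False, default=None)
    groups: np.ndarray = field(repr=False, default=None)
    km_low: coxph.KMCurve = field(repr=False, default=None)
    km_high: coxph.KMCurve = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            f"transfer evaluation: {self.name}",
            f"  signature genes on platform: {self.genes_present}/{self.signature_size}",
            f"  Somers' Dxy (score vs time): {self.dxy:+.4f}",
            f"  mean AUC(t) over {len(self.auc_times)} horizon(s): {self.mean_auc:.4f}",
        ]
        if self.logrank_p is None:
            lines.append("  log-rank: undefined (single risk group)")
        else:
            lines.append(f"  log-rank chi2={self.logrank_chi2:.3f} "
                         f"p={self.logrank_p:.3g}")
        return "\n".join(lines)


def forward_select(dataset: SurvivalDataset, ranked_genes: list[str],
                   max_genes: int | None = None, k_policy="select",
                   k_max: int = 20) -> tuple[list[str], np.ndarray]:
    """Best prefix of the ranked list by training |Dxy| under partial Cox.

    Returns (gene subset, |Dxy| trace over prefix lengths; NaN where a
    prefix fit failed).
    """
    if not ranked_genes:
        raise ValueError("ranked gene list is empty")
    if max_genes is None:
        max_genes = len(ranked_genes)
    max_genes = min(max_genes, len(ranked_genes))
    idx = dataset.gene_index(ranked_genes[:max_genes])
    Xfull = dataset.expr[idx].T
    trace = np.full(max_genes, np.nan)
    for m in range(1, max_genes + 1):
        try:
            model = partialcox.fit_auto(Xfull[:, :m], dataset.time, dataset.event,
                                        k_policy=k_policy,
                                        K_max=min(k_max, m))
            trace[m - 1] = abs(model.dxy)
        except ValueError as exc:
            logger.warning("forward selection skipped prefix m=%d: %s", m, exc)
    if np.isnan(trace).all():
        raise ValueError("every prefix fit failed")
    best = int(np.nanargmax(trace)) + 1
    return list(ranked_genes[:best]), trace


def loocv_signature(dataset: SurvivalDataset, B: int = 200, alpha: float = 0.01,
                    screen_threshold: float = 0.80, freq_threshold: float = 0.5,
                    rerank_per_fold: bool = True, max_genes: int = 120,
                    k_policy="select", k_max: int = 20, seed: int = 0,
                    ranking: ranking_mod.GeneRanking | None = None) -> Signature:
    """Leave-one-out cross-validated signature selection.

    Each of the n folds drops one sample, (re)ranks genes, screens at the
    bootstrap-frequency threshold, and runs forward selection; the final
    signature keeps genes present in strictly more than ``freq_threshold``
    of the usable folds, ordered by frequency.
    """
    n = dataset.n_samples
    if n < 10:
        raise ValueError("LOOCV needs at least 10 samples")
    rng = np.random.default_rng(seed)
    rank_seed = int(rng.integers(2 ** 31))
    global_ranking = ranking if ranking is not None else \
        ranking_mod.bootstrap_frequencies(dataset, B=B, alpha=alpha,
                                          seed=rank_seed)
    global_screen = ranking_mod.select_screened(global_ranking, screen_threshold)

    fold_sets: list[list[str]] = []
    n_folds = 0
    for i in range(n):
        keep = np.r_[0:i, i + 1:n]
        fold = dataset.subset_samples(keep)
        if fold.event.sum() == 0:
            logger.warning("fold %d has no events; skipped", i)
            continue
        if rerank_per_fold:
            fold_ranking = ranking_mod.bootstrap_frequencies(
                fold, B=B, alpha=alpha, seed=int(rng.integers(2 ** 31)))
            screened = ranking_mod.select_screened(fold_ranking, screen_threshold)
        else:
            screened = global_screen
        n_folds += 1
        if not screened:
            fold_sets.append([])
            continue
        try:
            subset, _ = forward_select(fold, screened, max_genes=max_genes,
                                       k_policy=k_policy, k_max=k_max)
        except ValueError as exc:
            logger.warning("fold %d forward selection failed: %s", i, exc)
            subset = []
        fold_sets.append(subset)

    if n_folds == 0:
        raise ValueError("no usable LOOCV fold")
    counts: dict[str, int] = {}
    for subset in fold_sets:
        for g in subset:
            counts[g] = counts.get(g, 0) + 1
    freqs = {g: c / n_folds for g, c in counts.items()}
    rank_of = {g: r for r, g in enumerate(global_ranking.ranked_genes())}
    genes = sorted([g for g, f in freqs.items() if f > freq_threshold],
                   key=lambda g: (-freqs[g], rank_of.get(g, np.inf), g))
    if not genes:
        logger.warning("LOOCV produced an empty signature")
    return Signature(genes=genes, frequencies=freqs,
                     freq_threshold=freq_threshold, fold_subsets=fold_sets,
                     config={"B": B, "alpha": alpha,
                             "screen_threshold": screen_threshold,
                             "rerank_per_fold": rerank_per_fold,
                             "max_genes": max_genes, "k_policy": str(k_policy),
                             "k_max": k_max, "seed": seed, "n_folds": n_folds})


def transfer_evaluate(signature, test_dataset: SurvivalDataset,
                      k_policy="select", k_max: int = 20,
                      t_grid=None, span: float | None = None,
                      name: str = "test") -> TransferReport:
    """Refit the signature's risk-score model on an independent dataset.

    Only signature genes present on the test platform are used (at least
    2); the partial Cox fit, risk scores, Dxy, AUC(t) and the log-rank test
    between sign-based risk groups are all computed on the test set.
    """
    genes = list(signature.genes) if isinstance(signature, Signature) else list(signature)
    present = [g for g in genes if g in set(test_dataset.gene_ids)]
    if len(present) < 2:
        raise ValueError(f"only {len(present)} signature gene(s) on the test "
                         "platform; need at least 2")
    if test_dataset.event.sum() < 1:
        raise ValueError("test dataset has no events")
    X = test_dataset.expr[test_dataset.gene_index(present)].T
    model = partialcox.fit_auto(X, test_dataset.time, test_dataset.event,
                                k_policy=k_policy, K_max=min(k_max, len(present)),
                                gene_ids=present)
    rs = partialcox.risk_scores(model, X)
    conc = metrics.somers_dxy(rs.scores, test_dataset.time, test_dataset.event)
    if t_grid is None:
        ev = np.sort(test_dataset.time[test_dataset.event == 1])
        t_grid = np.unique(np.quantile(ev, [0.25, 0.5, 0.75]))
    auc = metrics.auc_curve(rs.scores, test_dataset.time, test_dataset.event,
                            t_grid, span=span)
    high = rs.high_mask
    if high.all() or (~high).all():
        logger.warning("all samples fell in one risk group; log-rank undefined")
        chi2 = pval = None
        km_low = km_high = None
    else:
        chi2, pval = coxph.logrank_test(test_dataset.time, test_dataset.event,
                                        high.astype(int))
        km_low = coxph.km_estimate(test_dataset.time[~high],
                                   test_dataset.event[~high])
        km_high = coxph.km_estimate(test_dataset.time[high],
                                    test_dataset.event[high])
    return TransferReport(name=name, genes_present=len(present),
                          signature_size=len(genes), dxy=conc.dxy,
                          auc_times=np.atleast_1d(t_grid), auc=auc,
                          mean_auc=float(np.nanmean(auc)),
                          logrank_chi2=chi2, logrank_p=pval,
                          scores=rs.scores, groups=rs.groups,
                          km_low=km_low, km_high=km_high)
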