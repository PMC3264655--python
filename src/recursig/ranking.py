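"""Per-gene recurrence screening by stratified Cox models under bootstrap
resampling.

Each gene is screened with a Cox model containing the gene's expression and
age, stratified by gender x stage (the categorical covariates get their own
baseline hazards rather than coefficients, the appropriate treatment when
they violate proportional hazards). The screen is repeated over B bootstrap
resamples of the samples — stratified by the Cox strata so no resample
empties a stratum — and each gene's bootstrap frequency is the fraction of
resamples in which its Wald p-value falls below alpha. Genes are ranked by
frequency (ties broken by full-data p-value, then identifier), and the
screened list keeps genes with frequency strictly above the threshold
(default 80%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import coxph
from .datasets import SurvivalDataset

logger = logging.getLogger(__name__)


@dataclass
class GeneRanking:
    """Per-gene hazard ratios, p-values and bootstrap frequencies."""

    table: pd.DataFrame          # index gene_id; HR, p, bootstrap_freq, rank
    B: int
    alpha: float

    def ranked_genes(self) -> list[str]:
        return list(self.table.sort_values("rank").index)

    def write(self, path) -> None:
        out = self.table.sort_values("rank").reset_index()
        out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def per_gene_cox(dataset: SurvivalDataset) -> pd.DataFrame:
    """Stratified, age-adjusted Cox screen of every gene on the full data.

    Returns a frame indexed by gene with ``HR`` (hazard ratio of the gene
    term), ``p`` (Wald) and a ``constant`` flag; constant genes are recorded
    with HR=1, p=1.
    """
    const = np.ptp(dataset.expr, axis=1) == 0
    hr = np.ones(dataset.n_genes)
    pval = np.ones(dataset.n_genes)
    if (~const).any():
        res = coxph.batch_cox(dataset.expr[~const], dataset.time, dataset.event,
                              shared=dataset.age[:, None],
                              strata=dataset.strata_labels())
        hr[~const] = np.exp(res["coef"])
        pval[~const] = res["p"]
    if const.any():
        logger.warning("%d constant gene(s) recorded with HR=1, p=1",
                       int(const.sum()))
    return pd.DataFrame({"HR": hr, "p": pval, "constant": const},
                        index=pd.Index(dataset.gene_ids, name="gene_id"))


def _stratified_resample(rng, strata_idx: list[np.ndarray],
                         event: np.ndarray, max_attempts: int = 100) -> np.ndarray:
    """Bootstrap sample indices, within-stratum, requiring >=1 event each."""
    for _ in range(max_attempts):
        draw = np.concatenate([rng.choice(idx, size=len(idx), replace=True)
                               for idx in strata_idx])
        ok = True
        start = 0
        for idx in strata_idx:
            part = draw[start:start + len(idx)]
            start += len(idx)
            if event[part].sum() == 0:
                ok = False
                break
        if ok:
            return draw
        logger.info("bootstrap resample left a stratum without events; redrawing")
    raise RuntimeError("could not draw a bootstrap resample with events in "
                       f"every stratum after {max_attempts} attempts")


def bootstrap_frequencies(dataset: SurvivalDataset, B: int = 1000,
                          alpha: float = 0.01, seed: int = 0) -> GeneRanking:
    """Bootstrap frequency f_g = #{resamples with p_g < alpha} / B per gene."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    full = per_gene_cox(dataset)
    const = full["constant"].values
    labels = dataset.strata_labels()
    strata_idx = [np.flatnonzero(labels == s) for s in np.unique(labels.astype(str))]
    expr = dataset.expr[~const]
    age = dataset.age
    counts = np.zeros(dataset.n_genes)
    warm = None
    for _ in range(B):
        draw = _stratified_resample(rng, strata_idx, dataset.event)
        res = coxph.batch_cox(expr[:, draw], dataset.time[draw],
                              dataset.event[draw], shared=age[draw, None],
                              strata=labels[draw], init=warm)
        warm = res["beta_full"]
        counts[~const] += (res["p"] < alpha)
    freq = counts / B
    table = full.assign(bootstrap_freq=freq)
    order = table.reset_index().sort_values(
        ["bootstrap_freq", "p", "gene_id"], ascending=[False, True, True])
    table.loc[order["gene_id"].values, "rank"] = np.arange(1, len(table) + 1)
    table["rank"] = table["rank"].astype(int)
    return GeneRanking(table=table, B=B, alpha=alpha)


def select_screened(ranking: GeneRanking,
                    freq_threshold: float = 0.80) -> list[str]:
    """Genes with bootstrap frequency strictly above the threshold, ranked."""
    tab = ranking.table
    keep = tab[tab["bootstrap_freq"] > freq_threshold].sort_values("rank")
    if keep.empty:
        logger.warning("no gene passed the bootstrap frequency threshold %.2f",
                       freq_threshold)
    return list(keep.index)
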