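"""Pathway-level survival scans.

For each gene set, a partial Cox model restricted to the set's genes (those
present in the dataset) produces per-sample risk scores; samples are
dichotomized at score zero and the two risk groups are compared with the
Mantel-Haenszel log-rank test. Sets are flagged significant at a raw
p-value threshold (default 1e-4); no multiple-testing correction is
applied, but a Bonferroni-adjusted column is emitted for reference.

Caveat, documented rather than corrected: the dichotomization reuses the
outcome that the log-rank test then evaluates, so nominal p-values are
optimistic. Interpret the scan as a ranking of pathways, not as calibrated
hypothesis tests.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import coxph, partialcox
from .datasets import GeneSetCollection, SurvivalDataset

logger = logging.getLogger(__name__)


def pathway_survival_scan(dataset: SurvivalDataset,
                          gene_sets: GeneSetCollection,
                          alpha: float = 1e-4, k_policy="select",
                          k_max: int = 20, min_genes: int = 2) -> pd.DataFrame:
    """Log-rank significance of risk-score groups per pathway.

    Returns a frame (set, n_genes_present, chi2, p, p_bonferroni,
    significant) sorted by p ascending. Sets with fewer than ``min_genes``
    genes present are skipped with a log entry; duplicate genes within a
    set count once.
    """
    if len(gene_sets) == 0:
        raise ValueError("empty gene set collection")
    panel = set(dataset.gene_ids)
    rows = []
    for name, members in gene_sets.sets.items():
        present = sorted(set(members) & panel)
        if len(present) < min_genes:
            logger.info("pathway %s skipped: %d gene(s) present", name,
                        len(present))
            continue
        X = dataset.expr[dataset.gene_index(present)].T
        try:
            model = partialcox.fit_auto(X, dataset.time, dataset.event,
                                        k_policy=k_policy,
                                        K_max=min(k_max, len(present)),
                                        gene_ids=present)
        except ValueError as exc:
            logger.warning("pathway %s fit failed: %s", name, exc)
            continue
        rs = partialcox.risk_scores(model, X)
        high = rs.high_mask
        if high.all() or (~high).all():
            chi2, p = np.nan, np.nan
        else:
            chi2, p = coxph.logrank_test(dataset.time, dataset.event,
                                         high.astype(int))
        rows.append({"set": name, "n_genes_present": len(present),
                     "chi2": chi2, "p": p})
    if not rows:
        raise ValueError("no gene set could be scanned")
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    out["significant"] = out["p"] < alpha
    return out.sort_values("p", kind="stable").reset_index(drop=True)
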