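"""Significance-thresholded signed Pearson correlation networks.

An edge joins two taxa when the absolute Pearson correlation of their
autoscaled biomass across samples reaches the two-tailed critical value
at the chosen significance level for the pair's sample size:

    r_crit = t / sqrt(t^2 + n - 2),   t = t-quantile(1 - alpha/2, n - 2)

so that |r| >= r_crit is exactly the P <= alpha decision of the usual
t test for a correlation coefficient.  Edges keep the signed r, its
sign, and |r| as weight; taxa that end up without any significant
partner stay in the node set, flagged as isolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "critical_r",
    "pearson_matrix",
    "threshold_network",
    "correlation_pvalues",
]

logger = logging.getLogger(__name__)

MIN_PAIR_N = 4


@dataclass(frozen=True)
class CorrelationResult:
    """Pairwise-complete Pearson correlations with per-pair critical thresholds.

    ``r``, ``n_eff`` and ``r_crit`` are symmetric taxon x taxon frames;
    pairs with fewer than four complete observations carry NaN in ``r``.
    """

    taxa: tuple[str, ...]
    r: pd.DataFrame
    n_eff: pd.DataFrame
    alpha: float
    r_crit: pd.DataFrame


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Two-tailed critical |r| for a Pearson correlation at sample size n.

    Strictly decreasing in n for fixed alpha; at n = 5, alpha = 0.05 it
    reproduces the textbook table value 0.878 for df = 3.
    """
    if n < MIN_PAIR_N:
        raise ValueError(f"need n >= {MIN_PAIR_N} observations, got {n}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    t = stats.t.ppf(1 - alpha / 2, n - 2)
    return float(t / np.sqrt(t**2 + n - 2))


def pearson_matrix(scaled: pd.DataFrame, alpha: float = 0.05) -> CorrelationResult:
    """All-pairs Pearson correlation with pairwise-complete handling of missing cells.

    Each pair uses the samples where both taxa are present; the per-pair
    count n_eff feeds the critical threshold.  Pairs with n_eff < 4 are
    dropped (NaN) and logged.
    """
    taxa = tuple(scaled.columns)
    present = scaled.notna().to_numpy()
    n_eff = pd.DataFrame(
        present.T.astype(int) @ present.astype(int), index=taxa, columns=taxa
    )
    r = scaled.corr(method="pearson", min_periods=MIN_PAIR_N)
    r = r.reindex(index=list(taxa), columns=list(taxa))
    iu = np.triu_indices(len(taxa), k=1)
    short = [
        (taxa[i], taxa[j])
        for i, j in zip(*iu)
        if n_eff.iat[i, j] < MIN_PAIR_N
    ]
    if short:
        logger.warning("%d taxon pairs have < %d complete observations and were dropped: %s",
                       len(short), MIN_PAIR_N, short[:10])

    crit = np.full((len(taxa), len(taxa)), np.nan)
    for i, j in zip(*iu):
        n = int(n_eff.iat[i, j])
        if n >= MIN_PAIR_N:
            crit[i, j] = crit[j, i] = critical_r(n, alpha)
    r_crit = pd.DataFrame(crit, index=taxa, columns=taxa)
    return CorrelationResult(taxa, r, n_eff, alpha, r_crit)


def correlation_pvalues(c: CorrelationResult) -> pd.DataFrame:
    """Two-tailed p-values of every pairwise correlation (t test, df = n - 2)."""
    taxa = list(c.taxa)
    p = np.full((len(taxa), len(taxa)), np.nan)
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            r = c.r.iat[i, j]
            n = int(c.n_eff.iat[i, j])
            if not np.isfinite(r) or n < MIN_PAIR_N:
                continue
            if abs(r) >= 1.0:
                p[i, j] = p[j, i] = 0.0
                continue
            t = abs(r) * np.sqrt((n - 2) / (1 - r * r))
            p[i, j] = p[j, i] = 2 * stats.t.sf(t, n - 2)
    return pd.DataFrame(p, index=taxa, columns=taxa)


def threshold_network(c: CorrelationResult, correction: str = "none") -> nx.Graph:
    """Build the signed network of significant correlations.

    With ``correction='none'`` an edge appears iff |r| >= r_crit for the
    pair's sample size (the P <= alpha rule).  With
    ``correction='benjamini_hochberg'`` the pairwise p-values are BH
    adjusted and edges keep only the rejected pairs.  Isolated taxa stay
    in the node set with ``isolated=True``.
    """
    if correction not in ("none", "benjamini_hochberg"):
        raise ValueError(f"unknown correction {correction!r}; use 'none' or 'benjamini_hochberg'")
    taxa = list(c.taxa)
    g = nx.Graph(alpha=c.alpha, correction=correction)
    g.add_nodes_from(taxa)

    iu = np.triu_indices(len(taxa), k=1)
    pairs = [(i, j) for i, j in zip(*iu) if np.isfinite(c.r.iat[i, j])]
    if correction == "benjamini_hochberg" and pairs:
        pmat = correlation_pvalues(c)
        pvals = [pmat.iat[i, j] for i, j in pairs]
        reject = multipletests(pvals, alpha=c.alpha, method="fdr_bh")[0]
        keep = {pair for pair, rej in zip(pairs, reject) if rej}
    else:
        keep = {
            (i, j)
            for i, j in pairs
            if abs(c.r.iat[i, j]) >= c.r_crit.iat[i, j]
        }
    for i, j in sorted(keep):
        r = float(c.r.iat[i, j])
        g.add_edge(taxa[i], taxa[j], r=r, sign="+" if r > 0 else "-", weight=abs(r))
    for node in g.nodes:
        g.nodes[node]["isolated"] = g.degree(node) == 0
    return g
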