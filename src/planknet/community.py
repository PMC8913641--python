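"""Community-level statistics: autoscaling, diversity indices, class comparisons.

Autoscaling (z-score standardisation per taxon) precedes correlation
analysis.  Shannon diversity H' and Pielou evenness J' are computed from
biomass shares per sample.  Between-class differences are tested with
one-way ANOVA plus Tukey HSD letter groups, or the Kruskal-Wallis test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import BiomassMatrix

__all__ = [
    "DiversityRecord",
    "ComparisonResult",
    "autoscale",
    "diversity",
    "diversity_table",
    "compare_classes",
]

logger = logging.getLogger(__name__)

_LOG = {"e": math.log, 2: math.log2, 10: math.log10, "2": math.log2, "10": math.log10}


@dataclass(frozen=True)
class DiversityRecord:
    """Richness S, Shannon H' and Pielou J' for one sample.

    ``pielou_j`` is None when S < 2 (evenness is undefined for a
    single-taxon sample).
    """

    sample_id: str | None
    richness: int
    shannon_h: float
    pielou_j: float | None


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a between-class test on one variable.

    ``tukey_groups`` maps class names to superscript-style letter
    groups: classes sharing no letter differ at the stated alpha.
    Present only for ANOVA.
    """

    variable: str
    test: str
    statistic: float
    df: tuple[int, ...]
    p_value: float
    tukey_groups: dict[str, str] | None = None


# ---------------------------------------------------------------------------
# Autoscaling
# ---------------------------------------------------------------------------

def autoscale(m: BiomassMatrix | pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Standardise every taxon column to mean 0, sample sd 1.

    Missing cells stay missing; statistics use the present values only.
    Columns with zero variance (or fewer than two present values) carry
    no correlation information and are dropped; the drop list is
    returned and logged.
    """
    values = m.values if isinstance(m, BiomassMatrix) else m
    dropped: list[str] = []
    cols = {}
    for taxon in values.columns:
        col = values[taxon].astype(float)
        present = col.dropna()
        sd = present.std(ddof=1)
        if len(present) < 2 or not np.isfinite(sd) or sd == 0:
            dropped.append(taxon)
            continue
        cols[taxon] = (col - present.mean()) / sd
    if dropped:
        logger.warning("autoscale dropped %d zero-variance taxa: %s", len(dropped), dropped)
    return pd.DataFrame(cols, index=values.index), dropped


# ---------------------------------------------------------------------------
# Diversity indices
# ---------------------------------------------------------------------------

def diversity(
    biomass: Sequence[float],
    log_base: str | int = "e",
    sample_id: str | None = None,
) -> DiversityRecord:
    """Shannon H' and Pielou J' from one sample's biomass vector.

    H' = -sum p_i log p_i over taxa with positive biomass, with p_i the
    biomass share; J' = H'/log S.  Natural log by default.
    """
    log = _LOG[log_base]
    x = np.asarray(biomass, dtype=float)
    x = x[np.isfinite(x)]
    if np.any(x < 0):
        raise ValueError("biomass values must be non-negative")
    x = x[x > 0]
    if x.size == 0:
        raise ValueError(
            f"diversity is undefined for an all-zero biomass vector (sample {sample_id!r})"
        )
    p = x / x.sum()
    h = float(-np.sum(p * np.array([log(v) for v in p])))
    s = int(x.size)
    j = h / log(s) if s >= 2 else None
    return DiversityRecord(sample_id, s, h, j)


def diversity_table(m: BiomassMatrix, log_base: str | int = "e") -> pd.DataFrame:
    """Per-sample diversity records as a DataFrame (all-zero samples skipped)."""
    rows = []
    for sid in m.sample_ids:
        vec = m.values.loc[sid].to_numpy(dtype=float)
        vec = np.nan_to_num(vec, nan=0.0)
        if not np.any(vec > 0):
            logger.warning("sample %s has no positive biomass; diversity skipped", sid)
            continue
        rec = diversity(vec, log_base, sample_id=sid)
        rows.append(
            {
                "sample_id": rec.sample_id,
                "richness": rec.richness,
                "shannon_h": rec.shannon_h,
                "pielou_j": rec.pielou_j,
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "richness", "shannon_h", "pielou_j"])


# ---------------------------------------------------------------------------
# Between-class tests
# ---------------------------------------------------------------------------

def _tukey_letters(groups: dict[str, np.ndarray], alpha: float) -> dict[str, str]:
    """Compact letter display from pairwise Tukey HSD decisions.

    Classes are letter-grouped via the maximal cliques of the
    "not significantly different" graph, the standard way superscript
    letters in summary tables are produced.
    """
    names = sorted(groups, key=lambda g: -float(np.mean(groups[g])))
    if len(names) == 1:
        return {names[0]: "a"}
    data = np.concatenate([groups[g] for g in names])
    labels = np.concatenate([[g] * len(groups[g]) for g in names])
    with np.errstate(divide="ignore", invalid="ignore"):  # zero within-group variance
        res = pairwise_tukeyhsd(data, labels, alpha=alpha)
    nonsig = nx.Graph()
    nonsig.add_nodes_from(names)
    uniq = [str(g) for g in res.groupsunique]
    pairs = [(uniq[i], uniq[j]) for i in range(len(uniq)) for j in range(i + 1, len(uniq))]
    for (g1, g2), reject in zip(pairs, np.asarray(res.reject)):
        if not reject:
            nonsig.add_edge(g1, g2)
    cliques = [sorted(c, key=names.index) for c in nx.find_cliques(nonsig)]
    cliques.sort(key=lambda c: names.index(c[0]))
    letters: dict[str, list[str]] = {g: [] for g in names}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for g in clique:
            letters[g].append(letter)
    return {g: "".join(sorted(ls)) for g, ls in letters.items()}


def compare_classes(
    groups: Mapping[str, Sequence[float]],
    method: str = "anova",
    alpha: float = 0.05,
    variable: str = "",
    letters: bool = True,
) -> ComparisonResult:
    """Test whether a variable differs between turbidity classes.

    ``anova`` runs one-way ANOVA with conventional df (k-1, N-k) and
    attaches Tukey HSD letter groups at ``alpha`` (skipped when
    ``letters=False``; the studentized-range quantile dominates the
    runtime); ``kruskal_wallis`` runs the rank-based test with df k-1.
    """
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    k = len(arrays)
    n_total = sum(v.size for v in arrays.values())
    values = list(arrays.values())

    if method == "anova":
        all_equal = len({float(x) for v in values for x in v}) == 1
        if all_equal:
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.f_oneway(*values)
            if not np.isfinite(stat):  # zero within-group variance, equal means
                stat, p = 0.0, 1.0
        groups_out = None
        if letters:
            groups_out = _tukey_letters(arrays, alpha) if not all_equal else {g: "a" for g in arrays}
        return ComparisonResult(variable, "anova", float(stat), (k - 1, n_total - k), float(p), groups_out)
    if method == "kruskal_wallis":
        if len({float(x) for v in values for x in v}) == 1:
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.kruskal(*values)
        return ComparisonResult(variable, "kruskal_wallis", float(stat), (k - 1,), float(p))
    raise ValueError(f"unknown method {method!r}; use 'anova' or 'kruskal_wallis'")
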