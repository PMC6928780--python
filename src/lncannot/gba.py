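"""Guilt-by-association annotation of a single target gene.

The pipeline: Spearman-correlate every other gene with the target across the
cohort, take the top fraction of genes by correlation, and ask — via the
hypergeometric over-representation test — which annotated gene sets are
enriched in that selection. Function is then imputed to the target from the
enriched sets of its co-expressed neighbours.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "CorrelationResult",
    "CorrelationRanking",
    "OraResult",
    "correlate_all",
    "select_top_fraction",
    "ora",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    gene_id: str
    rho: float
    p_value: float
    rank: int  # 1-based position in descending-rho order


@dataclass
class CorrelationRanking:
    """All-vs-one correlation results, sorted by descending rho.

    Behaves as a sequence of :class:`CorrelationResult`. ``excluded`` lists
    genes dropped because their expression had zero variance (Spearman is
    undefined there).
    """

    target: str
    results: list[CorrelationResult]
    excluded: list[str]

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    def __getitem__(self, i):
        return self.results[i]


def _spearman_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p via the t approximation with n-2 df (reporting only)."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    return np.clip(p, 0.0, 1.0)


def correlate_all(m: ExpressionMatrix, target: str) -> CorrelationRanking:
    """Spearman correlation of every gene against the target gene.

    Average ranks are used for ties (so the result is invariant under any
    strictly monotone transform of either gene). The target itself and any
    zero-variance gene are excluded; exclusions are recorded on the result.
    Output is sorted by descending rho, ties broken by gene id.
    """
    if m.n_samples < 3:
        raise ValueError("Spearman correlation needs at least 3 samples")
    ti = m.gene_index(target)  # raises KeyError if absent
    n = m.n_samples

    ranks = stats.rankdata(m.values, axis=1)  # average ranks for ties
    target_ranks = ranks[ti]
    if np.ptp(target_ranks) == 0:
        raise ValueError(f"target gene {target!r} has zero variance")

    sd = ranks.std(axis=1)
    keep = (sd > 0) & (np.arange(m.n_genes) != ti)
    excluded = [
        g
        for i, g in enumerate(m.gene_ids)
        if sd[i] == 0 and i != ti
    ]
    if excluded:
        logger.warning(
            "excluding %d zero-variance genes from correlation", len(excluded)
        )

    centered = ranks - ranks.mean(axis=1, keepdims=True)
    tc = centered[ti]
    denom = np.sqrt((centered**2).sum(axis=1)) * np.sqrt((tc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (centered @ tc) / denom
    rho = np.clip(rho, -1.0, 1.0)

    idx = np.flatnonzero(keep)
    pvals = _spearman_p(rho[idx], n)
    order = sorted(
        range(len(idx)), key=lambda k: (-rho[idx[k]], m.gene_ids[idx[k]])
    )
    results = [
        CorrelationResult(
            gene_id=m.gene_ids[idx[k]],
            rho=float(rho[idx[k]]),
            p_value=float(pvals[k]),
            rank=r + 1,
        )
        for r, k in enumerate(order)
    ]
    return CorrelationRanking(target=target, results=results, excluded=excluded)


def select_top_fraction(
    ranked: CorrelationRanking | list[CorrelationResult],
    fraction: float,
    direction: str = "top",
) -> list[str]:
    """Select ``ceil(fraction * N)`` genes from a correlation ranking.

    ``direction='top'`` takes the most positively correlated prefix,
    ``'bottom'`` the most negatively correlated suffix, ``'abs'`` the genes
    of largest |rho|. The ceil convention makes 5% of 19,547 tested genes a
    selection of exactly 978.
    """
    results = list(ranked)
    if not results:
        raise ValueError("empty ranking")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if direction not in ("top", "bottom", "abs"):
        raise ValueError(f"unknown direction {direction!r}")
    k = math.ceil(fraction * len(results))
    if direction == "top":
        chosen = results[:k]
    elif direction == "bottom":
        chosen = results[-k:]
    else:
        chosen = sorted(results, key=lambda r: (-abs(r.rho), r.gene_id))[:k]
    return [r.gene_id for r in chosen]


@dataclass(frozen=True)
class OraResult:
    set_name: str
    overlap: int  # k
    set_size: int  # K, within the universe
    selected: int  # n
    universe: int  # N
    p_value: float  # hypergeometric upper tail P[X >= k]
    q_value: float  # Benjamini-Hochberg across retained sets


def ora(
    selected: set[str] | list[str],
    universe: set[str] | list[str],
    collection: GeneSetCollection,
    min_size: int = 5,
    max_size: int = 500,
) -> list[OraResult]:
    """Hypergeometric over-representation of ``selected`` in each gene set.

    Sets are intersected with ``universe`` first and dropped when the
    intersection size falls outside ``[min_size, max_size]``. For each
    retained set with K universe members, overlap k and selection size n in
    a universe of N genes, p = P[X >= k] for X ~ Hypergeom(N, K, n);
    q-values are Benjamini-Hochberg across retained sets. Results are sorted
    by (p, set name).
    """
    selected = set(selected)
    universe = set(universe)
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    N, n = len(universe), len(selected)

    retained = collection.filter_sizes(min_size, max_size, universe=universe)
    names, pvals, ks, Ks = [], [], [], []
    for set_name, genes in retained.sets.items():
        K = len(genes)
        k = len(selected.intersection(genes))
        # upper tail P[X >= k] = sf(k - 1)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        names.append(set_name)
        pvals.append(min(max(p, 0.0), 1.0))
        ks.append(k)
        Ks.append(K)

    if not names:
        return []
    qvals = multipletests(pvals, method="fdr_bh")[1]
    results = [
        OraResult(
            set_name=name,
            overlap=k,
            set_size=K,
            selected=n,
            universe=N,
            p_value=p,
            q_value=float(q),
        )
        for name, k, K, p, q in zip(names, ks, Ks, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results
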