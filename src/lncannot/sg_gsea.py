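"""Single-gene GSEA: enrichment analysis against a phenotype defined by one gene.

GSEA needs two phenotype classes. When the question is "what does gene X
do?", the classes are manufactured from X itself: samples are sorted by X's
expression, the top quantile becomes the "high" class and the bottom
quantile the "low" class. Genes are then ranked by a two-class metric
(default signal-to-noise) and each gene set S is scored with the weighted
Kolmogorov-Smirnov running-sum statistic:

    P_hit(S, i)  = sum_{g_j in S, j <= i} |r_j|^p / N_R,
                   N_R = sum_{g_j in S} |r_j|^p
    P_miss(S, i) = sum_{g_j not in S, j <= i} 1 / (N - N_H)

    ES(S) = the signed extremum of P_hit - P_miss over positions i.

Significance comes from a gene-label permutation null: random gene subsets
of the same size are scored on the fixed ranking. ES is normalized by the
mean of same-sign null magnitudes (NES); the nominal p is the same-sign
tail fraction with add-one smoothing; FWER uses the permutation max over
sets of the normalized null; FDR q uses the GSEA ratio-of-tails on pooled
normalized nulls, clipped to [0, 1] and made monotone in |NES|.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "PhenotypeSplit",
    "RankedList",
    "GseaResult",
    "stratify_by_target",
    "rank_genes",
    "enrichment_score",
    "permutation_null",
    "normalize_and_test",
    "gsea_collection",
]

METRICS = ("signal2noise", "log2_ratio", "t_stat")


@dataclass(frozen=True)
class PhenotypeSplit:
    """Disjoint high/low sample groups defined by target-gene expression."""

    high: list[str]
    low: list[str]
    fraction: float

    def __post_init__(self) -> None:
        if set(self.high) & set(self.low):
            raise ValueError("high and low groups must be disjoint")
        if not self.high or not self.low:
            raise ValueError("both groups must be nonempty")


@dataclass
class RankedList:
    """Genes ordered by a two-class metric, best (most 'high'-like) first."""

    gene_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.gene_ids) != len(self.scores):
            raise ValueError("gene_ids and scores length mismatch")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("metric scores must be finite")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.gene_ids)


def stratify_by_target(
    m: ExpressionMatrix, target: str, q: float
) -> PhenotypeSplit:
    """Split samples into high/low groups of size ceil(q * n) by target expression.

    One total sample order is used — expression descending, ties broken by
    sample id ascending — so the split is deterministic even when the target
    value is constant. ``q`` must satisfy 0 < q <= 0.5 and leave the two
    groups disjoint.
    """
    if not (0 < q <= 0.5):
        raise ValueError("q must be in (0, 0.5]")
    n = m.n_samples
    k = math.ceil(q * n)
    if k < 2:
        raise ValueError(f"q={q} gives group size {k} < 2")
    if 2 * k > n:
        raise ValueError(f"q={q}: groups of {k} would overlap in {n} samples")
    x = m.gene_values(target)
    order = sorted(range(n), key=lambda j: (-x[j], m.sample_ids[j]))
    high = [m.sample_ids[j] for j in order[:k]]
    low = [m.sample_ids[j] for j in order[-k:]]
    return PhenotypeSplit(high=high, low=low, fraction=q)


def _floored_sd(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Group mean and sd with the GSEA-style floor max(sd, 0.2|mean|, 0.2)."""
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    sd = np.maximum(sd, np.maximum(0.2 * np.abs(mu), 0.2))
    return mu, sd


def rank_genes(
    m: ExpressionMatrix,
    split: PhenotypeSplit,
    metric: str = "signal2noise",
    exclude: tuple[str, ...] = (),
) -> RankedList:
    """Rank genes by a two-class high-vs-low metric, descending.

    ``signal2noise`` is (mu_high - mu_low) / (sd_high + sd_low) with each sd
    floored at max(sd, 0.2|mu|, 0.2); ``log2_ratio`` is the difference of
    group means (values are expected on a log2 scale); ``t_stat`` is a
    Welch-style t with the same floored sds. Ties are broken by gene id; the
    target gene should be passed via ``exclude`` so it cannot enrich itself.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    col = {s: j for j, s in enumerate(m.sample_ids)}
    try:
        hi_idx = [col[s] for s in split.high]
        lo_idx = [col[s] for s in split.low]
    except KeyError as exc:
        raise ValueError(f"split sample {exc} not in matrix") from None
    if metric in ("signal2noise", "t_stat") and (len(hi_idx) < 2 or len(lo_idx) < 2):
        raise ValueError(f"metric {metric!r} needs >= 2 samples per group")

    keep = [i for i, g in enumerate(m.gene_ids) if g not in set(exclude)]
    xh = m.values[np.ix_(keep, hi_idx)]
    xl = m.values[np.ix_(keep, lo_idx)]

    if metric == "log2_ratio":
        scores = xh.mean(axis=1) - xl.mean(axis=1)
    else:
        mu_h, sd_h = _floored_sd(xh)
        mu_l, sd_l = _floored_sd(xl)
        if metric == "signal2noise":
            scores = (mu_h - mu_l) / (sd_h + sd_l)
        else:
            scores = (mu_h - mu_l) / np.sqrt(
                sd_h**2 / len(hi_idx) + sd_l**2 / len(lo_idx)
            )

    genes = [m.gene_ids[i] for i in keep]
    order = sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))
    return RankedList(
        gene_ids=[genes[i] for i in order], scores=scores[np.array(order)]
    )


def _running_sum(
    weights: np.ndarray, hit_mask: np.ndarray, n_hits: int
) -> np.ndarray:
    """Weighted KS running sum P_hit - P_miss over the ranked list."""
    n = len(weights)
    n_r = weights[hit_mask].sum()
    inc = np.where(
        hit_mask,
        (weights / n_r) if n_r > 0 else (1.0 / n_hits),
        -1.0 / (n - n_hits),
    )
    return np.cumsum(inc)


def enrichment_score(
    ranked: RankedList,
    gene_set: set[str] | list[str],
    p_exp: float = 1.0,
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS enrichment score of ``gene_set`` on a ranked list.

    Returns ``(ES, running_sum, leading_edge)``: ES is the running-sum value
    of maximal magnitude (first such position on ties); the running sum has
    one entry per ranked gene, for plotting; the leading edge contains the
    set members at or before the extremum for positive ES, and strictly
    after it for negative ES.
    """
    members = set(gene_set)
    hit_mask = np.array([g in members for g in ranked.gene_ids], dtype=bool)
    n_hits = int(hit_mask.sum())
    n = len(ranked)
    if n_hits == 0:
        raise ValueError("gene set shares no genes with the ranked list")
    if n_hits == n:
        raise ValueError("gene set covers the whole ranked list")

    weights = np.abs(ranked.scores) ** p_exp
    running = _running_sum(weights, hit_mask, n_hits)
    i_star = int(np.argmax(np.abs(running)))
    # cumulative float error can push the extremum a few ulp past +-1
    es = float(np.clip(running[i_star], -1.0, 1.0))

    if es >= 0:
        lead_idx = np.flatnonzero(hit_mask[: i_star + 1])
    else:
        lead_idx = i_star + 1 + np.flatnonzero(hit_mask[i_star + 1 :])
    leading_edge = [ranked.gene_ids[i] for i in lead_idx]
    return es, running, leading_edge


def permutation_null(
    ranked: RankedList,
    set_size: int,
    B: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    p_exp: float = 1.0,
) -> np.ndarray:
    """Gene-label permutation null: B random same-size gene subsets scored
    on the fixed ranked list. Returns the B null enrichment scores.

    The draws are uniform over subsets of the ranked genes, reproducible
    from ``seed``; the whole batch is scored vectorized.
    """
    n = len(ranked)
    if B < 1:
        raise ValueError("B must be >= 1")
    if not (0 < set_size < n):
        raise ValueError(f"set_size must be in (0, {n})")
    rng = np.random.default_rng(seed)
    weights = np.abs(ranked.scores) ** p_exp

    # uniform random subsets: the first set_size entries of a random
    # permutation per draw, via argpartition of iid uniforms
    u = rng.random((B, n))
    chosen = np.argpartition(u, set_size - 1, axis=1)[:, :set_size]
    mask = np.zeros((B, n), dtype=bool)
    np.put_along_axis(mask, chosen, True, axis=1)

    n_r = (mask * weights[None, :]).sum(axis=1)
    hit_inc = np.where(
        n_r[:, None] > 0, weights[None, :] / np.where(n_r, n_r, 1.0)[:, None],
        1.0 / set_size,
    )
    inc = np.where(mask, hit_inc, -1.0 / (n - set_size))
    running = np.cumsum(inc, axis=1)
    i_star = np.argmax(np.abs(running), axis=1)
    return np.clip(running[np.arange(B), i_star], -1.0, 1.0)


def normalize_and_test(
    es: float, null_sample: np.ndarray
) -> tuple[float, float]:
    """Normalize an ES by the same-sign null mean and compute its nominal p.

    NES = ES / mean(|null ES| of the same sign); p is the same-sign tail
    fraction with add-one smoothing, (1 + #{|null| >= |ES|}) / (1 + #same-sign),
    so a reported p is never exactly zero.
    """
    null_sample = np.asarray(null_sample, dtype=float)
    same = null_sample >= 0 if es >= 0 else null_sample < 0
    same_vals = np.abs(null_sample[same])
    if same_vals.size == 0:
        raise ValueError("no same-sign values in the permutation null")
    nes = es / same_vals.mean()
    p = (1.0 + np.count_nonzero(same_vals >= abs(es))) / (1.0 + same_vals.size)
    return float(nes), float(p)


@dataclass
class GseaResult:
    set_name: str
    size: int
    es: float
    nes: float
    p_nominal: float
    p_fwer: float
    q_fdr: float
    leading_edge: list[str]
    null_summary: dict[str, float] = field(default_factory=dict)


def _set_seed(master_seed: int, genes: list[str]) -> np.random.SeedSequence:
    """Child seed derived from a stable hash of the set's membership, so
    adding or removing a set never changes another set's null, and the same
    set filed under two names draws the identical null."""
    digest = hashlib.sha256("\x00".join(sorted(genes)).encode("utf-8")).digest()
    return np.random.SeedSequence(
        [int(master_seed), int.from_bytes(digest[:4], "little")]
    )


def _normalize_null(null: np.ndarray) -> np.ndarray:
    """Divide each null ES by the mean same-sign null magnitude."""
    out = np.zeros_like(null)
    pos = null >= 0
    if pos.any():
        out[pos] = null[pos] / np.abs(null[pos]).mean()
    if (~pos).any():
        out[~pos] = null[~pos] / np.abs(null[~pos]).mean()
    return out


def gsea_collection(
    m: ExpressionMatrix,
    target: str,
    collection: GeneSetCollection,
    q: float = 0.10,
    metric: str = "signal2noise",
    B: int = 1000,
    seed: int = 0,
    min_size: int = 15,
    max_size: int = 500,
    p_exp: float = 1.0,
) -> list[GseaResult]:
    """Run single-gene GSEA for every set of a collection.

    Stratifies samples by ``target`` at quantile ``q``, ranks genes with
    ``metric``, scores each size-filtered set, and attaches NES, nominal p,
    permutation FWER and ratio-of-tails FDR q. Results are sorted by
    descending NES. Reproducible from ``seed``: each set draws its null from
    a child seed keyed by the set name.
    """
    split = stratify_by_target(m, target, q)
    ranked = rank_genes(m, split, metric=metric, exclude=(target,))
    universe = set(ranked.gene_ids)
    filtered = collection.filter_sizes(min_size, max_size, universe=universe)
    if len(filtered) == 0:
        raise ValueError(
            f"no gene set has between {min_size} and {max_size} members "
            "among the ranked genes"
        )

    names = sorted(filtered.sets)
    es_obs = np.empty(len(names))
    leads: list[list[str]] = []
    nulls = np.empty((len(names), B))
    for i, name in enumerate(names):
        genes = filtered.sets[name]
        es, _, lead = enrichment_score(ranked, genes, p_exp=p_exp)
        es_obs[i] = es
        leads.append(lead)
        nulls[i] = permutation_null(
            ranked, len(genes), B=B, seed=_set_seed(seed, genes), p_exp=p_exp
        )

    nes = np.empty(len(names))
    p_nom = np.empty(len(names))
    summaries: list[dict[str, float]] = []
    norm_nulls = np.empty_like(nulls)
    for i in range(len(names)):
        nes[i], p_nom[i] = normalize_and_test(es_obs[i], nulls[i])
        norm_nulls[i] = _normalize_null(nulls[i])
        pos = nulls[i][nulls[i] >= 0]
        neg = nulls[i][nulls[i] < 0]
        summaries.append(
            {
                "n_pos": float(pos.size),
                "mean_pos": float(pos.mean()) if pos.size else float("nan"),
                "sd_pos": float(pos.std(ddof=1)) if pos.size > 1 else float("nan"),
                "n_neg": float(neg.size),
                "mean_neg": float(neg.mean()) if neg.size else float("nan"),
                "sd_neg": float(neg.std(ddof=1)) if neg.size > 1 else float("nan"),
            }
        )

    # FWER: per permutation draw, the most extreme same-sign normalized null
    # over all sets; smoothed tail fraction against |NES|.
    max_pos = np.max(np.where(norm_nulls >= 0, norm_nulls, 0.0), axis=0)
    max_neg = np.max(np.where(norm_nulls < 0, -norm_nulls, 0.0), axis=0)
    p_fwer = np.empty(len(names))
    for i in range(len(names)):
        extremes = max_pos if nes[i] >= 0 else max_neg
        p_fwer[i] = (1.0 + np.count_nonzero(extremes >= abs(nes[i]))) / (1.0 + B)

    # FDR: GSEA ratio of tails on the pooled normalized null, per sign.
    pooled = norm_nulls.ravel()
    pooled_pos = pooled[pooled >= 0]
    pooled_neg = -pooled[pooled < 0]
    q_fdr = np.empty(len(names))
    for i in range(len(names)):
        v = abs(nes[i])
        if nes[i] >= 0:
            null_tail = (
                np.count_nonzero(pooled_pos >= v) / pooled_pos.size
                if pooled_pos.size
                else 1.0
            )
            obs_tail = np.count_nonzero(nes[nes >= 0] >= v) / max(
                np.count_nonzero(nes >= 0), 1
            )
        else:
            null_tail = (
                np.count_nonzero(pooled_neg >= v) / pooled_neg.size
                if pooled_neg.size
                else 1.0
            )
            obs_tail = np.count_nonzero(-nes[nes < 0] >= v) / max(
                np.count_nonzero(nes < 0), 1
            )
        q_fdr[i] = min(max(null_tail / obs_tail if obs_tail > 0 else 1.0, 0.0), 1.0)

    # monotone in |NES| within each sign: a larger |NES| never has a larger q.
    # Traverse from least to most extreme taking the running minimum, so each
    # set's q is the smallest raw q among sets at least as extreme as itself.
    for sign_mask in (nes >= 0, nes < 0):
        idx = np.flatnonzero(sign_mask)
        if idx.size:
            order = idx[np.argsort(np.abs(nes[idx]), kind="stable")]
            q_fdr[order] = np.minimum.accumulate(q_fdr[order])

    results = [
        GseaResult(
            set_name=names[i],
            size=len(filtered.sets[names[i]]),
            es=float(es_obs[i]),
            nes=float(nes[i]),
            p_nominal=float(p_nom[i]),
            p_fwer=float(p_fwer[i]),
            q_fdr=float(q_fdr[i]),
            leading_edge=leads[i],
            null_summary=summaries[i],
        )
        for i in range(len(names))
    ]
    results.sort(key=lambda r: (-r.nes, r.set_name))
    return results
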