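"""Synthetic expression cohorts and clinical cohorts with known structure.

The expression generator emulates a bulk RNA-seq tumor cohort in which a
single target gene (a lncRNA of interest) co-varies with planted gene sets:

* a latent per-sample target activity ``t_j ~ N(0, 1)``;
* the target gene's counts are negative binomial with log-mean
  ``a0 + a1 * t_j`` (``a1 > 0``), so observed target expression tracks the
  latent activity;
* each gene of a planted set ``k`` has log-mean ``base_g + beta_k * t_j``;
  a negative coupling ``beta_k < 0`` emulates a pathway suppressed when the
  target is high (the cell-cycle-like relationship), a positive coupling the
  estrogen-response-like relationship;
* background genes are independent of ``t_j``;
* every log-mean is offset by a per-sample log library factor, lognormal.

Counts are NB with variance = mean + dispersion * mean^2.

Seeding: a single global seed fans out to per-component ``SeedSequence``
children keyed by (seed, component, index), so adding genes or samples never
perturbs draws of existing components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    ExpressionMatrix,
    GeneSetCollection,
    MatrixKind,
    write_expression_tsv,
    write_gmt,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_expression",
    "generate_paired_cohort",
    "default_config",
    "write_simulation",
    "SUBTYPES",
    "PAPER_SUBTYPE_PROPORTIONS",
]

SUBTYPES = ("LuminalA", "LuminalB", "HER2", "TNBC")

# cohort composition of the 98-patient clinical series (19/23/31/25)
PAPER_SUBTYPE_PROPORTIONS: dict[str, float] = {
    "LuminalA": 19 / 98,
    "LuminalB": 23 / 98,
    "HER2": 31 / 98,
    "TNBC": 25 / 98,
}


@dataclass
class PlantedSet:
    set_id: str
    size: int
    beta: float


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic expression cohort."""

    n_genes: int = 2000
    n_samples: int = 300
    target_gene_id: str = "TARGET_LNC"
    planted_sets: list[PlantedSet] = field(
        default_factory=lambda: [
            PlantedSet("CELL_CYCLE_LIKE", 50, -0.8),
            PlantedSet("ESTROGEN_LIKE", 50, +0.8),
        ]
    )
    n_decoy_sets: int = 20
    decoy_set_size: int = 50
    baseline_log_mean_range: tuple[float, float] = (2.0, 6.0)
    target_log_mean: float = 4.0
    target_slope: float = 1.0  # a1 > 0: counts of the target track t_j
    dispersion: float = 0.2
    library_size_log_sd: float = 0.2
    seed: int = 0

    def validate(self) -> list[str]:
        problems: list[str] = []
        if self.n_genes < 1 or self.n_samples < 1:
            problems.append("n_genes and n_samples must be positive")
        planted_total = sum(p.size for p in self.planted_sets)
        if planted_total > self.n_genes:
            problems.append(
                f"planted set sizes sum to {planted_total} > n_genes={self.n_genes}"
            )
        n_background = self.n_genes - planted_total
        if self.n_decoy_sets > 0 and self.decoy_set_size > max(n_background, 0):
            problems.append(
                "decoy_set_size exceeds the number of background genes"
            )
        if self.dispersion <= 0:
            problems.append("dispersion must be > 0")
        if self.library_size_log_sd <= 0:
            problems.append("library_size_log_sd must be > 0")
        if self.target_slope <= 0:
            problems.append("target_slope must be > 0")
        names = [p.set_id for p in self.planted_sets]
        if len(set(names)) != len(names):
            problems.append("planted set ids must be unique")
        return problems


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort for recovery tests."""

    target_gene_id: str
    gene_set: dict[str, str]  # gene id -> set id or "background"
    gene_beta: dict[str, float]  # gene id -> coupling (0 for background)
    latent_target: np.ndarray  # t_j per sample
    library_factor: np.ndarray  # l_j per sample
    collection: GeneSetCollection  # planted + decoy sets as a toy GMT

    def planted_genes(self, set_id: str) -> list[str]:
        return [g for g, s in self.gene_set.items() if s == set_id]


def default_config(seed: int = 0) -> SyntheticConfig:
    """Desk-scale default cohort: 2,000 genes x 300 samples, one negatively
    and one positively coupled 50-gene set, 20 decoy sets of background genes."""
    return SyntheticConfig(seed=seed)


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(key)))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with variance = mean + dispersion*mean^2, i.e. shape n = 1/dispersion."""
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def generate_expression(cfg: SyntheticConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a raw-count cohort with planted target-coupled gene sets."""
    problems = cfg.validate()
    if problems:
        raise ValueError("invalid SyntheticConfig: " + "; ".join(problems))

    n_g, n_s = cfg.n_genes, cfg.n_samples
    t = _rng(cfg.seed, 0).standard_normal(n_s)  # latent target activity
    lib = np.exp(_rng(cfg.seed, 1).normal(0.0, cfg.library_size_log_sd, n_s))
    log_lib = np.log(lib)

    # gene labels: planted genes first (set by set), then background
    gene_ids: list[str] = []
    gene_set: dict[str, str] = {}
    gene_beta: dict[str, float] = {}
    betas = np.zeros(n_g)
    idx = 0
    for planted in cfg.planted_sets:
        for i in range(planted.size):
            gid = f"{planted.set_id}_G{i:04d}"
            gene_ids.append(gid)
            gene_set[gid] = planted.set_id
            gene_beta[gid] = planted.beta
            betas[idx] = planted.beta
            idx += 1
    n_background = n_g - idx
    for i in range(n_background):
        gid = f"BG_G{i:05d}"
        gene_ids.append(gid)
        gene_set[gid] = "background"
        gene_beta[gid] = 0.0

    lo, hi = cfg.baseline_log_mean_range
    counts = np.empty((n_g, n_s), dtype=float)
    for g in range(n_g):
        rg = _rng(cfg.seed, 2, g)
        base = rg.uniform(lo, hi)
        log_mu = base + betas[g] * t + log_lib
        counts[g] = _nb_draw(rg, np.exp(log_mu), cfg.dispersion)

    # target gene appended last so its index never shifts planted genes
    rt = _rng(cfg.seed, 3)
    target_mu = np.exp(cfg.target_log_mean + cfg.target_slope * t + log_lib)
    target_counts = _nb_draw(rt, target_mu, cfg.dispersion)

    all_ids = gene_ids + [cfg.target_gene_id]
    values = np.vstack([counts, target_counts[None, :]])
    sample_ids = [f"S{j:04d}" for j in range(n_s)]
    matrix = ExpressionMatrix(all_ids, sample_ids, values, MatrixKind.RAW_COUNTS)

    # toy GMT: planted sets plus decoy sets drawn from background genes
    sets: dict[str, list[str]] = {
        p.set_id: [g for g in gene_ids if gene_set[g] == p.set_id]
        for p in cfg.planted_sets
    }
    bg_ids = [g for g in gene_ids if gene_set[g] == "background"]
    rd = _rng(cfg.seed, 4)
    for d in range(cfg.n_decoy_sets):
        members = rd.choice(len(bg_ids), size=cfg.decoy_set_size, replace=False)
        sets[f"DECOY_{d:02d}"] = [bg_ids[i] for i in sorted(members)]
    collection = GeneSetCollection(name="synthetic_sets", sets=sets)

    truth = SyntheticTruth(
        target_gene_id=cfg.target_gene_id,
        gene_set=gene_set,
        gene_beta=gene_beta,
        latent_target=t,
        library_factor=lib,
        collection=collection,
    )
    return matrix, truth


def generate_paired_cohort(
    n_patients: int,
    subtype_effects: Mapping[str, float],
    noise_sd: float,
    seed: int,
    *,
    subtype_proportions: Mapping[str, float] | None = None,
    baseline_mean: float = 5.0,
    baseline_sd: float = 1.0,
    gamma: float = 1.0,
    baseline_hazard: float = 0.02,
    censor_max: float = 120.0,
) -> pd.DataFrame:
    """Simulate a paired tumor/peritumor cohort with survival follow-up.

    Per patient: peritumor log expression is normal
    ``N(baseline_mean, baseline_sd)``; tumor = peritumor + shift(subtype)
    + ``N(0, noise_sd)``. Survival time is exponential with rate
    ``baseline_hazard`` multiplied by ``exp(gamma)`` for the low-expression
    half (tumor expression below the cohort median); censoring times are
    uniform on ``[0, censor_max]`` months.

    Returns a tidy DataFrame with columns ``patient_id, subtype, tumor,
    peritumor, time, event``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    for s, shift in subtype_effects.items():
        if not np.isfinite(shift):
            raise ValueError(f"non-finite shift for subtype {s!r}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    subtypes = list(subtype_effects.keys())
    if subtype_proportions is None:
        props = {
            s: PAPER_SUBTYPE_PROPORTIONS.get(s, 0.0) for s in subtypes
        }
        if sum(props.values()) == 0:
            props = {s: 1.0 / len(subtypes) for s in subtypes}
    else:
        props = {s: subtype_proportions.get(s, 0.0) for s in subtypes}
    total = sum(props.values())
    props = {s: v / total for s, v in props.items()}

    # deterministic largest-remainder allocation of subtype counts
    raw = {s: props[s] * n_patients for s in subtypes}
    counts = {s: int(np.floor(raw[s])) for s in subtypes}
    remainder = n_patients - sum(counts.values())
    by_frac = sorted(subtypes, key=lambda s: (-(raw[s] - counts[s]), s))
    for s in by_frac[:remainder]:
        counts[s] += 1

    labels: list[str] = []
    for s in subtypes:
        labels.extend([s] * counts[s])

    rng = _rng(seed, 10)
    peritumor = rng.normal(baseline_mean, baseline_sd, n_patients)
    noise = rng.normal(0.0, noise_sd, n_patients)
    shifts = np.array([subtype_effects[s] for s in labels])
    tumor = peritumor + shifts + noise

    median = np.median(tumor)
    low = tumor < median
    hazard = baseline_hazard * np.exp(gamma * low.astype(float))
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, censor_max, n_patients)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n_patients)],
            "subtype": labels,
            "tumor": tumor,
            "peritumor": peritumor,
            "time": time,
            "event": event,
        }
    )


def write_simulation(
    cfg: SyntheticConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Run :func:`generate_expression` and write matrix, truth and GMT files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, truth = generate_expression(cfg)

    expr_path = out / "expression.tsv"
    write_expression_tsv(matrix, expr_path)

    gmt_path = out / "gene_sets.gmt"
    write_gmt(truth.collection, gmt_path)

    truth_path = out / "truth.tsv"
    truth_df = pd.DataFrame(
        {
            "gene_id": list(truth.gene_set.keys()),
            "set_id": list(truth.gene_set.values()),
            "beta": [truth.gene_beta[g] for g in truth.gene_set],
        }
    )
    truth_df.to_csv(truth_path, sep="\t", index=False)
    return {"expression": expr_path, "gmt": gmt_path, "truth": truth_path}
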