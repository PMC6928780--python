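"""Full annotation pipeline: normalize -> guilt-by-association -> ORA ->
single-gene GSEA -> clinical report, driven by one config.

Every stage writes plain TSV; the run report is a manifest of output files
with content hashes plus the parameter echo, so two runs with the same
config and seed are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clinical as clin
from . import core_io, gba, sg_gsea

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters of one end-to-end annotation run."""

    expression: str
    target: str
    gmt_files: list[str] = field(default_factory=list)
    cohort: str | None = None
    out_dir: str = "lncannot_out"

    gba_fraction: float = 0.05
    gba_direction: str = "top"
    gba_min_size: int = 5
    gba_max_size: int = 500

    gsea_quantile: float = 0.10
    permutations: int = 1000
    metric: str = "signal2noise"
    gsea_min_size: int = 15
    gsea_max_size: int = 500

    pseudocount: float = 1.0
    already_normalized: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def validate_config(cfg: RunConfig, check_paths: bool = True) -> list[str]:
    """Return the list of invariant violations (empty iff the config is valid)."""
    v: list[str] = []
    if not (0 < cfg.gba_fraction <= 1):
        v.append("gba.fraction must be in (0, 1]")
    if cfg.gba_direction not in ("top", "bottom", "abs"):
        v.append("gba.direction must be top, bottom or abs")
    if not (0 < cfg.gsea_quantile <= 0.5):
        v.append("gsea.quantile must be in (0, 0.5] (groups must not overlap)")
    if cfg.permutations < 1:
        v.append("permutations must be >= 1")
    if cfg.metric not in sg_gsea.METRICS:
        v.append(f"metric must be one of {sg_gsea.METRICS}")
    if cfg.pseudocount <= 0:
        v.append("pseudocount must be > 0")
    for lo, hi, name in (
        (cfg.gba_min_size, cfg.gba_max_size, "gba"),
        (cfg.gsea_min_size, cfg.gsea_max_size, "gsea"),
    ):
        if lo < 1 or hi < lo:
            v.append(f"{name} set-size filter [{lo}, {hi}] is invalid")
    if not cfg.target:
        v.append("target gene id must be nonempty")
    if check_paths:
        if not Path(cfg.expression).is_file():
            v.append(f"expression file not found: {cfg.expression}")
        for g in cfg.gmt_files:
            if not Path(g).is_file():
                v.append(f"GMT file not found: {g}")
        if cfg.cohort is not None and not Path(cfg.cohort).is_file():
            v.append(f"cohort file not found: {cfg.cohort}")
    return v


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage of the annotation and return the run report.

    The report holds the parameter echo, the seed, and a manifest mapping
    each output file to its sha256. Any stage failure aborts with the stage
    name in the exception message.
    """
    violations = validate_config(cfg)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    run_logger = logging.getLogger("lncannot.run")
    run_logger.setLevel(logging.INFO)
    run_logger.addHandler(handler)

    outputs: list[Path] = []

    def stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            run_logger.error("stage %s failed: %s", name, exc)
            handler.close()
            run_logger.removeHandler(handler)
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        run_logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return result

    try:
        matrix = stage("read_expression",
                       lambda: core_io.read_expression_tsv(cfg.expression))
        run_logger.info(
            "expression: %d genes x %d samples", matrix.n_genes, matrix.n_samples
        )

        if cfg.already_normalized:
            normalized = core_io.ExpressionMatrix(
                matrix.gene_ids, matrix.sample_ids, matrix.values,
                core_io.MatrixKind.NORMALIZED,
            )
        else:
            factors = stage("size_factors",
                            lambda: core_io.estimate_size_factors(matrix))
            normalized = core_io.normalize(matrix, factors)
        logged = core_io.log_transform(normalized, cfg.pseudocount)

        ranking = stage("correlate", lambda: gba.correlate_all(logged, cfg.target))
        corr_path = out / "correlation.tsv"
        _write_tsv(
            pd.DataFrame(
                {
                    "gene_id": [r.gene_id for r in ranking],
                    "rho": [r.rho for r in ranking],
                    "p_value": [r.p_value for r in ranking],
                    "rank": [r.rank for r in ranking],
                }
            ),
            corr_path,
        )
        outputs.append(corr_path)

        selected = gba.select_top_fraction(
            ranking, cfg.gba_fraction, direction=cfg.gba_direction
        )
        sel_path = out / "selected_genes.tsv"
        _write_tsv(pd.DataFrame({"gene_id": selected}), sel_path)
        outputs.append(sel_path)

        universe = {r.gene_id for r in ranking}
        for gmt_file in cfg.gmt_files:
            coll = core_io.read_gmt(gmt_file)
            ora_results = stage(
                f"ora[{coll.name}]",
                lambda c=coll: gba.ora(
                    selected, universe, c,
                    min_size=cfg.gba_min_size, max_size=cfg.gba_max_size,
                ),
            )
            ora_path = out / f"ora_{coll.name}.tsv"
            _write_tsv(
                pd.DataFrame(
                    {
                        "set_name": [r.set_name for r in ora_results],
                        "overlap": [r.overlap for r in ora_results],
                        "set_size": [r.set_size for r in ora_results],
                        "selected": [r.selected for r in ora_results],
                        "universe": [r.universe for r in ora_results],
                        "p_value": [r.p_value for r in ora_results],
                        "q_value": [r.q_value for r in ora_results],
                    }
                ),
                ora_path,
            )
            outputs.append(ora_path)

            gsea_results = stage(
                f"sggsea[{coll.name}]",
                lambda c=coll: sg_gsea.gsea_collection(
                    logged, cfg.target, c,
                    q=cfg.gsea_quantile, metric=cfg.metric,
                    B=cfg.permutations, seed=cfg.seed,
                    min_size=cfg.gsea_min_size, max_size=cfg.gsea_max_size,
                ),
            )
            gsea_path = out / f"gsea_{coll.name}.tsv"
            _write_tsv(
                pd.DataFrame(
                    {
                        "set_name": [r.set_name for r in gsea_results],
                        "size": [r.size for r in gsea_results],
                        "es": [r.es for r in gsea_results],
                        "nes": [r.nes for r in gsea_results],
                        "p_nominal": [r.p_nominal for r in gsea_results],
                        "p_fwer": [r.p_fwer for r in gsea_results],
                        "q_fdr": [r.q_fdr for r in gsea_results],
                        "leading_edge": [
                            ",".join(r.leading_edge) for r in gsea_results
                        ],
                    }
                ),
                gsea_path,
            )
            outputs.append(gsea_path)

        if cfg.cohort is not None:
            cohort = clin.ClinicalCohort.from_tsv(cfg.cohort)
            paired = stage("paired_tests",
                           lambda: clin.paired_tests_by_subtype(cohort))
            paired_path = out / "paired_tests.tsv"
            _write_tsv(
                pd.DataFrame(
                    {
                        "subtype": [r.subtype for r in paired],
                        "n": [r.n for r in paired],
                        "mean_difference": [r.mean_difference for r in paired],
                        "t_statistic": [r.t_statistic for r in paired],
                        "p_value": [r.p_value for r in paired],
                    }
                ),
                paired_path,
            )
            outputs.append(paired_path)

            frac = clin.fraction_downregulated(cohort)
            frac_path = out / "fraction_downregulated.tsv"
            _write_tsv(
                pd.DataFrame({"n_pairs": [len(cohort)],
                              "fraction_downregulated": [frac]}),
                frac_path,
            )
            outputs.append(frac_path)

            if cohort.has_survival:
                hi, lo, chi2, p = stage("km_logrank",
                                        lambda: clin.km_logrank(cohort))
                for curve in (hi, lo):
                    p_curve = out / f"km_{curve.label}.tsv"
                    _write_tsv(
                        pd.DataFrame(
                            {
                                "time": curve.times,
                                "survival": curve.survival,
                                "at_risk": curve.at_risk,
                            }
                        ),
                        p_curve,
                    )
                    outputs.append(p_curve)
                lr_path = out / "logrank.tsv"
                _write_tsv(
                    pd.DataFrame({"chi_square": [chi2], "p_value": [p]}),
                    lr_path,
                )
                outputs.append(lr_path)

        report = {
            "parameters": dataclasses.asdict(cfg),
            "seed": cfg.seed,
            "outputs": {str(p.name): _sha256(p) for p in outputs},
        }
        manifest_path = out / "manifest.json"
        with open(manifest_path, "wt") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        run_logger.info("wrote %d outputs", len(outputs))
        return report
    finally:
        handler.close()
        run_logger.removeHandler(handler)
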