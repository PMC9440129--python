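"""End-to-end orchestration: read -> filter -> log2 -> impute ->
background-filter -> t-test -> proteinase-K control exclusion -> meta.

The stage order is fixed.  Within each experiment: decoy/contaminant
removal, spectral-count inclusion filter, log2 transform, downshifted
imputation, background filter (on the pre-imputation observed mask),
Student's t-test.  Candidate sets are then pruned by the RAPIGest
control, and with two or more experiments the full protein intersection
is meta-analysed.  Everything is deterministic given the config seed;
per-experiment imputation seeds are spawned from it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .differential import filter_background, replicate_correlation, ttest_volcano
from .imputation import ImputationParams, ImputedMatrix, impute_downshifted
from .io import (
    ExperimentDesign,
    LfqTable,
    read_design,
    read_protein_table,
    write_results_table,
)
from .meta import meta_analyse
from .preprocess import (
    exclude_protk_resistant,
    filter_spectral_counts,
    log2_transform,
    remove_flagged,
)

logger = logging.getLogger("degradome")


@dataclass
class PipelineConfig:
    """Paths, thresholds and the master seed for a full run.

    ``tables`` maps experiment id -> protein-group table path; the
    design file must cover exactly those experiments.  The optional
    ``rapigest_candidates`` path lists proteinase-K-resistant proteins
    (TSV with a ``protein_id`` column, or one bare id per line).
    """

    tables: dict[str, str]
    design: str
    out_dir: str
    dialect: str = "maxquant"
    min_msms_total: int = 3
    msms_mode: str = "summed"
    min_observed: int = 2
    imputation: ImputationParams = field(default_factory=ImputationParams)
    alpha: float = 0.05
    fdr_threshold: float = 0.05
    rapigest_candidates: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tables:
            raise ValueError("at least one input table required")
        if not 0 < self.alpha < 1 or not 0 < self.fdr_threshold < 1:
            raise ValueError("alpha and fdr_threshold must be in (0, 1)")


@dataclass
class ExperimentResult:
    table: LfqTable  # after row filters
    matrix: ImputedMatrix  # after imputation + background filter
    differential: pd.DataFrame
    correlations: dict[str, pd.DataFrame]
    candidates: set[str]


@dataclass
class StudyResult:
    experiments: dict[str, ExperimentResult]
    candidates: dict[str, set[str]]  # after RAPIGest exclusion
    meta: pd.DataFrame | None


def run_experiment(
    table: LfqTable,
    design: ExperimentDesign,
    *,
    min_msms_total: int = 3,
    msms_mode: str = "summed",
    min_observed: int = 2,
    imputation: ImputationParams = ImputationParams(),
    alpha: float = 0.05,
) -> ExperimentResult:
    """Run the per-experiment stages on in-memory objects."""
    n0 = len(table)
    table = remove_flagged(table)
    logger.info("flag filter: %d -> %d proteins", n0, len(table))
    n1 = len(table)
    table = filter_spectral_counts(table, design, min_msms_total, msms_mode)
    logger.info("spectral-count filter (>=%d %s): %d -> %d proteins",
                min_msms_total, msms_mode, n1, len(table))
    matrix = log2_transform(table, design)
    imputed = impute_downshifted(matrix, imputation)
    n2 = len(imputed.values)
    imputed = filter_background(imputed, design, min_observed)
    logger.info("background filter (>=%d observed in a condition): %d -> %d",
                min_observed, n2, len(imputed.values))
    diff = ttest_volcano(imputed, design, alpha)
    corr = replicate_correlation(imputed, design)
    candidates = set(diff.loc[diff["candidate"], "protein_id"])
    logger.info("candidates at p < %g, log2fc > 0: %d", alpha, len(candidates))
    return ExperimentResult(table, imputed, diff, corr, candidates)


def run_study(
    tables: dict[str, LfqTable],
    design: ExperimentDesign,
    *,
    min_msms_total: int = 3,
    msms_mode: str = "summed",
    min_observed: int = 2,
    imputation: ImputationParams = ImputationParams(),
    alpha: float = 0.05,
    fdr_threshold: float = 0.05,
    rapigest_candidates: set[str] | None = None,
) -> StudyResult:
    """Run every experiment, prune candidates, meta-analyse if >= 2."""
    unknown = set(tables) - set(design.experiments)
    if unknown:
        raise ValueError(f"experiments absent from design: {sorted(unknown)}")
    results: dict[str, ExperimentResult] = {}
    for i, exp in enumerate(e for e in design.experiments if e in tables):
        sub = design.restrict(exp)
        params = dataclasses.replace(imputation, seed=imputation.seed + i)
        logger.info("=== experiment %s (n = %d) ===", exp,
                    design.n_per_experiment[exp])
        try:
            results[exp] = run_experiment(
                tables[exp], sub,
                min_msms_total=min_msms_total, msms_mode=msms_mode,
                min_observed=min_observed, imputation=params, alpha=alpha,
            )
        except Exception as err:
            raise RuntimeError(f"experiment {exp!r} failed: {err}") from err
    rapigest = rapigest_candidates or set()
    candidates = {
        exp: exclude_protk_resistant(res.candidates, rapigest)
        for exp, res in results.items()
    }
    if rapigest:
        for exp in results:
            dropped = len(results[exp].candidates) - len(candidates[exp])
            logger.info("RAPIGest exclusion removed %d %s candidate(s)",
                        dropped, exp)
    meta = None
    if len(results) >= 2:
        meta = meta_analyse(
            {e: r.differential for e, r in results.items()},
            design,
            fdr_threshold,
        )
        keep = ~meta["protein_id"].isin(rapigest)
        meta = meta.loc[keep].reset_index(drop=True)
        logger.info("meta-analysis: %d shared proteins, %d significant "
                    "at FDR < %g", len(meta), int(meta["significant"].sum()),
                    fdr_threshold)
    return StudyResult(results, candidates, meta)


def _read_id_list(path: str | Path) -> set[str]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        return set()
    if "\t" in lines[0] or lines[0].strip() == "protein_id":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if "protein_id" not in df.columns:
            raise ValueError(f"{path}: expected a protein_id column")
        return set(df["protein_id"])
    return {ln.strip() for ln in lines if ln.strip()}


def run(config: PipelineConfig) -> StudyResult:
    """Run from files per the config and write all artefacts to out_dir."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    design = read_design(config.design)
    tables = {
        exp: read_protein_table(path, config.dialect)  # type: ignore[arg-type]
        for exp, path in config.tables.items()
    }
    for exp in tables:
        missing = [
            s for s in design.restrict(exp).all_sample_ids
            if s not in tables[exp].sample_ids
        ]
        if missing:
            raise ValueError(
                f"design sample(s) {missing} absent from table {exp!r}"
            )
    rapigest = (
        _read_id_list(config.rapigest_candidates)
        if config.rapigest_candidates
        else None
    )
    imputation = dataclasses.replace(config.imputation, seed=config.seed)
    result = run_study(
        tables, design,
        min_msms_total=config.min_msms_total, msms_mode=config.msms_mode,
        min_observed=config.min_observed, imputation=imputation,
        alpha=config.alpha, fdr_threshold=config.fdr_threshold,
        rapigest_candidates=rapigest,
    )
    for exp, res in result.experiments.items():
        write_results_table(res.differential, out_dir / f"differential_{exp}.tsv")
        pd.DataFrame(
            sorted(result.candidates[exp]), columns=["protein_id"]
        ).to_csv(out_dir / f"candidates_{exp}.tsv", sep="\t", index=False)
    if result.meta is not None:
        write_results_table(result.meta, out_dir / "meta.tsv")
    manifest = {
        "package": "degradome",
        "version": __version__,
        "seed": config.seed,
        "dialect": config.dialect,
        "min_msms_total": config.min_msms_total,
        "msms_mode": config.msms_mode,
        "min_observed": config.min_observed,
        "imputation": dataclasses.asdict(imputation),
        "alpha": config.alpha,
        "fdr_threshold": config.fdr_threshold,
        "experiments": {
            e: design.n_per_experiment[e] for e in result.experiments
        },
        "rapigest_candidates": config.rapigest_candidates,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result


def configure_logging(level: int = logging.INFO) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)
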