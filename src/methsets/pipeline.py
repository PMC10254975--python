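"""End-to-end orchestration: QC -> cell proportions -> EWAS -> DMP
selection -> DGE -> ORA -> gene-set construction -> rotation tests.

Each stage writes its artifact (TSV/GMT) into the output directory and
records counts in a run manifest; the genomic inflation factor is
computed and logged as a diagnostic but never used to rescale p-values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import ProbeAnnotation
from .cells import estimate_cell_proportions
from .enrichment import AnnotationDB, ora_test
from .genesets import bonferroni_threshold, build_gene_sets, select_significant_dmps
from .io import write_gmt, write_matrix, write_table
from .lm import (
    build_design,
    ebayes_moderate,
    fit_feature_lm,
    genomic_inflation,
    pca_scores,
    results_table,
)
from .qc import QCConfig, filter_probes, filter_samples
from .roast import RoastConfig, roast_all_sets
from .simulate import SimConfig, SimulatedCohort, generate_cohort

log = logging.getLogger("methsets")

DEFAULT_COVARIATES = ("age", "sex", "bmi", "alcohol", "ses")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Settings for one pipeline run.

    ``ewas_covariates``/``dge_covariates`` name columns of the sample
    table; physical activity, when present, is deliberately not in the
    default set (it is nearly collinear with the exposure).  PC counts
    default to 30 (methylation) and 10 (expression) score columns.
    """

    qc: QCConfig = field(default_factory=QCConfig)
    ewas_covariates: tuple = DEFAULT_COVARIATES
    dge_covariates: tuple = DEFAULT_COVARIATES
    n_pcs_ewas: int = 30
    n_pcs_dge: int = 10
    alpha: float = 0.05
    dge_fdr: float = 0.05
    roast: RoastConfig = field(default_factory=RoastConfig)
    use_cell_proportions: bool = True
    drop_cell_type: str = "Gran"
    extra_excluded_genes: tuple = ()
    n_tests: int | None = None   # Bonferroni denominator; default = probes tested
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1 or not 0 < self.dge_fdr < 1:
            raise ValueError("alpha and dge_fdr must be in (0,1)")


@dataclass
class PipelineResult:
    ewas: pd.DataFrame
    dge: pd.DataFrame
    sets: list
    roast: pd.DataFrame
    cell_proportions: pd.DataFrame | None
    inflation: float
    manifest: dict


def run_pipeline(
    cohort: SimulatedCohort,
    config: PipelineConfig,
    out_dir=None,
    detection_p: pd.DataFrame | None = None,
    panel: pd.DataFrame | None = None,
    go_db: AnnotationDB | None = None,
) -> PipelineResult:
    """Run the full integrative analysis on a cohort.

    ``detection_p`` enables the QC stage (skipped when absent, as for
    simulated data); ``panel`` enables reference-based cell-proportion
    covariates; ``go_db`` enables the over-representation stage.  A
    failing stage aborts with a :class:`PipelineStageError` naming it;
    artifacts written before the failure keep a ``.partial`` suffix.
    """
    state = {"stage": "setup"}
    import time

    t0 = time.time()
    try:
        return _run_stages(cohort, config, out_dir, detection_p, panel, go_db, state)
    except Exception as exc:
        if out_dir is not None:
            out = Path(out_dir)
            if out.is_dir():
                for f in out.iterdir():
                    if f.is_file() and f.stat().st_mtime >= t0 and f.suffix != ".partial":
                        f.rename(f.with_name(f.name + ".partial"))
        raise PipelineStageError(state["stage"], exc) from exc


def _run_stages(
    cohort: SimulatedCohort,
    config: PipelineConfig,
    out_dir,
    detection_p: pd.DataFrame | None,
    panel: pd.DataFrame | None,
    go_db: AnnotationDB | None,
    state: dict,
) -> PipelineResult:
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    beta, expr, cov = cohort.beta, cohort.expression, cohort.covariates

    # ---- QC ---------------------------------------------------------------
    state["stage"] = "qc"
    if detection_p is not None:
        samples, sample_report = filter_samples(detection_p, config.qc)
        probes, probe_report = filter_probes(
            beta[samples], detection_p[samples], cohort.annotation, config.qc
        )
        beta = beta.loc[probes, samples]
        expr = expr[samples]
        cov = cov.loc[samples]
        if out is not None:
            write_table(pd.concat([probe_report, sample_report]), out / "qc_exclusions.tsv")
        manifest["stages"]["qc"] = {
            "probes_retained": len(probes),
            "samples_retained": len(samples),
        }
    log.info("analysis matrix: %d probes x %d samples", *beta.shape)

    # ---- cell proportions -------------------------------------------------
    state["stage"] = "cell_proportions"
    cell_props = None
    cell_cov = None
    if config.use_cell_proportions and panel is not None:
        cell_props = estimate_cell_proportions(beta, panel)
        keep = [c for c in cell_props.columns if c != config.drop_cell_type]
        cell_cov = cell_props[keep]
        if out is not None:
            write_matrix(cell_props, out / "cell_proportions.tsv", index_label="sample")
        manifest["stages"]["cells"] = {"types": list(cell_props.columns)}

    # ---- EWAS -------------------------------------------------------------
    state["stage"] = "ewas"
    k_meth = min(config.n_pcs_ewas, beta.shape[1] - 1, beta.shape[0])
    meth_pcs = pca_scores(beta, k_meth).scores if k_meth > 0 else None
    X_ewas = build_design(cov, ["exposure", *config.ewas_covariates], pcs=meth_pcs)
    if cell_cov is not None:
        X_ewas = pd.concat([X_ewas, cell_cov], axis=1)
    ewas_fit = fit_feature_lm(beta, X_ewas, "exposure")
    ewas = ebayes_moderate(ewas_fit)
    lam = genomic_inflation(ewas.p.to_numpy())
    log.info("genomic inflation factor lambda = %.3f (diagnostic only)", lam)
    ewas_tab = results_table(ewas, cohort.annotation.to_frame())
    if out is not None:
        write_matrix(ewas_tab, out / "ewas.tsv", index_label="probe")
    manifest["stages"]["ewas"] = {
        "n_probes": int(len(ewas.p)),
        "lambda": lam,
        "design_columns": list(X_ewas.columns),
    }

    # ---- DMP selection ----------------------------------------------------
    state["stage"] = "dmp_selection"
    n_tests = config.n_tests if config.n_tests is not None else len(ewas.p)
    dmps, undefined = select_significant_dmps(
        ewas_tab.rename(columns={"coef": "coef"}), n_tests, config.alpha
    )
    manifest["stages"]["dmps"] = {
        "threshold": bonferroni_threshold(n_tests, config.alpha),
        "n_significant": int(len(dmps)),
        "n_direction_undefined": len(undefined),
    }

    # ---- DGE --------------------------------------------------------------
    state["stage"] = "dge"
    k_expr = min(config.n_pcs_dge, expr.shape[1] - 1, expr.shape[0])
    expr_pcs = pca_scores(expr, k_expr).scores if k_expr > 0 else None
    X_dge = build_design(cov, ["exposure", *config.dge_covariates], pcs=expr_pcs)
    dge_fit = fit_feature_lm(expr, X_dge, "exposure")
    dge = ebayes_moderate(dge_fit)
    dge_tab = results_table(dge)
    if out is not None:
        write_matrix(dge_tab, out / "dge.tsv", index_label="gene")
    degs = dge_tab.index[dge_tab["fdr"] < config.dge_fdr]
    manifest["stages"]["dge"] = {
        "n_genes": int(len(dge.p)),
        "n_degs": int(len(degs)),
        "n_up": int((dge_tab.loc[degs, "coef"] > 0).sum()),
        "n_down": int((dge_tab.loc[degs, "coef"] < 0).sum()),
    }

    # ---- GO over-representation (up/down separately) ----------------------
    state["stage"] = "ora"
    if go_db is not None:
        for label, mask in (
            ("up", dge_tab.loc[degs, "coef"] > 0),
            ("down", dge_tab.loc[degs, "coef"] < 0),
        ):
            hits = ora_test(set(degs[mask]), go_db) if mask.any() else pd.DataFrame()
            if out is not None and len(hits):
                write_table(hits, out / f"ora_{label}.tsv")
            manifest["stages"][f"ora_{label}"] = {"n_terms_tested": int(len(hits))}

    # ---- gene sets --------------------------------------------------------
    state["stage"] = "gene_sets"
    exclude = set(degs) | set(config.extra_excluded_genes)
    sets, set_report = build_gene_sets(dmps, cohort.annotation, exclude)
    if out is not None:
        write_gmt(sets, out / "gene_sets.gmt")
    manifest["stages"]["gene_sets"] = {
        "n_sets": len(sets),
        "sizes": set_report["set_sizes"],
        "n_excluded_genes_hit": set_report["n_excluded_genes_hit"],
    }

    # ---- rotation gene set tests ------------------------------------------
    state["stage"] = "roast"
    roast_cfg = config.roast
    if roast_cfg.seed != config.seed:
        roast_cfg = RoastConfig(
            nrot=roast_cfg.nrot,
            set_statistic=roast_cfg.set_statistic,
            seed=config.seed,
            hypotheses=roast_cfg.hypotheses,
        )
    roast_tab = roast_all_sets(expr, X_dge, "exposure", sets, roast_cfg)
    roast_out = roast_tab.copy()
    roast_out.insert(0, "set", roast_out.index)
    if out is not None:
        write_table(roast_out, out / "roast.tsv")
    manifest["stages"]["roast"] = {
        "nrot": roast_cfg.nrot,
        "n_sets_tested": int((roast_tab["n_genes"] > 0).sum()),
    }

    if out is not None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(
        ewas=ewas_tab,
        dge=dge_tab,
        sets=sets,
        roast=roast_tab,
        cell_proportions=cell_props,
        inflation=lam,
        manifest=manifest,
    )


def simulate_and_run(
    sim: SimConfig,
    config: PipelineConfig,
    annotation: ProbeAnnotation,
    out_dir=None,
    panel: pd.DataFrame | None = None,
) -> tuple[SimulatedCohort, PipelineResult]:
    """Convenience wrapper: generate a cohort, then analyse it."""
    cohort = generate_cohort(sim, annotation, panel=panel)
    result = run_pipeline(cohort, config, out_dir=out_dir, panel=panel)
    return cohort, result
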