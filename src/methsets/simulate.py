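"""Synthetic paired methylome/transcriptome cohorts with a truth ledger.

Emulates the statistical structure the analysis assumes: logit-normal
beta values with exposure effects planted in chosen (region, direction)
cells, coordinated small log2-expression shifts in the genes of the
affected sets, covariate and (optional) cell-composition confounding,
and a majority of null features.  Every planted effect is recorded in a
:class:`TruthLedger`, so each downstream stage can be tested without
access to any real cohort.

Methylation effects are planted on the logit scale as the shift that
induces the requested beta-scale group difference at the probe's
baseline, which keeps beta values bounded without truncation artifacts:
at vanishing noise the realized exposed-minus-unexposed difference
equals ``delta_beta`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .annotation import ProbeAnnotation
from .cells import BLOOD_MEAN, CELL_TYPES
from .genesets import ARRAY_REGIONS
from .io import read_matrix, read_table, write_matrix, write_table

__all__ = [
    "SimConfig",
    "SimulatedCohort",
    "TruthLedger",
    "generate_annotation",
    "generate_cohort",
    "export_cohort",
    "read_cohort",
]

DATA_FILES = ("beta.tsv", "expression.tsv", "covariates.tsv",
              "annotation.tsv", "truth.tsv")


class ConfigurationError(ValueError):
    """Raised when a simulation request cannot be satisfied."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Cohort-generator settings.

    Defaults mirror the structure of a large adult whole-blood cohort:
    ~13.5% exposed (150 of 1114), beta-scale exposure effects of a few
    percent, and coordinated log2 expression shifts small enough to be
    individually non-significant.  ``n_affected_per_region`` maps
    ``(region, direction)`` cells to the number of planted probes;
    ``expr_cells`` lists the cells whose linked genes also receive the
    (signed) ``delta_expr`` expression shift.
    """

    n_samples: int = 1114
    exposure_fraction: float = 150 / 1114
    n_genes: int = 240
    probes_per_gene: int = 8
    n_affected_per_region: dict = field(default_factory=dict)
    delta_beta: float = 0.05
    delta_expr: float = 0.15
    expr_cells: tuple = (("Body", "hypo"),)
    noise_sd_meth: float = 0.12
    noise_sd_expr: float = 0.5
    confounder_effects: dict = field(
        default_factory=lambda: {"age": 0.05, "sex": 0.1, "bmi": 0.05,
                                 "alcohol": 0.03, "ses": 0.05}
    )
    cell_mixing: dict | None = None       # Dirichlet concentration per cell type
    cell_exposure_tilt: float = 0.5       # relative Gran shift in exposed samples
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.exposure_fraction < 1:
            raise ValueError("exposure_fraction must be strictly inside (0,1)")
        if self.n_samples < 0 or self.n_genes < 0 or self.probes_per_gene < 0:
            raise ValueError("counts must be non-negative")
        if self.noise_sd_meth <= 0 or self.noise_sd_expr <= 0:
            raise ValueError("noise SDs must be positive")
        for (region, direction), count in self.n_affected_per_region.items():
            if region not in ARRAY_REGIONS:
                raise ValueError(f"unknown region label {region!r}")
            if direction not in ("hypo", "hyper"):
                raise ValueError(f"unknown direction {direction!r}")
            if count < 0:
                raise ValueError("affected counts must be >= 0")


@dataclass
class TruthLedger:
    """Planted effects: affected probes/genes and the null remainder."""

    affected_cpgs: pd.DataFrame   # probe, gene, region, direction, delta_beta
    affected_genes: pd.DataFrame  # gene, delta_expr
    null_probes: pd.Index
    null_genes: pd.Index


@dataclass
class SimulatedCohort:
    beta: pd.DataFrame
    expression: pd.DataFrame
    covariates: pd.DataFrame
    annotation: ProbeAnnotation
    true_proportions: pd.DataFrame
    truth: TruthLedger
    config: SimConfig | None = None

    @property
    def samples(self) -> pd.Index:
        return self.beta.columns


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(
    n_genes: int,
    probes_per_gene: int = 8,
    seed: int = 0,
    intergenic_fraction: float = 0.2,
    multi_gene_fraction: float = 0.05,
    ensure_all_regions: bool = True,
    n_intergenic: int | None = None,
) -> ProbeAnnotation:
    """Random autosomal probe annotation.

    Every gene receives one probe per array region label (when
    ``ensure_all_regions``) plus a Poisson number of extra probes with
    random labels.  A fraction of gene-linked probes link to a second
    gene; intergenic probes carry no gene link.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if n_genes == 0 and not n_intergenic:
        raise ValueError(
            "n_genes = 0 requires an explicit intergenic-only configuration "
            "(set n_intergenic > 0)"
        )
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i:04d}" for i in range(1, n_genes + 1)]
    links: list[dict] = []
    probe_regions: list[list[str]] = []
    probe_genes: list[list[str]] = []
    for g in genes:
        labels = list(ARRAY_REGIONS) if ensure_all_regions else []
        extra = rng.poisson(max(probes_per_gene - len(labels), 0))
        labels += list(rng.choice(ARRAY_REGIONS, size=extra))
        for lab in labels:
            probe_genes.append([g])
            probe_regions.append([lab])
    n_gene_probes = len(probe_genes)
    # second gene links
    if n_genes > 1 and multi_gene_fraction > 0 and n_gene_probes:
        n_multi = int(round(multi_gene_fraction * n_gene_probes))
        for i in rng.choice(n_gene_probes, size=n_multi, replace=False):
            other = rng.choice([g for g in genes if g != probe_genes[i][0]])
            probe_genes[i].append(str(other))
            probe_regions[i].append(str(rng.choice(ARRAY_REGIONS)))
    # intergenic probes
    if n_intergenic is None:
        if not 0 <= intergenic_fraction < 1:
            raise ValueError("intergenic_fraction must be in [0,1)")
        n_intergenic = int(round(
            intergenic_fraction / (1 - intergenic_fraction) * n_gene_probes
        ))
    for _ in range(n_intergenic):
        probe_genes.append([])
        probe_regions.append([])

    n_probes = len(probe_genes)
    ids = [f"cg{i:08d}" for i in range(1, n_probes + 1)]
    probes = pd.DataFrame(
        {
            "chrom": [f"chr{c}" for c in rng.integers(1, 23, size=n_probes)],
            "pos": rng.integers(1, 2_500_000_00, size=n_probes),
        },
        index=pd.Index(ids, name="probe"),
    )
    for pid, gs, regs in zip(ids, probe_genes, probe_regions):
        for g, r in zip(gs, regs):
            links.append({"probe": pid, "gene": g, "region": r})
    gene_map = pd.DataFrame(links, columns=["probe", "gene", "region"])
    return ProbeAnnotation(probes=probes, gene_map=gene_map)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def _draw_covariates(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_samples
    samples = pd.Index([f"S{i:04d}" for i in range(1, n + 1)], name="sample")
    n_exposed = int(round(cfg.exposure_fraction * n))
    exposure = np.zeros(n, dtype=int)
    exposure[rng.choice(n, size=n_exposed, replace=False)] = 1
    return pd.DataFrame(
        {
            "exposure": exposure,
            "age": np.clip(rng.normal(42, 5, n), 34, 49).round(1),
            "sex": rng.binomial(1, 0.46, n),                 # 1 = male
            "bmi": np.clip(rng.normal(26.5, 5, n), 16, 50).round(1),
            "alcohol": rng.gamma(1.2, 0.8, n).round(2),
            "ses": rng.choice(["low", "medium", "high"], n, p=[0.2, 0.4, 0.4]),
        },
        index=samples,
    )


def _covariate_design(cov: pd.DataFrame) -> dict[str, np.ndarray]:
    """Standardized numeric encodings used to build confounder signal."""
    ses_num = cov["ses"].map({"low": 0.0, "medium": 1.0, "high": 2.0}).to_numpy()
    return {
        "age": _standardize(cov["age"].to_numpy(float)),
        "sex": _standardize(cov["sex"].to_numpy(float)),
        "bmi": _standardize(cov["bmi"].to_numpy(float)),
        "alcohol": _standardize(cov["alcohol"].to_numpy(float)),
        "ses": _standardize(ses_num),
    }


def _pick_affected(
    cfg: SimConfig, annotation: ProbeAnnotation, rng: np.random.Generator
) -> pd.DataFrame:
    """Choose distinct probes per (region, direction) cell; error naming
    the cell when a region has too few gene-linked probes left."""
    gm = annotation.gene_map
    chosen: list[dict] = []
    used: set[str] = set()
    used_genes: set[str] = set()
    for (region, direction), count in sorted(cfg.n_affected_per_region.items()):
        avail = gm.loc[(gm["region"] == region) & ~gm["probe"].isin(used), "probe"]
        avail = avail.drop_duplicates()
        if len(avail) < count:
            raise ConfigurationError(
                f"not enough probes for cell (region={region}, "
                f"direction={direction}): need {count}, have {len(avail)}"
            )
        # prefer probes of genes not already carrying an effect, so the
        # planted (region, direction) cells stay distinct
        fresh_probes = set(
            gm.loc[~gm["gene"].isin(used_genes), "probe"]
        ) - set(gm.loc[gm["gene"].isin(used_genes), "probe"])
        fresh = avail[avail.isin(fresh_probes)]
        pool = fresh if len(fresh) >= count else avail
        picks = rng.choice(pool.to_numpy(), size=count, replace=False)
        used.update(picks)
        used_genes.update(gm.loc[gm["probe"].isin(picks), "gene"])
        sign = -1.0 if direction == "hypo" else 1.0
        for p in picks:
            for _, link in gm[gm["probe"] == p].iterrows():
                chosen.append(
                    {
                        "probe": p,
                        "gene": link["gene"],
                        "region": link["region"],
                        "direction": direction,
                        "delta_beta": sign * abs(cfg.delta_beta),
                        "cell": (region, direction),
                    }
                )
    return pd.DataFrame(
        chosen, columns=["probe", "gene", "region", "direction", "delta_beta", "cell"]
    )


def generate_cohort(
    config: SimConfig,
    annotation: ProbeAnnotation,
    panel: pd.DataFrame | None = None,
) -> SimulatedCohort:
    """Generate a paired beta/expression cohort with planted effects.

    Beta values: logit-scale baseline + confounder effects + (optional)
    cell-composition signal + exposure effect on affected probes +
    Gaussian noise, mapped through the inverse logit (hence in (0,1)).
    Expression: per-gene baseline + confounder effects + exposure x
    ``delta_expr`` on genes of the affected ``expr_cells`` + noise.
    """
    rng = np.random.default_rng(config.seed)
    cov = _draw_covariates(config, rng)
    exposed = cov["exposure"].to_numpy() == 1
    n = config.n_samples
    if n == 0:
        raise ConfigurationError("cannot generate a cohort with 0 samples")

    probes = annotation.probes.index
    n_probes = len(probes)
    affected = _pick_affected(config, annotation, rng)
    affected_idx = pd.Index(affected["probe"].unique())

    # cell proportions (always drawn; only confound methylation when enabled)
    conc = (
        pd.Series(config.cell_mixing, dtype=float)
        if config.cell_mixing is not None
        else pd.Series({c: 30 * BLOOD_MEAN[c] for c in CELL_TYPES})
    )
    conc = conc.reindex(list(CELL_TYPES)).dropna()
    alpha = np.tile(conc.to_numpy(), (n, 1))
    if config.cell_mixing is not None and "Gran" in conc.index:
        gcol = list(conc.index).index("Gran")
        alpha[exposed, gcol] *= 1 + config.cell_exposure_tilt
    props = np.vstack([rng.dirichlet(a) for a in alpha])
    true_props = pd.DataFrame(props, index=cov.index, columns=conc.index)

    # baseline logit methylation; affected probes kept mid-range so the
    # requested beta-scale delta fits inside (0,1)
    mu = rng.normal(0.0, 1.2, size=n_probes)
    mid = logit(rng.uniform(0.3, 0.7, size=len(affected_idx)))
    mu_series = pd.Series(mu, index=probes)
    mu_series.loc[affected_idx] = mid
    L = np.tile(mu_series.to_numpy()[:, None], (1, n))

    # confounder effects on a random subset of probes
    enc = _covariate_design(cov)
    for name, scale in config.confounder_effects.items():
        if name not in enc or scale == 0:
            continue
        mask = rng.random(n_probes) < 0.3
        coefs = rng.normal(0.0, scale, size=n_probes) * mask
        L += np.outer(coefs, enc[name])

    # optional cell-composition signal on the panel probes
    if config.cell_mixing is not None and panel is not None:
        common = panel.index.intersection(probes)
        if len(common):
            mix = true_props[panel.columns].to_numpy() @ panel.loc[common].to_numpy().T
            rowpos = mu_series.index.get_indexer(common)
            L[rowpos, :] = logit(np.clip(mix.T, 1e-6, 1 - 1e-6))

    # exposure effect: logit shift inducing delta_beta at the baseline
    for probe, delta in (
        affected[["probe", "delta_beta"]].drop_duplicates("probe").to_numpy()
    ):
        i = mu_series.index.get_loc(probe)
        p0 = expit(mu_series.iloc[i])
        shift = logit(np.clip(p0 + delta, 1e-6, 1 - 1e-6)) - logit(p0)
        L[i, exposed] += shift

    L += rng.normal(0.0, config.noise_sd_meth, size=L.shape)
    beta = pd.DataFrame(expit(L), index=probes, columns=cov.index)

    # expression
    genes = annotation.genes
    base = rng.normal(7.0, 1.0, size=len(genes))
    E = np.tile(base[:, None], (1, n))
    for name, scale in config.confounder_effects.items():
        if name not in enc or scale == 0:
            continue
        mask = rng.random(len(genes)) < 0.3
        coefs = rng.normal(0.0, scale, size=len(genes)) * mask
        E += np.outer(coefs, enc[name])
    # coordinated expression shifts go to genes whose own (region,
    # direction) link matches an expr_cell, i.e. exactly the genes that a
    # perfect EWAS would place in those sets
    expr_cells = set(map(tuple, config.expr_cells))
    link_cells = list(zip(affected["region"], affected["direction"]))
    aff_genes = sorted(
        set(affected.loc[[c in expr_cells for c in link_cells], "gene"])
    )
    gpos = genes.get_indexer(aff_genes)
    for i in gpos:
        E[i, exposed] += config.delta_expr
    E += rng.normal(0.0, config.noise_sd_expr, size=E.shape)
    expression = pd.DataFrame(E, index=genes, columns=cov.index)

    truth = TruthLedger(
        affected_cpgs=affected.drop(columns="cell").reset_index(drop=True),
        affected_genes=pd.DataFrame(
            {"gene": aff_genes, "delta_expr": config.delta_expr}
        ),
        null_probes=probes.difference(affected_idx),
        null_genes=genes.difference(pd.Index(aff_genes)),
    )
    return SimulatedCohort(
        beta=beta,
        expression=expression,
        covariates=cov,
        annotation=annotation,
        true_proportions=true_props,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

def export_cohort(cohort: SimulatedCohort, directory) -> dict:
    """Write the cohort as five TSV data files plus a manifest; the
    readers round-trip the result losslessly."""
    if cohort.beta.shape[1] == 0:
        raise ValueError("refusing to export a cohort with 0 samples")
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_matrix(cohort.beta, d / "beta.tsv", index_label="probe")
    write_matrix(cohort.expression, d / "expression.tsv", index_label="gene")
    write_matrix(cohort.covariates, d / "covariates.tsv", index_label="sample")
    write_matrix(cohort.annotation.to_frame(), d / "annotation.tsv",
                 index_label="probe")
    truth = pd.concat(
        [
            cohort.truth.affected_cpgs.assign(kind="cpg"),
            cohort.truth.affected_genes.assign(kind="gene"),
        ]
    )
    write_table(truth, d / "truth.tsv")
    seed = cohort.config.seed if cohort.config else None
    manifest = {"files": list(DATA_FILES), "seed": seed}
    lines = [f"seed\t{seed}"] + [f"file\t{f}" for f in DATA_FILES]
    (d / "manifest.txt").write_text("\n".join(lines) + "\n")
    return manifest


def read_cohort(directory) -> SimulatedCohort:
    """Reconstruct a cohort from :func:`export_cohort` output."""
    d = Path(directory)
    beta = read_matrix(d / "beta.tsv")
    expression = read_matrix(d / "expression.tsv")
    covariates = read_matrix(d / "covariates.tsv")
    beta.columns.name = expression.columns.name = "sample"
    expression.index.name = "gene"
    annotation = ProbeAnnotation.from_frame(read_matrix(d / "annotation.tsv"))
    truth_tab = read_table(d / "truth.tsv")
    cpgs = truth_tab.loc[
        truth_tab["kind"] == "cpg",
        ["probe", "gene", "region", "direction", "delta_beta"],
    ]
    genes_t = truth_tab[truth_tab["kind"] == "gene"][["gene", "delta_expr"]]
    truth = TruthLedger(
        affected_cpgs=cpgs.reset_index(drop=True),
        affected_genes=genes_t.reset_index(drop=True),
        null_probes=beta.index.difference(pd.Index(cpgs["probe"].unique())),
        null_genes=expression.index.difference(pd.Index(genes_t["gene"].unique())),
    )
    return SimulatedCohort(
        beta=beta,
        expression=expression,
        covariates=covariates,
        annotation=annotation,
        true_proportions=pd.DataFrame(index=covariates.index),
        truth=truth,
        config=None,
    )
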