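# methsets

Gene-set based integrative analysis of blood DNA methylation and gene
expression measured on the same individuals.

Single-CpG epigenome-wide association studies (EWAS) readily find CpG
sites whose methylation tracks an exposure such as cigarette smoking,
but the downstream transcriptomic consequences are usually too small to
reach single-gene significance. `methsets` implements the system-level
alternative: pool the genes that carry exposure-associated CpGs in the
same genomic region, and test each pooled set for coordinated expression
change with a self-contained rotation gene set test. Small, individually
invisible shifts become detectable when they are consistent across a set.

## What it computes

1. **EWAS / DGE engine** — per-feature OLS of beta values (or log2
   expression) on exposure plus covariates (age, sex, BMI, alcohol,
   socioeconomic status, estimated cell proportions, principal-component
   scores), with empirical-Bayes variance moderation: the moderated
   t-statistic is `t̃_g = β̂_g / (s̃_g √v)` with
   `s̃²_g = (d₀s₀² + d s²_g)/(d₀ + d)` on `d₀ + d` df, where `(d₀, s₀²)`
   are method-of-moments estimates from all features' log s².
   Benjamini–Hochberg FDR and the genomic inflation factor
   `λ = median(χ²_obs)/0.4549` are computed alongside.
2. **Cell composition** — Houseman-type constrained projection of each
   sample onto purified-leukocyte reference profiles
   (`min‖Profile·w − β‖²`, `w ≥ 0`, `Σw = 1`) for CD8T, CD4T, NK, B
   cells, monocytes and granulocytes.
3. **Gene sets** — 16 sets over 8 region categories (TSS1500, TSS200,
   5′UTR, first exon, body, 3′UTR, exon boundary, and promoter = the
   union of the first four) × 2 directions (hypo-/hypermethylated),
   built from CpGs passing the Bonferroni cutoff (e.g. 0.05/769,683 ≈
   6.5×10⁻⁸ at EPIC scale), with FDR-significant DEGs removed.
4. **Rotation gene set test (ROAST-style)** — for each set, genes are
   reduced to an effect coordinate plus residual coordinates via the
   design's QR basis; each of `nrot` rotations draws one random unit
   direction shared across genes (preserving inter-gene correlation)
   and recomputes moderated t's; set statistics mean(t̃), −mean(t̃) and
   mean(|t̃|) give p.up / p.down / p.mixed as `(b+1)/(nrot+1)`.
5. **ORA** — hypergeometric over-representation of up-/downregulated
   gene lists against a GMT database, universe = measured genes.
6. **Synthetic cohorts** — a generator that plants beta-scale
   methylation effects per (region, direction) cell, coordinated small
   log2-expression shifts in the affected sets, covariate and optional
   cell-composition confounding, with a full truth ledger.

## Worked example

```python
import methsets as m

regions = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR", "ExonBnd")
cells = {(r, d): 3 for r in regions for d in ("hypo", "hyper")}
cells[("Body", "hypo")] = 12          # the set with coordinated upregulation

ann = m.generate_annotation(n_genes=240, probes_per_gene=8, seed=7)
sim = m.SimConfig(n_samples=200, exposure_fraction=0.3, n_genes=240,
                  n_affected_per_region=cells, seed=7)
cohort = m.generate_cohort(sim, ann)

cfg = m.PipelineConfig(n_pcs_ewas=3, n_pcs_dge=3,
                       roast=m.RoastConfig(nrot=9999, seed=7), seed=7)
res = m.run_pipeline(cohort, cfg)

print(f"lambda = {res.inflation:.2f}")
print(f"DMPs at p < 0.05/{len(res.ewas)}: "
      f"{res.manifest['stages']['dmps']['n_significant']}")
print(f"single-gene DEGs at FDR < 0.05: {res.manifest['stages']['dge']['n_degs']}")
cols = ["n_genes", "p.up", "p.mixed", "FDR.up", "FDR.mixed"]
print(res.roast.sort_values("p.up")[cols].head(4).to_string())
```

prints

```
lambda = 1.10
DMPs at p < 0.05/2398: 51
single-gene DEGs at FDR < 0.05: 0
               n_genes    p.up  p.mixed    FDR.up  FDR.mixed
set
Body_hypo           12  0.0001   0.0001  0.001600   0.001600
Body_hyper           3  0.0092   0.0549  0.073600   0.439200
1stExon_hyper        4  0.0247   0.2639  0.131733   0.909547
TSS200_hypo          3  0.0992   0.4685  0.396800   0.909547
```

Read: association tests are well calibrated (λ ≈ 1.1); all 51 planted
CpGs reach epigenome-wide significance; *no* gene is individually
differentially expressed — yet the set of genes with hypomethylated
body-region CpGs, whose expression was shifted by only +0.15 log2, is
detected with p.up = 1/(nrot+1), the smallest achievable rotation
p-value, while the 15 sets without coordinated shifts are not.

A thin CLI mirrors the stages
(`methsets simulate|qc|ewas|dge|sets|roast|ora|run`), e.g.

```bash
methsets run --seed 7 --nrot 9999 --out results/demo
```

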