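"""Synthetic cohort generator: annotation, planted effects, export."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, ttest_ind

import methsets as m
from methsets.simulate import ConfigurationError, DATA_FILES

REGIONS = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR", "ExonBnd")


class TestAnnotation:
    def test_every_region_label_present_per_gene(self):
        ann = m.generate_annotation(10, seed=0, ensure_all_regions=True)
        counts = ann.gene_map["region"].value_counts()
        for region in REGIONS:
            assert counts.get(region, 0) >= 10

    def test_intergenic_only_configuration_has_no_gene_links(self):
        ann = m.generate_annotation(0, seed=0, n_intergenic=7)
        assert len(ann.gene_map) == 0
        assert len(ann) == 7

    def test_invalid_gene_counts_rejected(self):
        with pytest.raises(ValueError):
            m.generate_annotation(-1, seed=0)
        with pytest.raises(ValueError):
            m.generate_annotation(0, seed=0)  # no intergenic-only config

    def test_same_seed_reproduces_annotation(self):
        a = m.generate_annotation(15, seed=42)
        b = m.generate_annotation(15, seed=42)
        pd.testing.assert_frame_equal(a.probes, b.probes)
        pd.testing.assert_frame_equal(a.gene_map, b.gene_map)

    def test_intergenic_and_multigene_fractions(self):
        ann = m.generate_annotation(100, seed=3, intergenic_fraction=0.2,
                                    multi_gene_fraction=0.05)
        linked = set(ann.gene_map["probe"])
        frac_intergenic = 1 - len(linked) / len(ann)
        assert 0.15 < frac_intergenic < 0.25
        per_probe = ann.gene_map.groupby("probe")["gene"].nunique()
        assert (per_probe == 2).sum() > 0
        assert ann.probes["chrom"].str.match(r"chr([1-9]|1[0-9]|2[0-2])$").all()

    def test_flat_frame_round_trips(self, annotation):
        flat = annotation.to_frame()
        back = m.ProbeAnnotation.from_frame(flat)
        pd.testing.assert_frame_equal(
            annotation.gene_map.sort_values(["probe", "gene"]).reset_index(drop=True),
            back.gene_map.sort_values(["probe", "gene"]).reset_index(drop=True),
        )


class TestCohort:
    def test_null_config_gives_uniform_pvalues(self, annotation):
        cfg = m.SimConfig(
            n_samples=120, exposure_fraction=0.5, n_genes=40,
            delta_beta=0.0, delta_expr=0.0, confounder_effects={}, seed=5,
        )
        co = m.generate_cohort(cfg, annotation)
        exposed = co.covariates["exposure"] == 1
        B = co.beta.to_numpy()
        p = ttest_ind(B[:, exposed.to_numpy()], B[:, ~exposed.to_numpy()], axis=1).pvalue
        assert kstest(p, "uniform").pvalue > 0.01

    def test_planted_beta_difference_recovered(self, annotation):
        cells = {("Body", "hypo"): 1}
        cfg = m.SimConfig(
            n_samples=1000, exposure_fraction=0.5, n_genes=40,
            n_affected_per_region=cells, delta_beta=0.05,
            noise_sd_meth=0.02, confounder_effects={}, seed=6,
        )
        co = m.generate_cohort(cfg, annotation)
        probe = co.truth.affected_cpgs["probe"].iloc[0]
        exposed = (co.covariates["exposure"] == 1).to_numpy()
        diff = co.beta.loc[probe, exposed].mean() - co.beta.loc[probe, ~exposed].mean()
        assert diff == pytest.approx(-0.05, abs=0.01)

    def test_vanishing_noise_gives_exact_logit_induced_delta(self, annotation):
        cells = {("TSS200", "hyper"): 2}
        cfg = m.SimConfig(
            n_samples=40, exposure_fraction=0.5, n_genes=40,
            n_affected_per_region=cells, delta_beta=0.04,
            noise_sd_meth=1e-9, confounder_effects={}, seed=7,
        )
        co = m.generate_cohort(cfg, annotation)
        exposed = (co.covariates["exposure"] == 1).to_numpy()
        for probe in co.truth.affected_cpgs["probe"].unique():
            diff = (co.beta.loc[probe, exposed].mean()
                    - co.beta.loc[probe, ~exposed].mean())
            assert diff == pytest.approx(0.04, abs=1e-6)

    @pytest.mark.parametrize("noise", [0.1, 1.0, 5.0])
    def test_beta_always_bounded(self, annotation, noise):
        cfg = m.SimConfig(n_samples=30, exposure_fraction=0.4, n_genes=40,
                          noise_sd_meth=noise, seed=8)
        co = m.generate_cohort(cfg, annotation)
        assert ((co.beta >= 0) & (co.beta <= 1)).all().all()
        assert np.isfinite(co.expression.to_numpy()).all()

    def test_identical_config_and_seed_identical_cohorts(self, annotation):
        cfg = m.SimConfig(n_samples=25, exposure_fraction=0.4, n_genes=40, seed=9)
        a = m.generate_cohort(cfg, annotation)
        b = m.generate_cohort(cfg, annotation)
        pd.testing.assert_frame_equal(a.beta, b.beta)
        pd.testing.assert_frame_equal(a.expression, b.expression)
        pd.testing.assert_frame_equal(a.covariates, b.covariates)

    def test_truth_ledger_consistency(self, small_cohort):
        truth = small_cohort.truth
        ann = small_cohort.annotation
        assert set(truth.affected_cpgs["probe"]) <= set(ann.probes.index)
        assert set(truth.affected_cpgs["direction"]) <= {"hypo", "hyper"}
        assert set(truth.affected_genes["gene"]) <= set(ann.genes)
        assert len(truth.null_probes) + truth.affected_cpgs["probe"].nunique() == len(ann)

    def test_insufficient_probes_error_names_cell(self, annotation):
        cfg = m.SimConfig(
            n_samples=20, exposure_fraction=0.4, n_genes=40,
            n_affected_per_region={("ExonBnd", "hyper"): 10_000}, seed=1,
        )
        with pytest.raises(ConfigurationError, match="ExonBnd"):
            m.generate_cohort(cfg, annotation)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            m.SimConfig(exposure_fraction=0.0)
        with pytest.raises(ValueError):
            m.SimConfig(noise_sd_meth=0.0)
        with pytest.raises(ValueError):
            m.SimConfig(n_affected_per_region={("NotARegion", "hypo"): 1})


class TestExport:
    def test_round_trip_through_tsv(self, small_cohort, tmp_path):
        manifest = m.export_cohort(small_cohort, tmp_path)
        assert sorted(manifest["files"]) == sorted(DATA_FILES)
        back = m.read_cohort(tmp_path)
        pd.testing.assert_frame_equal(small_cohort.beta, back.beta)
        pd.testing.assert_frame_equal(small_cohort.expression, back.expression)
        pd.testing.assert_frame_equal(
            small_cohort.truth.affected_cpgs, back.truth.affected_cpgs
        )

    def test_manifest_lists_exactly_five_data_files(self, small_cohort, tmp_path):
        manifest = m.export_cohort(small_cohort, tmp_path)
        assert len(manifest["files"]) == 5
        for f in manifest["files"]:
            assert (tmp_path / f).exists()

    def test_refuses_empty_cohort(self, small_cohort, tmp_path):
        import dataclasses

        empty = dataclasses.replace(
            small_cohort,
            beta=small_cohort.beta.iloc[:, :0],
            expression=small_cohort.expression.iloc[:, :0],
            covariates=small_cohort.covariates.iloc[:0],
        )
        with pytest.raises(ValueError, match="0 samples"):
            m.export_cohort(empty, tmp_path / "empty")
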