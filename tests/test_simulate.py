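"""Synthetic-data generators: determinism, planted effects, bookkeeping."""

from dataclasses import replace

import numpy as np
import pytest

from surface_triage.simulate import (
    GroundTruth,
    PlantedTarget,
    SimConfig,
    gen_bulk_counts,
    gen_flow_events,
    gen_protein_abundance,
    gen_sc_dataset,
    gen_surfaceome_annotation,
    gen_tissue_reference,
    protein_panel,
)
from surface_triage.flow import antigens_per_cell, fit_bead_calibration


class TestDeterminism:
    def test_bulk_counts_reproducible(self, config):
        a, _ = gen_bulk_counts(config)
        b, _ = gen_bulk_counts(config)
        assert a.counts.equals(b.counts)
        assert a.samples.equals(b.samples)

    def test_sc_counts_reproducible(self, config):
        a, _ = gen_sc_dataset(config)
        b, _ = gen_sc_dataset(config)
        assert (a.X != b.X).nnz == 0
        assert a.obs.equals(b.obs)

    def test_protein_and_flow_reproducible(self, config):
        a, _ = gen_protein_abundance(config)
        b, _ = gen_protein_abundance(config)
        assert a.abundance.equals(b.abundance)
        e1, b1 = gen_flow_events(config)
        e2, b2 = gen_flow_events(config)
        assert e1.equals(e2) and b1.equals(b2)

    def test_different_seeds_differ(self, config):
        a, _ = gen_bulk_counts(config)
        b, _ = gen_bulk_counts(config.with_seed(config.seed + 1))
        assert not a.counts.equals(b.counts)


class TestBulkGenerator:
    def test_planted_fold_change_recovered_empirically(self):
        cfg = SimConfig(
            seed=123,
            n_genes=50,
            planted_targets=[PlantedTarget("T01", true_log2fc_bulk=3.0, surface_sources=("HPA",))],
        )
        m, _ = gen_bulk_counts(cfg)
        groups = m.samples["group"]
        cpm = m.counts / m.counts.sum(axis=0) * 1e6
        ratio = (
            cpm.loc["T01", groups[groups == "disease"].index].mean()
            / cpm.loc["T01", groups[groups == "control"].index].mean()
        )
        assert 2**2.5 <= ratio <= 2**3.5

    def test_zero_planted_targets_means_empty_truth(self):
        cfg = SimConfig(seed=5, n_genes=30, planted_targets=[])
        _, gt = gen_bulk_counts(cfg)
        assert gt.expected_final_candidates == set()
        assert gt.expected_funnel_counts["expressed_surface"] == 0

    def test_planted_qc_failures_fail_qc(self):
        cfg = SimConfig(seed=7, n_qc_fail_samples=2)
        m, _ = gen_bulk_counts(cfg)
        assert m.counts.shape[1] == 32
        failing = m.samples[
            (m.samples["total_mapped_reads"] <= 30e6) | (m.samples["mito_ratio"] >= 0.10)
        ]
        assert len(failing) == 2

    def test_invalid_config_names_field(self):
        with pytest.raises(ValueError, match="missing_rate"):
            gen_protein_abundance(replace(SimConfig(), missing_rate=1.0))
        with pytest.raises(ValueError, match="nb_dispersion"):
            gen_bulk_counts(replace(SimConfig(), nb_dispersion=0.0))
        with pytest.raises(ValueError, match="lineage"):
            cfg = SimConfig()
            cfg.lineage_mixture = {"Blast": 1.0}
            gen_sc_dataset(cfg)

    def test_yaml_config_round_trip(self, tmp_path):
        import yaml

        spec = {
            "seed": 42,
            "n_genes": 80,
            "missing_rate": 0.05,
            "planted_targets": [
                {
                    "gene_id": "T01",
                    "true_log2fc_bulk": 7.0,
                    "surface_sources": ["HPA"],
                    "tissue_safe": False,
                    "tissue_tpm_overrides": {"Liver": 99.0},
                }
            ],
        }
        path = tmp_path / "sim.yaml"
        path.write_text(yaml.safe_dump(spec))
        cfg = SimConfig.from_yaml(path)
        assert cfg.seed == 42 and cfg.n_genes == 80
        assert cfg.planted_targets[0].tissue_tpm_overrides == {"Liver": 99.0}
        m, gt = gen_bulk_counts(cfg)
        assert m.counts.shape == (80, 30)
        assert gt.expected_funnel_counts == {
            "expressed_surface": 1,
            "enriched": 1,
            "tissue_safe": 0,
            "stringent": 0,
        }

    def test_inconsistent_tissue_safety_flag_rejected(self):
        bad = PlantedTarget("X1", tissue_safe=True, tissue_tpm_overrides={"Liver": 100.0})
        with pytest.raises(ValueError, match="tissue_safe"):
            SimConfig(planted_targets=[bad]).validate()


class TestScGenerator:
    def test_hsc_profile_by_construction(self, config):
        prof = config.lineage_profiles["HSC"]
        assert prof["CD34"] >= 5.0
        assert prof["CD38"] == 0.0 and prof["CD14"] == 0.0

    def test_planted_qc_fail_fraction_exact(self):
        cfg = replace(SimConfig(seed=11), n_sc_samples_per_group=4, n_cells_per_sample=125)
        cfg.sc_qc_fail_fraction = 0.1
        adata, _ = gen_sc_dataset(cfg)
        assert adata.n_obs == 1000
        violates = (
            (adata.obs["n_features"] < 200)
            | (adata.obs["n_features"] > 4000)
            | (adata.obs["total_counts"] < 1000)
            | (adata.obs["mito_fraction"] > 0.15)
        )
        assert int(adata.obs["planted_qc_fail"].sum()) == 100
        assert bool(violates[adata.obs["planted_qc_fail"]].all())
        assert int(violates.sum()) == 100

    def test_qc_metrics_consistent_with_matrix(self, config):
        adata, _ = gen_sc_dataset(config)
        import scipy.sparse as sp

        x = sp.csr_matrix(adata.X)
        assert (adata.obs["n_features"].to_numpy() == (x > 0).sum(axis=1).A1).all()
        assert (adata.obs["total_counts"].to_numpy() == x.sum(axis=1).A1).all()


class TestProteinGenerator:
    def test_missing_rate_zero_gives_complete_table(self):
        cfg = replace(SimConfig(seed=2), missing_rate=0.0, n_protein_high_missing=0)
        t, _ = gen_protein_abundance(cfg)
        assert not t.abundance.isna().any().any()

    def test_missing_fraction_within_binomial_tolerance(self):
        cfg = replace(SimConfig(seed=2), missing_rate=0.2, n_protein_high_missing=0)
        t, _ = gen_protein_abundance(cfg)
        frac = t.abundance.isna().to_numpy().mean()
        assert 0.15 <= frac <= 0.25

    def test_intensity_dependent_missingness_biases_low_abundance(self):
        cfg = replace(
            SimConfig(seed=9), missing_rate=0.2, missing_mode="intensity", n_protein_high_missing=0
        )
        t, _ = gen_protein_abundance(cfg)
        cfg_full = replace(cfg, missing_rate=0.0)
        full, _ = gen_protein_abundance(cfg_full)
        mask = t.abundance.isna().to_numpy()
        values = full.abundance.to_numpy()
        assert values[mask].mean() < values[~mask].mean()
        assert 0.1 <= mask.mean() <= 0.3

    def test_unknown_missing_mode_rejected(self):
        cfg = replace(SimConfig(), missing_mode="sometimes")
        with pytest.raises(ValueError, match="missing_mode"):
            gen_protein_abundance(cfg)

    def test_planted_contaminant_count_exact(self):
        cfg = replace(SimConfig(seed=2), n_protein_contaminants=5)
        t, _ = gen_protein_abundance(cfg)
        assert int(t.meta["contaminant"].sum()) == 5

    def test_high_missing_rows_cross_half(self):
        t, _ = gen_protein_abundance(SimConfig(seed=2))
        panel = protein_panel(SimConfig(seed=2)).set_index("accession")
        frac = t.abundance.isna().mean(axis=1)
        assert (frac[panel.index[panel["high_missing"]]] >= 0.5).all()


class TestTissueAndAnnotation:
    def test_safe_genes_capped_unsafe_exceed(self, config, ground_truth):
        ref = gen_tissue_reference(config)
        max_tpm = ref.max_non_exempt_tpm()
        for t in config.planted_targets:
            if t.tissue_safe:
                assert max_tpm[t.gene_id] <= 20.0
            else:
                assert max_tpm[t.gene_id] > 20.0

    def test_override_honored_exactly(self, config):
        ref = gen_tissue_reference(config)
        for t in config.planted_targets:
            for tissue, value in t.tissue_tpm_overrides.items():
                assert ref.tpm.loc[t.gene_id, tissue] == value

    def test_exempt_tissues_may_run_high_for_safe_genes(self, config):
        ref = gen_tissue_reference(config)
        exempt_cols = list(config.exempt_tissues)
        surface_safe = [t.gene_id for t in config.planted_targets if t.tissue_safe and t.is_surface]
        assert (ref.tpm.loc[surface_safe, exempt_cols].max(axis=1) > 20).all()

    def test_exempt_not_subset_is_config_error(self):
        cfg = replace(SimConfig(), tissue_names=("Liver", "Lung"))
        with pytest.raises(ValueError, match="exempt"):
            gen_tissue_reference(cfg)

    def test_annotation_membership_matches_planted_flags(self, config):
        ann, _ = gen_surfaceome_annotation(config)
        for t in config.planted_targets:
            assert ann.membership[t.gene_id] == frozenset(t.surface_sources)
        assert ann.membership["G0001"] == frozenset()

    def test_unmapped_accessions_absent_from_id_map(self, config):
        ann, id_map = gen_surfaceome_annotation(config)
        panel = protein_panel(config)
        mapped_acc = set(id_map.pairs["accession"])
        unmapped = set(panel.loc[~panel["mapped"] & ~panel["contaminant"], "accession"])
        assert len(unmapped) == config.n_protein_unmapped
        assert not (unmapped & mapped_acc)


class TestFlowGenerator:
    def test_noiseless_bead_round_trip_returns_planted_density(self, config):
        events, beads = gen_flow_events(config)
        cal = fit_bead_calibration(beads["molecules_per_bead"], beads["mfi"])
        stained = events[events["condition"] == "stained"]
        pos_median = stained.loc[stained["true_positive"], "intensity"].median()
        assert antigens_per_cell(cal, pos_median) == pytest.approx(
            config.antigen_density, rel=0.02
        )

    def test_planted_positive_fraction_recovered(self, config):
        events, _ = gen_flow_events(config)
        stained = events[events["condition"] == "stained"]
        assert stained["true_positive"].mean() == pytest.approx(0.6, abs=0.03)

    def test_fmo_has_no_positive_component(self, config):
        events, _ = gen_flow_events(config)
        fmo = events[events["condition"] == "FMO"]
        assert not fmo["true_positive"].any()

    def test_nonpositive_intensity_request_rejected(self):
        with pytest.raises(ValueError, match="flow"):
            gen_flow_events(replace(SimConfig(), flow_background_median=0.0))


class TestGroundTruthBookkeeping:
    def test_expected_counts_by_independent_brute_force(self, config, ground_truth):
        """Re-derive every expected set from the planted parameters alone."""
        surface = {t.gene_id for t in config.planted_targets if t.surface_sources}
        expressed = {t.gene_id for t in config.planted_targets if t.expressed}
        universe = surface & expressed
        enriched = {
            g for g in universe
            if next(t for t in config.planted_targets if t.gene_id == g).true_log2fc_bulk > 0
        }
        safe = {
            g for g in enriched
            if next(t for t in config.planted_targets if t.gene_id == g).tissue_safe
        }
        stringent = {
            g for g in safe
            if next(t for t in config.planted_targets if t.gene_id == g).true_log2fc_bulk > 6.5
        }
        assert ground_truth.expected_universe == universe
        assert ground_truth.expected_enriched == enriched
        assert ground_truth.expected_tissue_safe == safe
        assert ground_truth.expected_stringent == stringent
        counts = ground_truth.expected_funnel_counts
        assert (
            counts["expressed_surface"]
            >= counts["enriched"]
            >= counts["tissue_safe"]
            >= counts["stringent"]
        )
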