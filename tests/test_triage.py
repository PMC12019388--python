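"""Funnel filters, cross-modal intersection, report, correlation."""

import json

import numpy as np
import pandas as pd
import pytest

from surface_triage.triage import (
    IDMap,
    SurfaceomeAnnotation,
    TissueReference,
    TriageConfig,
    build_funnel_report,
    filter_enriched,
    filter_expressed,
    filter_stringency,
    filter_surfaceome,
    filter_tissue_safety,
    intersect_modalities,
    rna_protein_correlation,
)


def de_frame(rows):
    """rows: {gene: (log2fc, adj_p)}"""
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=["log2fc", "adj_p"])
    frame["p_value"] = frame["adj_p"] / 2
    return frame


def tissue_ref(rows, exempt=("Whole Blood", "Spleen", "Cells - EBV-transformed lymphocytes")):
    """rows: {gene: {tissue: tpm}}; unspecified tissues get 1.0."""
    tissues = sorted({t for r in rows.values() for t in r} | set(exempt) | {"Liver"})
    tpm = pd.DataFrame(1.0, index=list(rows), columns=tissues)
    for g, overrides in rows.items():
        for t, v in overrides.items():
            tpm.loc[g, t] = v
    return TissueReference(tpm, frozenset(exempt))


class TestFilterBoundaries:
    def test_enriched_strict_rules(self):
        de = de_frame(
            {
                "A": (0.8, 0.04),   # kept
                "B": (0.8, 0.06),   # adj_p boundary out
                "C": (0.8, 0.05),   # boundary: strict < removes
                "D": (-2.0, 1e-5),  # wrong direction
                "E": (0.0, 0.001),  # floor is strict >
            }
        )
        assert filter_enriched(de) == {"A"}

    def test_tissue_safety_strict_and_exempt(self):
        ref = tissue_ref(
            {
                "A": {"Brain": 25.0, "Whole Blood": 500.0},
                "B": {"Whole Blood": 500.0, "Spleen": 300.0, "Liver": 2.0},
                "C": {"Liver": 20.0},
                "D": {"Liver": 20.0001},
            }
        )
        out = filter_tissue_safety({"A", "B", "C", "D"}, ref)
        assert out == {"B", "C"}

    def test_gene_absent_from_reference_excluded(self):
        ref = tissue_ref({"A": {}})
        assert filter_tissue_safety({"A", "MYSTERY"}, ref) == {"A"}

    def test_stringency_strict_and_composed(self):
        de = de_frame({"A": (6.6, 0.01), "B": (6.5, 0.01), "C": (7.0, 0.01)})
        assert filter_stringency(de, {"A", "B"}) == {"A"}  # C not in input set

    def test_surfaceome_at_least_one_source(self):
        ann = SurfaceomeAnnotation(
            ("S1", "S2", "S3"),
            {"A": frozenset({"S1"}), "B": frozenset(), "C": frozenset({"S1", "S2", "S3"})},
        )
        assert filter_surfaceome({"A", "B", "C", "UNKNOWN"}, ann) == {"A", "C"}

    def test_expression_median_cpm_rule(self, bundle, config):
        de = bundle["bulk_de"]
        counts = bundle["counts"]
        out = filter_expressed(de, counts)
        unexpressed = {t.gene_id for t in config.planted_targets if not t.expressed}
        assert not (out & unexpressed)
        assert "T01" in out
        tighter = filter_expressed(de, counts, TriageConfig(expression_min_median_cpm=100.0))
        assert tighter <= out


class TestIntersection:
    def test_published_style_example(self):
        sc = de_frame(
            {"CD48": (2.0, 0.01), "ADGRE2": (1.5, 0.01), "CLEC12A": (3.0, 0.001), "CD7": (1.0, 0.02)}
        )
        prot = de_frame(
            {"p1": (1.2, 0.01), "p2": (0.8, 0.02), "p3": (2.5, 0.001), "p4": (1.1, 0.03)}
        )
        id_map = IDMap(
            pd.DataFrame(
                {
                    "gene_symbol": ["CD48", "ADGRE2", "CLEC12A", "CD38"],
                    "accession": ["p1", "p2", "p3", "p4"],
                }
            )
        )
        ref = tissue_ref({g: {} for g in ["CD48", "ADGRE2", "CLEC12A", "CD7", "CD38"]})
        out = intersect_modalities(sc, prot, ref, id_map)
        assert out.common_final == {"CD48", "ADGRE2", "CLEC12A"}
        assert out.cardinalities == {
            "n_sc_hits": 4,
            "n_protein_hits": 4,
            "n_overlap": 3,
            "n_sc_hits_safe": 4,
            "n_protein_hits_safe": 4,
            "n_common_final": 3,
        }

    def test_disjoint_hit_sets_give_zero_overlap(self):
        sc = de_frame({"A": (2.0, 0.01)})
        prot = de_frame({"p1": (2.0, 0.01)})
        id_map = IDMap(pd.DataFrame({"gene_symbol": ["B"], "accession": ["p1"]}))
        ref = tissue_ref({"A": {}, "B": {}})
        out = intersect_modalities(sc, prot, ref, id_map)
        assert out.overlap == set() and out.common_final == set()
        assert out.cardinalities["n_sc_hits"] == 1
        assert out.cardinalities["n_protein_hits"] == 1

    def test_unmapped_accessions_excluded_and_logged(self):
        prot = de_frame({"p1": (2.0, 0.01), "pX": (3.0, 0.001)})
        sc = de_frame({"A": (2.0, 0.01)})
        id_map = IDMap(pd.DataFrame({"gene_symbol": ["A"], "accession": ["p1"]}))
        ref = tissue_ref({"A": {}})
        out = intersect_modalities(sc, prot, ref, id_map)
        assert out.unmapped_accessions == {"pX"}
        assert out.protein_hits == {"A"}

    def test_bundle_cardinalities_equal_ground_truth(self, bundle, ground_truth):
        out = intersect_modalities(
            bundle["sc_de"], bundle["protein_de"], bundle["tissue_ref"], bundle["id_map"]
        )
        assert out.cardinalities == ground_truth.expected_intersection()
        assert out.common_final == {
            t.gene_id
            for t in ground_truth.targets
            if t.true_log2fc_sc > 0 and t.true_log2fc_protein > 0 and t.tissue_safe
        }


def brute_force_funnel(de, counts, annotation, ref, cfg):
    """Independent set-logic pass: plain loops over the gene universe."""
    disease_cols = counts.samples.index[counts.samples["group"] == "disease"]
    lib = counts.counts[disease_cols].sum(axis=0)
    universe, enriched, safe, stringent = set(), set(), set(), set()
    non_exempt = [t for t in ref.tpm.columns if t not in ref.exempt_tissues]
    for gene in counts.counts.index:
        cpms = sorted(
            counts.counts.loc[gene, s] / lib[s] * 1e6 for s in disease_cols
        )
        n = len(cpms)
        median = (
            cpms[n // 2] if n % 2 else (cpms[n // 2 - 1] + cpms[n // 2]) / 2
        )
        if median < cfg.expression_min_median_cpm or gene not in de.index:
            continue
        if not annotation.membership.get(gene, frozenset()):
            continue
        universe.add(gene)
        if not (
            de.loc[gene, "adj_p"] < cfg.enrichment_alpha
            and de.loc[gene, "log2fc"] > cfg.enrichment_log2fc_floor
        ):
            continue
        enriched.add(gene)
        if gene not in ref.tpm.index:
            continue
        if any(ref.tpm.loc[gene, t] > cfg.tissue_tpm_cutoff for t in non_exempt):
            continue
        safe.add(gene)
        if de.loc[gene, "log2fc"] > cfg.stringency_log2fc:
            stringent.add(gene)
    return universe, enriched, safe, stringent


class TestFunnelReport:
    def test_counts_match_brute_force_set_logic(self, bundle):
        cfg = TriageConfig()
        report = build_funnel_report(
            bundle["bulk_de"], bundle["counts"], bundle["annotation"], bundle["tissue_ref"], cfg
        )
        expected = brute_force_funnel(
            bundle["bulk_de"], bundle["counts"], bundle["annotation"], bundle["tissue_ref"], cfg
        )
        for stage, exp in zip(report.stage_sets, expected):
            assert report.stage_sets[stage] == exp

    def test_counts_monotone_and_candidates_pass_all_filters(self, bundle):
        report = build_funnel_report(
            bundle["bulk_de"], bundle["counts"], bundle["annotation"], bundle["tissue_ref"]
        )
        counts = list(report.funnel_counts.values())
        assert counts == sorted(counts, reverse=True)
        assert report.candidates[["enriched", "tissue_safe", "stringent"]].all().all()

    def test_threshold_tightening_never_grows_sets(self, bundle):
        base = TriageConfig()
        tighter = TriageConfig(
            expression_min_median_cpm=5.0,
            enrichment_alpha=0.01,
            enrichment_log2fc_floor=1.0,
            tissue_tpm_cutoff=5.0,
            stringency_log2fc=7.0,
        )
        args = (bundle["bulk_de"], bundle["counts"], bundle["annotation"], bundle["tissue_ref"])
        r1 = build_funnel_report(*args, base)
        r2 = build_funnel_report(*args, tighter)
        for stage in r1.stage_sets:
            assert r2.stage_sets[stage] <= r1.stage_sets[stage]

    def test_report_deterministic_json(self, bundle):
        args = (bundle["bulk_de"], bundle["counts"], bundle["annotation"], bundle["tissue_ref"])
        j1 = build_funnel_report(*args).to_json()
        j2 = build_funnel_report(*args).to_json()
        assert j1 == j2
        payload = json.loads(j1)
        assert payload["funnel_counts"]["expressed_surface"] >= payload["funnel_counts"]["stringent"]


class TestCorrelation:
    @staticmethod
    def _map_and_table(n=20):
        from surface_triage.proteomics import ProteinTable

        genes = [f"G{i}" for i in range(n)]
        accs = [f"p{i}" for i in range(n)]
        rna = pd.Series(np.linspace(1, 10, n), index=genes)
        id_map = IDMap(pd.DataFrame({"gene_symbol": genes, "accession": accs}))
        return rna, accs, id_map, ProteinTable

    def test_monotone_relationship_gives_rho_one(self):
        rna, accs, id_map, ProteinTable = self._map_and_table()
        abundance = pd.DataFrame({"s1": np.exp(rna.to_numpy()), "s2": np.exp(rna.to_numpy())})
        abundance.index = accs
        meta = pd.DataFrame(
            {"gene_symbol": rna.index, "contaminant": False, "unique_peptides": 2, "membrane": True},
            index=abundance.index,
        )
        table = ProteinTable(abundance, meta, pd.Series(["disease", "control"], index=["s1", "s2"]))
        out = rna_protein_correlation(rna, table, id_map)
        assert out["rho"] == pytest.approx(1.0)
        assert out["n_pairs"] == 20

    def test_reversed_ranking_gives_minus_one(self):
        rna, accs, id_map, ProteinTable = self._map_and_table()
        abundance = pd.DataFrame({"s1": -rna.to_numpy()})
        abundance.index = accs
        meta = pd.DataFrame(
            {"gene_symbol": rna.index, "contaminant": False, "unique_peptides": 2, "membrane": True},
            index=abundance.index,
        )
        table = ProteinTable(abundance, meta, pd.Series(["disease"], index=["s1"]))
        assert rna_protein_correlation(rna, table, id_map)["rho"] == pytest.approx(-1.0)

    def test_too_few_pairs_is_error(self):
        rna, accs, id_map, ProteinTable = self._map_and_table(n=5)
        abundance = pd.DataFrame({"s1": np.ones(5)}, index=accs)
        meta = pd.DataFrame(
            {"gene_symbol": rna.index, "contaminant": False, "unique_peptides": 2, "membrane": True},
            index=abundance.index,
        )
        table = ProteinTable(abundance, meta, pd.Series(["disease"], index=["s1"]))
        with pytest.raises(ValueError, match="pairs"):
            rna_protein_correlation(rna, table, id_map)

    def test_bundle_rna_protein_correlation_positive(self, bundle):
        rna = np.log2(
            bundle["counts"].counts.div(
                bundle["norm"].effective_library_size, axis=1
            )
            * 1e6
            + 1
        ).mean(axis=1)
        out = rna_protein_correlation(rna, bundle["protein_norm"], bundle["id_map"])
        assert out["rho"] > 0.3 and out["p_value"] < 0.05
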