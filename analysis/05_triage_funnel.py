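#!/usr/bin/env python
"""Target triage: funnel, cross-modal intersection, RNA-protein correlation.

Combines the bulk DE table with surfaceome membership, the tissue-safety
reference and the fold-change stringency cut, intersects single-cell and
proteomic hits, and compares everything against the planted ground truth.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from surface_triage import io
from surface_triage.proteomics import ProteinTable, filter_proteins, knn_impute, median_normalize
from surface_triage.triage import (
    TriageConfig,
    build_funnel_report,
    intersect_modalities,
    rna_protein_correlation,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--bundle", type=Path, default=Path("results/bundle"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    counts = io.read_counts(args.bundle / "bulk_counts.tsv", args.bundle / "bulk_samples.tsv")
    from surface_triage.bulk import drop_unexpressed_genes, filter_samples_qc, tmm_normalize

    counts = drop_unexpressed_genes(filter_samples_qc(counts))
    bulk_de = io.read_de_result(args.results / "bulk_de.tsv")
    sc_de = io.read_de_result(args.results / "sc_de_HSC.tsv")
    protein_de = io.read_de_result(args.results / "protein_de.tsv")
    annotation = io.read_surfaceome_annotation(args.bundle / "surfaceome.tsv")
    ref = io.read_tissue_reference(args.bundle / "tissue_tpm.tsv", args.bundle / "exempt_tissues.txt")
    id_map = io.read_id_map(args.bundle / "id_map.tsv")

    cfg = TriageConfig()
    intersection = intersect_modalities(sc_de, protein_de, ref, id_map, cfg)
    report = build_funnel_report(bulk_de, counts, annotation, ref, cfg, intersection)

    # RNA-protein correlation on the normalized protein table
    groups = io.read_groups(args.bundle / "protein_groups.tsv")
    table = io.read_protein_table(args.bundle / "proteins.tsv", groups)
    normalized = median_normalize(knn_impute(filter_proteins(table)))
    norm = tmm_normalize(counts)
    rna = np.log2(counts.counts.div(norm.effective_library_size, axis=1) * 1e6 + 1).mean(axis=1)
    corr = rna_protein_correlation(rna, normalized, id_map)

    (args.results / "triage_report.json").write_text(report.to_json() + "\n")
    report.candidates.to_csv(args.results / "candidates.tsv", sep="\t")

    gt = json.loads((args.bundle / "ground_truth.json").read_text())
    print("funnel counts:", report.funnel_counts)
    print("  expected:   ", gt["expected_funnel_counts"])
    print("intersection: ", intersection.cardinalities)
    print("  expected:   ", gt["expected_intersection"])
    print("final cross-modal candidates:", sorted(intersection.common_final))
    print(f"RNA-protein Spearman rho = {corr['rho']:.3f} (p = {corr['p_value']:.2e}, n = {corr['n_pairs']})")


if __name__ == "__main__":
    main()
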