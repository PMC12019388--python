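import logging

import pytest

from surface_triage.bulk import run_bulk_de
from surface_triage.proteomics import run_protein_de
from surface_triage.sc import (
    assign_gates,
    default_gating_model,
    filter_cells_qc,
    normalize_cells,
    sc_de,
)
from surface_triage.simulate import (
    GroundTruth,
    SimConfig,
    gen_bulk_counts,
    gen_protein_abundance,
    gen_sc_dataset,
    gen_surfaceome_annotation,
    gen_tissue_reference,
)

logging.getLogger("surface_triage").setLevel(logging.ERROR)

BUNDLE_SEED = 1


@pytest.fixture(scope="session")
def config() -> SimConfig:
    return SimConfig(seed=BUNDLE_SEED)


@pytest.fixture(scope="session")
def ground_truth(config) -> GroundTruth:
    return GroundTruth.from_config(config)


@pytest.fixture(scope="session")
def bundle(config):
    """The standard synthetic study bundle, fully processed once per session."""
    counts, _ = gen_bulk_counts(config)
    bulk_de, norm, voom_fit, prior, counts_qc = run_bulk_de(counts)
    annotation, id_map = gen_surfaceome_annotation(config)
    tissue_ref = gen_tissue_reference(config)

    adata, _ = gen_sc_dataset(config)
    adata = filter_cells_qc(adata)
    adata = normalize_cells(adata)
    assign_gates(adata, default_gating_model())
    sc_result = sc_de(adata, "HSC")

    protein_table, _ = gen_protein_abundance(config)
    protein_result, protein_norm = run_protein_de(protein_table)

    return {
        "counts_raw": counts,
        "counts": counts_qc,
        "bulk_de": bulk_de,
        "norm": norm,
        "voom_fit": voom_fit,
        "prior": prior,
        "annotation": annotation,
        "id_map": id_map,
        "tissue_ref": tissue_ref,
        "adata": adata,
        "sc_de": sc_result,
        "protein_table": protein_table,
        "protein_de": protein_result,
        "protein_norm": protein_norm,
    }
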