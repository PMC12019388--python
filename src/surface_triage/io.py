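"""Plain-text readers/writers for every pipeline input and output.

Formats: tab-delimited counts (genes x samples, first column gene symbol),
a tab-delimited sample sheet (group + QC metrics), MatrixMarket triplets
plus gene/cell label files for sparse single-cell counts, tab-delimited
protein/tissue/annotation/ID-map tables (empty cell = missing abundance),
and JSON for ground truth and triage reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

from .bulk import CountMatrix
from .proteomics import ProteinTable
from .triage import IDMap, SurfaceomeAnnotation, TissueReference

# ---------------------------------------------------------------------------
# bulk


def write_counts(m: CountMatrix, counts_path, samples_path) -> None:
    m.counts.to_csv(counts_path, sep="\t", index_label="gene")
    m.samples.to_csv(samples_path, sep="\t", index_label="sample")


def read_counts(counts_path, samples_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
    return CountMatrix(counts, samples)


def write_de_result(result: pd.DataFrame, path) -> None:
    result.to_csv(path, sep="\t", index_label="gene")


def read_de_result(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# single cell (MatrixMarket triplet + label files + cell metadata)


def write_sc_dataset(adata: AnnData, prefix) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(prefix) + ".mtx", sp.coo_matrix(adata.X))
    pd.Series(adata.var_names).to_csv(
        str(prefix) + ".genes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(adata.obs_names).to_csv(
        str(prefix) + ".cells.tsv", sep="\t", index=False, header=False
    )
    adata.obs.to_csv(str(prefix) + ".obs.tsv", sep="\t", index_label="cell")


def read_sc_dataset(prefix) -> AnnData:
    prefix = str(prefix)
    x = sp.csr_matrix(scipy.io.mmread(prefix + ".mtx"))
    genes = pd.read_csv(prefix + ".genes.tsv", sep="\t", header=None)[0].to_list()
    cells = pd.read_csv(prefix + ".cells.tsv", sep="\t", header=None)[0].to_list()
    obs = pd.read_csv(prefix + ".obs.tsv", sep="\t", index_col="cell")
    obs = obs.loc[cells]
    return AnnData(X=x, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))


# ---------------------------------------------------------------------------
# proteomics


def write_protein_table(t: ProteinTable, path) -> None:
    frame = pd.concat([t.meta, t.abundance], axis=1)
    frame.to_csv(path, sep="\t", index_label="accession", na_rep="")


def read_protein_table(path, groups: pd.Series) -> ProteinTable:
    frame = pd.read_csv(path, sep="\t", index_col="accession")
    meta_cols = ["gene_symbol", "contaminant", "unique_peptides", "membrane"]
    meta = frame[meta_cols]
    abundance = frame.drop(columns=meta_cols)
    return ProteinTable(abundance, meta, groups)


def write_groups(groups: pd.Series, path) -> None:
    groups.rename("group").to_csv(path, sep="\t", index_label="sample")


def read_groups(path) -> pd.Series:
    return pd.read_csv(path, sep="\t", index_col="sample")["group"]


# ---------------------------------------------------------------------------
# tissue reference / annotation / id map


def write_tissue_reference(ref: TissueReference, tpm_path, exempt_path) -> None:
    ref.tpm.to_csv(tpm_path, sep="\t", index_label="gene")
    Path(exempt_path).write_text("\n".join(sorted(ref.exempt_tissues)) + "\n")


def read_tissue_reference(tpm_path, exempt_path) -> TissueReference:
    tpm = pd.read_csv(tpm_path, sep="\t", index_col="gene")
    exempt = frozenset(
        line.strip() for line in Path(exempt_path).read_text().splitlines() if line.strip()
    )
    return TissueReference(tpm, exempt)


def write_surfaceome_annotation(ann: SurfaceomeAnnotation, path) -> None:
    frame = pd.DataFrame(
        {src: [int(src in ann.membership.get(g, ())) for g in ann.membership] for src in ann.sources},
        index=pd.Index(list(ann.membership), name="gene"),
    )
    frame.to_csv(path, sep="\t")


def read_surfaceome_annotation(path) -> SurfaceomeAnnotation:
    frame = pd.read_csv(path, sep="\t", index_col="gene")
    return SurfaceomeAnnotation.from_frame(frame)


def write_id_map(id_map: IDMap, path) -> None:
    id_map.pairs.to_csv(path, sep="\t", index=False)


def read_id_map(path) -> IDMap:
    return IDMap(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# flow


def write_flow_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_flow_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_beads(beads: pd.DataFrame, path) -> None:
    beads.to_csv(path, sep="\t", index=False)


def read_beads(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# ground truth


def write_ground_truth(gt, path) -> None:
    payload = {
        "expected_funnel_counts": gt.expected_funnel_counts,
        "expected_universe": sorted(gt.expected_universe),
        "expected_enriched": sorted(gt.expected_enriched),
        "expected_tissue_safe": sorted(gt.expected_tissue_safe),
        "expected_stringent": sorted(gt.expected_stringent),
        "expected_sc_hits": sorted(gt.expected_sc_hits),
        "expected_protein_hits": sorted(gt.expected_protein_hits),
        "expected_intersection": gt.expected_intersection(),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_json(payload: dict, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=default) + "\n")
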