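#!/usr/bin/env python
"""Single-cell pipeline: QC, normalization, lineage gating, HSC-level DE.

Wilcoxon rank-sum of disease vs control within the gated population.
"""

import argparse
from pathlib import Path

from surface_triage import io
from surface_triage.sc import (
    GatingModel,
    assign_gates,
    default_gating_model,
    filter_cells_qc,
    normalize_cells,
    sc_de,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--bundle", type=Path, default=Path("results/bundle"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--population", default="HSC")
    ap.add_argument("--gates", type=Path, help="optional gating model YAML")
    args = ap.parse_args()

    adata = io.read_sc_dataset(args.bundle / "sc")
    n_raw = adata.n_obs
    adata = filter_cells_qc(adata)
    adata = normalize_cells(adata)
    model = GatingModel.from_yaml(args.gates) if args.gates else default_gating_model()
    assign_gates(adata, model)
    result = sc_de(adata, args.population)

    args.outdir.mkdir(parents=True, exist_ok=True)
    result.to_csv(args.outdir / f"sc_de_{args.population}.tsv", sep="\t")
    adata.obs[["sample", "group", "lineage"]].to_csv(args.outdir / "cell_annotation.tsv", sep="\t")

    hits = result[(result["adj_p"] < 0.05) & (result["log2fc"] > 0)]
    print(f"cells: {n_raw} -> {adata.n_obs} after QC")
    print(adata.obs["lineage"].value_counts().to_string())
    print(f"{len(result)} genes tested in {args.population}; {len(hits)} upregulated hits:")
    print(hits.sort_values("log2fc", ascending=False).round(3).to_string())


if __name__ == "__main__":
    main()
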