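#!/usr/bin/env python
"""Proteomics differential abundance on the LFQ table.

Filter (contaminants, unique peptides, missingness, membrane annotation)
-> feature-wise KNN imputation -> median normalization -> Wilcoxon + BH.
"""

import argparse
from pathlib import Path

from surface_triage import io
from surface_triage.proteomics import run_protein_de


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--bundle", type=Path, default=Path("results/bundle"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()

    groups = io.read_groups(args.bundle / "protein_groups.tsv")
    table = io.read_protein_table(args.bundle / "proteins.tsv", groups)
    result, normalized = run_protein_de(table, alpha=args.alpha)

    args.outdir.mkdir(parents=True, exist_ok=True)
    result.to_csv(args.outdir / "protein_de.tsv", sep="\t")

    hits = result[result["significant"] & (result["log2fc"] > 0)]
    print(f"{table.abundance.shape[0]} proteins -> {len(result)} tested after filtering")
    print(f"{len(hits)} upregulated at adj_p < {args.alpha}:")
    print(hits.sort_values("log2fc", ascending=False).round(3).to_string())


if __name__ == "__main__":
    main()
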