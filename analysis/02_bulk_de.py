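#!/usr/bin/env python
"""Bulk RNA-seq differential expression on the study bundle.

Sample QC -> TMM -> precision weights -> moderated t with BH adjustment.
Writes the per-gene DE table and the TMM factors.
"""

import argparse
from pathlib import Path

from surface_triage import io
from surface_triage.bulk import run_bulk_de


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--bundle", type=Path, default=Path("results/bundle"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--no-qc-filter", action="store_true")
    args = ap.parse_args()

    counts = io.read_counts(args.bundle / "bulk_counts.tsv", args.bundle / "bulk_samples.tsv")
    de, norm, fit, prior, counts_qc = run_bulk_de(counts, qc_filter=not args.no_qc_filter)

    args.outdir.mkdir(parents=True, exist_ok=True)
    io.write_de_result(de, args.outdir / "bulk_de.tsv")
    norm.tmm_factor.to_frame().to_csv(args.outdir / "tmm_factors.tsv", sep="\t")

    n_sig = int(((de["adj_p"] < 0.05) & (de["log2fc"] > 0)).sum())
    print(f"{counts.counts.shape[1] - counts_qc.counts.shape[1]} sample(s) removed by QC")
    print(f"moderation prior: d0={prior.d0:.2f}, s0^2={prior.s0_sq:.4f}")
    print(f"{n_sig} genes overexpressed in disease at adj_p < 0.05")
    print(de.sort_values("log2fc", ascending=False).head(5).round(3))


if __name__ == "__main__":
    main()
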