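"""Downstream label-free proteomics statistics.

Starts from a protein-level LFQ abundance table (proteins x samples, log2
scale, missing values allowed) with per-protein metadata: contaminant
flag, unique peptide count, membrane annotation, accession, optional gene
symbol.  The pipeline order is fixed and asserted:
filter -> impute -> normalize -> test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import bh_adjust, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

META_COLUMNS = ["gene_symbol", "contaminant", "unique_peptides", "membrane"]

_STAGE_ORDER = ["raw", "filtered", "imputed", "normalized"]


@dataclass
class ProteinTable:
    """Log2 abundances plus protein metadata and per-sample group labels.

    ``abundance`` is indexed by accession; ``meta`` carries
    ``gene_symbol``, ``contaminant`` (bool), ``unique_peptides`` (int),
    ``membrane`` (bool).  ``groups`` maps sample id to
    ``disease``/``control``.  ``stage`` tracks the pipeline step the table
    has reached so the fixed order can be asserted.
    """

    abundance: pd.DataFrame
    meta: pd.DataFrame
    groups: pd.Series
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.abundance.index.duplicated().any():
            raise ValueError("duplicate protein accessions")
        if not self.abundance.index.equals(self.meta.index):
            self.meta = self.meta.loc[self.abundance.index]

    def _advance(self, new_stage: str) -> None:
        if _STAGE_ORDER.index(new_stage) < _STAGE_ORDER.index(self.stage):
            raise ValueError(
                f"pipeline order violated: {self.stage} -> {new_stage}"
            )
        self.stage = new_stage


@dataclass
class ImputationModel:
    """Feature-wise KNN settings.

    Neighbors are other proteins; distances are Euclidean on row-
    standardized log2 abundances over mutually observed samples; imputed
    values are distance-weighted means of neighbor raw values.
    """

    k: int = 10
    distance: str = "euclidean"
    standardize: bool = True


def filter_proteins(t: ProteinTable, max_missing_frac: float = 0.5) -> ProteinTable:
    """Remove contaminants, proteins without a unique peptide, and proteins
    missing in >= ``max_missing_frac`` of samples (note: the boundary is
    removed)."""
    miss_frac = t.abundance.isna().mean(axis=1)
    keep = (
        ~t.meta["contaminant"].astype(bool)
        & (t.meta["unique_peptides"] >= 1)
        & (miss_frac < max_missing_frac)
    )
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("protein filter removed %d of %d proteins", n_drop, len(keep))
    if not keep.any():
        raise ValueError("protein filtering removed every protein")
    out = ProteinTable(t.abundance.loc[keep].copy(), t.meta.loc[keep].copy(), t.groups, t.stage)
    out._advance("filtered")
    return out


def knn_impute(t: ProteinTable, model: ImputationModel | None = None) -> ProteinTable:
    """Feature-wise K-nearest-neighbor imputation of missing abundances.

    For each protein with missing entries, the k nearest other proteins
    (Euclidean distance on standardized rows over mutually observed
    samples, scaled by the number of shared samples) that are observed at
    the missing sample supply a distance-weighted mean of their values at
    that sample, each neighbor re-centered by the mean difference between
    target and neighbor over their mutually observed samples (so an exact
    copy imputes its own value, and abundance-level offsets between
    neighboring proteins do not leak into the imputation).  Observed cells
    are never modified; entries with no eligible neighbor are left missing
    with a warning.
    """
    model = model or ImputationModel()
    x = t.abundance.to_numpy(dtype=float)
    n_prot, n_samp = x.shape
    k = min(model.k, n_prot - 1)
    if k < 1:
        raise ValueError("need at least two proteins to impute")
    observed = ~np.isnan(x)

    if model.standardize:
        mu = np.nanmean(x, axis=1, keepdims=True)
        sd = np.nanstd(x, axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (x - mu) / sd
    else:
        z = x.copy()

    imputed = x.copy()
    n_unfilled = 0
    missing_rows = np.where(~observed.all(axis=1))[0]
    for i in missing_rows:
        shared = observed[i][None, :] & observed  # candidates x samples
        diff = z[i][None, :] - z
        diff[~shared] = 0.0
        n_shared = shared.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.sqrt((diff**2).sum(axis=1) / n_shared)
            target_shared_mean = np.where(shared, x[i][None, :], 0.0).sum(axis=1) / n_shared
            neighbor_shared_mean = np.where(shared, x, 0.0).sum(axis=1) / n_shared
        offset = target_shared_mean - neighbor_shared_mean
        dist[i] = np.inf
        dist[n_shared == 0] = np.inf
        for j in np.where(~observed[i])[0]:
            eligible = np.isfinite(dist) & observed[:, j]
            if not eligible.any():
                n_unfilled += 1
                continue
            cand = np.where(eligible)[0]
            order = cand[np.argsort(dist[cand], kind="mergesort")][:k]
            d = dist[order]
            if np.any(d == 0):
                w = (d == 0).astype(float)
            else:
                w = 1.0 / d
            imputed[i, j] = float(np.sum(w * (x[order, j] + offset[order])) / w.sum())
    if n_unfilled:
        warnings.warn(f"{n_unfilled} missing entr(ies) had no eligible neighbor")
    out = ProteinTable(
        pd.DataFrame(imputed, index=t.abundance.index, columns=t.abundance.columns),
        t.meta.copy(),
        t.groups,
        t.stage,
    )
    out._advance("imputed")
    return out


def median_normalize(t: ProteinTable) -> ProteinTable:
    """Additive per-sample shift in log2 space aligning every sample median
    to the grand median of the pre-shift sample medians."""
    medians = t.abundance.median(axis=0, skipna=True)
    target = medians.median()
    shifted = t.abundance - (medians - target)
    out = ProteinTable(shifted, t.meta.copy(), t.groups, t.stage)
    out._advance("normalized")
    return out


def protein_de(t: ProteinTable, alpha: float = 0.05, exact_cutoff: int = 16) -> pd.DataFrame:
    """Per-protein Wilcoxon rank-sum differential abundance with BH.

    ``log2fc`` = mean(disease) - mean(control) on normalized log2
    abundances.  The documented significance defaults are alpha = 0.05
    and, more permissively, 0.2.
    """
    groups = t.groups.loc[t.abundance.columns]
    dis = (groups == "disease").to_numpy()
    ctl = (groups == "control").to_numpy()
    if dis.sum() < 2 or ctl.sum() < 2:
        raise ValueError("need at least two samples per group")
    x = t.abundance.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("protein DE requires complete (imputed) abundances")
    rows = []
    for i in range(x.shape[0]):
        res = wilcoxon_rank_sum(x[i, dis], x[i, ctl], exact_cutoff=exact_cutoff)
        rows.append(
            (x[i, dis].mean() - x[i, ctl].mean(), res.statistic, res.p_value, res.method)
        )
    result = pd.DataFrame(
        rows, columns=["log2fc", "U", "p_value", "method"], index=t.abundance.index
    )
    result["adj_p"] = bh_adjust(result["p_value"].to_numpy())
    result["significant"] = result["adj_p"] < alpha
    result.insert(0, "gene_symbol", t.meta["gene_symbol"])
    return result


def filter_membrane(t: ProteinTable) -> ProteinTable:
    """Retain membrane-annotated proteins only (empty result allowed)."""
    keep = t.meta["membrane"].astype(bool)
    if not keep.any():
        warnings.warn("membrane filter removed every protein")
    return ProteinTable(t.abundance.loc[keep].copy(), t.meta.loc[keep].copy(), t.groups, t.stage)


def run_protein_de(
    t: ProteinTable,
    alpha: float = 0.05,
    max_missing_frac: float = 0.5,
    imputation: ImputationModel | None = None,
    membrane_only: bool = True,
) -> tuple[pd.DataFrame, ProteinTable]:
    """filter -> (membrane) -> impute -> median-normalize -> Wilcoxon + BH."""
    t = filter_proteins(t, max_missing_frac)
    if membrane_only:
        t = filter_membrane(t)
    t = knn_impute(t, imputation)
    t = median_normalize(t)
    return protein_de(t, alpha=alpha), t
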