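"""Target-nomination funnel and cross-modal intersection.

Implements the triage of cell-surface protein-encoding genes: an expressed
surface-gene universe, differential-expression enrichment, a normal-tissue
"on-target off-tumor" safety filter with hematopoietic-tissue exemptions,
a fold-change stringency cut, the RNA/protein cross-modality intersection,
funnel accounting, and the RNA-protein correlation summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)

EXEMPT_TISSUES_DEFAULT = frozenset(
    {"Whole Blood", "Spleen", "Cells - EBV-transformed lymphocytes"}
)

FUNNEL_STAGES = ("expressed_surface", "enriched", "tissue_safe", "stringent")


@dataclass
class TriageConfig:
    """Numeric cutoffs of the funnel; strictness follows the quoted rules.

    * ``expression_min_median_cpm`` — "expressed" means median disease CPM
      at or above this (>=, default 1).
    * ``enrichment_alpha`` — adjusted p strictly below (default 0.05), with
      an optional fold-change floor (strictly above, default 0).
    * ``tissue_tpm_cutoff`` — excluded if median TPM strictly above this in
      any non-exempt tissue (default 20).
    * ``stringency_log2fc`` — retained if log2FC strictly above (default 6.5).
    * ``sc_alpha`` / ``protein_alpha`` — hit definitions per modality.
    """

    expression_min_median_cpm: float = 1.0
    enrichment_alpha: float = 0.05
    enrichment_log2fc_floor: float = 0.0
    tissue_tpm_cutoff: float = 20.0
    stringency_log2fc: float = 6.5
    sc_alpha: float = 0.05
    protein_alpha: float = 0.05


@dataclass
class SurfaceomeAnnotation:
    """Gene symbol -> subset of annotation sources (surface iff nonempty)."""

    sources: tuple[str, ...]
    membership: dict[str, frozenset[str]]

    def is_surface(self, gene: str) -> bool:
        return bool(self.membership.get(gene))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SurfaceomeAnnotation":
        """Build from a 0/1 table indexed by gene with one column per source."""
        sources = tuple(frame.columns)
        membership = {
            gene: frozenset(s for s in sources if bool(row[s]))
            for gene, row in frame.iterrows()
        }
        return cls(sources, membership)


@dataclass
class TissueReference:
    """Per-gene median TPM per tissue with an exempt (hematopoietic) subset."""

    tpm: pd.DataFrame  # genes x tissues
    exempt_tissues: frozenset[str] = EXEMPT_TISSUES_DEFAULT

    def __post_init__(self) -> None:
        missing = set(self.exempt_tissues) - set(self.tpm.columns)
        if missing:
            raise ValueError(f"exempt tissues absent from reference: {sorted(missing)}")

    @property
    def non_exempt(self) -> list[str]:
        return [t for t in self.tpm.columns if t not in self.exempt_tissues]

    def max_non_exempt_tpm(self, genes=None) -> pd.Series:
        tpm = self.tpm if genes is None else self.tpm.reindex(genes)
        return tpm[self.non_exempt].max(axis=1)


@dataclass
class IDMap:
    """Explicit gene-symbol <-> protein-accession pairs (no fuzzy matching)."""

    pairs: pd.DataFrame  # columns: gene_symbol, accession

    def __post_init__(self) -> None:
        self.pairs = self.pairs.copy()
        self.pairs["gene_symbol"] = self.pairs["gene_symbol"].str.upper()

    def symbols_for(self, accessions) -> tuple[set[str], set[str]]:
        """Map accessions to symbols; returns (symbols, unmapped accessions)."""
        lookup = self.pairs.groupby("accession")["gene_symbol"].agg(set)
        symbols: set[str] = set()
        unmapped: set[str] = set()
        for acc in accessions:
            if acc in lookup.index:
                symbols |= lookup[acc]
            else:
                unmapped.add(acc)
        return symbols, unmapped


# ---------------------------------------------------------------------------
# funnel filters


def filter_expressed(
    de: pd.DataFrame, counts, cfg: TriageConfig | None = None
) -> set[str]:
    """Genes whose median CPM across disease samples meets the floor.

    ``counts`` is a :class:`surface_triage.bulk.CountMatrix`; CPM uses raw
    library sizes.
    """
    cfg = cfg or TriageConfig()
    disease_cols = counts.samples.index[counts.samples["group"] == "disease"]
    sub = counts.counts[disease_cols]
    cpm = sub / sub.sum(axis=0) * 1e6
    median_cpm = cpm.median(axis=1)
    expressed = set(median_cpm.index[median_cpm >= cfg.expression_min_median_cpm])
    return expressed & set(de.index)


def filter_surfaceome(genes: set[str], ann: SurfaceomeAnnotation) -> set[str]:
    """Genes annotated in at least one surfaceome resource."""
    unknown = [g for g in genes if g not in ann.membership]
    if unknown:
        logger.info("%d gene(s) absent from surfaceome annotation -> non-surface", len(unknown))
    return {g for g in genes if ann.is_surface(g)}


def filter_enriched(
    de: pd.DataFrame, cfg: TriageConfig | None = None, genes: set[str] | None = None
) -> set[str]:
    """Disease-overexpressed genes: adj_p < alpha and log2FC above the floor."""
    cfg = cfg or TriageConfig()
    hits = de.index[
        (de["adj_p"] < cfg.enrichment_alpha) & (de["log2fc"] > cfg.enrichment_log2fc_floor)
    ]
    out = set(hits)
    return out if genes is None else out & genes


def filter_tissue_safety(
    genes: set[str], ref: TissueReference, cfg: TriageConfig | None = None
) -> set[str]:
    """Drop genes with median TPM strictly above the cutoff in any
    non-exempt tissue; exempt (hematopoietic) tissues are ignored.  Genes
    absent from the reference are excluded with a warning."""
    cfg = cfg or TriageConfig()
    present = [g for g in genes if g in ref.tpm.index]
    absent = genes - set(present)
    if absent:
        logger.warning("%d gene(s) absent from tissue reference -> excluded", len(absent))
    max_tpm = ref.max_non_exempt_tpm(present)
    return set(max_tpm.index[max_tpm <= cfg.tissue_tpm_cutoff])


def filter_stringency(
    de: pd.DataFrame, genes: set[str], cfg: TriageConfig | None = None
) -> set[str]:
    """High-fold-change candidates: log2FC strictly above the cutoff."""
    cfg = cfg or TriageConfig()
    in_de = genes & set(de.index)
    return set(de.loc[sorted(in_de)].index[
        de.loc[sorted(in_de), "log2fc"] > cfg.stringency_log2fc
    ])


# ---------------------------------------------------------------------------
# cross-modal intersection


@dataclass
class IntersectionResult:
    sc_hits: set[str]
    protein_hits: set[str]
    overlap: set[str]
    sc_hits_safe: set[str]
    protein_hits_safe: set[str]
    common_final: set[str]
    unmapped_accessions: set[str] = field(default_factory=set)

    @property
    def cardinalities(self) -> dict[str, int]:
        return {
            "n_sc_hits": len(self.sc_hits),
            "n_protein_hits": len(self.protein_hits),
            "n_overlap": len(self.overlap),
            "n_sc_hits_safe": len(self.sc_hits_safe),
            "n_protein_hits_safe": len(self.protein_hits_safe),
            "n_common_final": len(self.common_final),
        }


def intersect_modalities(
    sc_de: pd.DataFrame,
    protein_de: pd.DataFrame,
    ref: TissueReference,
    id_map: IDMap,
    cfg: TriageConfig | None = None,
) -> IntersectionResult:
    """Single-cell x proteomics hit intersection with tissue-safety filtering.

    Hits are adj_p below the modality alpha with positive log2FC; protein
    hits are mapped to gene symbols (unmapped accessions logged and
    excluded).  Both hit sets are tissue-safety filtered and the final
    common set is the overlap of the safe sets.
    """
    cfg = cfg or TriageConfig()
    sc_hits = set(
        sc_de.index[(sc_de["adj_p"] < cfg.sc_alpha) & (sc_de["log2fc"] > 0)]
    )
    prot_acc = protein_de.index[
        (protein_de["adj_p"] < cfg.protein_alpha) & (protein_de["log2fc"] > 0)
    ]
    protein_hits, unmapped = id_map.symbols_for(prot_acc)
    if unmapped:
        logger.warning("%d significant accession(s) unmapped: %s", len(unmapped), sorted(unmapped))
    overlap = sc_hits & protein_hits
    sc_safe = filter_tissue_safety(sc_hits, ref, cfg)
    prot_safe = filter_tissue_safety(protein_hits, ref, cfg)
    return IntersectionResult(
        sc_hits=sc_hits,
        protein_hits=protein_hits,
        overlap=overlap,
        sc_hits_safe=sc_safe,
        protein_hits_safe=prot_safe,
        common_final=sc_safe & prot_safe,
        unmapped_accessions=unmapped,
    )


# ---------------------------------------------------------------------------
# funnel accounting


@dataclass
class TriageReport:
    """Per-stage funnel sets/counts, per-gene flags, thresholds, provenance."""

    stage_sets: dict[str, set[str]]
    config: TriageConfig
    candidates: pd.DataFrame
    intersection: IntersectionResult | None = None
    input_digests: dict[str, str] = field(default_factory=dict)
    version: str = "0.1.0"

    @property
    def funnel_counts(self) -> dict[str, int]:
        return {stage: len(self.stage_sets[stage]) for stage in FUNNEL_STAGES}

    def to_json(self) -> str:
        payload = {
            "funnel_counts": self.funnel_counts,
            "stages": {k: sorted(v) for k, v in self.stage_sets.items()},
            "thresholds": asdict(self.config),
            "candidates": self.candidates.reset_index().to_dict(orient="records"),
            "input_digests": self.input_digests,
            "version": self.version,
        }
        if self.intersection is not None:
            payload["intersection"] = {
                **self.intersection.cardinalities,
                "common_final": sorted(self.intersection.common_final),
            }
        return json.dumps(payload, indent=2, sort_keys=True)


def _digest(frame: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(frame, index=True).to_numpy().tobytes()
    ).hexdigest()[:16]


def build_funnel_report(
    bulk_de: pd.DataFrame,
    counts,
    annotation: SurfaceomeAnnotation,
    ref: TissueReference,
    cfg: TriageConfig | None = None,
    intersection: IntersectionResult | None = None,
) -> TriageReport:
    """Run the funnel in its fixed order and assemble the report.

    Order: expressed+surface universe -> enriched -> tissue-safe ->
    stringency.  Counts are monotone nonincreasing by construction.
    """
    cfg = cfg or TriageConfig()
    expressed = filter_expressed(bulk_de, counts, cfg)
    universe = filter_surfaceome(expressed, annotation)
    enriched = filter_enriched(bulk_de, cfg, universe)
    safe = filter_tissue_safety(enriched, ref, cfg)
    stringent = filter_stringency(bulk_de, safe, cfg)
    stage_sets = dict(
        zip(FUNNEL_STAGES, (universe, enriched, safe, stringent))
    )

    flags = pd.DataFrame(index=sorted(universe))
    flags["expressed_surface"] = True
    flags["enriched"] = flags.index.isin(enriched)
    flags["tissue_safe"] = flags.index.isin(safe)
    flags["stringent"] = flags.index.isin(stringent)
    flags["log2fc"] = bulk_de["log2fc"].reindex(flags.index)
    flags["adj_p"] = bulk_de["adj_p"].reindex(flags.index)
    flags["max_non_exempt_tpm"] = ref.max_non_exempt_tpm(flags.index)
    candidates = flags[flags["stringent"]].sort_values("log2fc", ascending=False)

    return TriageReport(
        stage_sets=stage_sets,
        config=cfg,
        candidates=candidates,
        intersection=intersection,
        input_digests={
            "bulk_de": _digest(bulk_de),
            "counts": _digest(counts.counts),
            "tissue_reference": _digest(ref.tpm),
        },
    )


# ---------------------------------------------------------------------------
# RNA-protein correlation


def rna_protein_correlation(
    bulk_expression: pd.Series,
    protein_table,
    id_map: IDMap,
) -> dict:
    """Spearman correlation of mean log2(CPM+1) against mean log2 protein
    abundance over explicitly mapped gene-protein pairs.

    ``bulk_expression`` is a per-gene mean log2(CPM+1) series; requires at
    least 10 mapped pairs.
    """
    mean_abundance = protein_table.abundance.mean(axis=1, skipna=True)
    pairs = id_map.pairs
    rows = []
    for _, row in pairs.iterrows():
        gene, acc = row["gene_symbol"], row["accession"]
        if gene in bulk_expression.index and acc in mean_abundance.index:
            rows.append((bulk_expression[gene], mean_abundance[acc]))
    if len(rows) < 10:
        raise ValueError(f"only {len(rows)} mapped gene-protein pairs (need >= 10)")
    arr = np.asarray(rows)
    rho, p = spearmanr(arr[:, 0], arr[:, 1])
    return {"rho": float(rho), "p_value": float(p), "n_pairs": len(rows)}
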