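"""Synthetic multi-omic inputs with planted ground truth.

Every pipeline input — bulk negative-binomial counts, sparse single-cell
counts with lineage structure, log-normal protein abundances with
missingness, a tissue reference with hematopoietic-exempt tissues,
multi-source surface annotations, an ID map, and flow event tables with
bead standards — is generated from one :class:`SimConfig`, fully
determined by its seed.  The accompanying :class:`GroundTruth` is derived
by brute-force application of the filter definitions to the generating
parameters, so every downstream stage can be checked against what was
planted.

The default configuration is the package's standard study-scale bundle:
a 600-gene bulk universe (20 disease vs 10 control, NB dispersion 0.1)
whose 45-gene surface panel contains three cross-modal targets, six
high-fold-change but tissue-unsafe genes (two of them also single-cell and
protein hits), twelve moderately enriched safe genes, modality-private
hits, surface nulls and unexpressed surface genes; single-cell data from
eight donors with HSC/GMP/monocyte structure; a 40-protein LFQ panel at
the study's 9-vs-3 design; and one stained/FMO flow pair with bead
standards.  Planted non-null effects are large enough to be detected with
near-certainty at these sample sizes, and most non-hit genes carry a mild
disease-down shift, so the realized hit sets coincide with the
parameter-derived expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .bulk import CountMatrix
from .proteomics import ProteinTable
from .sc import compute_cell_qc
from .triage import (
    EXEMPT_TISSUES_DEFAULT,
    IDMap,
    SurfaceomeAnnotation,
    TissueReference,
)

ANNOTATION_SOURCES_DEFAULT = ("HPA", "CSPA", "SurfaceomeAtlas")

NON_EXEMPT_TISSUES_DEFAULT = (
    "Brain - Cortex",
    "Liver",
    "Lung",
    "Heart - Left Ventricle",
    "Kidney - Cortex",
    "Pancreas",
    "Colon - Transverse",
    "Skin - Sun Exposed",
    "Muscle - Skeletal",
    "Adipose - Subcutaneous",
    "Thyroid",
    "Testis",
)


@dataclass
class PlantedTarget:
    """Ground-truth effect sizes and annotations for one gene."""

    gene_id: str
    true_log2fc_bulk: float = 0.0
    true_log2fc_sc: float = 0.0
    true_log2fc_protein: float = 0.0
    surface_sources: tuple[str, ...] = ()
    tissue_safe: bool = True
    tissue_tpm_overrides: dict = field(default_factory=dict)
    expressed: bool = True

    @property
    def is_surface(self) -> bool:
        return len(self.surface_sources) > 0


def default_planted_targets() -> list[PlantedTarget]:
    """The standard bundle's surface-gene panel (see module docstring)."""
    src = ANNOTATION_SOURCES_DEFAULT
    tissues = NON_EXEMPT_TISSUES_DEFAULT
    targets: list[PlantedTarget] = []
    # cross-modal, tissue-safe targets (the planted analogue of the
    # CD48/ADGRE2/CLEC12A-style final hits)
    for i in range(3):
        targets.append(
            PlantedTarget(
                f"T{i + 1:02d}",
                true_log2fc_bulk=8.0,
                true_log2fc_sc=3.0,
                true_log2fc_protein=3.0,
                surface_sources=src,
            )
        )
    # high-fold-change but tissue-unsafe; the first two are also
    # single-cell + protein hits (removed only by the safety filter)
    for i in range(6):
        cross = i < 2
        targets.append(
            PlantedTarget(
                f"U{i + 1:02d}",
                true_log2fc_bulk=7.5,
                true_log2fc_sc=3.0 if cross else -0.5,
                true_log2fc_protein=3.0 if cross else 0.0,
                surface_sources=src[: 1 + i % 3],
                tissue_safe=False,
                tissue_tpm_overrides={tissues[i % len(tissues)]: 150.0},
            )
        )
    # moderately enriched, tissue-safe (fail only the stringency cut)
    for i in range(12):
        targets.append(
            PlantedTarget(
                f"M{i + 1:02d}",
                true_log2fc_bulk=3.5,
                true_log2fc_sc=-0.5,
                surface_sources=src[: 1 + i % 3],
            )
        )
    # modality-private hits
    for i in range(2):
        targets.append(
            PlantedTarget(
                f"SC{i + 1:02d}", true_log2fc_sc=3.0, surface_sources=(src[i],)
            )
        )
    for i in range(2):
        targets.append(
            PlantedTarget(
                f"PR{i + 1:02d}",
                true_log2fc_protein=3.0,
                true_log2fc_sc=-0.5,
                surface_sources=(src[i],),
            )
        )
    # surface nulls: seven honest nulls, the rest mildly disease-down
    for i in range(15):
        targets.append(
            PlantedTarget(
                f"SN{i + 1:02d}",
                true_log2fc_sc=0.0 if i < 7 else -0.5,
                surface_sources=(src[i % 3],),
            )
        )
    # surface but not expressed: never enter the funnel universe
    for i in range(5):
        targets.append(
            PlantedTarget(f"SX{i + 1:02d}", surface_sources=(src[i % 3],), expressed=False)
        )
    return targets


@dataclass
class SimConfig:
    """All knobs of the synthetic study; the seed fully determines output."""

    seed: int = 1

    # bulk RNA-seq
    n_genes: int = 600
    n_disease_samples: int = 20
    n_control_samples: int = 10
    nb_dispersion: float = 0.1
    baseline_log2_mean_range: tuple[float, float] = (3.0, 9.0)
    library_size_sigma: float = 0.2
    unexpressed_mean: float = 0.02
    n_qc_fail_samples: int = 0

    planted_targets: list[PlantedTarget] = field(default_factory=default_planted_targets)

    # single-cell
    n_sc_samples_per_group: int = 4
    n_cells_per_sample: int = 150
    lineage_profiles: dict = field(
        default_factory=lambda: {
            "HSC": {"CD34": 8.0, "CD38": 0.0, "CD14": 0.0, "CD3E": 0.0, "CD19": 0.0},
            "GMP": {"CD34": 8.0, "CD38": 8.0, "CD14": 0.0, "CD3E": 0.0, "CD19": 0.0},
            "Monocyte": {"CD34": 0.0, "CD38": 2.0, "CD14": 8.0, "CD3E": 0.0, "CD19": 0.0},
        }
    )
    lineage_mixture: dict = field(
        default_factory=lambda: {"HSC": 0.35, "GMP": 0.25, "Monocyte": 0.40}
    )
    sc_baseline_mean: float = 1.5
    n_feature_genes: int = 250
    feature_gene_mean: float = 4.0
    feature_gene_tilt: float = -0.085
    n_housekeeping_genes: int = 16
    housekeeping_mean: float = 60.0
    n_mito_genes: int = 5
    mito_mean: float = 8.0
    cell_depth_sigma: float = 0.05
    sc_qc_fail_fraction: float = 0.05

    # proteomics (study-scale 9 vs 3)
    n_protein_disease: int = 9
    n_protein_control: int = 3
    protein_sigma: float = 0.5
    missing_rate: float = 0.1
    missing_mode: str = "mar"  # "mar" or "intensity" (low-abundance-biased)
    protein_null_tilt: float = -0.5
    n_protein_null_tilted: int = 14
    n_protein_null_true: int = 7
    n_protein_nonmembrane: int = 3
    n_protein_contaminants: int = 4
    n_protein_zero_peptide: int = 2
    n_protein_high_missing: int = 4
    n_protein_unmapped: int = 3

    # tissue reference
    tissue_names: tuple[str, ...] = tuple(sorted(EXEMPT_TISSUES_DEFAULT)) + NON_EXEMPT_TISSUES_DEFAULT
    exempt_tissues: frozenset = EXEMPT_TISSUES_DEFAULT
    tissue_safety_threshold: float = 20.0
    safe_tpm_max: float = 8.0
    background_unsafe_fraction: float = 0.1

    annotation_sources: tuple[str, ...] = ANNOTATION_SOURCES_DEFAULT

    # flow cytometry
    n_flow_events: int = 10_000
    flow_positive_fraction: float = 0.6
    antigen_density: float = 5000.0
    flow_background_median: float = 50.0
    flow_background_sigma: float = 0.4
    flow_positive_sigma: float = 0.5
    bead_molecules: tuple[float, ...] = (480.0, 5100.0, 24_000.0, 62_000.0)
    bead_slope: float = 1.0
    bead_intercept: float = 0.0
    bead_noise_sigma: float = 0.0

    def validate(self) -> None:
        for name in (
            "n_genes",
            "n_disease_samples",
            "n_control_samples",
            "n_cells_per_sample",
            "n_sc_samples_per_group",
            "n_protein_disease",
            "n_protein_control",
            "n_flow_events",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"configuration error: {name} must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("configuration error: missing_rate must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("configuration error: nb_dispersion must be positive")
        if not set(self.exempt_tissues) <= set(self.tissue_names):
            raise ValueError("configuration error: exempt_tissues not a subset of tissue_names")
        for lineage in self.lineage_mixture:
            if lineage not in self.lineage_profiles:
                raise ValueError(f"configuration error: unknown lineage {lineage!r} in lineage_mixture")
        if self.flow_background_median <= 0 or self.antigen_density <= 0:
            raise ValueError("configuration error: flow intensities must be positive")
        gene_ids = [t.gene_id for t in self.planted_targets]
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("configuration error: duplicate gene ids in planted_targets")
        if len(gene_ids) > self.n_genes:
            raise ValueError("configuration error: more planted_targets than n_genes")
        for t in self.planted_targets:
            unsafe_override = any(
                v > self.tissue_safety_threshold
                for tissue, v in t.tissue_tpm_overrides.items()
                if tissue not in self.exempt_tissues
            )
            if t.tissue_safe and unsafe_override:
                raise ValueError(
                    f"configuration error: {t.gene_id} marked tissue_safe but has an unsafe override"
                )

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        """Load a configuration from YAML (or JSON, a YAML subset).

        ``planted_targets`` entries are mappings with the
        :class:`PlantedTarget` fields; omitted fields keep their defaults.
        """
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "planted_targets" in raw:
            raw["planted_targets"] = [
                PlantedTarget(
                    gene_id=entry["gene_id"],
                    true_log2fc_bulk=float(entry.get("true_log2fc_bulk", 0.0)),
                    true_log2fc_sc=float(entry.get("true_log2fc_sc", 0.0)),
                    true_log2fc_protein=float(entry.get("true_log2fc_protein", 0.0)),
                    surface_sources=tuple(entry.get("surface_sources", ())),
                    tissue_safe=bool(entry.get("tissue_safe", True)),
                    tissue_tpm_overrides=dict(entry.get("tissue_tpm_overrides", {})),
                    expressed=bool(entry.get("expressed", True)),
                )
                for entry in raw["planted_targets"]
            ]
        for tuple_field in ("baseline_log2_mean_range", "tissue_names", "annotation_sources", "bead_molecules"):
            if tuple_field in raw:
                raw[tuple_field] = tuple(raw[tuple_field])
        if "exempt_tissues" in raw:
            raw["exempt_tissues"] = frozenset(raw["exempt_tissues"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    # -- derived gene universe ------------------------------------------------

    def gene_ids(self) -> list[str]:
        planted = [t.gene_id for t in self.planted_targets]
        n_background = self.n_genes - len(planted)
        return planted + [f"G{i + 1:04d}" for i in range(n_background)]

    def target_map(self) -> dict[str, PlantedTarget]:
        return {t.gene_id: t for t in self.planted_targets}


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _gene_baselines(config: SimConfig) -> pd.Series:
    """Per-gene baseline mean counts (shared by bulk and proteomics so
    RNA and protein abundances correlate)."""
    rng = _rng(config, 10)
    lo, hi = config.baseline_log2_mean_range
    log2_means = rng.uniform(lo, hi, size=config.n_genes)
    means = pd.Series(2.0**log2_means, index=config.gene_ids())
    for t in config.planted_targets:
        if not t.expressed:
            means[t.gene_id] = config.unexpressed_mean
    return means


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Parameter-level expectations for every filter stage."""

    targets: list[PlantedTarget]
    expected_universe: set[str]
    expected_enriched: set[str]
    expected_tissue_safe: set[str]
    expected_stringent: set[str]
    expected_sc_hits: set[str]
    expected_protein_hits: set[str]

    @property
    def expected_funnel_counts(self) -> dict[str, int]:
        return {
            "expressed_surface": len(self.expected_universe),
            "enriched": len(self.expected_enriched),
            "tissue_safe": len(self.expected_tissue_safe),
            "stringent": len(self.expected_stringent),
        }

    def expected_intersection(self, exempt=None, threshold: float = 20.0) -> dict[str, int]:
        overlap = self.expected_sc_hits & self.expected_protein_hits
        safe = {t.gene_id for t in self.targets if t.tissue_safe}
        sc_safe = self.expected_sc_hits & safe
        prot_safe = self.expected_protein_hits & safe
        return {
            "n_sc_hits": len(self.expected_sc_hits),
            "n_protein_hits": len(self.expected_protein_hits),
            "n_overlap": len(overlap),
            "n_sc_hits_safe": len(sc_safe),
            "n_protein_hits_safe": len(prot_safe),
            "n_common_final": len(sc_safe & prot_safe),
        }

    @property
    def expected_final_candidates(self) -> set[str]:
        return set(self.expected_stringent)

    @classmethod
    def from_config(
        cls,
        config: SimConfig,
        stringency_log2fc: float = 6.5,
        enrichment_log2fc_floor: float = 0.0,
    ) -> "GroundTruth":
        targets = config.planted_targets
        universe = {t.gene_id for t in targets if t.is_surface and t.expressed}
        enriched = {
            g
            for g in universe
            if config.target_map()[g].true_log2fc_bulk > enrichment_log2fc_floor
        }
        safe = {g for g in enriched if config.target_map()[g].tissue_safe}
        stringent = {
            g for g in safe if config.target_map()[g].true_log2fc_bulk > stringency_log2fc
        }
        sc_hits = {t.gene_id for t in targets if t.true_log2fc_sc > 0 and t.expressed}
        panel = protein_panel(config)
        mapped = panel[panel["mapped"] & panel["tested"]]
        prot_hits = set(mapped.loc[mapped["true_log2fc"] > 0, "gene_symbol"])
        return cls(
            targets=list(targets),
            expected_universe=universe,
            expected_enriched=enriched,
            expected_tissue_safe=safe,
            expected_stringent=stringent,
            expected_sc_hits=sc_hits,
            expected_protein_hits=prot_hits,
        )


# ---------------------------------------------------------------------------
# bulk counts


def gen_bulk_counts(config: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Negative-binomial bulk counts with planted group fold changes.

    Disease-group means are the baseline shifted by ``2**true_log2fc_bulk``;
    library sizes vary log-normally per sample; QC metrics all pass unless
    ``n_qc_fail_samples`` plants failing extra disease samples.
    """
    config.validate()
    rng = _rng(config, 1)
    baselines = _gene_baselines(config)
    tmap = config.target_map()
    fc = np.array([2.0 ** tmap[g].true_log2fc_bulk if g in tmap else 1.0 for g in baselines.index])

    n_dis, n_ctl, n_fail = (
        config.n_disease_samples,
        config.n_control_samples,
        config.n_qc_fail_samples,
    )
    sample_ids = (
        [f"JMML{i + 1:02d}" for i in range(n_dis + n_fail)]
        + [f"CTRL{i + 1:02d}" for i in range(n_ctl)]
    )
    groups = ["disease"] * (n_dis + n_fail) + ["control"] * n_ctl
    scale = rng.lognormal(0.0, config.library_size_sigma, size=len(sample_ids))

    base = baselines.to_numpy()[:, None]
    mu = base * np.where(np.array(groups)[None, :] == "disease", fc[:, None], 1.0)
    mu = mu * scale[None, :]
    r = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    qc = pd.DataFrame(
        {
            "group": groups,
            "total_mapped_reads": rng.uniform(32e6, 60e6, len(sample_ids)),
            "nonscaled_library_reads": rng.uniform(4e6, 8e6, len(sample_ids)),
            "unique_mapped_reads": 0.0,
            "mito_ratio": rng.uniform(0.01, 0.08, len(sample_ids)),
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    qc["unique_mapped_reads"] = 0.8 * qc["total_mapped_reads"]
    # planted QC failures occupy the extra disease slots, alternating modes
    for i in range(n_fail):
        sid = sample_ids[n_dis + i]
        if i % 2 == 0:
            qc.loc[sid, "total_mapped_reads"] = 25e6
        else:
            qc.loc[sid, "mito_ratio"] = 0.12

    m = CountMatrix(
        pd.DataFrame(counts, index=baselines.index, columns=sample_ids), qc
    )
    return m, GroundTruth.from_config(config)


# ---------------------------------------------------------------------------
# single-cell dataset


def _sc_gene_table(config: SimConfig) -> pd.DataFrame:
    """Mean expression per (gene, lineage) and disease multipliers."""
    tmap = config.target_map()
    markers = sorted({m for prof in config.lineage_profiles.values() for m in prof})
    rows = []
    for g in config.gene_ids():
        t = tmap.get(g)
        active = t is not None and t.expressed and t.is_surface
        base = config.sc_baseline_mean if active else 0.0
        fc = 2.0 ** t.true_log2fc_sc if (t is not None and active) else 1.0
        rows.append((g, "uniform", base, fc))
    for g in markers:
        rows.append((g, "marker", np.nan, 1.0))
    for i in range(config.n_housekeeping_genes):
        rows.append((f"HK{i + 1:02d}", "uniform", config.housekeeping_mean, 1.0))
    for i in range(config.n_mito_genes):
        rows.append((f"MT-G{i + 1}", "uniform", config.mito_mean, 1.0))
    # background transcriptome: always-detected genes that give every cell
    # a realistic feature count; the mild disease-down tilt keeps the
    # housekeeping composition balance on the negative side
    for i in range(config.n_feature_genes):
        rows.append(
            (f"BG{i + 1:04d}", "uniform", config.feature_gene_mean, 2.0**config.feature_gene_tilt)
        )
    return pd.DataFrame(rows, columns=["gene", "kind", "base_mean", "disease_factor"])


def gen_sc_dataset(config: SimConfig) -> tuple[AnnData, GroundTruth]:
    """Sparse single-cell counts with lineage marker structure.

    Each cell draws a lineage from the configured mixture; counts are
    Poisson with a log-normal per-cell depth factor (marker means come
    from the lineage profile, everything else is lineage-uniform).  A
    configurable fraction of cells is planted to fail QC, by one of three
    modes (shallow depth, inflated mitochondrial content, few features);
    ``obs["planted_qc_fail"]`` records them exactly.
    """
    config.validate()
    if not config.lineage_profiles:
        raise ValueError("configuration error: lineage_profiles must be nonempty")
    rng = _rng(config, 2)
    table = _sc_gene_table(config)
    genes = table["gene"].to_list()
    lineages = sorted(config.lineage_mixture)
    probs = np.array([config.lineage_mixture[l] for l in lineages], dtype=float)
    probs /= probs.sum()

    sample_ids, sample_groups = [], []
    for group, prefix in (("disease", "JMML"), ("control", "CTRL")):
        for i in range(config.n_sc_samples_per_group):
            sample_ids.append(f"{prefix}-SC{i + 1}")
            sample_groups.append(group)

    n_total = len(sample_ids) * config.n_cells_per_sample
    cell_sample = np.repeat(sample_ids, config.n_cells_per_sample)
    cell_group = np.repeat(sample_groups, config.n_cells_per_sample)
    cell_lineage = np.array(lineages)[rng.choice(len(lineages), size=n_total, p=probs)]
    depth = rng.lognormal(0.0, config.cell_depth_sigma, size=n_total)

    # per-gene mean matrix rows: start from lineage-uniform means
    base_mean = table["base_mean"].to_numpy(dtype=float)
    disease_factor = table["disease_factor"].to_numpy(dtype=float)
    marker_rows = table.index[table["kind"] == "marker"]
    marker_names = table.loc[marker_rows, "gene"].to_list()
    hk_rows = np.where(table["gene"].str.startswith("HK"))[0]
    hk_total = float(base_mean[hk_rows].sum()) if hk_rows.size else 0.0

    counts = np.zeros((n_total, len(genes)), dtype=np.int64)
    for lineage in lineages:
        mask = cell_lineage == lineage
        if not mask.any():
            continue
        mean_vec = base_mean.copy()
        for row, name in zip(marker_rows, marker_names):
            mean_vec[row] = config.lineage_profiles[lineage].get(name, 0.0)
        # Composition balancing: depth normalization makes expression
        # shares zero-sum, so planted effects would leak into every null
        # gene's normalized value.  The housekeeping block absorbs the
        # planted imbalance (a computed mild down/up-shift) so that null
        # genes keep identical expected shares in both groups.
        disease_factor_lin = disease_factor.copy()
        if hk_rows.size and hk_total > 0:
            delta = float(np.sum(np.delete(mean_vec * (disease_factor - 1.0), hk_rows)))
            disease_factor_lin[hk_rows] = max(1.0 - delta / hk_total, 0.05)
        disease_mean = mean_vec * disease_factor_lin
        for group in ("disease", "control"):
            gmask = mask & (cell_group == group)
            if not gmask.any():
                continue
            mu = (disease_mean if group == "disease" else mean_vec)[None, :] * depth[
                gmask
            ][:, None]
            counts[gmask] = rng.poisson(mu)

    # plant QC failures: cycle shallow-depth / high-mito / few-features
    n_fail = int(round(config.sc_qc_fail_fraction * n_total))
    fail_idx = rng.choice(n_total, size=n_fail, replace=False) if n_fail else np.array([], int)
    mito_cols = np.where(table["gene"].str.startswith("MT-"))[0]
    for j, i in enumerate(sorted(fail_idx)):
        mode = j % 3
        if mode == 0:
            counts[i] = rng.binomial(counts[i], 0.3)  # total < 1000
        elif mode == 1:
            counts[i, mito_cols] = counts[i, mito_cols] * 10 + 100  # mito > 15%
        else:
            keep = rng.choice(len(genes), size=100, replace=False)
            zero = np.ones(len(genes), dtype=bool)
            zero[keep] = False
            counts[i, zero] = 0  # features < 200

    obs = pd.DataFrame(
        {
            "sample": cell_sample,
            "group": cell_group,
            "lineage_true": cell_lineage,
            "planted_qc_fail": np.isin(np.arange(n_total), fail_idx),
        },
        index=pd.Index([f"cell{i + 1:05d}" for i in range(n_total)], name="cell"),
    )
    adata = AnnData(
        X=sp.csr_matrix(counts),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    compute_cell_qc(adata)
    return adata, GroundTruth.from_config(config)


# ---------------------------------------------------------------------------
# proteomics


def protein_panel(config: SimConfig) -> pd.DataFrame:
    """Deterministic composition of the LFQ protein panel.

    Columns: accession, gene_symbol, true_log2fc, membrane, contaminant,
    unique_peptides_zero, high_missing, mapped, tested.  ``tested`` marks
    rows expected to survive the filter + membrane stage.
    """
    tmap = config.target_map()
    rows: list[dict] = []

    def add(symbol, fc, membrane=True, contaminant=False, zero_pep=False, high_missing=False):
        rows.append(
            dict(
                gene_symbol=symbol,
                true_log2fc=fc,
                membrane=membrane,
                contaminant=contaminant,
                unique_peptides_zero=zero_pep,
                high_missing=high_missing,
            )
        )

    hits = [g for g, t in tmap.items() if t.true_log2fc_protein > 0]
    for g in hits:
        add(g, tmap[g].true_log2fc_protein)
    surface_nonhit = [
        g for g, t in tmap.items() if t.is_surface and t.expressed and t.true_log2fc_protein <= 0
    ]
    n_tilt, n_true = config.n_protein_null_tilted, config.n_protein_null_true
    # honest nulls first (the genes planted with no effect anywhere), then tilted
    honest = [g for g in surface_nonhit if tmap[g].true_log2fc_bulk == 0 and tmap[g].true_log2fc_sc == 0]
    others = [g for g in surface_nonhit if g not in honest]
    for g in honest[:n_true]:
        add(g, 0.0)
    for g in others[:n_tilt]:
        add(g, config.protein_null_tilt)
    background = [g for g in config.gene_ids() if g not in tmap]
    bg = iter(background)
    for _ in range(config.n_protein_nonmembrane):
        add(next(bg), 0.0, membrane=False)
    for _ in range(config.n_protein_zero_peptide):
        add(next(bg), 0.0, zero_pep=True)
    for _ in range(config.n_protein_high_missing):
        add(next(bg), 0.0, high_missing=True)
    for i in range(config.n_protein_contaminants):
        add(f"CONTAM{i + 1}", 0.0, contaminant=True)

    panel = pd.DataFrame(rows)
    panel["accession"] = [f"P{i + 1:05d}" for i in range(len(panel))]
    panel["tested"] = (
        panel["membrane"]
        & ~panel["contaminant"]
        & ~panel["unique_peptides_zero"]
        & ~panel["high_missing"]
    )
    # unmapped accessions come from the tilted-null block (never from hits)
    tilted_idx = panel.index[panel["true_log2fc"] == config.protein_null_tilt]
    unmapped = set(tilted_idx[: config.n_protein_unmapped])
    panel["mapped"] = ~panel.index.isin(unmapped) & ~panel["contaminant"]
    return panel


def gen_protein_abundance(config: SimConfig) -> tuple[ProteinTable, GroundTruth]:
    """Log-normal protein abundances with planted fold changes and
    missing-at-random values at ``missing_rate``.

    Baseline log2 abundance tracks the gene's bulk baseline (plus noise),
    so RNA-protein correlation is positive by construction.  Planted
    high-missingness rows are missing in at least half the samples;
    contaminant and zero-unique-peptide metadata are planted exactly.
    """
    config.validate()
    rng = _rng(config, 3)
    panel = protein_panel(config)
    baselines = np.log2(_gene_baselines(config))
    n_dis, n_ctl = config.n_protein_disease, config.n_protein_control
    samples = [f"MS-JMML{i + 1}" for i in range(n_dis)] + [f"MS-CTRL{i + 1}" for i in range(n_ctl)]
    groups = pd.Series(["disease"] * n_dis + ["control"] * n_ctl, index=samples, name="group")

    base = np.array(
        [
            20.0 + 0.8 * baselines.get(sym, 2.0) + rng.normal(0, 1.0)
            for sym in panel["gene_symbol"]
        ]
    )
    effect = panel["true_log2fc"].to_numpy()
    mean = base[:, None] + np.where(
        np.array(groups)[None, :] == "disease", effect[:, None], 0.0
    )
    x = mean + rng.normal(0.0, config.protein_sigma, size=mean.shape)

    if config.missing_mode == "mar":
        prob = np.full(x.shape, config.missing_rate)
    elif config.missing_mode == "intensity":
        # low-abundance values go missing preferentially; the logistic is
        # scaled so the overall rate stays close to missing_rate
        z = (x - x.mean()) / max(x.std(), 1e-9)
        prob = np.clip(config.missing_rate * 2.0 / (1.0 + np.exp(2.0 * z)), 0.0, 1.0)
    else:
        raise ValueError("configuration error: missing_mode must be 'mar' or 'intensity'")
    missing = rng.random(x.shape) < prob
    n_half = len(samples) // 2 + 1
    for i in np.where(panel["high_missing"])[0]:
        cols = rng.choice(len(samples), size=n_half, replace=False)
        missing[i, :] = False
        missing[i, cols] = True
    x = np.where(missing, np.nan, x)

    meta = pd.DataFrame(
        {
            "gene_symbol": panel["gene_symbol"].to_numpy(),
            "contaminant": panel["contaminant"].to_numpy(),
            "unique_peptides": np.where(
                panel["unique_peptides_zero"], 0, rng.integers(1, 20, len(panel))
            ),
            "membrane": panel["membrane"].to_numpy(),
        },
        index=pd.Index(panel["accession"], name="accession"),
    )
    table = ProteinTable(
        pd.DataFrame(x, index=meta.index, columns=samples), meta, groups
    )
    return table, GroundTruth.from_config(config)


# ---------------------------------------------------------------------------
# tissue reference, annotation, id map


def gen_tissue_reference(config: SimConfig) -> TissueReference:
    """Per-gene median TPM per tissue honoring planted safety flags.

    Tissue-safe genes stay at or below the safety threshold in every
    non-exempt tissue (exempt hematopoietic tissues may run to hundreds of
    TPM); unsafe genes exceed the threshold in at least one non-exempt
    tissue via their overrides.
    """
    config.validate()
    rng = _rng(config, 4)
    genes = config.gene_ids()
    tissues = list(config.tissue_names)
    non_exempt = [t for t in tissues if t not in config.exempt_tissues]
    tmap = config.target_map()

    tpm = pd.DataFrame(
        rng.uniform(0.0, config.safe_tpm_max, size=(len(genes), len(tissues))),
        index=pd.Index(genes, name="gene"),
        columns=tissues,
    )
    # hematopoietic expression for surface genes in exempt tissues
    for g, t in tmap.items():
        if t.is_surface:
            tpm.loc[g, list(config.exempt_tissues)] = rng.uniform(
                100.0, 500.0, size=len(config.exempt_tissues)
            )
        for tissue, value in t.tissue_tpm_overrides.items():
            tpm.loc[g, tissue] = value
        if not t.tissue_safe and not t.tissue_tpm_overrides:
            tpm.loc[g, non_exempt[0]] = config.tissue_safety_threshold + 10.0
    # a slice of the background is unsafe, as in any real tissue atlas
    background = [g for g in genes if g not in tmap]
    n_unsafe = int(len(background) * config.background_unsafe_fraction)
    unsafe_bg = rng.choice(background, size=n_unsafe, replace=False)
    for g in unsafe_bg:
        tpm.loc[g, non_exempt[int(rng.integers(len(non_exempt)))]] = float(
            rng.uniform(30.0, 200.0)
        )
    return TissueReference(tpm, frozenset(config.exempt_tissues))


def gen_surfaceome_annotation(config: SimConfig) -> tuple[SurfaceomeAnnotation, IDMap]:
    """Multi-source surface annotations plus the symbol<->accession map."""
    config.validate()
    membership = {g: frozenset() for g in config.gene_ids()}
    for t in config.planted_targets:
        bad = set(t.surface_sources) - set(config.annotation_sources)
        if bad:
            raise ValueError(f"configuration error: unknown annotation sources {sorted(bad)}")
        membership[t.gene_id] = frozenset(t.surface_sources)
    annotation = SurfaceomeAnnotation(tuple(config.annotation_sources), membership)

    panel = protein_panel(config)
    mapped = panel[panel["mapped"]]
    id_map = IDMap(
        pd.DataFrame(
            {"gene_symbol": mapped["gene_symbol"].to_numpy(), "accession": mapped["accession"].to_numpy()}
        )
    )
    return annotation, id_map


# ---------------------------------------------------------------------------
# flow cytometry


def gen_flow_events(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stained + FMO event tables and bead standards.

    FMO events are pure log-normal background.  Stained events are a
    mixture: a ``flow_positive_fraction`` positive component whose median
    intensity corresponds to the planted antigen density through the bead
    calibration line, and background otherwise.  Beads follow
    ``log10(molecules) = intercept + slope * log10(MFI)`` exactly unless
    ``bead_noise_sigma`` is set.
    """
    config.validate()
    rng = _rng(config, 6)
    n = config.n_flow_events
    bg_mu = np.log(config.flow_background_median)

    fmo = rng.lognormal(bg_mu, config.flow_background_sigma, size=n)
    is_pos = rng.random(n) < config.flow_positive_fraction
    # invert the calibration line to place the positive median
    pos_median_mfi = 10.0 ** (
        (np.log10(config.antigen_density) - config.bead_intercept) / config.bead_slope
    )
    stained = np.where(
        is_pos,
        rng.lognormal(np.log(pos_median_mfi), config.flow_positive_sigma, size=n),
        rng.lognormal(bg_mu, config.flow_background_sigma, size=n),
    )
    events = pd.DataFrame(
        {
            "intensity": np.concatenate([stained, fmo]),
            "condition": ["stained"] * n + ["FMO"] * n,
            "sample": "S1",
            "true_positive": np.concatenate([is_pos, np.zeros(n, dtype=bool)]),
        }
    )
    molecules = np.asarray(config.bead_molecules, dtype=float)
    mfi = 10.0 ** ((np.log10(molecules) - config.bead_intercept) / config.bead_slope)
    if config.bead_noise_sigma > 0:
        mfi = mfi * 10.0 ** rng.normal(0.0, config.bead_noise_sigma, size=mfi.size)
    beads = pd.DataFrame({"molecules_per_bead": molecules, "mfi": mfi})
    return events, beads
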