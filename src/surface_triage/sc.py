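"""Single-cell QC, normalization, lineage gating, and Wilcoxon DE.

Cells live in an :class:`anndata.AnnData` (cells x genes, sparse counts in
``X``) with per-cell metadata in ``obs``: ``sample``, ``group``
(``disease``/``control``), ``n_features``, ``total_counts`` and
``mito_fraction``.  The depth-normalized log layer is stored under
``layers["lognorm"]``.

Lineage identity is assigned by a hierarchical marker gating model — a cell
passes a gate when enough of its positive markers are detected and none of
its negative markers are — mirroring signature-based gating of
hematopoietic compartments (HSC, GMP, monocytes) rather than cluster-level
labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml
from anndata import AnnData

from .stats import bh_adjust, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class CellQCThresholds:
    """Removal bounds: a cell is dropped iff ``n_features < min_features``,
    ``n_features > max_features``, ``total_counts < min_total`` or
    ``mito_fraction > max_mito`` (boundaries retain)."""

    min_features: int = 200
    max_features: int = 4000
    min_total: int = 1000
    max_mito: float = 0.15


def compute_cell_qc(adata: AnnData, mito_prefix: str = "MT-") -> AnnData:
    """Attach ``n_features``, ``total_counts`` and ``mito_fraction`` to obs."""
    x = sp.csr_matrix(adata.X)
    adata.obs["n_features"] = np.asarray((x > 0).sum(axis=1)).ravel()
    total = np.asarray(x.sum(axis=1)).ravel()
    adata.obs["total_counts"] = total
    mito_mask = adata.var_names.str.startswith(mito_prefix)
    mito = np.asarray(x[:, mito_mask].sum(axis=1)).ravel() if mito_mask.any() else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        adata.obs["mito_fraction"] = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return adata


def filter_cells_qc(
    adata: AnnData, thresholds: CellQCThresholds | None = None
) -> AnnData:
    """Drop cells violating any QC bound; error if none survive."""
    th = thresholds or CellQCThresholds()
    obs = adata.obs
    fail = (
        (obs["n_features"] < th.min_features)
        | (obs["n_features"] > th.max_features)
        | (obs["total_counts"] < th.min_total)
        | (obs["mito_fraction"] > th.max_mito)
    )
    n_fail = int(fail.sum())
    if n_fail:
        logger.info("cell QC removed %d of %d cells", n_fail, adata.n_obs)
    if n_fail == adata.n_obs:
        raise ValueError("cell QC removed every cell")
    return adata[~fail.to_numpy()].copy()


def normalize_cells(adata: AnnData, scale: float = 1e4) -> AnnData:
    """Depth-scaled log normalization: ``log1p(count / total * scale)``.

    Stored as ``layers["lognorm"]``; raw counts are left untouched.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    total = np.asarray(sp.csr_matrix(adata.X).sum(axis=1)).ravel()
    if (total <= 0).any():
        raise ValueError("every cell needs positive total counts")
    norm = sp.csr_matrix(adata.X, dtype=float).multiply(1.0 / total[:, None] * scale)
    norm = sp.csr_matrix(norm)
    norm.data = np.log1p(norm.data)
    adata.layers["lognorm"] = norm
    return adata


# ---------------------------------------------------------------------------
# gating


@dataclass
class Gate:
    name: str
    parent: str | None
    positive_markers: tuple[str, ...]
    negative_markers: tuple[str, ...] = ()
    min_positive_detected: int = 1

    def __post_init__(self) -> None:
        if set(self.positive_markers) & set(self.negative_markers):
            raise ValueError(f"gate {self.name}: marker sets overlap")


@dataclass
class GatingModel:
    """A forest of marker gates; assignment is the deepest passed gate."""

    gates: list[Gate] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [g.name for g in self.gates]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gate names")
        by_name = {g.name: g for g in self.gates}
        for g in self.gates:
            if g.parent is not None and g.parent not in by_name:
                raise ValueError(f"gate {g.name}: unknown parent {g.parent}")
        # cycle check by walking each ancestor chain
        for g in self.gates:
            seen = set()
            node = g
            while node.parent is not None:
                if node.name in seen:
                    raise ValueError("gate graph contains a cycle")
                seen.add(node.name)
                node = by_name[node.parent]

    def children(self, name: str) -> list[Gate]:
        return [g for g in self.gates if g.parent == name]

    def roots(self) -> list[Gate]:
        return [g for g in self.gates if g.parent is None]

    def path(self, name: str) -> list[str]:
        by_name = {g.name: g for g in self.gates}
        chain = [name]
        node = by_name[name]
        while node.parent is not None:
            chain.append(node.parent)
            node = by_name[node.parent]
        return chain[::-1]

    @classmethod
    def from_yaml(cls, path) -> "GatingModel":
        with open(path) as fh:
            spec = yaml.safe_load(fh)
        gates = [
            Gate(
                name=entry["name"],
                parent=entry.get("parent"),
                positive_markers=tuple(entry.get("positive", ())),
                negative_markers=tuple(entry.get("negative", ())),
                min_positive_detected=int(entry.get("min_positive_detected", 1)),
            )
            for entry in spec["gates"]
        ]
        return cls(gates)


def default_gating_model() -> GatingModel:
    """Marker gates for the hematopoietic compartments the study compares.

    Lin-CD34+ HSPCs split into CD38- HSCs and CD38+ GMPs; CD14+ monocytes
    are gated separately.
    """
    lin = ("CD3E", "CD19", "CD14")
    return GatingModel(
        [
            Gate("HSPC", None, positive_markers=("CD34",), negative_markers=lin),
            Gate("HSC", "HSPC", positive_markers=("CD34",), negative_markers=("CD38",)),
            Gate("GMP", "HSPC", positive_markers=("CD34", "CD38"), min_positive_detected=2),
            Gate(
                "Monocyte",
                None,
                positive_markers=("CD14",),
                negative_markers=("CD34", "CD3E", "CD19"),
            ),
        ]
    )


def assign_gates(adata: AnnData, model: GatingModel) -> pd.DataFrame:
    """Assign each cell the deepest passed gate along a root-to-leaf path.

    "Detected" means raw count > 0.  Markers missing from the gene universe
    are warned about and ignored.  If two passed gates are both deepest
    (no passed child), the cell is left ``unassigned``.

    Returns a DataFrame indexed like ``obs`` with ``lineage`` and
    ``gate_path`` columns; also stored on ``obs``.
    """
    x = sp.csc_matrix(adata.X)
    var_index = {g: i for i, g in enumerate(adata.var_names)}
    detected: dict[str, np.ndarray] = {}

    def detect(marker: str) -> np.ndarray | None:
        if marker not in var_index:
            logger.warning("gating marker %s absent from gene universe; ignored", marker)
            return None
        if marker not in detected:
            col = x[:, var_index[marker]]
            detected[marker] = np.asarray((col > 0).todense()).ravel()
        return detected[marker]

    passed: dict[str, np.ndarray] = {}
    for gate in model.gates:
        pos = [detect(m) for m in gate.positive_markers]
        pos = [p for p in pos if p is not None]
        neg = [detect(m) for m in gate.negative_markers]
        neg = [p for p in neg if p is not None]
        n_pos = np.sum(pos, axis=0) if pos else np.zeros(adata.n_obs)
        ok = n_pos >= min(gate.min_positive_detected, len(pos)) if pos else np.ones(
            adata.n_obs, dtype=bool
        )
        for neg_mask in neg:
            ok = ok & ~neg_mask
        passed[gate.name] = np.asarray(ok, dtype=bool)

    # a gate fully passes only if its whole ancestor chain passes
    full_pass: dict[str, np.ndarray] = {}
    for gate in model.gates:
        mask = passed[gate.name].copy()
        for ancestor in model.path(gate.name)[:-1]:
            mask &= passed[ancestor]
        full_pass[gate.name] = mask

    labels = np.full(adata.n_obs, UNASSIGNED, dtype=object)
    paths = np.full(adata.n_obs, "", dtype=object)
    # deepest passed gates = fully-passed gates with no fully-passed child
    terminal = {}
    for gate in model.gates:
        kids = model.children(gate.name)
        child_any = (
            np.any([full_pass[k.name] for k in kids], axis=0)
            if kids
            else np.zeros(adata.n_obs, dtype=bool)
        )
        terminal[gate.name] = full_pass[gate.name] & ~np.asarray(child_any, dtype=bool)
    terminal_stack = np.vstack([terminal[g.name] for g in model.gates])
    n_terminal = terminal_stack.sum(axis=0)
    unique_idx = np.where(n_terminal == 1)[0]
    which = terminal_stack[:, unique_idx].argmax(axis=0)
    gate_names = [g.name for g in model.gates]
    for cell_i, gate_i in zip(unique_idx, which):
        labels[cell_i] = gate_names[gate_i]
        paths[cell_i] = "/".join(model.path(gate_names[gate_i]))
    n_ambiguous = int((n_terminal > 1).sum())
    if n_ambiguous:
        logger.warning("%d cell(s) ambiguous across sibling gates -> unassigned", n_ambiguous)
    out = pd.DataFrame({"lineage": labels, "gate_path": paths}, index=adata.obs_names)
    adata.obs["lineage"] = out["lineage"]
    adata.obs["gate_path"] = out["gate_path"]
    return out


# ---------------------------------------------------------------------------
# within-population differential expression


def sc_de(
    adata: AnnData,
    population: str,
    min_detect_frac: float = 0.10,
    exact_cutoff: int = 16,
) -> pd.DataFrame:
    """Two-group Wilcoxon DE within one gated population.

    Genes are tested when detected (raw count > 0) in at least
    ``min_detect_frac`` of the population's cells in either group.  The
    test runs on the log-normalized layer; ``log2fc`` is the difference of
    group means of log-normalized expression divided by ln 2 (positive =
    higher in disease).  BH adjustment is over tested genes.
    """
    if "lineage" not in adata.obs:
        raise ValueError("run assign_gates first")
    if "lognorm" not in adata.layers:
        raise ValueError("run normalize_cells first")
    mask = (adata.obs["lineage"] == population).to_numpy()
    if not mask.any():
        raise ValueError(f"no cells assigned to population {population!r}")
    sub = adata[mask]
    groups = sub.obs["group"].to_numpy()
    dis, ctl = groups == "disease", groups == "control"
    if not dis.any() or not ctl.any():
        raise ValueError(f"population {population!r} missing one group")

    counts = sp.csc_matrix(sub.X)
    lognorm = sp.csc_matrix(sub.layers["lognorm"])
    det_dis = np.asarray((counts[dis] > 0).mean(axis=0)).ravel()
    det_ctl = np.asarray((counts[ctl] > 0).mean(axis=0)).ravel()
    testable = np.where((det_dis >= min_detect_frac) | (det_ctl >= min_detect_frac))[0]

    rows = []
    for j in testable:
        vals = np.asarray(lognorm[:, j].todense()).ravel()
        res = wilcoxon_rank_sum(vals[dis], vals[ctl], exact_cutoff=exact_cutoff)
        lfc = (vals[dis].mean() - vals[ctl].mean()) / np.log(2.0)
        rows.append((sub.var_names[j], lfc, res.statistic, res.p_value))
    result = pd.DataFrame(
        rows, columns=["gene", "log2fc", "U", "p_value"]
    ).set_index("gene")
    result["adj_p"] = bh_adjust(result["p_value"].to_numpy())
    result["detect_frac_disease"] = det_dis[testable]
    result["detect_frac_control"] = det_ctl[testable]
    return result
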