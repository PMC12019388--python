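"""Bulk RNA-seq differential expression.

The stage mirrors the standard count-based workflow for two-group cohort
comparisons: strict per-sample QC on alignment metrics, trimmed-mean-of-
M-values (TMM) composition normalization, a log-CPM transform, precision
weights from a fitted mean-variance trend, and empirical-Bayes moderated
t-statistics with Benjamini-Hochberg adjustment.

Sign convention: positive ``log2fc`` means higher in the disease group.
This is used everywhere downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special
from scipy.stats import rankdata, t as t_dist
from statsmodels.nonparametric.smoothers_lowess import lowess

from .stats import bh_adjust

logger = logging.getLogger(__name__)

DISEASE, CONTROL = "disease", "control"


# ---------------------------------------------------------------------------
# containers


@dataclass
class QCThresholds:
    """Strict sample-level QC bounds.

    A sample is kept only if total mapped reads, non-scaled library reads
    and unique mapped reads all strictly exceed their thresholds and the
    mitochondrial ratio is strictly below ``max_mito_ratio``.
    """

    min_total_mapped: float = 30e6
    min_nonscaled_reads: float = 3e6
    min_unique_mapped: float = 3e6
    max_mito_ratio: float = 0.10


@dataclass
class CountMatrix:
    """Gene x sample integer counts plus a sample sheet.

    ``samples`` is indexed by sample id and carries at least a ``group``
    column (``disease``/``control``); QC metric columns
    (``total_mapped_reads``, ``nonscaled_library_reads``,
    ``unique_mapped_reads``, ``mito_ratio``) are required by
    :func:`filter_samples_qc`.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids in count matrix")
        if not self.counts.columns.equals(self.samples.index):
            self.samples = self.samples.loc[self.counts.columns]
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def groups(self) -> pd.Series:
        return self.samples["group"]


@dataclass
class NormalizationModel:
    """TMM scaling factors and the effective library sizes they imply."""

    tmm_factor: pd.Series
    library_size: pd.Series
    reference_sample: str

    @property
    def effective_library_size(self) -> pd.Series:
        return self.library_size * self.tmm_factor


@dataclass
class VoomFit:
    """Log-CPM observations with mean-variance precision weights."""

    log_cpm: pd.DataFrame
    weights: pd.DataFrame
    trend_x: np.ndarray
    trend_y: np.ndarray
    groups: pd.Series = field(repr=False, default=None)


@dataclass(frozen=True)
class EBayesPrior:
    """Scaled-inverse-chi-square prior on residual variances."""

    d0: float
    s0_sq: float


# ---------------------------------------------------------------------------
# sample QC


def filter_samples_qc(
    m: CountMatrix, thresholds: QCThresholds | None = None
) -> CountMatrix:
    """Drop samples failing any strict QC criterion.

    Raises ``ValueError`` if no sample survives.
    """
    thresholds = thresholds or QCThresholds()
    qc = m.samples
    keep = (
        (qc["total_mapped_reads"] > thresholds.min_total_mapped)
        & (qc["nonscaled_library_reads"] > thresholds.min_nonscaled_reads)
        & (qc["unique_mapped_reads"] > thresholds.min_unique_mapped)
        & (qc["mito_ratio"] < thresholds.max_mito_ratio)
    )
    dropped = list(qc.index[~keep])
    if dropped:
        logger.info("sample QC removed %d sample(s): %s", len(dropped), dropped)
    if not keep.any():
        raise ValueError("sample QC removed every sample")
    return CountMatrix(m.counts.loc[:, keep[keep].index], qc.loc[keep])


def drop_unexpressed_genes(m: CountMatrix) -> CountMatrix:
    """Remove genes with zero counts in all samples (undefined M-values)."""
    keep = m.counts.sum(axis=1) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d all-zero gene(s) before normalization", n_dropped)
    return CountMatrix(m.counts.loc[keep], m.samples)


# ---------------------------------------------------------------------------
# TMM normalization


def _tmm_pair_factor(
    obs_counts: np.ndarray,
    ref_counts: np.ndarray,
    obs_lib: float,
    ref_lib: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """log2 TMM factor for one sample against the reference."""
    shared = (obs_counts > 0) & (ref_counts > 0)
    if not shared.any():
        warnings.warn("sample shares no expressed genes with TMM reference")
        return 0.0
    o = obs_counts[shared] / obs_lib
    r = ref_counts[shared] / ref_lib
    m_vals = np.log2(o / r)
    a_vals = 0.5 * np.log2(o * r)
    if np.max(np.abs(m_vals)) < 1e-6:
        return 0.0
    n = m_vals.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m_vals)
    rank_a = rankdata(a_vals)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    # asymptotic (delta-method) variance of each M-value
    oc = obs_counts[shared]
    rc = ref_counts[shared]
    var = (obs_lib - oc) / (obs_lib * oc) + (ref_lib - rc) / (ref_lib * rc)
    w = 1.0 / var
    return float(np.sum(m_vals[keep] * w[keep]) / np.sum(w[keep]))


def tmm_normalize(m: CountMatrix) -> NormalizationModel:
    """Trimmed mean of M-values scaling factors.

    The reference is the sample whose upper-quartile count proportion is
    closest to the across-sample mean (lowest index on ties).  Per sample,
    M/A values over genes expressed in both sample and reference are
    two-sided trimmed (30% on M, 5% on A) and combined by a
    precision-weighted mean; factors are rescaled to geometric mean 1.
    """
    counts = m.counts.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample needs a positive library size")
    upper_quartile = np.array(
        [np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])]
    )
    ref_idx = int(np.argmin(np.abs(upper_quartile - upper_quartile.mean())))
    log_factors = np.array(
        [
            _tmm_pair_factor(counts[:, j], counts[:, ref_idx], lib[j], lib[ref_idx])
            for j in range(counts.shape[1])
        ]
    )
    factors = 2.0**log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    sample_ids = m.counts.columns
    return NormalizationModel(
        tmm_factor=pd.Series(factors, index=sample_ids, name="tmm_factor"),
        library_size=pd.Series(lib, index=sample_ids, name="library_size"),
        reference_sample=str(sample_ids[ref_idx]),
    )


# ---------------------------------------------------------------------------
# log-CPM transforms


def log_cpm(
    m: CountMatrix,
    nm: NormalizationModel | None = None,
    variant: str = "reporting",
    prior: float = 0.5,
) -> pd.DataFrame:
    """Log-scale CPM matrix.

    ``variant="reporting"`` is ``log2(CPM + 1)`` on effective library
    sizes, used for expression summaries.  ``variant="voom"`` is
    ``log2((count + prior) / (effective_library + 1) * 1e6)``, the
    modeling transform (``prior`` defaults to 0.5).
    """
    if prior <= 0:
        raise ValueError("prior must be positive")
    counts = m.counts
    if nm is None:
        elib = counts.sum(axis=0).astype(float)
    else:
        elib = nm.effective_library_size.loc[counts.columns]
    if (elib <= 0).any():
        raise ValueError("effective library sizes must be positive")
    if variant == "reporting":
        cpm = counts / elib * 1e6
        return np.log2(cpm + 1.0)
    if variant == "voom":
        return np.log2((counts + prior) / (elib + 1.0) * 1e6)
    raise ValueError(f"unknown log-CPM variant {variant!r}")


# ---------------------------------------------------------------------------
# precision weights


def _group_indicator(groups: pd.Series) -> np.ndarray:
    levels = set(groups)
    if not levels <= {DISEASE, CONTROL}:
        raise ValueError(f"group labels must be {{{DISEASE!r}, {CONTROL!r}}}")
    if len(levels) < 2:
        raise ValueError("both groups must be present")
    return (groups == DISEASE).to_numpy(dtype=float)


def voom_weights(
    m: CountMatrix,
    nm: NormalizationModel,
    groups: pd.Series,
    span: float = 0.5,
    iterations: int = 3,
) -> VoomFit:
    """Precision weights from the fitted mean-variance trend.

    A two-group-means model is fitted per gene on the voom-transformed
    log-CPM; a lowess of sqrt residual SD against average log-count gives
    the trend, interpolated linearly between lowess points and held
    constant outside their range; each observation's weight is the trend
    evaluated at its fitted log-count, raised to the power -4.
    """
    g = _group_indicator(groups.loc[m.counts.columns])
    if min((g == 1).sum(), (g == 0).sum()) < 2:
        raise ValueError("need at least two samples per group")
    if m.counts.shape[0] < 10:
        raise ValueError("too few genes to estimate the mean-variance trend")
    y = log_cpm(m, nm, variant="voom").to_numpy(dtype=float)
    elib = nm.effective_library_size.loc[m.counts.columns].to_numpy(dtype=float)

    fitted = _fit_group_means(y, g)
    resid = y - fitted
    df = y.shape[1] - 2
    sigma = np.sqrt((resid**2).sum(axis=1) / df)

    lib_offset = np.log2(elib + 1.0) - np.log2(1e6)
    sx = y.mean(axis=1) + lib_offset.mean()
    sy = np.sqrt(sigma)
    smooth = lowess(sy, sx, frac=span, it=iterations, return_sorted=True)
    trend_x, trend_y = _dedupe_sorted(smooth[:, 0], smooth[:, 1])

    fitted_log_count = fitted + lib_offset[np.newaxis, :]
    trend_at = np.interp(fitted_log_count, trend_x, trend_y)
    trend_at = np.maximum(trend_at, 1e-6)
    weights = trend_at**-4.0
    idx, cols = m.counts.index, m.counts.columns
    return VoomFit(
        log_cpm=pd.DataFrame(y, index=idx, columns=cols),
        weights=pd.DataFrame(weights, index=idx, columns=cols),
        trend_x=trend_x,
        trend_y=trend_y,
        groups=groups.loc[cols],
    )


def _fit_group_means(y: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Unweighted per-gene fitted values under the two-group-means model."""
    mean1 = y[:, g == 1].mean(axis=1)
    mean0 = y[:, g == 0].mean(axis=1)
    return np.where(g[np.newaxis, :] == 1, mean1[:, np.newaxis], mean0[:, np.newaxis])


def _dedupe_sorted(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average y over duplicate x so np.interp sees strictly increasing x."""
    ux, inverse = np.unique(x, return_inverse=True)
    sums = np.bincount(inverse, weights=y)
    counts = np.bincount(inverse)
    return ux, sums / counts


# ---------------------------------------------------------------------------
# empirical-Bayes moderated fit


def trigamma_inverse(y: float, tol: float = 1e-12, max_iter: int = 100) -> float:
    """Solve ``trigamma(x) = y`` for x by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma is positive")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-8:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + step
        if abs(step) < tol * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> EBayesPrior:
    """Method-of-moments fit of the scaled-inverse-chi-square prior.

    Works on log sample variances: under the model
    ``s2 ~ s0_sq * F(df, d0)``, the log variances have known digamma /
    trigamma moments from which ``d0`` is recovered by trigamma inversion.
    """
    ok = s2 > 0
    if not ok.any():
        raise ValueError("no positive residual variances")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - special.polygamma(1, df / 2.0) if e.size > 1 else 0.0
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s0_sq = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(e_mean)
    return EBayesPrior(d0=float(d0), s0_sq=float(s0_sq))


def fit_moderated_de(fit: VoomFit, groups: pd.Series | None = None):
    """Weighted two-group fit with empirical-Bayes moderated t-statistics.

    Returns ``(DEResult, EBayesPrior)`` where ``DEResult`` is a DataFrame
    indexed by gene with columns ``log2fc`` (disease minus control),
    ``t``, ``p_value``, ``adj_p`` and ``mean_log_cpm``.
    """
    groups = groups if groups is not None else fit.groups
    g = _group_indicator(groups.loc[fit.log_cpm.columns])
    y = fit.log_cpm.to_numpy(dtype=float)
    w = fit.weights.to_numpy(dtype=float)
    n = y.shape[1]
    df = n - 2
    if df < 1:
        raise ValueError("no residual degrees of freedom")

    s0 = w.sum(axis=1)
    s1 = (w * g).sum(axis=1)
    sy = (w * y).sum(axis=1)
    sgy = (w * g * y).sum(axis=1)
    det = s1 * (s0 - s1)
    beta1 = (s0 * sgy - s1 * sy) / det
    beta0 = (s1 * sy - s1 * sgy) / det
    fitted = beta0[:, None] + beta1[:, None] * g[None, :]
    s2 = (w * (y - fitted) ** 2).sum(axis=1) / df
    stdev_unscaled = np.sqrt(s0 / det)

    prior = fit_variance_prior(s2, df)
    if np.isinf(prior.d0):
        post_s2 = np.full_like(s2, prior.s0_sq)
        df_total = np.inf
    else:
        post_s2 = (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)
        df_total = df + prior.d0
    t_stat = beta1 / (stdev_unscaled * np.sqrt(post_s2))
    if np.isinf(df_total):
        from scipy.stats import norm

        p = 2.0 * norm.sf(np.abs(t_stat))
    else:
        p = 2.0 * t_dist.sf(np.abs(t_stat), df_total)
    result = pd.DataFrame(
        {
            "log2fc": beta1,
            "t": t_stat,
            "p_value": p,
            "adj_p": bh_adjust(p),
            "mean_log_cpm": y.mean(axis=1),
        },
        index=fit.log_cpm.index,
    )
    return result, prior


# ---------------------------------------------------------------------------
# convenience pipeline


def run_bulk_de(
    m: CountMatrix,
    thresholds: QCThresholds | None = None,
    qc_filter: bool = True,
):
    """QC -> TMM -> voom weights -> moderated DE in the fixed order.

    Returns ``(DEResult, NormalizationModel, VoomFit, EBayesPrior,
    CountMatrix)`` where the count matrix is the post-QC one.
    """
    if qc_filter:
        m = filter_samples_qc(m, thresholds)
    m = drop_unexpressed_genes(m)
    nm = tmm_normalize(m)
    fit = voom_weights(m, nm, m.groups)
    result, prior = fit_moderated_de(fit)
    return result, nm, fit, prior, m
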