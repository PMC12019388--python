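"""Flow-cytometry quantitation metrics.

Event tables are tabular (one row per event, linear-scale intensities);
stained samples are paired with fluorescence-minus-one (FMO) controls.
Metrics: MFI-ratio positivity (median by default), percent positive
against an FMO quantile threshold, the staining index used for antibody
titration, bead-standard log-log calibration, antigen-per-cell conversion
(1:1 PE:antibody assumption), and cytotoxicity normalization to
untransduced (UTD) T-cell controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BeadCalibration",
    "mfi",
    "mfi_ratio",
    "percent_positive",
    "staining_index",
    "fit_bead_calibration",
    "antigens_per_cell",
    "normalize_cytotoxicity",
]


def _intensities(events) -> np.ndarray:
    if isinstance(events, pd.DataFrame):
        events = events["intensity"]
    x = np.asarray(events, dtype=float)
    if x.size == 0:
        raise ValueError("event table is empty")
    if not np.isfinite(x).all():
        raise ValueError("intensities must be finite")
    return x


def mfi(events, statistic: str = "median") -> float:
    """Sample fluorescence summary: median (default) or geometric mean."""
    x = _intensities(events)
    if statistic == "median":
        return float(np.median(x))
    if statistic == "geometric_mean":
        if (x <= 0).any():
            raise ValueError("geometric mean requires positive intensities")
        return float(np.exp(np.mean(np.log(x))))
    raise ValueError(f"unknown MFI statistic {statistic!r}")


def mfi_ratio(
    stained, fmo, threshold: float = 1.5, statistic: str = "median"
) -> dict:
    """MFI of stained over FMO; positive iff the ratio strictly exceeds
    the threshold (default 1.5)."""
    stained_mfi = mfi(stained, statistic)
    fmo_mfi = mfi(fmo, statistic)
    if fmo_mfi <= 0:
        raise ValueError("FMO MFI must be positive")
    ratio = stained_mfi / fmo_mfi
    return {
        "mfi_stained": stained_mfi,
        "mfi_fmo": fmo_mfi,
        "mfi_ratio": ratio,
        "positive": bool(ratio > threshold),
    }


def percent_positive(stained, fmo, quantile: float = 0.99) -> dict:
    """Fraction of stained events above the FMO background quantile."""
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    s = _intensities(stained)
    f = _intensities(fmo)
    threshold = float(np.quantile(f, quantile))
    frac = float((s > threshold).mean())
    return {"threshold": threshold, "percent_positive": frac}


def staining_index(pos, neg) -> float:
    """(median(pos) - median(neg)) / (2 x robust SD of neg), with robust SD
    the 84.13th-percentile-minus-median spread of the negative sample."""
    p = _intensities(pos)
    n = _intensities(neg)
    robust_sd = float(np.percentile(n, 84.13) - np.median(n))
    if robust_sd <= 0:
        raise ValueError("negative population has zero robust SD")
    return float((np.median(p) - np.median(n)) / (2.0 * robust_sd))


@dataclass
class BeadCalibration:
    """log10(molecules) = intercept + slope * log10(MFI), least squares."""

    slope: float
    intercept: float
    r_squared: float
    molecules: np.ndarray
    mfi: np.ndarray


def fit_bead_calibration(molecules, bead_mfi) -> BeadCalibration:
    """Quantibrite-style log-log regression of molecules-per-bead on MFI."""
    mol = np.asarray(molecules, dtype=float)
    m = np.asarray(bead_mfi, dtype=float)
    if mol.size != m.size or mol.size < 2:
        raise ValueError("need at least two bead populations")
    if (mol <= 0).any() or (m <= 0).any():
        raise ValueError("bead molecules and MFI must be positive")
    if not np.all(np.diff(mol) > 0):
        raise ValueError("bead molecule counts must be strictly increasing")
    if np.unique(m).size < 2:
        raise ValueError("bead MFIs must be distinct")
    x, y = np.log10(m), np.log10(mol)
    slope, intercept = np.polyfit(x, y, 1)
    fitted = intercept + slope * x
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return BeadCalibration(float(slope), float(intercept), r2, mol, m)


def antigens_per_cell(cal: BeadCalibration, cell_mfi: float) -> float:
    """Antibodies bound per cell from the bead calibration (reported as
    antigen density under the 1:1 PE-conjugate assumption)."""
    if cell_mfi <= 0:
        raise ValueError("cell MFI must be positive")
    return float(10.0 ** (cal.intercept + cal.slope * np.log10(cell_mfi)))


def normalize_cytotoxicity(treated_signal: float, utd_signal: float) -> dict:
    """Percent viable cells relative to the UTD control at the same E:T.

    Values above 100 are allowed and flagged rather than capped.
    """
    if utd_signal <= 0:
        raise ValueError("UTD signal must be positive")
    if treated_signal < 0:
        raise ValueError("treated signal must be non-negative")
    pct = 100.0 * treated_signal / utd_signal
    return {"percent_viable": pct, "over_100": bool(pct > 100.0)}
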