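"""Per-cell immunofluorescence quantification for tumour explants.

Operates on per-cell measurement tables exported by a cell-detection tool
(QuPath-style columns): QC filtering on nucleus area and total DAPI
signal, Otsu-threshold marker-positivity calls (e.g. PDPN+ alpha-SMA+
myCAFs, PDPN+ IL-6+ IL-iCAFs), and the treated-vs-control median
percentage-change statistic with a Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QcBounds",
    "QUPATH_DETECTION_DEFAULTS",
    "qc_filter",
    "otsu_threshold",
    "classify_positive",
    "percent_change_stat",
]

# Cell-detection parameters used upstream of the exported tables; recorded
# here for documentation/config only — detection itself happens elsewhere.
QUPATH_DETECTION_DEFAULTS = {
    "background_radius_um": 13.0,
    "median_radius_um": 0.0,
    "sigma": 3.0,
    "minimum_area_um2": 3.6,
    "maximum_area_um2": 722.5,
    "threshold": 10.0,
    "cell_expansion_um": 8.5,
    "smooth_boundaries": True,
}


@dataclass(frozen=True)
class QcBounds:
    """Closed-interval QC bounds on nucleus area (um^2) and total DAPI signal."""

    nucleus_area_min: float
    nucleus_area_max: float
    dapi_total_min: float
    dapi_total_max: float

    def __post_init__(self) -> None:
        if not (self.nucleus_area_min < self.nucleus_area_max):
            raise ValueError("nucleus area bounds require min < max")
        if not (self.dapi_total_min < self.dapi_total_max):
            raise ValueError("DAPI bounds require min < max")


def qc_filter(cells: pd.DataFrame, bounds: QcBounds) -> pd.DataFrame:
    """Keep cells inside both closed QC intervals (bounds themselves pass)."""
    area = cells["nucleus_area"].astype(float)
    dapi = cells["dapi_total"].astype(float)
    keep = (
        (area >= bounds.nucleus_area_min)
        & (area <= bounds.nucleus_area_max)
        & (dapi >= bounds.dapi_total_min)
        & (dapi <= bounds.dapi_total_max)
    )
    return cells[keep].copy()


def otsu_threshold(values, n_bins: int = 256) -> float:
    """Histogram threshold maximising between-class variance (Otsu).

    Returned as the centre of the optimal split bin; values strictly above
    it are called positive.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2 or np.ptp(v) == 0:
        raise ValueError("Otsu threshold requires >= 2 distinct values")
    hist, edges = np.histogram(v, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2.0

    w = hist.astype(float)
    w0 = np.cumsum(w)
    w1 = w0[-1] - w0
    cum = np.cumsum(w * centers)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum / w0
        mu1 = (cum[-1] - cum) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -np.inf
    # split after bin i: classes are bins [0..i] vs (i..]; exclude the last.
    # The variance is flat across empty gaps between modes, so the threshold
    # is the centre of the maximising plateau, not its first bin.
    splits = between[:-1]
    # plateau membership up to last-bit rounding of the variance
    best = np.flatnonzero(splits >= splits.max() * (1.0 - 1e-12))
    return float(centers[best].mean())


def classify_positive(
    cells: pd.DataFrame, markers: dict[str, float]
) -> pd.DataFrame:
    """Boolean positivity calls per marker (value strictly above threshold).

    ``markers`` maps column names to thresholds. A ``double_positive``
    column (AND over all markers) is added when more than one marker is
    given.
    """
    out = cells.copy()
    for col, thr in markers.items():
        out[f"{col}_positive"] = out[col].astype(float) > thr
    if len(markers) > 1:
        flags = [out[f"{c}_positive"] for c in markers]
        out["double_positive"] = np.logical_and.reduce(flags)
    return out


def percent_change_stat(
    treated_values,
    control_values,
    definition: str = "per_cell_median",
) -> dict:
    """Median percentage change with treatment, plus Wilcoxon rank-sum p.

    Default definition ("per_cell_median"): for each treated cell compute
    100 * (x - median(control)) / median(control) and report the median of
    these. The alternative ("median_ratio") reports 100 * (median(treated)
    - median(control)) / median(control). Both a rank-sum test on the raw
    intensities and one on the per-cell percentage changes (against zero
    shift relative to control) are emitted, since either convention is
    defensible; the definition used is recorded in the result.
    """
    t = np.asarray(treated_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("both groups must be non-empty")
    med_c = float(np.median(c))
    if med_c <= 0:
        raise ValueError("control median must be positive")

    per_cell = 100.0 * (t - med_c) / med_c
    if definition == "per_cell_median":
        change = float(np.median(per_cell))
    elif definition == "median_ratio":
        change = float(100.0 * (np.median(t) - med_c) / med_c)
    else:
        raise ValueError(f"unknown definition {definition!r}")

    stat_raw, p_raw = stats.ranksums(t, c)
    control_pct = 100.0 * (c - med_c) / med_c
    stat_pct, p_pct = stats.ranksums(per_cell, control_pct)
    return {
        "median_percent_change": change,
        "definition": definition,
        "p_value_intensity": float(p_raw),
        "statistic_intensity": float(stat_raw),
        "p_value_percent_change": float(p_pct),
        "statistic_percent_change": float(stat_pct),
        "n_treated": int(t.size),
        "n_control": int(c.size),
        "control_median": med_c,
    }
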