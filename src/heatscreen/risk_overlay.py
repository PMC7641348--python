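"""Overlay of heat-exposure change against vulnerability percentiles.

Risk is a function of hazard, exposure, and vulnerability: the tracts most
at risk are those that are both highly vulnerable and facing the largest
increases in extreme heat.  This module produces the statewide trend curves
(mean exposure delta per fixed-width vulnerability-percentile bin) and a
simple joint risk flag (vulnerable AND upper-quartile exposure delta).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_BIN_WIDTH = 2.5


def bin_by_vulnerability(percentiles,
                         deltas,
                         bin_width: float = DEFAULT_BIN_WIDTH,
                         statistic: str = "mean",
                         index_name: str = "") -> pd.DataFrame:
    """Summarize exposure deltas in fixed-width vulnerability-percentile bins.

    Bins tile [0, 100] as [0, w), [w, 2w), …, [100-w, 100]; the top edge is
    inclusive so a 100th-percentile tract lands in the last bin.  With the
    default 2.5-wide bins and percentiles that form a complete percentile
    ranking, each of the 40 bins holds ~1/40 of the tracts.  Empty bins are
    reported with ``n_tracts = 0`` and a missing statistic.

    Returns columns: ``index_name, bin_lower, bin_upper, n_tracts,
    mean_delta`` (``mean_delta`` holds the median when
    ``statistic="median"``).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = round(100.0 / bin_width)
    if abs(n_bins * bin_width - 100.0) > 1e-9:
        raise ValueError("bin_width must divide 100")
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    pct = np.asarray(percentiles, dtype=float)
    dlt = np.asarray(deltas, dtype=float)
    if pct.shape != dlt.shape:
        raise ValueError("percentiles and deltas must be aligned")
    keep = ~np.isnan(pct)
    pct, dlt = pct[keep], dlt[keep]
    if ((pct < 0) | (pct > 100)).any():
        raise ValueError("percentiles must lie in [0, 100]")
    idx = np.minimum(np.floor(pct / bin_width).astype(int), n_bins - 1)
    stat_fn = np.mean if statistic == "mean" else np.median
    rows = []
    for b in range(n_bins):
        in_bin = idx == b
        n = int(in_bin.sum())
        value = float(stat_fn(dlt[in_bin])) if n else np.nan
        rows.append((index_name, b * bin_width, (b + 1) * bin_width, n, value))
    return pd.DataFrame(rows, columns=["index_name", "bin_lower", "bin_upper",
                                       "n_tracts", "mean_delta"])


def joint_risk_flag(vulnerable,
                    deltas,
                    exposure_quantile: float = 0.75) -> np.ndarray:
    """Flag tracts that are vulnerable AND in the statewide top exposure band.

    The exposure cutoff is the given quantile of the supplied deltas
    (upper quartile by default); a delta exactly at the cutoff is included.
    ``vulnerable`` may be any boolean operationalization (single-index flag
    or a compound-score condition).
    """
    if not 0 <= exposure_quantile <= 1:
        raise ValueError("exposure_quantile must lie in [0, 1]")
    vul = np.asarray(vulnerable, dtype=bool)
    dlt = np.asarray(deltas, dtype=float)
    if vul.shape != dlt.shape:
        raise ValueError("vulnerable flags and deltas must be aligned")
    cutoff = np.quantile(dlt, exposure_quantile)
    return vul & (dlt >= cutoff)
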