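"""Harmonization and comparison of tract-level social-vulnerability indices.

California-style equity screening designates a census tract "disadvantaged"
when its vulnerability-index percentile falls in the upper quartile.  This
module harmonizes three indices onto a common percentile scale —

* **CES**  (CalEnviroScreen 3.0) — pollution burden plus population
  characteristics, published directly as tract percentiles;
* **HHAI** (Heat-Health Action Index) — heat-specific vulnerability,
  published as raw scores that must be converted to percentile ranks;
* **SVI**  (CDC Social Vulnerability Index) — all-hazards social
  vulnerability, published as an overall ranking on [0, 1];

— flags tracts as vulnerable under each, counts the flags into a *compound
vulnerability score* (0–3), and summarizes agreement between the indices
(Venn partition, per-region score distributions, density- and
pollution-stratified medians).

All tabular operations take and return :class:`pandas.DataFrame` objects
using the canonical column names in :data:`INDEX_PERCENTILE_COLUMNS`.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

#: Canonical percentile column per index.
INDEX_PERCENTILE_COLUMNS = {
    "ces": "ces_percentile",
    "hhai": "hhai_percentile",
    "svi": "svi_percentile",
}

#: Default "disadvantaged" cutoff: upper quartile of the index percentile.
DEFAULT_THRESHOLD = 75.0

#: The eight cells of the three-index Venn partition, in reporting order.
VENN_CELLS = (
    "none",
    "ces_only",
    "hhai_only",
    "svi_only",
    "ces_hhai",
    "ces_svi",
    "hhai_svi",
    "all_three",
)

#: Fixed column order for the harmonized tract table written by the pipeline.
HARMONIZED_COLUMNS = [
    "tract_id",
    "region",
    "population_density",
    "low_income",
    "ces_percentile",
    "hhai_percentile",
    "svi_percentile",
    "vulnerable_ces",
    "vulnerable_hhai",
    "vulnerable_svi",
    "compound_score",
]


def filter_complete_tracts(table: pd.DataFrame) -> pd.DataFrame:
    """Drop tracts missing any of the three index percentiles.

    Index developers assign NA to tracts with zero population or unreliable
    data; such tracts cannot be scored consistently across indices and are
    removed before any comparison.  Input row order is preserved and the
    number of removed rows is logged.
    """
    if table.empty:
        raise ValueError("tract table is empty")
    cols = list(INDEX_PERCENTILE_COLUMNS.values())
    complete = table[cols].notna().all(axis=1)
    removed = int((~complete).sum())
    logger.info("filter_complete_tracts: removed %d of %d tracts with missing index values",
                removed, len(table))
    out = table.loc[complete].copy()
    if out.empty:
        logger.warning("filter_complete_tracts: no tracts remain after completeness filter")
    return out


def to_percentile_ranks(scores) -> np.ndarray:
    """Convert raw scores to percentile ranks on (0, 100].

    The percentile of item *i* is ``100 * average_rank(i) / n``; ties receive
    the mean of the ranks they span, so the maximum attainable value is 100
    and the output is invariant under any strictly monotone transform of the
    scores.  Used to place raw HHAI scores on the same scale as CES/SVI
    percentiles.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.ndim != 1:
        raise ValueError("scores must be one-dimensional")
    if arr.size == 0:
        raise ValueError("cannot rank an empty score vector")
    if np.isnan(arr).any():
        raise ValueError("scores contain missing values; filter before ranking")
    return 100.0 * rankdata(arr, method="average") / arr.size


def classify_vulnerable(percentile, threshold: float = DEFAULT_THRESHOLD):
    """True where the percentile is at or above the threshold (inclusive).

    Accepts a scalar or array; raises on values outside [0, 100].
    """
    arr = np.asarray(percentile, dtype=float)
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 100).any():
        raise ValueError("percentile values must lie in [0, 100]")
    result = arr >= threshold
    if np.isscalar(percentile) or arr.ndim == 0:
        return bool(result)
    return result


def compound_score(flags: Sequence[bool]) -> int:
    """Count of indices (0–3) under which a tract is vulnerable."""
    flags = tuple(flags)
    if len(flags) != 3:
        raise ValueError("compound score is defined over exactly three index flags")
    return int(sum(bool(f) for f in flags))


def assess_vulnerability(table: pd.DataFrame,
                         threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Flag each tract under each index and attach the compound score.

    Expects a complete table (see :func:`filter_complete_tracts`).  Returns a
    frame with ``tract_id``, one boolean ``vulnerable_<index>`` column per
    index, and the integer ``compound_score``.
    """
    out = pd.DataFrame({"tract_id": table["tract_id"].to_numpy()})
    for index, col in INDEX_PERCENTILE_COLUMNS.items():
        out[f"vulnerable_{index}"] = classify_vulnerable(table[col].to_numpy(), threshold)
    flag_cols = [f"vulnerable_{i}" for i in INDEX_PERCENTILE_COLUMNS]
    out["compound_score"] = out[flag_cols].sum(axis=1).astype(int)
    return out


def agreement_partition(assessments: pd.DataFrame) -> dict[str, int]:
    """Count tracts in each cell of the three-index Venn diagram.

    Returns a mapping over :data:`VENN_CELLS`; the counts always sum to the
    number of assessed tracts.
    """
    counts = dict.fromkeys(VENN_CELLS, 0)
    if len(assessments):
        c = assessments["vulnerable_ces"].to_numpy(bool)
        h = assessments["vulnerable_hhai"].to_numpy(bool)
        s = assessments["vulnerable_svi"].to_numpy(bool)
        cells = {
            "none": ~c & ~h & ~s,
            "ces_only": c & ~h & ~s,
            "hhai_only": ~c & h & ~s,
            "svi_only": ~c & ~h & s,
            "ces_hhai": c & h & ~s,
            "ces_svi": c & ~h & s,
            "hhai_svi": ~c & h & s,
            "all_three": c & h & s,
        }
        counts = {k: int(v.sum()) for k, v in cells.items()}
    return counts


def assign_region(overlaps: Mapping[str, float]) -> str:
    """Assign a tract to the region holding its largest area fraction.

    A tract straddling a region boundary goes to the region with greater
    area.  Ties are broken lexicographically (with a warning) so the
    assignment is deterministic.
    """
    if not overlaps:
        raise ValueError("no region overlaps provided")
    items = {str(k): float(v) for k, v in overlaps.items()}
    if any(v < 0 for v in items.values()):
        raise ValueError("area fractions must be non-negative")
    best = max(items.values())
    if best <= 0:
        raise ValueError("all region overlaps are zero")
    winners = sorted(k for k, v in items.items() if v == best)
    if len(winners) > 1:
        logger.warning("assign_region: tie between %s; choosing %r lexicographically",
                       winners, winners[0])
    return winners[0]


def regional_summary(assessments: pd.DataFrame,
                     regions: pd.Series | Mapping[str, str],
                     region_set: Iterable[str] | None = None) -> pd.DataFrame:
    """Per-region tract totals and compound-score composition.

    ``regions`` maps tract_id to region label.  Returns one row per region
    with ``total``, ``score_0`` … ``score_3`` counts and ``frac_score_ge2``,
    the share of the region's tracts vulnerable under two or more indices.
    """
    region_map = pd.Series(regions)
    if len(assessments) == 0:
        return pd.DataFrame(
            columns=["total", "score_0", "score_1", "score_2", "score_3", "frac_score_ge2"]
        )
    labels = assessments["tract_id"].map(region_map)
    if labels.isna().any():
        missing = assessments.loc[labels.isna(), "tract_id"].head().tolist()
        raise KeyError(f"tracts without a region assignment, e.g. {missing}")
    if region_set is not None:
        unknown = set(labels) - set(region_set)
        if unknown:
            raise KeyError(f"unknown region labels: {sorted(unknown)}")
    df = pd.DataFrame({"region": labels.to_numpy(),
                       "score": assessments["compound_score"].to_numpy()})
    table = (df.pivot_table(index="region", columns="score", aggfunc="size", fill_value=0)
               .reindex(columns=range(4), fill_value=0))
    table.columns = [f"score_{s}" for s in range(4)]
    table["total"] = table.sum(axis=1)
    table["frac_score_ge2"] = (table["score_2"] + table["score_3"]) / table["total"]
    return table[["total", "score_0", "score_1", "score_2", "score_3", "frac_score_ge2"]]


def stratified_median(table: pd.DataFrame, stratum) -> pd.Series:
    """Median percentile of each index within a boolean stratum of tracts.

    ``stratum`` is a boolean mask aligned with ``table`` (e.g. membership in
    the top decile of population density, or the upper quartile of pollution
    burden).  For even stratum sizes the median is the midpoint of the two
    central order statistics.
    """
    mask = np.asarray(stratum, dtype=bool)
    if mask.shape[0] != len(table):
        raise ValueError("stratum mask length does not match the table")
    if not mask.any():
        raise ValueError("stratum is empty")
    sub = table.loc[mask]
    return pd.Series(
        {idx: float(np.median(sub[col].to_numpy(float)))
         for idx, col in INDEX_PERCENTILE_COLUMNS.items()},
        name="median_percentile",
    )


def decile_labels(values, n_bins: int = 10) -> np.ndarray:
    """Quantile-bin labels 1..n_bins using linear-interpolation quantile edges.

    Used to stratify tracts by population density; edges are computed on the
    raw values (a log transform changes nothing, quantile bins being
    invariant under monotone maps).
    """
    arr = np.asarray(values, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("values contain NaN")
    edges = np.quantile(arr, np.linspace(0, 1, n_bins + 1))
    labels = np.searchsorted(edges[1:-1], arr, side="left") + 1
    return labels.astype(int)


def upper_quartile_mask(values) -> np.ndarray:
    """Boolean mask for values at or above their 75th percentile."""
    arr = np.asarray(values, dtype=float)
    return arr >= np.quantile(arr, 0.75)
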