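"""Readers and writers for the pipeline's CSV dialects.

Index tables come from different agencies with different conventions: CES
ships a precomputed percentile column, the CDC SVI encodes its overall
ranking on [0, 1], and the HHAI ships raw scores.  Rather than hard-coding
any agency's column names, each reader takes a column-mapping configuration
(a plain dict, loadable from YAML) with the keys::

    tract_id_col, score_col, percentile_col, na_sentinels, scale, version

``scale`` is ``"percent"`` (used as-is) or ``"unit"`` (multiplied by 100);
``na_sentinels`` lists values treated as missing in addition to empty cells
(the common SVI dialect uses -999); ``version`` is an opaque release tag
carried through for provenance.

Tract identifiers are always read as strings so GEOID leading zeros
survive.  Every table written by the pipeline gets a ``.schema.json``
sidecar declaring its column names and dtypes.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

from .interventions import KeywordRule
from .vulnerability import HARMONIZED_COLUMNS

DEFAULT_NA_SENTINELS = [-999, -999.0, "-999"]

#: Default column mappings for the three index dialects.
DEFAULT_INDEX_MAPPINGS = {
    "ces": {"tract_id_col": "tract_id", "score_col": None,
            "percentile_col": "ces_percentile", "scale": "percent",
            "na_sentinels": DEFAULT_NA_SENTINELS, "version": "3.0"},
    "hhai": {"tract_id_col": "tract_id", "score_col": "hhai_raw_score",
             "percentile_col": None, "scale": "percent",
             "na_sentinels": DEFAULT_NA_SENTINELS, "version": "unspecified"},
    "svi": {"tract_id_col": "tract_id", "score_col": None,
            "percentile_col": "svi_ranking", "scale": "unit",
            "na_sentinels": DEFAULT_NA_SENTINELS, "version": "unspecified"},
}

#: Default mapping for funded-project tables (the state list's column names).
DEFAULT_INTERVENTION_MAPPING = {
    "project_id_col": "project_id",
    "tract_id_col": "tract_id",
    "year_col": "year",
    "text_cols": {
        "project_description": "ProjectDescription",
        "dac_benefits_description": "DisadvantagedCommunityBenefitsDescription",
        "other_benefits_description": "OtherProjectBenefitsDescription",
    },
    "award_col": None,
}


def _apply_sentinels(series: pd.Series, sentinels) -> pd.Series:
    if sentinels:
        series = series.replace(list(sentinels), np.nan)
    return pd.to_numeric(series, errors="coerce")


def read_index_table(path, mapping: Mapping) -> pd.DataFrame:
    """Read one vulnerability-index CSV into canonical columns.

    Returns ``tract_id`` plus whichever of ``score`` and ``percentile`` the
    mapping declares; unit-scaled percentiles are rescaled to [0, 100].
    """
    df = pd.read_csv(path, dtype={mapping["tract_id_col"]: str})
    out = pd.DataFrame({"tract_id": df[mapping["tract_id_col"]].astype(str)})
    sentinels = mapping.get("na_sentinels", DEFAULT_NA_SENTINELS)
    if mapping.get("score_col"):
        out["score"] = _apply_sentinels(df[mapping["score_col"]], sentinels)
    if mapping.get("percentile_col"):
        pct = _apply_sentinels(df[mapping["percentile_col"]], sentinels)
        if mapping.get("scale", "percent") == "unit":
            pct = pct * 100.0
        out["percentile"] = pct
    if "score" not in out.columns and "percentile" not in out.columns:
        raise ValueError("mapping declares neither a score nor a percentile column")
    return out


def read_climate_csv(path) -> pd.DataFrame:
    """Read a long-format daily climate CSV and validate its invariants."""
    df = pd.read_csv(path, dtype={"tract_id": str}, parse_dates=["date"])
    missing = [c for c in ("tract_id", "model_id", "date", "tmax_c", "tmin_c", "rhmin_pct")
               if c not in df.columns]
    if missing:
        raise ValueError(f"climate CSV missing columns: {missing}")
    validate_climate(df)
    return df


def validate_climate(df: pd.DataFrame) -> None:
    rh = df["rhmin_pct"].to_numpy(float)
    ok = ~np.isnan(rh)
    if ((rh[ok] < 0) | (rh[ok] > 100)).any():
        raise ValueError("rhmin_pct outside [0, 100]")
    bad = (df["tmin_c"].to_numpy(float) > df["tmax_c"].to_numpy(float) + 1e-6)
    if bad.any():
        raise ValueError(f"{int(bad.sum())} rows with tmin > tmax")
    if df.duplicated(subset=["tract_id", "model_id", "date"]).any():
        raise ValueError("duplicate (tract, model, date) rows")


def read_interventions_csv(path, mapping: Mapping | None = None) -> pd.DataFrame:
    """Read a funded-project CSV into canonical intervention columns."""
    mapping = mapping or DEFAULT_INTERVENTION_MAPPING
    df = pd.read_csv(path, dtype={mapping["tract_id_col"]: str,
                                  mapping["project_id_col"]: str})
    out = pd.DataFrame({
        "project_id": df[mapping["project_id_col"]].astype(str),
        "tract_id": df[mapping["tract_id_col"]].astype(str),
        "year": pd.to_numeric(df[mapping["year_col"]], errors="coerce").astype("Int64"),
    })
    for canonical, source in mapping["text_cols"].items():
        if source in df.columns:
            out[canonical] = df[source].fillna("")
        else:
            logger.warning("read_interventions_csv: text column %r absent; "
                           "using empty strings", source)
            out[canonical] = ""
    if mapping.get("award_col") and mapping["award_col"] in df.columns:
        out["award_amount"] = pd.to_numeric(df[mapping["award_col"]], errors="coerce")
    return out


def load_keyword_rules(path) -> dict[str, KeywordRule]:
    """Load an iteration rule set from YAML: {category: {include: [...], exclude: [...]}}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    rules = {}
    for cat, spec in raw.items():
        rules[cat] = KeywordRule(category=cat,
                                 include=list(spec.get("include", [])),
                                 exclude=list(spec.get("exclude", [])))
    return rules


def write_keyword_rules(rules: Mapping[str, KeywordRule], path) -> None:
    payload = {cat: {"include": rule.include, "exclude": rule.exclude}
               for cat, rule in rules.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a CSV (UTF-8, RFC-4180 quoting) plus a .schema.json sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8")
    schema = {"columns": [{"name": c, "dtype": str(df[c].dtype)} for c in df.columns],
              "n_rows": int(len(df))}
    path.with_suffix(path.suffix + ".schema.json").write_text(
        json.dumps(schema, indent=2) + "\n")
    return path


def write_harmonized_tracts(table: pd.DataFrame, path) -> Path:
    """Write the harmonized tract table with its fixed column order."""
    cols = [c for c in HARMONIZED_COLUMNS if c in table.columns]
    return write_table(table[cols], path)
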