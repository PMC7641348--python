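"""Classification and allocation analysis of funded adaptation projects.

State climate-investment project lists record one row per project, year and
census tract, with free-text description columns.  The analysis here:

1. deduplicates rows into *tract interventions* — one record per unique
   (project id, tract) pair, with the earliest year and concatenated text;
2. screens interventions into heat-related categories (heat, outdoor
   workers, greening & surfaces, weatherization) via a two-iteration
   keyword procedure: an iteration-1 phrase-frequency table supports manual
   pruning, and the iteration-2 rule set assigns a category when at least
   one include phrase matches and no exclude phrase matches (case-
   insensitive substring over whitespace-normalized text; an intervention
   may fall in several categories);
3. computes allocation statistics: shares of interventions by compound
   vulnerability score, by index (including the CES-without-HHAI vs
   HHAI-without-CES disjoint-set ratio), and the pre/post comparison around
   the 2016 low-income investment mandate (AB 1550), with 2015–2016
   projects "pre" and 2017–2019 "post".

Award amounts are carried through but never aggregated.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The four heat-related project categories.
CATEGORIES = ("heat", "outdoor_workers", "greening_surfaces", "weatherization")

#: Free-text columns searched by the keyword screen (canonical names).
TEXT_COLUMNS = ["project_description", "dac_benefits_description", "other_benefits_description"]

PRE_YEARS = (2015, 2016)
POST_YEARS = (2017, 2018, 2019)

AB1550_GROUPS = ("disadvantaged", "low_income_not_ces", "neither")


@dataclass
class KeywordRule:
    """Inclusion/exclusion phrase lists for one category."""
    category: str
    include: list[str] = field(default_factory=list)
    exclude: list[str] = field(default_factory=list)


def normalize_text(text) -> str:
    """Lowercase and collapse all whitespace runs to single spaces."""
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return ""
    return " ".join(str(text).lower().split())


def _blobs(interventions: pd.DataFrame) -> pd.Series:
    cols = [c for c in TEXT_COLUMNS if c in interventions.columns]
    if not cols:
        raise ValueError(f"no text columns found; expected some of {TEXT_COLUMNS}")
    return interventions[cols].apply(
        lambda row: " \n ".join(normalize_text(v) for v in row), axis=1)


def _phrase_matches(blobs: pd.Series, phrase: str, word_boundary: bool) -> pd.Series:
    p = normalize_text(phrase)
    if word_boundary:
        return blobs.str.contains(r"\b" + re.escape(p) + r"\b", regex=True)
    return blobs.str.contains(p, regex=False)


def dedupe_tract_interventions(raw_rows: pd.DataFrame) -> pd.DataFrame:
    """Collapse raw project rows into unique (project_id, tract_id) records.

    Multi-year rows of the same project in the same tract become one
    intervention with the earliest year (used later for the pre/post AB 1550
    assignment) and de-duplicated concatenated text per column.  Rows missing
    either identifier are rejected with a logged count.
    """
    df = raw_rows.copy()
    ok = df["project_id"].notna() & df["tract_id"].notna()
    rejected = int((~ok).sum())
    if rejected:
        logger.info("dedupe_tract_interventions: rejected %d rows missing identifiers", rejected)
    df = df.loc[ok]
    if df.empty:
        cols = ["project_id", "tract_id", "year"] + [
            c for c in TEXT_COLUMNS if c in raw_rows.columns]
        return pd.DataFrame(columns=cols)

    def join_unique(values) -> str:
        seen, parts = set(), []
        for v in values:
            s = str(v).strip() if v is not None and not (isinstance(v, float) and np.isnan(v)) else ""
            if s and s not in seen:
                seen.add(s)
                parts.append(s)
        return "; ".join(parts)

    agg: dict = {"year": "min"}
    for col in TEXT_COLUMNS:
        if col in df.columns:
            agg[col] = join_unique
    if "award_amount" in df.columns:
        agg["award_amount"] = "first"
    extra = [c for c in df.columns
             if c not in agg and c not in ("project_id", "tract_id")]
    for col in extra:
        agg[col] = "first"
    out = (df.sort_values(["project_id", "tract_id", "year"])
             .groupby(["project_id", "tract_id"], sort=True, as_index=False)
             .agg(agg))
    return out


def phrase_frequency_table(interventions: pd.DataFrame,
                           phrases: Sequence[str],
                           word_boundary: bool = False) -> pd.DataFrame:
    """Iteration-1 report: interventions matched per phrase.

    A phrase counts once per intervention no matter how many times or in how
    many text fields it occurs; phrases with zero matches are the candidates
    for removal before iteration 2.
    """
    if not phrases:
        raise ValueError("phrase list is empty")
    blobs = _blobs(interventions) if len(interventions) else pd.Series(dtype=str)
    rows = []
    for phrase in phrases:
        n = int(_phrase_matches(blobs, phrase, word_boundary).sum()) if len(blobs) else 0
        rows.append((phrase, n))
    return pd.DataFrame(rows, columns=["phrase", "n_interventions"])


def keyword_screen(interventions: pd.DataFrame,
                   rules: Mapping[str, KeywordRule],
                   word_boundary: bool = False) -> pd.DataFrame:
    """Iteration-2 screen: assign heat-related categories to interventions.

    A category is assigned iff at least one of its include phrases matches
    any text field and none of its exclude phrases matches any text field.
    Multiple categories may apply to the same intervention.  Returns a copy
    of the input with one boolean ``category_<name>`` column per rule and a
    ``heat_related`` column (any category).
    """
    for cat, rule in rules.items():
        if not rule.include:
            raise ValueError(f"category {cat!r} has an empty include list")
    out = interventions.copy()
    if len(out) == 0:
        for cat in rules:
            out[f"category_{cat}"] = pd.Series(dtype=bool)
        out["heat_related"] = pd.Series(dtype=bool)
        return out
    blobs = _blobs(out)
    any_cat = np.zeros(len(out), dtype=bool)
    for cat, rule in rules.items():
        inc = np.zeros(len(out), dtype=bool)
        for phrase in rule.include:
            inc |= _phrase_matches(blobs, phrase, word_boundary).to_numpy()
        exc = np.zeros(len(out), dtype=bool)
        for phrase in rule.exclude:
            exc |= _phrase_matches(blobs, phrase, word_boundary).to_numpy()
        assigned = inc & ~exc
        out[f"category_{cat}"] = assigned
        any_cat |= assigned
    out["heat_related"] = any_cat
    return out


def category_columns(classified: pd.DataFrame) -> list[str]:
    return [c for c in classified.columns if c.startswith("category_")]


@dataclass
class ScoreAllocation:
    """Percent of interventions by compound vulnerability score, per category."""
    table: pd.DataFrame           # rows: categories + all_heat_related + all_interventions
    reference_pct_score_ge1: float  # percent of tracts statewide vulnerable under >=1 index


def allocation_by_compound_score(classified: pd.DataFrame,
                                 assessments: pd.DataFrame) -> ScoreAllocation:
    """Distribute interventions over compound vulnerability scores 0–3.

    Cross-category duplicates count once per category in the per-category
    rows and once in the overall rows.  Interventions whose tract has no
    assessment are excluded with a logged count.  The reference statistic is
    the percent of assessed tracts with compound score >= 1.
    """
    merged = classified.merge(assessments[["tract_id", "compound_score"]],
                              on="tract_id", how="left")
    unmatched = int(merged["compound_score"].isna().sum())
    if unmatched:
        logger.info("allocation_by_compound_score: %d interventions in unassessed tracts excluded",
                    unmatched)
    merged = merged.dropna(subset=["compound_score"])
    merged["compound_score"] = merged["compound_score"].astype(int)

    def pct_row(sub: pd.DataFrame) -> dict:
        n = len(sub)
        row = {"n": n}
        for s in range(4):
            row[f"pct_score_{s}"] = 100.0 * (sub["compound_score"] == s).sum() / n if n else np.nan
        row["pct_score_ge2"] = (row["pct_score_2"] + row["pct_score_3"]) if n else np.nan
        return row

    rows = {}
    for col in category_columns(merged):
        rows[col.removeprefix("category_")] = pct_row(merged.loc[merged[col]])
    if "heat_related" in merged.columns:
        rows["all_heat_related"] = pct_row(merged.loc[merged["heat_related"]])
    rows["all_interventions"] = pct_row(merged)
    table = pd.DataFrame(rows).T
    table["n"] = table["n"].astype(int)
    reference = float(100.0 * (assessments["compound_score"] >= 1).mean())
    return ScoreAllocation(table=table, reference_pct_score_ge1=reference)


@dataclass
class IndexAllocation:
    """Shares of interventions in vulnerable tracts per index, plus disjoint sets."""
    per_index: pd.DataFrame        # rows ces/hhai/svi: pct_in_vulnerable, n_in_vulnerable
    ces_not_hhai: int
    hhai_not_ces: int
    ratio: float                   # ces_not_hhai / hhai_not_ces; NaN when undefined
    all_three: int
    n_total: int


def allocation_by_index(classified: pd.DataFrame,
                        assessments: pd.DataFrame) -> IndexAllocation:
    """Per-index allocation over the supplied interventions.

    Reports, for each index, the percent of interventions landing in tracts
    vulnerable under it; the intervention counts in the disjoint sets
    CES-not-HHAI and HHAI-not-CES with their ratio (NaN when the denominator
    is zero); and the count in tracts vulnerable under all three indices.
    Pass a heat-related subset or the full table depending on the question.
    """
    flag_cols = ["vulnerable_ces", "vulnerable_hhai", "vulnerable_svi"]
    merged = classified.merge(assessments[["tract_id"] + flag_cols],
                              on="tract_id", how="left")
    unmatched = int(merged[flag_cols[0]].isna().sum())
    if unmatched:
        logger.info("allocation_by_index: %d interventions in unassessed tracts excluded",
                    unmatched)
    merged = merged.dropna(subset=flag_cols)
    n = len(merged)
    per_index = pd.DataFrame({
        index: {
            "pct_in_vulnerable": 100.0 * merged[f"vulnerable_{index}"].mean() if n else np.nan,
            "n_in_vulnerable": int(merged[f"vulnerable_{index}"].sum()),
        }
        for index in ("ces", "hhai", "svi")
    }).T
    ces = merged["vulnerable_ces"].to_numpy(bool)
    hhai = merged["vulnerable_hhai"].to_numpy(bool)
    svi = merged["vulnerable_svi"].to_numpy(bool)
    ces_not_hhai = int((ces & ~hhai).sum())
    hhai_not_ces = int((hhai & ~ces).sum())
    ratio = ces_not_hhai / hhai_not_ces if hhai_not_ces else float("nan")
    return IndexAllocation(per_index=per_index,
                           ces_not_hhai=ces_not_hhai,
                           hhai_not_ces=hhai_not_ces,
                           ratio=ratio,
                           all_three=int((ces & hhai & svi).sum()),
                           n_total=n)


def ab1550_comparison(classified: pd.DataFrame,
                      tract_flags: pd.DataFrame) -> pd.DataFrame:
    """Pre/post-2016 shift of intervention shares across equity groups.

    ``tract_flags`` needs ``tract_id``, ``vulnerable_ces`` and ``low_income``.
    Each intervention is assigned to exactly one group — ``disadvantaged``
    (CES-vulnerable, regardless of income), ``low_income_not_ces``, or
    ``neither`` — and to the pre (2015–2016) or post (2017–2019) era by its
    earliest project year; other years are excluded with a logged count.
    Returns per-group ``pre_pct``, ``post_pct`` (each column sums to 100 when
    its era is populated) and ``change_points = post_pct - pre_pct``.
    """
    merged = classified.merge(tract_flags[["tract_id", "vulnerable_ces", "low_income"]],
                              on="tract_id", how="left")
    unmatched = int(merged["vulnerable_ces"].isna().sum())
    if unmatched:
        logger.info("ab1550_comparison: %d interventions in unassessed tracts excluded", unmatched)
    merged = merged.dropna(subset=["vulnerable_ces", "low_income"])
    years = merged["year"].astype(int)
    in_range = years.isin(PRE_YEARS + POST_YEARS)
    out_of_range = int((~in_range).sum())
    if out_of_range:
        logger.info("ab1550_comparison: excluded %d interventions outside 2015-2019", out_of_range)
    merged = merged.loc[in_range.to_numpy()]
    ces = merged["vulnerable_ces"].to_numpy(bool)
    low = merged["low_income"].to_numpy(bool)
    group = np.where(ces, "disadvantaged",
                     np.where(low, "low_income_not_ces", "neither"))
    era = np.where(merged["year"].astype(int).isin(PRE_YEARS), "pre", "post")
    rows = {}
    for g in AB1550_GROUPS:
        row = {}
        for e in ("pre", "post"):
            in_era = era == e
            n_era = int(in_era.sum())
            row[f"{e}_pct"] = (100.0 * ((group == g) & in_era).sum() / n_era
                               if n_era else np.nan)
            row[f"n_{e}"] = int(((group == g) & in_era).sum())
        row["change_points"] = row["post_pct"] - row["pre_pct"]
        rows[g] = row
    out = pd.DataFrame(rows).T
    out[["n_pre", "n_post"]] = out[["n_pre", "n_post"]].astype(int)
    return out[["pre_pct", "post_pct", "change_points", "n_pre", "n_post"]]
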