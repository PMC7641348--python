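"""Synthetic tract, climate, and funded-project data generators.

The screening pipeline consumes three state datasets that are not shipped
with it: tract-level vulnerability-index tables, daily downscaled climate
series, and a funded-project list.  These generators emit tables with the
statistical structure the analysis assumes, so every stage is testable
end-to-end without downloads:

* **Tracts** — a latent vulnerability factor drives all three index scores;
  CES additionally loads on a pollution component, HHAI loads strongly and
  SVI only weakly on an urban-density covariate (mirroring how the real
  indices rank low-density tracts very differently); scores become
  percentile ranks; a small fraction of missing values exercises the
  completeness filter.
* **Climate** — per tract, model and day: Tmax = tract baseline + seasonal
  sinusoid + model offset + period warming + AR(1) noise; Tmin = Tmax minus
  a positive diurnal range; minimum RH anti-correlated with Tmax and clipped
  to [0, 100].  The projected-period warming can be amplified in
  high-vulnerability tracts (``exposure_coupling``) to plant a positive
  vulnerability–exposure trend.
* **Interventions** — projects sampled with probability increasing in CES
  percentile (``targeting_strength``), with text assembled from a planted
  category's vocabulary plus filler, years 2015–2019, and deliberate
  multi-year duplicate rows to exercise deduplication.

All three generators are fully deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .heat_exposure import (CURRENT_PERIOD, DEFAULT_MODELS, HISTORICAL_PERIOD,
                            PROJECTED_PERIOD)
from .interventions import CATEGORIES, KeywordRule
from .vulnerability import to_percentile_ranks

#: Nine climate regions with sampling weights roughly proportional to the
#: real tract shares (the populous south and the Bay Area dominate).
DEFAULT_REGIONS: dict[str, float] = {
    "North Coast": 0.03,
    "Sierra Nevada": 0.02,
    "Sacramento Valley": 0.08,
    "Bay Area": 0.19,
    "San Joaquin Valley": 0.11,
    "Central Coast": 0.05,
    "Los Angeles": 0.37,
    "Inland Desert": 0.06,
    "San Diego": 0.09,
}

#: Disjoint per-category vocabularies: planted text is exactly recoverable
#: by a substring screen built from the same phrases.
DEFAULT_CATEGORY_VOCAB: dict[str, list[str]] = {
    "heat": ["cooling center", "extreme heat preparedness",
             "air conditioning upgrade", "heat illness prevention"],
    "outdoor_workers": ["farmworker shade structure", "outdoor crew hydration",
                        "agricultural worker safety training"],
    "greening_surfaces": ["urban tree canopy", "neighborhood park greening",
                          "reflective pavement installation"],
    "weatherization": ["attic insulation", "low income home weatherization",
                       "energy efficient envelope retrofit"],
}

#: Exclusion phrases for every category's iteration-2 rules.
DEFAULT_EXCLUDE_PHRASES = ["manure management", "fire prevention grant"]

#: Neutral filler never matched by the default rules.
SAFE_FILLER_PHRASES = [
    "transit bus replacement", "affordable housing construction",
    "watershed restoration planning", "zero emission vehicle rebate",
    "recycling infrastructure expansion", "community outreach workshops",
    "bicycle lane improvements", "solar panel installation",
]

#: Filler that contains exclusion-worthy program names (only drawn for
#: unplanted projects, sometimes alongside an include phrase, to exercise
#: the exclusion path).
TRAP_FILLER_PHRASES = [
    "dairy digester manure management program",
    "forest fire prevention grant program",
]


@dataclass
class SyntheticConfig:
    """Scenario parameters; defaults describe the statewide study conditions."""

    n_tracts: int = 8000
    regions: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_REGIONS))
    seed: int = 0

    # tract-index structure
    index_correlation: Mapping[str, float] = field(
        default_factory=lambda: {"ces": 0.75, "hhai": 0.75, "svi": 0.75})
    density_loadings: Mapping[str, float] = field(
        default_factory=lambda: {"ces": 0.25, "hhai": 0.6, "svi": 0.1})
    pollution_loading_ces: float = 0.45
    urban_fraction: float = 0.9
    na_fraction: float = 0.02

    # climate structure (°C)
    models: tuple[str, ...] = DEFAULT_MODELS
    model_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"HadGEM2-ES": 0.6, "CNRM-CM5": -0.3,
                                 "CanESM2": 0.3, "MIROC5": -0.6})
    scenario: str = "RCP4.5"
    historical: tuple[int, int] = HISTORICAL_PERIOD
    current: tuple[int, int] = CURRENT_PERIOD
    projected: tuple[int, int] = PROJECTED_PERIOD
    baseline_tmax_mean: float = 25.0      # seasonal mid-level of daily Tmax; the
    baseline_tmax_sd: float = 4.0         # sinusoid adds +/-seasonal_amplitude
    seasonal_amplitude: float = 10.0      # half-range of the seasonal cycle
    warming_delta_current: float = 0.8    # shift of the current period vs historical
    warming_delta_projected: float = 2.0  # shift of the projected period vs historical
    exposure_coupling: float = 0.5        # extra projected warming per unit latent percentile
    ar1_coefficient: float = 0.7
    daily_noise_sd: float = 3.0
    diurnal_range_mean: float = 14.0
    diurnal_range_sd: float = 2.0
    rh_base_mean: float = 30.0            # daily-minimum RH in a dry-summer climate
    rh_base_sd: float = 8.0
    rh_temp_slope: float = 1.5            # % RH lost per °C of daily Tmax anomaly
    rh_noise_sd: float = 8.0

    # interventions
    n_projects: int = 2000
    targeting_strength: float = 2.0
    heat_related_fraction: float = 0.6
    multiyear_fraction: float = 0.2
    multitract_fraction: float = 0.1
    trap_fraction: float = 0.1            # share of unplanted projects drawing trap filler
    category_vocab: Mapping[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_CATEGORY_VOCAB.items()})

    def validate(self) -> None:
        if self.n_tracts < 1:
            raise ValueError("n_tracts must be >= 1")
        for name, value in self.index_correlation.items():
            if not 0 <= value <= 1:
                raise ValueError(f"index_correlation[{name!r}] must lie in [0, 1]")
        if not 0 <= self.urban_fraction <= 1:
            raise ValueError("urban_fraction must lie in [0, 1]")
        if not 0 <= self.na_fraction < 1:
            raise ValueError("na_fraction must lie in [0, 1)")
        if not 0 <= self.ar1_coefficient < 1:
            raise ValueError("ar1_coefficient must lie in [0, 1)")
        if self.targeting_strength < 0:
            raise ValueError("targeting_strength must be >= 0")
        if abs(sum(self.regions.values()) - 1.0) > 1e-9:
            raise ValueError("region weights must sum to 1")


def default_keyword_rules(config: SyntheticConfig | None = None) -> dict[str, KeywordRule]:
    """Iteration-2 rule set matching the generator's planted vocabularies."""
    vocab = (config.category_vocab if config is not None else DEFAULT_CATEGORY_VOCAB)
    return {cat: KeywordRule(category=cat,
                             include=list(phrases),
                             exclude=list(DEFAULT_EXCLUDE_PHRASES))
            for cat, phrases in vocab.items()}


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent stream per generator so calling one never perturbs another
    return np.random.default_rng([config.seed, stream])


def generate_tracts(config: SyntheticConfig) -> pd.DataFrame:
    """Draw a correlated tract-level vulnerability table.

    Each index score is ``loading * latent + sqrt(1 - loading^2) * rest``
    where *rest* mixes index-specific noise with the density covariate (and,
    for CES, the pollution component), normalized to unit variance.  At a
    loading of 1 every auxiliary term vanishes and the three percentiles
    coincide exactly.
    """
    config.validate()
    rng = _rng(config, 1)
    n = config.n_tracts
    latent = rng.normal(size=n)
    pollution = rng.normal(size=n)
    urban = rng.random(n) < config.urban_fraction
    log_density = np.where(urban, rng.normal(7.3, 0.9, n), rng.normal(2.5, 1.1, n))
    dens_z = (log_density - log_density.mean()) / max(log_density.std(), 1e-12)

    scores = {}
    for index in ("ces", "hhai", "svi"):
        loading = float(config.index_correlation[index])
        w_dens = float(config.density_loadings[index])
        w_pol = config.pollution_loading_ces if index == "ces" else 0.0
        eps = rng.normal(size=n)
        w_eps = 1.0
        norm = np.sqrt(w_dens ** 2 + w_pol ** 2 + w_eps ** 2)
        rest = (w_dens * dens_z + w_pol * pollution + w_eps * eps) / norm
        scores[index] = loading * latent + np.sqrt(max(0.0, 1.0 - loading ** 2)) * rest

    tract_ids = np.array([f"06{i:09d}" for i in range(1, n + 1)])
    region_labels = np.array(list(config.regions))
    region_probs = np.array(list(config.regions.values()), dtype=float)
    regions = rng.choice(region_labels, size=n, p=region_probs)
    low_income = rng.random(n) < 1.0 / (1.0 + np.exp(-(1.2 * latent + 0.2)))

    table = pd.DataFrame({
        "tract_id": tract_ids,
        "region": regions,
        "population_density": np.exp(log_density),
        "low_income": low_income,
        "latent_percentile": to_percentile_ranks(latent),
        "ces_percentile": to_percentile_ranks(scores["ces"]),
        "hhai_raw_score": scores["hhai"],
        "hhai_percentile": to_percentile_ranks(scores["hhai"]),
        "svi_percentile": to_percentile_ranks(scores["svi"]),
        "pollution_burden_percentile": to_percentile_ranks(0.8 * pollution + 0.2 * latent),
    })
    if config.na_fraction > 0:
        for col in ("ces_percentile", "hhai_percentile", "svi_percentile"):
            mask = rng.random(n) < config.na_fraction
            table.loc[mask, col] = np.nan
            if col == "hhai_percentile":
                table.loc[mask, "hhai_raw_score"] = np.nan
    return table


def _season_dates(years: np.ndarray) -> pd.DatetimeIndex:
    parts = [pd.date_range(f"{y}-04-01", f"{y}-10-31", freq="D") for y in years]
    return parts[0].append(parts[1:]) if len(parts) > 1 else parts[0]


def generate_climate(config: SyntheticConfig,
                     tracts: pd.DataFrame,
                     periods: tuple[str, ...] = ("historical", "current", "projected"),
                     ) -> pd.DataFrame:
    """Daily seasonal Tmax/Tmin/RHmin series for the given tracts.

    Emits only in-season days (Apr 1 – Oct 31) of the requested periods for
    every tract × model combination, in the long format the exposure reader
    consumes.  Projected-period warming per tract is
    ``warming_delta_projected * (1 + exposure_coupling * (latent_pct/100 - 0.5))``
    so high-vulnerability tracts warm faster when the coupling is positive.
    """
    config.validate()
    rng = _rng(config, 2)
    period_bounds = {"historical": config.historical,
                     "current": config.current,
                     "projected": config.projected}
    years = np.concatenate([np.arange(period_bounds[p][0], period_bounds[p][1] + 1)
                            for p in periods])
    dates = _season_dates(years)
    n_days = len(dates)
    doy = dates.dayofyear.to_numpy()
    year_of_day = dates.year.to_numpy()
    seasonal = config.seasonal_amplitude * np.cos(2 * np.pi * (doy - 201) / 365.25)

    warm_by_year = np.zeros(n_days)
    cur, proj = config.current, config.projected
    in_current = (year_of_day >= cur[0]) & (year_of_day <= cur[1])
    in_projected = (year_of_day >= proj[0]) & (year_of_day <= proj[1])
    warm_by_year[in_current] = config.warming_delta_current

    n_tracts = len(tracts)
    base = rng.normal(config.baseline_tmax_mean, config.baseline_tmax_sd, n_tracts)
    diurnal = np.maximum(rng.normal(config.diurnal_range_mean, config.diurnal_range_sd,
                                    n_tracts), 2.0)
    rh_base = np.clip(rng.normal(config.rh_base_mean, config.rh_base_sd, n_tracts), 5, 95)
    if "latent_percentile" in tracts.columns:
        latent_pct = tracts["latent_percentile"].to_numpy(float)
    else:  # externally supplied tracts: couple on the CES percentile instead
        latent_pct = tracts["ces_percentile"].fillna(50.0).to_numpy(float)
    proj_warm = config.warming_delta_projected * (
        1.0 + config.exposure_coupling * (latent_pct / 100.0 - 0.5))

    phi = config.ar1_coefficient
    innov_sd = config.daily_noise_sd * np.sqrt(1.0 - phi ** 2)
    frames = []
    tract_ids = tracts["tract_id"].to_numpy()
    for i, tract in enumerate(tract_ids):
        warm = warm_by_year.copy()
        warm[in_projected] = proj_warm[i]
        mean_tmax = base[i] + seasonal + warm
        for model in config.models:
            noise = lfilter([1.0], [1.0, -phi], rng.normal(0.0, innov_sd, n_days))
            tmax = mean_tmax + config.model_offsets.get(model, 0.0) + noise
            rng_range = np.maximum(diurnal[i] + rng.normal(0.0, 1.5, n_days), 0.5)
            tmin = tmax - rng_range
            rh = np.clip(rh_base[i] - config.rh_temp_slope * (tmax - base[i])
                         + rng.normal(0.0, config.rh_noise_sd, n_days), 0.0, 100.0)
            frames.append(pd.DataFrame({
                "tract_id": pd.Categorical([tract] * n_days, categories=tract_ids),
                "model_id": pd.Categorical([model] * n_days, categories=config.models),
                "scenario": pd.Categorical([config.scenario] * n_days),
                "date": dates,
                "tmax_c": tmax.astype(np.float32),
                "tmin_c": tmin.astype(np.float32),
                "rhmin_pct": rh.astype(np.float32),
            }))
    return pd.concat(frames, ignore_index=True)


def generate_interventions(config: SyntheticConfig,
                           tracts: pd.DataFrame) -> pd.DataFrame:
    """Raw funded-project rows with planted heat-related categories.

    Projects land in tracts with probability proportional to
    ``exp(targeting_strength * ces_percentile / 100)``; a fraction carry a
    planted category whose vocabulary phrase is embedded in one of the three
    text columns (recorded in ``planted_category`` for ground truth, which
    downstream readers ignore).  Some projects emit duplicate rows in a
    second year or a second tract to exercise deduplication.
    """
    config.validate()
    rng = _rng(config, 3)
    tract_ids = tracts["tract_id"].to_numpy()
    ces = tracts["ces_percentile"].fillna(50.0).to_numpy(float)
    weights = np.exp(config.targeting_strength * ces / 100.0)
    weights /= weights.sum()

    cats = list(config.category_vocab)
    rows = []
    for k in range(config.n_projects):
        project_id = f"P{k + 1:05d}"
        tract = rng.choice(tract_ids, p=weights)
        year = int(rng.integers(2015, 2020))
        planted = (str(rng.choice(cats)) if rng.random() < config.heat_related_fraction
                   else "")
        texts = ["", "", ""]
        if planted:
            phrase = str(rng.choice(config.category_vocab[planted]))
            texts[int(rng.integers(0, 3))] = phrase
            fillers = rng.choice(SAFE_FILLER_PHRASES, size=2, replace=False)
        else:
            pool = SAFE_FILLER_PHRASES
            if rng.random() < config.trap_fraction:
                # an include phrase plus an excluded program name: the screen
                # must reject it, matching the empty planted label
                cat = str(rng.choice(cats))
                texts[0] = str(rng.choice(config.category_vocab[cat]))
                texts[1] = str(rng.choice(TRAP_FILLER_PHRASES))
            fillers = rng.choice(pool, size=2, replace=False)
        for f in fillers:
            slot = int(rng.integers(0, 3))
            texts[slot] = (texts[slot] + "; " + str(f)).strip("; ")
        record = {
            "project_id": project_id,
            "tract_id": tract,
            "year": year,
            "project_description": texts[0],
            "dac_benefits_description": texts[1],
            "other_benefits_description": texts[2],
            "award_amount": float(np.round(rng.lognormal(11.5, 1.2), 2)),
            "planted_category": planted,
        }
        rows.append(record)
        if year < 2019 and rng.random() < config.multiyear_fraction:
            dup = dict(record)
            dup["year"] = year + 1
            rows.append(dup)
        if rng.random() < config.multitract_fraction:
            other = dict(record)
            other["tract_id"] = str(rng.choice(tract_ids, p=weights))
            if other["tract_id"] != record["tract_id"]:
                rows.append(other)
    return pd.DataFrame(rows)
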