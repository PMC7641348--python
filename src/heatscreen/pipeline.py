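"""End-to-end orchestration of the screening pipeline.

Stages run in order — vulnerability, exposure, overlay, interventions —
each consuming either real input files named in the configuration or the
synthetic generators.  Per-stage CSV outputs (with schema sidecars), a
machine-readable ``summary.json``, the resolved configuration, and a run
log with package versions and a config hash are written to the output
directory.  Reruns with the same inputs and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__, heat_exposure, io, risk_overlay, synthetic_data, vulnerability
from . import interventions as iv
from .config import PipelineConfig, save_config

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """In-memory handles to every stage output plus the summary dict."""
    tracts: pd.DataFrame | None = None
    assessments: pd.DataFrame | None = None
    exposure: heat_exposure.ExposureResult | None = None
    overlay_bins: pd.DataFrame | None = None
    classified: pd.DataFrame | None = None
    summary: dict[str, Any] = field(default_factory=dict)
    outdir: Path | None = None


def _load_tracts(config: PipelineConfig) -> pd.DataFrame:
    if config.ces_path or config.hhai_path or config.svi_path:
        if not (config.ces_path and config.hhai_path and config.svi_path):
            raise ValueError("provide all three index files or none")
        ces = io.read_index_table(config.ces_path, io.DEFAULT_INDEX_MAPPINGS["ces"])
        hhai = io.read_index_table(config.hhai_path, io.DEFAULT_INDEX_MAPPINGS["hhai"])
        svi = io.read_index_table(config.svi_path, io.DEFAULT_INDEX_MAPPINGS["svi"])
        table = ces.rename(columns={"percentile": "ces_percentile"})
        # raw HHAI scores are converted to percentile ranks over complete rows
        hhai = hhai.rename(columns={"score": "hhai_raw_score"})
        ok = hhai["hhai_raw_score"].notna()
        hhai.loc[ok, "hhai_percentile"] = vulnerability.to_percentile_ranks(
            hhai.loc[ok, "hhai_raw_score"].to_numpy())
        table = table.merge(hhai[["tract_id", "hhai_raw_score", "hhai_percentile"]],
                            on="tract_id", how="outer")
        table = table.merge(svi.rename(columns={"percentile": "svi_percentile"})
                            [["tract_id", "svi_percentile"]], on="tract_id", how="outer")
        return table
    return synthetic_data.generate_tracts(config.synthetic)


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Execute the configured stages; optionally write all outputs to disk."""
    config.validate()
    result = PipelineResult()
    outdir = Path(config.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        result.outdir = outdir
    summary: dict[str, Any] = {"package_version": __version__, "seed": config.seed}

    tracts = _load_tracts(config)
    stage = "vulnerability"
    try:
        filtered = vulnerability.filter_complete_tracts(tracts)
        assessments = vulnerability.assess_vulnerability(
            filtered, threshold=config.vulnerability_threshold)
        result.tracts = filtered
        result.assessments = assessments
        if stage in config.stages:
            venn = vulnerability.agreement_partition(assessments)
            regions = pd.Series(filtered["region"].to_numpy(),
                                index=filtered["tract_id"].to_numpy())
            regional = vulnerability.regional_summary(assessments, regions)
            summary["n_tracts_input"] = int(len(tracts))
            summary["n_tracts_complete"] = int(len(filtered))
            summary["venn_cells"] = venn
            summary["pct_vulnerable_any_index"] = float(
                100.0 * (assessments["compound_score"] >= 1).mean())
            summary["pct_vulnerable_all_three"] = float(
                100.0 * (assessments["compound_score"] == 3).mean())
            if write:
                harmonized = filtered.merge(assessments, on="tract_id")
                io.write_harmonized_tracts(harmonized, outdir / "tracts_harmonized.csv")
                io.write_table(regional.reset_index(names="region"),
                               outdir / "regional_summary.csv")
    except Exception as err:
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    exposure = None
    if "exposure" in config.stages:
        stage = "exposure"
        try:
            if config.climate_path:
                climate = io.read_climate_csv(config.climate_path)
            else:
                n_sub = min(config.n_climate_tracts, len(filtered))
                # deterministic, evenly spread subsample of the filtered tracts
                pick = np.linspace(0, len(filtered) - 1, n_sub).round().astype(int)
                climate = synthetic_data.generate_climate(
                    config.synthetic, filtered.iloc[pick])
            exposure = heat_exposure.compute_exposure(
                climate,
                periods={"current": config.current, "projected": config.projected},
                historical=config.historical,
                season_start=config.season_start, season_end=config.season_end,
                q=config.heatwave_quantile, hi_threshold_f=config.hi_threshold_f,
                min_duration=config.min_duration)
            result.exposure = exposure
            medians = (exposure.summary.groupby("metric")[["projected_rate", "delta"]]
                       .median())
            summary["exposure_n_tracts"] = int(exposure.summary["tract_id"].nunique())
            summary["median_projected_rate"] = {
                m: float(v) for m, v in medians["projected_rate"].items()}
            summary["mean_delta"] = {
                m: float(v) for m, v in
                exposure.summary.groupby("metric")["delta"].mean().items()}
            if write:
                io.write_table(exposure.summary, outdir / "exposure_summary.csv")
                io.write_table(exposure.thresholds.reset_index(),
                               outdir / "heat_thresholds.csv")
        except Exception as err:
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    if "overlay" in config.stages and exposure is not None:
        stage = "overlay"
        try:
            metric = exposure.summary.loc[
                exposure.summary["metric"] == config.overlay_metric]
            merged = metric.merge(filtered[["tract_id", "ces_percentile",
                                            "hhai_percentile", "svi_percentile"]],
                                  on="tract_id")
            bins = []
            for index in ("ces", "hhai", "svi"):
                bins.append(risk_overlay.bin_by_vulnerability(
                    merged[f"{index}_percentile"], merged["delta"],
                    bin_width=config.bin_width, index_name=index))
            result.overlay_bins = pd.concat(bins, ignore_index=True)
            if write:
                io.write_table(result.overlay_bins, outdir / "overlay_bins.csv")
        except Exception as err:
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    if "interventions" in config.stages:
        stage = "interventions"
        try:
            if config.projects_path:
                raw = io.read_interventions_csv(config.projects_path)
            else:
                raw = synthetic_data.generate_interventions(config.synthetic, filtered)
            rules = (io.load_keyword_rules(config.rules_path) if config.rules_path
                     else synthetic_data.default_keyword_rules(config.synthetic))
            deduped = iv.dedupe_tract_interventions(raw)
            classified = iv.keyword_screen(deduped, rules)
            result.classified = classified
            heat_sub = classified.loc[classified["heat_related"]]
            alloc = iv.allocation_by_compound_score(classified, assessments)
            by_index = iv.allocation_by_index(heat_sub, assessments)
            flags = filtered[["tract_id", "low_income"]].merge(
                assessments[["tract_id", "vulnerable_ces"]], on="tract_id")
            ab1550 = iv.ab1550_comparison(heat_sub, flags)
            summary["n_tract_interventions"] = int(len(classified))
            summary["n_heat_related"] = int(len(heat_sub))
            summary["pct_heat_interventions_score_ge2"] = float(
                alloc.table.loc["all_heat_related", "pct_score_ge2"])
            summary["reference_pct_tracts_score_ge1"] = alloc.reference_pct_score_ge1
            summary["ces_not_hhai_over_hhai_not_ces"] = (
                None if np.isnan(by_index.ratio) else float(by_index.ratio))
            summary["ab1550_change_points"] = {
                g: float(ab1550.loc[g, "change_points"]) for g in ab1550.index}
            if write:
                io.write_table(classified, outdir / "interventions_classified.csv")
                io.write_table(alloc.table.reset_index(names="category"),
                               outdir / "allocation_by_score.csv")
                io.write_table(ab1550.reset_index(names="group"),
                               outdir / "ab1550_comparison.csv")
        except Exception as err:
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    result.summary = summary
    if write:
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                        sort_keys=True) + "\n")
        save_config(config, outdir / "config_resolved.yaml")
        cfg_hash = hashlib.sha256(
            (outdir / "config_resolved.yaml").read_bytes()).hexdigest()
        (outdir / "run_log.txt").write_text(
            f"heatscreen {__version__}\nnumpy {np.__version__}\n"
            f"pandas {pd.__version__}\nseed {config.seed}\n"
            f"config_sha256 {cfg_hash}\nstages {','.join(config.stages)}\n")
    return result
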