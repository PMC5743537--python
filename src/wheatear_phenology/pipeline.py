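"""End-to-end pipeline: thermal → spring indicator → matching → selection → GLMMs.

Also hosts the model-frame builders that translate the breeding-record
table into the design used by the mixed models: the *trend* frame (focal
predictor = year) and the *matching* frame (focal = annual median thermal
sum at hatching, with the individual thermal sum replacing lay date).
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

import wheatear_phenology
from wheatear_phenology import io as wio
from wheatear_phenology import matching, mixed, selection, spring
from wheatear_phenology.selection import RATES
from wheatear_phenology.thermal import ClimateSeries

__all__ = ["build_model_frame", "model_spec_for_rate", "run_pipeline", "PipelineResult"]

log = logging.getLogger("wheatear")

GLMM_RESPONSE = {
    "nest_success": "nest_success",
    "fledglings": "n_fledglings",
    "recruits": "n_recruits",
    "female_survival": "female_survival",
    "male_survival": "male_survival",
    "nestling_weight": "weight",
}


def build_model_frame(
    records: pd.DataFrame,
    series: ClimateSeries,
    rate: str,
    focal: str = "year",
    nestling_weights: pd.DataFrame | None = None,
    t_base: float = 3.0,
) -> pd.DataFrame:
    """Model frame for one rate's GLMM.

    ``focal="year"`` builds the temporal-trend frame (year, lay date,
    female age, rain, density and field layer as fixed effects).
    ``focal="median_ts"`` builds the matching frame: the annual median of
    individual thermal sums at hatching is the focal predictor and the
    individual thermal sum replaces lay date.  Survival models additionally
    carry nest success; the nestling-weight model adds nestling age and
    brood size and is at the nestling level.

    Continuous covariates are centered so the intercept sits at sample
    means; year is counted from the first study year.
    """
    grp = selection._fitness_subset(records).copy()
    if len(grp) == 0:
        raise ValueError("no usable records after the first-attempt/failed-before-hatching filter")
    age_col = "male_age" if rate == "male_survival" else "female_age"
    indiv_col = "male" if rate == "male_survival" else "female"

    grp["year_c"] = grp["year"] - grp["year"].min()
    grp["lay_doy"] = grp["lay_date"].map(lambda d: pd.Timestamp(d).dayofyear).astype(float)
    grp["lay_doy"] -= grp["lay_doy"].mean()
    density = grp.groupby("year")["nest_id"].transform("count").astype(float)
    grp["density"] = density - density.mean()
    grp["flh_tall"] = (grp["field_layer"] == "tall").astype(float)
    grp["age_young"] = (grp[age_col] == "young").astype(float)
    grp["rain_c"] = grp["rain_days"] - grp["rain_days"].mean()

    if focal == "median_ts":
        ts_hatch = matching.individual_thermal_sum(grp, series, t_base, at="hatch")
        grp["indiv_ts"] = ts_hatch - ts_hatch.mean()
        median_ts = ts_hatch.groupby(grp["year"]).transform(matching.lower_median)
        grp["median_ts"] = median_ts - median_ts.mean()
    elif focal != "year":
        raise ValueError(f"focal must be 'year' or 'median_ts', got {focal!r}")

    if rate == "nestling_weight":
        if nestling_weights is None:
            raise ValueError("nestling_weight GLMM needs the nestling-weight table")
        cols = ["nest_id", "year", "territory", "year_c", "lay_doy", "density", "flh_tall", "age_young", "rain_c", indiv_col]
        if focal == "median_ts":
            cols += ["indiv_ts", "median_ts"]
        frame = nestling_weights.merge(grp[cols + ["n_fledglings"]], on="nest_id", how="inner").copy()
        frame["nestling_age"] = frame["nestling_age"].astype(float) - frame["nestling_age"].mean()
        frame["brood_size"] = frame["n_fledglings"].astype(float) - frame["n_fledglings"].mean()
    else:
        frame = grp.copy()
        frame["nest_success_cov"] = frame["nest_success"].astype(float)
    frame = frame.rename(columns={indiv_col: "individual"})
    frame["year"] = frame["year"].astype(str)
    return frame


def model_spec_for_rate(rate: str, focal: str = "year") -> mixed.ModelSpec:
    """Table-2-shaped (focal year) or Table-4-shaped (focal median_ts) spec."""
    family = selection.FAMILIES[rate]
    focal_term = "year_c" if focal == "year" else "median_ts"
    date_term = "lay_doy" if focal == "year" else "indiv_ts"
    fixed = [focal_term, date_term, "age_young", "rain_c", "density", "flh_tall"]
    if rate == "nestling_weight":
        fixed = [focal_term, "nestling_age", "brood_size", date_term, "flh_tall", "age_young", "rain_c", "density"]
    elif rate in ("female_survival", "male_survival"):
        fixed = [focal_term, "nest_success_cov", date_term, "flh_tall", "age_young", "rain_c", "density"]
    return mixed.ModelSpec(
        response=GLMM_RESPONSE[rate],
        family=family,
        fixed=tuple(fixed),
        random=("year", "territory", "individual"),
        focal=focal_term,
    )


@dataclass
class PipelineResult:
    """Everything the pipeline produced, stage by stage."""

    indicator: spring.SpringIndicator = None
    annual: pd.DataFrame = None
    matching_correlation: matching.CorrelationResult = None
    estimates: pd.DataFrame = None
    trend_table: pd.DataFrame = None
    matching_trend_table: pd.DataFrame = None
    glmm_fits: dict = field(default_factory=dict)
    failed_stage: str | None = None
    error: str | None = None


def _estimates_frame(all_estimates: list[selection.SelectionEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "year": [e.year for e in all_estimates],
            "rate": [e.rate for e in all_estimates],
            "covariate_set": [e.covariate_set for e in all_estimates],
            "slope": [e.slope for e in all_estimates],
            "slope_se": [e.slope_se for e in all_estimates],
            "intercept": [e.intercept for e in all_estimates],
            "n": [e.n for e in all_estimates],
            "flag": [e.flag for e in all_estimates],
        }
    )


def _trend_frame(fits: dict[str, selection.TrendFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rate": list(fits),
            "estimate": [f.estimate for f in fits.values()],
            "se": [f.se for f in fits.values()],
            "t": [f.t for f in fits.values()],
            "p": [f.p for f in fits.values()],
            "r2": [f.r2 for f in fits.values()],
            "n_years": [f.n_years for f in fits.values()],
        }
    )


def run_pipeline(config: wio.PipelineConfig, glmm_rates: tuple[str, ...] = RATES) -> PipelineResult:
    """Execute every stage in order, writing report tables under ``out_dir``.

    On a stage failure the partial outputs written so far are retained and
    the failing stage is named in the result.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed, chash = config.seed, wio.config_hash(config)
    result = PipelineResult()
    stage = "read_inputs"
    try:
        series = wio.read_climate_csv(config.climate_csv)
        records, _report = wio.read_breeding_csv(config.breeding_csv)
        nestw = wio.read_nestling_csv(config.nestling_csv) if config.nestling_csv else None

        stage = "spring_progression"
        firsts = records[records["first_attempt"] == 1]
        median_lay = {int(y): matching.lower_median_date(g["lay_date"]) for y, g in firsts.groupby("year")}
        latest_lay = {int(y): max(g["lay_date"]) for y, g in firsts.groupby("year")}
        indicator = spring.derive_spring_indicator(
            series, median_lay, latest_lay, config.t_base_grid, config.threshold_step
        )
        result.indicator = indicator
        wio.write_table(indicator.grid, out / "spring_grid.csv", seed, chash)
        log.info(
            "stage=spring_progression winner_t_base=%s winner_threshold=%s r2=%.3f",
            indicator.t_base, indicator.threshold, indicator.best.r2,
        )

        stage = "matching"
        t_base = config.matching_t_base if config.matching_t_base is not None else indicator.t_base
        annual = matching.annual_matching(records, series, indicator, t_base)
        result.annual = annual
        result.matching_correlation = matching.correlate_matching_measures(annual)
        wio.write_table(annual, out / "annual_summary.csv", seed, chash)

        stage = "selection_patterns"
        all_estimates: list[selection.SelectionEstimate] = []
        trend_fits: dict[str, selection.TrendFit] = {}
        match_fits: dict[str, selection.TrendFit] = {}
        median_ts = dict(zip(annual["year"], annual["match_median_ts_hatch"]))
        for rate in RATES:
            for covset in ("none", "standard"):
                ests = selection.fit_all_years(records, rate, covset, nestw)
                all_estimates.extend(ests)
                if covset == "none":
                    trend_fits[rate] = selection.weighted_trend(ests, "year", weight_rule=config.weight_rule)
                    match_fits[rate] = selection.weighted_trend(
                        ests, "median_ts", median_ts, weight_rule=config.weight_rule
                    )
        result.estimates = _estimates_frame(all_estimates)
        result.trend_table = _trend_frame(trend_fits)
        result.matching_trend_table = _trend_frame(match_fits)
        wio.write_table(result.estimates, out / "selection_estimates.csv", seed, chash)
        t1 = result.trend_table.copy()
        if config.weight_rule != "inv_se":
            t1["weight_rule_deviation"] = config.weight_rule
        wio.write_table(t1, out / "slope_year_trends.csv", seed, chash)
        wio.write_table(result.matching_trend_table, out / "slope_matching_trends.csv", seed, chash)

        stage = "mixed_models"
        glmm_report = []
        for rate in glmm_rates:
            for focal in ("year", "median_ts"):
                frame = build_model_frame(records, series, rate, focal, nestw, t_base)
                spec = model_spec_for_rate(rate, focal)
                fit = mixed.fit_glmm(frame, spec)
                result.glmm_fits[(rate, focal)] = fit
                coef = fit.coefficients.reset_index()
                coef.insert(0, "rate", rate)
                coef.insert(1, "focal", focal)
                glmm_report.append(coef)
                log.info(
                    "stage=mixed_models rate=%s focal=%s n=%d loglik=%.2f r2m=%.3f r2c=%.3f",
                    rate, focal, fit.n, fit.loglik, fit.r2_marginal, fit.r2_conditional,
                )
        if glmm_report:
            wio.write_table(pd.concat(glmm_report, ignore_index=True), out / "glmm_coefficients.csv", seed, chash)

        stage = "manifest"
        manifest = {
            "package_version": wheatear_phenology.__version__,
            "python": platform.python_version(),
            "seed": seed,
            "config_hash": chash,
            "config": config.to_dict(),
            "winner": {"t_base": indicator.t_base, "threshold": indicator.threshold, "r2": indicator.best.r2},
            "matching_correlation_r": result.matching_correlation.r,
        }
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:  # noqa: BLE001 - surface the failing stage, keep partials
        result.failed_stage = stage
        result.error = f"{type(exc).__name__}: {exc}"
        log.error("stage=%s failed: %s", stage, result.error)
    return result
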