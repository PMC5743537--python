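"""Within-season selection for breeding time and its between-year trends.

Per year and demographic rate: a GLM slope of the rate on relative lay
date (negative = early breeders do better).  Annual slopes are then
regressed on year and on the annual median thermal sum at hatching with
1/SE weights, and the slope–intercept correlation is computed — the
signature of early-breeder deterioration is a strongly negative r.
"""

import argparse
from pathlib import Path

import pandas as pd

from wheatear_phenology import io as wio, matching, selection, spring


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results")
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    data = Path(args.data)
    series = wio.read_climate_csv(data / "climate.csv")
    records, _ = wio.read_breeding_csv(data / "breeding.csv")
    nestw = wio.read_nestling_csv(data / "nestling_weights.csv")
    firsts = records[records["first_attempt"] == 1]
    median_lay = {int(y): matching.lower_median_date(g["lay_date"]) for y, g in firsts.groupby("year")}
    latest_lay = {int(y): max(g["lay_date"]) for y, g in firsts.groupby("year")}
    indicator = spring.derive_spring_indicator(series, median_lay, latest_lay)
    annual = matching.annual_matching(records, series, indicator)
    median_ts = dict(zip(annual["year"], annual["match_median_ts_hatch"]))

    cfg = wio.PipelineConfig(seed=args.seed)
    chash = wio.config_hash(cfg)
    rows_est, rows_trend = [], []
    print(f"{'rate':16s} {'year trend':>12s} {'p':>7s}   {'matching trend':>14s} {'p':>7s}   {'r(int,slope)':>12s}")
    for rate in selection.RATES:
        ests = selection.fit_all_years(records, rate, "none", nestw)
        for e in ests:
            rows_est.append(vars(e).copy())
        yr = selection.weighted_trend(ests, "year")
        ts = selection.weighted_trend(ests, "median_ts", median_ts)
        corr = selection.slope_intercept_correlation(ests)
        rows_trend.append(
            {"rate": rate, "year_estimate": yr.estimate, "year_se": yr.se, "year_p": yr.p, "year_r2": yr.r2,
             "ts_estimate": ts.estimate, "ts_se": ts.se, "ts_p": ts.p, "slope_intercept_r": corr.r}
        )
        print(
            f"{rate:16s} {yr.estimate:+12.5f} {yr.p:7.3f}   {ts.estimate:+14.6f} {ts.p:7.3f}   {corr.r:12.2f}"
        )
    wio.write_table(pd.DataFrame(rows_est), Path(args.out) / "selection_estimates.csv", args.seed, chash)
    wio.write_table(pd.DataFrame(rows_trend), Path(args.out) / "selection_trends.csv", args.seed, chash)


if __name__ == "__main__":
    main()
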