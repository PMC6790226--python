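#!/usr/bin/env python
"""Statistical linkage between stocks and fluxes across the chronosequence.

Per-transect contrasts of the standardised indices by one-way ANOVA with
Tukey grouping letters, then multiple linear regression of each flux index
on the stock variables: VIF collinearity screen, backward deletion under
AIC, and LMG relative-importance shares of the explained variance.
Writes results/anova_letters.csv and results/regression_models.csv.
"""
import argparse
from pathlib import Path

import pandas as pd

from chamberflux.io import read_table, write_table
from chamberflux.stats import backward_aic, lmg_shares, one_way_anova, vif
from chamberflux.stocks import plot_stocks
from chamberflux.config import ChamberGeometry

PREDICTORS = ["ag_biomass", "ag_c", "ag_n", "bg_biomass", "bg_c", "bg_n",
              "soil_c", "soil_n", "tair"]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    ix = read_table(args.out / "indices.csv")
    lrt = read_table(args.out / "light_response.csv")
    # R10 comes from one temperature fit per transect, so it has no
    # within-transect replication; per-plot daytime respiration (rd)
    # carries the respiration contrast instead
    ix = ix.merge(lrt[["plot_id", "campaign", "rd", "tair"]],
                  on=["plot_id", "campaign"])
    cores = read_table(args.data / "soil_cores.csv")
    ag = read_table(args.data / "aboveground.csv")
    area = ChamberGeometry().collar_area

    # per-transect ANOVA with letters on each index
    anova_rows = []
    for col in ("nee2000", "gee2000", "rd", "alpha_qy"):
        groups = {t: g[col].to_numpy() for t, g in ix.groupby("transect_id")}
        res = one_way_anova(groups)
        for tid, letters in sorted(res.group_letters.items()):
            anova_rows.append({"index": col, "transect_id": tid,
                               "mean": float(ix[ix["transect_id"] == tid][col].mean()),
                               "letters": letters, "f": res.f_stat,
                               "p": res.p_value})
        print(f"  {col}: F={res.f_stat:.1f}, p={res.p_value:.2g}, "
              f"letters {res.group_letters}")
    write_table(pd.DataFrame(anova_rows), args.out / "anova_letters.csv")

    # merged per-plot table: stocks + flux indices
    per_plot = (plot_stocks(cores, area)
                .groupby(["transect_id", "plot_id"])
                [["soil_c", "soil_n", "bg_biomass", "bg_c", "bg_n"]]
                .sum().reset_index())
    ag = ag.assign(ag_biomass=ag["dry_mass"] / ag["collar_area"],
                   ag_c=ag["dry_mass"] * ag["c_frac"] / ag["collar_area"],
                   ag_n=ag["dry_mass"] * ag["n_frac"] / ag["collar_area"])
    merged = (ix.merge(per_plot, on=["transect_id", "plot_id"])
              .merge(ag[["plot_id", "ag_biomass", "ag_c", "ag_n"]],
                     on="plot_id"))

    model_rows = []
    for resp in ("rd", "gee2000", "nee2000"):
        fit = backward_aic(merged[resp], merged[PREDICTORS], resp)
        shares = lmg_shares(merged[resp], merged[list(fit.predictors)])
        vifs = vif(merged[PREDICTORS])
        print(f"  {resp}: {100 * fit.multiple_r2:.2f}% variance explained "
              f"by {list(fit.predictors)}")
        for p in fit.predictors:
            model_rows.append({
                "response": resp, "predictor": p,
                "coefficient": fit.coefficients[p], "vif": vifs[p],
                "lmg_share": shares.shares[p],
                "multiple_r2": fit.multiple_r2, "aic": fit.aic,
                "residual_se": fit.residual_se, "n": fit.n})
    write_table(pd.DataFrame(model_rows), args.out / "regression_models.csv")


if __name__ == "__main__":
    main()
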