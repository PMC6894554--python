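"""Fit the hierarchical RSPF with density interactions and diagnose it.

The model regresses used/unused on the habitat covariates, regional wolf
density and covariate-by-density interactions, with iid year intercepts and
per-pack random coefficients.  Outputs: a posterior-summary table (mean,
s.e., percentiles, mode, mean/s.e.), diagnostics (Pearson r, AUC, WAIC,
mean log CPO), density-response curves for the interacting covariates, and
the pack-size vs selection-strength post-hoc comparison.
"""

import argparse
import pathlib

import numpy as np
import pandas as pd

from denshab.rspf import (ModelSpec, density_response_curves, diagnostics,
                          fit_rspf, pack_heterogeneity_test)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=pathlib.Path, default=pathlib.Path("results"))
    args = ap.parse_args()
    table = pd.read_csv(args.out / "sample_table.csv")

    covariates = ["prey", "cover", "human", "noise1", "noise2"]
    spec = ModelSpec(fixed=covariates, interactions=["prey", "human"])
    fit = fit_rspf(table, spec)
    summary = fit.summary().sort_values("mean/s.e.", key=np.abs, ascending=False)
    summary.to_csv(args.out / "rspf_summary.csv")
    print(summary.round(3).to_string())

    rep = diagnostics(fit, table, seed=args.seed)
    pd.DataFrame([{"pearson_r": rep.pearson_r, "auc": rep.auc,
                   "waic": rep.waic, "p_waic": rep.p_waic,
                   "mean_log_cpo": rep.mean_log_cpo}]).to_csv(
        args.out / "rspf_diagnostics.csv", index=False)
    print(f"\ndiagnostics: r={rep.pearson_r:.3f} AUC={rep.auc:.3f} "
          f"WAIC={rep.waic:.0f}")

    no_int = fit_rspf(table, ModelSpec(fixed=covariates, interactions=[]))
    rep0 = diagnostics(no_int, table, seed=args.seed)
    print(f"without density interactions: AUC={rep0.auc:.3f} WAIC={rep0.waic:.0f} "
          f"(dWAIC={rep0.waic - rep.waic:+.0f})")

    curves = []
    for cov in spec.interactions:
        c = density_response_curves(fit, cov, density_grid=[-1.5, 0.0, 1.5])
        c["covariate"] = cov
        curves.append(c)
    pd.concat(curves).to_csv(args.out / "density_response_curves.csv", index=False)

    sizes = table[table["y"] == 1].groupby("pack_id").size()  # rows ~ area
    try:
        mean_sizes = pd.read_csv(args.out / "pack_year_matrix_filled.csv",
                                 index_col=0).replace(0, np.nan).mean(axis=1)
        comp = pack_heterogeneity_test(fit, mean_sizes.dropna(), "prey")
        # the generator assigns pack sizes independently of habitat, so a
        # non-significant difference here is the expected (true-null) outcome
        print(f"\npack sizes, strong vs weak prey response: "
              f"{comp.strong_mean_size:.2f} vs {comp.weak_mean_size:.2f} wolves "
              f"(rank-sum p={comp.rank_sum_pvalue:.3f})")
    except ValueError as err:
        print(f"pack-heterogeneity comparison skipped: {err}")


if __name__ == "__main__":
    main()
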