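"""Draw the used/unused point design for the RSPF.

Used points: one per 50 km² inside each pack-year territory.  Unused
points: one per 1000 km² of the 165-km availability disc (0.95 dispersal
quantile), spatially balanced with inclusion weight 1 − P(occupied), with a
fraction equal to the year's measured territory overlap allowed inside
other occupied territories.  Covariates and regional density are attached
standardized.
"""

import argparse
import pathlib

from denshab.density import DensityRaster, DispersalKernel
from denshab.grids import read_ascii_grid
from denshab.occupancy import OccupancyRaster
from denshab.records import territories_from_geojson
from denshab.sampling import design_table
from denshab.synthetic_world import CovariateStack


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=pathlib.Path, default=pathlib.Path("results"))
    args = ap.parse_args()
    world = args.out / "world"

    layers = {}
    grid = None
    for path in sorted(world.glob("covariate_*.asc")):
        grid, vals = read_ascii_grid(path)
        layers[path.stem.removeprefix("covariate_")] = vals
    stack = CovariateStack(grid=grid, layers=layers)

    records = territories_from_geojson(args.out / "territories.geojson")
    by_year = {}
    for rec in records:
        by_year.setdefault(rec.year, []).append(rec)
    density_by_year = {}
    for path in sorted((args.out / "density").glob("density_*.asc")):
        year = int(path.stem.split("_")[1])
        g, vals = read_ascii_grid(path)
        density_by_year[year] = DensityRaster(g, year, vals)
    occupancy_by_year = {}
    for path in sorted((args.out / "occupancy").glob("occupancy_*.asc")):
        year = int(path.stem.split("_")[1])
        g, vals = read_ascii_grid(path)
        occupancy_by_year[year] = OccupancyRaster(g, year, vals, n_sim=100)

    table, cov_scaler, dens_scaler = design_table(
        by_year, stack, density_by_year, occupancy_by_year,
        kernel=DispersalKernel(), seed=args.seed)
    table.to_csv(args.out / "sample_table.csv", index=False)
    cov_scaler.to_json(args.out / "covariate_scaler.json")
    dens_scaler.to_json(args.out / "density_scaler.json")

    n_used = int(table["y"].sum())
    print(f"sample table: {len(table)} rows, {n_used} used / "
          f"{len(table) - n_used} unused across {table['year'].nunique()} years")
    print(f"availability radius {DispersalKernel().q95_km:.1f} km; "
          f"mean used points per pack-year "
          f"{n_used / table.groupby(['pack_id', 'year']).ngroups:.1f}")


if __name__ == "__main__":
    main()
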