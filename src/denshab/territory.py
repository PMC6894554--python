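"""Territory estimation from telemetry and track locations.

Annual territory boundaries follow a cascade: a yearly fixed-kernel
utilization distribution (UD) when >= 30 fixes exist in the year, a 3-year
moving-window UD when >= 30 fixes exist over (t-1, t, t+1), and otherwise a
long-term estimate — (A) carry forward the most recent kernel estimate,
(B) a pooled telemetry+track kernel estimate, or (C) a minimum convex
polygon of track locations.  The territory boundary is the 95% volume
isopleth of the UD.  Kernel bandwidths use a two-stage direct plug-in
selector (diagonal bandwidth matrix) with a normal-reference fallback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from shapely.geometry import MultiPoint, Polygon

from .grids import GridSpec
from .records import TerritoryRecord

MIN_LOCATIONS = 30  # usability threshold for a kernel estimate


class TooFewPointsError(ValueError):
    pass


class DegenerateBandwidthError(ValueError):
    """All locations coincident or collinear: no 2-D bandwidth exists."""


class DegeneratePolygonError(ValueError):
    pass


@dataclass
class UtilizationDistribution:
    """Gridded probability mass of space use; cell masses sum to one."""

    grid: GridSpec
    density: np.ndarray  # probability mass per cell
    bandwidth: np.ndarray  # 2x2 (km^2 entries on the diagonal are h_x^2, h_y^2)

    def __post_init__(self) -> None:
        total = self.density.sum()
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"UD mass {total} != 1")


# ---------------------------------------------------------------------------
# outlier screening


def remove_outliers(locs: pd.DataFrame, k: float = 6.0,
                    max_fraction: float = 0.05) -> pd.DataFrame:
    """Drop locations far from the pack's median centre.

    A point is an outlier when its distance from the coordinate-wise median
    centre exceeds median(distance) + k * MAD(distance).  With the default
    k=6 this is conservative; at most ``max_fraction`` of points (the worst
    offenders) are ever removed.  Order-preserving.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if len(locs) < 3:
        raise TooFewPointsError("need at least 3 locations")
    x = locs["x_km"].to_numpy(float)
    y = locs["y_km"].to_numpy(float)
    d = np.hypot(x - np.median(x), y - np.median(y))
    mad = np.median(np.abs(d - np.median(d)))
    cutoff = np.median(d) + k * mad
    out = d > cutoff
    max_remove = int(math.floor(max_fraction * len(locs)))
    if out.sum() > max_remove:
        keep_rank = np.argsort(d)[::-1][:max_remove]
        out = np.zeros(len(locs), dtype=bool)
        out[keep_rank] = True
    return locs.loc[~out]


# ---------------------------------------------------------------------------
# bandwidth selection


def _phi4(x):
    return (x ** 4 - 6 * x ** 2 + 3) * np.exp(-0.5 * x ** 2) / math.sqrt(2 * math.pi)


def _phi6(x):
    return (x ** 6 - 15 * x ** 4 + 45 * x ** 2 - 15) * np.exp(-0.5 * x ** 2) / math.sqrt(2 * math.pi)


def _psi_hat(x: np.ndarray, g: float, deriv) -> float:
    diff = (x[:, None] - x[None, :]) / g
    n = x.size
    return float(deriv(diff).sum() / (n ** 2 * g ** (7 if deriv is _phi6 else 5)))


def _dpik(x: np.ndarray) -> float:
    """Two-stage direct plug-in bandwidth for a univariate Gaussian KDE."""
    n = x.size
    sigma = min(x.std(ddof=1), (np.percentile(x, 75) - np.percentile(x, 25)) / 1.349)
    if sigma <= 0:
        sigma = x.std(ddof=1)
    if sigma <= 0:
        raise DegenerateBandwidthError("zero spread")
    psi8 = 105.0 / (32.0 * math.sqrt(math.pi) * sigma ** 9)
    g1 = (2.0 * (15.0 / math.sqrt(2 * math.pi)) / (psi8 * n)) ** (1.0 / 9.0)
    psi6 = _psi_hat(x, g1, _phi6)
    g2 = (2.0 * (3.0 / math.sqrt(2 * math.pi)) / (-psi6 * n)) ** (1.0 / 7.0)
    psi4 = _psi_hat(x, g2, _phi4)
    if psi4 <= 0:
        raise DegenerateBandwidthError("plug-in functional non-positive")
    return (1.0 / (2.0 * math.sqrt(math.pi) * psi4 * n)) ** 0.2


def select_bandwidth(x: np.ndarray, y: np.ndarray,
                     method: str = "plug_in") -> tuple[float, float]:
    """Per-axis kernel sds (km) for a diagonal bivariate bandwidth matrix.

    ``normal_reference`` is the bivariate Gaussian reference rule
    h_j = sigma_j * n^(-1/6); ``plug_in`` is the two-stage direct plug-in
    applied per axis, falling back to the reference rule if it degenerates.
    """
    n = x.size
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx <= 0 or sy <= 0:
        raise DegenerateBandwidthError("locations are collinear or coincident")
    if method == "normal_reference":
        f = n ** (-1.0 / 6.0)
        return sx * f, sy * f
    if method == "plug_in":
        sub = slice(None)
        if n > 4000:  # pairwise plug-in functionals are O(n^2)
            sub = np.linspace(0, n - 1, 4000).astype(int)
        try:
            return _dpik(x[sub]), _dpik(y[sub])
        except DegenerateBandwidthError:
            f = n ** (-1.0 / 6.0)
            return sx * f, sy * f
    raise ValueError(f"unknown bandwidth method {method!r}")


# ---------------------------------------------------------------------------
# kernel UD and isopleths


def fit_kernel_ud(locs: pd.DataFrame, grid: GridSpec | None = None,
                  bandwidth_method: str = "plug_in",
                  cell_size: float = 0.5, min_locs: int = MIN_LOCATIONS) -> UtilizationDistribution:
    """Bivariate Gaussian-kernel UD on a grid (binned, FFT-convolved).

    When no grid is supplied one is built around the points with a margin of
    3 bandwidth sds.  Cell masses are renormalized to sum to one (edge
    truncation is negligible given the margin but not exactly zero).
    """
    if len(locs) < min_locs:
        raise TooFewPointsError(f"need >= {min_locs} locations, got {len(locs)}")
    x = locs["x_km"].to_numpy(float)
    y = locs["y_km"].to_numpy(float)
    hx, hy = select_bandwidth(x, y, bandwidth_method)
    if grid is None:
        margin = 3.0 * max(hx, hy) + cell_size
        x0 = math.floor((x.min() - margin) / cell_size) * cell_size
        y0 = math.floor((y.min() - margin) / cell_size) * cell_size
        n_cols = int(math.ceil((x.max() + margin - x0) / cell_size))
        n_rows = int(math.ceil((y.max() + margin - y0) / cell_size))
        grid = GridSpec(x0, y0, cell_size, n_rows, n_cols)
    h = grid.cell_size
    counts = np.zeros(grid.shape)
    row, col = grid.index_of(x, y)
    np.add.at(counts, (row, col), 1.0)
    # Gaussian kernel sampled at cell-centre offsets, truncated at 4 sd
    kx = int(math.ceil(4 * hx / h))
    ky = int(math.ceil(4 * hy / h))
    gx = np.exp(-0.5 * (np.arange(-kx, kx + 1) * h / hx) ** 2)
    gy = np.exp(-0.5 * (np.arange(-ky, ky + 1) * h / hy) ** 2)
    kernel = np.outer(gy, gx)
    density = fftconvolve(counts, kernel, mode="same")
    density = np.clip(density, 0.0, None)
    density /= density.sum()
    bw = np.diag([hx ** 2, hy ** 2])
    return UtilizationDistribution(grid=grid, density=density, bandwidth=bw)


def extract_isopleth(ud: UtilizationDistribution, level: float = 0.95):
    """Smallest union of cells holding >= ``level`` of the UD mass, polygonized."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    flat = ud.density.ravel()
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order])
    n_keep = int(np.searchsorted(csum, level) + 1)
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:n_keep]] = True
    return ud.grid.cells_to_polygon(mask.reshape(ud.grid.shape))


def isopleth_mass(ud: UtilizationDistribution, polygon) -> float:
    mask = ud.grid.rasterize(polygon)
    return float(ud.density[mask].sum())


def minimum_convex_polygon(locs: pd.DataFrame) -> Polygon:
    """Convex hull of all locations (the track-only fallback estimator)."""
    if len(locs) < 3:
        raise TooFewPointsError("need at least 3 locations")
    pts = MultiPoint(list(zip(locs["x_km"], locs["y_km"])))
    hull = pts.convex_hull
    if not isinstance(hull, Polygon) or hull.area == 0:
        raise DegeneratePolygonError("locations are collinear")
    return hull


# ---------------------------------------------------------------------------
# the estimation cascade


def _kde_isopleth(locs, bandwidth_method, cell_size, level, outlier_k):
    # the >=30 usability threshold applies to available locations; outlier
    # screening may drop a few below it without invalidating the estimate
    if len(locs) >= 3 and outlier_k is not None:
        locs = remove_outliers(locs, k=outlier_k)
    ud = fit_kernel_ud(locs, bandwidth_method=bandwidth_method, cell_size=cell_size,
                       min_locs=10)
    return extract_isopleth(ud, level), len(locs)


def estimate_territories(all_locs: pd.DataFrame, track_locs: pd.DataFrame,
                         pack_years: pd.DataFrame, min_locs: int = MIN_LOCATIONS,
                         bandwidth_method: str = "plug_in", cell_size: float = 0.5,
                         level: float = 0.95, outlier_k: float = 6.0,
                         ) -> tuple[list[TerritoryRecord], list[tuple]]:
    """Apply the A/B/C cascade to every pack-year known present.

    ``pack_years`` is the (possibly gap-filled) pack-by-year matrix; a
    pack-year is "present" when its cell holds a size >= 2.  Returns the
    estimated records plus a list of (pack_id, year) that no method could
    resolve.
    """
    records: list[TerritoryRecord] = []
    unresolved: list[tuple] = []
    tel_by_pack = {pid: df for pid, df in all_locs.groupby("pack_id")} if len(all_locs) else {}
    trk_by_pack = {pid: df for pid, df in track_locs.groupby("pack_id")} if len(track_locs) else {}

    for pack_id in pack_years.index:
        tel = tel_by_pack.get(pack_id)
        trk = trk_by_pack.get(pack_id)
        last_kde: Polygon | None = None
        pooled_cache: tuple[Polygon, int] | None = None
        for year in pack_years.columns:
            size = pack_years.loc[pack_id, year]
            if pd.isna(size) or size < 2:
                continue
            poly = None
            tag = None
            n_used = 0
            yearly = tel[tel["year"] == year] if tel is not None else None
            if yearly is not None and len(yearly) >= min_locs:
                poly, n_used = _kde_isopleth(yearly, bandwidth_method, cell_size, level, outlier_k)
                tag = "A-yearly"
            else:
                window = (tel[tel["year"].between(year - 1, year + 1)]
                          if tel is not None else None)
                if window is not None and len(window) >= min_locs:
                    poly, n_used = _kde_isopleth(window, bandwidth_method, cell_size, level, outlier_k)
                    tag = "A-window"
                elif last_kde is not None:
                    poly, tag, n_used = last_kde, "A", 0
                else:
                    pooled = pd.concat([df for df in (tel, trk) if df is not None]) \
                        if (tel is not None or trk is not None) else None
                    if pooled is not None and len(pooled) >= min_locs:
                        if pooled_cache is None:
                            pooled_cache = _kde_isopleth(
                                pooled, bandwidth_method, cell_size, level, outlier_k)
                        poly, n_used = pooled_cache
                        tag = "B"
                    elif trk is not None and len(trk) >= 3:
                        try:
                            poly = minimum_convex_polygon(trk)
                            tag, n_used = "C", len(trk)
                        except DegeneratePolygonError:
                            poly = None
            if poly is None:
                unresolved.append((pack_id, year))
                continue
            if tag in ("A-yearly", "A-window"):
                last_kde = poly
            records.append(TerritoryRecord(
                pack_id=pack_id, year=int(year), polygon=poly,
                method_tag=tag, n_locations_used=int(n_used),
                size=float(size),
            ))
    return records, unresolved


def method_log(records: list[TerritoryRecord]) -> pd.DataFrame:
    """Per-pack-year log of method and data volume (External-interface CSV)."""
    return pd.DataFrame(
        [(r.pack_id, r.year, r.method_tag, r.n_locations_used, r.area_km2)
         for r in records],
        columns=["pack_id", "year", "method", "n_locations", "area_km2"],
    )
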