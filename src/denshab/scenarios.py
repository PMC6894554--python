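"""Theory simulations of used/available habitat distributions under rising occupancy.

Habitat use is a weighted distribution: f_u(X) ∝ w(X) f_a(X), so the
selection ratio f_u(X)/f_a(X) tracks the RSF w(X) — and its apparent change
over time depends entirely on how the used and available distributions
converge or diverge as territories fill the landscape.  Four qualitative
scenarios are simulated as 1-D Gaussian families whose means and sds follow
linear paths in occupancy:

* ``limited_important`` — a scarce, preferred habitat: occupancy strips the
  good end out of availability faster than out of use, so the ratio at high
  covariate values *grows*.
* ``abundant_important`` — preferred but plentiful: use converges toward
  availability and the ratio flattens toward 1.
* ``limited_substitutable`` — scarce but replaceable: use degrades toward
  the available distribution faster than availability changes; selection
  weakens.
* ``abundant_substitutable`` — plentiful and replaceable: both
  distributions barely move; the ratio stays ~constant.

The empirical counterpart summarizes used and available covariate means (and
their ratio) per year, ordered by regional wolf density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .covariates import ScalerRecord

RATIO_FLOOR = 1e-8


@dataclass
class ParamPath:
    """Linear path of a Gaussian's (mean, sd) as occupancy runs 0 → 1."""

    mean0: float
    mean1: float
    sd0: float
    sd1: float

    def at(self, occ: float) -> tuple[float, float]:
        mean = self.mean0 + (self.mean1 - self.mean0) * occ
        sd = self.sd0 + (self.sd1 - self.sd0) * occ
        if sd <= 0:
            raise ValueError("degenerate sd on the parameter path")
        return mean, sd


@dataclass
class ScenarioConfig:
    scenario: str
    occupancy_levels: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    used: ParamPath = None
    available: ParamPath = None

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy_levels, float)
        if not (np.all(np.diff(occ) > 0) and occ.min() >= 0 and occ.max() <= 1):
            raise ValueError("occupancy levels must be strictly increasing in [0, 1]")
        if self.used is None or self.available is None:
            defaults = DEFAULT_SCENARIOS[self.scenario]
            self.used = self.used or defaults["used"]
            self.available = self.available or defaults["available"]


DEFAULT_SCENARIOS: dict[str, dict[str, ParamPath]] = {
    # used stays on quality habitat while availability collapses downward
    "limited_important": {
        "used": ParamPath(mean0=1.5, mean1=0.9, sd0=1.0, sd1=0.9),
        "available": ParamPath(mean0=0.0, mean1=-1.2, sd0=1.0, sd1=0.8),
    },
    # plenty of quality habitat: use converges to availability
    "abundant_important": {
        "used": ParamPath(mean0=1.5, mean1=0.4, sd0=1.0, sd1=1.0),
        "available": ParamPath(mean0=0.0, mean1=0.0, sd0=1.0, sd1=1.0),
    },
    # scarce but substitutable: use degrades faster than availability
    "limited_substitutable": {
        "used": ParamPath(mean0=1.2, mean1=-0.2, sd0=1.0, sd1=1.1),
        "available": ParamPath(mean0=0.0, mean1=-0.4, sd0=1.0, sd1=1.0),
    },
    # plentiful substitute: neither distribution moves much
    "abundant_substitutable": {
        "used": ParamPath(mean0=0.5, mean1=0.4, sd0=1.0, sd1=1.0),
        "available": ParamPath(mean0=0.0, mean1=0.0, sd0=1.0, sd1=1.0),
    },
}


@dataclass
class SelectionRatioCurve:
    grid: np.ndarray
    f_u: dict[float, np.ndarray] = field(default_factory=dict)
    f_a: dict[float, np.ndarray] = field(default_factory=dict)
    ratio: dict[float, np.ndarray] = field(default_factory=dict)
    valid: dict[float, np.ndarray] = field(default_factory=dict)  # f_a above floor

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for occ in self.ratio:
            frames.append(pd.DataFrame({
                "occupancy": occ, "x": self.grid,
                "f_u": self.f_u[occ], "f_a": self.f_a[occ],
                "ratio": self.ratio[occ], "valid": self.valid[occ],
            }))
        return pd.concat(frames, ignore_index=True)


def simulate_scenario(config: ScenarioConfig, n_draws: int = 20_000,
                      seed: int = 0) -> SelectionRatioCurve:
    """Draw used/available samples per occupancy level and form ratio curves.

    Both densities are kernel-estimated on a shared grid; the pointwise
    ratio is reported only where the available density exceeds a small
    floor (division blow-ups at the tails are flagged invalid).
    """
    if n_draws < 1000:
        raise ValueError("need at least 1000 draws per level")
    rng = np.random.default_rng(seed)
    # shared evaluation grid spanning every level's 4-sd envelope
    lo, hi = np.inf, -np.inf
    for occ in config.occupancy_levels:
        for path in (config.used, config.available):
            m, s = path.at(occ)
            lo, hi = min(lo, m - 4 * s), max(hi, m + 4 * s)
    grid = np.linspace(lo, hi, 512)
    curve = SelectionRatioCurve(grid=grid)
    for occ in config.occupancy_levels:
        mu_u, sd_u = config.used.at(occ)
        mu_a, sd_a = config.available.at(occ)
        draws_u = rng.normal(mu_u, sd_u, n_draws)
        draws_a = rng.normal(mu_a, sd_a, n_draws)
        f_u = gaussian_kde(draws_u)(grid)
        f_a = gaussian_kde(draws_a)(grid)
        valid = f_a > RATIO_FLOOR
        ratio = np.where(valid, f_u / np.clip(f_a, RATIO_FLOOR, None), np.nan)
        curve.f_u[occ] = f_u
        curve.f_a[occ] = f_a
        curve.ratio[occ] = ratio
        curve.valid[occ] = valid
    return curve


def empirical_selection_ratio(tables: dict[int, pd.DataFrame], covariate: str,
                              density_by_year: dict[int, float],
                              scaler: ScalerRecord | None = None) -> pd.DataFrame:
    """Used mean, available mean and their ratio per year, ordered by density.

    ``tables`` holds each year's design rows (column ``y`` and the
    covariate, standardized); with a scaler the means are reported in
    original units.  Years whose available mean is zero get a NaN ratio and
    a flag.
    """
    rows = []
    for year, tab in tables.items():
        if tab["y"].min() == tab["y"].max():
            raise ValueError(f"year {year}: need both used and unused rows")
        vals = tab[covariate].to_numpy(float)
        if scaler is not None:
            vals = scaler.inverse(covariate, vals)
        used_mean = float(vals[tab["y"] == 1].mean())
        avail_mean = float(vals[tab["y"] == 0].mean())
        flagged = avail_mean == 0.0
        rows.append({
            "year": year, "wolf_density": density_by_year[year],
            "used_mean": used_mean, "available_mean": avail_mean,
            "ratio": np.nan if flagged else used_mean / avail_mean,
            "ratio_undefined": flagged,
        })
    return pd.DataFrame(rows).sort_values("wolf_density").reset_index(drop=True)
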