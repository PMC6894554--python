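"""Covariate engineering: circular focal means, distance decay, standardization.

These transforms are shared by synthetic and real inputs.  The focal mean
implements the circular "assessment window" used to put every landscape
metric on a common scale of analysis; the default window area of 50.75 km²
is one quarter of a mean wolf home range.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve


class DegenerateCovariateError(ValueError):
    """A covariate with zero variance cannot be standardized."""


class InvalidParameterError(ValueError):
    pass


def disc_kernel(radius_km: float, cell_size: float) -> np.ndarray:
    """Binary disc: 1 for kernel cells whose centre is within ``radius_km``."""
    r_cells = int(math.floor(radius_km / cell_size))
    idx = np.arange(-r_cells, r_cells + 1)
    dx, dy = np.meshgrid(idx, idx)
    return ((dx ** 2 + dy ** 2) * cell_size ** 2 <= radius_km ** 2).astype(float)


def circular_mean_filter(values: np.ndarray, radius_km: float, cell_size: float) -> np.ndarray:
    """Mean over a circular moving window; edge cells use the truncated window.

    Implemented as two FFT convolutions (value sum and cell count) so edge
    windows are averaged over the cells actually inside the grid.
    """
    values = np.asarray(values, dtype=float)
    kernel = disc_kernel(radius_km, cell_size)
    if kernel.sum() <= 1:
        warnings.warn("window radius smaller than one cell; focal mean is a no-op")
        return values.copy()
    num = fftconvolve(values, kernel, mode="same")
    den = fftconvolve(np.ones_like(values), kernel, mode="same")
    return num / den


def focal_mean(values: np.ndarray, cell_size: float, window_area_km2: float = 50.75) -> np.ndarray:
    """Circular focal mean with window of the given *area* (radius = sqrt(area/pi))."""
    if window_area_km2 <= 0:
        raise InvalidParameterError("window area must be positive")
    radius = window_radius_km(window_area_km2)
    return circular_mean_filter(values, radius, cell_size)


def window_radius_km(window_area_km2: float = 50.75) -> float:
    """Radius of the circular assessment window, km (default sqrt(50.75/pi) ≈ 4.019)."""
    return math.sqrt(window_area_km2 / math.pi)


def distance_decay(distance, alpha_km: float):
    """Exponential distance decay exp(-d/alpha).

    ``alpha`` is conventionally set to the mean distance observed at used
    locations (see :func:`alpha_from_used_distances`), so the decayed value at
    a typical used location is e^-1.
    """
    if alpha_km <= 0:
        raise InvalidParameterError("alpha must be positive")
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise InvalidParameterError("distances must be nonnegative")
    return np.exp(-d / alpha_km)


def alpha_from_used_distances(distances) -> float:
    """Decay scale: the mean distance over all used locations (pooled across years)."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise InvalidParameterError("no used distances supplied")
    return float(d.mean())


@dataclass
class ScalerRecord:
    """Per-covariate mean/sd (original units) used for standardization.

    Uses the population standard deviation (ddof=0); recorded here so fitted
    coefficients can be mapped back to original units.
    """

    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    sd_convention: str = "population"

    def transform(self, name: str, x):
        return (np.asarray(x, dtype=float) - self.means[name]) / self.sds[name]

    def inverse(self, name: str, z):
        return np.asarray(z, dtype=float) * self.sds[name] + self.means[name]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"means": self.means, "sds": self.sds, "sd_convention": self.sd_convention},
                fh, indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "ScalerRecord":
        with open(path) as fh:
            d = json.load(fh)
        return cls(means=d["means"], sds=d["sds"], sd_convention=d.get("sd_convention", "population"))


def fit_scaler(layers: dict[str, np.ndarray], mask: np.ndarray | None = None) -> ScalerRecord:
    """Compute a ScalerRecord from named arrays (optionally over a basis mask).

    Constant layers are rejected: a zero-sd covariate carries no information
    and would divide by zero.
    """
    rec = ScalerRecord()
    for name, layer in layers.items():
        vals = np.asarray(layer, dtype=float)
        if mask is not None:
            vals = vals[mask]
        mu = float(vals.mean())
        sd = float(vals.std(ddof=0))
        if sd <= 0 or not np.isfinite(sd):
            raise DegenerateCovariateError(f"covariate {name!r} has zero variance")
        rec.means[name] = mu
        rec.sds[name] = sd
    return rec


def standardize(layers: dict[str, np.ndarray], mask: np.ndarray | None = None,
                scaler: ScalerRecord | None = None) -> tuple[dict[str, np.ndarray], ScalerRecord]:
    """z = (x - mean)/sd per layer; returns standardized layers and the scaler used."""
    if scaler is None:
        scaler = fit_scaler(layers, mask)
    out = {name: scaler.transform(name, layer) for name, layer in layers.items()}
    return out, scaler
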