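"""Synthetic station networks sampled from a known smooth space-time field.

The field is a baseline plus a seasonal sinusoid plus a sum of traveling
Gaussian plumes, clamped at zero (concentrations are non-negative):

    f(x, y, t) = max(0, baseline + A_s * sin(2*pi*t / n_days)
                        + sum_j A_j * exp(-|r - c_j(t)|^2 / (2 * w_j^2)))

with plume centers drifting linearly, c_j(t) = c_j(1) + v_j * (t - 1).  This
emulates the structure of the daily PM2.5 monitoring data — point stations
over a CONUS-like bounding box producing one value per day — while remaining
smooth in space and time, which is the regime where IDW interpolation is
meaningful.  Observations are truth plus additive Gaussian noise, clamped at
zero.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import Measurement, TargetSite
from .errors import InvalidDayError

__all__ = ["Plume", "FieldSpec", "CONUS_BBOX", "truth", "sample_stations",
           "make_grid", "add_decoy_stations"]

# printed extent of the 2009 CONUS monitoring network (x_min, x_max, y_min, y_max)
CONUS_BBOX = (-124.1775, -68.0162, 25.4714, 48.3997)


@dataclass(frozen=True)
class Plume:
    """A traveling Gaussian concentration plume."""

    center0: tuple[float, float]
    drift: tuple[float, float]  # degrees/day
    amplitude: float  # µg/m³
    width: float  # degrees (Gaussian sigma)

    def __post_init__(self):
        if not self.width > 0:
            raise ValueError(f"plume width must be > 0, got {self.width}")

    def center(self, day: float) -> tuple[float, float]:
        return (self.center0[0] + self.drift[0] * (day - 1),
                self.center0[1] + self.drift[1] * (day - 1))


def _default_plumes() -> tuple[Plume, ...]:
    # two plumes crossing the domain in opposite directions, wide enough that
    # a ~200-station network resolves them
    return (
        Plume(center0=(-110.0, 34.0), drift=(0.08, 0.02), amplitude=20.0, width=6.0),
        Plume(center0=(-80.0, 42.0), drift=(-0.06, -0.015), amplitude=14.0, width=8.0),
    )


@dataclass(frozen=True)
class FieldSpec:
    """Ground-truth field and observation-noise description.

    Defaults mirror the study conditions: the printed CONUS bounding box, a
    365-day year, a typical ~8 µg/m³ background with a ±3 µg/m³ seasonal
    swing, and 1 µg/m³ observation noise.
    """

    bbox: tuple[float, float, float, float] = CONUS_BBOX
    n_days: int = 365
    plumes: tuple[Plume, ...] = field(default_factory=_default_plumes)
    baseline: float = 8.0
    seasonal_amplitude: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_days < 1:
            raise ValueError(f"n_days must be >= 1, got {self.n_days}")


def truth(spec: FieldSpec, x, y, day):
    """Noise-free field value at (x, y, day); accepts numpy arrays.

    Day must lie within [1, n_days].
    """
    day_arr = np.asarray(day)
    if np.any((day_arr < 1) | (day_arr > spec.n_days)):
        raise InvalidDayError(f"day must be in [1, {spec.n_days}]")
    value = (spec.baseline
             + spec.seasonal_amplitude * np.sin(2 * np.pi * day_arr / spec.n_days))
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    for plume in spec.plumes:
        cx0, cy0 = plume.center0
        cx = cx0 + plume.drift[0] * (day_arr - 1)
        cy = cy0 + plume.drift[1] * (day_arr - 1)
        sq = (x - cx) ** 2 + (y - cy) ** 2
        value = value + plume.amplitude * np.exp(-sq / (2 * plume.width ** 2))
    value = np.maximum(value, 0.0)
    return float(value) if np.ndim(value) == 0 else value


def _station_locations(spec: FieldSpec, n_sites: int, clustering: float,
                       rng: np.random.Generator) -> np.ndarray:
    x_min, x_max, y_min, y_max = spec.bbox
    if not 0.0 <= clustering <= 1.0:
        raise ValueError(f"clustering must be in [0, 1], got {clustering}")
    xs = rng.uniform(x_min, x_max, n_sites)
    ys = rng.uniform(y_min, y_max, n_sites)
    if clustering > 0:
        n_clusters = 5
        cx = rng.uniform(x_min, x_max, n_clusters)
        cy = rng.uniform(y_min, y_max, n_clusters)
        sd_x = 0.05 * (x_max - x_min)
        sd_y = 0.05 * (y_max - y_min)
        member = rng.integers(0, n_clusters, n_sites)
        clustered = rng.random(n_sites) < clustering
        jitter_x = rng.normal(0.0, sd_x, n_sites)
        jitter_y = rng.normal(0.0, sd_y, n_sites)
        xs = np.where(clustered, np.clip(cx[member] + jitter_x, x_min, x_max), xs)
        ys = np.where(clustered, np.clip(cy[member] + jitter_y, y_min, y_max), ys)
    return np.column_stack([xs, ys])


def sample_stations(spec: FieldSpec, n_sites: int, clustering: float = 0.0,
                    seed: int | None = None) -> list[Measurement]:
    """Draw station locations and one noisy measurement per site per day.

    ``clustering = 0`` places stations uniformly over the bounding box;
    toward 1, stations concentrate around a few random cluster centers,
    leaving sparse regions (the situation that motivates the improved
    method's restricted neighborhood).
    """
    if n_sites < 1:
        raise ValueError(f"n_sites must be >= 1, got {n_sites}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    locations = _station_locations(spec, n_sites, clustering, rng)
    days = np.arange(1, spec.n_days + 1)
    measurements = []
    for site in range(n_sites):
        x, y = locations[site]
        values = truth(spec, x, y, days)
        noise = rng.normal(0.0, spec.noise_sd, spec.n_days) if spec.noise_sd > 0 else 0.0
        observed = np.maximum(np.asarray(values) + noise, 0.0)
        for day, v in zip(days, np.atleast_1d(observed)):
            measurements.append(Measurement(site + 1, float(x), float(y),
                                            int(day), float(v)))
    return measurements


def make_grid(bbox: tuple[float, float, float, float], nx: int, ny: int
              ) -> list[TargetSite]:
    """Regular nx-by-ny target grid over the bbox, row-major order.

    With a single row/column along an axis the grid sits at the bbox center
    of that axis; otherwise grid lines include the bbox edges.
    """
    if nx < 1 or ny < 1:
        raise ValueError("nx and ny must be >= 1")
    x_min, x_max, y_min, y_max = bbox
    xs = np.linspace(x_min, x_max, nx) if nx > 1 else np.array([(x_min + x_max) / 2])
    ys = np.linspace(y_min, y_max, ny) if ny > 1 else np.array([(y_min + y_max) / 2])
    targets = []
    i = 0
    for y in ys:
        for x in xs:
            targets.append(TargetSite(f"g{i:05d}", float(x), float(y)))
            i += 1
    return targets


def add_decoy_stations(measurements: list[Measurement], spec: FieldSpec,
                       n_decoys: int = 5, offset: float = 8.0,
                       value: float = 500.0, day: int | None = None
                       ) -> list[Measurement]:
    """Plant isolated aberrant readings well outside the bounding box.

    Each decoy is a station ``offset`` degrees beyond one of the box edges
    reporting a single grossly aberrant value on one day.  Under the original
    fixed-N method these records are still predicted (from far-away real
    stations, with large relative error) and can leak into edge
    neighborhoods; a restricted neighborhood excludes them entirely.
    """
    x_min, x_max, y_min, y_max = spec.bbox
    xc, yc = (x_min + x_max) / 2, (y_min + y_max) / 2
    edges = [
        (x_min - offset, yc), (x_max + offset, yc),
        (xc, y_min - offset), (xc, y_max + offset),
        (x_min - offset, y_min - offset),
    ]
    if day is None:
        day = (spec.n_days + 1) // 2
    out = list(measurements)
    for i in range(n_decoys):
        x, y = edges[i % len(edges)]
        # spread repeated edges out a little so decoys do not coincide
        out.append(Measurement(f"decoy{i}", x + (i // len(edges)) * 2.0, y,
                               int(day), float(value)))
    return out
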