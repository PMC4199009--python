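"""Extension-approach IDW: time scaling, spatiotemporal distance, weighting.

The extension approach treats the day index ``t`` as a third spatial axis
after multiplying it by a scale factor ``c`` (degrees per day), chosen so the
scaled time span of the dataset equals the mean of its spatial ranges:

    c = ((x_max - x_min) + (y_max - y_min)) / 2 / (n_days - 1)

Interpolation at a query point ``(x, y, c*t)`` is then ordinary inverse
distance weighting over the N nearest measurements in the scaled 3-d space,

    w = sum_i lambda_i * w_i,    lambda_i = d_i^(-p) / sum_k d_k^(-p)

with ``d_i`` the Euclidean distance in (cx*x, cy*y, ct*t) coordinates.  Two
variants are provided: the *original* method always uses all N nearest
neighbors; the *improved* method additionally discards any candidate farther
than ``max_distance`` (full scaled spatiotemporal distance) or more than
``max_time_diff`` days away, so sparse neighborhoods use fewer neighbors —
possibly none, in which case the prediction is explicitly missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .errors import InvalidExtentError, NoDataError, NoNeighborsError
from .kdtree import KdTree, build_tree, knn_search

__all__ = [
    "Measurement", "TargetSite", "AxisScales", "Method", "IdwConfig",
    "WeightedNeighbor", "PredictionRecord", "compute_scale_factor",
    "scaled_time", "st_distance", "idw_value", "select_neighbors",
    "build_station_tree", "interpolate_point",
]


@dataclass(frozen=True)
class Measurement:
    """One observed concentration at a station location on a given day.

    ``x``/``y`` are longitude/latitude in decimal degrees, treated as planar
    coordinates (no projection); ``day`` is a 1-based index within the study
    period; ``value`` is a concentration in µg/m³.
    """

    site_id: object
    x: float
    y: float
    day: int
    value: float

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates for site {self.site_id!r}")
        if not math.isfinite(self.value):
            raise ValueError(f"non-finite value for site {self.site_id!r}")
        if not (isinstance(self.day, int) and self.day >= 1):
            raise ValueError(f"day must be a positive integer, got {self.day!r}")


@dataclass(frozen=True)
class TargetSite:
    """An interpolation target (e.g. a county or block-group centroid)."""

    target_id: object
    x: float
    y: float

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates for target {self.target_id!r}")


@dataclass(frozen=True)
class AxisScales:
    """Per-axis coefficients of the scaled distance metric.

    ``cx`` and ``cy`` default to 1 (plain degrees); ``ct`` converts days to
    degrees and is normally obtained from :func:`compute_scale_factor`.
    """

    cx: float = 1.0
    cy: float = 1.0
    ct: float = 1.0

    def __post_init__(self):
        if not (self.cx > 0 and self.cy > 0 and self.ct > 0):
            raise ValueError("axis scales must be strictly positive")

    @classmethod
    def from_extent(cls, x_min, x_max, y_min, y_max, n_days) -> "AxisScales":
        """Scales with ct computed from the dataset extent (cx = cy = 1)."""
        return cls(1.0, 1.0, compute_scale_factor(x_min, x_max, y_min, y_max, n_days))


class Method(str, Enum):
    ORIGINAL = "original"
    IMPROVED = "improved"


@dataclass(frozen=True)
class IdwConfig:
    """IDW parameters: neighbor count N, exponent p, and the method variant.

    ``max_distance`` (scaled spatiotemporal units) and ``max_time_diff``
    (days) restrict the neighborhood and apply only to the improved method.
    """

    n_neighbors: int
    exponent: float
    method: Method = Method.ORIGINAL
    max_distance: float | None = None
    max_time_diff: float | None = None

    def __post_init__(self):
        if self.n_neighbors < 1:
            raise ValueError(f"n_neighbors must be >= 1, got {self.n_neighbors}")
        if not self.exponent > 0:
            raise ValueError(f"exponent must be > 0, got {self.exponent}")
        # accept plain strings for convenience
        object.__setattr__(self, "method", Method(self.method))


@dataclass(frozen=True)
class WeightedNeighbor:
    """A neighbor's measured value, its distance, and its IDW weight."""

    value: float
    distance: float
    weight: float


@dataclass(frozen=True)
class PredictionRecord:
    """One interpolation result; ``value`` is None iff no neighbor survived."""

    target_id: object
    day: int
    value: float | None
    neighbors_used: int

    def __post_init__(self):
        if (self.value is None) != (self.neighbors_used == 0):
            raise ValueError("value must be missing exactly when neighbors_used == 0")


def compute_scale_factor(x_min: float, x_max: float, y_min: float,
                         y_max: float, n_days: int) -> float:
    """Time-to-space scale factor c in degrees/day.

    Chosen so the scaled time span of the dataset, ``c * (n_days - 1)``,
    equals the mean of the spatial ranges.  For the 2009 CONUS PM2.5 extent
    (x: −124.1775..−68.0162, y: 25.4714..48.3997) over 365 days this gives
    c ≈ 0.1086.
    """
    if n_days < 2:
        raise InvalidExtentError(f"n_days must be >= 2, got {n_days}")
    if not (x_max > x_min and y_max > y_min):
        raise InvalidExtentError("degenerate spatial extent: require x_max > x_min and y_max > y_min")
    return ((x_max - x_min) + (y_max - y_min)) / 2.0 / (n_days - 1)


def scaled_time(day: float, c: float) -> float:
    """Scaled time coordinate ``c * day`` in degrees."""
    return c * day


def st_distance(a: Sequence[float], b: Sequence[float],
                scales: AxisScales) -> float:
    """Scaled spatiotemporal Euclidean distance between (x, y, day) triples."""
    ax, ay, at = a
    bx, by, bt = b
    return math.sqrt((scales.cx * (ax - bx)) ** 2
                     + (scales.cy * (ay - by)) ** 2
                     + (scales.ct * (at - bt)) ** 2)


def idw_value(neighbors: Iterable[tuple[float, float]], p: float
              ) -> tuple[float, list[WeightedNeighbor]]:
    """Inverse-distance-weighted value from (value, distance) pairs.

    Weights are ``d_i^(-p)`` normalized to sum to one.  The formula is
    undefined at zero distance; to keep the interpolator exact at measured
    points, any zero-distance neighbors take over entirely: the value is their
    mean and they share the unit weight equally, all others weighing zero.
    """
    pairs = list(neighbors)
    if not pairs:
        raise NoNeighborsError("idw_value requires at least one neighbor")
    zero_hits = [v for v, d in pairs if d == 0.0]
    if zero_hits:
        share = 1.0 / len(zero_hits)
        weighted = [WeightedNeighbor(v, d, share if d == 0.0 else 0.0)
                    for v, d in pairs]
        return sum(zero_hits) / len(zero_hits), weighted
    inv = [d ** -p for _, d in pairs]
    total = sum(inv)
    weighted = [WeightedNeighbor(v, d, w / total)
                for (v, d), w in zip(pairs, inv)]
    return sum(wn.value * wn.weight for wn in weighted), weighted


def select_neighbors(candidates: Sequence[tuple[Measurement, float]],
                     query_day: float, config: IdwConfig
                     ) -> list[tuple[Measurement, float]]:
    """Apply the improved method's neighborhood restriction.

    Under the original method candidates pass through unchanged.  Under the
    improved method a candidate survives only if its full scaled
    spatiotemporal distance is within ``max_distance`` and its day differs
    from the query day by at most ``max_time_diff``; order is preserved and
    the result may be empty (a missing prediction downstream).
    """
    if config.method is Method.ORIGINAL:
        return list(candidates)
    kept = []
    for m, d in candidates:
        if config.max_distance is not None and d > config.max_distance:
            continue
        if (config.max_time_diff is not None
                and abs(m.day - query_day) > config.max_time_diff):
            continue
        kept.append((m, d))
    return kept


def build_station_tree(measurements: Sequence[Measurement],
                       scales: AxisScales) -> KdTree:
    """3-d tree over measurements in scaled (cx*x, cy*y, ct*day) coordinates.

    Payloads are the measurements themselves; queries must use the same
    scales.
    """
    points = [(scales.cx * m.x, scales.cy * m.y, scales.ct * m.day)
              for m in measurements]
    return build_tree(points, payloads=list(measurements), k_dims=3)


def interpolate_point(tree: KdTree, query: Sequence[float], config: IdwConfig,
                      scales: AxisScales, target_id: object = None
                      ) -> PredictionRecord:
    """Interpolate at ``query = (x, y, day)`` using a prebuilt station tree.

    Runs the k-nearest-neighbor search in scaled coordinates, applies the
    method's neighborhood restriction, and combines the survivors by IDW.
    Returns an explicit missing record when no neighbor survives.
    """
    if tree.size == 0:
        raise NoDataError("interpolate_point on an empty tree")
    x, y, day = query
    scaled_q = (scales.cx * x, scales.cy * y, scales.ct * day)
    candidates = knn_search(tree, scaled_q, config.n_neighbors)
    kept = select_neighbors(candidates, day, config)
    if not kept:
        return PredictionRecord(target_id, int(day), None, 0)
    value, _ = idw_value([(m.value, d) for m, d in kept], config.exponent)
    return PredictionRecord(target_id, int(day), value, len(kept))
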