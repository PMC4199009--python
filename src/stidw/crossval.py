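"""Cross-validation of IDW configurations: LOOCV, k-fold, MARE/RMSPE, grids.

The error statistics are relative to the observed value,

    MARE  = mean_i |I_i - O_i| / O_i
    RMSPE = sqrt(mean_i ((O_i - I_i) / O_i)^2) * 100

so records observed at exactly zero cannot be scored and are excluded with a
counted skip, as are records the improved method could not predict (empty
restricted neighborhood).  k-fold statistics are pooled over all hold-out
pairs by default, which makes n-fold CV on n records coincide with LOOCV;
per-fold averaging is available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import numpy as np

from .core import (AxisScales, IdwConfig, Measurement, idw_value,
                   build_station_tree, select_neighbors)
from .errors import (InsufficientDataError, InvalidFoldsError,
                     NoEvaluablePairsError)
from .kdtree import build_tree, knn_search

__all__ = [
    "CvPair", "CvReport", "FoldAssignment", "mare", "rmspe", "loocv",
    "kfold_cv", "grid_search", "rank_by_mare", "rank_by_rmspe",
    "reports_to_frame", "format_reports",
]

PAPER_NEIGHBOR_GRID = (3, 4, 5, 6, 7)
PAPER_EXPONENT_GRID = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0)


@dataclass(frozen=True)
class CvPair:
    """One hold-out comparison; unusable when observed == 0 or prediction missing."""

    interpolated: float | None
    observed: float

    @property
    def usable(self) -> bool:
        return self.interpolated is not None and self.observed != 0


@dataclass(frozen=True)
class CvReport:
    """Cross-validation error summary for one IDW configuration."""

    config: IdwConfig
    mare: float
    rmspe: float
    n_evaluated: int
    n_skipped: int


@dataclass(frozen=True)
class FoldAssignment:
    """Seeded record-to-fold mapping with near-equal fold sizes."""

    n_folds: int
    fold_of: tuple[int, ...]
    seed: int

    @classmethod
    def make(cls, n_records: int, n_folds: int, seed: int) -> "FoldAssignment":
        if n_folds < 2:
            raise InvalidFoldsError(f"n_folds must be >= 2, got {n_folds}")
        if n_folds > n_records:
            raise InvalidFoldsError(
                f"n_folds={n_folds} exceeds dataset size {n_records}")
        rng = np.random.default_rng(seed)
        order = rng.permutation(n_records)
        fold_of = np.empty(n_records, dtype=int)
        for fold, chunk in enumerate(np.array_split(order, n_folds)):
            fold_of[chunk] = fold
        return cls(n_folds, tuple(int(f) for f in fold_of), seed)


def _usable(pairs: Iterable[CvPair]) -> list[CvPair]:
    usable = [p for p in pairs if p.usable]
    if not usable:
        raise NoEvaluablePairsError("no usable (interpolated, observed) pairs")
    return usable


def mare(pairs: Iterable[CvPair]) -> float:
    """Mean absolute relative error over usable pairs."""
    usable = _usable(pairs)
    return sum(abs(p.interpolated - p.observed) / p.observed for p in usable) / len(usable)


def rmspe(pairs: Iterable[CvPair]) -> float:
    """Root mean square percentage error over usable pairs."""
    usable = _usable(pairs)
    ms = sum(((p.observed - p.interpolated) / p.observed) ** 2 for p in usable) / len(usable)
    return math.sqrt(ms) * 100.0


def _report(config: IdwConfig, pairs: Sequence[CvPair]) -> CvReport:
    n_eval = sum(p.usable for p in pairs)
    return CvReport(config, mare(pairs), rmspe(pairs), n_eval, len(pairs) - n_eval)


def _predict_pairs(held_out: Sequence[Measurement], tree, config: IdwConfig,
                   scales: AxisScales) -> list[CvPair]:
    """Predict each held-out record from a tree that does not contain it."""
    pairs = []
    for m in held_out:
        q = (scales.cx * m.x, scales.cy * m.y, scales.ct * m.day)
        candidates = knn_search(tree, q, config.n_neighbors)
        kept = select_neighbors(candidates, m.day, config)
        if kept:
            value, _ = idw_value([(c.value, d) for c, d in kept], config.exponent)
        else:
            value = None
        pairs.append(CvPair(value, m.value))
    return pairs


def loocv(measurements: Sequence[Measurement], config: IdwConfig,
          scales: AxisScales,
          on_candidates: Callable[[int, list[int]], None] | None = None
          ) -> CvReport:
    """Leave-one-out cross-validation.

    Each record is predicted with itself removed from the candidate set;
    every other record — co-located duplicates included — stays eligible.
    A single tree indexed by record position is built once; each query asks
    for N+1 neighbors and drops the held-out record (or, when it was displaced
    by an equidistant tie, the surplus worst candidate), which yields exactly
    the N nearest other records.

    ``on_candidates(held_out_index, candidate_indices)`` is an
    instrumentation hook for asserting self-exclusion.
    """
    records = list(measurements)
    if len(records) < 2:
        raise InsufficientDataError("LOOCV needs at least 2 records")
    points = [(scales.cx * m.x, scales.cy * m.y, scales.ct * m.day)
              for m in records]
    tree = build_tree(points, payloads=list(range(len(records))), k_dims=3)
    k = min(config.n_neighbors + 1, len(records))
    pairs = []
    for i, m in enumerate(records):
        candidates = knn_search(tree, points[i], k)
        trimmed = [(j, d) for j, d in candidates if j != i]
        # i always has distance 0; if a tie crowded it out of the k returned,
        # the list holds k candidates none of which is i — drop the worst.
        trimmed = trimmed[:config.n_neighbors]
        if on_candidates is not None:
            on_candidates(i, [j for j, _ in trimmed])
        kept = select_neighbors([(records[j], d) for j, d in trimmed], m.day, config)
        if kept:
            value, _ = idw_value([(c.value, d) for c, d in kept], config.exponent)
        else:
            value = None
        pairs.append(CvPair(value, m.value))
    return _report(config, pairs)


def kfold_cv(measurements: Sequence[Measurement], n_folds: int,
             config: IdwConfig, scales: AxisScales, seed: int,
             pooling: str = "pooled") -> CvReport:
    """k-fold cross-validation with a seeded uniform shuffle into folds.

    Each fold is predicted from a tree over the remaining folds only.  With
    ``pooling="pooled"`` (default) all hold-out pairs are pooled before
    computing MARE/RMSPE; ``pooling="per_fold"`` averages the per-fold
    statistics instead (folds with no usable pair are skipped).
    """
    records = list(measurements)
    if n_folds < 2 or n_folds > len(records):
        raise InvalidFoldsError(
            f"n_folds must be in [2, {len(records)}], got {n_folds}")
    if pooling not in ("pooled", "per_fold"):
        raise ValueError(f"unknown pooling {pooling!r}")
    assignment = FoldAssignment.make(len(records), n_folds, seed)
    all_pairs: list[CvPair] = []
    fold_stats: list[tuple[float, float]] = []
    for fold in range(n_folds):
        train = [m for m, f in zip(records, assignment.fold_of) if f != fold]
        test = [m for m, f in zip(records, assignment.fold_of) if f == fold]
        tree = build_station_tree(train, scales)
        pairs = _predict_pairs(test, tree, config, scales)
        all_pairs.extend(pairs)
        if pooling == "per_fold" and any(p.usable for p in pairs):
            fold_stats.append((mare(pairs), rmspe(pairs)))
    if pooling == "per_fold":
        if not fold_stats:
            raise NoEvaluablePairsError("no fold had a usable pair")
        n_eval = sum(p.usable for p in all_pairs)
        return CvReport(config,
                        sum(m for m, _ in fold_stats) / len(fold_stats),
                        sum(r for _, r in fold_stats) / len(fold_stats),
                        n_eval, len(all_pairs) - n_eval)
    return _report(config, all_pairs)


def grid_search(measurements: Sequence[Measurement],
                neighbor_set: Sequence[int] = PAPER_NEIGHBOR_GRID,
                exponent_set: Sequence[float] = PAPER_EXPONENT_GRID,
                cv_kind: str = "loocv",
                base_config: IdwConfig | None = None,
                scales: AxisScales = AxisScales(),
                seed: int = 0,
                n_folds: int = 10) -> list[CvReport]:
    """Cross-validate every (N, p) combination; reports sorted by (N, p).

    The default grids are the study's 45 methods: N in {3..7} and p in
    {1, 1.5, ..., 5}.  ``cv_kind`` is "loocv" or "kfold" (``n_folds`` folds,
    default 10).
    """
    if not neighbor_set or not exponent_set:
        raise ValueError("neighbor_set and exponent_set must be non-empty")
    if cv_kind not in ("loocv", "kfold", "kfold10"):
        raise ValueError(f"unknown cv_kind {cv_kind!r}")
    if base_config is None:
        base_config = IdwConfig(n_neighbors=3, exponent=2.0)
    reports = []
    for n in sorted(neighbor_set):
        for p in sorted(exponent_set):
            config = replace(base_config, n_neighbors=n, exponent=p)
            if cv_kind == "loocv":
                reports.append(loocv(measurements, config, scales))
            else:
                reports.append(kfold_cv(measurements, n_folds, config, scales, seed))
    return reports


def rank_by_mare(reports: Sequence[CvReport]) -> list[CvReport]:
    """Reports sorted ascending by MARE (best first)."""
    return sorted(reports, key=lambda r: r.mare)


def rank_by_rmspe(reports: Sequence[CvReport]) -> list[CvReport]:
    """Reports sorted ascending by RMSPE (best first)."""
    return sorted(reports, key=lambda r: r.rmspe)


def reports_to_frame(reports: Sequence[CvReport]):
    """CV reports as a pandas DataFrame (one row per configuration)."""
    import pandas as pd

    return pd.DataFrame([
        {
            "method": r.config.method.value,
            "n_neighbors": r.config.n_neighbors,
            "exponent": r.config.exponent,
            "max_distance": r.config.max_distance,
            "max_time_diff": r.config.max_time_diff,
            "mare": r.mare,
            "rmspe": r.rmspe,
            "n_evaluated": r.n_evaluated,
            "n_skipped": r.n_skipped,
        }
        for r in reports
    ])


def format_reports(reports: Sequence[CvReport]) -> str:
    """Fixed-width table of neighbors/exponent/MARE/RMSPE, one row per config."""
    lines = [f"{'Neighbors':>9}  {'Exponent':>8}  {'MARE':>10}  {'RMSPE':>12}"]
    for r in reports:
        lines.append(f"{r.config.n_neighbors:>9}  {r.config.exponent:>8.1f}  "
                     f"{r.mare:>10.5f}  {r.rmspe:>12.4f}")
    return "\n".join(lines)
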