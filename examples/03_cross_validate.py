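"""Choose (N, p) by leave-one-out cross-validation over the standard grid.

Runs the full 45-method grid — neighbor counts 3..7 crossed with exponents
1.0..5.0 in steps of 0.5 — on a compact synthetic network, then reports the
configurations that minimize MARE (mean absolute relative error) and RMSPE
(root mean square percentage error).  Lower is better for both.
"""

from stidw import AxisScales, FieldSpec, grid_search, rank_by_mare, rank_by_rmspe, sample_stations
from stidw.crossval import format_reports

spec = FieldSpec(n_days=8, noise_sd=0.5, seed=13)
stations = sample_stations(spec, 30)
scales = AxisScales.from_extent(*spec.bbox, spec.n_days)

reports = grid_search(stations, scales=scales)
print(f"{len(reports)} configurations cross-validated "
      f"on {len(stations)} records")
print(format_reports(reports[:5]))
print("...")

best_mare = rank_by_mare(reports)[0]
best_rmspe = rank_by_rmspe(reports)[0]
print(f"best by MARE : N={best_mare.config.n_neighbors} "
      f"p={best_mare.config.exponent} -> MARE {best_mare.mare:.5f}")
print(f"best by RMSPE: N={best_rmspe.config.n_neighbors} "
      f"p={best_rmspe.config.exponent} -> RMSPE {best_rmspe.rmspe:.4f}")
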