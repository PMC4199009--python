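"""Why restricting the search neighborhood helps: the decoy experiment.

A fixed-N interpolator always finds N neighbors, however far away — so an
isolated aberrant reading is predicted from (and can contaminate) stations
hundreds of kilometres distant.  Restricting the neighborhood by a maximum
scaled distance and a maximum day difference drops such candidates, at the
price of leaving truly isolated points unpredicted.

Here 5 decoy stations with grossly aberrant single-day readings are planted
well outside the network; LOOCV error is compared between the two variants.
"""

from stidw import (AxisScales, FieldSpec, IdwConfig, add_decoy_stations,
                   loocv, sample_stations)

spec = FieldSpec(n_days=30, noise_sd=1.0, seed=42)
stations = add_decoy_stations(
    sample_stations(spec, 200, clustering=0.5), spec)
scales = AxisScales.from_extent(*spec.bbox, spec.n_days)

original = loocv(stations, IdwConfig(3, 2.0, "original"), scales)
improved = loocv(stations, IdwConfig(3, 2.0, "improved",
                                     max_distance=3.0, max_time_diff=7),
                 scales)

print(f"records: {len(stations)} (including 5 decoys)")
print(f"original (fixed N=3):      MARE {original.mare:.5f} "
      f"({original.n_evaluated} scored, {original.n_skipped} skipped)")
print(f"improved (d<=3.0, dt<=7d): MARE {improved.mare:.5f} "
      f"({improved.n_evaluated} scored, {improved.n_skipped} skipped)")
print("The restricted neighborhood refuses to predict the isolated decoys")
print("(skipped records) instead of scoring them against far-away stations,")
print("and its error over the remaining records is lower.")
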