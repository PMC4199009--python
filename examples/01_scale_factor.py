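"""Time-as-a-dimension scaling: compute c and the scaled-time table.

The factor c (degrees/day) makes the time axis commensurate with the spatial
axes: it is chosen so that the scaled length of the study period equals the
mean of the dataset's longitude and latitude ranges.  Here we compute it for
the 2009 CONUS PM2.5 monitoring extent and print the first and last scaled
time values — the coordinates actually used on the third axis.
"""

from stidw import CONUS_BBOX, compute_scale_factor, scaled_time

c = compute_scale_factor(*CONUS_BBOX, n_days=365)
print(f"bounding box: x {CONUS_BBOX[0]}..{CONUS_BBOX[1]}, "
      f"y {CONUS_BBOX[2]}..{CONUS_BBOX[3]}")
print(f"scale factor c = {c:.4f} degrees/day")
print()
print(f"{'day':>4}  {'c*t (degrees)':>14}")
for day in (1, 2, 3, 4, 365):
    print(f"{day:>4}  {scaled_time(day, round(c, 4)):>14.4f}")
print()
print("A one-day separation therefore counts the same as a "
      f"{c:.4f}-degree spatial offset in every distance computation.")
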