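"""Kernel utilization distributions, core/home isopleths and the two
overlap indices.

The UD turns equidistant positions into a probability surface of space
use; the 50% isopleth is the core range, the 95% the home range.  Percent
overlap is asymmetric area overlap; Bhattacharyya affinity compares whole
surfaces truncated at their isopleths (ceilings 0.50 / 0.95).
"""

import numpy as np
import whaletrack as wt
from whaletrack.homerange import (UDGrid, bhattacharyya, isopleth, kernel_ud,
                                  make_grid, percent_overlap)

rng = np.random.default_rng(0)
# two whales sharing part of their range (positions in projected metres)
pts_a = rng.normal([-12_000, 0], 15_000, (300, 2))
pts_b = rng.normal([+12_000, 0], 15_000, (300, 2))
grid = make_grid(np.vstack([pts_a, pts_b]), cell_size=10_000.0, h=12_000.0)
ud_a = kernel_ud(pts_a, grid=grid, h=12_000.0)
ud_b = kernel_ud(pts_b, grid=grid, h=12_000.0)

for name, ud in (("A", ud_a), ("B", ud_b)):
    core = isopleth(ud, 0.50)
    home = isopleth(ud, 0.95)
    print(f"whale {name}: core {core.area_km2:.0f} km2, home {home.area_km2:.0f} km2")

home_a, home_b = isopleth(ud_a, 0.95), isopleth(ud_b, 0.95)
print(f"percent overlap (A's home covered by B): {percent_overlap(home_a, home_b):.2f}")
print(f"percent overlap (B's home covered by A): {percent_overlap(home_b, home_a):.2f}")
print(f"Bhattacharyya affinity, home level: {bhattacharyya(ud_a, ud_b, 0.95):.2f} "
      "(0.95 would be identical space use)")
print(f"Bhattacharyya affinity, core level: {bhattacharyya(ud_a, ud_b, 0.50):.2f} "
      "(0.50 ceiling)")
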