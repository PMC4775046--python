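"""S1S2 reentry induction and RVI mapping on the 2D sheet.

Runs the half-scale (2.5 cm) sheet with the imposed proximal/distal APD
gradient: two S1 beats at 500 ms then a premature S2 at a 300 ms
coupling interval from a point in the upper-left (proximal) quadrant.
The premature wavefront blocks along the APD-gradient interface, detours
around the end of the line of block, and re-enters; the episode is
classified from the streamed activation events and the S2 marker map is
turned into an RVI map whose minimum localises the reentry site.

Takes about half a minute on one core.
"""

import numpy as np

from rvimap import (RVIConfig, classify_outcome, compute_rvi,
                    extract_markers, sheet_point_protocol, summarise)
from rvimap.geometry import build_2d_sheet
from rvimap.tissue import run_monodomain

model = build_2d_sheet(2.5, 200.0)  # distal half APD ~317 ms (g_Ks 0.2)
proto = sheet_point_protocol(model, ci_ms=300.0, n_s1=2, s1_cl_ms=500.0)
res = run_monodomain(model, proto, t_end=proto.t_s2 + 600.0, dt=0.1)

rec = classify_outcome(res)
print(f"outcome: {rec.outcome.value} "
      f"({rec.n_reactivated} nodes re-activated after S2)")

markers = extract_markers(res)
rmap = compute_rvi(markers, RVIConfig(search_radius_mm=5.0,
                                      electrode_pitch_mm=1.0))
rvi_min, pct = summarise(rmap, 50.0)
where = rmap.positions_um[np.argmin(rmap.values_ms)] / 1000.0
print(f"RVI map ({rmap.n_bins} bins): RVI_min {rvi_min:.1f} ms at "
      f"({where[0]:.1f}, {where[1]:.1f}) mm, %<50 ms {pct:.1f}")
print("negative RVI means tissue re-activates before its neighbourhood "
      "has repolarised - the hallmark of a reentry-vulnerable site; the "
      "minimum lies on the line of block where the wave re-entered")
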