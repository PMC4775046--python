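"""RVI mapping on analytic line-of-block marker fields (no PDE solve).

Generates activation/repolarisation markers for a paced wavefront that
blocks along a line and reaches the far side only by a slow detour —
the geometry of a premature beat meeting refractory tissue — then maps
the Reentry Vulnerability Index over the field for several search radii.
The minimum-RVI bin marks where late re-activation meets early
repolarisation: the vulnerable site. Runs in seconds.
"""

import numpy as np

from rvimap import RVIConfig, compute_rvi, summarise
from rvimap.synthetic import arrhythmogenic_scenario, generate_block_fields

scn = arrhythmogenic_scenario(apd_distal_ms=320.0, ci_ms=300.0)
mk = generate_block_fields(scn, pitch_mm=1.0)
print(f"scenario: block length "
      f"{scn.block_x_mm[1] - scn.block_x_mm[0]:.0f} mm, "
      f"{mk.n_sites} recording sites")

for r_s in (2.5, 5.0, 10.0):
    rmap = compute_rvi(mk, RVIConfig(search_radius_mm=r_s, bin_mm=1.0))
    rvi_min, pct = summarise(rmap, 50.0)
    where = rmap.positions_um[np.argmin(rmap.values_ms)] / 1000.0
    print(f"r_s {r_s:5.1f} mm: RVI_min {rvi_min:7.1f} ms at "
          f"({where[0]:.0f}, {where[1]:.0f}) mm, %<50 ms {pct:5.1f}")

print("the minimum sits on the line of block (y = "
      f"{scn.block_y_mm:.0f} mm), at its far (deep-detour) end; "
      "larger radii dilute the minimum but spread the low-RVI region")
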