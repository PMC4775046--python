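"""Regional action potential durations of the ten Tusscher cell.

Paces each regional cell variant (proximal/normal myocardium, distal
long-APD, border zone) to steady state at the package's 500 ms S1 cycle
length and measures APD as the interval between the -20 mV activation
crossing and the -70 mV repolarisation crossing. The three durations are
what create the conduction-block substrate in the tissue scenarios: the
premature beat blocks wherever the local APD exceeds its coupling
interval.
"""

from rvimap import Region, make_region_params
from rvimap.cell import final_beat_apd

for region in (Region.PROXIMAL, Region.DISTAL, Region.BZ):
    params = make_region_params(region)
    apd = final_beat_apd(params, cl_ms=500.0)
    print(f"{region.name:9s} g_Ks={params.gks:5.3f} nS/pF "
          f"(g_Kr x{params.gkr_frac:4.2f}, g_Na x{params.gna_frac:4.2f})"
          f" -> APD {apd:6.1f} ms")
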