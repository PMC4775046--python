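# rvimap

Reentry Vulnerability Index (RVI) mapping on idealised cardiac tissue
models.

Scar-related ventricular tachycardia is sustained by reentrant circuits
threading isthmuses of surviving myocardium through infarct scar, and
the classic ablation target is the isthmus *exit site*. Locating exits
usually requires inducing the tachycardia in the EP lab. The RVI is a
quantitative alternative computed from an ordinary S1S2 pacing run: for
every pair of recording sites *i*, *j* with *j* activated later than *i*
within a search radius *r*<sub>s</sub>,

&nbsp;&nbsp;&nbsp;&nbsp;RVI<sub>ij</sub> = RT<sub>i</sub> − AT<sub>j</sub>

where AT is the activation time (−20 mV upstroke crossing) and RT the
repolarisation time (−70 mV downstroke crossing) of the premature (S2)
beat. Each value is placed at the pair midpoint, midpoints are averaged
on a spatial lattice, and small or negative bins mark tissue the
returning wavefront can re-excite — vulnerability to reentry, visible
*without* inducing it. The map is summarised by its minimum
(RVI<sub>min</sub>) and the percentage of bins below 50 ms
(RVI<sub>%&lt;50ms</sub>); regions below 25 ms are ablation targets.

`rvimap` is aimed at computational electrophysiologists who want a
self-contained, desk-scale test bench for this mapping method. It
provides:

- the ten Tusscher 2006 human ventricular cell model (numba-compiled,
  table-driven Rush–Larsen) with the regional variants used by the
  in-silico scenarios: proximal/normal myocardium (g_Ks = 0.75 nS/pF,
  APD ≈ 250 ms), distal long-APD tissue (g_Ks = 0.2 nS/pF, ≈ 300 ms)
  and border zone (g_Kr × 0.20, g_Ks × 0.30, g_Na × 0.38, ≈ 330 ms);
- an explicit monodomain solver on structured 2D/3D grids with S1S2
  pacing, streamed AT/RT threshold-crossing events, and automatic
  classification of each episode as no-block, bi-directional block
  (failed reentry) or uni-directional block with reentry;
- geometry builders for the 5 × 5 cm sheet (proximal/distal halves) and
  the 2 × 2 × 1 cm cuboid with two ellipsoidal necrotic regions and a
  border-zone isthmus at configurable depth, plus a seed-point /
  geodesic-distance (Dijkstra) generator for synthetic scar anatomies
  on arbitrary meshes;
- the RVI core: pairwise computation, midpoint binning, surface and
  volume modes, regular electrode subsampling, summary statistics and
  connected-region target extraction;
- simulated ablation (insulating spherical or transmural-cylindrical
  lesions at target centroids, greedy coverage) with re-induction
  testing;
- an analytic line-of-block marker-field generator so the RVI pipeline
  is testable without any PDE solve, marker CSV interchange for
  clinical-style recordings, legacy-VTK/HDF5 I/O, a YAML-driven
  experiment runner and a thin `rvimap` CLI
  (`simulate | markers | rvi | ablate | sweep | synth`).

## Worked example

Mapping RVI over an analytic paced-wavefront-with-block field (runs in
seconds; `python examples/synthetic_block_fields.py`):

```
scenario: block length 16 mm, 2601 recording sites
r_s   2.5 mm: RVI_min   115.1 ms at (0, 24) mm, %<50 ms   0.0
r_s   5.0 mm: RVI_min    95.8 ms at (0, 24) mm, %<50 ms   0.0
r_s  10.0 mm: RVI_min    81.3 ms at (0, 24) mm, %<50 ms   0.0
```

The minimum-RVI bin sits on the line of block (y = 25 mm) at its
deep-detour end: the repolarisation margin between the early-repolarised
proximal side and the late, slowly-conducted activation on the distal
side is smallest exactly where a reentrant wavefront would break
through. The regional cell calibration behind the tissue scenarios
(`python examples/single_cell_apd.py`):

```
PROXIMAL  g_Ks=0.750 nS/pF (g_Kr x1.00, g_Na x1.00) -> APD  241.7 ms
DISTAL    g_Ks=0.200 nS/pF (g_Kr x1.00, g_Na x1.00) -> APD  316.8 ms
BZ        g_Ks=0.225 nS/pF (g_Kr x0.20, g_Na x0.38) -> APD  352.2 ms
```

Other examples: `sheet_reentry_rvi.py` (S1S2 reentry induction and RVI
localisation on the 2D sheet, ~30 s), `scar_generation.py` (seed-point
scar anatomies + VTK export), and `cuboid_scar_ablation.py` (full
induce → map → ablate → re-test loop on the 3D cuboid scar, ~10 min).

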