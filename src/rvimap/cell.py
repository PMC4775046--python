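"""Single-cell electrophysiology: regional parameter sets, paced
simulation, and action-potential-duration measurement.

The package's baseline "normal myocardium" cell is the epicardial
ten Tusscher 2006 model with g_Ks = 0.75 nS/pF, the value that yields an
APD (−20 mV activation to −70 mV repolarisation crossing) of ~250 ms —
the APD assigned to proximal/normal tissue throughout. The distal half of
the 2D sheet uses g_Ks = 0.2 nS/pF (APD ~300 ms), and border-zone tissue
scales the baseline g_Kr to 20%, g_Ks to 30% and g_Na to 38%
(APD ~330 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Optional

import numpy as np

from . import tt06
from .regions import Region

__all__ = [
    "CellParams",
    "make_region_params",
    "simulate_cell",
    "measure_apd",
    "crossing_time",
    "calibrate_gks_for_apd",
    "GKS_NORMAL",
    "GKS_DISTAL_DEFAULT",
    "BZ_FRACTIONS",
]

#: g_Ks of proximal / normal myocardium (absolute, nS/pF)
GKS_NORMAL = 0.75
#: g_Ks of the distal (long-APD) half of the 2D sheet
GKS_DISTAL_DEFAULT = 0.2
#: Border-zone conductance fractions applied to the baseline cell:
#: (g_Kr, g_Ks, g_Na)
BZ_FRACTIONS = (0.20, 0.30, 0.38)


@dataclass(frozen=True)
class CellParams:
    """Ionic parameter set: TT06 base model plus regional scalings.

    ``gks`` is an absolute maximal I_Ks conductance in nS/pF (replacing
    the model default); ``gkr_frac``/``gna_frac`` are fractions of the
    model-default conductances.
    """

    gks: float = GKS_NORMAL
    gkr_frac: float = 1.0
    gna_frac: float = 1.0
    subtype: str = "epi"

    def __post_init__(self):
        if self.gks <= 0:
            raise ValueError("absolute g_Ks must be positive")
        if not (0 < self.gkr_frac <= 1) or not (0 < self.gna_frac <= 1):
            raise ValueError("conductance fractions must lie in (0, 1]")

    def conductances(self):
        """Resolved (g_Na, g_Kr, g_Ks, g_to) in nS/pF."""
        gna0, gkr0, _, gto0 = tt06.default_conductances(self.subtype)
        return (gna0 * self.gna_frac, gkr0 * self.gkr_frac, self.gks, gto0)


def make_region_params(region: Region, distal_gks: float = GKS_DISTAL_DEFAULT,
                       subtype: str = "epi") -> CellParams:
    """Cell parameters for a tissue region.

    PROXIMAL/HEALTHY share the baseline (g_Ks 0.75 nS/pF); DISTAL gets the
    long-APD g_Ks (0.2 nS/pF by default, overridable for the
    arrhythmogenicity sweeps); BZ applies the (0.20, 0.30, 0.38)
    g_Kr/g_Ks/g_Na fractions to the baseline. SCAR and LESION carry no
    cell model and are rejected.
    """
    region = Region(region)
    if region in (Region.SCAR, Region.LESION):
        raise ValueError(f"{region.name} tissue has no ionic model")
    if region in (Region.PROXIMAL, Region.HEALTHY):
        return CellParams(gks=GKS_NORMAL, subtype=subtype)
    if region == Region.DISTAL:
        return CellParams(gks=distal_gks, subtype=subtype)
    if region == Region.BZ:
        fkr, fks, fna = BZ_FRACTIONS
        return CellParams(gks=GKS_NORMAL * fks, gkr_frac=fkr,
                          gna_frac=fna, subtype=subtype)
    raise ValueError(f"unhandled region {region!r}")


#: Stimulus defaults: 2 ms at roughly twice diastolic threshold.
STIM_DURATION_MS = 2.0
STIM_AMPLITUDE = 52.0  # pA/pF, depolarising


def simulate_cell(params: CellParams, cl_ms: float = 600.0, n_beats: int = 10,
                  dt: float = 0.02, extra_ms: float = 600.0,
                  s2_ci_ms: Optional[float] = None, rec_dt: float = 0.1,
                  stim_amp: float = STIM_AMPLITUDE):
    """Pace a single cell and return the (t_ms, V_mV) trace.

    ``n_beats`` S1 stimuli at cycle length ``cl_ms`` are applied (the
    pre-pacing train that approximates steady state); if ``s2_ci_ms`` is
    given, one premature S2 follows the last S1 at that coupling
    interval. The returned trace covers the whole run; downstream
    measurement selects the final (or S2) beat. Raises on numerical
    blow-up (|V| > 200 mV).
    """
    stim_starts = [i * cl_ms for i in range(n_beats)]
    t_last = stim_starts[-1]
    if s2_ci_ms is not None:
        stim_starts.append(t_last + s2_ci_ms)
        t_last = stim_starts[-1]
    t_end = t_last + extra_ms
    n_steps = int(round(t_end / dt))
    rec_every = max(1, int(round(rec_dt / dt)))
    tab, k1tab = _tables(dt, params.subtype)
    gna, gkr, gks, gto = params.conductances()
    V, S = tt06.initial_state(1)
    t, v, failed = tt06.run_cell(
        V, S,
        np.full(1, gna), np.full(1, gkr), np.full(1, gks), np.full(1, gto),
        dt, n_steps, np.asarray(stim_starts, dtype=np.float64),
        STIM_DURATION_MS, stim_amp, tab, k1tab, rec_every)
    if failed >= 0:
        raise FloatingPointError(
            f"membrane potential blew up at t={failed * dt:.2f} ms")
    return t, v


@lru_cache(maxsize=8)
def _tables(dt: float, subtype: str):
    return tt06.build_tables(dt, subtype)


def crossing_time(t: np.ndarray, v: np.ndarray, level: float,
                  direction: int, t_min: float = -np.inf) -> Optional[float]:
    """First time ``v`` crosses ``level`` in ``direction`` (+1 upward,
    −1 downward) at or after ``t_min``; linearly interpolated between
    samples. Returns ``None`` if no crossing exists.
    """
    v = np.asarray(v)
    t = np.asarray(t)
    if direction > 0:
        hit = (v[:-1] < level) & (v[1:] >= level)
    else:
        hit = (v[:-1] > level) & (v[1:] <= level)
    idx = np.flatnonzero(hit & (t[1:] >= t_min))
    for i in idx:
        frac = (level - v[i]) / (v[i + 1] - v[i])
        tc = t[i] + frac * (t[i + 1] - t[i])
        if tc >= t_min:
            return float(tc)
    return None


def measure_apd(t: np.ndarray, v: np.ndarray, at_mv: float = -20.0,
                rt_mv: float = -70.0, t_min: float = -np.inf) -> float:
    """APD = RT − AT for the first action potential at/after ``t_min``.

    AT is the upward crossing of ``at_mv``; RT the subsequent downward
    crossing of ``rt_mv``. Returns ``np.nan`` (flagged undefined) if
    either crossing is absent.
    """
    at = crossing_time(t, v, at_mv, +1, t_min)
    if at is None:
        return np.nan
    rt = crossing_time(t, v, rt_mv, -1, at)
    if rt is None:
        return np.nan
    return rt - at


def final_beat_apd(params: CellParams, cl_ms: float = 600.0,
                   n_beats: int = 10, dt: float = 0.02,
                   at_mv: float = -20.0, rt_mv: float = -70.0) -> float:
    """Steady-state APD: pace ``n_beats`` and measure the final beat."""
    t, v = simulate_cell(params, cl_ms=cl_ms, n_beats=n_beats, dt=dt)
    return measure_apd(t, v, at_mv, rt_mv, t_min=(n_beats - 1) * cl_ms)


def calibrate_gks_for_apd(target_apd_ms: float, cl_ms: float = 600.0,
                          n_beats: int = 10, tol_ms: float = 0.25,
                          gks_lo: float = 0.02, gks_hi: float = 2.0,
                          subtype: str = "epi") -> float:
    """g_Ks giving a requested steady-state APD, by bisection.

    APD is monotonically decreasing in g_Ks (a repolarising current), so
    bisection on log-g_Ks converges; used to translate the distal-APD
    sweep axes into cell parameters.
    """
    lo, hi = np.log(gks_lo), np.log(gks_hi)
    f_lo = final_beat_apd(CellParams(gks=gks_lo, subtype=subtype), cl_ms, n_beats)
    f_hi = final_beat_apd(CellParams(gks=gks_hi, subtype=subtype), cl_ms, n_beats)
    if not (f_hi <= target_apd_ms <= f_lo):
        raise ValueError(
            f"target APD {target_apd_ms} ms outside achievable range "
            f"[{f_hi:.1f}, {f_lo:.1f}] ms")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        apd = final_beat_apd(CellParams(gks=float(np.exp(mid)), subtype=subtype),
                             cl_ms, n_beats)
        if abs(apd - target_apd_ms) < tol_ms:
            return float(np.exp(mid))
        if apd > target_apd_ms:
            lo = mid  # APD too long -> need more g_Ks
        else:
            hi = mid
    return float(np.exp(0.5 * (lo + hi)))
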