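"""Monodomain reaction–diffusion simulation with S1S2 pacing.

The transmembrane potential obeys

    beta * Cm * dV/dt = div(sigma grad V) - beta * I_ion + I_stim

with isotropic conductivity ``sigma``, surface-to-volume ratio
``beta = 1400 / cm`` and ``Cm = 1 uF/cm^2``, reduced here to an effective
diffusivity D = sigma / (beta * Cm). SCAR and LESION nodes have D = 0 and
no ionic model: they are internal no-flux boundaries.

The solver streams activation/repolarisation threshold-crossing events
(AT/RT markers) rather than storing V histories; optional decimated
snapshots are available for small runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, Optional, Sequence

import numpy as np
import scipy.sparse as sp

from . import tt06
from ._kernel import face_weights, run_tissue
from .cell import CellParams, make_region_params, _tables
from .geometry import TissueModel, edge_graph, UM_PER_MM
from .regions import Region

__all__ = [
    "ConductivityField",
    "PacingProtocol",
    "SimulationResult",
    "Outcome",
    "OutcomeConfig",
    "OutcomeRecord",
    "run_monodomain",
    "measure_cv",
    "classify_outcome",
    "classify_events",
    "sheet_point_protocol",
    "cuboid_face_protocol",
]

BETA_PER_CM = 1400.0     # surface-to-volume ratio
CM_UF_PER_CM2 = 1.0      # membrane capacitance per area


def sigma_to_diffusivity(sigma_S_m) -> np.ndarray:
    """Effective diffusivity in mm^2/ms from conductivity in S/m."""
    return np.asarray(sigma_S_m, dtype=float) / (
        BETA_PER_CM * CM_UF_PER_CM2 * 1.0e-3)


@dataclass(frozen=True)
class ConductivityField:
    """Region-based isotropic conductivity assignment.

    BZ tissue gets ``sigma * bz_cv_fraction**2`` so that its conduction
    velocity is reduced to ``bz_cv_fraction`` of healthy CV (CV scales
    with the square root of conductivity); 0.55 reproduces the prescribed
    45% CV reduction. SCAR and LESION are exactly zero.
    """

    sigma_S_m: float = 0.1
    bz_cv_fraction: float = 0.55

    def node_sigma(self, labels: np.ndarray) -> np.ndarray:
        labels = np.asarray(labels)
        sigma = np.full(labels.shape, self.sigma_S_m, dtype=float)
        sigma[labels == Region.BZ] = self.sigma_S_m * self.bz_cv_fraction ** 2
        sigma[(labels == Region.SCAR) | (labels == Region.LESION)] = 0.0
        return sigma


@dataclass(frozen=True)
class PacingProtocol:
    """S1 train plus optional premature S2 from the same site.

    ``site_kind`` is ``"point"`` (all conducting nodes within
    ``radius_mm`` of ``point_um``), ``"face"`` (a domain face, e.g.
    ``"x0"`` for the x = 0 surface) or ``"nodes"`` (explicit ids).
    """

    n_s1: int = 2
    s1_cl_ms: float = 500.0
    ci_ms: float = 300.0
    with_s2: bool = True
    t0_ms: float = 0.0  # delay applied to the whole stimulus train
    site_kind: str = "point"
    point_um: tuple = (0.0, 0.0, 0.0)
    radius_mm: float = 1.0
    face: str = "x0"
    face_depth_mm: float = 0.4  # stimulated slab thickness behind a face
    node_ids: Optional[tuple] = None
    amplitude: float = 52.0   # pA/pF, depolarising
    duration_ms: float = 2.0

    def __post_init__(self):
        if self.with_s2 and self.ci_ms <= 0:
            raise ValueError("coupling interval must be positive")
        if self.n_s1 < 0:
            raise ValueError("n_s1 must be non-negative")

    def stim_times(self) -> np.ndarray:
        times = [self.t0_ms + i * self.s1_cl_ms for i in range(self.n_s1)]
        if self.with_s2:
            times.append(self.t_s2)
        return np.asarray(times, dtype=float)

    @property
    def t_s2(self) -> Optional[float]:
        if not self.with_s2:
            return None
        last_s1 = (self.n_s1 - 1) * self.s1_cl_ms if self.n_s1 else 0.0
        return self.t0_ms + last_s1 + self.ci_ms

    def stim_node_ids(self, model: TissueModel) -> np.ndarray:
        conducting = model.conducting_mask()
        if self.site_kind == "nodes":
            ids = np.asarray(self.node_ids, dtype=np.int64)
        elif self.site_kind == "point":
            d = np.linalg.norm(model.positions - np.asarray(self.point_um), axis=1)
            ids = np.flatnonzero(d <= self.radius_mm * UM_PER_MM)
        elif self.site_kind == "face":
            axis = {"x": 0, "y": 1, "z": 2}[self.face[0]]
            coords = model.positions[:, axis]
            depth = self.face_depth_mm * UM_PER_MM
            if self.face.endswith("0"):
                ids = np.flatnonzero(coords <= coords.min() + depth)
            else:
                ids = np.flatnonzero(coords >= coords.max() - depth)
        else:
            raise ValueError(f"unknown stimulus kind {self.site_kind!r}")
        ids = ids[conducting[ids]]
        if ids.size == 0:
            raise ValueError("stimulus covers no conducting node")
        return ids


def sheet_point_protocol(model: TissueModel, ci_ms: float = 300.0,
                         n_s1: int = 2, s1_cl_ms: float = 500.0,
                         radius_mm: float = 1.0) -> PacingProtocol:
    """Point pacing from the centre of the sheet's upper-left quadrant
    (the proximal half), as in the 2D scenarios."""
    side = model.positions[:, 0].max()
    return PacingProtocol(n_s1=n_s1, s1_cl_ms=s1_cl_ms, ci_ms=ci_ms,
                          site_kind="point",
                          point_um=(side / 4.0, 3.0 * side / 4.0, 0.0),
                          radius_mm=radius_mm)


def cuboid_face_protocol(ci_ms: float = 300.0, n_s1: int = 2,
                         s1_cl_ms: float = 500.0) -> PacingProtocol:
    """Plane pacing along the x = 0 surface of the cuboid."""
    return PacingProtocol(n_s1=n_s1, s1_cl_ms=s1_cl_ms, ci_ms=ci_ms,
                          site_kind="face", face="x0")


@dataclass
class SimulationResult:
    """Streamed marker events plus run metadata.

    ``up_times``/``dn_times`` hold per-node threshold-crossing times
    (fixed capacity, valid entries given by the clipped counts);
    ``snap_t``/``snap_nodes``/``snap_v`` hold optional decimated V
    snapshots.
    """

    model: TissueModel
    protocol: PacingProtocol
    dt: float
    t_end: float
    at_mv: float
    rt_mv: float
    up_times: np.ndarray
    up_counts: np.ndarray
    dn_times: np.ndarray
    dn_counts: np.ndarray
    snap_t: Optional[np.ndarray] = None
    snap_nodes: Optional[np.ndarray] = None
    snap_v: Optional[np.ndarray] = None

    @property
    def t_s2(self) -> Optional[float]:
        return self.protocol.t_s2

    def event_times(self, node: int, kind: str = "up") -> np.ndarray:
        times, counts = ((self.up_times, self.up_counts) if kind == "up"
                         else (self.dn_times, self.dn_counts))
        c = min(int(counts[node]), times.shape[1])
        return times[node, :c]

    def first_crossing_after(self, t0: float, kind: str = "up") -> np.ndarray:
        """Per-node first up/down crossing at or after ``t0`` (NaN if none)."""
        times, counts = ((self.up_times, self.up_counts) if kind == "up"
                         else (self.dn_times, self.dn_counts))
        cap = times.shape[1]
        out = np.full(times.shape[0], np.nan)
        for k in range(cap):
            valid = (counts > k) & np.isnan(out)
            cand = times[:, k]
            hit = valid & (cand >= t0)
            out[hit] = cand[hit]
        return out


_PREPACE_CACHE: Dict[tuple, np.ndarray] = {}


def _prepaced_state(params: CellParams, cl_ms: float, n_beats: int,
                    dt: float):
    """Single-cell (V, S-row) after ``n_beats`` paced beats: the tissue
    initial condition for that region (diastolic phase, ready for S1)."""
    key = (params, cl_ms, n_beats, dt)
    if key not in _PREPACE_CACHE:
        tab, k1tab = _tables(dt, params.subtype)
        gna, gkr, gks, gto = params.conductances()
        starts = np.arange(n_beats) * cl_ms
        n_steps = int(round(n_beats * cl_ms / dt))
        V, S = tt06.initial_state(1)
        _, _, failed = tt06.run_cell(
            V, S, np.full(1, gna), np.full(1, gkr),
            np.full(1, gks), np.full(1, gto), dt, n_steps, starts, 2.0,
            52.0, tab, k1tab, max(1, n_steps))
        if failed >= 0:
            raise FloatingPointError("pre-pacing blew up")
        _PREPACE_CACHE[key] = (float(V[0]), S[0].copy())
    v0, s0 = _PREPACE_CACHE[key]
    return v0, s0.copy()


def run_monodomain(
    model: TissueModel,
    protocol: PacingProtocol,
    cond: ConductivityField = ConductivityField(),
    cells: Optional[Dict[int, CellParams]] = None,
    t_end: Optional[float] = None,
    dt: float = 0.05,
    at_mv: float = -20.0,
    rt_mv: float = -70.0,
    n_prepace: int = 10,
    event_capacity: int = 8,
    record_nodes: Optional[np.ndarray] = None,
    record_dt: float = 1.0,
) -> SimulationResult:
    """Run the S1S2 monodomain simulation and stream AT/RT events.

    ``cells`` maps region label -> :class:`CellParams`; defaults come from
    :func:`rvimap.cell.make_region_params`. Each region's nodes start from
    that cell's single-cell paced limit cycle (``n_prepace`` beats at the
    S1 cycle length), so a short in-tissue S1 train suffices to reach the
    propagated steady state. Refuses to run if the explicit diffusion CFL
    bound is violated.
    """
    if model.shape is None:
        raise ValueError("the monodomain solver requires a structured grid")
    labels = model.labels
    present = np.unique(labels)
    if cells is None:
        cells = {}
    cells = dict(cells)
    for lab in present:
        if Region(lab) in (Region.SCAR, Region.LESION):
            continue
        cells.setdefault(int(lab), make_region_params(Region(lab)))

    n = model.n_nodes
    active = model.conducting_mask()
    sigma = cond.node_sigma(labels)
    D = sigma_to_diffusivity(sigma)
    dx_mm = model.dx_um / UM_PER_MM
    ndim = 3 if model.shape[2] > 1 else 2
    cfl = dt * D.max() * 2 * ndim / dx_mm ** 2
    if cfl > 1.0:
        raise ValueError(
            f"diffusion CFL violated (dt*D*2*ndim/dx^2 = {cfl:.2f} > 1); "
            "reduce dt or coarsen conservatively")

    gna = np.empty(n); gkr = np.empty(n); gks = np.empty(n); gto = np.empty(n)
    V, S = tt06.initial_state(n)
    subtype = None
    for lab in present:
        mask = labels == lab
        if Region(lab) in (Region.SCAR, Region.LESION):
            gna[mask] = gkr[mask] = gks[mask] = gto[mask] = 0.0
            continue
        p = cells[int(lab)]
        subtype = subtype or p.subtype
        a, b, c, d_ = p.conductances()
        gna[mask], gkr[mask], gks[mask], gto[mask] = a, b, c, d_
        v0, s0 = _prepaced_state(p, protocol.s1_cl_ms, n_prepace, dt)
        V[mask] = v0
        S[mask] = s0

    tab, k1tab = _tables(dt, subtype or "epi")
    stim_nodes = protocol.stim_node_ids(model)
    stim_starts = protocol.stim_times()
    if t_end is None:
        base = protocol.t_s2 if protocol.t_s2 is not None else (
            stim_starts.max() if stim_starts.size else 0.0)
        t_end = base + 700.0
    n_steps = int(round(t_end / dt))

    up_times = np.full((n, event_capacity), np.nan)
    dn_times = np.full((n, event_capacity), np.nan)
    up_counts = np.zeros(n, dtype=np.int64)
    dn_counts = np.zeros(n, dtype=np.int64)

    if record_nodes is not None:
        rec_nodes = np.asarray(record_nodes, dtype=np.int64)
        rec_every = max(1, int(round(record_dt / dt)))
        n_snap = n_steps // rec_every + 1
        rec_buf = np.empty((n_snap, rec_nodes.size))
        rec_t = np.empty(n_snap)
    else:
        rec_nodes = np.empty(0, dtype=np.int64)
        rec_every = 0
        rec_buf = np.empty((0, 0))
        rec_t = np.empty(0)

    W = face_weights(D, model.shape, dx_mm)
    failed = run_tissue(V, S, gna, gkr, gks, gto, active, W,
                        model.shape[0], model.shape[1], model.shape[2],
                        dt, n_steps, stim_nodes, stim_starts,
                        protocol.duration_ms, protocol.amplitude,
                        tab, k1tab, at_mv, rt_mv,
                        up_times, up_counts, dn_times, dn_counts,
                        rec_nodes, rec_every, rec_buf, rec_t)
    if failed >= 0:
        raise FloatingPointError(
            f"numerical blow-up at t = {failed * dt:.2f} ms")

    res = SimulationResult(
        model=model, protocol=protocol, dt=dt, t_end=t_end,
        at_mv=at_mv, rt_mv=rt_mv,
        up_times=up_times, up_counts=up_counts,
        dn_times=dn_times, dn_counts=dn_counts)
    if rec_every > 0:
        res.snap_t = rec_t
        res.snap_nodes = rec_nodes
        res.snap_v = rec_buf
    return res


def measure_cv(sigma_S_m: float = 0.1,
               params: Optional[CellParams] = None,
               length_mm: float = 10.0, width_mm: float = 1.0,
               dx_um: float = 200.0, dt: float = 0.05) -> float:
    """Plane-wave conduction velocity (m/s) on a homogeneous strip.

    A single S1 is delivered along the x = 0 face; CV is the probe
    separation over the AT difference between two mid-line probes at 30%
    and 60% of the strip length — clear of both the stimulus launch
    transient and the far-boundary collision acceleration. Raises if the
    wave never reaches the far probe.
    """
    from .geometry import TissueModel as _TM, _structured_positions

    params = params or make_region_params(Region.HEALTHY)
    nx = int(round(length_mm * UM_PER_MM / dx_um)) + 1
    ny = int(round(width_mm * UM_PER_MM / dx_um)) + 1
    shape = (nx, ny, 1)
    pos = _structured_positions(shape, dx_um)
    mdl = _TM(kind="structured-grid-2d", positions=pos,
              labels=np.full(nx * ny, int(Region.HEALTHY)),
              shape=shape, dx_um=dx_um)
    proto = PacingProtocol(n_s1=1, with_s2=False, site_kind="face", face="x0")
    res = run_monodomain(mdl, proto, ConductivityField(sigma_S_m=sigma_S_m),
                         cells={int(Region.HEALTHY): params},
                         t_end=length_mm / 0.05 + 50.0, dt=dt)
    iy = ny // 2
    idx = mdl.grid_index()
    flat = np.arange(mdl.n_nodes)
    probes = []
    ixs = [int(round(f * (nx - 1))) for f in (0.30, 0.60)]
    for ix in ixs:
        probes.append(flat[(idx[:, 0] == ix) & (idx[:, 1] == iy)][0])
    at = res.first_crossing_after(0.0, "up")
    if np.isnan(at[probes]).any():
        raise RuntimeError("wavefront failed to reach a CV probe")
    dist_mm = (ixs[1] - ixs[0]) * dx_um / UM_PER_MM
    return float(dist_mm / (at[probes[1]] - at[probes[0]]))  # mm/ms == m/s


class Outcome(str, Enum):
    NO_BLOCK = "NO_BLOCK"
    BDB = "BDB"                    # bi-directional block, failed reentry
    UDB_REENTRY = "UDB_REENTRY"    # uni-directional block with reentry
    UNDETERMINED = "UNDETERMINED"


@dataclass(frozen=True)
class OutcomeConfig:
    """Thresholds for the qualitative outcome classifier.

    ``block_jump_ms``: an adjacent conducting node pair whose S2
    activation times differ by more than this (or where only one of the
    two ever activates) marks a local conduction failure — a line-of-block
    segment. ``min_reentry_nodes`` guards against single-node artefacts.
    ``reactivation_deadtime_ms``: threshold crossings closer together than
    this are merged into one activation — cardiac tissue is absolutely
    refractory on this scale, so faster double-crossings are electrotonic
    notches near a block line, not re-excitation.
    """

    block_jump_ms: float = 25.0
    min_reentry_nodes: int = 5
    end_margin_ms: float = 30.0
    reactivation_deadtime_ms: float = 60.0


@dataclass
class OutcomeRecord:
    outcome: Outcome
    n_reactivated: int = 0
    n_blocked_pairs: int = 0
    n_activated: int = 0
    last_event_ms: float = np.nan
    detail: str = ""


def classify_events(at_s2: np.ndarray, n_post: np.ndarray,
                    pairs: np.ndarray, conducting: np.ndarray,
                    t_end: float, cfg: OutcomeConfig = OutcomeConfig()
                    ) -> OutcomeRecord:
    """Classify an S2 episode from per-node activation data.

    ``at_s2``: first post-S2 activation time per node (NaN if never);
    ``n_post``: number of post-S2 activations per node; ``pairs``:
    (m, 2) adjacent conducting node pairs. Reentry means repeated
    activation without further stimulation; block without reactivation is
    BDB; unbroken single activation everywhere is NO_BLOCK.
    """
    act = ~np.isnan(at_s2)
    n_act = int(np.count_nonzero(act & conducting))
    last = float(np.nanmax(at_s2)) if n_act else np.nan
    if n_act == 0:
        return OutcomeRecord(Outcome.UNDETERMINED, detail="no capture of S2")

    n_re = int(np.count_nonzero((n_post >= 2) & conducting))
    if n_re >= cfg.min_reentry_nodes:
        return OutcomeRecord(Outcome.UDB_REENTRY, n_reactivated=n_re,
                             n_activated=n_act, last_event_ms=last)

    u, v = pairs[:, 0], pairs[:, 1]
    both = act[u] & act[v]
    jump = np.zeros(pairs.shape[0], dtype=bool)
    jump[both] = np.abs(at_s2[u[both]] - at_s2[v[both]]) > cfg.block_jump_ms
    one_sided = act[u] ^ act[v]
    n_block = int(np.count_nonzero(jump | one_sided))

    if last > t_end - cfg.end_margin_ms:
        return OutcomeRecord(Outcome.UNDETERMINED, n_reactivated=n_re,
                             n_blocked_pairs=n_block, n_activated=n_act,
                             last_event_ms=last,
                             detail="activity still ongoing at t_end")
    if n_block > 0:
        return OutcomeRecord(Outcome.BDB, n_blocked_pairs=n_block,
                             n_activated=n_act, last_event_ms=last)
    return OutcomeRecord(Outcome.NO_BLOCK, n_activated=n_act,
                         last_event_ms=last)


def _adjacent_pairs(model: TissueModel) -> np.ndarray:
    g = sp.triu(edge_graph(model)).tocoo()
    pairs = np.column_stack([g.row, g.col])
    cond = model.conducting_mask()
    return pairs[cond[pairs[:, 0]] & cond[pairs[:, 1]]]


def classify_outcome(result: SimulationResult,
                     cfg: OutcomeConfig = OutcomeConfig()) -> OutcomeRecord:
    """Classify a simulated S1S2 episode as NO_BLOCK / BDB / UDB_REENTRY."""
    t_s2 = result.t_s2
    if t_s2 is None:
        raise ValueError("outcome classification requires an S2 stimulus")
    at_s2 = result.first_crossing_after(t_s2)
    cap = result.up_times.shape[1]
    n_nodes = result.model.n_nodes
    # count activations after S2, merging crossings within the dead time
    n_post = np.zeros(n_nodes, dtype=np.int64)
    last = np.full(n_nodes, -np.inf)
    for k in range(cap):
        tk = result.up_times[:, k]
        ok = (result.up_counts > k) & (tk >= t_s2) & (
            tk - last > cfg.reactivation_deadtime_ms)
        n_post[ok] += 1
        has = result.up_counts > k
        last[has] = tk[has]
    pairs = _adjacent_pairs(result.model)
    return classify_events(at_s2, n_post, pairs, result.model.conducting_mask(),
                           result.t_end, cfg)
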