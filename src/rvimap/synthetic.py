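"""Analytic AT/RT field generator: a paced wavefront with a line of block.

Emulates the premature-beat marker fields of the 2D sheet scenarios
without any PDE solve, so the RVI pipeline is testable in milliseconds.
Activation time is the geodesic travel time from the pacing origin on a
regular sampling lattice whose edges may not cross the (impassable)
line-of-block segment; tissue on the far side of the block is therefore
reached only by the detour around the segment ends. Repolarisation time
is AT plus the region APD: proximal (origin side of the block line)
versus distal.

The travel-time geodesic is computed by Dijkstra on the 8-neighbour
sampling lattice — that discrete metric is this fixture's definition of
travel time (closed-form checks in the tests use the same convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from .markers import MarkerMap

__all__ = ["BlockScenario", "generate_block_fields",
           "arrhythmogenic_scenario"]


@dataclass(frozen=True)
class BlockScenario:
    """Plane-wave-with-block scenario parameters.

    The block segment is horizontal at height ``block_y_mm``, spanning
    ``block_x_mm`` (a zero-length segment blocks nothing). The pacing
    origin must lie on the proximal side (y > block_y). ``cv_m_s`` is
    both the plane-wave speed and the detour speed; crossing the segment
    is impossible, so the distal side is reached around the segment ends
    with delay = extra path length / CV.
    """

    size_mm: tuple = (50.0, 50.0)
    origin_mm: tuple = (12.5, 37.5)
    cv_m_s: float = 0.5
    block_y_mm: float = 25.0
    block_x_mm: tuple = (0.0, 18.0)
    apd_proximal_ms: float = 250.0
    apd_distal_ms: float = 300.0
    distal_slow_factor: float = 5.0  # premature-wave slowing below the block

    def __post_init__(self):
        if self.cv_m_s <= 0:
            raise ValueError("CV must be positive")
        if min(self.apd_proximal_ms, self.apd_distal_ms) <= 0:
            raise ValueError("APDs must be positive")
        if not (0 <= self.block_y_mm <= self.size_mm[1]):
            raise ValueError("block segment outside the domain")
        if self.origin_mm[1] <= self.block_y_mm:
            raise ValueError("pacing origin must lie proximal to the block")


def arrhythmogenic_scenario(apd_distal_ms: float, ci_ms: float = 300.0,
                            mm_per_ms: float = 0.8,
                            **kw) -> BlockScenario:
    """Scenario whose block length scales with substrate arrhythmogenicity.

    In paced tissue the line of block extends over the region where the
    premature wavefront meets still-refractory long-APD tissue, so its
    length grows with the excess of the distal APD over the coupling
    interval. This helper encodes that coupling for the analytic
    fixture: block length = ``mm_per_ms * max(0, apd_distal - ci)``,
    anchored at the domain's left edge. Longer distal APD therefore
    means a longer detour, a larger conduction delay across the block,
    and a strictly lower minimum RVI.
    """
    base = BlockScenario(**kw)
    length = mm_per_ms * max(0.0, apd_distal_ms - ci_ms)
    length = min(length, 0.9 * base.size_mm[0])
    return BlockScenario(
        size_mm=base.size_mm, origin_mm=base.origin_mm, cv_m_s=base.cv_m_s,
        block_y_mm=base.block_y_mm, block_x_mm=(0.0, length),
        apd_proximal_ms=base.apd_proximal_ms, apd_distal_ms=apd_distal_ms,
        distal_slow_factor=base.distal_slow_factor)


def _edge_blocked(pu, pv, by, x0, x1):
    """True if lattice edge pu-pv crosses the horizontal block segment.

    Nodes exactly on the block line belong to the proximal (y >= by)
    side, so an edge from an on-line node down into distal tissue is
    blocked when its crossing abscissa falls within the segment.
    """
    su = pu[1] >= by
    sv = pv[1] >= by
    if su == sv:
        return False
    t = (by - pu[1]) / (pv[1] - pu[1])
    xc = pu[0] + t * (pv[0] - pu[0])
    return x0 <= xc <= x1


def generate_block_fields(scn: BlockScenario, pitch_mm: float = 1.0
                          ) -> MarkerMap:
    """Generate the marker map for a block scenario on a regular lattice.

    Deterministic; disconnected lattice nodes (possible only with a
    degenerate geometry) are flagged invalid (NaN markers).
    """
    if pitch_mm <= 0:
        raise ValueError("pitch must be positive")
    nx = int(round(scn.size_mm[0] / pitch_mm)) + 1
    ny = int(round(scn.size_mm[1] / pitch_mm)) + 1
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    pos = np.column_stack([ix.ravel() * pitch_mm, iy.ravel() * pitch_mm])
    n = pos.shape[0]

    x0, x1 = sorted(scn.block_x_mm)
    blocked = (x1 - x0) > 0

    # 8-neighbour lattice edges
    offsets = [(1, 0), (0, 1), (1, 1), (1, -1)]
    rows, cols = [], []
    flat = np.arange(n).reshape(nx, ny)
    for dx, dy in offsets:
        if dy >= 0:
            u = flat[:nx - dx or None, :ny - dy or None]
            v = flat[dx:, dy:]
        else:
            u = flat[:nx - dx or None, -dy:]
            v = flat[dx:, :ny + dy or None]
        rows.append(u.ravel())
        cols.append(v.ravel())
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    w = np.linalg.norm(pos[rows] - pos[cols], axis=1)

    if scn.distal_slow_factor != 1.0:
        mid_y = 0.5 * (pos[rows, 1] + pos[cols, 1])
        w = np.where(mid_y < scn.block_y_mm, w * scn.distal_slow_factor, w)

    if blocked:
        keep = np.array([
            not _edge_blocked(pos[r], pos[c], scn.block_y_mm, x0, x1)
            for r, c in zip(rows, cols)])
        rows, cols, w = rows[keep], cols[keep], w[keep]

    g = sp.coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    # travel time in ms: distance (mm) / CV (mm/ms == m/s)
    src = int(np.argmin(np.linalg.norm(pos - np.asarray(scn.origin_mm),
                                       axis=1)))
    dist = dijkstra(g, directed=False, indices=src)
    at = dist / scn.cv_m_s
    at[~np.isfinite(at)] = np.nan

    apd = np.where(pos[:, 1] >= scn.block_y_mm, scn.apd_proximal_ms,
                   scn.apd_distal_ms)
    rt = at + apd
    pos_um = np.column_stack([pos * 1000.0, np.zeros(n)])
    return MarkerMap(pos_um, at, rt,
                     meta={"scenario": scn, "pitch_mm": pitch_mm})
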