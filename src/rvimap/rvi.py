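"""The Reentry Vulnerability Index (RVI) algorithm.

For every recording site *i*, all sites *j* activated strictly later
(AT_j > AT_i) within a search radius r_s contribute

    RVI_ij = RT_i − AT_j,

the repolarisation margin of the earlier site against the later
activation: small or negative values mean the wavefront can find
re-excitable tissue — vulnerability to reentry. Each pair's value is
placed at the geometric midpoint of the pair, midpoints are aggregated
onto a regular spatial lattice, and each bin reports the mean of its
contributions. Summary statistics are the map minimum (RVI_min) and the
percentage of bins below 50 ms (RVI_%<50ms).

Surface mode restricts both *i* and *j* to the declared recording
surface (circular neighbourhoods, as on a mapping catheter); volume mode
uses all sites within a spherical neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.spatial import cKDTree

from .markers import MarkerMap

__all__ = [
    "RVIConfig",
    "RVIMap",
    "TargetRegion",
    "rvi_pair",
    "compute_rvi",
    "summarise",
    "subsample_electrodes",
    "extract_targets",
]

UM_PER_MM = 1.0e3


@dataclass(frozen=True)
class RVIConfig:
    """RVI computation parameters.

    ``search_radius_mm``: pair search radius r_s. ``mode``: ``"surface"``
    or ``"volume"``. ``electrode_pitch_mm``: regular subsampling pitch
    applied to the markers first (0 = use every site).
    ``bin_mm``: midpoint aggregation lattice spacing; ``None`` uses the
    marker-site pitch (median nearest-neighbour distance), which makes
    "the same location" well-defined on continuous midpoints.
    """

    search_radius_mm: float = 2.5
    mode: str = "surface"
    electrode_pitch_mm: float = 0.0
    low_threshold_ms: float = 50.0
    target_threshold_ms: float = 25.0
    bin_mm: Optional[float] = None

    def __post_init__(self):
        if self.search_radius_mm <= 0:
            raise ValueError("search radius must be positive")
        if self.mode not in ("surface", "volume"):
            raise ValueError("mode must be 'surface' or 'volume'")


@dataclass
class RVIMap:
    """Binned mean-RVI map.

    ``positions_um``: bin centres; ``values_ms``: per-bin mean RVI;
    ``n_pairs``: contributing pair count per bin. Only bins with at
    least one contribution are stored (the rest of space is masked).
    """

    positions_um: np.ndarray
    values_ms: np.ndarray
    n_pairs: np.ndarray
    bin_mm: float
    config: Optional[RVIConfig] = None
    meta: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return self.values_ms.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "x_um": self.positions_um[:, 0],
            "y_um": self.positions_um[:, 1],
            "z_um": self.positions_um[:, 2],
            "mean_rvi_ms": self.values_ms,
            "n_pairs": self.n_pairs,
        })

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    def summary(self, threshold_ms: float = 50.0) -> dict:
        rvi_min, pct = summarise(self, threshold_ms)
        return {"rvi_min_ms": rvi_min, f"pct_below_{threshold_ms:g}": pct,
                "n_bins": int(self.n_bins)}


def rvi_pair(rt_i_ms: float, at_j_ms: float) -> float:
    """RVI of one ordered site pair: RT_i − AT_j."""
    return rt_i_ms - at_j_ms


def _site_pitch_mm(pos_mm: np.ndarray) -> float:
    tree = cKDTree(pos_mm)
    d, _ = tree.query(pos_mm, k=2)
    return float(np.median(d[:, 1]))


def compute_rvi(markers: MarkerMap, cfg: RVIConfig = RVIConfig()) -> RVIMap:
    """Compute the binned mean-RVI map from an AT/RT marker map.

    Pair rule: *i* needs a valid RT, *j* a valid AT, AT_j strictly
    greater than AT_i (simultaneous activations contribute nothing), and
    ``|x_j − x_i| <= r_s`` in the exact Euclidean metric. Values land at
    pair midpoints and are averaged per lattice bin.
    """
    mk = markers
    if cfg.electrode_pitch_mm > 0:
        mk = subsample_electrodes(mk, cfg.electrode_pitch_mm)
    sel = mk.valid
    if cfg.mode == "surface":
        sel = sel & mk.surface
    idx = np.flatnonzero(sel)
    if idx.size < 2:
        raise ValueError("need at least two valid sites")

    pos_mm = mk.positions_um[idx] / UM_PER_MM
    at = mk.at_ms[idx]
    rt = mk.rt_ms[idx]
    has_rt = np.isfinite(rt)

    bin_mm = cfg.bin_mm if cfg.bin_mm else _site_pitch_mm(pos_mm)
    origin = pos_mm.min(axis=0)
    # lattice extents (midpoints lie within the site bounding box)
    nbin = np.floor((pos_mm.max(axis=0) - origin) / bin_mm).astype(np.int64) + 2
    n_flat = int(nbin.prod())
    sums = np.zeros(n_flat)
    cnts = np.zeros(n_flat, dtype=np.int64)

    tree = cKDTree(pos_mm)
    # chunked pair enumeration to bound memory on dense maps
    per_site = max(1, int(np.pi * (cfg.search_radius_mm / bin_mm) ** 3))
    chunk = min(idx.size, max(int(2e7 // per_site), 64))
    for lo in range(0, idx.size, chunk):
        hi = min(idx.size, lo + chunk)
        neigh = tree.query_ball_point(pos_mm[lo:hi], cfg.search_radius_mm)
        ii = np.concatenate(
            [np.full(len(nb), lo + a) for a, nb in enumerate(neigh)])
        jj = np.concatenate([np.asarray(nb, dtype=np.int64) for nb in neigh])
        keep = has_rt[ii] & (at[jj] > at[ii])
        ii, jj = ii[keep], jj[keep]
        if ii.size == 0:
            continue
        vals = rt[ii] - at[jj]
        mids = 0.5 * (pos_mm[ii] + pos_mm[jj])
        key = np.floor((mids - origin) / bin_mm).astype(np.int64)
        flat = (key[:, 0] * nbin[1] + key[:, 1]) * nbin[2] + key[:, 2]
        np.add.at(sums, flat, vals)
        np.add.at(cnts, flat, 1)

    used = np.flatnonzero(cnts)
    if used.size == 0:
        import warnings

        warnings.warn("no valid site pairs within the search radius; "
                      "empty RVI map")
        return RVIMap(np.empty((0, 3)), np.empty(0), np.empty(0, int),
                      bin_mm, cfg)

    kx, rem = np.divmod(used, nbin[1] * nbin[2])
    ky, kz = np.divmod(rem, nbin[2])
    keys = np.column_stack([kx, ky, kz])
    cnt = cnts[used]
    val = sums[used] / cnt
    # bin centres sit at half-offsets, so a lone neighbouring-site pair's
    # bin is centred on the pair midpoint; degenerate axes (all sites in
    # one plane, e.g. z on a surface map) keep the sites' coordinate
    centres = ((keys + 0.5) * bin_mm + origin) * UM_PER_MM
    degenerate = pos_mm.max(axis=0) == origin
    for ax in np.flatnonzero(degenerate):
        centres[:, ax] = origin[ax] * UM_PER_MM
    return RVIMap(centres, val, cnt, bin_mm, cfg,
                  meta={"n_sites": int(idx.size)})


def summarise(rvi_map: RVIMap, threshold_ms: float = 50.0):
    """(RVI_min, percentage of unmasked bins below ``threshold_ms``)."""
    if rvi_map.n_bins == 0:
        raise ValueError("empty RVI map has no summary statistics")
    v = rvi_map.values_ms
    return float(v.min()), float(100.0 * np.count_nonzero(v < threshold_ms)
                                 / v.size)


def subsample_electrodes(markers: MarkerMap, pitch_mm: float) -> MarkerMap:
    """Retain the site nearest each point of a regular ``pitch_mm``
    lattice — an idealised regular electrode array. No interpolation:
    the result is a subset of the original sites, deterministically
    chosen.
    """
    pos_mm = markers.positions_um / UM_PER_MM
    lo = pos_mm.min(axis=0)
    hi = pos_mm.max(axis=0)
    if pitch_mm <= 0:
        raise ValueError("pitch must be positive")
    axes = [np.arange(lo[d], hi[d] + 1e-9, pitch_mm) for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    tree = cKDTree(pos_mm)
    _, nearest = tree.query(grid)
    keep = np.unique(nearest)
    if keep.size < 2:
        raise ValueError("pitch larger than the domain leaves < 2 sites")
    return markers.subset(keep)


@dataclass
class TargetRegion:
    """A connected cluster of sub-threshold RVI bins (ablation target)."""

    bin_ids: np.ndarray
    positions_um: np.ndarray
    centroid_um: np.ndarray
    extent_um: np.ndarray
    min_rvi_ms: float

    @property
    def n_bins(self) -> int:
        return self.bin_ids.size


def extract_targets(rvi_map: RVIMap,
                    threshold_ms: float = 25.0) -> List[TargetRegion]:
    """Connected regions of bins with RVI below ``threshold_ms``.

    Bins are adjacent when within 1.5 bin spacings (8/26-connectivity on
    the aggregation lattice). Returns one region per connected component,
    largest first; an empty list is a valid result.
    """
    sel = np.flatnonzero(rvi_map.values_ms < threshold_ms)
    if sel.size == 0:
        return []
    pos = rvi_map.positions_um[sel]
    tree = cKDTree(pos)
    pairs = tree.query_pairs(1.8 * rvi_map.bin_mm * UM_PER_MM,
                             output_type="ndarray")
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    n = sel.size
    adj = sp.coo_matrix(
        (np.ones(pairs.shape[0]), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    n_comp, lab = connected_components(adj, directed=False)
    regions = []
    for c in range(n_comp):
        members = sel[lab == c]
        p = rvi_map.positions_um[members]
        regions.append(TargetRegion(
            bin_ids=members,
            positions_um=p,
            centroid_um=p.mean(axis=0),
            extent_um=p.max(axis=0) - p.min(axis=0),
            min_rvi_ms=float(rvi_map.values_ms[members].min())))
    regions.sort(key=lambda r: -r.n_bins)
    return regions
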