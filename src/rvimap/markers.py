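"""Activation/repolarisation marker maps for the premature (S2) beat.

A :class:`MarkerMap` holds, per recording site, the activation time (AT:
first upward crossing of −20 mV at or after the S2 stimulus) and
repolarisation time (RT: first downward crossing of −70 mV after that
activation). It is the sole input of the RVI computation and doubles as
the interchange container for clinical-style CSV recordings
(site_id, x_um, y_um, z_um, AT_ms, RT_ms, valid).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .cell import crossing_time

__all__ = ["MarkerMap", "extract_markers", "markers_from_history"]


@dataclass
class MarkerMap:
    """Per-site S2-beat AT/RT markers.

    ``at_ms``/``rt_ms`` are NaN where undefined; a site is *valid* when
    its AT is defined (sites never activated by the S2 beat are invalid
    and excluded from all downstream statistics). A site with valid AT
    but NaN RT may still serve as an AT donor in RVI pairs. ``surface``
    marks the recording-surface subset used in surface-mode RVI.
    """

    positions_um: np.ndarray
    at_ms: np.ndarray
    rt_ms: np.ndarray
    surface: Optional[np.ndarray] = None
    at_mv: float = -20.0
    rt_mv: float = -70.0
    beat: str = "S2"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions_um = np.asarray(self.positions_um, float).reshape(-1, 3)
        self.at_ms = np.asarray(self.at_ms, float).ravel()
        self.rt_ms = np.asarray(self.rt_ms, float).ravel()
        n = self.positions_um.shape[0]
        if self.at_ms.size != n or self.rt_ms.size != n:
            raise ValueError("positions/AT/RT length mismatch")
        if self.surface is None:
            self.surface = self.positions_um[:, 2] == 0.0
        self.surface = np.asarray(self.surface, bool).ravel()
        bad = np.isfinite(self.rt_ms) & np.isfinite(self.at_ms) & (
            self.rt_ms <= self.at_ms)
        if bad.any():
            raise ValueError("RT must exceed AT wherever both are defined")

    @property
    def n_sites(self) -> int:
        return self.positions_um.shape[0]

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.at_ms)

    @property
    def valid_rt(self) -> np.ndarray:
        return self.valid & np.isfinite(self.rt_ms)

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.positions_um[idx], self.at_ms[idx],
                         self.rt_ms[idx], surface=self.surface[idx],
                         at_mv=self.at_mv, rt_mv=self.rt_mv, beat=self.beat,
                         meta=dict(self.meta))

    def shifted(self, dt_ms: float) -> "MarkerMap":
        """Same markers with the time origin moved by ``dt_ms``."""
        return replace(self, at_ms=self.at_ms + dt_ms,
                       rt_ms=self.rt_ms + dt_ms)

    # ---------------------------------------------------------- interchange

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "site_id": np.arange(self.n_sites),
            "x_um": self.positions_um[:, 0],
            "y_um": self.positions_um[:, 1],
            "z_um": self.positions_um[:, 2],
            "AT_ms": self.at_ms,
            "RT_ms": self.rt_ms,
            "valid": self.valid.astype(int),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kw) -> "MarkerMap":
        df = pd.read_csv(path)
        pos = df[["x_um", "y_um", "z_um"]].to_numpy(float)
        at = df["AT_ms"].to_numpy(float)
        rt = df["RT_ms"].to_numpy(float)
        if "valid" in df:
            invalid = df["valid"].to_numpy() == 0
            at = np.where(invalid, np.nan, at)
            rt = np.where(invalid, np.nan, rt)
        return cls(pos, at, rt, **kw)


def extract_markers(result, beat_t0: Optional[float] = None) -> MarkerMap:
    """S2-beat markers from a solver result's streamed crossing events.

    AT is each node's first upward ``at_mv`` crossing at/after the S2
    onset (``beat_t0`` overrides, e.g. to extract an S1 beat); RT the
    first downward ``rt_mv`` crossing after that AT. Re-activations
    during reentry are deliberately ignored: the map describes the S2
    beat only. SCAR/LESION nodes are invalid.
    """
    if beat_t0 is None:
        beat_t0 = result.t_s2
        if beat_t0 is None:
            raise ValueError("result has no S2; pass beat_t0 explicitly")
    at = result.first_crossing_after(beat_t0, "up")
    rt = np.full_like(at, np.nan)
    dn_times, dn_counts = result.dn_times, result.dn_counts
    for k in range(dn_times.shape[1]):
        cand = dn_times[:, k]
        take = (dn_counts > k) & np.isnan(rt) & np.isfinite(at) & (cand > at)
        rt[take] = cand[take]
    conducting = result.model.conducting_mask()
    at[~conducting] = np.nan
    rt[~conducting] = np.nan
    return MarkerMap(result.model.positions, at, rt,
                     surface=result.model.surface_mask(),
                     at_mv=result.at_mv, rt_mv=result.rt_mv,
                     meta={"t_s2": beat_t0})


def markers_from_history(t_ms: np.ndarray, v_mv: np.ndarray,
                         positions_um: np.ndarray, beat_t0: float,
                         at_mv: float = -20.0, rt_mv: float = -70.0,
                         surface: Optional[np.ndarray] = None) -> MarkerMap:
    """Markers from a stored V history ``v_mv (n_times, n_sites)``.

    The slow-path equivalent of :func:`extract_markers` for externally
    recorded or snapshot data; crossing times are linearly interpolated
    between samples exactly as the solver's event stream.
    """
    v_mv = np.asarray(v_mv)
    n = v_mv.shape[1]
    at = np.full(n, np.nan)
    rt = np.full(n, np.nan)
    for k in range(n):
        a = crossing_time(t_ms, v_mv[:, k], at_mv, +1, beat_t0)
        if a is None:
            continue
        at[k] = a
        r = crossing_time(t_ms, v_mv[:, k], rt_mv, -1, a)
        if r is not None:
            rt[k] = r
    return MarkerMap(positions_um, at, rt, surface=surface,
                     at_mv=at_mv, rt_mv=rt_mv, meta={"t_s2": beat_t0})
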