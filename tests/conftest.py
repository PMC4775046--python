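"""Shared fixtures: small geometries and one cached small tissue run."""

import numpy as np
import pytest

from rvimap.geometry import build_2d_sheet, TissueModel
from rvimap.regions import Region
from rvimap.tissue import PacingProtocol, run_monodomain


@pytest.fixture(scope="session")
def tiny_sheet():
    """1 cm sheet at 1 mm spacing: 11 x 11 nodes."""
    return build_2d_sheet(1.0, 1000.0)


def make_strip(length_mm=6.0, width_mm=1.0, dx_um=200.0,
               label=Region.HEALTHY):
    from rvimap.geometry import _structured_positions

    nx = int(round(length_mm * 1000 / dx_um)) + 1
    ny = int(round(width_mm * 1000 / dx_um)) + 1
    shape = (nx, ny, 1)
    return TissueModel(kind="structured-grid-2d",
                       positions=_structured_positions(shape, dx_um),
                       labels=np.full(nx * ny, int(label)),
                       shape=shape, dx_um=dx_um)


@pytest.fixture(scope="session")
def strip_run():
    """One small paced S1S2 strip run with full decimated V snapshots.

    Shared by marker/stream-equality and RT-threshold tests; the strip is
    homogeneous so every node sees one clean propagated beat per
    stimulus.
    """
    model = make_strip(6.0, 1.0, 200.0)
    proto = PacingProtocol(n_s1=1, s1_cl_ms=500.0, ci_ms=300.0,
                           site_kind="face", face="x0")
    res = run_monodomain(model, proto, t_end=proto.t_s2 + 500.0, dt=0.05,
                         record_nodes=np.arange(model.n_nodes),
                         record_dt=0.05)
    return model, proto, res


@pytest.fixture()
def rng():
    return np.random.default_rng(20231107)
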