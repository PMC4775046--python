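"""Tissue region labels shared by every module.

A node carries exactly one label. SCAR and LESION are electrically inert:
they carry no ionic model and act as internal no-flux boundaries in the
monodomain solver. All other labels select an electrophysiology parameter
set (see :mod:`rvimap.cell`).
"""

from __future__ import annotations

from enum import IntEnum


class Region(IntEnum):
    HEALTHY = 0
    PROXIMAL = 1  # short-APD half of the 2D sheet
    DISTAL = 2    # long-APD half of the 2D sheet
    SCAR = 3      # necrotic, non-conducting
    BZ = 4        # border zone: remodelled, slow-conducting
    LESION = 5    # ablation lesion: insulating, non-conducting


#: Labels that conduct (carry an ionic model and couple diffusively).
CONDUCTING = frozenset({Region.HEALTHY, Region.PROXIMAL, Region.DISTAL, Region.BZ})

#: Labels that are electrically inert.
NON_CONDUCTING = frozenset({Region.SCAR, Region.LESION})


def is_conducting(labels):
    """Boolean mask of conducting nodes for an integer label array."""
    import numpy as np

    labels = np.asarray(labels)
    return (labels != Region.SCAR) & (labels != Region.LESION)
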