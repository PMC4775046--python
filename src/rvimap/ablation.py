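"""Simulated catheter ablation at RVI-identified targets.

Lesions are insulating spheres (optionally full-wall cylinders) grown
from surface centroids — electrically identical to necrotic scar. After
lesion creation, the pre-ablation inducing S1S2 protocol is repeated
verbatim; prevention means the outcome is no longer reentry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence
import warnings

import numpy as np

from .geometry import TissueModel, UM_PER_MM
from .regions import Region
from .rvi import RVIMap, TargetRegion, extract_targets
from .tissue import (OutcomeConfig, OutcomeRecord, PacingProtocol,
                     classify_outcome, run_monodomain)

__all__ = ["LesionSpec", "apply_lesions", "plan_lesions", "reinduction_test"]


@dataclass(frozen=True)
class LesionSpec:
    """One ablation lesion.

    ``shape='sphere'``: all tissue within ``radius_mm`` of the centre.
    ``shape='cylinder_z'``: a full-wall cylinder of that radius (clinical
    lesions aim to be transmural; in a wall thicker than the radius a
    sphere from the surface is not).
    """

    centre_um: tuple
    radius_mm: float = 3.5
    shape: str = "sphere"

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be positive")
        if self.shape not in ("sphere", "cylinder_z"):
            raise ValueError("shape must be 'sphere' or 'cylinder_z'")


def apply_lesions(model: TissueModel, lesions: Sequence[LesionSpec],
                  protocol: Optional[PacingProtocol] = None) -> TissueModel:
    """Relabel all conducting tissue inside the lesions as LESION.

    SCAR nodes are left untouched; overlapping lesions union. If a
    ``protocol`` is given and a lesion swallows its stimulus site
    entirely, a warning is raised (the protocol would no longer capture).
    """
    labels = model.labels.copy()
    conducting = model.conducting_mask()
    covered = np.zeros(model.n_nodes, dtype=bool)
    for les in lesions:
        c = np.asarray(les.centre_um, dtype=float)
        if les.shape == "sphere":
            d = np.linalg.norm(model.positions - c, axis=1)
        else:
            d = np.linalg.norm(model.positions[:, :2] - c[:2], axis=1)
        covered |= d <= les.radius_mm * UM_PER_MM
    labels[covered & conducting] = Region.LESION
    out = model.with_labels(labels)
    if protocol is not None:
        try:
            protocol.stim_node_ids(out)
        except ValueError:
            warnings.warn("lesion covers the entire stimulus site; "
                          "the pacing protocol will fail to capture")
    return out


def plan_lesions(targets: Sequence[TargetRegion] | RVIMap,
                 radius_mm: float = 3.5, shape: str = "sphere",
                 threshold_ms: float = 25.0) -> List[LesionSpec]:
    """Greedy lesion cover of the sub-threshold target regions.

    For each target region, lesions are placed at the surface projection
    of the bin containing the most uncovered sub-threshold bins within
    the lesion radius, repeating until the region is covered — the rule
    a proceduralist would follow when one lesion footprint cannot span a
    target.
    """
    if isinstance(targets, RVIMap):
        targets = extract_targets(targets, threshold_ms)
    lesions: List[LesionSpec] = []
    r_um = radius_mm * UM_PER_MM
    for region in targets:
        pos = np.asarray(region.positions_um, dtype=float).reshape(-1, 3)
        uncovered = np.ones(pos.shape[0], dtype=bool)
        while uncovered.any():
            cand = pos[uncovered]
            # pick the candidate bin covering the most uncovered bins
            d = np.linalg.norm(cand[:, None, :] - pos[None, :, :], axis=2)
            cover = (d <= r_um) & uncovered[None, :]
            best = int(np.argmax(cover.sum(axis=1)))
            centre = cand[best].copy()
            centre[2] = 0.0  # lesion grown from the recording surface
            lesions.append(LesionSpec(tuple(centre), radius_mm, shape))
            uncovered &= ~cover[best]
    return lesions


def reinduction_test(model_post: TissueModel, protocol: PacingProtocol,
                     outcome_cfg: OutcomeConfig = OutcomeConfig(),
                     **solver_kw) -> OutcomeRecord:
    """Repeat the inducing S1S2 protocol on the ablated model.

    Runs the monodomain solver with the *identical* protocol and
    classifies the outcome; ablation succeeded when the result is not
    UDB_REENTRY ("the activation died away"). A degenerate model whose
    stimulus site was entirely ablated cannot capture and comes back
    UNDETERMINED.
    """
    from .tissue import Outcome

    try:
        res = run_monodomain(model_post, protocol, **solver_kw)
    except ValueError as exc:
        if "stimulus covers no conducting node" in str(exc):
            return OutcomeRecord(Outcome.UNDETERMINED,
                                 detail="stimulus site fully ablated")
        raise
    return classify_outcome(res, outcome_cfg)
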