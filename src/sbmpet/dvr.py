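"""BP_ND -> DVR conversion against a whole-cerebellum reference region.

The distribution volume ratio referenced to a region R is

    DVR(v) = (BP_ND(v) + 1) / (BP_ND_R + 1)

where BP_ND_R is the arithmetic mean of the parametric BP_ND map over the
reference mask (a single scalar, so the reference-region mean of the output
is exactly 1). Voxels with BP_ND <= -1 are nonphysical; they are passed
through arithmetically but counted, because silently clipping them would
hide data problems upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .volumes import ParametricVolume, VoxelMask

logger = logging.getLogger(__name__)


@dataclass
class ReferenceRegion:
    """Reference-region definition (e.g. whole cerebellum) for DVR scaling."""

    mask: VoxelMask
    summary: str = "mean"

    def __post_init__(self) -> None:
        if self.summary != "mean":
            raise ValueError(f"unsupported reference summary {self.summary!r}")


def bp_to_dvr(bp: ParametricVolume, reference: ReferenceRegion) -> ParametricVolume:
    """Convert a parametric BP_ND map to a DVR map.

    Returns a volume with ``quantity="DVR"`` whose mean over the reference
    mask equals 1 by construction.
    """
    if bp.quantity != "BP_ND":
        raise ValueError(f"expected a BP_ND volume, got quantity={bp.quantity!r}")
    if reference.mask.grid_shape != bp.grid_shape:
        raise ValueError(
            f"reference mask grid {reference.mask.grid_shape} does not match "
            f"volume grid {bp.grid_shape}"
        )
    ref_values = reference.mask.flatten(bp.values)
    ref_mean = float(ref_values.mean())
    if ref_mean <= -1.0:
        raise ValueError(
            f"reference-region mean BP_ND = {ref_mean:.4f} <= -1; "
            "DVR denominator would be non-positive"
        )
    n_nonphysical = int(np.sum(bp.values <= -1.0))
    if n_nonphysical:
        logger.warning(
            "subject %s: %d voxels with BP_ND <= -1 (nonphysical DVR <= 0)",
            bp.subject_id,
            n_nonphysical,
        )
    dvr = (bp.values + 1.0) / (ref_mean + 1.0)
    return bp.with_values(dvr, quantity="DVR")
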