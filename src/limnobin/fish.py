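"""FISH census arithmetic.

Relative densities of hybridised cells are the product of the
probe-positive fraction of DAPI-stained objects on the filter section and
the DAPI direct count per mL; any filtration-volume/filter-area
calibration is assumed already folded into the DAPI count supplied in the
input table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass


@dataclass(frozen=True)
class FISHCount:
    sample_id: str
    depth_m: float
    probe_id: str
    fraction_of_dapi: float
    dapi_cells_per_ml: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_of_dapi <= 1.0:
            raise ValueError("fraction_of_dapi must be in [0, 1]")
        if self.dapi_cells_per_ml < 0:
            raise ValueError("counts must be >= 0")


def relative_density(count: FISHCount) -> float:
    """Cells/mL attributed to the probe: fraction-of-DAPI x DAPI count."""
    return count.fraction_of_dapi * count.dapi_cells_per_ml


def percent_of_group(probe_density: float, group_density: float) -> float:
    """Probe contribution as percent of a broader group's density."""
    if group_density <= 0:
        raise ValueError("group density must be > 0")
    pct = 100.0 * probe_density / group_density
    if pct > 100.0:
        warnings.warn(
            f"probe density exceeds group density ({pct:.1f}%); counting noise"
        )
    return pct
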