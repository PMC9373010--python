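"""FDG-PET lesion metrics: SUVmax, MTV at a fractional isocontour, and TLG.

Definitions follow the fixed-threshold convention used on clinical
workstations: SUVmax is the highest SUV inside the lesion ROI; the metabolic
tumor volume (MTV) sums the volume of all ROI voxels whose SUV exceeds a
fraction (default 40%) of SUVmax — no connected-component restriction, so
disjoint hot islands inside the ROI all count; total lesion glycolysis (TLG)
is MTV multiplied by the mean SUV of the included voxels.

MTV is reported in mL and TLG in g (SUV·mL), the field-standard units.
Input volumes are assumed to already be in SUV units; conversion from raw
activity, dose and body weight is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "SUVVolume",
    "LesionROI",
    "MetabolicMetrics",
    "suv_max",
    "metabolic_volume",
    "total_lesion_glycolysis",
    "compute_metrics",
]


@dataclass
class SUVVolume:
    """A 3D standardized-uptake-value image; ``voxel_volume`` in mm^3."""

    values: np.ndarray
    voxel_volume: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("SUV volume must be 3D")
        if np.any(self.values < 0):
            raise ValueError("SUV values must be nonnegative")
        if self.voxel_volume <= 0:
            raise ValueError("voxel_volume must be positive")


@dataclass
class LesionROI:
    """Boolean lesion mask on the same grid as its volume."""

    mask: np.ndarray
    provenance: Literal["manual", "synthetic"] = "synthetic"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class MetabolicMetrics:
    """The SUVmax / MTV / TLG triple plus the isocontour bookkeeping.

    Invariant: ``tlg == mtv * suvmean_included`` exactly, and
    ``suvmean_included <= suvmax``.
    """

    suvmax: float
    mtv: float  # mL
    tlg: float  # g (SUV * mL)
    suvmean_included: float
    threshold_fraction: float = 0.40


def _check(vol: SUVVolume, roi: LesionROI) -> None:
    if roi.mask.shape != vol.values.shape:
        raise ValueError("ROI and volume grids differ")
    if not roi.mask.any():
        raise ValueError("empty lesion ROI")


def suv_max(vol: SUVVolume, roi: LesionROI) -> float:
    """Highest SUV of the lesion as a whole."""
    _check(vol, roi)
    return float(vol.values[roi.mask].max())


def metabolic_volume(
    vol: SUVVolume,
    roi: LesionROI,
    fraction: float = 0.40,
    inclusive: bool = False,
) -> tuple[float, np.ndarray]:
    """MTV (mL) and the included-voxel mask at a ``fraction``·SUVmax isocontour.

    Inclusion is strict (SUV > threshold) by default, matching the "adding
    all the voxels larger than the threshold value" convention; set
    ``inclusive=True`` for SUV >= threshold.
    """
    _check(vol, roi)
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    threshold = fraction * suv_max(vol, roi)
    if inclusive:
        included = roi.mask & (vol.values >= threshold)
    else:
        included = roi.mask & (vol.values > threshold)
    mtv = float(included.sum()) * vol.voxel_volume / 1000.0
    return mtv, included


def total_lesion_glycolysis(
    vol: SUVVolume,
    roi: LesionROI,
    fraction: float = 0.40,
    inclusive: bool = False,
) -> float:
    """TLG = MTV x mean SUV over the included (isocontour) voxels."""
    mtv, included = metabolic_volume(vol, roi, fraction, inclusive)
    if not included.any():
        return 0.0
    return mtv * float(vol.values[included].mean())


def compute_metrics(
    vol: SUVVolume,
    roi: LesionROI,
    fraction: float = 0.40,
    inclusive: bool = False,
) -> MetabolicMetrics:
    """SUVmax, MTV and TLG for one lesion in a single pass."""
    smax = suv_max(vol, roi)
    mtv, included = metabolic_volume(vol, roi, fraction, inclusive)
    suvmean = float(vol.values[included].mean()) if included.any() else 0.0
    return MetabolicMetrics(
        suvmax=smax,
        mtv=mtv,
        tlg=mtv * suvmean,
        suvmean_included=suvmean,
        threshold_fraction=fraction,
    )
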