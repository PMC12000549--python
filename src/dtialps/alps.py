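"""The ALPS index: perivascular diffusivity relative to fiber-free axes.

At the body of the lateral ventricles the perivascular spaces run along
the x-axis, perpendicular both to the z-oriented projection fibers
(corticospinal tract) and the y-oriented association fibers (superior
longitudinal fasciculus).  The index is the ratio

    ALPS = mean(Dxx_projection, Dxx_association)
           / mean(Dyy_projection, Dzz_association)

where each term is the arithmetic mean of a diffusivity map over an ROI,
and the outer mean weights the two ROIs equally regardless of voxel count
(mean of two ROI means, never a voxel-pooled mean).  A value near 1
indicates no preferential diffusion along the perivascular axis; higher
values indicate more x-axis diffusion, read as better glymphatic transport.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dtialps.errors import InputError, RoiFailureError, UndefinedIndexError
from dtialps.roi import RoiMask, RoiSet
from dtialps.tensor import DiffusivityMaps


@dataclass
class AlpsResult:
    """Per-subject ALPS indices and the ROI means behind them.

    ``roi_means`` maps ``"<hemisphere>_<quantity>"`` (e.g. ``left_dxx_proj``)
    to the mean diffusivity in mm^2/s; ``voxel_counts`` is keyed the same
    way.  ``average`` is the arithmetic mean of the two hemispheric indices
    and is None when either side failed.
    """

    subject_id: str = ""
    method: str = "automatic"  # manual | automatic
    left: float | None = None
    right: float | None = None
    average: float | None = None
    roi_means: dict[str, float] = field(default_factory=dict)
    voxel_counts: dict[str, int] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def as_row(self) -> dict:
        row = {
            "subject_id": self.subject_id,
            "method": self.method,
            "alps_left": self.left,
            "alps_right": self.right,
            "alps_average": self.average,
            "flags": ";".join(self.flags),
        }
        row.update(self.roi_means)
        row.update({f"n_{k}": v for k, v in self.voxel_counts.items()})
        return row


def roi_mean(volume: np.ndarray, mask: RoiMask) -> float:
    """Arithmetic mean of ``volume`` over the mask voxels."""
    volume = np.asarray(volume, dtype=float)
    if volume.shape != mask.data.shape:
        raise InputError("map and mask shapes differ")
    if mask.voxel_count == 0:
        raise RoiFailureError(
            f"empty {mask.label} {mask.hemisphere} mask", mask_name=f"{mask.label}_{mask.hemisphere}"
        )
    return float(volume[mask.data].mean())


def compute_alps(
    maps: DiffusivityMaps,
    projection: RoiMask,
    association: RoiMask,
) -> tuple[float, dict[str, float], dict[str, int]]:
    """One-hemisphere ALPS index from the four ROI means.

    Returns ``(index, roi_means, voxel_counts)`` with keys
    ``dxx_proj, dxx_assoc, dyy_proj, dzz_assoc``.
    """
    means = {
        "dxx_proj": roi_mean(maps.dxx, projection),
        "dxx_assoc": roi_mean(maps.dxx, association),
        "dyy_proj": roi_mean(maps.dyy, projection),
        "dzz_assoc": roi_mean(maps.dzz, association),
    }
    counts = {
        "proj": projection.voxel_count,
        "assoc": association.voxel_count,
    }
    numerator = (means["dxx_proj"] + means["dxx_assoc"]) / 2.0
    denominator = (means["dyy_proj"] + means["dzz_assoc"]) / 2.0
    if denominator <= 0:
        raise UndefinedIndexError(
            f"non-positive ALPS denominator ({denominator:.3e} mm^2/s)"
        )
    return numerator / denominator, means, counts


def compute_bilateral(
    maps: DiffusivityMaps,
    rois: RoiSet,
    subject_id: str = "",
    method: str = "automatic",
) -> AlpsResult:
    """Left and right ALPS indices plus their average.

    A hemisphere whose ROIs fail (empty mask, non-positive denominator)
    yields None for that side; the average is then undefined and a flag is
    recorded, but the valid side is still reported.
    """
    result = AlpsResult(subject_id=subject_id, method=method)
    sides: dict[str, float | None] = {}
    for side in ("left", "right"):
        try:
            idx, means, counts = compute_alps(
                maps, rois[("projection", side)], rois[("association", side)]
            )
        except (RoiFailureError, UndefinedIndexError) as exc:
            sides[side] = None
            result.flags.append(f"{side}_failed:{exc}")
            continue
        sides[side] = idx
        result.roi_means.update({f"{side}_{k}": v for k, v in means.items()})
        result.voxel_counts.update({f"{side}_{k}": v for k, v in counts.items()})
    result.left, result.right = sides["left"], sides["right"]
    if result.left is not None and result.right is not None:
        result.average = (result.left + result.right) / 2.0
    else:
        result.flags.append("average_undefined")
    return result
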