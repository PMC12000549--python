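"""Projection and association ROI construction.

Two routes produce the four ROI masks (projection left/right, association
left/right) the ALPS index needs:

* **manual** — axis-aligned 6 x 6 x 6 mm cubes at rater-chosen world
  coordinates, rasterized by voxel-center inclusion with half-open bounds
  ``[center - edge/2, center + edge/2)``;
* **automatic** — atlas labels for the corticospinal tract (projection,
  z-oriented fibers) and superior longitudinal fasciculus (association,
  y-oriented fibers), restricted to an axial slab at the apex of the
  lateral ventricles, trimmed of voxels near the cortex, resampled into
  the subject's diffusion space through a single template-to-subject
  transform, and binarized.

World coordinates are mm in RAS+; voxel indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from dtialps.errors import GeometryError, InputError, RoiFailureError

LABELS = ("projection", "association")
HEMISPHERES = ("left", "right")


@dataclass
class RoiMask:
    """A binary ROI on some grid."""

    data: np.ndarray
    affine: np.ndarray
    label: str  # projection | association
    hemisphere: str  # left | right
    space: str = "subject"  # template | subject

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.label not in LABELS:
            raise InputError(f"label must be one of {LABELS}")
        if self.hemisphere not in HEMISPHERES:
            raise InputError(f"hemisphere must be one of {HEMISPHERES}")

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def save(self, path: str) -> None:
        img = nib.Nifti1Image(self.data.astype(np.uint8), self.affine)
        img.header["descrip"] = f"{self.label} {self.hemisphere} ({self.space})".encode()
        nib.save(img, path)


@dataclass
class RoiSet:
    """The four per-subject ROI masks keyed by (label, hemisphere)."""

    masks: dict[tuple[str, str], RoiMask]

    def __getitem__(self, key: tuple[str, str]) -> RoiMask:
        return self.masks[key]

    def hemisphere(self, side: str) -> dict[str, RoiMask]:
        return {label: self.masks[(label, side)] for label in LABELS}


@dataclass
class TransformSpec:
    """A template-to-subject spatial mapping.

    ``affine`` maps source-space world coordinates (mm) to target-space
    world coordinates.  ``displacement`` — optional dense field sampled on
    the target grid, shape ``target_shape + (3,)`` — instead gives, for each
    target voxel, the source-space world coordinate it pulls from (the
    convention of FSL warp fields).  ``target_affine``/``target_shape``
    define the output grid.
    """

    target_shape: tuple[int, int, int]
    target_affine: np.ndarray
    affine: np.ndarray | None = None
    displacement: np.ndarray | None = None
    source_space: str = "template"
    target_space: str = "subject"

    def __post_init__(self) -> None:
        self.target_affine = np.asarray(self.target_affine, dtype=float)
        if self.affine is not None:
            self.affine = np.asarray(self.affine, dtype=float)
            if abs(np.linalg.det(self.affine)) < 1e-12:
                raise InputError("transform affine is not invertible")
        if self.displacement is not None:
            self.displacement = np.asarray(self.displacement, dtype=float)
            if self.displacement.shape != tuple(self.target_shape) + (3,):
                raise InputError("displacement field does not match the target grid")
        if self.affine is None and self.displacement is None:
            raise InputError("transform needs an affine or a displacement field")

    def source_world_of_target_voxels(self, grid_shape: tuple[int, ...]) -> np.ndarray:
        """Source-space world coordinate pulled by each target voxel."""
        ii, jj, kk = np.meshgrid(*[np.arange(s) for s in grid_shape], indexing="ij")
        vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1).astype(float)
        world_t = vox @ self.target_affine.T  # (..., 4)
        if self.displacement is not None:
            return self.displacement
        inv = np.linalg.inv(self.affine)
        return (world_t @ inv.T)[..., :3]

    @classmethod
    def identity(cls, shape: tuple[int, int, int], affine: np.ndarray) -> "TransformSpec":
        return cls(target_shape=tuple(shape), target_affine=affine, affine=np.eye(4))


@dataclass
class RestrictionConfig:
    """Template-space restriction of atlas labels before transformation.

    ``slab_z_mm`` bounds (inferior, superior) the axial slab capturing the
    ventricle apex; ``max_lateral_mm`` drops voxels beyond that unsigned
    x-distance from the midline (cortex exclusion); ``threshold`` binarizes
    the resampled mask; ``min_voxels`` is the usability floor below which
    an ROI is declared failed.
    """

    slab_z_mm: tuple[float, float] = (-5.0, 5.0)
    max_lateral_mm: float = 32.0
    threshold: float = 0.5
    min_voxels: int = 2

    def __post_init__(self) -> None:
        lo, hi = self.slab_z_mm
        if not lo < hi:
            raise InputError("slab lower bound must be below the upper bound")
        if not 0.0 < self.threshold < 1.0:
            raise InputError("binarization threshold must lie in (0, 1)")


def build_manual_roi(
    center_mm: tuple[float, float, float],
    grid_shape: tuple[int, int, int],
    grid_affine: np.ndarray,
    label: str,
    hemisphere: str,
    edge_mm: float = 6.0,
) -> RoiMask:
    """Rasterize an axis-aligned cube of side ``edge_mm`` at ``center_mm``.

    A voxel belongs to the cube when its center falls in the half-open box
    ``[center - edge/2, center + edge/2)`` on every world axis.  On a 2 mm
    grid with the center on a voxel center this yields the canonical
    3 x 3 x 3 = 27 voxels.
    """
    grid_affine = np.asarray(grid_affine, dtype=float)
    center = np.asarray(center_mm, dtype=float)
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in grid_shape], indexing="ij")
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1).astype(float)
    world = (vox @ grid_affine.T)[..., :3]
    half = edge_mm / 2.0
    inside = np.all((world >= center - half) & (world < center + half), axis=-1)
    if not inside.any():
        raise GeometryError(f"manual cube at {tuple(center)} mm lies outside the grid")
    return RoiMask(inside, grid_affine, label=label, hemisphere=hemisphere, space="subject")


def apply_transform(
    mask: RoiMask,
    transform: TransformSpec,
    interpolation: str = "nearest",
    threshold: float = 0.5,
) -> RoiMask:
    """Resample a binary mask onto the transform's target grid.

    ``nearest`` keeps the mask binary directly; ``trilinear`` interpolates
    the 0/1 field and binarizes at ``threshold``.
    """
    if interpolation not in ("nearest", "trilinear"):
        raise InputError(f"unknown interpolation {interpolation!r}")
    if mask.space != transform.source_space:
        raise InputError(
            f"mask is in {mask.space!r} space but transform expects {transform.source_space!r}"
        )
    src_world = transform.source_world_of_target_voxels(transform.target_shape)
    inv_src = np.linalg.inv(mask.affine)
    ones = np.ones(src_world.shape[:-1] + (1,))
    src_vox = (np.concatenate([src_world, ones], axis=-1) @ inv_src.T)[..., :3]
    coords = np.moveaxis(src_vox, -1, 0)
    order = 0 if interpolation == "nearest" else 1
    values = ndimage.map_coordinates(
        mask.data.astype(float), coords, order=order, mode="constant", cval=0.0
    )
    out = values > 0.5 if interpolation == "nearest" else values >= threshold
    return RoiMask(
        out,
        transform.target_affine,
        label=mask.label,
        hemisphere=mask.hemisphere,
        space=transform.target_space,
    )


def restrict_labels(
    atlas: np.ndarray,
    atlas_affine: np.ndarray,
    codes: tuple[int, ...],
    restriction: RestrictionConfig,
) -> np.ndarray:
    """Binary template-space mask of ``codes`` inside the slab/lateral caps."""
    atlas = np.asarray(atlas)
    sel = np.isin(atlas, codes)
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in atlas.shape], indexing="ij")
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1).astype(float)
    world = (vox @ np.asarray(atlas_affine, dtype=float).T)[..., :3]
    lo, hi = restriction.slab_z_mm
    sel &= (world[..., 2] >= lo) & (world[..., 2] <= hi)
    sel &= np.abs(world[..., 0]) <= restriction.max_lateral_mm
    return sel


def build_automatic_rois(
    atlas: np.ndarray,
    atlas_affine: np.ndarray,
    slf_codes: dict[str, tuple[int, ...]],
    cst_codes: dict[str, tuple[int, ...]],
    restriction: RestrictionConfig,
    transform: TransformSpec,
    interpolation: str = "nearest",
) -> RoiSet:
    """Atlas labels -> restricted, subject-space, binarized ROI masks.

    ``slf_codes``/``cst_codes`` map hemisphere ("left"/"right") to atlas
    integer codes for the superior longitudinal fasciculus (association)
    and corticospinal tract (projection).  Raises :class:`RoiFailureError`
    naming the first mask whose voxel count falls below
    ``restriction.min_voxels`` — the subject is unusable, mirroring
    cohort-level exclusion of failed ROIs.
    """
    atlas = np.asarray(atlas)
    for side in HEMISPHERES:
        for codes in (slf_codes[side], cst_codes[side]):
            missing = [c for c in codes if not np.any(atlas == c)]
            if missing:
                raise InputError(f"atlas lacks requested label codes {missing}")
    masks: dict[tuple[str, str], RoiMask] = {}
    sources = {"association": slf_codes, "projection": cst_codes}
    for label, code_map in sources.items():
        for side in HEMISPHERES:
            restricted = restrict_labels(atlas, atlas_affine, tuple(code_map[side]), restriction)
            template_mask = RoiMask(
                restricted, atlas_affine, label=label, hemisphere=side, space="template"
            )
            subject_mask = apply_transform(
                template_mask, transform, interpolation=interpolation,
                threshold=restriction.threshold,
            )
            if subject_mask.voxel_count < restriction.min_voxels:
                raise RoiFailureError(
                    f"{label} {side} ROI has {subject_mask.voxel_count} voxels "
                    f"(minimum {restriction.min_voxels})",
                    mask_name=f"{label}_{side}",
                )
            masks[(label, side)] = subject_mask
    _warn_overlap(masks)
    return RoiSet(masks)


def _warn_overlap(masks: dict[tuple[str, str], RoiMask]) -> None:
    import logging

    for side in HEMISPHERES:
        overlap = masks[("projection", side)].data & masks[("association", side)].data
        if overlap.any():
            logging.getLogger(__name__).warning(
                "projection/association ROIs overlap in %d voxels (%s hemisphere)",
                int(overlap.sum()), side,
            )


def qc_rois(rois: RoiSet, maps) -> dict:
    """Per-mask voxel counts, diffusivity summaries, and QC flags."""
    report: dict = {"masks": {}, "flags": []}
    for (label, side), mask in rois.masks.items():
        name = f"{label}_{side}"
        entry: dict = {"voxel_count": mask.voxel_count}
        if mask.data.shape != maps.shape:
            raise InputError(f"mask {name} shape does not match the diffusivity maps")
        if mask.voxel_count == 0:
            entry["flags"] = ["empty"]
            report["flags"].append(f"{name}:empty")
        else:
            flags = []
            for mname, vol in (("dxx", maps.dxx), ("dyy", maps.dyy), ("dzz", maps.dzz)):
                vals = vol[mask.data]
                entry[f"{mname}_mean"] = float(vals.mean())
                entry[f"{mname}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
                n_neg = int((vals < 0).sum())
                if n_neg:
                    flags.append(f"negative_{mname}:{n_neg}")
            entry["flags"] = flags
            report["flags"].extend(f"{name}:{f}" for f in flags)
        report["masks"][name] = entry
    return report
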