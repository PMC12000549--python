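"""Per-voxel diffusion-tensor fitting from diffusion-weighted signals.

The fit is the standard log-linear least-squares inversion of the
mono-exponential tensor model

    S_k = S0 * exp(-b_k * g_k^T D g_k)

solved per voxel for the six unique tensor components and log(S0).  Only
the diagonal components Dxx, Dyy, Dzz feed the ALPS index, so the module
exposes :func:`extract_diagonal` to turn a fitted :class:`TensorField` into
:class:`DiffusivityMaps`.

Diffusivities are reported in the native acquisition axes with no tensor
reorientation; the ALPS ratio is axis-convention-sensitive (x = right-left,
y = anterior-posterior, z = inferior-superior), so a warning is emitted when
the voxel-to-world affine is rotated beyond a configurable angle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from dtialps.errors import InputError, RankDeficiencyError

# Columns of the log-linear design matrix, in order.
TENSOR_COMPONENTS = ("dxx", "dyy", "dzz", "dxy", "dxz", "dyz")


@dataclass
class DwiDataset:
    """A 4D diffusion-weighted acquisition.

    Parameters
    ----------
    signals : ndarray, shape (x, y, z, n_volumes)
        Non-negative magnitude signals.
    bvals : ndarray, shape (n_volumes,)
        b-values in s/mm^2.
    bvecs : ndarray, shape (n_volumes, 3)
        Unit gradient directions (ignored for b = 0 volumes).
    affine : ndarray, shape (4, 4)
        Voxel-to-world affine (RAS+ mm).
    mask : ndarray of bool, optional
        Brain mask; defaults to all voxels.
    """

    signals: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape == (3, len(self.bvals)) and self.bvecs.shape[0] != self.bvecs.shape[1]:
            self.bvecs = self.bvecs.T  # accept FSL row-major layout
        if self.signals.ndim != 4:
            raise InputError("signals must be a 4D (x, y, z, volume) array")
        if self.signals.shape[-1] != len(self.bvals) or self.bvecs.shape != (len(self.bvals), 3):
            raise InputError("bvals/bvecs do not match the number of volumes")
        if np.any(self.bvals < 0):
            raise InputError("negative b-values are not allowed")
        if np.any(self.signals < 0):
            raise InputError("signals must be non-negative")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.signals.shape[:3]:
                raise InputError("mask shape does not match the image grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.signals.shape[:3]


@dataclass
class TensorField:
    """Per-voxel symmetric tensor (mm^2/s) plus estimated S0.

    ``components`` stacks (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) on the last axis.
    ``flags`` marks voxels fitted on a reduced (positive-signal) subset or
    carrying a negative diagonal; values are kept as-is, never clamped.
    """

    components: np.ndarray  # (x, y, z, 6)
    s0: np.ndarray
    affine: np.ndarray
    flags: np.ndarray  # (x, y, z) bool
    mask: np.ndarray

    def component(self, name: str) -> np.ndarray:
        return self.components[..., TENSOR_COMPONENTS.index(name.lower())]


@dataclass
class DiffusivityMaps:
    """Co-registered Dxx/Dyy/Dzz scalar volumes (mm^2/s)."""

    dxx: np.ndarray
    dyy: np.ndarray
    dzz: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    provenance: str = "supplied"  # "fitted" | "supplied"
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dxx = np.asarray(self.dxx, dtype=float)
        self.dyy = np.asarray(self.dyy, dtype=float)
        self.dzz = np.asarray(self.dzz, dtype=float)
        if not (self.dxx.shape == self.dyy.shape == self.dzz.shape):
            raise InputError("Dxx/Dyy/Dzz must share one grid")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.dxx.shape

    def save(self, prefix: str) -> list[str]:
        """Write ``<prefix>_dxx.nii.gz`` etc.; returns the paths written."""
        paths = []
        for name, vol in (("dxx", self.dxx), ("dyy", self.dyy), ("dzz", self.dzz)):
            img = nib.Nifti1Image(vol.astype(np.float64), self.affine)
            img.header["descrip"] = f"dtialps {name} ({self.provenance})".encode()
            path = f"{prefix}_{name}.nii.gz"
            nib.save(img, path)
            paths.append(path)
        return paths


def _check_axis_alignment(affine: np.ndarray, max_angle_deg: float = 5.0) -> None:
    """Warn loudly if the grid axes are rotated relative to world axes."""
    rot = np.asarray(affine, dtype=float)[:3, :3]
    scales = np.linalg.norm(rot, axis=0)
    if np.any(scales == 0):
        raise InputError("degenerate affine: zero-length axis")
    cosines = np.abs(np.diag(rot) / scales)
    angles = np.degrees(np.arccos(np.clip(cosines, -1.0, 1.0)))
    if np.any(angles > max_angle_deg):
        warnings.warn(
            f"image axes rotated up to {angles.max():.1f} deg from world axes; "
            "the ALPS ratio assumes x/y/z are anatomically aligned",
            stacklevel=3,
        )


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Log-linear design: log S = X @ [log S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]."""
    b = np.asarray(bvals, dtype=float)[:, None]
    g = np.asarray(bvecs, dtype=float)
    return np.hstack(
        [
            np.ones_like(b),
            -b * g[:, [0]] ** 2,
            -b * g[:, [1]] ** 2,
            -b * g[:, [2]] ** 2,
            -2 * b * g[:, [0]] * g[:, [1]],
            -2 * b * g[:, [0]] * g[:, [2]],
            -2 * b * g[:, [1]] * g[:, [2]],
        ]
    )


def forward_signal(
    tensor: np.ndarray, bvals: np.ndarray, bvecs: np.ndarray, s0: float | np.ndarray = 1.0
) -> np.ndarray:
    """Predict DWI signals from a tensor: S = S0 exp(-b g^T D g).

    ``tensor`` may be a length-3 diagonal, a length-6 component vector
    (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz), or a full 3x3 symmetric matrix; any
    number of leading voxel dimensions is allowed.
    """
    bvals = np.asarray(bvals, dtype=float).ravel()
    bvecs = np.asarray(bvecs, dtype=float)
    if np.any(bvals < 0):
        raise InputError("negative b-values are not allowed")
    t = np.asarray(tensor, dtype=float)
    if t.shape[-1] == 3 and (t.ndim == 1 or t.shape[-2:] != (3, 3)):
        comps = np.concatenate([t, np.zeros(t.shape[:-1] + (3,))], axis=-1)
    elif t.shape[-2:] == (3, 3):
        comps = np.stack(
            [t[..., 0, 0], t[..., 1, 1], t[..., 2, 2], t[..., 0, 1], t[..., 0, 2], t[..., 1, 2]],
            axis=-1,
        )
    elif t.shape[-1] == 6:
        comps = t
    else:
        raise InputError("tensor must be diag(3), components(6), or a 3x3 matrix")
    X = design_matrix(bvals, bvecs)  # (n_vol, 7)
    log_atten = comps @ X[:, 1:].T  # (..., n_vol)
    return np.asarray(s0)[..., None] * np.exp(log_atten)


def fit_tensor_loglinear(dwi: DwiDataset, weighting: str = "wls") -> TensorField:
    """Fit the diffusion tensor per voxel by (weighted) log-linear least squares.

    OLS solves ``argmin ||log S - X beta||^2``; WLS weights each volume by
    the squared observed signal, the usual first-order variance
    stabilisation for log-transformed Rician data.  Voxels containing
    non-positive signals are fitted on their positive subset and flagged,
    as are voxels whose fitted diagonal goes negative.
    """
    if weighting not in ("ols", "wls"):
        raise InputError(f"unknown weighting {weighting!r}")
    _check_axis_alignment(dwi.affine)

    mask = dwi.mask if dwi.mask is not None else np.ones(dwi.shape, dtype=bool)
    if not mask.any():
        raise InputError("brain mask is empty")
    n_b0 = int(np.sum(dwi.bvals == 0))
    if n_b0 < 1:
        raise RankDeficiencyError("at least one b = 0 volume is required")
    # rank check on the diffusion-sensitising part of the design
    X = design_matrix(dwi.bvals, dwi.bvecs)
    if np.linalg.matrix_rank(X) < 7:
        raise RankDeficiencyError(
            "fewer than 6 non-collinear nonzero-b directions: tensor design is rank-deficient"
        )

    vox = dwi.signals[mask]  # (n_vox, n_vol)
    if np.any(vox[:, dwi.bvals == 0] <= 0):
        raise InputError("b = 0 signals must be strictly positive inside the mask")

    n_vox, n_vol = vox.shape
    betas = np.empty((n_vox, 7))
    reduced_flag = np.zeros(n_vox, dtype=bool)

    positive = vox > 0
    all_pos = positive.all(axis=1)
    logs = np.full_like(vox, np.nan)
    np.log(vox, out=logs, where=positive)

    if all_pos.any():
        y = logs[all_pos]
        if weighting == "ols":
            betas[all_pos] = np.linalg.lstsq(X, y.T, rcond=None)[0].T
        else:
            betas[all_pos] = _wls_batch(X, y, vox[all_pos] ** 2)
    bad = np.where(~all_pos)[0]
    for i in bad:
        keep = positive[i]
        Xi = X[keep]
        if np.linalg.matrix_rank(Xi) < 7:
            raise RankDeficiencyError(
                "voxel with non-positive signals leaves a rank-deficient design"
            )
        yi = logs[i, keep]
        if weighting == "ols":
            betas[i] = np.linalg.lstsq(Xi, yi, rcond=None)[0]
        else:
            betas[i] = _wls_batch(Xi, yi[None, :], vox[i, keep][None, :] ** 2)[0]
        reduced_flag[i] = True

    negative_diag = (betas[:, 1:4] < 0).any(axis=1)

    components = np.zeros(dwi.shape + (6,))
    s0 = np.zeros(dwi.shape)
    flags = np.zeros(dwi.shape, dtype=bool)
    components[mask] = betas[:, 1:]
    s0[mask] = np.exp(betas[:, 0])
    flags[mask] = reduced_flag | negative_diag
    return TensorField(components=components, s0=s0, affine=dwi.affine, flags=flags, mask=mask)


def _wls_batch(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Solve per-row weighted least squares: rows of y/w share the design X."""
    out = np.empty((y.shape[0], X.shape[1]))
    for i in range(y.shape[0]):
        sw = np.sqrt(w[i])
        out[i] = np.linalg.lstsq(X * sw[:, None], y[i] * sw, rcond=None)[0]
    return out


def extract_diagonal(field: TensorField) -> DiffusivityMaps:
    """Copy Dxx/Dyy/Dzz out of a fitted tensor field (provenance ``fitted``)."""
    if not np.all(np.isfinite(field.components[field.mask])):
        raise InputError("tensor field contains non-finite values inside the mask")
    return DiffusivityMaps(
        dxx=field.component("dxx").copy(),
        dyy=field.component("dyy").copy(),
        dzz=field.component("dzz").copy(),
        affine=field.affine,
        provenance="fitted",
        flags=field.flags.copy(),
    )


def load_fsl_bvals_bvecs(bval_path: str, bvec_path: str) -> tuple[np.ndarray, np.ndarray]:
    """Read FSL-style whitespace-separated bval/bvec text files."""
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return bvals, bvecs


def save_fsl_bvals_bvecs(bvals: np.ndarray, bvecs: np.ndarray, bval_path: str, bvec_path: str) -> None:
    np.savetxt(bval_path, np.asarray(bvals).reshape(1, -1), fmt="%.1f")
    np.savetxt(bvec_path, np.asarray(bvecs).T, fmt="%.8f")
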