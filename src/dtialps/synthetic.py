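"""Synthetic three-group cohort (PD / iRBD / HC) with imaging ground truth.

The simulator emulates the structure of a de-novo Parkinson's disease (PD),
isolated REM-sleep behavior disorder (iRBD), and healthy-control (HC)
study cohort:

* demographics (group sizes, age distributions, sex ratios),
* a latent per-subject ALPS index combining a group mean, a linear
  age decline, and between-subject noise,
* clinical scores (MoCA, MDS-UPDRS parts I-III with item-level part III)
  and DAT-SPECT specific-binding-ratio (SBR) Z-scores coupled to the
  latent ALPS through a Gaussian copula,
* per-subject diffusivity volumes in which anisotropic "projection"
  (z-oriented, corticospinal-tract-like) and "association" (y-oriented,
  superior-longitudinal-fasciculus-like) columns are painted into an
  isotropic background such that the true ALPS index equals the latent
  value exactly,
* a synthetic template-space atlas with distinct labels for the left and
  right tract columns, and small per-subject rigid template-to-subject
  transforms.

Every quantity needed to close the loop (true per-region diffusivities,
true ALPS, the true transform) is recorded in :class:`GroundTruth`, so the
downstream tensor-fit, ROI, ALPS, and statistics stages can be tested for
exact parameter recovery without any acquired data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from dtialps.errors import ConfigurationError, GeometryError, InputError
from dtialps.roi import RoiMask, TransformSpec, apply_transform
from dtialps.tensor import DiffusivityMaps, DwiDataset, forward_signal

GROUPS = ("PD", "iRBD", "HC")
ATLAS_CODES = {
    ("projection", "left"): 1,
    ("projection", "right"): 2,
    ("association", "left"): 3,
    ("association", "right"): 4,
}
EXCLUSION_REASONS = ("preprocessing_failure", "structural_abnormality", "head_position")

# MDS-UPDRS part III motor-examination items used by the subscores.
N_UPDRS3_ITEMS = 18


@dataclass
class CohortConfig:
    """Study-condition parameters for cohort metadata generation.

    Defaults reproduce the target study's demographic and clinical
    structure: final group sizes 79/57/48 (PD/iRBD/HC), group ages
    59.5 +/- 12.0, 66.5 +/- 7.2, 61.5 +/- 9.9 years, male fractions
    0.61/0.86/0.71, automatic-ROI ALPS group means 1.21/1.24/1.28 with an
    age decline of -0.008 index units per year, and clinical couplings in
    the observed r = 0.19-0.31 range (negative toward symptom burden,
    positive toward SBR Z-scores).
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"PD": 79, "iRBD": 57, "HC": 48}
    )
    age_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"PD": (59.5, 12.0), "iRBD": (66.5, 7.2), "HC": (61.5, 9.9)}
    )
    male_fraction: dict[str, float] = field(
        default_factory=lambda: {"PD": 0.61, "iRBD": 0.86, "HC": 0.71}
    )
    alps_group_means: dict[str, float] = field(
        default_factory=lambda: {"PD": 1.21, "iRBD": 1.24, "HC": 1.28}
    )
    age_slope_beta: float = -0.008  # index units per year
    noise_sd_index: float = 0.12  # between-subject SD of the latent index
    hemi_noise_sd: float = 0.02  # independent left/right deviation
    clinical_couplings: dict[str, float] = field(
        default_factory=lambda: {
            "updrs2": -0.36,
            "updrs3": -0.25,
            "sbr_putamen": 0.31,
            "sbr_caudate": 0.31,
        }
    )
    moca_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"PD": (24.7, 3.1), "iRBD": (23.7, 2.8), "HC": (25.6, 2.4)}
    )
    updrs1_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"PD": (5.8, 4.3), "iRBD": (7.5, 5.3), "HC": (3.0, 2.7)}
    )
    updrs2_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"PD": (7.5, 4.9), "iRBD": (2.6, 3.9), "HC": (0.7, 1.5)}
    )
    updrs3_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"PD": (30.3, 13.1), "iRBD": (6.1, 5.4), "HC": (3.4, 4.0)}
    )
    # SBR Z-score group means/SDs (lower = more nigrostriatal denervation)
    sbr_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"PD": (-2.0, 1.0), "iRBD": (-0.8, 1.0), "HC": (0.0, 1.0)}
    )
    sbr_asymmetry_sd: float = 0.4  # left/right half-difference of SBR Z-scores
    exclusion_rates: dict[str, float] = field(
        default_factory=lambda: {
            "preprocessing_failure": 12 / 209,
            "structural_abnormality": 1 / 209,
            "head_position": 12 / 209,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        for g in GROUPS:
            if g not in self.n_per_group or self.n_per_group[g] < 1:
                raise ConfigurationError(f"n_per_group[{g!r}] must be >= 1")
            if not 0.0 <= self.male_fraction[g] <= 1.0:
                raise ConfigurationError("male_fraction must lie in [0, 1]")
            if self.age_mean_sd[g][1] < 0:
                raise ConfigurationError("age SD must be >= 0")
        if self.noise_sd_index < 0 or self.hemi_noise_sd < 0:
            raise ConfigurationError("index noise SDs must be >= 0")
        for name, r in self.clinical_couplings.items():
            if abs(r) > 1:
                raise ConfigurationError(f"|coupling {name}| must be <= 1")
        for reason, rate in self.exclusion_rates.items():
            if reason not in EXCLUSION_REASONS:
                raise ConfigurationError(f"unknown exclusion reason {reason!r}")
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError("exclusion rates must lie in [0, 1]")
        if sum(self.exclusion_rates.values()) > 1.0:
            raise ConfigurationError("exclusion rates must sum to <= 1")
        self._copula_correlation()  # raises if not PSD

    def _copula_correlation(self) -> tuple[list[str], np.ndarray]:
        """Correlation matrix of [alps, couplings...]; must be PSD."""
        names = sorted(self.clinical_couplings)
        k = len(names) + 1
        corr = np.eye(k)
        for i, name in enumerate(names, start=1):
            corr[0, i] = corr[i, 0] = self.clinical_couplings[name]
        eigvals = np.linalg.eigvalsh(corr)
        if eigvals.min() < -1e-10:
            raise ConfigurationError(
                "clinical couplings do not form a positive semi-definite "
                f"correlation matrix (min eigenvalue {eigvals.min():.3g})"
            )
        return names, corr


@dataclass
class GeometryConfig:
    """Image-space parameters for the synthetic volumes.

    The grid is RAS+ with the world origin at the grid center, 2 mm
    isotropic voxels by default.  The projection and association regions
    are mirrored bounding boxes (mm, for the left hemisphere; x negated on
    the right) of z-elongated columns lateral to a midline ventricle slab.
    The acquisition emulates a 30-direction b = 1000 s/mm^2 protocol with
    one b = 0 volume.
    """

    shape: tuple[int, int, int] = (24, 24, 20)
    voxel_mm: float = 2.0
    ventricle_slab_z_mm: tuple[float, float] = (-5.0, 5.0)
    projection_box_mm: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"x": (-14.0, -7.0), "y": (-7.0, 7.0), "z": (-15.0, 15.0)}
    )
    association_box_mm: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"x": (-23.0, -16.0), "y": (-7.0, 7.0), "z": (-15.0, 15.0)}
    )
    cortex_margin_mm: float = 32.0  # |x| beyond this counts as near-cortex
    b_value: float = 1000.0  # s/mm^2
    n_directions: int = 30
    s0: float = 1000.0
    signal_noise_sd: float = 20.0  # Rician sigma (s0/50, i.e. SNR 50); 0 = noiseless
    # typical white-matter / background diffusivities, mm^2/s
    background_adc: float = 0.75e-3
    cross_fiber_adc: float = 0.8e-3  # Dyy in projection, Dzz in association
    along_fiber_adc: float = 1.6e-3  # Dzz in projection, Dyy in association
    transform_max_rotation_deg: float = 1.5
    transform_max_translation_mm: float = 2.0

    def validate(self) -> None:
        if self.b_value <= 0:
            raise GeometryError("b-value must be positive")
        if self.n_directions < 6:
            raise GeometryError("need >= 6 diffusion directions")
        half = np.array(self.shape) * self.voxel_mm / 2.0
        for name, box in (("projection", self.projection_box_mm),
                          ("association", self.association_box_mm)):
            for ax_i, ax in enumerate("xyz"):
                lo, hi = box[ax]
                if not lo < hi:
                    raise GeometryError(f"{name} box {ax} bounds are inverted")
                if lo < -half[ax_i] or hi > half[ax_i]:
                    raise GeometryError(f"{name} region extends outside the grid")
        if self._boxes_overlap():
            raise GeometryError("projection and association regions must be disjoint")

    def _boxes_overlap(self) -> bool:
        p, a = self.projection_box_mm, self.association_box_mm
        return all(p[ax][0] < a[ax][1] and a[ax][0] < p[ax][1] for ax in "xyz")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] *= self.voxel_mm
        aff[:3, 3] = -(np.array(self.shape) - 1) * self.voxel_mm / 2.0
        return aff

    def world_grid(self) -> np.ndarray:
        ii, jj, kk = np.meshgrid(*[np.arange(s) for s in self.shape], indexing="ij")
        vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1).astype(float)
        return (vox @ self.affine.T)[..., :3]

    def region_mask(self, label: str, hemisphere: str) -> np.ndarray:
        """Boolean template-space mask of one tract column."""
        box = self.projection_box_mm if label == "projection" else self.association_box_mm
        world = self.world_grid()
        sel = np.ones(self.shape, dtype=bool)
        for ax_i, ax in enumerate("xyz"):
            lo, hi = box[ax]
            if hemisphere == "right":
                if ax == "x":
                    lo, hi = -hi, -lo
            sel &= (world[..., ax_i] >= lo) & (world[..., ax_i] <= hi)
        return sel

    def gradient_table(self) -> tuple[np.ndarray, np.ndarray]:
        """One b = 0 volume plus ``n_directions`` Fibonacci-sphere directions."""
        n = self.n_directions
        i = np.arange(n) + 0.5
        phi = np.arccos(1 - 2 * i / n)
        theta = np.pi * (1 + 5 ** 0.5) * i
        dirs = np.stack(
            [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
        )
        bvals = np.concatenate([[0.0], np.full(n, self.b_value)])
        bvecs = np.vstack([[0.0, 0.0, 0.0], dirs])
        return bvals, bvecs


@dataclass
class GroundTruth:
    """Per-subject simulation truth for closed-loop testing."""

    subject_id: str
    alps_left: float
    alps_right: float
    # mm^2/s, keyed "<side>_<quantity>" as in AlpsResult.roi_means
    diffusivities: dict[str, float]
    transform: TransformSpec | None = None

    @property
    def alps_average(self) -> float:
        return (self.alps_left + self.alps_right) / 2.0

    def expected_index(self, side: str) -> float:
        """True ALPS recomputed from the true per-region diffusivities."""
        d = self.diffusivities
        num = (d[f"{side}_dxx_proj"] + d[f"{side}_dxx_assoc"]) / 2.0
        den = (d[f"{side}_dyy_proj"] + d[f"{side}_dzz_assoc"]) / 2.0
        return num / den

    def to_json(self) -> str:
        payload = {
            "subject_id": self.subject_id,
            "alps_left": self.alps_left,
            "alps_right": self.alps_right,
            "diffusivities": self.diffusivities,
        }
        if self.transform is not None and self.transform.affine is not None:
            payload["transform_affine"] = self.transform.affine.tolist()
        return json.dumps(payload, indent=1)


def generate_cohort_metadata(config: CohortConfig) -> pd.DataFrame:
    """Draw one subject table with latent ALPS and coupled clinical scores.

    The latent index is ``group_mean + beta * (age - cohort_mean_age) +
    noise``; clinical scores and SBR Z-scores share a Gaussian copula with
    the noise component at the configured correlations.  Deterministic
    given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    names, corr = config._copula_correlation()

    rows = []
    ages, groups = [], []
    for g in GROUPS:
        n = config.n_per_group[g]
        mu, sd = config.age_mean_sd[g]
        ages.append(rng.normal(mu, sd, n))
        groups += [g] * n
    ages = np.concatenate(ages)
    mean_age = ages.mean()
    n_total = len(ages)

    # joint latent draws: column 0 drives ALPS noise, others the couplings
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(corr.shape[0]))
    z = rng.standard_normal((n_total, corr.shape[0])) @ chol.T
    z_alps = z[:, 0]
    z_named = {name: z[:, i] for i, name in enumerate(names, start=1)}

    def zc(name: str) -> np.ndarray:
        # uncoupled scores fall back to independent standard normals
        return z_named.get(name, rng.standard_normal(n_total))

    males = np.concatenate(
        [rng.random(config.n_per_group[g]) < config.male_fraction[g] for g in GROUPS]
    )
    group_means = np.array([config.alps_group_means[g] for g in groups])
    latent = (
        group_means
        + config.age_slope_beta * (ages - mean_age)
        + config.noise_sd_index * z_alps
    )
    hemi = rng.normal(0.0, config.hemi_noise_sd, (n_total, 2))
    latent_left = latent + hemi[:, 0]
    latent_right = latent + hemi[:, 1]

    def _score(mean_sd_map, zcol, clip_lo=None, clip_hi=None, integer=False):
        mus = np.array([mean_sd_map[g][0] for g in groups])
        sds = np.array([mean_sd_map[g][1] for g in groups])
        vals = mus + sds * zcol
        if clip_lo is not None:
            vals = np.clip(vals, clip_lo, clip_hi)
        return np.rint(vals).astype(int) if integer else vals

    moca = _score(config.moca_mean_sd, rng.standard_normal(n_total), 0, 30, integer=True)
    updrs1 = _score(config.updrs1_mean_sd, rng.standard_normal(n_total), 0, 52, integer=True)
    updrs2 = _score(config.updrs2_mean_sd, -zc("updrs2"), 0, 52, integer=True)
    updrs3_latent = _score(config.updrs3_mean_sd, -zc("updrs3"), 0, 132)
    items = _updrs3_items(updrs3_latent, rng)

    sbr = {}
    for region in ("putamen", "caudate"):
        mus = np.array([config.sbr_mean_sd[g][0] for g in groups])
        sds = np.array([config.sbr_mean_sd[g][1] for g in groups])
        center = mus + sds * zc(f"sbr_{region}")
        asym = rng.normal(0.0, config.sbr_asymmetry_sd, n_total)
        sbr[f"sbr_{region}_left"] = center - asym
        sbr[f"sbr_{region}_right"] = center + asym

    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n_total)],
            "group": groups,
            "age": ages,
            "sex": np.where(males, "M", "F"),
            "sex_code": males.astype(int),
            "moca": moca,
            "updrs1_total": updrs1,
            "updrs2_total": updrs2,
            "updrs3_total": items.sum(axis=1),
            "latent_alps": latent,
            "latent_alps_left": latent_left,
            "latent_alps_right": latent_right,
            **sbr,
        }
    )
    for i in range(N_UPDRS3_ITEMS):
        table[f"updrs3_item{i + 1}"] = items[:, i]
    return table


def _updrs3_items(total_latent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Split a continuous part-III severity into 18 integer items (0-4 each).

    Item weights are Dirichlet-distributed per subject, so the item-level
    table is heterogeneous but the item sum tracks the latent severity.
    """
    n = len(total_latent)
    weights = rng.dirichlet(np.full(N_UPDRS3_ITEMS, 2.0), size=n)
    raw = weights * np.maximum(total_latent, 0.0)[:, None]
    return np.clip(np.rint(raw), 0, 4).astype(int)


def assign_exclusions(
    cohort: pd.DataFrame,
    rates: dict[str, float] | None = None,
    flags: pd.DataFrame | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Flag excluded subjects and produce the accounting.

    Either ``rates`` (per-reason probabilities; reasons mutually exclusive,
    assigned in the fixed order preprocessing failure -> structural
    abnormality -> head position) or an explicit ``flags`` table with
    columns ``subject_id`` and ``reason``.  Returns the cohort with
    ``excluded``/``exclusion_reason`` columns and a dict with per-reason,
    per-group, initial, and final counts.
    """
    out = cohort.copy()
    reason_col = np.array([""] * len(out), dtype=object)
    if flags is not None:
        dup = flags["subject_id"].duplicated()
        if dup.any():
            raise InputError(
                f"subjects flagged with multiple reasons: "
                f"{sorted(flags.loc[dup, 'subject_id'])}"
            )
        bad = set(flags["reason"]) - set(EXCLUSION_REASONS)
        if bad:
            raise InputError(f"unknown exclusion reasons {sorted(bad)}")
        lookup = dict(zip(flags["subject_id"], flags["reason"]))
        for i, sid in enumerate(out["subject_id"]):
            reason_col[i] = lookup.get(sid, "")
    else:
        rates = rates or {}
        for reason, rate in rates.items():
            if reason not in EXCLUSION_REASONS:
                raise InputError(f"unknown exclusion reason {reason!r}")
            if not 0.0 <= rate <= 1.0:
                raise InputError("exclusion rates must lie in [0, 1]")
        rng = np.random.default_rng(seed)
        u = rng.random(len(out))
        lower = np.zeros(len(out))
        for reason in EXCLUSION_REASONS:  # fixed assignment order
            rate = rates.get(reason, 0.0)
            hit = (u >= lower) & (u < lower + rate) & (reason_col == "")
            reason_col[hit] = reason
            lower += rate
    out["excluded"] = reason_col != ""
    out["exclusion_reason"] = reason_col

    accounting = {
        "initial": {g: int((out["group"] == g).sum()) for g in GROUPS},
        "excluded_by_reason": {
            r: int((reason_col == r).sum()) for r in EXCLUSION_REASONS
        },
        "excluded_by_group": {
            g: int(out.loc[out["group"] == g, "excluded"].sum()) for g in GROUPS
        },
        "final": {
            g: int(((out["group"] == g) & ~out["excluded"]).sum()) for g in GROUPS
        },
    }
    accounting["total_initial"] = sum(accounting["initial"].values())
    accounting["total_excluded"] = int(out["excluded"].sum())
    accounting["total_final"] = sum(accounting["final"].values())
    return out, accounting


def generate_atlas(geom: GeometryConfig) -> tuple[np.ndarray, np.ndarray]:
    """Template-space integer label volume (CST-like 1/2, SLF-like 3/4)."""
    geom.validate()
    atlas = np.zeros(geom.shape, dtype=np.int16)
    for (label, side), code in ATLAS_CODES.items():
        atlas[geom.region_mask(label, side)] = code
    return atlas, geom.affine


def generate_transforms(
    geom: GeometryConfig, subject_ids, seed: int = 0
) -> dict[str, TransformSpec]:
    """Small random rigid template-to-subject transforms, one per subject.

    Rotation about z up to ``transform_max_rotation_deg`` and translation
    up to ``transform_max_translation_mm`` per axis; deterministic by seed.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for sid in subject_ids:
        angle = np.radians(rng.uniform(-geom.transform_max_rotation_deg,
                                       geom.transform_max_rotation_deg))
        trans = rng.uniform(-geom.transform_max_translation_mm,
                            geom.transform_max_translation_mm, 3)
        c, s = np.cos(angle), np.sin(angle)
        aff = np.eye(4)
        aff[:2, :2] = [[c, -s], [s, c]]
        aff[:3, 3] = trans
        out[sid] = TransformSpec(
            target_shape=tuple(geom.shape), target_affine=geom.affine, affine=aff
        )
    return out


def _subject_region_masks(
    geom: GeometryConfig, transform: TransformSpec | None
) -> dict[tuple[str, str], np.ndarray]:
    """Tract-column masks on the subject grid (template masks pushed through
    the subject's true transform with nearest-neighbour resampling)."""
    masks = {}
    for (label, side) in ATLAS_CODES:
        template = geom.region_mask(label, side)
        if transform is None:
            masks[(label, side)] = template
        else:
            tm = RoiMask(template, geom.affine, label=label, hemisphere=side, space="template")
            masks[(label, side)] = apply_transform(tm, transform, "nearest").data
    return masks


def make_ground_truth(
    subject_id: str,
    alps_left: float,
    alps_right: float,
    geom: GeometryConfig,
    transform: TransformSpec | None = None,
) -> GroundTruth:
    """True per-region diffusivities realising the requested ALPS values.

    The cross-fiber diffusivities (Dyy in the projection column, Dzz in the
    association column) are fixed at ``geom.cross_fiber_adc``; Dxx in both
    columns is scaled so the true index equals the latent value exactly.
    """
    diff = {}
    for side, alps in (("left", alps_left), ("right", alps_right)):
        dxx = alps * geom.cross_fiber_adc
        diff[f"{side}_dxx_proj"] = dxx
        diff[f"{side}_dxx_assoc"] = dxx
        diff[f"{side}_dyy_proj"] = geom.cross_fiber_adc
        diff[f"{side}_dzz_assoc"] = geom.cross_fiber_adc
        diff[f"{side}_dzz_proj"] = geom.along_fiber_adc
        diff[f"{side}_dyy_assoc"] = geom.along_fiber_adc
    return GroundTruth(
        subject_id=subject_id,
        alps_left=alps_left,
        alps_right=alps_right,
        diffusivities=diff,
        transform=transform,
    )


def generate_subject_volumes(truth: GroundTruth, geom: GeometryConfig) -> DiffusivityMaps:
    """Paint the true per-region tensor diagonals into an isotropic background."""
    geom.validate()
    dxx = np.full(geom.shape, geom.background_adc)
    dyy = np.full(geom.shape, geom.background_adc)
    dzz = np.full(geom.shape, geom.background_adc)
    masks = _subject_region_masks(geom, truth.transform)
    for (label, side), mask in masks.items():
        if not mask.any():
            raise GeometryError(f"{label} {side} region fell outside the grid")
        d = truth.diffusivities
        if label == "projection":
            dxx[mask] = d[f"{side}_dxx_proj"]
            dyy[mask] = d[f"{side}_dyy_proj"]
            dzz[mask] = d[f"{side}_dzz_proj"]
        else:
            dxx[mask] = d[f"{side}_dxx_assoc"]
            dyy[mask] = d[f"{side}_dyy_assoc"]
            dzz[mask] = d[f"{side}_dzz_assoc"]
    return DiffusivityMaps(dxx=dxx, dyy=dyy, dzz=dzz, affine=geom.affine, provenance="supplied")


def generate_subject_dwi(
    truth: GroundTruth,
    geom: GeometryConfig,
    seed: int = 0,
    noise_model: str = "rician",
) -> DwiDataset:
    """Forward-model DWI signals from the true diagonal tensors.

    Noise: ``rician`` adds independent Gaussian noise of SD
    ``geom.signal_noise_sd`` to two quadrature channels and takes the
    magnitude; ``gaussian`` adds it to the magnitude directly.
    """
    if noise_model not in ("rician", "gaussian"):
        raise InputError(f"unknown noise model {noise_model!r}")
    maps = generate_subject_volumes(truth, geom)
    bvals, bvecs = geom.gradient_table()
    diag = np.stack([maps.dxx, maps.dyy, maps.dzz], axis=-1)
    signals = forward_signal(diag, bvals, bvecs, s0=np.full(geom.shape, geom.s0))
    sigma = geom.signal_noise_sd
    if sigma > 0:
        rng = np.random.default_rng(seed)
        if noise_model == "rician":
            real = signals + rng.normal(0, sigma, signals.shape)
            imag = rng.normal(0, sigma, signals.shape)
            signals = np.hypot(real, imag)
        else:
            signals = np.maximum(signals + rng.normal(0, sigma, signals.shape), 0.0)
    return DwiDataset(signals=signals, bvals=bvals, bvecs=bvecs, affine=geom.affine)


def simulate_cohort(
    config: CohortConfig | None = None,
    geom: GeometryConfig | None = None,
    with_transforms: bool = True,
) -> tuple[pd.DataFrame, dict[str, GroundTruth], np.ndarray, np.ndarray]:
    """Convenience wrapper: metadata + per-subject truth + atlas.

    Returns ``(cohort_table, truths, atlas, atlas_affine)``.  Volumes are
    produced on demand with :func:`generate_subject_volumes` /
    :func:`generate_subject_dwi` from the returned truths.
    """
    config = config or CohortConfig()
    geom = geom or GeometryConfig()
    cohort = generate_cohort_metadata(config)
    atlas, atlas_affine = generate_atlas(geom)
    transforms = (
        generate_transforms(geom, cohort["subject_id"], seed=config.seed + 1)
        if with_transforms
        else {sid: None for sid in cohort["subject_id"]}
    )
    truths = {
        row.subject_id: make_ground_truth(
            row.subject_id,
            row.latent_alps_left,
            row.latent_alps_right,
            geom,
            transforms[row.subject_id],
        )
        for row in cohort.itertuples()
    }
    return cohort, truths, atlas, atlas_affine
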