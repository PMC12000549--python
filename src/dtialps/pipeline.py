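"""End-to-end orchestration: simulate -> fit -> ROI -> ALPS -> statistics.

The pipeline runs a synthetic three-group cohort through the full ALPS
analysis and emits a demographics-and-indices report shaped like a study
summary table (per-group mean +/- SD of age-adjusted indices, inter-group
ANCOVA p and partial eta^2, LSD pairwise p) plus a manual-vs-automatic
reliability section (paired t with Cohen's d, Pearson r, Bland-Altman in
numeric and percent mode).  Every run writes a JSON manifest with the
config hash, software version, per-file checksums, and the exclusion
accounting; deterministic stages are bit-identical across reruns of the
same seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from dtialps import stats as cs
from dtialps._version import __version__ as _version
from dtialps.alps import compute_bilateral
from dtialps.errors import ConfigurationError, RoiFailureError, SchemaError, UndefinedIndexError
from dtialps.roi import (
    RestrictionConfig,
    RoiSet,
    build_automatic_rois,
    build_manual_roi,
)
from dtialps.synthetic import (
    ATLAS_CODES,
    CohortConfig,
    GeometryConfig,
    assign_exclusions,
    generate_atlas,
    generate_cohort_metadata,
    generate_subject_dwi,
    generate_subject_volumes,
    generate_transforms,
    make_ground_truth,
)
from dtialps.tensor import extract_diagonal, fit_tensor_loglinear

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "alps", "stats", "report")


@dataclass
class PipelineConfig:
    """Everything one run needs; serialisable to/from YAML or JSON."""

    output_dir: str = "dtialps_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    cohort: CohortConfig = field(default_factory=CohortConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    restriction: RestrictionConfig = field(default_factory=RestrictionConfig)
    use_dwi: bool = False  # simulate raw DWI and fit tensors instead of using maps
    tensor_weighting: str = "wls"
    cohens_d_variant: str = "average_variance"
    matching_age_tolerance: float = 8.0
    apply_exclusions: bool = True
    write_volumes: bool = False  # write per-subject NIfTI maps (off: in-memory)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages {sorted(unknown)}")
        # seeds derived from the master seed keep every stage deterministic
        self.cohort.seed = self.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        for key, typ in (("cohort", CohortConfig), ("geometry", GeometryConfig),
                         ("restriction", RestrictionConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = dict(kwargs[key])
                # YAML gives lists where dataclasses expect tuples
                for k, v in sub.items():
                    if isinstance(v, list):
                        sub[k] = tuple(v)
                    elif isinstance(v, dict):
                        sub[k] = {
                            kk: tuple(vv) if isinstance(vv, list) else vv
                            for kk, vv in v.items()
                        }
                kwargs[key] = typ(**sub)
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stages_run: list[str]
    outputs: dict[str, str]  # path -> sha256
    exclusion_accounting: dict
    stage_failures: dict[str, str]
    started: float = 0.0
    finished: float = 0.0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def atlas_code_maps() -> tuple[dict, dict]:
    slf = {side: (ATLAS_CODES[("association", side)],) for side in ("left", "right")}
    cst = {side: (ATLAS_CODES[("projection", side)],) for side in ("left", "right")}
    return slf, cst


def manual_roi_centers(geom: GeometryConfig, transform) -> dict[tuple[str, str], np.ndarray]:
    """Rater-emulating cube centers: transformed centers of the tract columns
    at the ventricle-apex level (z = slab midpoint)."""
    z_mid = float(np.mean(geom.ventricle_slab_z_mm))
    centers = {}
    for label in ("projection", "association"):
        box = geom.projection_box_mm if label == "projection" else geom.association_box_mm
        cx = float(np.mean(box["x"]))
        cy = float(np.mean(box["y"]))
        for side in ("left", "right"):
            c = np.array([cx if side == "left" else -cx, cy, z_mid, 1.0])
            if transform is not None and transform.affine is not None:
                c = transform.affine @ c
            centers[(label, side)] = c[:3]
    return centers


def _subject_maps(truth, config: PipelineConfig, seed: int):
    if config.use_dwi:
        dwi = generate_subject_dwi(truth, config.geometry, seed=seed)
        return extract_diagonal(fit_tensor_loglinear(dwi, weighting=config.tensor_weighting))
    return generate_subject_volumes(truth, config.geometry)


def run_pipeline(config: PipelineConfig) -> tuple[RunManifest, dict]:
    """Execute the enabled stages in order; returns (manifest, results).

    ``results`` carries the in-memory artifacts: ``cohort`` (DataFrame),
    ``alps`` (long DataFrame over methods), ``stats`` and ``report``
    dicts.  Subjects whose ROI or index computation fails are dropped with
    a named reason and surface in ``stage_failures`` and the accounting.
    """
    started = time.time()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    stage_failures: dict[str, str] = {}
    results: dict = {}
    accounting: dict = {}

    if "simulate" not in config.stages and any(
        s in config.stages for s in ("alps", "stats", "report")
    ):
        # downstream stages need the simulated inputs to exist already
        cohort_path = out_dir / "cohort.csv"
        if not cohort_path.exists():
            raise ConfigurationError(
                "stage 'simulate' is disabled but no cohort.csv exists in the output directory"
            )

    cohort = truths = atlas = atlas_affine = transforms = None
    if "simulate" in config.stages:
        cohort = generate_cohort_metadata(config.cohort)
        if config.apply_exclusions:
            cohort, accounting = assign_exclusions(
                cohort, rates=config.cohort.exclusion_rates, seed=config.seed + 17
            )
        else:
            cohort, accounting = assign_exclusions(cohort, rates={}, seed=config.seed + 17)
        atlas, atlas_affine = generate_atlas(config.geometry)
        transforms = generate_transforms(
            config.geometry, cohort["subject_id"], seed=config.seed + 1
        )
        truths = {
            row.subject_id: make_ground_truth(
                row.subject_id, row.latent_alps_left, row.latent_alps_right,
                config.geometry, transforms[row.subject_id],
            )
            for row in cohort.itertuples()
        }
        cohort_path = out_dir / "cohort.csv"
        cohort.to_csv(cohort_path, index=False)
        outputs[str(cohort_path)] = _sha256(cohort_path)
        atlas_path = out_dir / "atlas_labels.nii.gz"
        nib.save(nib.Nifti1Image(atlas, atlas_affine), atlas_path)
        outputs[str(atlas_path)] = _sha256(atlas_path)
        truth_path = out_dir / "ground_truth.json"
        truth_path.write_text(
            json.dumps({sid: json.loads(t.to_json()) for sid, t in truths.items()}, indent=1)
        )
        outputs[str(truth_path)] = _sha256(truth_path)
        results["cohort"] = cohort
        results["accounting"] = accounting
    else:
        cohort = pd.read_csv(out_dir / "cohort.csv")
        results["cohort"] = cohort

    if "alps" in config.stages:
        if truths is None:
            raise ConfigurationError("the 'alps' stage requires the simulate stage in this run")
        slf_codes, cst_codes = atlas_code_maps()
        rows = []
        included = cohort[~cohort["excluded"]] if "excluded" in cohort.columns else cohort
        for i, row in enumerate(included.itertuples()):
            sid = row.subject_id
            truth = truths[sid]
            maps = _subject_maps(truth, config, seed=config.seed + 1000 + i)
            if config.write_volumes:
                for p in maps.save(str(out_dir / sid)):
                    outputs[p] = _sha256(Path(p))
            try:
                auto_rois = build_automatic_rois(
                    atlas, atlas_affine, slf_codes, cst_codes,
                    config.restriction, truth.transform,
                )
            except RoiFailureError as exc:
                stage_failures[sid] = f"roi_failure:{exc.mask_name}"
                log.warning("subject %s dropped: %s", sid, exc)
                continue
            manual_masks = {}
            centers = manual_roi_centers(config.geometry, truth.transform)
            for (label, side), center in centers.items():
                manual_masks[(label, side)] = build_manual_roi(
                    tuple(center), config.geometry.shape, config.geometry.affine,
                    label=label, hemisphere=side,
                )
            for method, rois in (
                ("automatic", auto_rois),
                ("manual", RoiSet(manual_masks)),
            ):
                try:
                    res = compute_bilateral(maps, rois, subject_id=sid, method=method)
                except UndefinedIndexError as exc:
                    stage_failures[sid] = f"undefined_index:{method}"
                    log.warning("subject %s %s index undefined: %s", sid, method, exc)
                    continue
                rows.append(res.as_row())
        if not rows:
            raise RuntimeError("ALPS stage failed for every subject")
        alps_df = pd.DataFrame(rows)
        alps_path = out_dir / "alps.csv"
        alps_df.to_csv(alps_path, index=False)
        outputs[str(alps_path)] = _sha256(alps_path)
        results["alps"] = alps_df

    if "stats" in config.stages:
        if "alps" not in results:
            raise ConfigurationError("the 'stats' stage requires ALPS results")
        results["stats"] = compute_statistics(
            results["cohort"], results["alps"],
            d_variant=config.cohens_d_variant,
        )
        stats_path = out_dir / "stats.json"
        stats_path.write_text(json.dumps(results["stats"], indent=1, default=float))
        outputs[str(stats_path)] = _sha256(stats_path)

    if "report" in config.stages:
        if "stats" not in results:
            raise ConfigurationError("the 'report' stage requires the stats stage")
        report = make_report(results["cohort"], results["alps"], results["stats"])
        results["report"] = report
        report_path = out_dir / "report.json"
        report_path.write_text(json.dumps(report, indent=1, default=float))
        outputs[str(report_path)] = _sha256(report_path)
        table_path = out_dir / "table1.tsv"
        _table1_frame(report).to_csv(table_path, sep="\t", index=False)
        outputs[str(table_path)] = _sha256(table_path)

    manifest = RunManifest(
        config_hash=config.config_hash(),
        version=_version,
        seed=config.seed,
        stages_run=list(config.stages),
        outputs=outputs,
        exclusion_accounting=accounting,
        stage_failures=stage_failures,
        started=started,
        finished=time.time(),
    )
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(manifest.to_json())
    return manifest, results


def _alps_wide(alps: pd.DataFrame) -> pd.DataFrame:
    wide = alps.pivot(index="subject_id", columns="method",
                      values=["alps_left", "alps_right", "alps_average"])
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    return wide.reset_index()


def compute_statistics(
    cohort: pd.DataFrame,
    alps: pd.DataFrame,
    d_variant: str = "average_variance",
    reference_group: str = "HC",
) -> dict:
    """The full statistical battery on a cohort + ALPS long table.

    For each method and side: control-fitted age adjustment, then a
    one-way ANCOVA (sex covariate) on the adjusted index with LSD
    pairwise p and partial eta^2.  If both methods are present, a
    reliability section compares them (paired t + Cohen's d, Pearson r,
    numeric and percent Bland-Altman).  Subjects with missing values are
    dropped per analysis.
    """
    methods = sorted(alps["method"].unique())
    wide = _alps_wide(alps)
    merged = cohort.merge(wide, on="subject_id", how="inner")
    sex_code = (merged["sex"] == "M").astype(float).to_numpy()

    out: dict = {"ancova": {}, "age_models": {}, "adjusted": {}}
    adjusted_cols = {}
    for method in methods:
        for side in ("average", "left", "right"):
            col = f"alps_{side}_{method}"
            if col not in merged.columns:
                continue
            ok = merged[col].notna()
            sub = merged[ok]
            hc = sub[sub["group"] == reference_group]
            model = cs.fit_age_adjustment(
                hc[col].to_numpy(), hc["age"].to_numpy(), reference_group
            )
            adj = cs.apply_age_adjustment(
                sub[col].to_numpy(), sub["age"].to_numpy(), model
            )
            out["age_models"][f"{method}_{side}"] = {
                "beta": model.beta, "age_mean": model.age_mean,
            }
            key = f"{method}_{side}"
            adjusted_cols[key] = pd.Series(adj, index=sub.index)
            res = cs.ancova_oneway(adj, sub["group"].to_numpy(), sex_code[ok.to_numpy()])
            out["ancova"][key] = {
                "f": res.f, "df1": res.df1, "df2": res.df2, "p": res.p,
                "partial_eta_sq": res.partial_eta_sq,
                "adjusted_means": res.adjusted_means,
                "pairwise_p": {f"{a}|{b}": v for (a, b), v in res.lsd_pairwise_p.items()},
                "group_mean_sd": {
                    g: [float(adj[(sub["group"] == g).to_numpy()].mean()),
                        float(adj[(sub["group"] == g).to_numpy()].std(ddof=1))]
                    for g in sorted(sub["group"].unique())
                },
                "n": int(ok.sum()),
            }

    if len(methods) >= 2 and {"manual", "automatic"} <= set(methods):
        rel: dict = {}
        for side in ("average", "left", "right"):
            a_key, m_key = f"automatic_{side}", f"manual_{side}"
            if a_key not in adjusted_cols or m_key not in adjusted_cols:
                continue
            idx = adjusted_cols[m_key].index.intersection(adjusted_cols[a_key].index)
            man = adjusted_cols[m_key].loc[idx].to_numpy()
            auto = adjusted_cols[a_key].loc[idx].to_numpy()
            paired = cs.paired_t_and_cohens_d(man, auto, d_variant=d_variant)
            r = cs.partial_correlation(man, auto)
            rel[side] = {
                "paired_t": paired,
                "pearson": {"r": r.r, "df": r.df, "p": r.p},
                "bland_altman_numeric": dataclasses.asdict(cs.bland_altman(man, auto, "numeric")),
                "bland_altman_percent": dataclasses.asdict(cs.bland_altman(man, auto, "percent")),
            }
        out["reliability"] = rel
    else:
        log.warning("only one ALPS method present; reliability section omitted")

    out["demographics"] = cs.describe_cohort(merged)
    return out


def make_report(cohort: pd.DataFrame, alps: pd.DataFrame, stats: dict) -> dict:
    """Assemble the study-table report bundle from computed statistics."""
    if "method" not in alps.columns:
        raise SchemaError("ALPS table lacks the 'method' column")
    report = {
        "n_subjects": int(alps["subject_id"].nunique()),
        "methods": sorted(alps["method"].unique()),
        "demographics": stats["demographics"],
        "alps_table": stats["ancova"],
    }
    if "reliability" in stats:
        report["reliability"] = stats["reliability"]
    return report


def _table1_frame(report: dict) -> pd.DataFrame:
    rows = []
    demo = report["demographics"]["groups"]
    groups = sorted(demo)
    for key, entry in report["alps_table"].items():
        row = {"index": key, "p": entry["p"], "partial_eta_sq": entry["partial_eta_sq"]}
        for g in groups:
            m, s = entry["group_mean_sd"][g]
            row[g] = f"{m:.2f} +/- {s:.2f}"
        row.update({f"p_{k}": v for k, v in entry["pairwise_p"].items()})
        rows.append(row)
    return pd.DataFrame(rows)
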