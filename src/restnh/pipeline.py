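"""End-to-end orchestration: simulate -> preprocess -> features -> infer -> classify.

One :class:`RunConfig` drives a reproducible run: all randomness flows from
the single top-level seed, stage outputs land under ``output_dir``, and each
stage records a content hash of its configuration so re-runs skip work whose
inputs have not changed (and recompute bit-identically when they have been
deleted).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from . import features as _features
from . import inference as _inference
from .io import (
    CONTROL,
    PATIENT,
    FeatureMap,
    SubjectRecord,
    read_feature_map,
    read_manifest,
    write_feature_map,
    write_json,
    write_manifest,
    write_mask,
)
from .preprocess import PreprocessConfig, run_preprocess
from .synth import Cohort, SyntheticConfig, generate_cohort

__all__ = ["FeatureConfig", "RunConfig", "RunReport", "run_pipeline", "make_table_one"]

logger = logging.getLogger(__name__)


@dataclass
class FeatureConfig:
    band_hz: tuple[float, float] = (0.01, 0.08)
    nh_smooth_fwhm_mm: float = 4.0
    nh_smooth_passes: int = 1
    standardize: bool = True


@dataclass
class RunConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    inference: _inference.InferenceConfig = field(default_factory=_inference.InferenceConfig)
    svm: _classify.SvmConfig = field(default_factory=_classify.SvmConfig)
    output_dir: str = "restnh_run"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        # the top-level seed is the single source of randomness
        self.synthetic = replace(self.synthetic, seed=self.seed)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunReport:
    output_dir: Path
    table1: pd.DataFrame
    cluster_tables: dict[str, _inference.ClusterTable]
    correlations: pd.DataFrame | None
    classification: list[_classify.ClassifierReport]
    n_subjects: int
    n_excluded: int
    smoothness_fwhm_mm: dict[str, list[float]]
    k_min: dict[str, int]


def _hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _stage_fresh(stage_dir: Path, stage_hash: str) -> bool:
    marker = stage_dir / "stage.json"
    if not marker.exists():
        return False
    try:
        return json.loads(marker.read_text()).get("hash") == stage_hash
    except (json.JSONDecodeError, OSError):
        return False


# ---------------------------------------------------------------------------
# Table-1-style demographics
# ---------------------------------------------------------------------------

_TABLE1_ROWS = (
    ("Age (years)", lambda r: r.age_years),
    ("Education (years)", lambda r: r.education_years),
    ("Illness duration (months)", lambda r: r.illness_duration_months),
    ("Y-BOCS total score", lambda r: r.ybocs_total),
    ("Y-BOCS obsessive thinking", lambda r: r.ybocs_obsessive),
    ("Y-BOCS compulsive behavior", lambda r: r.ybocs_compulsive),
    ("HAMD", lambda r: r.hamd),
    ("HAMA", lambda r: r.hama),
    ("FD", lambda r: r.mean_fd_mm),
)


def make_table_one(records: list[SubjectRecord]) -> pd.DataFrame:
    """Demographics table: per variable, group mean ± SD, pooled two-sample t
    (chi-square for sex), two-tailed p, formatted to 2 decimals."""
    patients = [r for r in records if r.group == PATIENT]
    controls = [r for r in records if r.group == CONTROL]
    if not patients or not controls:
        raise ValueError("both groups must be present")

    def fmt(vals):
        if not vals:
            return ""
        a = np.asarray(vals, dtype=float)
        return f"{a.mean():.2f} ± {a.std(ddof=1):.2f}" if a.size > 1 else f"{a[0]:.2f}"

    rows = []
    pm = sum(r.sex == "male" for r in patients)
    cm = sum(r.sex == "male" for r in controls)
    x2, p = _inference.chi_square_2x2(pm, len(patients) - pm, cm, len(controls) - cm)
    rows.append(
        {
            "variable": "Sex (male/female)",
            "patients": f"{pm}/{len(patients) - pm}",
            "controls": f"{cm}/{len(controls) - cm}",
            "stat": f"{x2:.2f}",
            "p": f"{p:.2f}",
        }
    )
    for name, getter in _TABLE1_ROWS:
        pv = [getter(r) for r in patients if getter(r) is not None]
        cv = [getter(r) for r in controls if getter(r) is not None]
        row = {"variable": name, "patients": fmt(pv), "controls": fmt(cv), "stat": "", "p": ""}
        if len(pv) >= 2 and len(cv) >= 2:
            pa, ca = np.asarray(pv, float), np.asarray(cv, float)
            t, _, pval = _inference.pooled_t_test(
                pa.mean(), pa.std(ddof=1), pa.size, ca.mean(), ca.std(ddof=1), ca.size
            )
            row["stat"] = f"{t:.2f}"
            row["p"] = f"{pval:.2f}"
        if pv or cv:
            rows.append(row)
    return pd.DataFrame(rows, columns=["variable", "patients", "controls", "stat", "p"])


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _features_stage(config: RunConfig, out: Path, cohort: Cohort) -> tuple[list[SubjectRecord], dict[str, list[FeatureMap]]]:
    """Per-subject preprocessing and feature maps, cached on disk."""
    stage_dir = out / "features"
    fc = config.features
    stage_hash = _hash(
        {"synthetic": config.synthetic.to_dict(), "preprocess": asdict(config.preprocess), "features": asdict(fc)}
    )
    manifest_path = out / "manifest.tsv"
    if _stage_fresh(stage_dir, stage_hash) and manifest_path.exists():
        logger.info("features stage up to date; loading cached maps")
        records = read_manifest(manifest_path)
        maps = {"falff": [], "nh": []}
        for r in records:
            for kind in ("falff", "nh"):
                path = stage_dir / f"{r.subject_id}_{kind}_z.nii.gz"
                maps[kind].append(
                    read_feature_map(path, kind, subject_id=r.subject_id, standardized=True)
                )
        return records, maps

    stage_dir.mkdir(parents=True, exist_ok=True)
    mask = cohort.mask
    records: list[SubjectRecord] = []
    maps: dict[str, list[FeatureMap]] = {"falff": [], "nh": []}
    excluded = []
    for record in cohort.records:
        t0 = time.perf_counter()
        data = cohort.subject_data(record.subject_id)
        pp = run_preprocess(data.bold, data.motion, data.wm, data.csf, config.preprocess)
        record = replace(record, mean_fd_mm=round(pp.fd.mean_fd_mm, 6))
        if pp.flagged_for_exclusion:
            logger.warning("excluding %s: fewer than half the volumes retained", record.subject_id)
            excluded.append(record.subject_id)
            continue
        falff = _features.compute_falff(pp.falff_bold, mask, fc.band_hz)
        nh = _features.compute_nh(pp.nh_bold, mask)
        nh = _features.smooth_nh(nh, mask, fc.nh_smooth_fwhm_mm, fc.nh_smooth_passes)
        if fc.standardize:
            falff = _features.standardize_map(falff, mask)
            nh = _features.standardize_map(nh, mask)
        for kind, fmap in (("falff", falff), ("nh", nh)):
            write_feature_map(fmap, mask.affine, stage_dir / f"{record.subject_id}_{kind}_z.nii.gz")
            maps[kind].append(fmap)
        records.append(record)
        logger.debug("subject %s done in %.2fs", record.subject_id, time.perf_counter() - t0)
    write_manifest(records, manifest_path)
    write_mask(mask, out / "mask.nii.gz")
    write_json({"hash": stage_hash, "excluded": excluded}, stage_dir / "stage.json")
    return records, maps


def _infer_stage(
    config: RunConfig,
    out: Path,
    records: list[SubjectRecord],
    maps: dict[str, list[FeatureMap]],
    mask,
) -> tuple[dict[str, _inference.ClusterTable], dict[str, list[float]], dict[str, int]]:
    infer_dir = out / "infer"
    infer_dir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, _inference.ClusterTable] = {}
    smoothness: dict[str, list[float]] = {}
    kmins: dict[str, int] = {}
    ic = config.inference
    for kind in ("falff", "nh"):
        stat = _inference.voxelwise_glm(maps[kind], records, mask)
        fwhm = _inference.estimate_smoothness(stat.residuals, mask)
        if ic.correction == "grf":
            k_min = _inference.grf_cluster_extent(stat, fwhm, ic)
        else:
            rng = np.random.default_rng(config.seed + 104729)
            k_min = _inference.permutation_cluster_extent(maps[kind], records, mask, ic, rng=rng)
        table = _inference.extract_clusters(stat, k_min, ic)
        tables[kind] = table
        smoothness[kind] = [float(f) for f in fwhm]
        kmins[kind] = int(k_min)
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.nan_to_num(stat.t_values), mask.affine), str(infer_dir / f"tmap_{kind}.nii.gz"))
        table.to_dataframe().to_csv(infer_dir / f"clusters_{kind}.tsv", sep="\t", index=False)
        logger.info(
            "%s: FWHM=%s mm, k_min=%d, %d significant cluster(s)", kind, np.round(fwhm, 2), k_min, len(table)
        )
    return tables, smoothness, kmins


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the full pipeline on a synthetic cohort and write all reports."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    write_json(config.to_dict(), out / "run_config.json")

    cohort = generate_cohort(config.synthetic)
    records, maps = _features_stage(config, out, cohort)
    mask = cohort.mask

    table1 = make_table_one(records)
    table1.to_csv(out / "table1.tsv", sep="\t", index=False)

    tables, smoothness, kmins = _infer_stage(config, out, records, maps, mask)

    # cluster features: fALFF clusters first, then NH, ids "1".."K"
    all_clusters = list(tables["falff"]) + list(tables["nh"])
    cluster_kinds = ["falff"] * len(tables["falff"]) + ["nh"] * len(tables["nh"])
    correlations_df = None
    classification: list[_classify.ClassifierReport] = []
    if all_clusters:
        feats = np.column_stack(
            [
                _inference.cluster_means(maps[kind], [cl])
                for kind, cl in zip(cluster_kinds, all_clusters)
            ]
        )
        patient_idx = [i for i, r in enumerate(records) if r.group == PATIENT]
        feat_names = {
            str(j + 1): feats[patient_idx, j] for j in range(feats.shape[1])
        }
        scores = ("ybocs_total", "ybocs_obsessive", "ybocs_compulsive", "hamd", "hama", "illness_duration")
        try:
            corr = _inference.clinical_correlations(feat_names, records, scores)
            correlations_df = pd.DataFrame([asdict(c) for c in corr])
            correlations_df.to_csv(out / "correlations.tsv", sep="\t", index=False)
        except ValueError as exc:
            logger.warning("clinical correlations skipped: %s", exc)

        labels = [r.group for r in records]
        sids = [r.subject_id for r in records]
        classification = _classify.combination_search(
            feats, labels, config.svm, subject_ids=sids
        )
        rank_df = pd.DataFrame(
            [
                {
                    "rank": i + 1,
                    "feature_set": r.feature_set,
                    "accuracy_pct": r.accuracy_pct,
                    "sensitivity_pct": r.sensitivity_pct,
                    "specificity_pct": r.specificity_pct,
                    "best_log2c": r.best_log2c,
                    "best_log2g": r.best_log2g,
                }
                for i, r in enumerate(classification)
            ]
        )
        rank_df.to_csv(out / "classification_ranking.tsv", sep="\t", index=False)
        write_json([r.to_dict() for r in classification], out / "classification_reports.json")
    else:
        logger.info("no significant clusters; correlation and classification stages skipped")

    report = RunReport(
        output_dir=out,
        table1=table1,
        cluster_tables=tables,
        correlations=correlations_df,
        classification=classification,
        n_subjects=len(records),
        n_excluded=len(cohort.records) - len(records),
        smoothness_fwhm_mm=smoothness,
        k_min=kmins,
    )
    summary = {
        "n_subjects": report.n_subjects,
        "n_excluded": report.n_excluded,
        "k_min": kmins,
        "smoothness_fwhm_mm": smoothness,
        "clusters": {k: t.to_dataframe().to_dict(orient="records") for k, t in tables.items()},
        "best_combination": classification[0].to_dict() if classification else None,
    }
    write_json(summary, out / "run_report.json")
    return report
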