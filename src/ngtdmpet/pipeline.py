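"""End-to-end study orchestration: simulate/load -> extract -> filter ->
analyze -> report.

``run_study`` produces a deterministic report bundle: a per-lesion
feature table, a benign-vs-malignant group comparison (mean +/- SD,
rank-sum z and p), a per-feature ROC table (AUC, closest-to-corner
threshold, sensitivity/specificity/accuracy), fold-averaged
cross-validated summaries, a reader-score correlation table, the ROC
curve points, an exclusion log and a run manifest.  All randomness is
owned by ``RunConfig.seed``; identical configurations yield identical
bundles.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    FEATURE_COLUMNS,
    FeatureRecord,
    apply_inclusion_filters,
    records_to_frame,
    records_to_long_frame,
    write_exclusion_log,
)
from .simulate import (
    LesionSample,
    SyntheticCohort,
    generate_cohort,
    simulate_reader_scores,
)
from .stats import (
    cross_validated_auc,
    make_cv_plan,
    pearson_correlation,
    roc_analysis,
    wilcoxon_rank_sum,
)
from .texture import (
    TextureConfig,
    lesion_features,
    load_mask,
    load_volume,
    save_mask,
    save_volume,
)

__all__ = ["RunConfig", "ReportBundle", "run_study", "extract_records", "write_cohort_dir"]

logger = logging.getLogger("ngtdmpet")

#: Ordinal reader scores are driven by this feature (the strongest
#: discriminator of the delayed scan).
SCORE_DRIVER = "delayed_busyness"


@dataclass(frozen=True)
class RunConfig:
    """Study settings; defaults mirror the reference analysis: 128 gray
    tones, 5x5x5 sub-volumes, 11 folds, 35 benign / 81 malignant."""

    input_mode: str = "synthetic"
    input_dir: str | None = None
    out_dir: str = "study_out"
    n_bins: int = 128
    subvolume_size: int = 5
    policy: str = "strict-interior"
    epsilon: float = 1e-8
    all_slices: bool = False
    n_folds: int = 11
    stratified: bool = True
    n_benign: int = 35
    n_malignant: int = 81
    seed: int = 7
    min_voxels: int = 64
    min_suvmax: float = 2.5
    reader_noise_with: float = 0.8
    reader_noise_without: float = 1.2

    def texture_config(self) -> TextureConfig:
        return TextureConfig(
            n_bins=self.n_bins,
            subvolume_size=self.subvolume_size,
            policy=self.policy,
            epsilon=self.epsilon,
            all_slices=self.all_slices,
        )


@dataclass
class ReportBundle:
    """In-memory results plus the paths of everything written."""

    features: pd.DataFrame
    group_comparison: pd.DataFrame
    roc_table: pd.DataFrame
    cv_table: pd.DataFrame
    correlations: pd.DataFrame
    manifest: dict
    paths: dict[str, Path]


def extract_records(
    samples: list[LesionSample], config: TextureConfig
) -> list[FeatureRecord]:
    """Dual-time-point texture extraction for every lesion."""
    records = []
    for sample in samples:
        early = lesion_features(sample.early, sample.mask, config)
        delayed = lesion_features(sample.delayed, sample.mask, config)
        records.append(
            FeatureRecord(
                lesion_id=sample.lesion_id,
                label=sample.label,
                early=early.triplet,
                delayed=delayed.triplet,
                early_suvmax=early.suvmax,
                delayed_suvmax=delayed.suvmax,
                n_voxels=early.n_voxels,
                n_undefined_early=early.n_undefined,
                n_undefined_delayed=delayed.n_undefined,
            )
        )
    return records


def _load_samples(input_dir: str) -> list[LesionSample]:
    from .texture import LesionMask, PetVolume  # noqa: F401  (types only)

    root = Path(input_dir)
    table = pd.read_csv(root / "cohort.csv")
    required = {"lesion_id", "label", "early_path", "delayed_path", "mask_path"}
    if not required.issubset(table.columns):
        raise ValueError(f"cohort.csv must contain columns {sorted(required)}")
    samples = []
    for _, row in table.iterrows():
        lesion_id = str(row["lesion_id"])
        for col in ("early_path", "delayed_path", "mask_path"):
            if not (root / str(row[col])).exists():
                raise FileNotFoundError(f"lesion {lesion_id}: missing {row[col]}")
        samples.append(
            LesionSample(
                lesion_id=lesion_id,
                label=str(row["label"]),
                early=load_volume(root / str(row["early_path"]), "early"),
                delayed=load_volume(root / str(row["delayed_path"]), "delayed"),
                mask=load_mask(root / str(row["mask_path"])),
                params={},
            )
        )
    return samples


def write_cohort_dir(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Persist a synthetic cohort as NIfTI volumes + cohort.csv +
    truth.json, readable back through files-mode input."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    truth = {}
    for s in cohort.samples:
        early_p = f"{s.lesion_id}_early.nii.gz"
        delayed_p = f"{s.lesion_id}_delayed.nii.gz"
        mask_p = f"{s.lesion_id}_mask.nii.gz"
        save_volume(s.early, root / early_p)
        save_volume(s.delayed, root / delayed_p)
        save_mask(s.mask, s.early.spacing, root / mask_p)
        rows.append(
            {
                "lesion_id": s.lesion_id,
                "label": s.label,
                "early_path": early_p,
                "delayed_path": delayed_p,
                "mask_path": mask_p,
            }
        )
        truth[s.lesion_id] = s.params
    pd.DataFrame(rows).to_csv(root / "cohort.csv", index=False)
    (root / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return root


def _group_comparison(frame: pd.DataFrame) -> pd.DataFrame:
    rows = []
    benign = frame[frame["label"] == "benign"]
    malignant = frame[frame["label"] == "malignant"]
    for feat in FEATURE_COLUMNS:
        test = wilcoxon_rank_sum(benign[feat].to_numpy(), malignant[feat].to_numpy())
        rows.append(
            {
                "feature": feat,
                "malignant_mean": malignant[feat].mean(),
                "malignant_sd": malignant[feat].std(ddof=1),
                "benign_mean": benign[feat].mean(),
                "benign_sd": benign[feat].std(ddof=1),
                "z": test.z,
                "p": test.pvalue,
            }
        )
    return pd.DataFrame(rows)


def _roc_tables(
    frame: pd.DataFrame, features: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    y = (frame["label"] == "malignant").to_numpy()
    rows, points = [], []
    for feat in features:
        summary = roc_analysis(frame[feat].to_numpy(dtype=float), y)
        rows.append(
            {
                "feature": feat,
                "auc": summary.auc,
                "threshold": summary.threshold,
                "sensitivity": summary.sensitivity,
                "specificity": summary.specificity,
                "accuracy": summary.accuracy,
                "higher_is_malignant": summary.higher_is_malignant,
            }
        )
        for fpr, tpr in zip(summary.fpr, summary.tpr):
            points.append({"feature": feat, "fpr": fpr, "tpr": tpr})
    return pd.DataFrame(rows), pd.DataFrame(points)


def _cv_table(frame: pd.DataFrame, features: list[str], config: RunConfig) -> pd.DataFrame:
    plan = make_cv_plan(
        frame["lesion_id"].tolist(),
        frame["label"].tolist(),
        n_folds=config.n_folds,
        seed=config.seed,
        stratified=config.stratified,
    )
    y = dict(zip(frame["lesion_id"], frame["label"] == "malignant"))
    rows = []
    for feat in features:
        scores = dict(zip(frame["lesion_id"], frame[feat].astype(float)))
        result = cross_validated_auc(scores, y, plan)
        rows.append(
            {
                "feature": feat,
                "cv_auc": result.mean_auc,
                "cv_sensitivity": result.mean_sensitivity,
                "cv_specificity": result.mean_specificity,
                "cv_accuracy": result.mean_accuracy,
                "n_skipped_folds": len(result.skipped_folds),
            }
        )
    return pd.DataFrame(rows)


def _correlation_table(frame: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for score_col, tag in (
        ("score_with_texture", "with_texture"),
        ("score_without_texture", "without_texture"),
    ):
        scores = frame[score_col].to_numpy(dtype=float)
        for feat in FEATURE_COLUMNS:
            r, p = pearson_correlation(scores, frame[feat].to_numpy(dtype=float))
            rows.append({"scores": tag, "feature": feat, "r": r, "p": p})
    return pd.DataFrame(rows)


def run_study(config: RunConfig) -> ReportBundle:
    """Execute the full analysis and write the report bundle."""
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input_mode == "synthetic":
        cohort = generate_cohort(
            n_benign=config.n_benign, n_malignant=config.n_malignant, seed=config.seed
        )
        samples = cohort.samples
    elif config.input_mode == "files":
        if not config.input_dir:
            raise ValueError("files mode requires input_dir")
        samples = _load_samples(config.input_dir)
    else:
        raise ValueError("input_mode must be 'synthetic' or 'files'")
    logger.info("cohort ready: %d lesions (%.1fs)", len(samples), time.perf_counter() - t0)

    t1 = time.perf_counter()
    records = extract_records(samples, config.texture_config())
    logger.info("features extracted (%.1fs)", time.perf_counter() - t1)

    included, excluded = apply_inclusion_filters(
        records, min_voxels=config.min_voxels, min_suvmax=config.min_suvmax
    )
    if not included:
        raise ValueError("no lesion survives the inclusion filters")

    score_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 815]))
    driver = np.array([getattr(r, "delayed").busyness for r in included])
    with_scores = simulate_reader_scores(driver, config.reader_noise_with, score_rng)
    without_scores = simulate_reader_scores(driver, config.reader_noise_without, score_rng)
    for rec, sw, swo in zip(included, with_scores, without_scores):
        rec.score_with_texture = int(sw)
        rec.score_without_texture = int(swo)

    frame = records_to_frame(included)
    roc_features = FEATURE_COLUMNS + ["score_with_texture", "score_without_texture"]
    group = _group_comparison(frame)
    roc_table, roc_points = _roc_tables(frame, roc_features)
    cv = _cv_table(frame, FEATURE_COLUMNS, config)
    corr = _correlation_table(frame)

    config_record = asdict(config)
    config_record.pop("out_dir")  # environmental, not part of the science
    manifest = {
        "software": {"name": "ngtdmpet", "version": __version__},
        "config": config_record,
        "n_input_lesions": len(records),
        "n_included": len(included),
        "n_excluded": len(excluded),
    }

    paths = {
        "features": out / "features.csv",
        "features_long": out / "features_long.csv",
        "group_comparison": out / "group_comparison.csv",
        "roc_table": out / "roc_table.csv",
        "roc_points": out / "roc_points.csv",
        "cv_table": out / "cv_table.csv",
        "correlations": out / "correlations.csv",
        "exclusions": out / "exclusions.json",
        "manifest": out / "manifest.json",
    }
    fmt = "%.12g"
    frame.to_csv(paths["features"], index=False, float_format=fmt)
    records_to_long_frame(included).to_csv(
        paths["features_long"], index=False, float_format=fmt
    )
    group.to_csv(paths["group_comparison"], index=False, float_format=fmt)
    roc_table.to_csv(paths["roc_table"], index=False, float_format=fmt)
    roc_points.to_csv(paths["roc_points"], index=False, float_format=fmt)
    cv.to_csv(paths["cv_table"], index=False, float_format=fmt)
    corr.to_csv(paths["correlations"], index=False, float_format=fmt)
    write_exclusion_log(excluded, paths["exclusions"])
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("report bundle written to %s (%.1fs total)", out, time.perf_counter() - t0)

    return ReportBundle(
        features=frame,
        group_comparison=group,
        roc_table=roc_table,
        cv_table=cv,
        correlations=corr,
        manifest=manifest,
        paths=paths,
    )
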