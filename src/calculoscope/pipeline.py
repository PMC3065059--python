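"""End-to-end orchestration: images -> regions -> features -> CV report.

`run_pipeline` wires the stages together, persists every intermediate
(masks, region crops index, feature CSV, CV results) under an output
directory, and returns a report whose metrics are recomputable from those
files.  All randomness flows from the single seed in the config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import classify
from .glcm import feature_names, region_feature_vector
from .morphology import MorphConfig, extract_lumina, segment_suspicious_regions

logger = logging.getLogger("calculoscope")

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the pipeline, serializable to/from YAML."""

    window: int = 9
    compose_mode: str = "mean"
    lumen_polarity: str = "above"
    calculus_polarity: str = "below"
    selem_shape: str = "disk"
    selem_radius: int = 3
    min_area: int = 30
    fill_holes: bool = True
    exclude_border: bool = True
    glcm_levels: int = 16
    glcm_distance: int = 1
    alpha: float = 0.98
    svm_c: float = 1.0
    svm_gamma: "float | str" = "scale"
    cv_folds: int = 5
    cv_repeats: int = 10
    pca_mode: str = "train_only"
    seed: int = 0

    def morph(self) -> MorphConfig:
        return MorphConfig(
            selem_shape=self.selem_shape,
            selem_radius=self.selem_radius,
            min_area=self.min_area,
            fill_holes=self.fill_holes,
            exclude_border=self.exclude_border,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


@dataclass
class PipelineReport:
    """What one pipeline run produced and where it was persisted."""

    regions: list[dict]
    feature_table_path: str | None
    cv_summary: dict | None
    config: PipelineConfig
    errors: list[dict] = field(default_factory=list)
    cv_results_path: str | None = None


def _write_mask(path: Path, mask: np.ndarray) -> None:
    iio.imwrite(path, (mask.astype(np.uint8) * 255))


def run_pipeline(
    images: "list[str | Path]",
    labels: "dict[str, int] | None",
    config: PipelineConfig,
    out_dir: "str | Path",
) -> PipelineReport:
    """Run segmentation, feature extraction and (optionally) repeated CV.

    ``labels`` maps region ids (``"<image stem>:<label>"``) to {0, 1};
    when given and both classes are present, the repeated k-fold CV stage
    runs on the extracted feature table.  Unreadable images are recorded
    as per-file errors and the run continues.
    """
    if not images:
        raise ValueError("need at least one input image")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    rows = []
    inventory: list[dict] = []
    errors: list[dict] = []
    for path in images:
        path = Path(path)
        try:
            image = np.asarray(iio.imread(path))
        except Exception as exc:  # noqa: BLE001 - per-file errors are recorded
            logger.warning("skipping unreadable image %s: %s", path, exc)
            errors.append({"image": str(path), "error": str(exc)})
            continue
        if image.ndim == 3 and image.shape[2] == 4:
            image = image[:, :, :3]
        stem = path.stem
        lumen_mask, lumina = extract_lumina(
            image,
            window=config.window,
            compose_mode=config.compose_mode,
            morph=config.morph(),
            lumen_polarity=config.lumen_polarity,
        )
        _write_mask(out / f"{stem}_lumen_mask.png", lumen_mask)
        regions = segment_suspicious_regions(
            image,
            lumen_mask,
            morph=config.morph(),
            polarity=config.calculus_polarity,
            source_image_id=stem,
        )
        logger.info(
            "%s: %d lumina, %d suspicious regions", stem, lumina.n_regions, len(regions)
        )
        for reg in regions:
            rid = f"{stem}:{reg.source_label}"
            vec = region_feature_vector(
                reg, levels=config.glcm_levels, d=config.glcm_distance
            )
            row = dict(zip(feature_names(), vec))
            row["region_id"] = rid
            rows.append(row)
            inventory.append(
                {
                    "region_id": rid,
                    "image": str(path),
                    "bbox": list(reg.bbox),
                    "area": int(reg.mask.sum()),
                }
            )

    feature_path = None
    cv_summary = None
    cv_results_path = None
    if rows:
        table = pd.DataFrame(rows).set_index("region_id")
        if labels:
            table["label"] = [labels.get(rid, -1) for rid in table.index]
            table = table[table["label"] >= 0]
        feature_path = out / "features.csv"
        table.to_csv(feature_path)

        if labels and table["label"].nunique() == 2:
            feats = table.drop(columns="label")
            results = classify.repeated_kfold_cv(
                feats,
                table["label"].to_numpy(),
                k=config.cv_folds,
                repeats=config.cv_repeats,
                pca_mode=config.pca_mode,
                alpha=config.alpha,
                C=config.svm_c,
                gamma=config.svm_gamma,
                seed=config.seed,
            )
            cv_summary = classify.summarize_runs(results)
            per_run = pd.DataFrame(
                {
                    "run": np.arange(1, len(results) + 1),
                    "test_accuracy": [r.test_accuracy for r in results],
                    "train_accuracy": [r.train_accuracy for r in results],
                    "tns": [r.counts.tns for r in results],
                    "fps": [r.counts.fps for r in results],
                    "fns": [r.counts.fns for r in results],
                    "tps": [r.counts.tps for r in results],
                    "sensitivity": [r.sensitivity for r in results],
                    "specificity": [r.specificity for r in results],
                }
            )
            cv_results_path = out / "cv_results.csv"
            per_run.to_csv(cv_results_path, index=False)
        elif labels:
            logger.info("CV skipped: labeled regions do not cover both classes")

    report = PipelineReport(
        regions=inventory,
        feature_table_path=str(feature_path) if feature_path else None,
        cv_summary=cv_summary,
        config=config,
        errors=errors,
        cv_results_path=str(cv_results_path) if cv_results_path else None,
    )
    (out / "report.json").write_text(
        json.dumps(
            {
                "regions": inventory,
                "feature_table": report.feature_table_path,
                "cv_summary": cv_summary,
                "errors": errors,
            },
            indent=2,
        )
    )
    return report
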