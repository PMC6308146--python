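"""End-to-end reproducible pipeline: simulate -> extract -> select -> model.

Every run is a pure function of its :class:`RunConfig` (including the
seed): the second observer's contours, the fold assignment, and the
classifiers all derive their randomness from the config seed, so a rerun
under the same config writes byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import platform
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import N_FEATURES, extract_all
from .modeling import CvReport, run_cv
from .selection import SelectionReport, run_selection
from .synthetic import CohortSpec, build_cohort, perturb_contour

__all__ = ["RunConfig", "extract_cohort_features", "run_all"]


@dataclass
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    target_mm: float = 1.0
    n_levels: int = 64
    contour_perturbation_mm: float = 1.0
    icc_threshold: float = 0.8
    pcc_threshold: float = 0.80
    alpha: float = 0.05
    variance_threshold: float = 0.85
    folds: int = 10
    full_dataset_pca: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("icc_threshold", 0, 1),
            ("pcc_threshold", 0, 1),
            ("alpha", 0, 1),
            ("variance_threshold", 0, 1),
        ):
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ValueError(f"{name} must be in ({lo}, {hi}], got {v}")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortSpec(**raw.pop("cohort", {}))
        return cls(cohort=cohort, **raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def extract_cohort_features(
    config: RunConfig, second_observer: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame | None, pd.Series]:
    """Feature tables for the synthetic cohort.

    Returns (observer-1 table, observer-2 table or None, class labels),
    indexed by case id. The second observer is a perturbed contour on the
    same image, the reproducibility stand-in for repeated delineation.
    """
    cases = build_cohort(config.cohort)
    rows1, rows2, labels = {}, {}, {}
    for i, (case_id, label, vol, mask) in enumerate(cases):
        feats, _ = extract_all(vol, mask, config.target_mm, config.n_levels)
        rows1[case_id] = feats
        labels[case_id] = label
        if second_observer:
            mask2 = perturb_contour(
                mask, config.contour_perturbation_mm, seed=config.cohort.seed * 100003 + i
            )
            feats2, _ = extract_all(vol, mask2, config.target_mm, config.n_levels)
            rows2[case_id] = feats2
    obs1 = pd.DataFrame.from_dict(rows1, orient="index")
    obs2 = pd.DataFrame.from_dict(rows2, orient="index") if second_observer else None
    return obs1, obs2, pd.Series(labels)


def run_all(config: RunConfig, outdir: str | Path | None = None):
    """Full chain; optionally writes features/selection/model artifacts + log."""
    t0 = time.time()
    timings = {}

    obs1, obs2, labels = extract_cohort_features(config)
    timings["extract_s"] = round(time.time() - t0, 2)

    t1 = time.time()
    report: SelectionReport = run_selection(
        obs1.drop(columns=[], errors="ignore"),
        obs2,
        labels,
        icc_threshold=config.icc_threshold,
        pcc_threshold=config.pcc_threshold,
        alpha=config.alpha,
        positive_label="IFR",
    )
    timings["select_s"] = round(time.time() - t1, 2)

    cv: CvReport | None = None
    if report.significant_features:
        t2 = time.time()
        cv = run_cv(
            obs1[report.significant_features],
            labels,
            folds=config.folds,
            seed=config.seed,
            variance_threshold=config.variance_threshold,
            full_dataset_pca=config.full_dataset_pca,
        )
        timings["model_s"] = round(time.time() - t2, 2)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table1 = obs1.copy()
        table1["class_label"] = labels
        table1.to_csv(outdir / "features_obs1.csv", index_label="case_id")
        if obs2 is not None:
            obs2.to_csv(outdir / "features_obs2.csv", index_label="case_id")
        report.table().to_csv(outdir / "significant_features.csv", index=False)
        selection_json = {
            "retained_after_icc": len(report.retained_after_icc),
            "retained_after_pcc": len(report.retained_after_pcc),
            "significant_features": report.significant_features,
        }
        (outdir / "selection_report.json").write_text(json.dumps(selection_json, indent=2))
        if cv is not None:
            pd.DataFrame(cv.metrics).T.to_csv(outdir / "cv_metrics.csv", index_label="model")
        log = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_features": N_FEATURES,
            "versions": {
                "npcradiomics": __version__,
                "python": platform.python_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "timings_s": timings,
        }
        (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))

    return obs1, obs2, labels, report, cv
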