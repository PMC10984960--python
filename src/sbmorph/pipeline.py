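"""End-to-end analysis: simulate or load, decompose, classify, explain,
and summarize into a machine-readable report.

The report mirrors the reporting layout of the reference analysis: a
cohort-characteristics table, a by-feature-set performance table, a
by-diagnosis performance table, a component-by-clinical correlation table,
ROC/AUC of the final model, the fold-averaged SHAP importance ranking, and
a provenance block (config hash, seed, package versions) sufficient to
reproduce every number.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    CVConfig,
    PredictionSet,
    ablation,
    breakdown_by_diagnosis,
    compute_metrics,
)
from .decompose import decompose, zscore_component
from .explain import beeswarm_export, mean_abs_importance, shap_for_predictions
from .features import FEATURE_SET_NAMES
from .io import (
    read_mask,
    read_subject_table,
    read_volumes,
    save_json,
    write_ground_truth,
    write_subject_table,
    write_volumes,
)
from .simulate import CohortConfig, cohort_summary, generate_cohort
from .stats import CLINICAL_VARS, correlation_table, ttest_raw
from .volumes import BrainMask, flatten_volumes

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("sbmorph")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    Either ``simulate`` holds :class:`CohortConfig` keyword arguments, or
    ``volumes_dir``/``table_path`` point at existing data.  ``master seed``
    propagates to every stochastic stage.
    """

    out_dir: str = "sbmorph-run"
    seed: int = 0
    simulate: dict | None = None
    volumes_dir: str | None = None
    mask_path: str | None = None
    table_path: str | None = None
    cv: dict = field(default_factory=dict)
    feature_sets: list[str] = field(default_factory=lambda: list(FEATURE_SET_NAMES))
    shap: dict = field(default_factory=dict)
    n_boot: int = 2000
    zmap_threshold: float = 1.0
    save_volumes: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def canonical_hash(self) -> str:
        # out_dir identifies where the report lands, not what was computed
        fields = sorted(f for f in self.__dataclass_fields__
                        if f != "out_dir")
        blob = json.dumps({k: getattr(self, k) for k in fields},
                          sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name):
    log.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(config: RunConfig | dict) -> dict:
    """Execute the full analysis and write the report under ``out_dir``.

    Returns the report dict.  Fully seed-deterministic in nested mode
    (the report JSON contains no timestamps).
    """
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    # ---- stage 1: simulate or load -------------------------------------
    t0 = _stage("cohort")
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        if "grid_shape" in sim_kwargs:
            sim_kwargs["grid_shape"] = tuple(sim_kwargs["grid_shape"])
        cohort_cfg = CohortConfig(**sim_kwargs)
        volumes, table, truth = generate_cohort(cohort_cfg)
        mask = BrainMask.full(cohort_cfg.grid_shape)
        if config.save_volumes:
            write_volumes(volumes, out / "volumes")
            write_ground_truth(truth, out / "ground_truth")
        write_subject_table(table, out / "subjects.csv")
    else:
        if not (config.volumes_dir and config.table_path):
            raise ValueError(
                "config needs either 'simulate' or volumes_dir + table_path"
            )
        volumes = read_volumes(config.volumes_dir)
        table = read_subject_table(config.table_path)
        mask = (read_mask(config.mask_path) if config.mask_path
                else BrainMask.full(volumes[0].grid_shape))
    matrix = flatten_volumes(volumes, mask)
    timings["cohort"] = time.perf_counter() - t0

    # ---- stage 2: cohort summary and group tests -----------------------
    t0 = _stage("summary")
    summary = cohort_summary(table)
    group_tests = {}
    pos = table[table["ab_label"] == "positive"]
    neg = table[table["ab_label"] == "negative"]
    for var in [c for c in table.columns
                if pd.api.types.is_numeric_dtype(table[c])
                and c not in ("subject_id",)]:
        x1, x2 = pos[var].dropna(), neg[var].dropna()
        if len(x1) > 1 and len(x2) > 1:
            res = ttest_raw(x1, x2)
            group_tests[var] = {"t": res.statistic, "df": res.df, "p": res.p}
    timings["summary"] = time.perf_counter() - t0

    # ---- stage 3: classification ablation ------------------------------
    t0 = _stage("classification")
    cv = CVConfig(seed=config.seed, **config.cv)
    ablation_report, preds = ablation(
        matrix, table, config.feature_sets, cv, n_boot=config.n_boot
    )
    final_name = "ALL" if "ALL" in preds else config.feature_sets[-1]
    final: PredictionSet = preds[final_name]
    final_metrics = compute_metrics(final, subset_name=final_name,
                                    n_boot=config.n_boot, seed=config.seed)
    timings["classification"] = time.perf_counter() - t0

    # ---- stage 4: diagnosis breakdown ----------------------------------
    t0 = _stage("diagnosis breakdown")
    diag_reports = []
    if "diagnosis" in table.columns:
        diag_reports = breakdown_by_diagnosis(
            final, table, n_boot=config.n_boot, seed=config.seed
        )
    timings["diagnosis"] = time.perf_counter() - t0

    # ---- stage 5: final decomposition, z-maps, correlation table -------
    t0 = _stage("decomposition report")
    k_choices = [p["K"] for p in final.chosen_params if p.get("K")]
    if not k_choices:
        for name, ps in preds.items():
            k_choices += [p["K"] for p in ps.chosen_params if p.get("K")]
    final_K = (int(pd.Series(k_choices).mode().iloc[0]) if k_choices
               else max(2, min(7, len(table) - 1)))
    components = decompose(matrix, final_K, seed=config.seed)
    import nibabel as nib

    zmap_dir = out / "zmaps"
    zmap_dir.mkdir(exist_ok=True)
    for k in range(components.K):
        zm = zscore_component(components, k, threshold=config.zmap_threshold)
        nib.save(
            nib.Nifti1Image(zm.z.astype(np.float32), np.diag([2, 2, 2, 1.0])),
            zmap_dir / f"IC_{k + 1}_z.nii.gz",
        )
    variables = [v for v in CLINICAL_VARS
                 if v in table.columns or v in ("sex", "ab_positivity")]
    corr = correlation_table(components.loadings, table, variables=variables)
    timings["decomposition"] = time.perf_counter() - t0

    # ---- stage 6: SHAP --------------------------------------------------
    t0 = _stage("interpretation")
    shap_kwargs = dict(config.shap)
    shap_kwargs.setdefault("seed", config.seed)
    shaps = shap_for_predictions(final, **shap_kwargs)
    importance = mean_abs_importance(shaps, allow_union=True)
    beeswarm = beeswarm_export(shaps, final.fold_test_X)
    timings["interpretation"] = time.perf_counter() - t0

    # ---- assemble and write the report ---------------------------------
    roc_y = final.y_true.tolist()
    roc_s = final.scores.tolist()
    report = {
        "provenance": {
            "config_hash": config.canonical_hash(),
            "seed": config.seed,
            "sbmorph_version": __version__,
            "versions": _versions(),
            "n_subjects": len(table),
            "grid_shape": list(mask.grid_shape),
            "n_masked_voxels": mask.n_voxels_in,
        },
        "cohort_summary": summary.to_dict(),
        "group_tests": group_tests,
        "feature_set_performance": {
            name: preds[name] and compute_metrics(
                preds[name], subset_name=name, n_boot=0
            ).to_dict()
            for name in config.feature_sets
        },
        "final_model": {
            "feature_set": final_name,
            "chosen_params": final.chosen_params,
            "metrics": final_metrics.to_dict(),
        },
        "diagnosis_performance": [r.to_dict() for r in diag_reports],
        "correlation_table": {
            "variables": variables,
            "r": corr.xs("r", axis=1, level="stat").to_dict(),
            "p_bonferroni": corr.xs("p_bonferroni", axis=1,
                                    level="stat").to_dict(),
        },
        "roc": {"y_true": roc_y, "scores": roc_s,
                "auc": final_metrics.auc, "auc_ci": list(final_metrics.auc_ci)},
        "shap_importance": importance.to_dict(),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    save_json({k: v for k, v in report.items() if k != "timings_s"},
              out / "report.json")
    ablation_report.drop(columns=["auc_ci"]).to_csv(out / "table_feature_sets.csv")
    if diag_reports:
        pd.DataFrame([r.to_dict() for r in diag_reports]).drop(
            columns=["auc_ci"]
        ).to_csv(out / "table_diagnosis.csv", index=False)
    corr.to_csv(out / "table_correlations.csv")
    summary.to_csv(out / "table_cohort_summary.csv")
    importance.to_frame().to_csv(out / "shap_importance.csv")
    beeswarm.to_csv(out / "shap_beeswarm.csv", index=False)
    final.to_frame().to_csv(out / "predictions.csv", index=False)
    return report


def _versions() -> dict:
    import nibabel
    import scipy
    import sklearn

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "nibabel": nibabel.__version__,
    }
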