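"""End-to-end orchestration: impute, select, curve, rank tests, cluster.

One :class:`RunConfig` drives the whole analysis and every artifact is
serialized as canonical JSON (sorted keys) so a rerun with an identical
configuration reproduces byte-identical outputs.  A manifest records all
seeds, stage parameters and the package version.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from . import __version__
from .classifiers import ClassifierSpec
from .clustering import cluster_agreement, fit_multinomial_mixture
from .dataset import impute_class_conditional_mode, load_cohort, load_schema
from .feature_selection import (
    RaceConfig,
    bootstrap_selection_frequencies,
    incremental_subset_evaluation,
)
from .stats import rank_table

log = logging.getLogger("episelect")

__all__ = ["RunConfig", "run_full_analysis"]

DEFAULT_SEED = 20130430


@dataclass
class RunConfig:
    cohort_path: str
    schema_path: str
    out_dir: str
    paradigms: Sequence[str] = ("naive_bayes", "ridge_logistic", "knn")
    B: int = 1000
    seed: int = DEFAULT_SEED
    alpha: float = 0.05
    cluster_K: int = 2
    cluster_restarts: int = 10
    strict_cv_imputation: bool = False

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _curve_payload(curve) -> list[dict]:
    return [
        {
            "size": len(subset),
            "features": list(subset),
            "accuracy": res.accuracy,
            "auc": res.auc,
            "f_measure": res.f_measure,
            "confusion": res.confusion,
        }
        for subset, res in curve.points
    ]


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk).

    Stages: validate + impute the cohort (whole-cohort class-conditional
    imputation, as in the original procedure — this leaks outcome
    information into cross-validation estimates, which is logged), bootstrap
    race-search frequency ranking per paradigm, incremental subset curve per
    paradigm, per-feature rank tests against the outcome, and 2-component
    mixture clustering.  Any stage error aborts the run with the stage name
    in the log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "B": config.B,
        "alpha": config.alpha,
        "paradigms": list(config.paradigms),
        "artifacts": {},
    }

    stage = "load"
    try:
        schema = load_schema(config.schema_path)
        cohort = load_cohort(config.cohort_path, schema)
        stage = "impute"
        if cohort.n_missing():
            log.warning(
                "whole-cohort class-conditional imputation precedes "
                "cross-validation; CV estimates may be optimistic"
            )
            cohort = impute_class_conditional_mode(cohort)
        race_cfg = RaceConfig(alpha=config.alpha)
        for p_i, paradigm in enumerate(config.paradigms):
            spec = ClassifierSpec(paradigm=paradigm)
            stage = f"select[{paradigm}]"
            ranking = bootstrap_selection_frequencies(
                cohort, spec, B=config.B, seed=config.seed + p_i, config=race_cfg
            )
            rk_path = out / f"ranking_{paradigm}.json"
            _dump(
                {
                    "paradigm": paradigm,
                    "B": config.B,
                    "seed": config.seed + p_i,
                    "counts": ranking.counts,
                    "order": ranking.order,
                },
                rk_path,
            )
            manifest["artifacts"][f"ranking_{paradigm}"] = rk_path.name
            stage = f"curve[{paradigm}]"
            curve = incremental_subset_evaluation(ranking, cohort, spec)
            cv_path = out / f"curve_{paradigm}.json"
            _dump(
                {
                    "paradigm": paradigm,
                    "points": _curve_payload(curve),
                    "best": list(curve.best),
                },
                cv_path,
            )
            manifest["artifacts"][f"curve_{paradigm}"] = cv_path.name
        stage = "ranktest"
        table = rank_table(cohort, alpha=config.alpha)
        rt_path = out / "table4.json"
        _dump(table.to_dict(orient="records"), rt_path)
        manifest["artifacts"]["rank_tests"] = rt_path.name
        stage = "cluster"
        model = fit_multinomial_mixture(
            cohort,
            K=config.cluster_K,
            seed=config.seed,
            restarts=config.cluster_restarts,
        )
        report = cluster_agreement(
            model.responsibilities, cohort.outcome, cohort.patient_ids
        )
        cl_path = out / "clusters.json"
        _dump(
            {
                "K": config.cluster_K,
                "seed": config.seed,
                "restarts": config.cluster_restarts,
                "cases": [
                    {
                        "id": pid,
                        "p_c0": float(model.responsibilities[i, 0]),
                        "p_c1": float(model.responsibilities[i, 1]),
                        "outcome": cohort.outcome[i],
                        "correct": pid not in report.misassigned,
                    }
                    for i, pid in enumerate(cohort.patient_ids)
                ],
                "n_correct": report.n_correct,
                "misassigned": list(report.misassigned),
            },
            cl_path,
        )
        manifest["artifacts"]["clusters"] = cl_path.name
    except Exception:
        log.exception("stage %r failed", stage)
        raise
    _dump(manifest, out / "manifest.json")
    return manifest
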