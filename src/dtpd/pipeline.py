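"""Pipeline orchestration: simulate/read -> map -> cluster -> bridge -> rate
-> reliability, and score -> validate, with all artifacts written to disk and
a JSON run report echoing seeds, warnings and headline statistics."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import io as dio
from .concept_mapping import (
    bridging_values,
    build_similarity,
    cluster_ladder,
    embed_map,
    mean_pile_count,
    rating_summary,
    sorter_reliability,
)
from .decision_tool import ToolConfig, score_cohort
from .errors import DTPDError, InputError
from .synthetic import (
    PatientSimConfig,
    SortSimConfig,
    simulate_patients,
    simulate_ratings,
    simulate_sorting,
)
from .validation import roc_points, validate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(DTPDError):
    """A stage failed; the message names the stage, earlier artifacts remain."""


@dataclass
class RunConfig:
    """Everything one reproducible run needs.

    When an input path is None the corresponding dataset is simulated from
    the root seed (each stage draws from its own spawned child seed).
    """

    out_dir: str | Path = "dtpd_run"
    seed: int = 7
    sorts_path: str | None = None
    ratings_path: str | None = None
    patients_path: str | None = None
    # simulation sizes, used only when the corresponding path is None
    n_items: int = 95
    n_sorters: int = 22
    n_patients: int = 368
    n_centres: int = 7
    n_dims: int = 2
    n_starts: int = 8
    k_max: int = 15
    k_min: int = 2
    k_select: int = 6
    cutoff: int = 4
    ci_method: str = "delong"
    cluster_by: str = "centre_id"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stage_seeds(root_seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(root_seed).spawn(4)
    names = ("sorts", "ratings", "patients", "map")
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full three-phase computational pipeline; returns the run
    report (also written to ``out_dir/report.json``)."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    report: dict = {
        "version": __version__,
        "config": {k: str(v) if isinstance(v, Path) else v for k, v in vars(config).items()},
        "seeds": seeds,
        "stages": {},
        "warnings": [],
    }
    stage = "setup"
    try:
        # --- concept mapping phase -----------------------------------------
        stage = "sorts"
        t0 = time.perf_counter()
        if config.sorts_path:
            sorts = dio.read_sorts(config.sorts_path)
            truth = None
        else:
            sorts, truth = simulate_sorting(
                SortSimConfig(
                    n_items=config.n_items,
                    n_sorters=config.n_sorters,
                    seed=seeds["sorts"],
                )
            )
            dio.write_sorts(sorts, out / "sorts.csv")
        invalid = [s for s in sorts.sorters if not sorts.is_valid_sorter(s)]
        if invalid:
            report["warnings"].append(
                {"rule": "invalid_sorter_excluded", "sorters": invalid}
            )
        report["stages"]["sorts"] = {
            "n_items": sorts.n_items,
            "n_sorters": len(sorts.sorters),
            "n_valid_sorters": len(sorts.valid_sorters()),
            "mean_pile_count": mean_pile_count(sorts),
            "seconds": time.perf_counter() - t0,
        }

        stage = "map"
        t0 = time.perf_counter()
        sim = build_similarity(sorts, exclude_invalid=True)
        dio.write_similarity(sim, out / "similarity.csv")
        map_cfg = embed_map(
            sim, n_dims=config.n_dims, seed=seeds["map"], n_starts=config.n_starts
        )
        dio.write_map(map_cfg, out / "map.csv")
        report["stages"]["map"] = {
            "stress": map_cfg.stress,
            "n_iterations": len(map_cfg.stress_history),
            "seconds": time.perf_counter() - t0,
        }

        stage = "cluster"
        t0 = time.perf_counter()
        ladder = cluster_ladder(map_cfg, k_max=config.k_max, k_min=config.k_min)
        bridging = bridging_values(map_cfg, sim)
        selected = None
        for sol in ladder:
            sol = sol.with_bridging(bridging)
            dio.write_clusters(sol, out / f"clusters_k{sol.k}.csv")
            if sol.k == config.k_select:
                selected = sol
        if selected is None:
            raise InputError(
                f"k_select={config.k_select} outside the ladder "
                f"[{config.k_min}, {config.k_max}]"
            )
        report["stages"]["cluster"] = {
            "k_range": [config.k_min, config.k_max],
            "k_selected": config.k_select,
            "cluster_bridging": selected.cluster_bridging,
            "seconds": time.perf_counter() - t0,
        }

        stage = "rate"
        t0 = time.perf_counter()
        if config.ratings_path:
            ratings = dio.read_ratings(config.ratings_path)
        else:
            rng = np.random.default_rng(seeds["ratings"])
            means = {
                c: float(np.clip(rng.normal(4.0, 0.6), 1.0, 6.0))
                for c in set(selected.labels.values())
            }
            ratings = simulate_ratings(
                dict(selected.labels), means, sd=0.8, seed=seeds["ratings"]
            )
            dio.write_ratings(ratings, out / "ratings.csv")
        summary = rating_summary(ratings, selected)
        summary.tests.to_csv(out / "rating_tests.csv", index=False)
        report["stages"]["rate"] = {
            "cluster_means": summary.cluster_means,
            "bonferroni_threshold": summary.threshold,
            "n_significant": int(summary.tests["significant"].sum()),
            "seconds": time.perf_counter() - t0,
        }

        stage = "reliability"
        t0 = time.perf_counter()
        rel = sorter_reliability(sorts, spearman_brown=True)
        if rel.excluded:
            report["warnings"].append(
                {"rule": "constant_copile_vector_excluded", "sorters": list(rel.excluded)}
            )
        report["stages"]["reliability"] = {
            "mean_r": rel.mean_r,
            "sb_corrected": rel.sb_corrected,
            "leave_one_out": rel.leave_one_out,
            "seconds": time.perf_counter() - t0,
        }

        # --- validation phase ----------------------------------------------
        stage = "score"
        t0 = time.perf_counter()
        if config.patients_path:
            records = dio.read_patients(config.patients_path)
        else:
            records, _ = simulate_patients(
                PatientSimConfig(
                    n_patients=config.n_patients,
                    n_centres=config.n_centres,
                    seed=seeds["patients"],
                )
            )
            dio.write_patients(records, out / "patients.csv")
        n_na = sum(
            sum(1 for a in r.answers if a == "na") + (r.gate_q8 == "na")
            for r in records
        )
        if n_na:
            report["warnings"].append({"rule": "na_answers_scored_as_no", "count": n_na})
        tool_cfg = ToolConfig(cutoff=config.cutoff)
        decisions, dist = score_cohort(records, tool_cfg)
        dio.write_decisions(records, decisions, out / "decisions.csv")
        dist.to_csv(out / "score_distribution.csv")
        report["stages"]["score"] = {
            "n_patients": len(records),
            "referral_rate": float(np.mean([d.referral for d in decisions])),
            "seconds": time.perf_counter() - t0,
        }

        stage = "validate"
        t0 = time.perf_counter()
        val = validate_cohort(
            records,
            tool_cfg,
            cluster_by=config.cluster_by,
            ci_method=config.ci_method,
            seed=config.seed,
        )
        val.cutoffs.table.to_csv(out / "cutoff_table.csv", index=False)
        X_lp = val.gee.linear_predictor
        judged = np.array([r.clinical_judgement for r in records])
        roc_points(X_lp, judged).to_csv(out / "roc_points.csv", index=False)
        sens4, spec4 = val.cutoffs.row(config.cutoff)
        report["stages"]["validate"] = {
            "gee_params": dict(val.gee.params),
            "gee_working_corr": val.gee.working_corr,
            "auc": val.auc.auc,
            "auc_ci": [val.auc.ci_low, val.auc.ci_high],
            "cronbach_alpha": val.cronbach_alpha,
            "sensitivity_at_cutoff": sens4,
            "specificity_at_cutoff": spec4,
            "pilot_agreement": dict(val.pilot_agreement),
            "seconds": time.perf_counter() - t0,
        }
    except DTPDError as exc:
        dio.write_report(report, out / "report.json")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    dio.write_report(report, out / "report.json")
    return report
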