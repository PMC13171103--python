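"""Cohort-level orchestration: simulate, analyze, report.

Runs every stage over a synthetic cohort — behavioral labeling, single-cell
ROC tuning with chi-squared group comparisons, bootstrap PCA state
geometry, HMM state decoding, and logistic choice decoding — and collects
all summary statistics in a single JSON-serializable report.  With a fixed
master seed the report is byte-identical across reruns; wall-clock stage
timings go to the logger, not the report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import glm, hmm, tuning
from .behavior import label_states, trials_to_criterion
from .geometry import geometry_bootstrap, stack_group_trajectories
from .stats import compare_groups
from .synth import GeneratorConfig, Session, generate_cohort

log = logging.getLogger("setshift")

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class AnalysisConfig:
    alpha: float = 0.05
    n_perm: int = 1000
    geometry_subset_fraction: float = 0.8
    geometry_iterations: int = 20
    geometry_components: int = 6
    hmm_iterations: int = 200
    glm_iterations: int = 200
    neuron_fraction: float = 0.4
    train_fraction: float = 0.9
    decoder_components: int = 3
    balance_target: int = 31


def default_cohort_configs() -> dict[str, GeneratorConfig]:
    return {
        "control": GeneratorConfig.preset("control"),
        "test": GeneratorConfig.preset("test"),
    }


def _mean_sem(values: np.ndarray) -> dict:
    values = np.asarray(values, dtype=float)
    return {
        "mean": float(values.mean()),
        "sem": float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 else 0.0,
        "n": int(values.size),
    }


def run_pipeline(
    config_control: GeneratorConfig | None = None,
    config_test: GeneratorConfig | None = None,
    n_per_group: int = 4,
    analysis: AnalysisConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Simulate a cohort and run every analysis stage; return the report."""
    configs = default_cohort_configs()
    config_control = config_control or configs["control"]
    config_test = config_test or configs["test"]
    analysis = analysis or AnalysisConfig()
    master = np.random.SeedSequence(seed)
    analysis_seeds = master.spawn(1)[0]

    t0 = time.perf_counter()
    sessions = generate_cohort(config_control, config_test, n_per_group, seed)
    log.info("simulate: %d sessions in %.1fs", len(sessions), time.perf_counter() - t0)

    by_group: dict[str, list[Session]] = {"control": [], "test": []}
    for s in sessions:
        by_group[s.meta["group"]].append(s)

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": int(seed),
        "config": {
            "control": dataclasses.asdict(config_control),
            "test": dataclasses.asdict(config_test),
            "n_per_group": n_per_group,
            "analysis": dataclasses.asdict(analysis),
        },
    }

    # --- behavior ---------------------------------------------------------
    behavior = {}
    labelings = {}
    for group, group_sessions in by_group.items():
        rows = []
        for s in group_sessions:
            lab = label_states(s.trials)
            labelings[s.meta["mouse_id"]] = lab
            rows.append(
                {
                    "mouse_id": s.meta["mouse_id"],
                    "n_trials": int(lab.n_trials),
                    "switch_point": int(lab.switch_point),
                    "trials_to_criterion": trials_to_criterion(s.trials),
                }
            )
        behavior[group] = rows
    report["behavior"] = behavior

    # --- single-cell tuning ----------------------------------------------
    t0 = time.perf_counter()
    rng_tuning = np.random.default_rng(analysis_seeds.spawn(1)[0])
    results_by_group = {}
    for group, group_sessions in by_group.items():
        tables = []
        for s in group_sessions:
            df = tuning.classify_session(
                s,
                labelings[s.meta["mouse_id"]],
                alpha=analysis.alpha,
                n_perm=analysis.n_perm,
                rng=rng_tuning,
            )
            df.insert(0, "mouse_id", s.meta["mouse_id"])
            tables.append(df)
        results_by_group[group] = pd.concat(tables, ignore_index=True)
    fractions = tuning.fraction_table(results_by_group)
    chi2 = tuning.compare_fractions(fractions, "control", "test")
    report["tuning"] = {
        "fractions": fractions.to_dict(orient="records"),
        "group_comparison": chi2.to_dict(orient="records"),
    }
    log.info("tuning: %.1fs", time.perf_counter() - t0)

    # --- population geometry ---------------------------------------------
    t0 = time.perf_counter()
    geo_report = {}
    geo_means = {}
    for group, group_sessions in by_group.items():
        early, late, centers = stack_group_trajectories(group_sessions)
        rng_geo = np.random.default_rng(analysis_seeds.spawn(1)[0])
        metrics = geometry_bootstrap(
            early,
            late,
            centers,
            subset_fraction=analysis.geometry_subset_fraction,
            n_iterations=analysis.geometry_iterations,
            n_components=analysis.geometry_components,
            rng=rng_geo,
        )
        geo_means[group] = {
            "prechoice_mean": np.array([m.prechoice_mean for m in metrics]),
            "prechoice_peak": np.array([m.prechoice_peak for m in metrics]),
            "similarity": np.array([m.similarity for m in metrics]),
        }
        geo_report[group] = {
            key: _mean_sem(vals) for key, vals in geo_means[group].items()
        } | {
            "variance_explained_6pc": _mean_sem(
                np.array([m.variance_explained.sum() for m in metrics])
            )
        }
    for key in ("prechoice_mean", "prechoice_peak", "similarity"):
        res = compare_groups(geo_means["control"][key], geo_means["test"][key])
        geo_report[f"comparison_{key}"] = dataclasses.asdict(res)
    report["geometry"] = geo_report
    log.info("geometry: %.1fs", time.perf_counter() - t0)

    # --- decoders ---------------------------------------------------------
    t0 = time.perf_counter()
    hmm_report = {}
    glm_report = {}
    hmm_session_means = {"control": {"accuracy_all": [], "accuracy_heldout": [], "delta_switch": []}, "test": {"accuracy_all": [], "accuracy_heldout": [], "delta_switch": []}}
    glm_session_means = {"control": [], "test": []}
    for group, group_sessions in by_group.items():
        per_session_hmm = []
        per_session_glm = []
        for s in group_sessions:
            rng_h = np.random.default_rng(analysis_seeds.spawn(1)[0])
            dh = hmm.decode_bootstrap(
                s,
                labelings[s.meta["mouse_id"]],
                n_iterations=analysis.hmm_iterations,
                neuron_fraction=analysis.neuron_fraction,
                train_fraction=analysis.train_fraction,
                n_components=analysis.decoder_components,
                balance_target=analysis.balance_target,
                rng=rng_h,
            )
            sh = hmm.summarize_decode(dh)
            sh["mouse_id"] = s.meta["mouse_id"]
            per_session_hmm.append(sh)
            for key in ("accuracy_all", "accuracy_heldout", "delta_switch"):
                if sh[key]["mean"] is not None:
                    hmm_session_means[group][key].append(sh[key]["mean"])

            rng_g = np.random.default_rng(analysis_seeds.spawn(1)[0])
            dg = glm.choice_decode_bootstrap(
                s,
                n_iterations=analysis.glm_iterations,
                neuron_fraction=analysis.neuron_fraction,
                train_fraction=analysis.train_fraction,
                n_components=analysis.decoder_components,
                balance_target=analysis.balance_target,
                rng=rng_g,
            )
            sg = glm.summarize_choice_decode(dg)
            sg["mouse_id"] = s.meta["mouse_id"]
            per_session_glm.append(sg)
            if sg["accuracy"]["mean"] is not None:
                glm_session_means[group].append(sg["accuracy"]["mean"])
        hmm_report[group] = {
            "sessions": per_session_hmm,
            "group": {
                key: _mean_sem(np.array(vals)) if vals else None
                for key, vals in hmm_session_means[group].items()
            },
        }
        glm_report[group] = {
            "sessions": per_session_glm,
            "group": _mean_sem(np.array(glm_session_means[group]))
            if glm_session_means[group]
            else None,
        }
    for key in ("accuracy_all", "delta_switch"):
        xc = hmm_session_means["control"][key]
        xt = hmm_session_means["test"][key]
        if len(xc) >= 2 and len(xt) >= 2:
            hmm_report[f"comparison_{key}"] = dataclasses.asdict(
                compare_groups(xc, xt)
            )
    if len(glm_session_means["control"]) >= 2 and len(glm_session_means["test"]) >= 2:
        glm_report["comparison_accuracy"] = dataclasses.asdict(
            compare_groups(glm_session_means["control"], glm_session_means["test"])
        )
    report["hmm_decoding"] = hmm_report
    report["glm_decoding"] = glm_report
    log.info("decoders: %.1fs", time.perf_counter() - t0)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(report, out / "report.json")
    return report


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
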