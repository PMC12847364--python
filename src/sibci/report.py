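"""Report generation: per-scenario-size tables, confusion matrices, summaries.

Tables mirror the study layout: 2-class results as a 7 x 7 upper-triangular
grid; 4-, 5- and 6-class results as one row per task combination; every
table carries its significance-threshold row and the configuration hash.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .config import AnalysisConfig, config_hash
from .decode import ScenarioResult
from .stats import binomial_threshold


def scenario_table(results: list[ScenarioResult]) -> pd.DataFrame:
    """One row per scenario: tasks, mean and sd of balanced accuracy (%)."""
    rows = [
        {
            "tasks": r.scenario.name,
            "k": r.scenario.k,
            "mean_acc_pct": round(r.mean_accuracy, 1),
            "sd_acc_pct": round(r.std_accuracy, 1),
            "n_folds": r.fold_accuracies.size,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def pairwise_grid(results: list[ScenarioResult], tasks: tuple[str, ...]) -> pd.DataFrame:
    """Upper-triangular task x task grid of 2-class mean accuracies."""
    grid = pd.DataFrame(np.nan, index=list(tasks), columns=list(tasks))
    for r in results:
        if r.scenario.k != 2:
            raise ValueError("pairwise grid expects 2-class scenarios only")
        a, b = r.scenario.tasks
        i, j = tasks.index(a), tasks.index(b)
        if i > j:
            i, j = j, i
        grid.iloc[i, j] = round(r.mean_accuracy, 1)
    return grid


def confusion_table(result: ScenarioResult) -> pd.DataFrame:
    return pd.DataFrame(result.confusion, index=result.classes, columns=result.classes)


def build_report(
    results_by_size: dict[int, list[ScenarioResult]],
    cfg: AnalysisConfig,
    trials_per_class: int,
    out_dir,
    subjective_summary: pd.DataFrame | None = None,
    extra_meta: dict | None = None,
) -> dict[str, str]:
    """Write TSV tables + a JSON summary; returns {artifact name: path}.

    Every scenario size gets its accuracy table with the matching binomial
    significance threshold; 2-class results additionally get the
    upper-triangular grid; 6-class scenarios get pooled confusion matrices.
    """
    if not results_by_size:
        raise ValueError("no results to report")
    os.makedirs(out_dir, exist_ok=True)
    chash = config_hash(cfg)
    artifacts: dict[str, str] = {}
    summary: dict = {"config_hash": chash, "alpha": cfg.alpha, "sizes": {}}

    for k, results in sorted(results_by_size.items()):
        ks = {r.scenario.k for r in results}
        if ks != {k}:
            raise ValueError(f"mixed scenario sizes {ks} under key {k}")
        thr = binomial_threshold(trials_per_class * k, k, cfg.alpha)
        table = scenario_table(results)
        path = os.path.join(out_dir, f"accuracies_{k}class.tsv")
        with open(path, "w") as fh:
            fh.write(f"# config_hash\t{chash}\n")
            fh.write(
                f"# significance_threshold_pct\t{thr.threshold_pct}\t"
                f"(n={thr.n_trials}, alpha={cfg.alpha}, no multiple-testing correction)\n"
            )
            table.to_csv(fh, sep="\t", index=False)
        artifacts[f"accuracies_{k}class"] = path
        summary["sizes"][k] = {
            "threshold_pct": thr.threshold_pct,
            "chance_pct": round(thr.chance_pct, 1),
            "n_scenarios": len(results),
            "grand_mean_acc_pct": round(
                float(np.mean([r.mean_accuracy for r in results])), 1
            ),
        }
        if k == 2:
            tasks = tuple(
                dict.fromkeys(t for r in results for t in r.scenario.tasks)
            )
            gpath = os.path.join(out_dir, "accuracies_2class_grid.tsv")
            pairwise_grid(results, tasks).to_csv(gpath, sep="\t")
            artifacts["accuracies_2class_grid"] = gpath
        if k == 6:
            for r in results:
                cpath = os.path.join(out_dir, f"confusion_{r.scenario.name}.tsv")
                confusion_table(r).to_csv(cpath, sep="\t")
                artifacts[f"confusion_{r.scenario.name}"] = cpath

    if subjective_summary is not None:
        spath = os.path.join(out_dir, "subjective_summary.tsv")
        subjective_summary.to_csv(spath, sep="\t", index=False)
        artifacts["subjective_summary"] = spath

    if extra_meta:
        summary.update(extra_meta)
    jpath = os.path.join(out_dir, "summary.json")
    with open(jpath, "w") as fh:
        json.dump(summary, fh, indent=2)
    artifacts["summary"] = jpath
    return artifacts
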