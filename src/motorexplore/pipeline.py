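"""End-to-end orchestration on synthetic cohorts.

Reproduces the analysis workflow without any external data: generate
synthetic experiments, compute exploration metrics, run the group
statistics, fit the model family, and write a model-selection table plus a
manifest that makes every stage reproducible from its seeds.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .fitting import FitConfig, select_model
from .inference_stats import bootstrap_mean_test
from .metrics import CohortSummary, summarize_cohort
from .model_core import MODEL_SPECS, REFERENCE_PARAMS, ModelParams
from .synthetic_data import (
    DESIGNS,
    CohortConfig,
    design_from_id,
    generate_experiment,
    make_pd_cohort_config,
)

__all__ = [
    "Profile",
    "PROFILES",
    "RunManifest",
    "run_apriori_predictions",
    "run_full_pipeline",
]


@dataclass(frozen=True)
class Profile:
    """Budget profile stamped into every output.

    ``paper`` carries the full budgets (10,000 warm starts and bootstrap
    iterations, 500 simulated individuals, 1,000,000 test iterations);
    ``test`` is the desk-scale profile.
    """

    name: str
    n_warm_starts: int
    n_bootstrap: int
    n_sim_individuals: int
    n_test_iterations: int
    n_cohort: int  # simulees for a priori cohort predictions


PROFILES = {
    "paper": Profile("paper", 10_000, 10_000, 500, 1_000_000, 500),
    "test": Profile("test", 50, 200, 100, 10_000, 100),
}


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    seed: int
    profile: str
    stages: dict[str, dict] = field(default_factory=dict)

    def add_stage(self, name: str, outputs: list[str], elapsed_s: float, **extra):
        entry = {
            "outputs": outputs,
            "hashes": {p: _sha256(p) for p in outputs},
            "elapsed_s": round(elapsed_s, 3),
        }
        entry.update(extra)
        self.stages[name] = entry

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {"seed": self.seed, "profile": self.profile, "stages": self.stages},
                indent=2,
            )
        )


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _pd_alpha_scale(params: ModelParams, target_alpha: float = 0.5) -> float:
    return target_alpha / params.alpha_x


def run_apriori_predictions(
    output_dir,
    seed: int,
    n_individuals: int = 500,
    params: ModelParams = REFERENCE_PARAMS,
) -> dict[str, pd.DataFrame]:
    """Theory-driven cohort predictions for all three designs.

    Simulates the general model at the reference parameters for each design
    (the Parkinson's-like group with alpha reduced to 0.5) and writes, per
    design, the per-individual ACF distribution and the cell means -- the
    per-condition ACF distributions behind the a priori predictions.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    base_config = CohortConfig(
        params_by_group={g: params for g in ("young", "control")},
        spec=MODEL_SPECS[1],
    )
    pd_config = make_pd_cohort_config(base_config, _pd_alpha_scale(params))
    tables: dict[str, pd.DataFrame] = {}
    for design_id, design in DESIGNS.items():
        params_by_group = {}
        for group in design.groups:
            source = pd_config if group == "parkinsons" else base_config
            key = group if group in source.params_by_group else "control"
            params_by_group[group] = source.params_by_group[key]
        design = design.__class__(
            design.design_id,
            design.conditions,
            design.trials_per_condition,
            {g: n_individuals for g in design.groups},
        )
        config = CohortConfig(params_by_group=params_by_group, spec=MODEL_SPECS[1])
        series, _ = generate_experiment(design, config, seed)
        summary = summarize_cohort(series)
        summary.participant_acf.to_csv(out / f"apriori_{design_id}_acf.csv", index=False)
        summary.cells.to_csv(out / f"apriori_{design_id}_cells.csv", index=False)
        tables[design_id] = summary.cells
    return tables


def run_full_pipeline(
    design_ids: list[str],
    cohort_config: CohortConfig,
    fit_config: FitConfig,
    output_dir,
    seed: int,
    profile: str = "test",
    model_ids: list[int] | None = None,
) -> RunManifest:
    """Generate -> metrics -> group statistics -> model selection -> report.

    Every stage writes tidy CSV/JSON into ``output_dir`` and is logged in
    the returned manifest with output hashes, so a rerun from the same
    seeds reproduces the outputs byte for byte.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    prof = PROFILES[profile]
    manifest = RunManifest(seed=seed, profile=profile)

    # generate
    t0 = time.perf_counter()
    all_series = []
    gen_outputs = []
    for design_id in design_ids:
        design = design_from_id(design_id)
        series, gen_manifest = generate_experiment(design, cohort_config, seed)
        all_series.extend(series)
        data_path = out / f"{design_id}_trials.csv"
        io.write_trial_series_csv(series, data_path)
        man_path = out / f"{design_id}_manifest.json"
        man_path.write_text(json.dumps(gen_manifest, indent=2))
        gen_outputs += [str(data_path), str(man_path)]
    manifest.add_stage("generate", gen_outputs, time.perf_counter() - t0)

    # metrics
    t0 = time.perf_counter()
    summary = summarize_cohort(all_series)
    acf_path = out / "participant_acf.csv"
    cells_path = out / "summary_cells.csv"
    summary.participant_acf.to_csv(acf_path, index=False)
    summary.cells.to_csv(cells_path, index=False)
    manifest.add_stage(
        "metrics", [str(acf_path), str(cells_path)], time.perf_counter() - t0
    )

    # group statistics: reinforcement vs error along the major axis
    t0 = time.perf_counter()
    stats = {}
    acf = summary.participant_acf
    for (experiment, group), block in acf[acf["axis"] == "major"].groupby(
        ["experiment", "group"], sort=True
    ):
        by_cond = {
            cond: cblock.set_index("participant_id")["acf"].dropna()
            for cond, cblock in block.groupby("condition")
        }
        if {"reinforcement", "error"} <= set(by_cond):
            a = by_cond["reinforcement"]
            b = by_cond["error"].reindex(a.index).dropna()
            a = a.reindex(b.index)
            res = bootstrap_mean_test(
                a.to_numpy(),
                b.to_numpy(),
                paired=True,
                direction="greater",
                n_iterations=prof.n_test_iterations,
                seed=seed,
            )
            stats[f"{experiment}/{group}/reinforcement_gt_error"] = {
                "p": res.p,
                "effect_size_pct": res.effect_size,
                "mean_diff": res.mean_diff,
                "n_iterations": res.n_iterations,
            }
    stats_path = out / "group_stats.json"
    stats_path.write_text(json.dumps(stats, indent=2))
    manifest.add_stage("stats", [str(stats_path)], time.perf_counter() - t0)

    # model selection
    t0 = time.perf_counter()
    ids = model_ids if model_ids is not None else sorted(MODEL_SPECS)
    table = select_model(summary, [MODEL_SPECS[i] for i in ids], fit_config)
    table_path = out / "model_selection.csv"
    table.to_csv(table_path, index=False)
    manifest.add_stage(
        "select_models", [str(table_path)], time.perf_counter() - t0,
        model_ids=ids,
    )

    manifest.write(out / "run_manifest.json")
    return manifest
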