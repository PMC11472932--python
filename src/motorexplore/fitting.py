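"""Simulation-based model fitting and selection.

Models are fit to cohort-mean lag-1 autocorrelations, not to raw trials:
the objective regenerates a synthetic cohort at every candidate parameter
set and scores the squared difference between simulated and observed cell
means over (axis x condition [x group]) cells.  Common random numbers --
one fixed set of noise deviates per fit -- make the objective a
deterministic function of the parameters, which lets a derivative-free
local optimizer (Powell, bound-constrained) work on it.  Multi-start
optimization provides the warm start; a participant-level bootstrap
re-optimizes resampled data to give percentile posteriors, whose medians
are the reported parameters.  AIC/BIC on the cell loss rank the nine-model
family.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, minimize

from ._kernel import lag1_columns, simulate_paths
from .metrics import AXES, CohortSummary
from .model_core import (
    PARAM_NAMES,
    SIGMA_NAMES,
    ModelParams,
    ModelSpec,
    apply_condition,
    session_seeds,
)
from .synthetic_data import WIDTH_SCALE, ExperimentDesign, design_from_id

__all__ = [
    "FitConfig",
    "FitResult",
    "loss_components",
    "information_criteria",
    "simulated_acf_cells",
    "sigma_bounds_from_series",
    "fit_model",
    "fit_groups_shared_sigma",
    "select_model",
]

_EXPERIMENT_LOSS = {"exp1": "L1", "exp2": "L2", "exp3": "L3"}
_PCTS = (2.5, 25.0, 50.0, 75.0, 97.5)


@dataclass
class FitConfig:
    """Budgets, bounds and seeds of one fitting run.

    ``n_warm_starts`` random initializations are locally optimized with a
    per-start evaluation cap ``maxfev_start``; the best is polished with
    ``maxfev_polish`` and seeds ``n_bootstrap`` re-optimizations (cap
    ``maxfev_boot``) of participant-resampled data.  ``n_sim_individuals``
    is the cohort size simulated per objective evaluation.  Gains are
    bounded to [0, 1]; noise SDs to ``sigma_bounds`` (cm), ideally the
    smallest and largest observed participant variability.
    """

    n_warm_starts: int = 50
    n_bootstrap: int = 200
    n_sim_individuals: int = 100
    sigma_bounds: tuple[float, float] = (0.01, 3.0)
    seed: int = 0
    resample: bool = True
    maxfev_start: int = 200
    maxfev_polish: int = 600
    maxfev_boot: int = 80
    xtol: float = 1e-3
    ftol: float = 1e-4
    #: cohort size for scoring the final parameter set (defaults to
    #: n_sim_individuals); a larger scoring cohort stabilizes the reported
    #: loss the way the full protocol's 500-simulee estimates do
    n_sim_final: Optional[int] = None

    def __post_init__(self) -> None:
        if min(self.n_warm_starts, self.n_bootstrap, self.n_sim_individuals) < 1:
            raise ValueError("all fit budgets must be >= 1")
        lo, hi = self.sigma_bounds
        if not lo < hi:
            raise ValueError("sigma_bounds must be an ordered interval")


@dataclass
class FitResult:
    """Fitted parameters with losses, information criteria and bootstrap percentiles."""

    params: ModelParams
    spec: ModelSpec
    losses: dict[str, float]
    k: int
    n: int
    aic: float
    bic: float
    percentiles: dict[str, dict[float, float]]
    warm_start: dict[str, float]
    warm_loss: float

    @property
    def loss(self) -> float:
        return self.losses["L_total"]


def loss_components(
    data: CohortSummary, model: CohortSummary
) -> dict[str, float]:
    """Squared-difference loss between observed and simulated cell means.

    Cells are matched on (experiment, group, condition, axis); each
    experiment present contributes its own component (L1 for exp1, L2 for
    exp2, L3 for exp3 with both groups), and L_total is their sum.
    """
    dmeans = data.cell_means()
    mmeans = model.cell_means()
    if set(dmeans) != set(mmeans):
        raise ValueError("data and model summaries cover different cells")
    losses = {"L1": 0.0, "L2": 0.0, "L3": 0.0}
    for key, dval in dmeans.items():
        experiment = key[0]
        try:
            name = _EXPERIMENT_LOSS[experiment]
        except KeyError:
            raise ValueError(f"cell with unknown experiment label {experiment!r}")
        losses[name] += (dval - mmeans[key]) ** 2
    losses["L_total"] = losses["L1"] + losses["L2"] + losses["L3"]
    return losses


def information_criteria(k: int, n: int, L_total: float) -> tuple[float, float]:
    """AIC = 2k + n ln(L); BIC = k ln(n) + n ln(L).  Lower is better."""
    if L_total <= 0:
        raise ValueError("information criteria need a positive loss")
    if n < 1:
        raise ValueError("n must be >= 1")
    aic = 2.0 * k + n * np.log(L_total)
    bic = k * np.log(n) + n * np.log(L_total)
    return float(aic), float(bic)


def _cohort_deviates(seed: int, n_individuals: int, n_trials: int) -> np.ndarray:
    """Stacked per-individual deviates, (n_trials, 4, n_individuals).

    Individual i's column reproduces the stream simulate_session would draw
    from the i-th derived sub-seed, so the batched evaluator and the public
    cohort simulator are sample-for-sample identical.
    """
    seeds = session_seeds(seed, n_individuals)
    z = np.empty((n_trials, 4, n_individuals))
    for i, sub in enumerate(seeds):
        z[:, :, i] = np.random.default_rng(int(sub)).standard_normal((n_trials, 4))
    return z


def _acf_means_from_z(
    params: ModelParams, spec: ModelSpec, conditions: Sequence[str], z: np.ndarray
) -> dict[tuple[str, str], float]:
    """Mean ACF per (condition, axis) for a cohort sharing deviates ``z``."""
    n_sim = z.shape[2]
    hl = np.full(n_sim, 6.0)
    r0 = np.ones(n_sim, dtype=np.int8)
    width = WIDTH_SCALE * params.sigma_M_x
    hw = np.full(n_sim, width / 2.0)
    out: dict[tuple[str, str], float] = {}
    for condition in conditions:
        eff = apply_condition(params, condition, spec)
        theta = np.ascontiguousarray(
            np.repeat(eff.as_array()[:, None], n_sim, axis=1)
        )
        x, y, _, _, _ = simulate_paths(z, theta, hw, hl, r0)
        for axis, mat in (("minor", x), ("major", y)):
            acfs = lag1_columns(mat)
            out[(condition, axis)] = float(np.nanmean(acfs))
    return out


def simulated_acf_cells(
    params: ModelParams,
    spec: ModelSpec,
    design: ExperimentDesign,
    n_individuals: int,
    seed: int,
    group: str = "sim",
) -> CohortSummary:
    """Cohort-mean ACF cells for one design at fixed parameters.

    Equivalent to simulate_cohort + summarize_cohort at the same seed (a
    property the tests assert), but computed without materializing trial
    records.  The simulated target width follows the baseline-scaling rule
    applied to the candidate motor-noise SD.
    """
    z = _cohort_deviates(seed, n_individuals, design.trials_per_condition)
    means = _acf_means_from_z(params, spec, design.conditions, z)
    rows = [
        {
            "experiment": design.design_id,
            "group": group,
            "condition": condition,
            "axis": axis,
            "mean_acf": means[(condition, axis)],
            "n": n_individuals,
        }
        for condition in design.conditions
        for axis in AXES
    ]
    return CohortSummary(pd.DataFrame(rows))


def sigma_bounds_from_series(series_set) -> tuple[float, float]:
    """Noise-SD bounds from the smallest and largest participant endpoint SD."""
    sds = []
    for series in series_set:
        pts = series.endpoints()
        sds.extend(np.std(pts, axis=0, ddof=1))
    sds = np.asarray(sds)
    sds = sds[sds > 0]
    if sds.size == 0:
        raise ValueError("no usable endpoint variability in series set")
    return float(sds.min()), float(sds.max())


# ---------------------------------------------------------------------------
# internal optimization machinery


def _bounds_for(names: Sequence[str], config: FitConfig) -> list[tuple[float, float]]:
    return [
        config.sigma_bounds if name in SIGMA_NAMES else (0.0, 1.0) for name in names
    ]


def _minimize(objective, x0, bounds, config: FitConfig, maxfev: int):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OptimizeWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        res = minimize(
            objective,
            x0,
            method="Powell",
            bounds=bounds,
            options={
                "maxfev": maxfev,
                "xtol": config.xtol,
                "ftol": config.ftol,
            },
        )
    return np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds]), float(res.fun)


def _multistart(objective, bounds, config: FitConfig, rng) -> tuple[np.ndarray, float]:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    best_x, best_f = None, np.inf
    for _ in range(config.n_warm_starts):
        x0 = rng.uniform(lo, hi)
        x, f = _minimize(objective, x0, bounds, config, config.maxfev_start)
        if f < best_f:
            best_x, best_f = x, f
    if best_x is None or not np.isfinite(best_f):
        raise RuntimeError("all warm starts failed to produce a finite loss")
    x, f = _minimize(objective, best_x, bounds, config, config.maxfev_polish)
    if f < best_f:
        best_x, best_f = x, f
    return best_x, best_f


def _resample_cells(
    participant_acf: pd.DataFrame, rng
) -> dict[tuple[str, str, str, str], float]:
    """Participant-level bootstrap: resample ids within (experiment, group).

    A drawn participant contributes all of their condition x axis ACFs, so
    within-participant structure survives the resampling.
    """
    out: dict[tuple, list[float]] = {}
    for (experiment, group), block in participant_acf.groupby(
        ["experiment", "group"], sort=True
    ):
        ids = block["participant_id"].unique()
        draw = ids[rng.integers(0, len(ids), size=len(ids))]
        counts = pd.Series(draw).value_counts()
        sub = block[np.isfinite(block["acf"])]
        weights = sub["participant_id"].map(counts).fillna(0.0).to_numpy()
        for (condition, axis), cell in sub.groupby(["condition", "axis"], sort=True):
            w = weights[sub.index.get_indexer(cell.index)]
            if w.sum() == 0:
                continue
            out[(experiment, group, condition, axis)] = [
                float(np.average(cell["acf"], weights=w))
            ]
    return {key: val[0] for key, val in out.items()}


@dataclass
class _Problem:
    """One optimization problem: free names, bounds, and a model evaluator."""

    free_names: list[str]
    bounds: list[tuple[float, float]]
    cell_keys: list[tuple[str, str, str, str]]
    model_values: Callable[[np.ndarray], np.ndarray]  # theta -> per-cell values

    def objective_for(self, data_values: np.ndarray):
        def objective(theta):
            diff = data_values - self.model_values(theta)
            return float(diff @ diff)

        return objective


def _run_fit(
    problem: _Problem,
    data: CohortSummary,
    config: FitConfig,
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Multi-start + bootstrap on a problem; returns (warm, warm_loss, solutions, theta_hat)."""
    dmeans = data.cell_means()
    data_values = np.array([dmeans[key] for key in problem.cell_keys])
    rng = np.random.default_rng(config.seed)
    warm_x, warm_f = _multistart(
        problem.objective_for(data_values), problem.bounds, config, rng
    )
    if config.resample and config.n_bootstrap > 1:
        if data.participant_acf is None:
            raise ValueError("bootstrap resampling needs participant-level ACFs")
        solutions = np.empty((config.n_bootstrap, len(problem.free_names)))
        for b in range(config.n_bootstrap):
            cells = _resample_cells(data.participant_acf, rng)
            values = np.array(
                [cells.get(key, dmeans[key]) for key in problem.cell_keys]
            )
            x, _ = _minimize(
                problem.objective_for(values),
                warm_x,
                problem.bounds,
                config,
                config.maxfev_boot,
            )
            solutions[b] = x
    else:
        solutions = warm_x[None, :]
    theta_hat = np.median(solutions, axis=0)
    return warm_x, warm_f, solutions, theta_hat


def _percentiles(
    free_names: Sequence[str], solutions: np.ndarray
) -> dict[str, dict[float, float]]:
    pct = np.percentile(solutions, _PCTS, axis=0)
    return {
        name: {p: float(pct[i, j]) for i, p in enumerate(_PCTS)}
        for j, name in enumerate(free_names)
    }


def _clipped(name: str, value: float) -> float:
    # Powell's line search may probe a hair outside the box constraints
    if name in SIGMA_NAMES:
        return max(float(value), 0.0)
    return float(np.clip(value, 0.0, 1.0))


def _params_from_free(
    free_names: Sequence[str], theta: np.ndarray, spec: ModelSpec
) -> ModelParams:
    values = dict.fromkeys(PARAM_NAMES, 0.0)
    values.update({n: _clipped(n, v) for n, v in zip(free_names, theta)})
    return ModelParams(**values)


# ---------------------------------------------------------------------------
# public fitting entry points


def _single_group_problem(
    data: CohortSummary, spec: ModelSpec, config: FitConfig, n_sim: int
) -> _Problem:
    free_names = list(spec.free_params)
    bounds = _bounds_for(free_names, config)
    blocks = []  # (design, group, z)
    cell_keys: list[tuple[str, str, str, str]] = []
    for (experiment, group), block in data.cells.groupby(
        ["experiment", "group"], sort=True
    ):
        design = design_from_id(experiment)
        conditions = [c for c in design.conditions if c in set(block["condition"])]
        z = _cohort_deviates(
            config.seed + len(blocks), n_sim, design.trials_per_condition,
        )
        blocks.append((design, group, conditions, z))
        for condition in conditions:
            for axis in AXES:
                cell_keys.append((experiment, group, condition, axis))

    def model_values(theta: np.ndarray) -> np.ndarray:
        params = _params_from_free(free_names, theta, spec)
        values = []
        for design, group, conditions, z in blocks:
            means = _acf_means_from_z(params, spec, conditions, z)
            for condition in conditions:
                for axis in AXES:
                    values.append(means[(condition, axis)])
        return np.array(values)

    return _Problem(free_names, bounds, cell_keys, model_values)


def fit_model(
    data: CohortSummary,
    spec: ModelSpec,
    config: FitConfig,
    designs: Optional[Iterable[ExperimentDesign]] = None,
) -> FitResult:
    """Fit one model variant to observed cohort-mean ACF cells.

    The experiments fitted are read from the experiment labels in ``data``
    (``designs`` may restrict them).  The objective regenerates a cohort of
    ``config.n_sim_individuals`` per evaluation from fixed deviates, so it
    is deterministic in the parameters.  Reported parameters are bootstrap
    medians; k counts the variant's free parameters and n the cells scored.
    """
    if designs is not None:
        keep = {d.design_id for d in designs}
        data = data.subset(experiment=sorted(keep))
    problem = _single_group_problem(data, spec, config, config.n_sim_individuals)
    warm_x, warm_f, solutions, theta_hat = _run_fit(problem, data, config)
    params = _params_from_free(problem.free_names, theta_hat, spec)
    n_final = config.n_sim_final or config.n_sim_individuals
    score_problem = (
        problem
        if n_final == config.n_sim_individuals
        else _single_group_problem(data, spec, config, n_final)
    )
    model = _model_summary_like(data, score_problem, theta_hat)
    losses = loss_components(data, model)
    k, n = spec.n_free, len(data.cells)
    aic, bic = information_criteria(k, n, losses["L_total"])
    return FitResult(
        params=params,
        spec=spec,
        losses=losses,
        k=k,
        n=n,
        aic=aic,
        bic=bic,
        percentiles=_percentiles(problem.free_names, solutions),
        warm_start=dict(zip(problem.free_names, warm_x)),
        warm_loss=warm_f,
    )


def _model_summary_like(
    data: CohortSummary, problem: _Problem, theta: np.ndarray
) -> CohortSummary:
    values = problem.model_values(theta)
    rows = [
        {
            "experiment": experiment,
            "group": group,
            "condition": condition,
            "axis": axis,
            "mean_acf": float(np.clip(val, -1.0, 1.0)),
            "n": 1,
        }
        for (experiment, group, condition, axis), val in zip(
            problem.cell_keys, values
        )
    ]
    return CohortSummary(pd.DataFrame(rows))


def fit_groups_shared_sigma(
    data_pd: CohortSummary,
    data_control: CohortSummary,
    spec: ModelSpec,
    config: FitConfig,
) -> tuple[FitResult, FitResult]:
    """Joint two-group fit with shared noise SDs and per-group gains.

    Both groups share the four movement-variability terms; each group gets
    its own reinforcement and error-correction gains.  One optimization
    minimizes the summed loss; each group is then reported as its own
    FitResult (identical sigma values), with its own loss and AIC/BIC.
    k per group counts that group's free gains plus an equal (half) share
    of the shared SDs.

    Returns ``(result_pd, result_control)`` matching the argument order.
    """
    gain_names = [n for n in spec.free_params if n not in SIGMA_NAMES]
    free_names = (
        list(SIGMA_NAMES)
        + [f"pd:{n}" for n in gain_names]
        + [f"control:{n}" for n in gain_names]
    )
    bounds = (
        _bounds_for(SIGMA_NAMES, config)
        + _bounds_for(gain_names, config) * 2
    )
    n_gain = len(gain_names)

    group_data = {"pd": data_pd, "control": data_control}

    def build_blocks(n_sim: int):
        blocks = {}
        cell_keys: list[tuple[str, str, str, str]] = []
        for gi, (tag, gdata) in enumerate(group_data.items()):
            experiments = sorted(gdata.cells["experiment"].unique())
            groups = gdata.cells["group"].unique()
            if len(experiments) != 1 or len(groups) != 1:
                raise ValueError(
                    "each group summary must cover one experiment and one group"
                )
            design = design_from_id(experiments[0])
            conditions = [
                c for c in design.conditions if c in set(gdata.cells["condition"])
            ]
            z = _cohort_deviates(config.seed + gi, n_sim, design.trials_per_condition)
            blocks[tag] = (design, groups[0], conditions, z)
            for condition in conditions:
                for axis in AXES:
                    cell_keys.append((experiments[0], groups[0], condition, axis))
        return blocks, cell_keys

    blocks, cell_keys = build_blocks(config.n_sim_individuals)

    def split(theta: np.ndarray) -> dict[str, ModelParams]:
        sigmas = {n: _clipped(n, v) for n, v in zip(SIGMA_NAMES, theta[:4])}
        out = {}
        for gi, tag in enumerate(group_data):
            gains = {
                n: _clipped(n, v)
                for n, v in zip(
                    gain_names, theta[4 + gi * n_gain : 4 + (gi + 1) * n_gain]
                )
            }
            values = dict.fromkeys(PARAM_NAMES, 0.0)
            values.update(sigmas)
            values.update(gains)
            out[tag] = ModelParams(**values)
        return out

    def model_values_over(blocks_in):
        def model_values(theta: np.ndarray) -> np.ndarray:
            per_group = split(theta)
            values = []
            for tag, (design, group, conditions, z) in blocks_in.items():
                means = _acf_means_from_z(per_group[tag], spec, conditions, z)
                for condition in conditions:
                    for axis in AXES:
                        values.append(means[(condition, axis)])
            return np.array(values)

        return model_values

    problem = _Problem(free_names, bounds, cell_keys, model_values_over(blocks))
    merged = CohortSummary(
        pd.concat([data_pd.cells, data_control.cells], ignore_index=True),
        None
        if data_pd.participant_acf is None or data_control.participant_acf is None
        else pd.concat(
            [data_pd.participant_acf, data_control.participant_acf],
            ignore_index=True,
        ),
    )
    warm_x, warm_f, solutions, theta_hat = _run_fit(problem, merged, config)
    per_group = split(theta_hat)
    n_final = config.n_sim_final or config.n_sim_individuals
    if n_final != config.n_sim_individuals:
        final_blocks, _ = build_blocks(n_final)
        score_problem = _Problem(
            free_names, bounds, cell_keys, model_values_over(final_blocks)
        )
    else:
        score_problem = problem
    model = _model_summary_like(merged, score_problem, theta_hat)

    results = {}
    k_shared = len(SIGMA_NAMES) / 2.0
    for tag, gdata in group_data.items():
        gmodel = model.subset(group=blocks[tag][1], experiment=blocks[tag][0].design_id)
        losses = loss_components(gdata, gmodel)
        k = n_gain + k_shared
        n = len(gdata.cells)
        aic, bic = information_criteria(k, n, losses["L_total"])
        prefix = f"{tag}:"
        pct_names = list(SIGMA_NAMES) + [
            name for name in free_names if name.startswith(prefix)
        ]
        idx = [free_names.index(name) for name in pct_names]
        pct = _percentiles(
            [name.removeprefix(prefix) for name in pct_names], solutions[:, idx]
        )
        results[tag] = FitResult(
            params=per_group[tag],
            spec=spec,
            losses=losses,
            k=k,
            n=n,
            aic=aic,
            bic=bic,
            percentiles=pct,
            warm_start=dict(zip(free_names, warm_x)),
            warm_loss=warm_f,
        )
    return results["pd"], results["control"]


def select_model(
    data: CohortSummary,
    specs: Iterable[ModelSpec],
    config: FitConfig,
) -> pd.DataFrame:
    """Fit every model variant and rank by summed information criteria.

    Experiments 1 and 2 are fit jointly (one parameter set, one combined
    score); Experiment-3 groups are fit with shared noise SDs and scored
    separately.  The reported score per model is the sum of all its AIC
    (resp. BIC) scores; ranking is ascending AIC with ties broken by the
    smaller parameter count.
    """
    specs = list(specs)
    if len(specs) < 2:
        raise ValueError("model selection needs at least two specs")
    experiments = set(data.cells["experiment"].unique())
    rows = []
    for spec in specs:
        total = {"L_total": 0.0, "aic": 0.0, "bic": 0.0}
        exp12 = sorted(experiments & {"exp1", "exp2"})
        if exp12:
            res12 = fit_model(data.subset(experiment=exp12), spec, config)
            total["L_total"] += res12.loss
            total["aic"] += res12.aic
            total["bic"] += res12.bic
        if "exp3" in experiments:
            d3 = data.subset(experiment="exp3")
            groups = sorted(d3.cells["group"].unique())
            if len(groups) != 2:
                raise ValueError("exp3 selection expects exactly two groups")
            res_a, res_b = fit_groups_shared_sigma(
                d3.subset(group=groups[0]), d3.subset(group=groups[1]), spec, config
            )
            for res in (res_a, res_b):
                total["L_total"] += res.loss
                total["aic"] += res.aic
                total["bic"] += res.bic
        rows.append(
            {
                "model_id": spec.model_id,
                "k": spec.n_free,
                "removed": ",".join(sorted(spec.zeroed_params)) or "none",
                "L_total": total["L_total"],
                "AIC": total["aic"],
                "BIC": total["bic"],
            }
        )
    return _rank_table(rows)


def _rank_table(rows: list[dict]) -> pd.DataFrame:
    """Ascending AIC; ties go to the model with fewer free parameters."""
    table = pd.DataFrame(rows).sort_values(
        ["AIC", "k"], kind="mergesort", ignore_index=True
    )
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table
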