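"""Tests for the simulation-based loss, information criteria and fitting."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motorexplore import (
    MODEL_SPECS,
    REFERENCE_PARAMS,
    FitConfig,
    ModelParams,
    TargetGeometry,
    fit_groups_shared_sigma,
    fit_model,
    information_criteria,
    loss_components,
    simulate_cohort,
    simulated_acf_cells,
    summarize_cohort,
)
from motorexplore.fitting import _rank_table, sigma_bounds_from_series
from motorexplore.metrics import AXES, CohortSummary
from motorexplore.synthetic_data import EXP1, EXP3, CohortConfig, generate_experiment


def summary_from_values(values: dict) -> CohortSummary:
    rows = [
        {
            "experiment": e, "group": g, "condition": c, "axis": a,
            "mean_acf": v, "n": 5,
        }
        for (e, g, c, a), v in values.items()
    ]
    return CohortSummary(pd.DataFrame(rows))


def random_summary_pair(rng, experiments=("exp1", "exp2", "exp3")):
    conditions = {
        "exp1": ["reinforcement", "error"],
        "exp2": ["reinforcement", "error", "reinforcement_and_error"],
        "exp3": ["reinforcement", "error", "reinforcement_and_error"],
    }
    groups = {"exp1": ["young"], "exp2": ["young"], "exp3": ["control", "parkinsons"]}
    data, model = {}, {}
    for e in experiments:
        for g in groups[e]:
            for c in conditions[e]:
                for a in AXES:
                    data[(e, g, c, a)] = rng.uniform(-0.5, 0.9)
                    model[(e, g, c, a)] = rng.uniform(-0.5, 0.9)
    return data, model


class TestLossComponents:
    def test_perfect_fit_gives_zero(self):
        rng = np.random.default_rng(0)
        data, _ = random_summary_pair(rng)
        losses = loss_components(summary_from_values(data), summary_from_values(data))
        assert losses == {"L1": 0.0, "L2": 0.0, "L3": 0.0, "L_total": 0.0}

    def test_single_cell_difference(self):
        rng = np.random.default_rng(1)
        data, _ = random_summary_pair(rng, experiments=("exp1",))
        model = dict(data)
        key = ("exp1", "young", "error", "major")
        model[key] = data[key] + 0.1
        losses = loss_components(summary_from_values(data), summary_from_values(model))
        assert losses["L1"] == pytest.approx(0.01)
        assert losses["L_total"] == pytest.approx(0.01)
        assert losses["L2"] == losses["L3"] == 0.0

    def test_matches_brute_force_accumulation(self):
        rng = np.random.default_rng(2)
        data, model = random_summary_pair(rng)
        losses = loss_components(summary_from_values(data), summary_from_values(model))
        expected = {"L1": 0.0, "L2": 0.0, "L3": 0.0}
        for key, dval in data.items():
            expected[{"exp1": "L1", "exp2": "L2", "exp3": "L3"}[key[0]]] += (
                dval - model[key]
            ) ** 2
        for name in ("L1", "L2", "L3"):
            assert losses[name] == pytest.approx(expected[name], abs=1e-12)
        assert losses["L_total"] == pytest.approx(sum(expected.values()), abs=1e-12)

    def test_mismatched_cells_rejected(self):
        rng = np.random.default_rng(3)
        data, model = random_summary_pair(rng, experiments=("exp1",))
        model.pop(("exp1", "young", "error", "major"))
        with pytest.raises(ValueError, match="different cells"):
            loss_components(summary_from_values(data), summary_from_values(model))


class TestInformationCriteria:
    def test_unit_loss_zero_parameters(self):
        assert information_criteria(0, 17, 1.0) == (0.0, 0.0)

    def test_parameter_penalty_increments(self):
        n, L = 25, 0.4
        aic0, bic0 = information_criteria(3, n, L)
        aic1, bic1 = information_criteria(4, n, L)
        assert aic1 - aic0 == pytest.approx(2.0)
        assert bic1 - bic0 == pytest.approx(np.log(n))

    def test_closed_form(self):
        aic, bic = information_criteria(9, 10, 0.23)
        assert aic == pytest.approx(2 * 9 + 10 * np.log(0.23), abs=1e-10)
        assert bic == pytest.approx(9 * np.log(10) + 10 * np.log(0.23), abs=1e-10)

    @given(
        k=st.integers(0, 12),
        n=st.integers(1, 40),
        L=st.floats(1e-6, 10.0),
    )
    @settings(deadline=None, max_examples=50)
    def test_agrees_with_hand_evaluation(self, k, n, L):
        aic, bic = information_criteria(k, n, L)
        assert aic == pytest.approx(2 * k + n * np.log(L), abs=1e-10)
        assert bic == pytest.approx(k * np.log(n) + n * np.log(L), abs=1e-10)

    def test_nonpositive_loss_rejected(self):
        with pytest.raises(ValueError):
            information_criteria(2, 5, 0.0)


class TestSimulatedCells:
    def test_fast_path_equals_public_cohort_path(self):
        n, seed = 8, 77
        fast = simulated_acf_cells(
            REFERENCE_PARAMS, MODEL_SPECS[1], EXP1, n, seed, group="young"
        )
        geometry = TargetGeometry(minor_width=0.65 * REFERENCE_PARAMS.sigma_M_x)
        cohort = simulate_cohort(
            REFERENCE_PARAMS, MODEL_SPECS[1], EXP1.conditions, geometry,
            n_individuals=n, n_trials=EXP1.trials_per_condition, seed=seed,
            group="young", experiment="exp1",
        )
        slow = summarize_cohort(cohort)
        fast_means, slow_means = fast.cell_means(), slow.cell_means()
        assert set(fast_means) == set(slow_means)
        for key in fast_means:
            assert fast_means[key] == pytest.approx(slow_means[key], abs=1e-12)

    def test_objective_determinism(self):
        a = simulated_acf_cells(REFERENCE_PARAMS, MODEL_SPECS[4], EXP1, 20, 5)
        b = simulated_acf_cells(REFERENCE_PARAMS, MODEL_SPECS[4], EXP1, 20, 5)
        pd.testing.assert_frame_equal(a.cells, b.cells)


class TestFitModel:
    def test_realizable_optimum_reached(self):
        truth = ModelParams(0.4, 0.5, 0.4, 0.9, 0.9, 0.8, 0, 0, 0, 0)
        config = FitConfig(
            n_warm_starts=3, n_bootstrap=1, resample=False, n_sim_individuals=30,
            sigma_bounds=(0.05, 2.0), seed=13, maxfev_start=300, maxfev_polish=2000,
        )
        # data generated by the very simulator the objective uses, at the
        # objective's own seed: the optimum loss is exactly zero
        data = simulated_acf_cells(
            truth, MODEL_SPECS[2], EXP1, 30, seed=13, group="young"
        )
        result = fit_model(data, MODEL_SPECS[2], config)
        assert result.warm_loss < 1e-4

    def test_degenerate_bootstrap_collapses_to_warm_start(self):
        truth = ModelParams(0.4, 0.5, 0.4, 0.9, 0.9, 0.8, 0, 0, 0, 0)
        config = FitConfig(
            n_warm_starts=2, n_bootstrap=1, resample=False, n_sim_individuals=20,
            sigma_bounds=(0.05, 2.0), seed=3, maxfev_start=100, maxfev_polish=200,
        )
        data = simulated_acf_cells(truth, MODEL_SPECS[2], EXP1, 20, seed=3, group="g")
        result = fit_model(data, MODEL_SPECS[2], config)
        for name, warm_value in result.warm_start.items():
            pct = result.percentiles[name]
            assert pct[2.5] == pct[50.0] == pct[97.5] == pytest.approx(warm_value)

    def test_bootstrap_medians_inside_intervals(self):
        cfg = CohortConfig(
            params_by_group={"young": REFERENCE_PARAMS}, spec=MODEL_SPECS[2]
        )
        series, _ = generate_experiment(EXP1, cfg, 6)
        summary = summarize_cohort(series)
        config = FitConfig(
            n_warm_starts=2, n_bootstrap=12, resample=True, n_sim_individuals=30,
            sigma_bounds=(0.05, 2.0), seed=8, maxfev_start=80, maxfev_polish=150,
            maxfev_boot=40,
        )
        result = fit_model(summary, MODEL_SPECS[2], config)
        for name in result.percentiles:
            pct = result.percentiles[name]
            assert pct[2.5] <= pct[50.0] <= pct[97.5]
            assert getattr(result.params, name) == pytest.approx(pct[50.0], abs=1e-9)

    def test_nested_general_model_fits_no_worse(self):
        cfg = CohortConfig(
            params_by_group={"young": REFERENCE_PARAMS}, spec=MODEL_SPECS[1]
        )
        series, _ = generate_experiment(EXP1, cfg, 5)
        summary = summarize_cohort(series)
        config = FitConfig(
            n_warm_starts=4, n_bootstrap=1, resample=False, n_sim_individuals=80,
            sigma_bounds=(0.05, 2.0), seed=21, maxfev_start=200, maxfev_polish=800,
        )
        loss_general = fit_model(summary, MODEL_SPECS[1], config).loss
        loss_reduced = fit_model(summary, MODEL_SPECS[4], config).loss
        assert loss_general <= loss_reduced + 1e-3


class TestSharedSigmaGroups:
    def test_shared_sigma_constraint_holds(self):
        truth = REFERENCE_PARAMS
        cfg = CohortConfig(
            params_by_group={"control": truth, "parkinsons": truth},
            spec=MODEL_SPECS[4],
        )
        series, _ = generate_experiment(EXP3, cfg, 9)
        summary = summarize_cohort(series)
        config = FitConfig(
            n_warm_starts=2, n_bootstrap=1, resample=False, n_sim_individuals=40,
            sigma_bounds=(0.05, 2.0), seed=2, maxfev_start=100, maxfev_polish=200,
        )
        res_pd, res_c = fit_groups_shared_sigma(
            summary.subset(group="parkinsons"),
            summary.subset(group="control"),
            MODEL_SPECS[4],
            config,
        )
        for name in ("sigma_M_x", "sigma_M_y", "sigma_E_x", "sigma_E_y"):
            assert getattr(res_pd.params, name) == getattr(res_c.params, name)
        assert res_pd.n == res_c.n == 6
        assert res_pd.k == res_c.k == MODEL_SPECS[4].n_free - 4 + 2


class TestRanking:
    def test_tie_broken_by_smaller_k(self):
        rows = [
            {"model_id": 1, "k": 10, "removed": "none", "L_total": 0.2,
             "AIC": -5.0, "BIC": -4.0},
            {"model_id": 4, "k": 9, "removed": "beta_target_y", "L_total": 0.2,
             "AIC": -5.0, "BIC": -4.0},
        ]
        table = _rank_table(rows)
        assert list(table["model_id"]) == [4, 1]
        assert list(table["rank"]) == [1, 2]

    def test_ascending_aic_order(self):
        rows = [
            {"model_id": i, "k": 9, "removed": "x", "L_total": 1.0,
             "AIC": float(aic), "BIC": 0.0}
            for i, aic in [(1, 3.0), (2, -2.0), (3, 0.5)]
        ]
        assert list(_rank_table(rows)["model_id"]) == [2, 3, 1]


class TestSigmaBounds:
    def test_bounds_span_observed_variability(self, reinforcement_session):
        lo, hi = sigma_bounds_from_series([reinforcement_session])
        pts = reinforcement_session.endpoints()
        sds = np.std(pts, axis=0, ddof=1)
        assert lo == pytest.approx(sds.min())
        assert hi == pytest.approx(sds.max())
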