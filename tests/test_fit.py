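"""Objective construction, decline exclusion, staged fitting and Q0
estimation.

Heavier recovery checks live in the acceptance suite; here the optimizer
runs with small budgets on single stages.
"""

import numpy as np
import pytest

from synthgut import ModelParameters, Strain
from synthgut.fit import (
    FermentationExperiment,
    FitConfig,
    FitError,
    FitStage,
    _strain_params,
    estimate_Q0,
    exclude_decline,
    fit_parameters,
    normalized_rmse,
    parameterization2,
    predict_experiment,
)
from synthgut.model import ConfigurationError
from synthgut.simulate import SolverConfig, Trajectory


def _abundance_exp(counts, times=None) -> FermentationExperiment:
    times = times if times is not None else np.arange(len(counts), dtype=float)
    return FermentationExperiment(
        id="toy",
        strains=(Strain.RI,),
        times=times,
        observations={"X_RI": np.asarray(counts, dtype=float)[:, None]},
        initial={},
    )


class TestExcludeDecline:
    def test_monotone_untouched(self):
        exp = exclude_decline(_abundance_exp([1.0, 2.0, 5.0, 9.0]))
        assert not exp.excluded["X_RI"].any()

    def test_ninety_percent_rule(self):
        # peak 9 at index 2; 8.0 < 0.9*9 = 8.1 and 4 both decline
        exp = exclude_decline(_abundance_exp([1.0, 5.0, 9.0, 8.0, 4.0]))
        np.testing.assert_array_equal(
            exp.excluded["X_RI"], [False, False, False, True, True]
        )

    def test_plateau_is_not_decline(self):
        exp = exclude_decline(_abundance_exp([1.0, 5.0, 9.0, 8.5, 8.2]))
        assert not exp.excluded["X_RI"].any()

    def test_metabolites_never_excluded(self, clean_study):
        for exp in clean_study.values():
            for var in exp.metabolite_variables():
                assert exp.included_mask(var).all()


class TestNormalizedRmse:
    def test_zero_on_self_generated(self, params, clean_study):
        for eid in ("RI_8", "FP_BH_1", "TRI_2"):
            exp = clean_study[eid]
            traj = predict_experiment(
                params, exp, exp.truth["Q0"], SolverConfig()
            )
            assert normalized_rmse(traj, exp) == pytest.approx(0.0, abs=1e-5)

    def test_hand_arithmetic(self, params):
        # single variable, max 10, residuals +1 and -1 => sqrt(mean(0.1^2)) = 0.1
        times = np.array([1.0, 2.0])
        exp = FermentationExperiment(
            id="hand", strains=(Strain.RI,), times=times,
            observations={"S_fructose": np.array([[10.0], [4.0]])},
            initial={},
        )
        traj = Trajectory(
            t=np.array([0.0, 1.0, 2.0]),
            states=np.column_stack(
                [np.zeros(3)] * 6
                + [np.array([12.0, 11.0, 3.0])]  # S_fructose: residuals +1, -1
                + [np.zeros(3)] * 6
            ),
            params=params,
            initial_state=exp.initial_state(),
        )
        assert normalized_rmse(traj, exp) == pytest.approx(0.1)

    def test_scale_invariance(self, params):
        times = np.array([1.0, 2.0])
        def build(scale):
            exp = FermentationExperiment(
                id="s", strains=(Strain.RI,), times=times,
                observations={"S_fructose": scale * np.array([[10.0], [4.0]])},
                initial={},
            )
            traj = Trajectory(
                t=np.array([0.0, 1.0, 2.0]),
                states=np.column_stack(
                    [np.zeros(3)] * 6
                    + [scale * np.array([12.0, 11.0, 3.0])]
                    + [np.zeros(3)] * 6
                ),
                params=params,
                initial_state=exp.initial_state(),
            )
            return normalized_rmse(traj, exp)

        assert build(1.0) == pytest.approx(build(10.0))

    def test_all_zero_variable_skipped_with_warning(self, params, clean_study):
        exp = clean_study["FP_4"]  # FP produces no H2: S_H2 stays 0
        traj = predict_experiment(params, exp, exp.truth["Q0"])
        with pytest.warns(UserWarning, match="S_H2"):
            normalized_rmse(traj, exp)


class TestFitParameters:
    def test_empty_free_mask_returns_init(self, params, clean_study):
        cfg = FitConfig(
            stages=[FitStage("noop", ["RI_8"], [], q0_strains={"RI_8": []})],
            max_evaluations=10,
        )
        res = fit_parameters(clean_study, cfg, params)
        assert res.params.to_flat() == params.to_flat()

    def test_objective_trace_non_increasing(self, params, clean_study):
        init = params.updated({"mu.RI": params.mu[Strain.RI] * 1.3})
        cfg = FitConfig(
            stages=[FitStage("RI", ["RI_8"], ["mu.RI"])],
            max_evaluations=60, restarts=1,
        )
        res = fit_parameters(clean_study, cfg, init)
        assert np.all(np.diff(res.objective_trace) <= 0)
        assert res.objective <= res.objective_trace[0]

    def test_deterministic(self, params, noisy_study):
        init = params.updated({"mu.RI": params.mu[Strain.RI] * 1.2})
        cfg = FitConfig(
            stages=[FitStage("RI", ["RI_8"], ["mu.RI", "K.RI.fructose"])],
            max_evaluations=60, restarts=1,
        )
        a = fit_parameters(noisy_study, cfg, init)
        b = fit_parameters(noisy_study, cfg, init)
        assert a.params.to_flat() == b.params.to_flat()
        np.testing.assert_array_equal(a.objective_trace, b.objective_trace)

    def test_larger_budget_never_worse(self, params, clean_study):
        init = params.updated({"mu.RI": params.mu[Strain.RI] * 1.3})
        def run(budget):
            cfg = FitConfig(
                stages=[FitStage("RI", ["RI_8"], ["mu.RI"])],
                max_evaluations=budget, restarts=1,
            )
            return fit_parameters(clean_study, cfg, init).objective
        assert run(120) <= run(30) + 1e-12

    def test_missing_experiment_raises(self, params, clean_study):
        cfg = FitConfig(stages=[FitStage("x", ["NOPE"], ["mu.RI"])])
        with pytest.raises(ConfigurationError, match="NOPE"):
            fit_parameters(clean_study, cfg, params)

    def test_unknown_free_param_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown free"):
            FitConfig(stages=[FitStage("x", [], ["mu.QQ"])])

    def test_mu_recovery_single_stage(self, params, clean_study):
        # one-dimensional sanity recovery: mu.RI from its monoculture
        init = params.updated({"mu.RI": params.mu[Strain.RI] * 1.4})
        cfg = FitConfig(
            stages=[FitStage("RI", ["RI_8"], ["mu.RI"],
                             q0_strains={"RI_8": [Strain.RI]})],
            max_evaluations=300, restarts=2, xatol=1e-6, fatol=1e-10,
        )
        res = fit_parameters(clean_study, cfg, init)
        assert res.params.mu[Strain.RI] == pytest.approx(
            params.mu[Strain.RI], rel=0.05
        )


class TestParameterization2Plumbing:
    def test_permuted_stage_order_warns(self, params, clean_study):
        order = ("BH_yields", "FP_mono", "BH_kinetics", "RI_full")
        with pytest.warns(UserWarning, match="permuted"):
            parameterization2(
                clean_study, params, max_evaluations=2, restarts=1,
                stage_order=order,
            )

    def test_invalid_stage_order_rejected(self, params, clean_study):
        with pytest.raises(ConfigurationError):
            parameterization2(
                clean_study, params, max_evaluations=2,
                stage_order=("FP_mono",),
            )

    def test_heldout_prediction_without_refit(self, params, clean_study):
        # validation contract: forward-simulate the no-acetate bi-cultures
        exp = clean_study["FP_BH_3"]
        traj = predict_experiment(params, exp, exp.truth["Q0"])
        assert normalized_rmse(traj, exp) == pytest.approx(0.0, abs=1e-4)


class TestEstimateQ0:
    def test_recovery(self, params):
        from synthgut.synthetic import ExperimentDesign, NoiseConfig, generate_experiment

        design = ExperimentDesign(
            id="q", strains=(Strain.RI,), inoculum={Strain.RI: 0.1},
            lags={Strain.RI: 1.26}, acetate=50.0,
        )
        exp = generate_experiment(
            params, design,
            NoiseConfig(abundance_cv=0.0, metabolite_sd=0.0, decline_rate=0.0),
        )
        truth_q0 = exp.truth["Q0"][Strain.RI]  # = 0.5 for lag 1.26 at mu 0.55
        est = estimate_Q0(exp, Strain.RI, params.mu[Strain.RI], params)
        assert est == pytest.approx(truth_q0, rel=0.25)

    def test_no_lag_data_gives_Q0_above_one(self, params):
        from synthgut.synthetic import ExperimentDesign, NoiseConfig, generate_experiment

        design = ExperimentDesign(
            id="q", strains=(Strain.RI,), inoculum={Strain.RI: 0.1},
            lags={Strain.RI: -2.9}, acetate=50.0,  # Q0 = 5: head start
        )
        exp = generate_experiment(
            params, design,
            NoiseConfig(abundance_cv=0.0, metabolite_sd=0.0, decline_rate=0.0),
        )
        assert estimate_Q0(exp, Strain.RI, params.mu[Strain.RI], params) > 1.0

    def test_too_few_points_rejected(self, params):
        exp = _abundance_exp([1.0, 2.0])
        with pytest.raises(FitError, match=">= 3"):
            estimate_Q0(exp, Strain.RI, 0.5, params)

    def test_constant_data_hits_bound_with_warning(self, params):
        exp = FermentationExperiment(
            id="flat", strains=(Strain.BH,),
            times=np.array([0.5, 5.0, 20.0, 48.0]),
            observations={"X_BH": np.full((4, 1), 0.1)},
            initial={"X": {Strain.BH: 0.1}, "formate": 50.0},
        )
        with pytest.warns(UserWarning, match="bound"):
            estimate_Q0(exp, Strain.BH, params.mu[Strain.BH], params, n_grid=15)


class TestExhaustiveReplicateSelection:
    def test_best_subset_found(self, params, clean_study, noisy_study):
        from synthgut.fit import exhaustive_replicate_selection

        # candidates: a clean and a noisy version of the same design; with
        # parameters fixed at truth, the clean replicate must win
        study = dict(clean_study)
        study["RI_8_noisy"] = noisy_study["RI_8"]

        def runner(exps):
            cfg = FitConfig(
                stages=[FitStage(
                    "RI",
                    sorted(e for e in exps if e.startswith("RI_8")),
                    [],
                    q0_strains={e: [] for e in exps},
                )],
                max_evaluations=5,
            )
            init_q0 = {
                eid: exps[eid].truth["Q0"] for eid in exps
                if eid.startswith("RI_8") and exps[eid].truth
            }
            return fit_parameters(exps, cfg, params, init_Q0=init_q0)

        ids, result = exhaustive_replicate_selection(
            study, ["RI_8", "RI_8_noisy"], runner
        )
        assert ids == ("RI_8",)
        assert result.objective == pytest.approx(0.0, abs=1e-4)

    def test_missing_candidate_rejected(self, params, clean_study):
        from synthgut.fit import exhaustive_replicate_selection
        from synthgut.model import ConfigurationError

        with pytest.raises(ConfigurationError, match="NOPE"):
            exhaustive_replicate_selection(clean_study, ["NOPE"], lambda s: None)
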