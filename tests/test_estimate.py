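"""Double-reciprocal initialisation, residual pooling, least-squares refit."""

import math

import numpy as np
import pytest

from coferm import (
    GrowthPoint,
    SimOptions,
    Trajectory,
    fit_parameters,
    inhibition_thresholds,
    lineweaver_burk,
    pooled_rmse,
    residuals,
    simulate_monoculture,
    theoretical_yield_fraction,
    truncate_at_plateau,
)
from coferm.estimate import EstimationError
from coferm.synthetic import SyntheticSpec, generate_trajectory


class TestLineweaverBurk:
    def test_two_point_solve_matches_printed_sr8_constants(self):
        # log-phase growth rates at 10 and 40 g/L xylose
        points = [GrowthPoint(10.0, 0.136), GrowthPoint(40.0, 0.149)]
        mu_m, Ks = lineweaver_burk(points)
        assert mu_m == pytest.approx(0.1539, abs=1e-4)
        assert Ks == pytest.approx(1.3165, abs=1e-3)

    def test_two_point_solve_matches_printed_ej2_mu_max(self):
        points = [GrowthPoint(10.0, 0.146), GrowthPoint(40.0, 0.152)]
        mu_m, _ = lineweaver_burk(points)
        assert round(mu_m, 3) == 0.154

    def test_exact_on_noiseless_monod_data(self):
        mu_m_true, Ks_true = 0.2, 2.0
        points = [GrowthPoint(S, mu_m_true * S / (Ks_true + S))
                  for S in (1.0, 2.0, 5.0, 10.0, 20.0)]
        mu_m, Ks = lineweaver_burk(points)
        assert mu_m == pytest.approx(mu_m_true, rel=1e-10)
        assert Ks == pytest.approx(Ks_true, rel=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(EstimationError):
            lineweaver_burk([GrowthPoint(10.0, 0.1)])
        with pytest.raises(EstimationError):
            lineweaver_burk([GrowthPoint(10.0, 0.1), GrowthPoint(10.0, 0.12)])
        # super-Monod acceleration extrapolates to a nonpositive intercept
        with pytest.raises(EstimationError):
            lineweaver_burk([GrowthPoint(10.0, 0.05), GrowthPoint(40.0, 0.4)])


def _line_traj(t, X, S, P):
    t = np.asarray(t, dtype=float)
    return Trajectory.from_arrays(t, X, S, np.zeros_like(t), P)


class TestResiduals:
    def test_identical_trajectories_give_zero(self, ej2):
        traj = simulate_monoculture(ej2, 20.0, 0.45)
        res = residuals(traj, traj)
        assert np.all(res == 0.0)
        assert pooled_rmse(res) == 0.0

    def test_rss_rmse_arithmetic(self):
        t = [0.0, 1.0, 2.0]
        data = _line_traj(t, [1.0, 1.0, 1.0], [5.0, 4.0, 3.0], [0.0, 0.0, 0.0])
        model = _line_traj(t, [2.0, 3.0, 3.0], [5.0, 4.0, 3.0], [0.0, 0.0, 0.0])
        res = residuals(model, data)
        # only biomass deviates: residuals {1, 2, 2} pooled with zeros
        assert sorted(res[np.abs(res) > 0]) == [1.0, 2.0, 2.0]
        assert np.sum(res ** 2) == pytest.approx(9.0)
        assert pooled_rmse(np.array([1.0, 2.0, 2.0])) == pytest.approx(math.sqrt(3.0))

    def test_model_regenerates_its_own_synthetic_data(self, ej2):
        spec = SyntheticSpec(kinetics=ej2, cv=0.0, floor_sd=0.0,
                             replicates=1, seed=1)
        data = generate_trajectory(spec, 40.0, 0.45)[0]
        model = simulate_monoculture(ej2, 40.0, 0.45)
        assert pooled_rmse(residuals(model, data)) < 1e-6

    def test_rmse_invariant_to_ordering_and_rss_additive(self, ej2):
        spec = SyntheticSpec(kinetics=ej2, cv=0.05, floor_sd=0.0,
                             replicates=2, seed=3)
        reps = generate_trajectory(spec, 30.0, 0.45)
        model = simulate_monoculture(ej2, 30.0, 0.45)
        r1, r2 = (residuals(model, d) for d in reps)
        rss_split = np.sum(r1 ** 2) + np.sum(r2 ** 2)
        pooled = np.concatenate([r2, r1])  # order swapped
        assert np.sum(pooled ** 2) == pytest.approx(rss_split, rel=1e-12)
        assert pooled_rmse(pooled) == pytest.approx(
            math.sqrt(rss_split / len(pooled)), rel=1e-12)

    def test_empty_or_misaligned_data_rejected(self, ej2):
        model = simulate_monoculture(ej2, 20.0, 0.45)
        late = _line_traj([47.0, 49.0], [1, 1], [5, 4], [0, 0])
        with pytest.raises(EstimationError):
            residuals(model, late)


class TestFitParameters:
    def test_noiseless_two_parameter_recovery(self, ej2):
        spec = SyntheticSpec(kinetics=ej2, cv=0.0, floor_sd=0.0,
                             replicates=1, seed=0,
                             sample_times=tuple(np.arange(0.0, 36.1, 2.0)))
        data = [generate_trajectory(spec, S0, 0.45)[0] for S0 in (20.0, 60.0)]
        conds = [(20.0, 0.45, 0.0), (60.0, 0.45, 0.0)]
        start = ej2.with_updates(vm=ej2.vm * 1.4, Ksp=ej2.Ksp * 1.6)
        fit = fit_parameters(data, start, free=("vm", "Ksp"),
                             initial_conditions=conds)
        assert fit.converged
        assert fit.kinetics.vm == pytest.approx(ej2.vm, rel=1e-2)
        assert fit.kinetics.Ksp == pytest.approx(ej2.Ksp, rel=1e-2)
        assert fit.rmse < 1e-3

    def test_optimum_beats_singly_perturbed_parameters(self, ej2):
        spec = SyntheticSpec(kinetics=ej2, cv=0.0, floor_sd=0.0,
                             replicates=1, seed=0,
                             sample_times=tuple(np.arange(0.0, 30.1, 3.0)))
        data = [generate_trajectory(spec, 40.0, 0.45)[0]]
        conds = [(40.0, 0.45, 0.0)]
        fit = fit_parameters(data, ej2, free=("vm", "Ksp"),
                             initial_conditions=conds)
        from coferm.estimate import _pooled_residuals
        for name in ("vm", "Ksp"):
            perturbed = fit.kinetics.with_updates(
                **{name: getattr(fit.kinetics, name) * 1.1})
            rss_perturbed = float(np.sum(np.square(_pooled_residuals(
                perturbed, data, conds, "cellobiose"))))
            assert fit.rss <= rss_perturbed + 1e-12

    def test_fixed_parameters_unchanged(self, ej2):
        spec = SyntheticSpec(kinetics=ej2, cv=0.0, floor_sd=0.0,
                             replicates=1, seed=0,
                             sample_times=tuple(np.arange(0.0, 24.1, 4.0)))
        data = [generate_trajectory(spec, 20.0, 0.45)[0]]
        fit = fit_parameters(data, ej2, free=("vm",),
                             initial_conditions=[(20.0, 0.45, 0.0)])
        assert fit.kinetics.mu_m == ej2.mu_m
        assert fit.kinetics.Ks == ej2.Ks
        assert fit.fixed["mu_m"] == ej2.mu_m

    def test_empty_data_rejected(self, ej2):
        with pytest.raises(EstimationError):
            fit_parameters([], ej2, free=("vm",))

    def test_unknown_free_parameter_rejected(self, ej2):
        with pytest.raises(EstimationError, match="unknown"):
            fit_parameters([None], ej2, free=("not_a_param",))


class TestPlateauTruncation:
    def test_drops_post_plateau_samples(self):
        t = np.arange(0.0, 12.1, 1.0)
        S_x = np.array([40, 30, 20, 12, 6, 2, 1.95, 1.92, 1.9, 1.9, 1.9,
                        1.9, 1.9])
        traj = Trajectory.from_arrays(t, np.ones_like(t), np.zeros_like(t),
                                      S_x, np.zeros_like(t))
        cut = truncate_at_plateau(traj)
        assert len(cut) < len(traj)
        assert cut.column("xylose_g_L")[-1] > 1.8
        dS = np.abs(np.diff(traj.column("xylose_g_L")))[: len(cut) - 1]
        assert np.all(dS[:-1] >= 0.0)  # retained section precedes the plateau

    def test_no_plateau_returns_trajectory_unchanged(self):
        t = np.arange(0.0, 5.1, 1.0)
        S_x = 40.0 - 5.0 * t
        traj = Trajectory.from_arrays(t, np.ones_like(t), np.zeros_like(t),
                                      np.maximum(S_x, 0), np.zeros_like(t))
        assert len(truncate_at_plateau(traj)) == len(traj)


class TestAnalyticThresholds:
    def test_ej2_growth_and_production_arrest_loads(self, ej2):
        S_growth, S_production = inhibition_thresholds(ej2, Pm_exp=69.0,
                                                       Yps_basis=0.5)
        assert S_growth == pytest.approx(138.0)
        assert S_production == pytest.approx(200.0)

    def test_sr8_growth_arrest_load_from_literature_yield(self, sr8):
        S_growth, _ = inhibition_thresholds(sr8, Pm_exp=85.0, Yps_basis=0.35)
        assert S_growth == pytest.approx(242.857, abs=1e-2)
        assert S_growth > 240.0

    def test_identity_case_and_domain_errors(self, ej2):
        S_growth, _ = inhibition_thresholds(ej2, Pm_exp=1.0, Yps_basis=1.0)
        assert S_growth == 1.0
        with pytest.raises(ValueError):
            inhibition_thresholds(ej2, Pm_exp=0.0, Yps_basis=0.5)

    def test_yield_fraction(self):
        assert theoretical_yield_fraction(0.5, 0.511) == pytest.approx(97.85, abs=0.01)
        assert round(theoretical_yield_fraction(0.5, 0.511)) == 98
        assert theoretical_yield_fraction(0.3, 0.3) == 100.0
        assert theoretical_yield_fraction(0.25, 0.5) == 50.0
        with pytest.raises(ValueError):
            theoretical_yield_fraction(0.5, 0.0)
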