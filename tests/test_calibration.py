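"""Calibration objective, Latin-hypercube starts and multi-start search."""

import numpy as np
import pytest

from cellgrowth.calibration import (
    NLSObjective,
    SearchSpace,
    lhs_starts,
    multistart_fit,
    multistart_minimize,
    physical_search_space,
    planned_runs,
    weighted_nls_objective,
)
from cellgrowth.models import CandidateModel, EffectKind, FixedConstants, ParameterSet

from conftest import manual_dataset

ZERO = EffectKind.ZERO_ORDER

#: a model whose predictions are constants (all-zero-order effects,
#: vanishing rates), so objective values can be computed by hand
STATIC_MODEL = CandidateModel(ZERO, ZERO, ZERO)
STATIC_PARAMS = ParameterSet(beta=1e-30, delta=0.0, V_g=0.0, cbar_g=1.0)
STATIC_CONSTS = FixedConstants(V_o=0.0)


def _static_conditions(n0=3.0, cg0=1.0, cl0=0.0):
    from cellgrowth.models import CultureCondition

    return {"c0": CultureCondition(n0=n0, cg0=cg0, cl0=cl0, co=0.18)}


class TestObjective:
    def test_single_cell_unit_weight(self):
        # Zbar=5, z=3, w=1 -> 0.5*(5-3)^2 = 2
        ds = manual_dataset([("c0", 10.0, "n", [5.0])])
        loss = weighted_nls_objective(
            STATIC_PARAMS, STATIC_MODEL, STATIC_CONSTS, ds,
            _static_conditions(n0=3.0), weight_mode="unit",
        )
        assert loss == pytest.approx(2.0, rel=1e-9)

    def test_perfect_prediction_zero_loss(self):
        ds = manual_dataset([("c0", 10.0, "n", [3.0]),
                             ("c0", 20.0, "cg", [1.0])])
        loss = weighted_nls_objective(
            STATIC_PARAMS, STATIC_MODEL, STATIC_CONSTS, ds,
            _static_conditions(n0=3.0, cg0=1.0), weight_mode="unit",
        )
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_doubling_sigma_quarters_loss(self):
        # replicates {4,6}: sd = sqrt(2); {3,7}: sd = 2*sqrt(2)
        narrow = manual_dataset([("c0", 10.0, "n", [4.0, 6.0])])
        wide = manual_dataset([("c0", 10.0, "n", [3.0, 7.0])])
        args = (STATIC_MODEL, STATIC_CONSTS)
        l_narrow = weighted_nls_objective(
            STATIC_PARAMS, *args, narrow, _static_conditions(n0=3.0))
        l_wide = weighted_nls_objective(
            STATIC_PARAMS, *args, wide, _static_conditions(n0=3.0))
        assert l_narrow == pytest.approx(4 * l_wide, rel=1e-9)

    def test_inverse_variance_value(self):
        # mean 5, sd sqrt(2), z=3: 0.5 * (1/2) * 4 = 1
        ds = manual_dataset([("c0", 10.0, "n", [4.0, 6.0])])
        loss = weighted_nls_objective(
            STATIC_PARAMS, STATIC_MODEL, STATIC_CONSTS, ds,
            _static_conditions(n0=3.0))
        assert loss == pytest.approx(1.0, rel=1e-9)

    def test_sigma_floor_keeps_noiseless_finite(self, fixture_model,
                                                fixture_consts,
                                                noiseless_dataset, cond_map):
        obj = NLSObjective(fixture_model, fixture_consts, noiseless_dataset,
                           cond_map)
        assert np.all(np.isfinite(obj.weights))

    def test_loss_at_truth_is_tiny(self, fixture_model, fixture_params,
                                   fixture_consts, noiseless_dataset,
                                   cond_map):
        obj = NLSObjective(fixture_model, fixture_consts, noiseless_dataset,
                           cond_map)
        names = obj.param_names
        assert obj(fixture_params.to_array(names)) < 1e-3

    def test_penalty_for_invalid_parameters(self, fixture_model,
                                            fixture_consts,
                                            noiseless_dataset, cond_map):
        obj = NLSObjective(fixture_model, fixture_consts, noiseless_dataset,
                           cond_map)
        bad = np.array([1e-5, 1e-6, 1e-12, 1.0, -1.0, 1.0, 1.0])  # K_o < 0
        assert obj(bad) >= 1e12

    def test_penalty_is_sloped_outward(self, fixture_model, fixture_consts,
                                       noiseless_dataset, cond_map):
        obj = NLSObjective(fixture_model, fixture_consts, noiseless_dataset,
                           cond_map)
        near = np.array([1e-5, 1e-6, 1e-12, 1.0, -1.0, 1.0, 1.0])
        far = np.array([1e6, 1e-6, 1e-12, 1.0, -1.0, 1e6, 1e6])
        assert obj(far) > obj(near) >= 1e12

    def test_residuals_square_to_loss(self, fixture_model, fixture_params,
                                      fixture_consts, noiseless_dataset,
                                      cond_map):
        obj = NLSObjective(fixture_model, fixture_consts, noiseless_dataset,
                           cond_map)
        theta = fixture_params.to_array(obj.param_names) * 1.3
        r = obj.residuals(theta)
        assert np.sum(r**2) == pytest.approx(obj(theta), rel=1e-9)


class TestLhsStarts:
    def _space(self, d, scale="linear"):
        if scale == "linear":
            return SearchSpace(tuple(f"x{i}" for i in range(d)),
                               (0.0,) * d, (1.0,) * d, scale="linear")
        return SearchSpace(tuple(f"x{i}" for i in range(d)),
                           (1e-7,) * d, (1e7,) * d)

    def test_single_point_is_midpoint(self):
        pts = lhs_starts(self._space(3), 1, seed=0)
        assert np.allclose(pts, 0.5)

    @pytest.mark.parametrize("n,d", [(50, 3), (1300, 7)])
    def test_bin_occupancy_exactly_one(self, n, d):
        pts = lhs_starts(self._space(d), n, seed=1, maximin_iters=20)
        bins = np.floor(pts * n).astype(int)
        for j in range(d):
            assert sorted(bins[:, j]) == list(range(n))

    def test_log_scale_occupancy(self):
        space = self._space(2, scale="log")
        pts = lhs_starts(space, 40, seed=2)
        unit = (np.log10(pts) + 7) / 14.0
        bins = np.floor(unit * 40).astype(int)
        for j in range(2):
            assert sorted(bins[:, j]) == list(range(40))

    def test_maximin_not_worse_than_plain(self):
        from scipy.spatial.distance import pdist

        space = self._space(4)
        plain = lhs_starts(space, 60, seed=3, maximin_iters=0)
        improved = lhs_starts(space, 60, seed=3, maximin_iters=200)
        assert pdist(improved).min() >= pdist(plain).min()

    def test_determinism(self):
        space = self._space(5)
        assert np.array_equal(lhs_starts(space, 30, seed=9),
                              lhs_starts(space, 30, seed=9))

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            lhs_starts(self._space(2), 0)


class TestSearchSpace:
    def test_bounds_validation(self):
        with pytest.raises(ValueError):
            SearchSpace(("a",), (2.0,), (1.0,))
        with pytest.raises(ValueError):
            SearchSpace(("a",), (-1.0,), (1.0,), scale="log10")

    def test_round_trip(self):
        space = SearchSpace(("a", "b"), (1e-7, 1e-7), (1e7, 1e7))
        theta = np.array([1e-3, 42.0])
        assert np.allclose(space.to_natural(space.from_natural(theta)), theta)


class TestMultistart:
    def test_convex_quadratic(self):
        target = np.array([0.3, -1.2, 2.0])

        def fun(x):
            return float(np.sum((x - target) ** 2))

        res = multistart_minimize(
            fun, np.full(3, -5.0), np.full(3, 5.0), n_starts=8, seed=0,
            options={"stage1_iters": 30, "stage1_step": 0.2, "n_refine": 3,
                     "log_loss": False},
        )
        assert np.allclose(res["x"], target, atol=1e-4)
        assert res["loss"] < 1e-8

    def test_monotone_improvement(self):
        def fun(x):
            return float(np.sum(x**2) + 1.0)

        res = multistart_minimize(
            fun, np.full(2, -3.0), np.full(2, 3.0), n_starts=6, seed=1,
            options={"stage1_iters": 10, "n_refine": 6},
        )
        arch = res["archive"]
        refined = arch.dropna(subset=["refined_loss"])
        assert (refined["refined_loss"] <= refined["stage1_loss"] + 1e-12).all()
        assert (arch["stage1_loss"] <= arch["initial_loss"] + 1e-12).all()

    def test_seeded_determinism_on_ode_fit(self, fixture_model,
                                           fixture_consts, noiseless_dataset,
                                           cond_map):
        opts = {"stage1_iters": 3, "n_refine": 2, "refine_maxiter": 5,
                "polish_n": 1, "polish_maxfev": 20}
        kwargs = dict(
            space=physical_search_space(fixture_model), n_starts=6, seed=17,
            stage_options=opts,
        )
        a = multistart_fit(fixture_model, fixture_consts, noiseless_dataset,
                           cond_map, **kwargs)
        b = multistart_fit(fixture_model, fixture_consts, noiseless_dataset,
                           cond_map, **kwargs)
        assert a.loss == b.loss
        assert np.array_equal(a.theta_array(), b.theta_array())
        assert a.archive.equals(b.archive)

    def test_objective_argmin_matches_loglik_argmax(self, fixture_model,
                                                    fixture_params,
                                                    fixture_consts,
                                                    noiseless_dataset,
                                                    cond_map):
        # minimising the weighted NLS loss and maximising loglik = -loss
        # pick the same point on a 1-parameter grid
        obj = NLSObjective(fixture_model, fixture_consts, noiseless_dataset,
                           cond_map)
        names = obj.param_names
        base = fixture_params.to_array(names)
        grid = np.linspace(0.5, 2.0, 21)
        losses = []
        for g in grid:
            theta = base.copy()
            theta[0] = base[0] * g
            losses.append(obj(theta))
        losses = np.array(losses)
        assert np.argmin(losses) == np.argmax(-losses)

    def test_space_name_mismatch_rejected(self, fixture_model,
                                          fixture_consts, noiseless_dataset,
                                          cond_map):
        wrong = SearchSpace(("beta", "delta"), (1e-7, 1e-7), (1e7, 1e7))
        with pytest.raises(ValueError):
            multistart_fit(fixture_model, fixture_consts, noiseless_dataset,
                           cond_map, space=wrong)


class TestRecovery:
    """Properties of the session-scope 100-start fit on noiseless data."""

    def test_best_loss_far_below_median_start(self, recovery_fit):
        median_start = np.median(recovery_fit.archive["initial_loss"])
        assert recovery_fit.loss <= 1e-6 * median_start

    def test_multiple_local_optimum_clusters(self, recovery_fit):
        arch = recovery_fit.archive
        final = arch["refined_loss"].fillna(arch["stage1_loss"]).to_numpy()
        final = final[np.isfinite(final) & (final < 1e11)]
        # distinct clusters: final per-start losses span orders of magnitude
        assert np.ptp(np.log10(final + 1e-12)) > 2.0

    def test_trajectory_recovery(self, recovery_fit, fixture_model,
                                 fixture_params, fixture_consts,
                                 noiseless_dataset, cond_map):
        obj = NLSObjective(fixture_model, fixture_consts, noiseless_dataset,
                           cond_map)
        z_true = obj.predict(fixture_params)
        z_fit = obj.predict(recovery_fit.theta_star)
        assert np.max(np.abs(z_fit - z_true) / np.abs(z_true)) < 0.01


def test_planned_runs_bookkeeping():
    assert planned_runs(1300, 22) == 28600
    assert planned_runs(1, 1) == 1
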