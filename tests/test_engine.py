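import numpy as np
import pytest

from lgmf import units
from lgmf.engine import (
    CorrectorState,
    Expansion,
    LGMFConfig,
    PredictorError,
    approx_gradients,
    bfgs_update,
    corrector_iterate,
    enforce_force_budget,
    predictor_step,
    run_corrector,
    run_ramp,
    split_perp,
    verify_exact,
)
from lgmf.quadratic import optimal_at_force
from lgmf.surfaces import (
    SurfacePoint,
    make_model_2d_pair,
    make_quadratic_pair,
)


def nn(x):
    return units.convert(x, "nN", "hartree/bohr")


def expansion_at(pes, q):
    q = np.asarray(q, dtype=float)
    return Expansion(
        q,
        pes.state0.evaluate(q, want_hessian=True),
        pes.state1.evaluate(q, want_hessian=True),
    )


class TestConfig:
    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            LGMFConfig(cos_tolerance=0.5)
        with pytest.raises(ValueError):
            LGMFConfig(force_budget=0.2)
        with pytest.raises(ValueError):
            LGMFConfig(force_step=-1.0)
        with pytest.raises(ValueError):
            LGMFConfig(hessian_policy="magic")

    def test_default_step_is_fifty_piconewton(self):
        cfg = LGMFConfig()
        assert units.convert(cfg.force_step, "hartree/bohr",
                             "nN") == pytest.approx(0.05)


class TestPredictor:
    def test_scalar_from_minimum(self):
        sp = SurfacePoint(0.0, [0.0], [[2.0]])
        dq = predictor_step(sp, np.array([1.0]), 0.3)
        assert dq[0] == pytest.approx(0.15)

    def test_zero_target_zero_step(self):
        sp = SurfacePoint(0.0, [0.1, 0.0], np.eye(2))
        np.testing.assert_array_equal(
            predictor_step(sp, np.array([1.0, 0.0]), 0.0), np.zeros(2)
        )

    def test_closed_form_from_minimum(self):
        pes = make_quadratic_pair(4, seed=2)
        sp = pes.state0.evaluate(np.zeros(4), want_hessian=True)
        d = np.array([1.0, -2.0, 0.5, 0.0])
        dq = predictor_step(sp, d, 0.01)
        dhat = d / np.linalg.norm(d)
        expected = 0.01 / np.linalg.norm(sp.hessian @ dhat)
        assert np.linalg.norm(dq) == pytest.approx(expected)
        # and the model force indeed grew by the target
        f = np.linalg.norm(sp.gradient + sp.hessian @ dq)
        assert f == pytest.approx(0.01, rel=1e-12)

    def test_force_neutral_direction_errors(self):
        sp = SurfacePoint(0.0, [0.0, 0.0], np.diag([1.0, 0.0]))
        with pytest.raises(PredictorError, match="[Ff]lip|direction"):
            predictor_step(sp, np.array([0.0, 1.0]), 0.1)


class TestApproxGradients:
    def test_scalar_plug_in(self, pair_1d):
        exp = expansion_at(pair_1d, [0.0])
        grad_gap, grad_fsq = approx_gradients(exp, np.array([0.5]))
        assert grad_gap[0] == pytest.approx(1.5)
        assert grad_fsq[0] == pytest.approx(1.0)

    def test_zero_force_gradient_at_minimum(self, quad_pair_6d):
        exp = expansion_at(quad_pair_6d, np.zeros(6))
        _, grad_fsq = approx_gradients(exp, np.zeros(6))
        assert np.linalg.norm(grad_fsq) == 0.0

    def test_exact_on_quadratic_pairs(self, quad_pair_6d):
        """On quadratic surfaces the model gradients equal the exact ones
        anywhere."""
        rng = np.random.default_rng(0)
        exp = expansion_at(quad_pair_6d, np.zeros(6))
        dq = rng.uniform(-0.3, 0.3, 6)
        grad_gap, grad_fsq = approx_gradients(exp, dq)
        sp0 = quad_pair_6d.state0.evaluate(dq, want_hessian=True)
        sp1 = quad_pair_6d.state1.evaluate(dq)
        np.testing.assert_allclose(grad_gap, sp1.gradient - sp0.gradient,
                                   atol=1e-14)
        np.testing.assert_allclose(grad_fsq,
                                   2 * sp0.hessian @ sp0.gradient, atol=1e-14)


class TestSplitPerp:
    @pytest.mark.parametrize(
        "v, w, par, perp",
        [
            ([1, 1], [1, 0], [1, 0], [0, 1]),
            ([3, 4], [0, 2], [0, 4], [3, 0]),
            ([2, 0], [1, 0], [2, 0], [0, 0]),
        ],
    )
    def test_projection_arithmetic(self, v, w, par, perp):
        p, q = split_perp(np.array(v, float), np.array(w, float))
        np.testing.assert_allclose(p, par, atol=1e-14)
        np.testing.assert_allclose(q, perp, atol=1e-14)

    def test_reconstruction_and_orthogonality(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            v, w = rng.standard_normal((2, 5))
            p, q = split_perp(v, w)
            np.testing.assert_allclose(p + q, v, atol=1e-12)
            assert abs(q @ w) < 1e-10 * np.linalg.norm(w)

    def test_vanishing_normal_rejected(self):
        with pytest.raises(ValueError, match="1e-12"):
            split_perp(np.ones(3), np.zeros(3))


class TestCorrector:
    def test_parallel_entry_converges_immediately(self, pair_1d):
        exp = expansion_at(pair_1d, [0.0])
        dq = np.array([0.2])  # 1D: gradients always collinear
        out, cos, converged = corrector_iterate(exp, dq, LGMFConfig())
        assert converged
        np.testing.assert_array_equal(out, dq)
        assert abs(cos) == pytest.approx(1.0)

    def test_perp_residual_decreases_monotonically(self, quad_pair_6d):
        cfg = LGMFConfig(cos_tolerance=1 - 1e-10)
        exp = expansion_at(quad_pair_6d, np.zeros(6))
        ggap = exp.sp1.gradient - exp.sp0.gradient
        target = nn(0.1)
        dq = predictor_step(exp.sp0, ggap, target)
        state = CorrectorState()
        norms = []
        for _ in range(200):
            grad_gap, grad_fsq = approx_gradients(exp, dq)
            _, perp = split_perp(grad_gap, grad_fsq)
            norms.append(np.linalg.norm(perp))
            dq, _, converged = corrector_iterate(exp, dq, cfg, 1.0, target,
                                                 state)
            if converged:
                break
        assert converged
        # accepted iterates never increase the perpendicular residual
        assert all(b <= a * (1 + 1e-12) for a, b in zip(norms, norms[1:]))

    def test_converged_point_matches_closed_form(self, quad_pair_6d):
        cfg = LGMFConfig(cos_tolerance=1 - 1e-10)
        exp = expansion_at(quad_pair_6d, np.zeros(6))
        ggap = exp.sp1.gradient - exp.sp0.gradient
        target = nn(0.1)
        dq = predictor_step(exp.sp0, ggap, target)
        dq, cos, iters = run_corrector(exp, dq, cfg, 1.0, target)
        ref = optimal_at_force(quad_pair_6d, target, "increase")
        np.testing.assert_allclose(dq, ref.q_opt.coordinates, atol=1e-6)
        from lgmf.surfaces import gap_variation

        assert gap_variation(quad_pair_6d, dq) == pytest.approx(
            ref.gap_variation, abs=1e-10
        )

    def test_iteration_budget_exhaustion_reports_best_cos(self, quad_pair_6d):
        from lgmf.exceptions import ConvergenceError

        cfg = LGMFConfig(cos_tolerance=1 - 1e-10, corrector_max_iter=3)
        exp = expansion_at(quad_pair_6d, np.zeros(6))
        ggap = exp.sp1.gradient - exp.sp0.gradient
        dq = predictor_step(exp.sp0, ggap, nn(0.1))
        with pytest.raises(ConvergenceError) as err:
            run_corrector(exp, dq, cfg, 1.0, nn(0.1))
        assert err.value.best_cos_alpha is not None


class TestVerifyAndBudget:
    def test_quadratic_model_point_verifies_exactly(self, quad_pair_6d):
        cfg = LGMFConfig(cos_tolerance=0.999)
        exp = expansion_at(quad_pair_6d, np.zeros(6))
        ggap = exp.sp1.gradient - exp.sp0.gradient
        dq = predictor_step(exp.sp0, ggap, nn(0.1))
        dq, _, _ = run_corrector(exp, dq, cfg, 1.0, nn(0.1))
        verified, cos, _ = verify_exact(quad_pair_6d, dq, cfg)
        assert verified

    def test_anharmonic_model_point_fails_then_recovers(self, model2d):
        """An oversized first step mispredicts on the true surface; the
        refreshed expansion at the candidate restores convergence."""
        cfg = LGMFConfig(cos_tolerance=0.99999)
        exp = expansion_at(model2d, [0.0, 0.0])
        ggap = exp.sp1.gradient - exp.sp0.gradient
        target = nn(0.5)  # deliberately coarse
        dq = predictor_step(exp.sp0, ggap, target)
        dq, _, _ = run_corrector(exp, dq, cfg, 1.0, target)
        verified, cos, fresh = verify_exact(model2d, exp.q0 + dq, cfg)
        assert not verified
        dq2, cos2, _ = run_corrector(fresh, np.zeros(2), cfg, 1.0, target)
        verified2, _, _ = verify_exact(model2d, fresh.q0 + dq2, cfg)
        assert verified2

    def test_minimum_with_zero_force_trivially_verified(self, quad_pair_6d):
        verified, cos, _ = verify_exact(quad_pair_6d, np.zeros(6),
                                        LGMFConfig())
        assert verified and cos == 1.0

    @pytest.mark.parametrize(
        "achieved, expected",
        [(1.04, "ok"), (1.06, "recalibrate"), (1.0, "ok"), (0.951, "ok"),
         (0.94, "recalibrate")],
    )
    def test_five_percent_rule(self, achieved, expected):
        assert enforce_force_budget(achieved, 1.0, LGMFConfig()) == expected


class TestBFGS:
    def test_rank_two_arithmetic(self):
        h = bfgs_update(np.eye(2), np.array([1.0, 0.0]), np.array([2.0, 0.0]))
        np.testing.assert_allclose(h, np.diag([2.0, 1.0]), atol=1e-14)

    def test_secant_identity(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a = rng.standard_normal((4, 4))
            h = a @ a.T + np.eye(4)
            dq = rng.standard_normal(4)
            y = h @ dq + 0.1 * rng.standard_normal(4)
            if dq @ y <= 0:
                continue
            h2 = bfgs_update(h, dq, y)
            np.testing.assert_allclose(h2 @ dq, y, atol=1e-12)
            np.testing.assert_allclose(h2, h2.T, atol=1e-14)

    def test_fixed_point_when_secant_already_holds(self):
        h = np.diag([2.0, 3.0])
        dq = np.array([1.0, 1.0])
        h2 = bfgs_update(h, dq, h @ dq)
        np.testing.assert_allclose(h2, h, atol=1e-13)

    def test_curvature_floor_rejected(self):
        with pytest.raises(ValueError, match="curvature"):
            bfgs_update(np.eye(2), np.array([1.0, 0.0]),
                        np.array([-1.0, 0.0]))


class TestRunRamp:
    def test_quadratic_ramp_matches_closed_form(self, quad_pair_6d,
                                                tight_config):
        up, dn = run_ramp(quad_pair_6d, tight_config)
        for ramp in (up, dn):
            assert ramp.termination_reason == "ceiling"
            for p in ramp.points[1:]:
                ref = optimal_at_force(quad_pair_6d, p.force_magnitude,
                                       ramp.branch)
                assert p.gap_variation == pytest.approx(ref.gap_variation,
                                                        abs=1e-6)

    def test_branch_duality_from_minimum(self, quad_pair_6d, model2d):
        cfg = LGMFConfig(force_max=nn(0.2))
        for pes in (quad_pair_6d, model2d):
            up, dn = run_ramp(pes, cfg)
            assert up.points[1].gap_variation > 0
            assert dn.points[1].gap_variation < 0

    def test_ceiling_below_step_yields_start_only(self, quad_pair_6d):
        cfg = LGMFConfig(force_step=nn(0.05), force_max=nn(0.01))
        up, dn = run_ramp(quad_pair_6d, cfg)
        assert len(up.points) == 1 and len(dn.points) == 1
        assert up.points[0].force_magnitude < 1e-10

    def test_force_magnitudes_strictly_increase(self, model2d):
        cfg = LGMFConfig(force_max=nn(0.6))
        for ramp in run_ramp(model2d, cfg):
            mags = [p.force_magnitude for p in ramp.points]
            assert all(b > a for a, b in zip(mags, mags[1:]))

    def test_all_points_verified_within_budget(self, model2d):
        cfg = LGMFConfig(force_max=nn(0.6))
        for ramp in run_ramp(model2d, cfg):
            for p in ramp.points[1:]:
                assert p.verified_exact
                assert abs(p.cos_alpha) >= cfg.cos_tolerance
                assert abs(p.force_magnitude - p.scheduled_force) <= (
                    cfg.force_budget * p.scheduled_force
                )

    def test_requires_optimized_start(self):
        from lgmf.surfaces import QuadraticSurface, TwoStatePES

        s0 = QuadraticSurface([0.0], 0.0, [0.5], [[1.0]])
        s1 = QuadraticSurface([0.0], 1.0, [0.1], [[2.0]])
        with pytest.raises(ValueError, match="optimized"):
            run_ramp(TwoStatePES(s0, s1), LGMFConfig())

    def test_stationary_gap_seeds_from_pencil(self):
        """With a vanishing gap gradient the branches grow along the
        extreme eigenvectors of the curvature pencil and still split by
        sign."""
        pes = make_quadratic_pair(4, seed=2, g1_scale=0.0)
        up, dn = run_ramp(pes, LGMFConfig(force_max=nn(0.2)))
        assert up.points[1].gap_variation > 0 > dn.points[1].gap_variation

    def test_small_force_slope_continuity(self):
        """The first ramp point recovers the zero-force response slope."""
        from lgmf.quadratic import initial_response_slope

        pes = make_quadratic_pair(5, seed=12)
        g1n = np.linalg.norm(pes.state1.evaluate(np.zeros(5)).gradient)
        step = 1e-3 * g1n
        cfg = LGMFConfig(force_step=step, force_max=step * 1.5,
                         cos_tolerance=1 - 1e-10)
        slope = initial_response_slope(pes)
        up, dn = run_ramp(pes, cfg)
        for ramp, sign in ((up, 1), (dn, -1)):
            p = ramp.points[1]
            assert sign * p.gap_variation / p.force_magnitude == (
                pytest.approx(slope, rel=0.01)
            )

    def test_bfgs_policy_matches_exact_on_quadratic(self):
        pes = make_quadratic_pair(5, seed=11)
        kw = dict(force_max=nn(0.3), cos_tolerance=1 - 1e-10)
        exact = run_ramp(pes, LGMFConfig(hessian_policy="exact", **kw))
        bfgs = run_ramp(pes, LGMFConfig(hessian_policy="bfgs", **kw))
        for re_, rb in zip(exact, bfgs):
            assert len(re_.points) == len(rb.points)
            for a, b in zip(re_.points, rb.points):
                assert b.gap_variation == pytest.approx(a.gap_variation,
                                                        abs=1e-4)

    def test_bfgs_policy_tracks_exact_on_anharmonic(self, model2d):
        kw = dict(force_max=nn(0.4), cos_tolerance=0.99999)
        exact = run_ramp(model2d, LGMFConfig(hessian_policy="exact", **kw))
        bfgs = run_ramp(model2d, LGMFConfig(hessian_policy="bfgs", **kw))
        for re_, rb in zip(exact, bfgs):
            for a, b in zip(re_.points, rb.points):
                assert b.gap_variation == pytest.approx(a.gap_variation,
                                                        rel=0.02, abs=1e-5)
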