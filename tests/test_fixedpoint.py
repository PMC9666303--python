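import numpy as np
import pytest

import wdbcm as wb
from wdbcm.fixedpoint import Classification


@pytest.fixture(scope="module")
def wd13(pair04):
    cfg = wb.PlasticityConfig(rule="weight_dependent", u=1.3, tau_theta=20, tau_w=200)
    return cfg, wb.all_fixed_points_2d(pair04, cfg)


@pytest.fixture(scope="module")
def wd23(pair04):
    cfg = wb.PlasticityConfig(rule="weight_dependent", u=2.3, tau_theta=20, tau_w=200)
    return cfg, wb.all_fixed_points_2d(pair04, cfg)


class TestStandardFixedPoints:
    def test_identity_stimuli(self):
        reports = wb.standard_fixed_points(np.eye(2))
        ws = sorted(tuple(r.w_star) for r in reports if r.classification is Classification.STANDARD_BCM)
        assert np.allclose(ws, [(0, 2), (2, 0)])

    def test_phi_04_weights(self, pair04):
        reports = wb.standard_fixed_points(pair04)
        std = [r for r in reports if r.classification is Classification.STANDARD_BCM]
        assert np.allclose(std[0].w_star, [2.64404227, -1.11788314], atol=1e-6)
        assert np.allclose(std[1].w_star, [-1.11788314, 2.64404227], atol=1e-6)

    def test_responses_are_winner_take_all(self):
        # odd N: the even-N, omega=0.5 circulant is exactly singular
        # (its Nyquist-mode eigenvalue vanishes)
        ens = wb.make_triangular(19, 19, 0.5)
        reports = wb.standard_fixed_points(ens)
        std = [r for r in reports if r.classification is Classification.STANDARD_BCM]
        assert len(std) == 19
        for m, r in enumerate(std):
            y = ens.patterns @ r.w_star
            expected = np.zeros(19)
            expected[m] = 19.0
            assert np.allclose(y, expected, atol=1e-9)

    def test_even_n_half_width_triangular_is_singular(self, triangular20):
        with pytest.raises(wb.SingularStimulusError):
            wb.standard_fixed_points(triangular20)

    def test_singular_stimuli_rejected(self):
        with pytest.raises(wb.SingularStimulusError):
            wb.standard_fixed_points(wb.make_pair2d(np.pi / 4))

    def test_symmetric_points_included(self, pair04):
        reports = wb.standard_fixed_points(pair04)
        sym = [r for r in reports if r.classification is Classification.SYMMETRIC_UNSTABLE]
        assert len(sym) == 2
        assert np.allclose(sym[0].w_star, 0.0)
        assert np.allclose(pair04.patterns @ sym[1].w_star, [1.0, 1.0])


class TestMeanUpdate:
    def test_zero_at_standard_fixed_point_standard_rule(self, pair04):
        cfg = wb.PlasticityConfig(rule="standard", tau_theta=20, tau_w=200)
        for r in wb.standard_fixed_points(pair04)[:2]:
            assert np.max(np.abs(wb.mean_update(r.w_star, pair04, cfg))) < 1e-12

    def test_zero_at_standard_fp_wd_rule_any_u(self, pair04):
        # F = 0 on every pattern, so the weight factor is irrelevant
        for u in (0.5, 1.3, 2.3):
            cfg = wb.PlasticityConfig(rule="weight_dependent", u=u, tau_theta=20, tau_w=200)
            for r in wb.standard_fixed_points(pair04)[:2]:
                assert np.max(np.abs(wb.mean_update(r.w_star, pair04, cfg))) < 1e-12

    def test_root_consistency_of_wd_points(self, pair04, wd13):
        cfg, reports = wd13
        wd = [r for r in reports if r.classification is Classification.WEIGHT_DEPENDENT]
        assert wd, "expected weight-dependent fixed points at u=1.3"
        for r in wd:
            assert np.max(np.abs(wb.mean_update(r.w_star, pair04, cfg))) < 1e-9


class TestWeightDependentPoints:
    def test_two_mirror_points_at_weak_inhibition(self, wd13):
        _, reports = wd13
        wd = [r for r in reports if r.classification is Classification.WEIGHT_DEPENDENT]
        assert len(wd) == 2
        assert np.allclose(wd[0].w_star, wd[1].w_star[::-1])
        assert all(r.stable for r in wd)
        # both responses strictly positive: partial selectivity
        for r in wd:
            assert np.all(r.responses > 0.1)

    def test_no_new_points_at_strong_inhibition(self, wd23):
        _, reports = wd23
        assert not any(
            r.classification is Classification.WEIGHT_DEPENDENT for r in reports
        )

    def test_merging_as_inhibition_approaches_critical(self, pair04):
        """The weight-dependent points converge onto the winner-take-all
        points as u increases towards u*."""
        u_star = float(np.max(wb.critical_inhibition_upper(pair04)))
        std_w = wb.standard_fixed_points(pair04)[1].w_star
        dists = []
        for u in (1.5, 1.7, 1.85, 1.93):
            cfg = wb.PlasticityConfig(rule="weight_dependent", u=u, tau_theta=20, tau_w=200)
            fps = wb.wd_fixed_points_2d(pair04, cfg)
            dists.append(min(np.linalg.norm(fp.w_star - std_w) for fp in fps))
        assert all(a > b for a, b in zip(dists, dists[1:]))
        assert dists[-1] < 0.01
        assert 1.93 < u_star < 1.94


class TestStability:
    def test_origin_unstable(self, wd13):
        _, reports = wd13
        origin = next(r for r in reports if np.allclose(r.w_star, 0.0))
        assert not origin.stable and not origin.inconclusive

    def test_symmetric_point_unstable(self, wd13):
        _, reports = wd13
        sym = next(
            r
            for r in reports
            if r.classification is Classification.SYMMETRIC_UNSTABLE
            and not np.allclose(r.w_star, 0.0)
        )
        assert not sym.stable

    def test_standard_points_unstable_below_critical(self, wd13):
        _, reports = wd13
        std = [r for r in reports if r.classification is Classification.STANDARD_BCM]
        assert all(not r.stable for r in std)

    def test_standard_points_stable_above_critical(self, wd23):
        _, reports = wd23
        std = [r for r in reports if r.classification is Classification.STANDARD_BCM]
        assert all(r.stable for r in std)

    def test_standard_rule_standard_points_stable(self, pair04):
        cfg = wb.PlasticityConfig(rule="standard", tau_theta=20, tau_w=200)
        for r in wb.standard_fixed_points(pair04)[:2]:
            assert wb.stability(r, pair04, cfg)["stable"]


class TestNullclines:
    @pytest.mark.parametrize("u,n_expected", [(1.3, 5), (2.3, 3)])
    def test_crossing_counts(self, pair04, u, n_expected):
        cfg = wb.PlasticityConfig(rule="weight_dependent", u=u, tau_theta=20, tau_w=200)
        nc = wb.nullclines_2d(pair04, cfg)
        crossings = wb.count_nullcline_crossings(nc, pair04, cfg)
        assert len(crossings) == n_expected

    def test_crossings_match_reported_fixed_points(self, pair04, wd13):
        """Brute-force grid oracle: every sign-change cell resolves to a
        reported fixed point and no reported point is missed."""
        cfg, reports = wd13
        nc = wb.nullclines_2d(pair04, cfg, n_grid=120)
        crossings = wb.count_nullcline_crossings(nc, pair04, cfg)
        interior = [
            r.w_star
            for r in reports
            if not np.allclose(r.w_star, 0.0)
            and r.classification is not Classification.PINNED_AT_BOUND
        ]
        assert len(crossings) == len(interior)
        for w in interior:
            assert min(np.linalg.norm(w - c) for c in crossings) < 1e-6

    def test_standard_rule_crossings_are_standard_points(self, pair04):
        cfg = wb.PlasticityConfig(rule="standard", tau_theta=20, tau_w=200)
        # standard BCM has no lower bound on w: open the window wide
        nc = wb.nullclines_2d(pair04, cfg, w_range=(-2.0, 4.2))
        crossings = wb.count_nullcline_crossings(nc, pair04, cfg)
        expected = [
            r.w_star
            for r in wb.standard_fixed_points(pair04)
            if not np.allclose(r.w_star, 0.0)
        ]
        assert len(crossings) == len(expected)
        for w in expected:
            assert min(np.linalg.norm(w - c) for c in crossings) < 1e-6

    def test_restricted_region_mask(self, pair04):
        cfg = wb.PlasticityConfig(rule="weight_dependent", u=1.3, tau_theta=20, tau_w=200)
        nc = wb.nullclines_2d(pair04, cfg, w_range=(-2.0, 4.0), n_grid=50)
        assert nc["restricted_mask"].any()


class TestCriticalInhibition:
    def test_upper_value_and_closed_form(self, pair04):
        u_star = wb.critical_inhibition_upper(pair04)
        assert np.allclose(u_star, 1.9367117250076153, atol=1e-10)
        closed = wb.critical_inhibition_upper_closed_form(0.4)
        assert abs(u_star[0] - closed) < 1e-10

    def test_upper_vanishes_for_orthogonal_stimuli(self):
        assert wb.critical_inhibition_upper_closed_form(1e-9) == pytest.approx(0.0, abs=1e-8)

    def test_lower_value_and_closed_form(self, pair04):
        u_ss = wb.critical_inhibition_lower(pair04)
        assert u_ss == pytest.approx(-0.7630795635546546, abs=1e-12)
        assert u_ss == pytest.approx(wb.critical_inhibition_lower_closed_form(0.4), abs=1e-12)

    def test_lower_at_parallel_angle(self):
        assert wb.critical_inhibition_lower_closed_form(np.pi / 4) == pytest.approx(
            -1.0 / np.sqrt(2.0), abs=1e-12
        )

    def test_simulation_straddles_transition(self, pair04):
        """Equilibria just below/above u* are partial vs winner-take-all."""
        for u, partial in ((1.8, True), (2.1, False)):
            cfg = wb.PlasticityConfig(
                rule="weight_dependent", u=u, tau_theta=20, tau_w=200, rng_seed=3
            )
            traj = wb.simulate(pair04, cfg, n_presentations=60_000, record_every=2000)
            loser = float(np.min(pair04.patterns @ traj.final_state.w))
            if partial:
                assert loser > 1e-2
            else:
                assert abs(loser) < 1e-3

    def test_pinned_equilibrium_below_lower_critical(self, pair04):
        u = wb.critical_inhibition_lower(pair04) - 0.1
        cfg = wb.PlasticityConfig(
            rule="weight_dependent", u=u, tau_theta=20, tau_w=200, rng_seed=5
        )
        traj = wb.simulate(pair04, cfg, n_presentations=60_000, record_every=2000)
        assert np.allclose(traj.final_state.w, -u, atol=1e-6)


class TestNoiseFixedPoints:
    @pytest.mark.parametrize(
        "sigma,y1,y2,theta",
        [
            (0.0, 2.0, 0.0, 2.0),
            (0.6, 1.8, 0.2, 2.0),
            (1.0, 1.0, 1.0, 2.0),
            (1.2, 1.0, 1.0, 2.44),
        ],
    )
    def test_closed_form(self, sigma, y1, y2, theta):
        fp = wb.noise_fixed_points(sigma)
        assert fp["responses"][0] == pytest.approx(y1, abs=1e-12)
        assert fp["responses"][1] == pytest.approx(y2, abs=1e-12)
        assert fp["theta"] == pytest.approx(theta, abs=1e-12)

    def test_sum_rule_below_collapse(self):
        for sigma in np.linspace(0.0, 0.99, 12):
            assert wb.noise_fixed_points(sigma)["responses"].sum() == pytest.approx(2.0)

    def test_simulation_matches_analytic(self, pair04):
        """Time-averaged noisy equilibria agree with the closed form to
        within three standard errors plus the O(1/tau_theta) offset of
        the finite-time-constant orbit from the mean-field limit."""
        for sigma in (0.3, 0.6, 0.9):
            cfg = wb.PlasticityConfig(
                rule="standard", tau_theta=20, tau_w=200, sigma_y=sigma, rng_seed=7
            )
            traj = wb.simulate(pair04, cfg, n_presentations=60_000, record_every=2000)
            ta = wb.tail_average(pair04, cfg, traj, n_epochs=4000, n_batches=10)
            an = np.sort(wb.noise_fixed_points(sigma)["responses"])
            y = np.sort(ta["responses"])
            se = np.maximum(ta["responses_se"], 1e-4)
            assert np.all(np.abs(y - an) < 3 * se + 2.0 / cfg.tau_theta)
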