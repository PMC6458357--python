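"""Stance mechanics: contact kinematics, collision, push-off, observables."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from runsim.model_core import (
    BodyState,
    ContactEvent,
    Phase,
    PushoffImpulse,
    RunnerParams,
    apply_pushoff,
    contact_point_velocity,
    effective_eps_t,
    epsilon_hat,
    kinetic_energy,
    angular_momentum_about,
    passive_collision,
    pushoff_impulse,
)


def state(phase="pre_collision", **kw):
    d = dict(x=0.0, y=1.0, phi=0.0, v_x=0.96, v_y=-0.26, omega=0.0)
    d.update(kw)
    return BodyState(**d, phase=phase)


def flat_contact():
    return ContactEvent.from_slope(P=[0.0, 0.0], theta=0.0, r_PG=[0.0, -1.0])


class TestRunnerParams:
    @pytest.mark.parametrize(
        "kw",
        [
            {"eps_n": 1.5},
            {"eps_n": -0.1},
            {"eps_tc": 2.0},
            {"I_G": 0.0},
            {"v_x0": -1.0},
            {"delta_eps_t": -0.5},
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            RunnerParams(**kw)

    def test_human_like_defaults(self, human_like):
        assert (human_like.I_G, human_like.eps_n) == (0.17, 0.63)
        assert human_like.phi_tol == pytest.approx(math.pi / 6)
        assert (human_like.v_x0, human_like.v_y0) == (0.96, 0.26)


class TestContactPointVelocity:
    def test_pure_spin_about_com(self):
        s = state(v_x=0.0, v_y=0.0, omega=1.0)
        v_t, v_n = contact_point_velocity(s, flat_contact())
        assert (v_t, v_n) == pytest.approx((1.0, 0.0))

    def test_pure_translation(self):
        v_t, v_n = contact_point_velocity(state(), flat_contact())
        assert (v_t, v_n) == pytest.approx((0.96, -0.26))

    def test_sloped_contact_matches_vector_algebra(self):
        # independent oracle: rotate v_G + omega z x r into (t, n) explicitly
        theta = math.radians(10.0)
        r = np.array([math.sin(theta), -math.cos(theta)])
        c = ContactEvent.from_slope(P=r, theta=theta, r_PG=r)
        s = state(v_x=1.0, v_y=0.0, omega=0.5)
        v_P = np.array([1.0, 0.0]) + 0.5 * np.array([-r[1], r[0]])
        t_hat = np.array([math.cos(theta), math.sin(theta)])
        n_hat = np.array([-math.sin(theta), math.cos(theta)])
        expect = (float(v_P @ t_hat), float(v_P @ n_hat))
        assert contact_point_velocity(s, c) == pytest.approx(expect, abs=1e-14)

    def test_non_unit_leg_rejected(self):
        with pytest.raises(ValueError):
            ContactEvent.from_slope(P=[0, 0], theta=0.0, r_PG=[0.0, -2.0])


class TestEffectiveEpsT:
    def test_open_loop_at_nominal_speed(self, human_like):
        p = human_like.replace(eps_tc=0.5)
        assert effective_eps_t(p, p.v_x0) == pytest.approx(0.5)

    def test_open_loop_ratio(self, human_like):
        p = human_like.replace(eps_tc=0.5)
        assert effective_eps_t(p, 1.2) == pytest.approx(0.5 * 0.96 / 1.2)

    def test_anticipatory_is_intended_value(self, anticipatory):
        p = anticipatory(eps_tc=1.0)
        for v in (0.2, 0.96, 3.0):
            assert effective_eps_t(p, v) == 1.0

    def test_open_loop_degenerate_contact_raises(self, human_like):
        with pytest.raises(ZeroDivisionError):
            effective_eps_t(human_like.replace(eps_tc=0.5), 0.0)

    def test_noise_perturbs_intended_coefficient(self, anticipatory, rng):
        p = anticipatory(eps_tc=0.9, delta_eps_t=0.1)
        vals = [effective_eps_t(p, 1.0, rng) for _ in range(500)]
        assert all(0.8 <= v <= 1.0 for v in vals)
        assert np.std(vals) > 0.01  # actually random
        # noise enters before the open-loop ratio
        p_ol = RunnerParams(eps_tc=0.9, delta_eps_t=0.1)
        v = effective_eps_t(p_ol, 2 * p_ol.v_x0, np.random.default_rng(0))
        eta = np.random.default_rng(0).uniform(-1, 1)
        assert v == pytest.approx((0.9 + 0.1 * eta) / 2.0)


class TestPassiveCollision:
    def test_elastic_reflection(self, human_like):
        post = passive_collision(state(), flat_contact(), 1.0, 1.0, human_like.I_G)
        assert post.v_x == pytest.approx(0.96, abs=1e-14)
        assert post.v_y == pytest.approx(0.26, abs=1e-14)
        assert post.omega == pytest.approx(0.0, abs=1e-14)
        assert post.phase is Phase.POST_COLLISION

    def test_sticking_tangential_collision_spins_body(self):
        # solved by hand from the three collision constraints
        post = passive_collision(
            state(v_x=1.0), flat_contact(), 0.0, 0.63, I_G=0.17
        )
        assert post.omega == pytest.approx(-1.0 / 1.17, abs=1e-12)
        assert post.v_x == pytest.approx(1.0 / 1.17, abs=1e-12)
        assert post.v_y == pytest.approx(0.63 * 0.26, abs=1e-12)

    def test_separating_contact_rejected(self, human_like):
        with pytest.raises(ValueError):
            passive_collision(
                state(v_y=+0.1), flat_contact(), 0.5, 0.5, human_like.I_G
            )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        eps_t=st.floats(0, 1),
        eps_n=st.floats(0, 1),
        theta=st.floats(-0.5, 0.5),
        v_x=st.floats(0.2, 2.0),
        v_y=st.floats(-1.5, -0.05),
        omega=st.floats(-1.0, 1.0),
        I_G=st.floats(0.05, 0.8),
    )
    def test_collision_contract_and_dissipativity(
        self, eps_t, eps_n, theta, v_x, v_y, omega, I_G
    ):
        """Post contact-point velocities and angular momentum about P obey
        the collision law exactly, and kinetic energy never increases."""
        r = np.array([math.sin(theta), -math.cos(theta)])
        contact = ContactEvent.from_slope(P=np.array([0.0, 1.0]) + r,
                                          theta=theta, r_PG=r)
        pre = state(v_x=v_x, v_y=v_y, omega=omega)
        v_t0, v_n0 = contact_point_velocity(pre, contact)
        if v_n0 >= 0:
            return  # not a collision
        post = passive_collision(pre, contact, eps_t, eps_n, I_G)
        v_t1, v_n1 = contact_point_velocity(post, contact)
        assert v_t1 == pytest.approx(eps_t * v_t0, abs=1e-12)
        assert v_n1 == pytest.approx(-eps_n * v_n0, abs=1e-12)
        H0 = angular_momentum_about(pre, contact.P, I_G)
        H1 = angular_momentum_about(post, contact.P, I_G)
        assert H1 == pytest.approx(H0, abs=1e-12)
        assert kinetic_energy(post, I_G) <= kinetic_energy(pre, I_G) + 1e-12


class TestPushoffImpulse:
    def test_elastic_limit_is_impulse_free(self, human_like):
        imp = pushoff_impulse(human_like.replace(eps_n=1.0, eps_tc=1.0))
        assert (imp.J_t, imp.J_n, imp.J_phi) == (0.0, 0.0, 0.0)

    @pytest.mark.parametrize("eps_n", [0.0, 0.5, 0.63, 1.0])
    @pytest.mark.parametrize("eps_tc", [0.0, 0.3, 1.0])
    @pytest.mark.parametrize("I_G", [0.05, 0.17, 0.6])
    def test_closed_form_equals_numerical_periodicity_solve(
        self, eps_n, eps_tc, I_G
    ):
        """Independent oracle: solve the flat-ground periodicity condition
        for (J_t, J_n) numerically and compare with the closed form."""
        from scipy.optimize import fsolve

        p = RunnerParams(eps_n=eps_n, eps_tc=eps_tc, I_G=I_G)
        post_c = passive_collision(
            state(), flat_contact(), eps_tc, eps_n, I_G
        )

        def residual(J):
            imp = PushoffImpulse(J_t=J[0], J_n=J[1])
            post = apply_pushoff(post_c, flat_contact(), imp, I_G)
            return [post.v_x - p.v_x0, post.v_y - p.v_y0]

        J_num = fsolve(residual, [0.1, 0.1], xtol=1e-13)
        imp = pushoff_impulse(p)
        assert imp.J_t == pytest.approx(J_num[0], abs=1e-10)
        assert imp.J_n == pytest.approx(J_num[1], abs=1e-10)
        # and the take-off spin also vanishes without any angular impulse
        post = apply_pushoff(post_c, flat_contact(), imp, I_G)
        assert post.omega == pytest.approx(0.0, abs=1e-12)
        assert imp.J_phi == 0.0

    def test_defining_property_reproduces_gait(self, human_like):
        post_c = passive_collision(
            state(), flat_contact(), human_like.eps_tc, human_like.eps_n, human_like.I_G
        )
        post = apply_pushoff(post_c, flat_contact(), pushoff_impulse(human_like),
                             human_like.I_G)
        assert (post.v_x, post.v_y, post.omega) == pytest.approx(
            (0.96, 0.26, 0.0), abs=1e-14
        )


class TestApplyPushoff:
    def test_zero_impulse_is_identity(self, human_like):
        s = state(phase="post_collision")
        post = apply_pushoff(s, flat_contact(), PushoffImpulse(0.0, 0.0), human_like.I_G)
        assert (post.v_x, post.v_y, post.omega) == (s.v_x, s.v_y, s.omega)

    def test_frames_coincide_on_flat_ground(self, human_like):
        s = state(phase="post_collision")
        a = apply_pushoff(
            s, flat_contact(),
            PushoffImpulse(0.1, 0.2, frame="terrain_fixed"), human_like.I_G,
        )
        b = apply_pushoff(
            s, flat_contact(),
            PushoffImpulse(0.1, 0.2, frame="laboratory_fixed"), human_like.I_G,
        )
        assert (a.v_x, a.v_y, a.omega) == pytest.approx((b.v_x, b.v_y, b.omega))

    def test_frames_differ_on_slope(self, human_like):
        theta = 0.2
        r = np.array([math.sin(theta), -math.cos(theta)])
        c = ContactEvent.from_slope(P=r + [0, 1], theta=theta, r_PG=r)
        s = state(phase="post_collision")
        a = apply_pushoff(s, c, PushoffImpulse(0.1, 0.2, frame="terrain_fixed"),
                          human_like.I_G)
        b = apply_pushoff(s, c, PushoffImpulse(0.1, 0.2, frame="laboratory_fixed"),
                          human_like.I_G)
        assert abs(a.v_x - b.v_x) > 1e-3


class TestEpsilonHat:
    def test_no_loss_gives_unity(self):
        assert epsilon_hat(0.96, 0.96) == 1.0

    def test_flat_terrain_recovers_eps_t(self, human_like):
        # on flat ground eps-hat equals the true tangential restitution
        for eps_t in (0.0, 0.4, 1.0):
            pre = state()
            post = passive_collision(pre, flat_contact(), eps_t, 0.63, human_like.I_G)
            # forward contact-point momentum change maps through 1/(1+I_G);
            # compare against the direct observable definition
            got = epsilon_hat(pre.v_x, post.v_x)
            v_t0, _ = contact_point_velocity(pre, flat_contact())
            v_t1, _ = contact_point_velocity(post, flat_contact())
            assert v_t1 == pytest.approx(eps_t * v_t0, abs=1e-13)
            assert 0.0 <= got <= 1.0 + 1e-12

    def test_undefined_for_nonpositive_speed(self):
        with pytest.raises(ValueError):
            epsilon_hat(0.0, 0.1)


class TestFlatGroundPeriodicity:
    @pytest.mark.parametrize("eps_n", [0.0, 0.25, 0.63, 1.0])
    @pytest.mark.parametrize("eps_tc", [0.0, 0.5, 1.0])
    def test_full_step_map_is_periodic(self, eps_n, eps_tc, flat):
        """The complete step (flight + collision + push-off + flight) maps
        the take-off state to itself on flat ground, to 1e-12."""
        from runsim.flight import take_step, initial_takeoff_state
        from runsim.model_core import pushoff_impulse as pimp

        p = RunnerParams(eps_n=eps_n, eps_tc=eps_tc)
        s0 = initial_takeoff_state(p, flat)
        rec = take_step(s0, flat, p, pimp(p))
        s1 = rec.post_state
        assert s1.y == pytest.approx(s0.y, abs=1e-12)
        assert s1.v_x == pytest.approx(s0.v_x, abs=1e-12)
        assert s1.v_y == pytest.approx(s0.v_y, abs=1e-12)
        assert s1.phi == pytest.approx(0.0, abs=1e-12)
        assert s1.omega == pytest.approx(0.0, abs=1e-12)
        assert s1.x - s0.x == pytest.approx(2 * p.v_x0 * p.v_y0, abs=1e-12)

    def test_anticipatory_unity_eps_tc_spin_free_on_any_slope(self):
        """Perfect tangential-collision avoidance leaves the body spin-free
        after push-off regardless of the local slope."""
        from runsim.model_core import collision_with_targets

        p = RunnerParams(strategy="anticipatory", eps_tc=1.0)
        imp = pushoff_impulse(p)
        for theta in (-0.3, -0.1, 0.05, 0.2, 0.45):
            r = np.array([math.sin(theta), -math.cos(theta)])
            c = ContactEvent.from_slope(P=np.array([0., 1.]) + r, theta=theta,
                                        r_PG=r)
            pre = state(omega=0.0)
            v_t, v_n = contact_point_velocity(pre, c)
            post_c = collision_with_targets(pre, c, 1.0 * v_t, -p.eps_n * v_n,
                                            p.I_G)
            post = apply_pushoff(post_c, c, imp, p.I_G)
            assert post.omega == pytest.approx(0.0, abs=1e-12)
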