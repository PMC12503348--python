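import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rhangio.af_solver import AFField
from rhangio.capillary import CapillaryState
from rhangio.geometry import SimDomain
from rhangio.tip_cells import (
    S_p,
    TipCell,
    activate_tips,
    assign_velocities,
    deactivate_tips,
    imprint_tips,
    move_tips,
    n_active,
    tip_velocity,
)


@pytest.fixture
def domain():
    return SimDomain(dim=2, extent=(0.2, 0.2), h=0.01)


def linear_af(domain, slope=2.0, offset=0.6):
    """AF rising along x with uniform gradient `slope` (>= G_m default)."""
    X, _ = domain.meshgrid()
    return AFField(af=offset + slope * (X - 0.1), h=domain.h)


class TestActivation:
    def test_eligible_node_activates(self, domain, params):
        c = np.full(domain.shape, -1.0)
        c[10, 10] = 1.0
        aff = linear_af(domain)
        tips = activate_tips(c, aff, [], params, domain)
        assert n_active(tips) == 1
        np.testing.assert_allclose(tips[0].position, [0.1, 0.1])

    def test_below_T_c_not_activated(self, domain, params):
        c = np.full(domain.shape, -1.0)
        c[10, 10] = 1.0
        aff = AFField(af=np.full(domain.shape, 0.4) + 2.0 * domain.meshgrid()[0] * 0,
                      h=domain.h)
        # uniform 0.4 < T_c = 0.5 (gradient is zero too, but T_c alone blocks)
        tips = activate_tips(c, aff, [], params, domain)
        assert n_active(tips) == 0

    def test_notch_exclusion_two_close_nodes(self, domain, params):
        # two eligible nodes 0.03 sau apart < delta4 = 0.05: exactly one
        c = np.full(domain.shape, -1.0)
        c[10, 10] = 1.0
        c[10, 13] = 1.0
        aff = linear_af(domain)
        tips = activate_tips(c, aff, [], params, domain)
        assert n_active(tips) == 1

    def test_notch_respects_existing_tips(self, domain, params):
        c = np.full(domain.shape, -1.0)
        c[10, 10] = 1.0
        existing = [
            TipCell(position=np.array([0.1, 0.12]), velocity=np.zeros(2))
        ]
        aff = linear_af(domain)
        tips = activate_tips(c, aff, existing, params, domain)
        assert n_active(tips) == 1  # only the pre-existing one

    def test_pairwise_distance_invariant(self, domain, params):
        c = np.full(domain.shape, 1.0)  # everything eligible
        aff = linear_af(domain)
        tips = activate_tips(c, aff, [], params, domain)
        act = [tc.position for tc in tips if tc.active]
        assert len(act) > 1
        for i in range(len(act)):
            for j in range(i + 1, len(act)):
                assert np.linalg.norm(act[i] - act[j]) >= params.delta4 - 1e-12

    def test_deterministic_lex_order(self, domain, params):
        c = np.full(domain.shape, 1.0)
        aff = linear_af(domain)
        a = activate_tips(c, aff, [], params, domain)
        b = activate_tips(c, aff, [], params, domain)
        assert len(a) == len(b)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.position, tb.position)

    def test_seeded_random_order_reproducible(self, domain, params):
        c = np.full(domain.shape, 1.0)
        aff = linear_af(domain)
        rng1 = np.random.default_rng(7)
        rng2 = np.random.default_rng(7)
        a = activate_tips(c, aff, [], params, domain, order="random", rng=rng1)
        b = activate_tips(c, aff, [], params, domain, order="random", rng=rng2)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.position, tb.position)


class TestDeactivation:
    def make_tip(self, pos):
        return TipCell(position=np.asarray(pos, dtype=float), velocity=np.zeros(2))

    def test_low_af_deactivates(self, domain, params):
        aff = AFField(af=np.full(domain.shape, 0.3), h=domain.h)
        tips = deactivate_tips([self.make_tip([0.1, 0.1])], aff, params, domain)
        assert not tips[0].active

    def test_low_gradient_deactivates(self, domain, params):
        aff = AFField(af=np.full(domain.shape, 0.6), h=domain.h)  # G = 0
        tips = deactivate_tips([self.make_tip([0.1, 0.1])], aff, params, domain)
        assert not tips[0].active

    def test_thresholds_met_stays_active(self, domain, params):
        aff = linear_af(domain)
        tips = deactivate_tips([self.make_tip([0.1, 0.1])], aff, params, domain)
        assert tips[0].active


class TestVelocity:
    def test_below_cap(self, params):
        v = tip_velocity(np.array([2.0, 0.0]), params)
        np.testing.assert_allclose(v, [params.chi * 2.0, 0.0])
        assert v[0] == pytest.approx(0.004062, abs=5e-6)

    def test_cap_branch(self, params):
        g = 2.0 * params.G_M  # 11.2
        v = tip_velocity(np.array([g, 0.0]), params)
        assert np.linalg.norm(v) == pytest.approx(params.chi * params.G_M)
        assert np.linalg.norm(v) == pytest.approx(0.0113736, abs=2e-6)
        assert v[1] == 0.0

    def test_branch_continuity_at_cap(self, params):
        v = tip_velocity(np.array([0.0, params.G_M]), params)
        assert np.linalg.norm(v) == pytest.approx(params.chi * params.G_M, rel=1e-12)

    def test_below_G_m_is_contract_violation(self, params):
        with pytest.raises(ValueError):
            tip_velocity(np.array([0.1, 0.0]), params)

    @settings(max_examples=50, deadline=None)
    @given(
        gx=st.floats(-50, 50),
        gy=st.floats(-50, 50),
    )
    def test_speed_cap_property(self, gx, gy, params):
        g = math.hypot(gx, gy)
        if g < params.G_m:
            return
        v = tip_velocity(np.array([gx, gy]), params)
        assert np.linalg.norm(v) <= params.chi * params.G_M * (1 + 1e-12)
        # parallel to the gradient
        cross = v[0] * gy - v[1] * gx
        assert abs(cross) <= 1e-9 * max(1.0, g)


class TestImprint:
    def test_imprint_value(self, domain, params):
        # c_c = S_p(af) * pi * R_c^2 / |v| with af = 0.3, |v| = 0.004062
        c = np.full(domain.shape, -1.0)
        state = CapillaryState(c=c, mu=np.zeros_like(c))
        aff = AFField(af=np.full(domain.shape, 0.3), h=domain.h)
        speed = 0.004062
        tip = TipCell(position=np.array([0.1, 0.1]), velocity=np.array([speed, 0.0]))
        out = imprint_tips(state, [tip], aff, params, domain)
        expected = (
            float(S_p(0.3, params)) * math.pi * params.R_c**2 / speed
        )
        assert expected == pytest.approx(0.0508, abs=2e-4)
        assert out.c[10, 10] == pytest.approx(expected, rel=1e-12)
        # nodes beyond R_c untouched (R_c = 0.0125 < 2h = 0.02)
        assert out.c[10, 12] == -1.0

    def test_no_active_tips_unchanged(self, domain, params):
        c = np.random.default_rng(0).normal(size=domain.shape)
        state = CapillaryState(c=c.copy(), mu=np.zeros_like(c))
        out = imprint_tips(state, [], AFField(af=c, h=domain.h), params, domain)
        np.testing.assert_array_equal(out.c, c)

    def test_nonpositive_af_imprints_zero(self, domain, params):
        c = np.full(domain.shape, -1.0)
        state = CapillaryState(c=c, mu=np.zeros_like(c))
        aff = AFField(af=np.full(domain.shape, -0.2), h=domain.h)
        tip = TipCell(position=np.array([0.1, 0.1]), velocity=np.array([0.01, 0.0]))
        out = imprint_tips(state, [tip], aff, params, domain)
        assert out.c[10, 10] == 0.0

    def test_speed_floor(self, domain, params):
        c = np.full(domain.shape, -1.0)
        state = CapillaryState(c=c, mu=np.zeros_like(c))
        aff = AFField(af=np.full(domain.shape, 0.3), h=domain.h)
        tip = TipCell(position=np.array([0.1, 0.1]), velocity=np.zeros(2))
        out = imprint_tips(state, [tip], aff, params, domain)
        expected = float(S_p(0.3, params)) * math.pi * params.R_c**2 / params.v_min
        assert out.c[10, 10] == pytest.approx(expected, rel=1e-12)


class TestMove:
    def test_displacement(self, domain, params):
        tip = TipCell(position=np.array([0.1, 0.1]), velocity=np.array([0.004062, 0.0]))
        (out,) = move_tips([tip], 1.0, domain)
        assert out.position[0] == pytest.approx(0.104062)
        # 0.004062 sau = 3.25 um at sau = 800 um
        assert 0.004062 * 800 == pytest.approx(3.25, abs=0.01)

    def test_zero_dt(self, domain, params):
        tip = TipCell(position=np.array([0.1, 0.1]), velocity=np.array([1.0, 0.0]))
        (out,) = move_tips([tip], 0.0, domain)
        np.testing.assert_array_equal(out.position, [0.1, 0.1])

    def test_boundary_clamp(self, domain, params):
        tip = TipCell(position=np.array([0.19, 0.1]), velocity=np.array([10.0, 0.0]))
        (out,) = move_tips([tip], 1.0, domain)
        assert out.position[0] == pytest.approx(0.2)

    def test_inactive_tips_do_not_move(self, domain, params):
        tip = TipCell(
            position=np.array([0.1, 0.1]),
            velocity=np.array([1.0, 0.0]),
            active=False,
        )
        (out,) = move_tips([tip], 1.0, domain)
        np.testing.assert_array_equal(out.position, [0.1, 0.1])


class TestAssignVelocities:
    def test_velocity_from_local_gradient(self, domain, params):
        aff = linear_af(domain, slope=2.0)
        tip = TipCell(position=np.array([0.1, 0.1]), velocity=np.zeros(2))
        (out,) = assign_velocities([tip], aff, params, domain)
        np.testing.assert_allclose(out.velocity, [params.chi * 2.0, 0.0], rtol=1e-9)
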