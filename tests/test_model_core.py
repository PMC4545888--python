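"""Unit tests for the deterministic model pieces."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from covertsearch.model_core import (
    LIP_UNITS,
    LipTopology,
    ModelParameters,
    TrialCondition,
    condition_inputs,
    drift,
    gate,
    heaviside,
    load_params,
    mirror_state,
    motor_inhibition,
    orientation_input,
    perceptual_input,
    phi,
    state_index,
    target_input,
)

COND = TrialCondition(4, "R1", "E_right")


class TestPhi:
    def test_removable_singularity_matches_series_limit(self):
        # series limit of 0.352 u / (352 u + 3.52 u) as u -> 0
        limit = 0.001 + 0.352 / 355.52
        assert phi(0.384) == pytest.approx(limit, abs=1e-12)
        for eps in (1e-9, -1e-9):
            assert phi(0.384 + eps) == pytest.approx(limit, rel=1e-5)

    def test_asymptotes(self):
        assert phi(1e6) == pytest.approx(0.101, abs=1e-6)
        assert phi(-1e6) == pytest.approx(0.001, abs=1e-12)
        assert phi(-100.0) == pytest.approx(0.001, abs=1e-12)

    def test_strictly_increasing_and_bounded(self):
        grid = np.concatenate([
            np.linspace(-5.0, 5.0, 4001),
            0.384 + np.linspace(-1e-6, 1e-6, 201),
        ])
        grid = np.sort(grid)
        vals = phi(grid)
        assert np.all(np.diff(vals) >= 0.0)
        assert np.all(vals > 0.001 - 1e-15)
        assert np.all(vals < 0.101)
        # continuity across the singular point
        assert abs(phi(0.384 + 1e-9) - phi(0.384 - 1e-9)) < 1e-9


class TestHeavisideGate:
    @pytest.mark.parametrize("x,expected", [(0.0, 1.0), (-0.001, 0.0),
                                            (5.0, 1.0), (-0.0, 1.0)])
    def test_heaviside(self, x, expected):
        assert heaviside(x) == expected

    def test_heaviside_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            heaviside(float("nan"))

    @pytest.mark.parametrize("current,g,expected", [
        (0.5, 0.1, 0.4), (0.05, 0.1, 0.0), (0.1, 0.1, 0.0), (-1.0, 0.0, 0.0)])
    def test_gate(self, current, g, expected):
        assert gate(current, g) == pytest.approx(expected)


class TestInputSchedules:
    @pytest.mark.parametrize("ss,loc,active", [
        (2, "L1", True), (2, "R1", True), (2, "L2", False), (2, "R3", False),
        (4, "L2", True), (4, "R2", True), (4, "L3", False),
        (6, "R3", True), (6, "L3", True)])
    def test_perceptual_schedule(self, ss, loc, active):
        s = perceptual_input(ss, loc, s_lip=0.7)
        assert s == (0.7 if active else 0.0)

    def test_perceptual_unknown_location(self):
        with pytest.raises(ValueError):
            perceptual_input(4, "Q1")

    @pytest.mark.parametrize("pos,loc,expected", [
        ("R1", "R1", 0.4), ("R1", "L1", 0.0), ("L2", "L2", 0.4)])
    def test_target_input(self, pos, loc, expected):
        assert target_input(pos, loc, s_tar=0.4) == expected

    @pytest.mark.parametrize("ori,unit,expected", [
        ("E_right", "E_right", 1.2), ("E_right", "E_left", 0.0),
        ("E_left", "E_left", 1.2)])
    def test_orientation_input(self, ori, unit, expected):
        assert orientation_input(ori, unit, s_ori=1.2) == expected

    def test_motor_inhibition(self):
        assert motor_inhibition((0.0, 0.0), 11.02) == 0.0
        assert motor_inhibition((0.01, 0.02), 11.02) == pytest.approx(0.3306)
        assert motor_inhibition((0.3, 0.1), 2.0) == motor_inhibition(
            (0.1, 0.3), 2.0)


class TestTopology:
    # neighbor groupings as written out unit-by-unit in the LIP equations
    EXPECTED = {
        "L1": ({"R1", "L2"}, {"R2", "L3"}, {"R3"}),
        "L2": ({"L1", "L3"}, {"R1", "R3"}, {"R2"}),
        "L3": ({"L2", "R3"}, {"L1", "R2"}, {"R1"}),
        "R1": ({"L1", "R2"}, {"L2", "R3"}, {"L3"}),
        "R2": ({"R1", "R3"}, {"L1", "L3"}, {"L2"}),
        "R3": ({"L3", "R2"}, {"L2", "R1"}, {"L1"}),
    }

    @pytest.mark.parametrize("unit", LIP_UNITS)
    def test_ring_distances_reproduce_equation_groupings(self, unit):
        one, two, three = self.EXPECTED[unit]
        assert set(LipTopology.neighbors(unit, 1)) == one
        assert set(LipTopology.neighbors(unit, 2)) == two
        assert set(LipTopology.neighbors(unit, 3)) == three

    def test_inhibition_matrix_symmetric_and_weighted(self):
        W = LipTopology.inhibition_matrix(2.0, 0.8, 0.1)
        assert np.allclose(W, W.T)
        assert np.all(np.diag(W) == 0.0)
        i, j = LIP_UNITS.index("L1"), LIP_UNITS.index("R3")
        assert W[i, j] == pytest.approx(2.0 * 0.8 * 0.1)


class TestTrialCondition:
    @pytest.mark.parametrize("ss,pos,ori,cong", [
        (4, "R1", "E_right", True), (4, "L1", "E_right", False),
        (2, "L1", "E_left", True), (6, "R3", "E_left", False)])
    def test_congruence(self, ss, pos, ori, cong):
        assert TrialCondition(ss, pos, ori).congruent is cong

    def test_positions_restricted_by_set_size(self):
        with pytest.raises(ValueError):
            TrialCondition(2, "L2", "E_right")
        with pytest.raises(ValueError):
            TrialCondition(4, "R3", "E_left")

    def test_mirror(self):
        m = TrialCondition(4, "R1", "E_right").mirrored()
        assert (m.position, m.orientation) == ("L1", "E_left")
        assert m.congruent


class TestParameters:
    def test_fixture_values_match_published_table(self, p11, p12):
        assert p11.p_delay == 24.08 and p11.t_0 == 169.8
        assert p11.eta_lip == 2.936 and p11.theta == 0.0926
        assert p12.w_itaip == 18.75 and p12.theta == 0.0961
        # shared parameters identical across subjects
        for name in ("tau_m", "tau_lip", "eta_maipit", "beta_mitlip",
                     "k_aip", "g_aip", "s_back", "s_ori"):
            assert getattr(p11, name) == getattr(p12, name)

    def test_roundtrip_yaml(self, p11, tmp_path):
        path = tmp_path / "p.yaml"
        p11.to_yaml(path)
        assert ModelParameters.from_yaml(path) == p11

    def test_dict_roundtrip_and_validation(self, p11):
        d = p11.to_dict()
        assert len(d) == 31
        assert ModelParameters.from_dict(d) == p11
        with pytest.raises(KeyError):
            ModelParameters.from_dict({**d, "bogus": 1.0})
        with pytest.raises(ValueError):
            p11.replace(tau_lip=-1.0)

    def test_delay_sum(self, p11, p12):
        assert p11.delay_sum == pytest.approx(249.6)
        assert p12.delay_sum == pytest.approx(188.95)


class TestDrift:
    def test_zero_state_before_perceptual_delay(self, p11):
        params = p11.replace(s_back=0.0)
        f, sigma = drift(np.zeros(20), params, COND, t=0.0)
        # OU inputs quiescent, LIP units charge from phi[0] > 0
        assert np.allclose(f[6:12], 0.0)
        assert np.all(f[0:6] > 0.0)
        assert f[0] == pytest.approx(phi(0.0) / params.tau_lip)
        assert sigma.shape == (20,)

    def test_system_has_twenty_state_variables(self, p11):
        f, _ = drift(np.zeros(20), p11, COND, t=0.0)
        assert f.shape == (20,)
        with pytest.raises(ValueError):
            drift(np.zeros(19), p11, COND, t=0.0)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.0, 0.2), min_size=20, max_size=20),
           st.floats(0.0, 600.0))
    def test_bilateral_symmetry(self, state, t):
        params = load_params("m11")
        x = np.array(state)
        f, _ = drift(x, params, COND, t)
        f_m, _ = drift(mirror_state(x), params, COND.mirrored(), t)
        np.testing.assert_allclose(mirror_state(f), f_m, rtol=1e-12,
                                   atol=1e-15)

    def test_l1_inhibition_term_matches_written_equation(self, p11):
        rng = np.random.default_rng(4)
        x = rng.uniform(0.0, 0.1, 20)
        f, _ = drift(x, p11, COND, t=0.0)
        g = lambda u: x[state_index("x_lip", u)]
        inh = (p11.eta_lip * (g("R1") + g("L2"))
               + p11.eta_lip_decay1 * p11.eta_lip * (g("R2") + g("L3"))
               + p11.eta_lip_decay1 * p11.eta_lip_decay2 * p11.eta_lip
               * g("R3"))
        i_mi = p11.beta_mitlip * (x[18] + x[19])
        arg = (p11.w_aiplip * x[16] - p11.beta_aiplip * x[17]
               + p11.alpha_lip * g("L1") - i_mi - inh + x[6])
        expected = (phi(arg) - g("L1")) / p11.tau_lip
        assert f[0] == pytest.approx(expected, rel=1e-12)

    def test_zero_weights_reduce_to_leak(self, p11):
        params = p11.replace(
            eta_maipit=0.0, w_itaip=0.0, w_lipaip=0.0, w_aipm=0.0,
            beta_maip=0.0, beta_mitlip=0.0, g_aip=0.0, g_m=0.0)
        x = np.zeros(20)
        x[12:14] = 0.05   # IT
        x[16:18] = 0.04   # AIP
        x[18:20] = 0.03   # motor
        f, _ = drift(x, params, COND, t=0.0)
        # IT decays toward phi[rho=0]; AIP and motor decay with leaks
        np.testing.assert_allclose(
            f[12:14], (phi(0.0) - 0.05) / params.tau_it)
        np.testing.assert_allclose(f[16:18],
                                   -params.k_aip * 0.04 / params.tau_aip)
        np.testing.assert_allclose(f[18:20],
                                   -params.k_m * 0.03 / params.tau_m)

    def test_condition_inputs_shapes(self, p11):
        ins = condition_inputs(p11, COND)
        assert ins["i_per"].tolist() == [p11.s_lip, p11.s_lip, 0.0,
                                         p11.s_lip, p11.s_lip, 0.0]
        assert ins["i_tar"][LIP_UNITS.index("R1")] == p11.s_tar
        assert ins["i_tar"].sum() == p11.s_tar
        assert ins["i_ori"].tolist() == [0.0, p11.s_ori]
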