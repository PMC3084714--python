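"""Orientation-vector tests: cell geometry, steady/dynamic vectors, maps, sweeps."""

import math

import numpy as np
import pytest

import chemonav as cn
from chemonav.orientation import (
    CellGeometry,
    ligand_orientation_steady,
    net_orientation_steady,
    orientation_from_states,
    orientation_map,
    sweep_orientation,
    unit_positions,
)


class TestGeometry:
    def test_four_units_on_axes(self):
        pts = unit_positions((0.0, 0.0), CellGeometry())
        np.testing.assert_array_equal(
            pts, [[5.0, 0.0], [0.0, 5.0], [-5.0, 0.0], [0.0, -5.0]]
        )

    def test_translation_equivariance(self):
        g = CellGeometry()
        np.testing.assert_allclose(
            unit_positions((100.0, 0.0), g),
            unit_positions((0.0, 0.0), g) + np.array([100.0, 0.0]),
        )

    def test_eight_units_spacing(self):
        pts = unit_positions((0.0, 0.0), CellGeometry(n_units=8))
        ang = np.arctan2(pts[:, 1], pts[:, 0])
        gaps = np.diff(np.unwrap(ang))
        np.testing.assert_allclose(gaps, np.pi / 4, atol=1e-12)
        np.testing.assert_allclose(np.hypot(pts[:, 0], pts[:, 1]), 5.0)

    def test_invalid_geometry(self):
        with pytest.raises(cn.ParameterError):
            CellGeometry(n_units=6)
        with pytest.raises(cn.ParameterError):
            CellGeometry(n_units=2)
        with pytest.raises(cn.ParameterError):
            CellGeometry(unit_radius=0.0)


class TestSteadyOrientation:
    def test_symmetric_position_zero_vector(self, single_env, desens):
        v = ligand_orientation_steady((0.0, 0.0), single_env, "L", desens)
        assert v.magnitude == pytest.approx(0.0, abs=1e-12)

    def test_points_up_gradient_with_closed_form_oracle(self, single_env, desens):
        # cell on the +x axis at rho = 800: the source is in the -x direction
        v = ligand_orientation_steady((800.0, 0.0), single_env, "L", desens)
        assert v.vy == pytest.approx(0.0, abs=1e-12)
        assert v.vx < 0
        # independent per-unit oracle from the closed-form steady state
        def lr(rho):
            L = 17.6 * (1 - rho / 1000.0) ** 3 if rho < 1000 else 0.0
            return cn.steady_state(L, desens).LR_act

        assert v.vx == pytest.approx(lr(805.0) - lr(795.0), rel=1e-12)
        vy_expected = lr(math.hypot(800.0, 5.0)) - lr(math.hypot(800.0, 5.0))
        assert vy_expected == 0.0

    @pytest.mark.parametrize("n_units", [36, 72])
    @pytest.mark.parametrize("rho", [600.0, 800.0, 900.0])
    def test_fine_unit_agreement(self, single_env, desens, n_units, rho):
        # 4-unit magnitude within 0.03% of the 36-/72-unit generalization
        m4 = ligand_orientation_steady((rho, 0.0), single_env, "L", desens).magnitude
        mn = ligand_orientation_steady(
            (rho, 0.0), single_env, "L", desens, CellGeometry(n_units=n_units)
        ).magnitude
        assert abs(mn - m4) / m4 * 100.0 <= 0.03

    def test_mirror_symmetry(self, desens):
        env = cn.LigandEnvironment([cn.PowerGradientField("L", center=(100.0, 250.0))])
        env_m = cn.LigandEnvironment([cn.PowerGradientField("L", center=(100.0, -250.0))])
        v = ligand_orientation_steady((400.0, 300.0), env, "L", desens)
        vm = ligand_orientation_steady((400.0, -300.0), env_m, "L", desens)
        assert vm.vx == pytest.approx(v.vx, rel=1e-12)
        assert vm.vy == pytest.approx(-v.vy, rel=1e-12)

    def test_rotational_equivariance_90deg(self, desens):
        env = cn.LigandEnvironment([cn.PowerGradientField("L", center=(300.0, 0.0))])
        env_r = cn.LigandEnvironment([cn.PowerGradientField("L", center=(0.0, 300.0))])
        v = ligand_orientation_steady((800.0, 100.0), env, "L", desens)
        vr = ligand_orientation_steady((-100.0, 800.0), env_r, "L", desens)
        assert vr.vx == pytest.approx(-v.vy, rel=1e-12, abs=1e-12)
        assert vr.vy == pytest.approx(v.vx, rel=1e-12, abs=1e-12)


class TestNetOrientation:
    def test_singleton_equals_per_ligand(self, single_env, desens):
        pos = (700.0, 50.0)
        v1 = ligand_orientation_steady(pos, single_env, "L", desens)
        v = net_orientation_steady(pos, single_env, {"L": desens})
        assert (v.vx, v.vy) == (v1.vx, v1.vy)

    def test_opposing_midpoint_cancels(self, desens):
        env = cn.LigandEnvironment(
            [
                cn.PowerGradientField("L1", center=(-700.0, 0.0)),
                cn.PowerGradientField("L2", center=(+700.0, 0.0)),
            ]
        )
        v = net_orientation_steady((0.0, 0.0), env, {"L1": desens, "L2": desens})
        assert v.magnitude == pytest.approx(0.0, abs=1e-12)

    def test_missing_params_raises(self, desens):
        env = cn.LigandEnvironment(
            [cn.PowerGradientField("L1"), cn.PowerGradientField("L2")]
        )
        with pytest.raises(cn.ConfigurationError):
            net_orientation_steady((0.0, 0.0), env, {"L1": desens})

    def test_opposing_preset_signs(self):
        # inside the overlap band on the L1 side: desensitizable receptors
        # orient toward the distant source L2, nondesensitizable toward the
        # local source L1, mixed toward the nondesensitizing ligand L1
        scd = cn.build_scenario("opposing_desens")
        scn = cn.build_scenario("opposing_nondesens")
        scm = cn.build_scenario("opposing_mixed")
        pos = (-160.0, 0.0)
        assert net_orientation_steady(pos, scd.env, scd.params_by_ligand).vx > 0
        assert net_orientation_steady(pos, scn.env, scn.params_by_ligand).vx < 0
        assert net_orientation_steady(pos, scm.env, scm.params_by_ligand).vx < 0


class TestOrientationFromStates:
    def test_equal_states_zero(self, desens):
        s = cn.steady_state(1.0, desens)
        v = orientation_from_states({"L": [s, s, s, s]})
        assert v.magnitude == 0.0

    def test_hand_built_difference(self):
        states = np.zeros((4, 4))
        states[:, 1] = [30.0, 0.0, 10.0, 0.0]  # LR* on (+x, +y, -x, -y)
        v = orientation_from_states({"L": states})
        assert (v.vx, v.vy) == (20.0, 0.0)

    def test_consistency_with_steady_variant(self, single_env, desens):
        pos = (750.0, 120.0)
        pts = unit_positions(pos, CellGeometry())
        states = [
            cn.steady_state(single_env.ligand_concentration("L", p), desens) for p in pts
        ]
        v = orientation_from_states({"L": states})
        vs = ligand_orientation_steady(pos, single_env, "L", desens)
        assert v.vx == pytest.approx(vs.vx, rel=1e-12, abs=1e-12)
        assert v.vy == pytest.approx(vs.vy, rel=1e-12, abs=1e-12)

    def test_length_mismatch(self, desens):
        with pytest.raises(cn.ConfigurationError):
            orientation_from_states({"L": [cn.steady_state(1.0, desens)] * 3})


class TestOrientationMap:
    def test_outside_supports_all_undirected(self, single_env, desens):
        df = orientation_map(
            single_env, {"L": desens}, bbox=(2000.0, 2000.0, 2500.0, 2500.0), step=100.0
        )
        assert not df["directed"].any()
        assert (df[["vx", "vy"]].to_numpy() == 0).all()

    def test_desens_band_and_inner_random_zone(self, single_env, desens):
        df = orientation_map(
            single_env, {"L": desens}, bbox=(0.0, 0.0, 1000.0, 0.0), step=10.0
        )
        rho = df["x_um"]
        assert df.loc[(rho > 770) & (rho < 900), "directed"].all()
        assert not df.loc[rho < 700, "directed"].any()

    def test_nondesens_directed_region_contains_desens(self, single_env, desens, nondesens):
        kw = dict(bbox=(-1000.0, -1000.0, 1000.0, 1000.0), step=100.0)
        dd = orientation_map(single_env, {"L": desens}, **kw)["directed"]
        dn = orientation_map(single_env, {"L": nondesens}, **kw)["directed"]
        assert (dn | ~dd).all()        # superset on the same grid
        assert dn.sum() > dd.sum() > 0  # strictly larger, both non-empty


class TestSweep:
    def test_single_value_matches_net(self, single_env, desens):
        df = sweep_orientation("k_des", [0.065], [(800.0, 0.0)], single_env, {"L": desens})
        assert len(df) == 1
        v = net_orientation_steady((800.0, 0.0), single_env, {"L": desens})
        # component toward the source at the origin is -vx for a +x position
        assert df["component"].iloc[0] == pytest.approx(-v.vx, rel=1e-12)

    def test_unknown_parameter(self, single_env, desens):
        with pytest.raises(cn.ParameterError):
            sweep_orientation("k_q", [0.1], [(800.0, 0.0)], single_env, {"L": desens})

    def test_kdes1_only_touches_first_ligand(self):
        sc = cn.build_scenario("opposing_desens")
        df0 = sweep_orientation(
            "k_des1", [0.065], [(-160.0, 0.0)], sc.env, sc.params_by_ligand
        )
        base = sweep_orientation(
            "k_des", [0.065], [(-160.0, 0.0)], sc.env, sc.params_by_ligand
        )
        assert df0["component"].iloc[0] == pytest.approx(base["component"].iloc[0])
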