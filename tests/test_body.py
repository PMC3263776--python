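import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from endurosim.body import (
    BLOOD_NODE,
    BRAIN,
    N_TISSUE,
    SKIN_NODES,
    BodyModel,
    BodyParams,
    BodyState,
    ControllerParams,
    EffectorSignals,
    Environment,
    blood_convection,
    conduction_flow,
    controller_step,
    load_default_model,
    node_index,
    skin_exchange,
)


class TestConduction:
    def test_equal_temperatures_no_flow(self):
        assert conduction_flow(37.0, 37.0, 5.0) == 0.0

    def test_hand_value(self):
        assert conduction_flow(38.5, 37.0, 2.0) == pytest.approx(3.0)

    @given(a=st.floats(25, 45), b=st.floats(25, 45), tc=st.floats(0, 50))
    def test_antisymmetry(self, a, b, tc):
        assert conduction_flow(a, b, tc) == pytest.approx(-conduction_flow(b, a, tc))

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            conduction_flow(37.0, 36.0, -1.0)


class TestBloodConvection:
    def test_no_flow_no_exchange(self):
        assert blood_convection(38.0, 37.0, 0.0) == 0.0

    def test_hand_value(self):
        # 1 l/min at a 1 K gradient: 3850/60 W
        assert blood_convection(38.0, 37.0, 1 / 60, 3850.0) == pytest.approx(64.2, abs=0.1)

    def test_perfusion_conserves_energy(self, body_model):
        """Summed tissue-to-blood exchanges equal the blood node's gain."""
        T = body_model.set_points + np.linspace(-1, 1, 25)
        dT, aux = body_model.derivative(T, body_model.thermoneutral)
        bf = aux["blood_flow_l_per_s"]
        bc = bf * body_model.params.blood_heat_capacity_J_per_l_K * (T[:N_TISSUE] - T[BLOOD_NODE])
        blood_gain = dT[BLOOD_NODE] * body_model.params.C_blood_node_J_per_K
        assert blood_gain == pytest.approx(bc.sum(), rel=1e-9)


class TestSkinExchange:
    def test_equilibrium_leaves_only_basal_diffusion(self):
        env = Environment(33.0, 33.0, 0.40, 0.1)
        rad, conv, evap = skin_exchange(33.0, env, 1.0, 0.0)
        assert rad == 0.0 and conv == 0.0
        assert evap > 0.0  # insensible diffusion

    def test_saturated_air_at_skin_temperature_blocks_evaporation(self):
        env = Environment(34.0, 34.0, 1.0, 0.1)
        _, _, evap = skin_exchange(34.0, env, 1.0, 500.0)
        assert evap == 0.0

    def test_wind_increases_convective_loss(self):
        env1 = Environment(25.0, 25.0, 0.4, 1.0)
        env2 = Environment(25.0, 25.0, 0.4, 2.0)
        _, c1, _ = skin_exchange(34.0, env1, 1.0, 0.0)
        _, c2, _ = skin_exchange(34.0, env2, 1.0, 0.0)
        assert c2 > c1

    def test_humidity_bounds_enforced(self):
        with pytest.raises(ValueError):
            Environment(relative_humidity=1.2)


class TestController:
    params = ControllerParams(ref_brain_C=37.0, ref_skin_mean_C=34.0)

    def test_zero_at_reference(self):
        eff = controller_step(37.0, 34.0, self.params)
        assert eff == EffectorSignals(0.0, 0.0, 0.0, 0.0)

    def test_warm_brain_drives_sweat_not_shiver(self):
        eff = controller_step(38.0, 34.0, self.params)
        assert eff.sweat_command_W > 0 and eff.vasodilation > 0
        assert eff.shiver_heat_W == 0

    def test_cold_brain_drives_shiver_not_sweat(self):
        eff = controller_step(36.0, 33.0, self.params)
        assert eff.shiver_heat_W > 0 and eff.vasoconstriction > 0
        assert eff.sweat_command_W == 0

    @given(eps=st.floats(1e-6, 0.01))
    def test_continuity_at_reference(self, eps):
        """Signals vanish continuously approaching the set point."""
        for db, ds in ((eps, 0), (-eps, 0), (0, eps), (0, -eps)):
            eff = controller_step(37.0 + db, 34.0 + ds, self.params)
            biggest = max(eff.sweat_command_W, eff.vasodilation,
                          eff.vasoconstriction, eff.shiver_heat_W)
            assert biggest <= 400 * eps


def _isolated_two_node_model():
    """A body where only trunk core<->muscle are coupled, by conduction."""
    order = [(s, l) for s in ("head", "trunk", "arms", "hands", "legs", "feet")
             for l in ("core", "muscle", "fat", "skin")]
    rows = []
    for seg, layer in order:
        rows.append({
            "segment": seg, "layer": layer, "mass_kg": 1.0,
            "C_J_per_degC": 40000.0 if (seg, layer) == ("trunk", "core") else
                            20000.0 if (seg, layer) == ("trunk", "muscle") else 3500.0,
            "QB_W": 0.0, "BF_basal_l_per_s": 0.0,
            "TC_out_W_per_degC": 2.0 if (seg, layer) == ("trunk", "core") else 0.0,
            "area_m2": 0.3 if layer == "skin" else 0.0,
        })
    params = BodyParams.from_table(pd.DataFrame(rows))
    model = BodyModel(params)
    T0 = np.full(25, 30.0)
    model._set_points = T0.copy()
    model._controller = ControllerParams(
        ref_brain_C=30.0, ref_skin_mean_C=30.0,
        sweat_brain_W_per_K=0, sweat_skin_W_per_K=0, dilation_brain_per_K=0,
        dilation_skin_per_K=0, constrict_brain_per_K=0, constrict_skin_per_K=0,
        shiver_product_W_per_K2=0,
    )
    return model, T0


class TestTwoNodeAnalyticOracle:
    def test_conductive_relaxation_matches_closed_form(self):
        """Two nodes coupled only by conduction relax as one exponential with
        rate TC (1/C1 + 1/C2); the trajectory must match to 0.1 %."""
        model, T0 = _isolated_two_node_model()
        i, j = node_index("trunk", "core"), node_index("trunk", "muscle")
        C1, C2, TC = 40000.0, 20000.0, 2.0
        T0[i], T0[j] = 39.0, 33.0
        env = Environment(30.0, 30.0, 1.0, 0.0)  # saturated, still, isothermal
        traj = model.integrate(BodyState(T0.copy()), 3600.0, env, sample_dt_s=60.0)
        rate = TC * (1 / C1 + 1 / C2)
        T_eq = (C1 * 39.0 + C2 * 33.0) / (C1 + C2)
        for k, t in enumerate(traj.time_s):
            delta = (39.0 - 33.0) * np.exp(-rate * t)
            expect_i = T_eq + delta * C2 / (C1 + C2)
            expect_j = T_eq - delta * C1 / (C1 + C2)
            assert abs(traj.states[k, i] - expect_i) / 6.0 < 1e-3
            assert abs(traj.states[k, j] - expect_j) / 6.0 < 1e-3

    def test_uncoupled_nodes_stay_put(self):
        model, T0 = _isolated_two_node_model()
        env = Environment(30.0, 30.0, 1.0, 0.0)
        traj = model.integrate(BodyState(T0.copy()), 600.0, env, sample_dt_s=100.0)
        np.testing.assert_allclose(traj.states[-1], T0, atol=1e-6)


class TestDefaultModel:
    def test_parameter_table_magnitudes(self, body_model):
        p = body_model.params
        assert p.mass_kg[node_index("head", "core")] == pytest.approx(3.0)
        assert p.mass_kg[node_index("legs", "muscle")] == pytest.approx(10.0, rel=0.05)
        assert p.area_m2[SKIN_NODES].sum() == pytest.approx(1.89, rel=0.02)

    def test_set_points_are_physiological(self, body_model):
        sp = body_model.set_points
        assert 36.8 < sp[BRAIN] < 37.6
        assert 33.0 < body_model.mean_skin_C(sp) < 34.2

    def test_thermoneutral_rest_is_stationary(self, body_model):
        """At the reference state, node temperatures drift < 0.02 degC/min."""
        dT, _ = body_model.derivative(body_model.set_points, body_model.thermoneutral)
        assert np.max(np.abs(dT)) * 60.0 < 0.02

    def test_first_law_bookkeeping(self, body_model):
        """Sum of C dT/dt equals production minus external losses."""
        T = body_model.set_points + np.linspace(-0.5, 0.5, 25)
        dT, aux = body_model.derivative(T, Environment(20.0, 20.0, 0.4, 1.0))
        C = np.append(body_model.params.C_J_per_K, body_model.params.C_blood_node_J_per_K)
        assert float(C @ dT) == pytest.approx(aux["production_W"] - aux["loss_W"], rel=1e-9)

    def test_energy_ledger_closes_over_a_transient(self, body_model):
        traj = body_model.integrate(
            BodyState(body_model.set_points.copy()), 1800.0,
            Environment(40.0, 40.0, 0.3, 0.5), sample_dt_s=30.0)
        assert abs(traj.ledger()["relative_residual"]) < 0.01

    def test_segment_duplication_symmetry(self):
        """Giving arms exactly the legs' parameters yields identical
        temperature trajectories for the two segments."""
        import importlib.resources
        from pathlib import Path

        table = pd.read_csv(
            Path(importlib.resources.files("endurosim") / "data" / "body_nodes.tsv"), sep="\t")
        legs = table[table.segment == "legs"].set_index("layer")
        for layer in ("core", "muscle", "fat", "skin"):
            for col in table.columns[2:]:
                table.loc[(table.segment == "arms") & (table.layer == layer), col] = \
                    legs.loc[layer, col]
        params = BodyParams.from_table(table)
        dist = {k: [0.07, 0.33, 0.16, 0.05, 0.16, 0.23] for k in
                ("skin_sensor_weight", "sweat_fraction", "dilation_fraction",
                 "constrict_fraction")}
        dist["shiver_fraction"] = [0.02, 0.80, 0.08, 0.0, 0.08, 0.02]
        model = BodyModel(params, distribution=dist)
        sp = model.set_points
        arms = slice(node_index("arms", "core"), node_index("arms", "skin") + 1)
        legs_sl = slice(node_index("legs", "core"), node_index("legs", "skin") + 1)
        np.testing.assert_allclose(sp[arms], sp[legs_sl], rtol=1e-8)
        traj = model.integrate(BodyState(sp.copy()), 1200.0,
                               Environment(42.0, 42.0, 0.3, 0.5), sample_dt_s=120.0)
        np.testing.assert_allclose(traj.states[:, arms], traj.states[:, legs_sl], rtol=1e-6)

    def test_guard_band_warns_not_clips(self):
        state = BodyState(np.full(25, 46.0))
        with pytest.warns(Warning, match="25-45"):
            state.check_physiological()
        assert state.T_C[0] == 46.0

    def test_rescaling_preserves_structure(self, body_model):
        small = body_model.params.scaled_to(60.0, 1.70)
        ratio = small.mass_kg.sum() / body_model.params.mass_kg.sum()
        assert ratio == pytest.approx(60.0 / 74.0)
        assert (small.area_m2[SKIN_NODES] > 0).all()

    def test_zero_mass_rejected(self, body_model):
        import dataclasses

        bad = body_model.params.mass_kg.copy()
        bad[0] = 0.0
        with pytest.raises(ValueError):
            dataclasses.replace(body_model.params, mass_kg=bad)
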