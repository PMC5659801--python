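"""Structure and dynamics of the trafficking ODE models."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eportraffic.model import (
    BleachModel,
    CellParameters,
    ChxModel,
    ModelVariant,
    StimulusProtocol,
    enumerate_variants,
    prestimulus_steady_state,
    receptor_steady_state,
    reduced_model,
    rhs,
    simulate,
    system_matrices,
)

rate = st.floats(min_value=1e-4, max_value=10.0)
conc = st.floats(min_value=0.0, max_value=100.0)


def params_for(variant: ModelVariant, value: float = 1.0, **overrides) -> CellParameters:
    values = {name: value for name in variant.kinetic_param_names}
    values.update(overrides)
    return CellParameters.for_variant(variant, values)


class TestVariants:
    def test_sixteen_distinct_variants(self):
        variants = enumerate_variants()
        assert len(variants) == 16
        assert len({v.name for v in variants}) == 16

    def test_names_determine_flags(self):
        for v in enumerate_variants():
            assert ModelVariant.from_name(v.name) == v

    @pytest.mark.parametrize(
        "name,n_kinetic", [("", 7), ("A", 8), ("AC", 9), ("ACD", 10), ("ABCD", 11)]
    )
    def test_kinetic_parameter_counts(self, name, n_kinetic):
        assert ModelVariant.from_name(name).n_kinetic == n_kinetic

    def test_every_variant_has_six_state_equations(self):
        state = np.ones(6)
        for v in enumerate_variants():
            assert rhs(v, params_for(v), state, epo=1.0).shape == (6,)

    def test_invalid_name_rejected(self):
        with pytest.raises(ValueError):
            ModelVariant.from_name("AA")
        with pytest.raises(ValueError):
            ModelVariant.from_name("X")


class TestParameters:
    def test_excluded_parameter_raises(self, acd):
        values = {n: 1.0 for n in acd.kinetic_param_names}
        values["k_REtoI"] = 1.0  # part B absent from ACD
        with pytest.raises(ValueError, match="k_REtoI"):
            CellParameters.for_variant(acd, values)

    def test_missing_parameter_raises(self, acd):
        values = {n: 1.0 for n in acd.kinetic_param_names}
        values.pop("k_REtoM")
        with pytest.raises(ValueError):
            CellParameters.for_variant(acd, values)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            CellParameters(k_on=0.1, k_off=-0.1, k_syn=1, k_deg=1,
                           k_ItoM=1, k_MtoI=1, k_MtoRE=1)


class TestRhs:
    def test_no_ligand_no_complexes_reduces_to_turnover(self, acd):
        p = params_for(acd)
        state = np.array([2.0, 3.0, 0.0, 0.0, 0.0, 0.0])
        d = rhs(acd, p, state, epo=0.0)
        assert d[2] == d[3] == d[4] == d[5] == 0.0
        assert d[0] == pytest.approx(1 - 2 - 2 + 3)   # syn - deg - ItoM + MtoI
        assert d[1] == pytest.approx(2 - 3)

    def test_hand_evaluated_acd_unit_case(self, acd):
        # all rates one, unit state, epo = 1
        d = rhs(acd, params_for(acd), np.ones(6), epo=1.0)
        np.testing.assert_allclose(d, [0.0, 1.0, -1.0, -2.0, 1.0, 1.0])

    @settings(max_examples=50, deadline=None)
    @given(
        name=st.sampled_from([v.name for v in enumerate_variants()]),
        values=st.lists(rate, min_size=11, max_size=11),
        state=st.lists(conc, min_size=6, max_size=6),
        epo=conc,
    )
    def test_receptor_mass_balance_identity(self, name, values, state, epo):
        """d/dt of total receptor equals synthesis minus the degradation fluxes."""
        v = ModelVariant.from_name(name)
        p = CellParameters.for_variant(
            v, dict(zip(v.kinetic_param_names, values))
        )
        state = np.asarray(state)
        d = rhs(v, p, state, epo)
        expected = p.k_syn - p.k_deg * state[0]
        if v.has_C:
            expected -= p.k_deg_REtoEx * state[3]
        if v.has_D:
            expected -= p.k_deg_REtoI * state[3]
        assert d[:4].sum() == pytest.approx(expected, rel=1e-9, abs=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(
        name=st.sampled_from([v.name for v in enumerate_variants()]),
        values=st.lists(rate, min_size=11, max_size=11),
        state=st.lists(conc, min_size=6, max_size=6),
        epo=conc,
    )
    def test_internalized_label_bookkeeping_identity(self, name, values, state, epo):
        """Endosomal pool + degraded-ligand pools + intact release balance endocytosis."""
        v = ModelVariant.from_name(name)
        p = CellParameters.for_variant(v, dict(zip(v.kinetic_param_names, values)))
        state = np.asarray(state)
        d = rhs(v, p, state, epo)
        release_A = (p.k_REtoM or 0.0) * state[3] if v.has_A else 0.0
        assert d[3] + d[4] + d[5] + release_A == pytest.approx(
            p.k_MtoRE * state[2], rel=1e-9, abs=1e-9
        )


class TestSteadyState:
    def test_prestimulus_values(self):
        v = ModelVariant()
        p = params_for(v, k_syn=1.0, k_deg=0.1, k_ItoM=0.1, k_MtoI=1.0)
        epor_i, epor_m = prestimulus_steady_state(p)
        assert epor_i == pytest.approx(10.0)
        assert epor_m == pytest.approx(1.0)

    def test_no_synthesis_empty_steady_state(self):
        p = params_for(ModelVariant(), k_syn=0.0, k_deg=0.1, k_ItoM=0.1, k_MtoI=1.0)
        assert prestimulus_steady_state(p) == (0.0, 0.0)

    def test_symmetric_exchange_half_membrane_fraction(self):
        p = params_for(ModelVariant(), k_syn=1.0, k_deg=0.5, k_ItoM=0.3, k_MtoI=0.3)
        epor_i, epor_m = prestimulus_steady_state(p)
        assert epor_m / (epor_m + epor_i) == pytest.approx(0.5)

    def test_zero_divisor_raises(self):
        p = params_for(ModelVariant(), k_deg=0.0)
        with pytest.raises(ZeroDivisionError):
            prestimulus_steady_state(p)

    def test_linear_solve_matches_long_integration(self, acd, median_params):
        """Stimulated steady state: direct solve vs long-time integration."""
        ss = receptor_steady_state(acd, median_params, epo=4.2)
        protocol = StimulusProtocol("epo", (0.0, 50000.0), epo_conc=4.2)
        traj = simulate(acd, median_params, protocol, method="lsoda",
                        rtol=1e-11, atol=1e-13)
        np.testing.assert_allclose(traj[-1, :4], ss, rtol=1e-8)


class TestSimulate:
    def test_two_state_exchange_matches_closed_form(self):
        """Basic variant, no ligand, no turnover: analytic 2x2 solution."""
        v = ModelVariant()
        a, b = 0.3, 0.7  # k_ItoM, k_MtoI
        p = params_for(v, k_syn=0.0, k_deg=0.0, k_ItoM=a, k_MtoI=b)
        x0 = np.array([5.0, 1.0, 0, 0, 0, 0])
        times = (0.0, 1.0, 5.0, 20.0)
        traj = simulate(v, p, StimulusProtocol("epo", times, epo_conc=0.0), init=x0)
        total = x0[0] + x0[1]
        for t, row in zip(times, traj):
            # eigen-decomposition of the exchange: relaxation rate a+b
            m_ss = total * a / (a + b)
            m_t = m_ss + (x0[1] - m_ss) * np.exp(-(a + b) * t)
            assert row[1] == pytest.approx(m_t, rel=1e-10)
            assert row[0] == pytest.approx(total - m_t, rel=1e-10)

    def test_no_binding_no_complexes(self, acd, median_params):
        values = median_params.as_dict(acd)
        values["k_on"] = 0.0
        p = CellParameters.for_variant(acd, values)
        protocol = StimulusProtocol("epo", tuple(np.arange(0.0, 100.0, 10.0)),
                                    epo_conc=4.2)
        traj = simulate(acd, p, protocol)
        np.testing.assert_allclose(traj[:, 2:], 0.0, atol=1e-12)

    def test_steady_state_is_fixed_point_without_ligand(self, acd, median_params):
        protocol = StimulusProtocol("epo", (0.0, 10.0, 100.0, 500.0), epo_conc=0.0)
        traj = simulate(acd, median_params, protocol)
        np.testing.assert_allclose(
            traj, np.tile(traj[0], (len(traj), 1)), rtol=1e-9, atol=1e-12
        )

    def test_expm_and_lsoda_agree(self, acd, median_params):
        protocol = StimulusProtocol(
            "epo", tuple(np.arange(0.0, 301.0, 20.0)), epo_conc=4.2
        )
        t1 = simulate(acd, median_params, protocol, method="expm")
        t2 = simulate(acd, median_params, protocol, method="lsoda",
                      rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(t1, t2, rtol=1e-6, atol=1e-9)

    def test_nonnegativity_and_monotone_cumulative_states(self, acd, median_params):
        protocol = StimulusProtocol(
            "epo", tuple(np.arange(0.0, 301.0, 5.0)), epo_conc=4.2
        )
        traj = simulate(acd, median_params, protocol)
        assert (traj >= -1e-12).all()
        assert (np.diff(traj[:, 4]) >= -1e-12).all()  # Epo_deg_i nondecreasing
        assert (np.diff(traj[:, 5]) >= -1e-12).all()  # Epo_deg_ext nondecreasing

    def test_negative_init_rejected(self, acd, median_params):
        protocol = StimulusProtocol("epo", (0.0, 10.0), epo_conc=4.2)
        with pytest.raises(ValueError):
            simulate(acd, median_params, protocol, init=[-1, 0, 0, 0, 0, 0])


class TestReducedModels:
    def test_bleach_model_counts(self):
        m = reduced_model("bleach")
        assert isinstance(m, BleachModel)
        assert m.n_states == 3
        assert len(m.kinetic_param_names) == 5

    def test_chx_model_counts(self):
        m = reduced_model("chx")
        assert isinstance(m, ChxModel)
        assert m.n_states == 3
        assert len(m.kinetic_param_names) == 3

    def test_unknown_condition(self):
        with pytest.raises(ValueError):
            reduced_model("epo")

    def test_zero_bleach_rate_is_null_perturbation(self):
        times = tuple(np.arange(0.0, 61.0, 5.0))
        protocol = StimulusProtocol("bleach", times)
        kin = dict(k_syn=0.4, k_deg=0.01, k_ItoM=0.011, k_MtoI=0.14)
        init = [kin["k_syn"] / kin["k_deg"],
                kin["k_ItoM"] / kin["k_MtoI"] * kin["k_syn"] / kin["k_deg"], 0.0]
        with_pulse = reduced_model("bleach").simulate({**kin, "k_bleach": 0.0},
                                                      protocol, init)
        # at the ligand-free steady state with no bleaching, nothing moves
        np.testing.assert_allclose(with_pulse[:, :2], [init[:2]] * len(times),
                                   rtol=1e-9)
        np.testing.assert_allclose(with_pulse[:, 2], 0.0, atol=1e-12)

    def test_bleach_pulse_depletes_fluorescent_pools(self):
        times = tuple(np.arange(0.0, 61.0, 5.0))
        protocol = StimulusProtocol("bleach", times, bleach_start=5.0,
                                    bleach_duration=0.5)
        kin = dict(k_syn=0.4, k_deg=0.01, k_ItoM=0.011, k_MtoI=0.14, k_bleach=3.0)
        init = [40.0, 3.0, 0.0]
        traj = reduced_model("bleach").simulate(kin, protocol, init)
        i_after = list(times).index(10.0)
        assert traj[i_after, 0] < 0.3 * init[0]       # ~78 % bleached
        assert traj[i_after, 2] > 0.7 * sum(init[:2])  # moved to the dark pool
        assert traj[-1, 0] > traj[i_after, 0]          # replenished by synthesis

    def test_chx_decay_without_synthesis(self):
        times = tuple(np.arange(0.0, 301.0, 30.0))
        protocol = StimulusProtocol("chx", times, chx_time=0.0)
        kin = dict(k_deg=0.01, k_ItoM=0.011, k_MtoI=0.14)
        init = [40.0, 3.0, 0.0]
        traj = reduced_model("chx").simulate(kin, protocol, init)
        total = traj[:, 0] + traj[:, 1]
        assert (np.diff(total) < 0).all()
        # degraded pool accounts for all lost receptor
        np.testing.assert_allclose(total + traj[:, 2], sum(init[:2]), rtol=1e-9)
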