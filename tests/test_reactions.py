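"""Reaction network construction, propensities and the exact simulator."""

import numpy as np
import pytest

from mazsim import (KineticParams, OperatorState, StressMode, StressProtocol,
                    apply_cleavage_outcome, build_network, propensities,
                    simulate_cell)
from mazsim.errors import MazsimError, ParameterError, StateError
from mazsim.reactions import SpeciesState

from conftest import linear_ode_means


class TestBuildNetwork:
    def test_no_cleavage_network_has_no_toxin_catalysed_mrna_loss(self, params):
        net = build_network(params, include_cleavage=False)
        assert all(not r.name.startswith("cleave") for r in net)

    def test_cleavage_adds_exactly_the_cleavage_channels(self, params):
        with_c = build_network(params, include_cleavage=True)
        without = build_network(params, include_cleavage=False)
        extra = [r.name for r in with_c][len(without):]
        assert [r.name for r in with_c][:len(without)] == [r.name for r in without]
        assert set(extra) == {"cleave_F_mEF", "cleave_E_mEF", "cleave_E_mE",
                              "cleave_F_mect"}

    def test_full_length_transcript_has_two_cleavage_channels_with_site_ratio(
            self, params, no_stress):
        net = build_network(params, include_cleavage=True)
        state = SpeciesState(m_EF=4, T=10)
        a = dict(zip(net.names(), net.propensities(state, 0.0, no_stress)))
        assert a["cleave_F_mEF"] / a["cleave_E_mEF"] == pytest.approx(
            params.w_F / params.w_E)
        assert a["cleave_F_mEF"] / a["cleave_E_mEF"] == pytest.approx(4.5)

    def test_antitoxin_must_be_less_stable_than_toxin(self):
        with pytest.raises(ParameterError, match="delta_A"):
            build_network(KineticParams(delta_A=0.001, delta_T=0.01))

    @pytest.mark.parametrize("field,value", [
        ("k_tx", -1.0), ("alpha_OC", 1.5), ("w_E", 0.0), ("kon", -0.1),
    ])
    def test_invalid_parameters_name_the_offending_field(self, field, value):
        with pytest.raises(ParameterError, match=field):
            build_network(KineticParams(**{field: value}))


class TestPropensities:
    def test_empty_cell_only_transcribes(self, params, no_stress):
        a = propensities(SpeciesState(), params, 0.0, no_stress)
        net = build_network(params)
        nonzero = [n for n, x in zip(net.names(), a) if x > 0]
        assert nonzero == ["transcribe_mEF"]

    def test_stress_scales_antitoxin_degradation_threefold(self, params):
        proto = StressProtocol(mode=StressMode.ANTITOXIN_DEGRADATION,
                               multiplier=3.0, t_on=100.0, t_off=200.0)
        state = SpeciesState(A=7, C=3)
        net = build_network(params)
        a_out = dict(zip(net.names(), net.propensities(state, 50.0, proto)))
        a_in = dict(zip(net.names(), net.propensities(state, 150.0, proto)))
        assert a_in["degrade_A"] == pytest.approx(3.0 * a_out["degrade_A"])
        assert a_in["degrade_A_in_C"] == pytest.approx(3.0 * a_out["degrade_A_in_C"])

    def test_ectopic_transcription_only_inside_window(self, params):
        proto = StressProtocol(mode=StressMode.TOXIN_PRODUCTION,
                               t_on=100.0, t_off=200.0)
        net = build_network(params)
        s = SpeciesState()
        on = dict(zip(net.names(), net.propensities(s, 150.0, proto)))
        off = dict(zip(net.names(), net.propensities(s, 250.0, proto)))
        assert on["transcribe_ect"] == pytest.approx(params.beta_ect)
        assert off["transcribe_ect"] == 0.0

    def test_operator_state_gates_transcription(self, params, no_stress):
        net = build_network(params)
        for op, alpha in [(OperatorState.FREE, 1.0),
                          (OperatorState.O_A, params.alpha_OA),
                          (OperatorState.O_C, params.alpha_OC),
                          (OperatorState.O_CT, params.alpha_OCT)]:
            a = dict(zip(net.names(), net.propensities(
                SpeciesState(op_state=op), 0.0, no_stress)))
            assert a["transcribe_mEF"] == pytest.approx(params.k_tx * alpha)

    def test_negative_count_raises_state_error(self, params, no_stress):
        net = build_network(params)
        vec = SpeciesState().to_vector()
        vec[3] = -1
        with pytest.raises(StateError):
            net.propensity_vector(vec, 0.0, no_stress)


class TestCleavageOutcome:
    def test_toxin_region_cut_leaves_antitoxin_template(self):
        out = apply_cleavage_outcome(SpeciesState(m_EF=3, T=5), "F")
        assert (out.m_EF, out.m_E) == (2, 1)

    def test_antitoxin_region_cut_inactivates_transcript(self):
        out = apply_cleavage_outcome(SpeciesState(m_EF=1, m_E=2), "E")
        assert (out.m_EF, out.m_E) == (0, 2)

    @pytest.mark.parametrize("region", ["E", "F"])
    def test_toxin_is_catalytic(self, region):
        before = SpeciesState(m_EF=2, T=9, C=1)
        after = apply_cleavage_outcome(before, region)
        assert after.T == before.T and after.C == before.C

    def test_requires_a_transcript(self):
        with pytest.raises(StateError):
            apply_cleavage_outcome(SpeciesState(m_EF=0), "F")


class TestSpeciesState:
    def test_totals_count_operator_sequestered_molecules(self):
        s = SpeciesState(A=2, T=3, C=4, op_state=OperatorState.O_CT)
        assert s.total_toxin == 3 + 4 + 2
        assert s.total_antitoxin == 2 + 4 + 1

    def test_vector_roundtrip(self):
        s = SpeciesState(m_EF=1, m_E=2, m_ect=3, A=4, T=5, C=6,
                         op_state=OperatorState.O_C)
        assert SpeciesState.from_vector(s.to_vector()) == s


class TestSimulateCell:
    def test_all_rates_zero_keeps_state_constant(self, no_stress):
        p = KineticParams(k_tx=0, b_A=0, b_T=0, delta_A=0.1, delta_T=0,
                          delta_m=0, k_cleave=0, kon=0, koff=0, kb_A=0,
                          kb_C=0, kb_T2=0, ku_A=0, ku_C=0, ku_T2=0, beta_ect=0)
        init = SpeciesState(m_EF=2, T=3, op_state=OperatorState.O_C)
        traj = simulate_cell(init, p, no_stress, 100.0, seed=0)
        assert len(traj.times) == 1
        assert traj.final_state() == init

    def test_birth_death_long_run_mean(self, no_stress):
        # pure transcription/decay: stationary mean k_tx/delta_m = 10
        p = KineticParams(k_tx=2.0, delta_m=0.2, b_A=0, b_T=0, delta_A=0.01,
                          delta_T=0, k_cleave=0, kon=0, koff=0, kb_A=0,
                          kb_C=0, kb_T2=0, beta_ect=0)
        traj = simulate_cell(SpeciesState(), p, no_stress, 3000.0, seed=7)
        ts = np.arange(300.0, 3000.0, 1.0)
        m = traj.species("m_EF", ts)
        # samples are autocorrelated (relaxation time 1/delta_m = 5 min);
        # inflate the naive SE by the integrated autocorrelation factor
        n_eff = len(ts) / (2 * 5.0)
        se = np.sqrt(10.0 / n_eff)
        assert abs(m.mean() - 10.0) < 3 * se

    def test_identical_seed_reproduces_event_sequence(self, params, no_stress):
        init = SpeciesState(m_EF=1, A=5, C=2)
        t1 = simulate_cell(init, params, no_stress, 200.0, seed=42)
        t2 = simulate_cell(init, params, no_stress, 200.0, seed=42)
        assert np.array_equal(t1.times, t2.times)
        assert np.array_equal(t1.states, t2.states)

    def test_binding_unbinding_conserves_totals(self, no_stress):
        # only complexing and operator binding: totals are invariant
        p = KineticParams(k_tx=0, b_A=0, b_T=0, delta_A=1e-9, delta_T=0,
                          delta_m=0, k_cleave=0, kon=1.0, koff=0.5,
                          kb_A=0.5, ku_A=1.0, kb_C=0.5, ku_C=1.0,
                          kb_T2=0.5, ku_T2=2.0, beta_ect=0)
        init = SpeciesState(A=10, T=8)
        traj = simulate_cell(init, p, no_stress, 100.0, seed=3)
        for vec in traj.states:
            s = SpeciesState.from_vector(vec)
            assert s.total_toxin == 8
            assert s.total_antitoxin == 10

    def test_ensemble_means_match_linear_ode(self, linear_params, no_stress):
        t_end = 20.0
        m_exp, a_exp, t_exp = linear_ode_means(linear_params, t_end)
        finals = np.array([
            simulate_cell(SpeciesState(), linear_params, no_stress, t_end,
                          seed=s).final_state().to_vector()[:6]
            for s in range(300)])
        for idx, expect in ((0, m_exp), (3, a_exp), (4, t_exp)):
            mean = finals[:, idx].mean()
            se = finals[:, idx].std(ddof=1) / np.sqrt(len(finals))
            assert abs(mean - expect) < 3 * max(se, 1e-9)

    def test_trajectory_sampling_is_piecewise_constant(self, params, no_stress):
        traj = simulate_cell(SpeciesState(A=5), params, no_stress, 50.0, seed=1)
        mid = 0.5 * (traj.times[1] + traj.times[2]) if len(traj.times) > 2 else 1.0
        assert np.array_equal(traj.at(mid), traj.at(traj.times[1]))

    def test_invalid_horizon_rejected(self, params, no_stress):
        with pytest.raises(ParameterError):
            simulate_cell(SpeciesState(), params, no_stress, 0.0, seed=0)
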