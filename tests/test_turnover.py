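"""Membrane pools, insertion schedules and transient elimination."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import invadosim as iv
import invadosim.turnover as tv
from invadosim.kinetics import compile_network, integrate_rk4
from invadosim.network import build_core_network


class TestPulseInterval:
    def test_printed_pool_intervals(self):
        x = tv.pool_x()
        d = tv.pool_d()
        assert tv.pulse_interval(0.1 * x.M_F0, x.k_ins, x.M_F0) == \
            pytest.approx(25.9, rel=1e-12)
        assert tv.pulse_interval(0.1 * d.M_F0, d.k_ins, d.M_F0) == \
            pytest.approx(2.6, rel=1e-12)

    @given(ph=st.floats(1e-3, 1e3), k=st.floats(1e-6, 1.0),
           mf0=st.floats(1e-3, 1e3))
    def test_linear_in_single_insertion_amount(self, ph, k, mf0):
        t1 = tv.pulse_interval(ph, k, mf0)
        t2 = tv.pulse_interval(2 * ph, k, mf0)
        assert t2 == pytest.approx(2 * t1, rel=1e-9)

    @pytest.mark.parametrize("bad", [(0, 1, 1), (1, 0, 1), (1, 1, -2)])
    def test_nonpositive_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            tv.pulse_interval(*bad)


@pytest.fixture(scope="module")
def xd_model(params):
    net = build_core_network(params, pools="XD")
    net = tv.add_turnover(net, tv.default_pools())
    return compile_network(net)


class TestContinuousTurnover:
    def test_empty_membrane_insertion_flux(self, xd_model):
        y = np.zeros(xd_model.n_species)
        dy = xd_model.rhs(y)
        x = tv.pool_x()
        d = tv.pool_d()
        assert dy[xd_model.index["M14X"]] == pytest.approx(
            x.k_ins * x.M_F0)
        assert dy[xd_model.index["M14D"]] == pytest.approx(
            d.k_ins * d.M_F0)

    def test_saturated_pool_has_zero_insertion(self, xd_model, params):
        y = np.zeros(xd_model.n_species)
        y[xd_model.index["M14X"]] = tv.pool_x().M_F0
        dy = xd_model.rhs(y)
        # identical to a model with the insertion switched off entirely
        net0 = build_core_network(params, pools="XD")
        import dataclasses
        no_ins = tv.add_turnover(net0, [
            dataclasses.replace(tv.pool_x(), k_ins=0.0), tv.pool_d()])
        dy0 = compile_network(no_ins).rhs(y)
        np.testing.assert_allclose(dy, dy0, rtol=1e-12, atol=0)

    def test_occupancy_counts_m14_monomer_equivalents(self, xd_model):
        y = np.zeros(xd_model.n_species)
        y[xd_model.index["M14X.M14X"]] = tv.pool_x().M_F0 / 2  # dimers: full
        assert xd_model.pool_free_sites(y, "X") == pytest.approx(0.0)

    def test_pool_occupancy_fixed_point(self, params):
        # no TIMP-2/MMP-2: occupancy relaxes to M_F0 * k_ins/(k_ins + k_int)
        pool = tv.PoolConfig("X", 30.0, 1.0 / 259.0, 1.0 / 259.0)
        net = build_core_network(params, pools="XD")
        net = tv.add_turnover(net, [pool, tv.pool_d()])
        model = compile_network(net)
        traj = integrate_rk4(model, {}, 6 * 259.0, dt=0.05, record_every=10.0)
        occ = pool.M_F0 - model.pool_free_sites(traj.states[-1], "X")
        expect = pool.M_F0 * pool.k_ins / (pool.k_ins + pool.k_int)
        assert occ == pytest.approx(expect, rel=5e-3)

    def test_internalization_covers_every_membrane_species(self, params):
        net = build_core_network(params, include_ecm=True, pools="XD")
        rxns = tv.continuous_turnover_reactions(tv.pool_x(), net)
        internalized = {r.reactants[0] for r in rxns
                        if r.tag == "internalization"}
        membrane_x = {s.name for s in net.species
                      if s.location.value == "membrane_X"}
        assert internalized == membrane_x
        # ECM-engaged complexes release their ECM on internalization
        ecm_rxns = [r for r in rxns if r.tag == "internalization"
                    and r.reactants[0].endswith(".ECM")]
        assert ecm_rxns
        assert all(r.products == ("ECM",) for r in ecm_rxns)


class TestSchedules:
    def test_regular_schedule_pulse_counts(self):
        sched = tv.InsertionSchedule(mode="pulsatile")
        events = tv.generate_schedule(sched, tv.default_pools(), 51.8)
        x = [e for e in events if e.pool_id == "X"]
        d = [e for e in events if e.pool_id == "D"]
        assert [round(e.time, 6) for e in x] == [0.0, 25.9, 51.8]
        assert len(d) == 20
        assert all(e.amount == pytest.approx(3.0) for e in x)
        assert all(e.amount == pytest.approx(7.0) for e in d)

    def test_random_interval_mean_matches_regular(self):
        sched = tv.InsertionSchedule(mode="pulsatile", interval_mode="random",
                                     seed=11)
        events = tv.generate_schedule(sched, [tv.pool_x()], 25.9 * 1e5)
        times = np.array([e.time for e in events])
        waits = np.diff(np.sort(times))
        assert waits.mean() == pytest.approx(25.9, rel=0.01)

    def test_random_amount_mean_matches_regular(self):
        sched = tv.InsertionSchedule(mode="pulsatile", amount_mode="random",
                                     seed=7)
        events = tv.generate_schedule(sched, [tv.pool_d()], 2.6 * 2e4)
        amounts = np.array([e.amount for e in events])
        assert amounts.mean() == pytest.approx(7.0, rel=0.02)
        assert amounts.min() >= 0.0

    def test_same_seed_reproduces_schedule(self):
        sched = tv.InsertionSchedule(mode="pulsatile", interval_mode="random",
                                     amount_mode="random", seed=3)
        a = tv.generate_schedule(sched, tv.default_pools(), 500.0)
        b = tv.generate_schedule(sched, tv.default_pools(), 500.0)
        assert [(e.time, e.pool_id, e.amount) for e in a] == \
            [(e.time, e.pool_id, e.amount) for e in b]

    def test_random_mode_requires_seed(self):
        sched = tv.InsertionSchedule(mode="pulsatile", interval_mode="random")
        with pytest.raises(ValueError):
            tv.generate_schedule(sched, tv.default_pools(), 100.0)

    def test_fold_pair_preserves_time_average(self):
        pool = tv.pool_x()
        base = tv.InsertionSchedule(mode="pulsatile")
        scaled = tv.InsertionSchedule(mode="pulsatile", freq_fold=4.0,
                                      conc_fold=0.25)
        t1 = base.base_interval(pool) * 4.0
        assert scaled.base_interval(pool) * 4.0 == pytest.approx(
            base.base_interval(pool))
        assert scaled.pulse_amount(pool) * 4.0 == pytest.approx(
            base.pulse_amount(pool))
        del t1


class TestApplyPulse:
    def test_empty_pool_receives_full_amount(self, xd_model):
        y = np.zeros(xd_model.n_species)
        y2, applied = tv.apply_pulse(xd_model, y, "X", 3.0)
        assert applied == pytest.approx(3.0)
        assert y2[xd_model.index["M14X"]] == pytest.approx(3.0)

    def test_nearly_full_pool_scales_down_delivery(self, xd_model):
        # delivery scales with free sites: a 10%-capacity vesicle docks
        # 10% of the single free nM left on a 29/30 occupied pool
        y = np.zeros(xd_model.n_species)
        y[xd_model.index["M14X"]] = 29.0
        y2, applied = tv.apply_pulse(xd_model, y, "X", 3.0)
        assert applied == pytest.approx(0.1)
        assert y2[xd_model.index["M14X"]] == pytest.approx(29.1)

    def test_saturated_pool_receives_nothing(self, xd_model):
        y = np.zeros(xd_model.n_species)
        y[xd_model.index["M14X"]] = 30.0
        y2, applied = tv.apply_pulse(xd_model, y, "X", 100.0)
        assert applied == 0.0
        assert y2[xd_model.index["M14X"]] == pytest.approx(30.0)

    def test_oversized_vesicle_fills_free_sites(self, xd_model):
        # amounts beyond pool capacity saturate: delivery equals free sites
        y = np.zeros(xd_model.n_species)
        y[xd_model.index["M14X"]] = 12.0
        y2, applied = tv.apply_pulse(xd_model, y, "X", 300.0)
        assert applied == pytest.approx(18.0)

    def test_regular_train_matches_continuous_time_average(self, xd_model):
        # over one interval the docked amount equals k_ins * M_F * t_int0
        pool = tv.pool_x()
        y = np.zeros(xd_model.n_species)
        y[xd_model.index["M14X"]] = 15.0  # half occupied
        _, applied = tv.apply_pulse(xd_model, y, "X", 3.0)
        t_int0 = tv.pulse_interval(3.0, pool.k_ins, pool.M_F0)
        assert applied == pytest.approx(pool.k_ins * 15.0 * t_int0)

    def test_zero_amount_is_identity(self, xd_model):
        y = np.random.default_rng(0).uniform(0, 1, xd_model.n_species)
        y2, applied = tv.apply_pulse(xd_model, y, "D", 0.0)
        assert applied == 0.0
        np.testing.assert_array_equal(y, y2)


@pytest.fixture(scope="module")
def fractions(turnover_model):
    model, y0 = turnover_model
    return model, y0, tv.steady_state_fractions(model, y0, "X")


class TestTransientElimination:
    def test_fractions_sum_to_one(self, fractions):
        _, _, fr = fractions
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in fr.values())

    def test_fractions_cover_only_x_pool_species(self, fractions):
        _, _, fr = fractions
        assert all(name.startswith("M14X") for name in fr)

    def test_without_inhibitor_mass_stays_active(self, params):
        import dataclasses

        p = dataclasses.replace(params, T2_0=0.0, M2_0=0.0)
        model, y0 = tv.build_turnover_model(p)
        fr = tv.steady_state_fractions(model, y0, "X")
        active = fr.get("M14X", 0.0) + fr.get("M14X.M14X", 0.0)
        assert active == pytest.approx(1.0, abs=1e-6)

    def test_distribution_reduces_to_free_pulse(self, fractions):
        model, _, _ = fractions
        y = np.zeros(model.n_species)
        a, applied_a = tv.distribute_insertion(model, y, "X", 2.0,
                                               {"M14X": 1.0})
        b, applied_b = tv.apply_pulse(model, y, "X", 2.0)
        np.testing.assert_allclose(a, b)
        assert applied_a == applied_b

    def test_distribution_conserves_inserted_enzyme(self, fractions):
        model, y0, fr = fractions
        y = y0.conc.copy()
        occ0 = model.p_mf0[model.pool_ids.index("X")] - \
            model.pool_free_sites(y, "X")
        y2, applied = tv.distribute_insertion(model, y, "X", 1.5, fr)
        occ1 = model.p_mf0[model.pool_ids.index("X")] - \
            model.pool_free_sites(y2, "X")
        assert occ1 - occ0 == pytest.approx(applied, rel=1e-9)

    def test_eliminated_m14a_is_flat(self, params):
        from invadosim.experiments import (compute_m14a, m14a_weights,
                                           run_turnover)

        model, traj = run_turnover(params, timp2=100.0,
                                   eliminate_transient=True, t_end=100.0,
                                   dt=0.01, record_every=0.5)
        series = compute_m14a(traj, m14a_weights(model.net))
        steady = series[-1]
        assert np.max(series) - steady < 0.02 * steady
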