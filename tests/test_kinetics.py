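"""ODE assembly and fixed-step RK4 integration."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import invadosim as iv
from invadosim.kinetics import (
    IntegrationError,
    StateVector,
    compile_network,
    detect_steady_state,
    integrate_rk4,
    mass_action_rhs,
)
from invadosim.network import (
    Location,
    MolecularSpecies,
    Reaction,
    ReactionNetwork,
)


def toy_network(reactions, names=("A", "B", "C", "D", "E")):
    species = [MolecularSpecies(n, {}, Location.SOLUTION) for n in names]
    return ReactionNetwork(species=species, reactions=reactions)


class TestMassActionRhs:
    def test_empty_reaction_list_gives_zero_derivative(self):
        net = toy_network([])
        dy = mass_action_rhs(net, {"A": 5.0})
        assert all(v == 0.0 for v in dy.values())

    def test_bimolecular_closed_form(self):
        k = 0.37
        net = toy_network([Reaction(("A", "B"), ("C",), k, "binding")])
        dy = mass_action_rhs(net, {"A": 1.0, "B": 1.0})
        assert dy["C"] == pytest.approx(k)
        assert dy["A"] == pytest.approx(-k)

    def test_identical_reactants_distinct_pair_convention(self):
        k = 0.2
        net = toy_network([Reaction(("A", "A"), ("C",), k, "binding")])
        dy = mass_action_rhs(net, {"A": 3.0})
        assert dy["C"] == pytest.approx(k * 9.0)
        assert dy["A"] == pytest.approx(-2 * k * 9.0)

    def test_full_network_m14_consumed_at_t0(self, core_net, core_model):
        state = {"M14": 100.0, "T2": 100.0, "M2": 100.0}
        dy = mass_action_rhs(core_model, state)
        # independent brute-force sum over the reaction list
        conc = {n: state.get(n, 0.0) for n in core_net.species_names}
        expect = {n: 0.0 for n in conc}
        for r in core_net.reactions:
            rate = r.rate_constant * r.multiplicity
            for n in r.reactants:
                rate *= conc[n]
            for n in r.reactants:
                expect[n] -= rate
            for n in r.products:
                expect[n] += rate
        for n in conc:
            assert dy[n] == pytest.approx(expect[n], rel=1e-12, abs=1e-12)
        assert dy["M14"] < 0  # fresh enzyme is immediately consumed


class TestIntegrateRk4:
    def test_exponential_decay_closed_form(self):
        net = toy_network([Reaction(("A",), (), 0.1, "dissociation")])
        traj = integrate_rk4(net, {"A": 100.0}, 10.0, dt=0.01)
        assert traj.series("A")[-1] == pytest.approx(100.0 * np.exp(-1.0),
                                                     rel=1e-6)

    def test_fourth_order_convergence(self):
        net = toy_network([Reaction(("A",), (), 1.0, "dissociation")])
        errs = []
        for dt in (0.2, 0.1):
            traj = integrate_rk4(net, {"A": 1.0}, 2.0, dt=dt)
            errs.append(abs(traj.series("A")[-1] - np.exp(-2.0)))
        assert errs[0] / errs[1] == pytest.approx(16.0, rel=0.3)

    def test_matches_adaptive_reference_on_small_network(self):
        # A + B <-> C, C -> D + E: 5 species, independent LSODA oracle
        rxns = [
            Reaction(("A", "B"), ("C",), 0.05, "binding"),
            Reaction(("C",), ("A", "B"), 0.02, "dissociation"),
            Reaction(("C",), ("D", "E"), 0.04, "activation"),
        ]
        net = toy_network(rxns)
        model = compile_network(net)
        traj = integrate_rk4(model, {"A": 10.0, "B": 8.0}, 50.0, dt=0.005,
                             record_every=1.0)

        def rhs(t, y):
            a, b, c, d, e = y
            f1 = 0.05 * a * b
            f2 = 0.02 * c
            f3 = 0.04 * c
            return [-f1 + f2, -f1 + f2, f1 - f2 - f3, f3, f3]

        ref = solve_ivp(rhs, (0, 50.0), [10.0, 8.0, 0, 0, 0], method="LSODA",
                        t_eval=traj.times, rtol=1e-10, atol=1e-12)
        scale = np.maximum(np.abs(ref.y.T), 1e-9)
        assert np.max(np.abs(traj.states - ref.y.T) / scale) < 1e-5

    def test_full_network_self_convergence(self, core_model):
        y0 = {"M14": 100.0, "T2": 100.0, "M2": 100.0}
        a = integrate_rk4(core_model, y0, 1000.0, dt=0.02, record_every=100.0)
        b = integrate_rk4(core_model, y0, 1000.0, dt=0.01, record_every=100.0)
        scale = np.maximum(np.abs(b.states), 1e-6 * np.max(b.states))
        assert np.max(np.abs(a.states - b.states) / scale) < 1e-6

    def test_closed_system_conservation_long_run(self, core_net, core_model):
        traj = integrate_rk4(core_model, {"M14": 100.0, "T2": 100.0,
                                          "M2": 100.0}, 10000.0, dt=0.01,
                             record_every=1000.0)
        tot0 = iv.conservation_totals(core_net,
                                      dict(zip(traj.species, traj.states[0])))
        tot1 = iv.conservation_totals(core_net,
                                      dict(zip(traj.species, traj.states[-1])))
        for key in ("M14", "T2", "M2"):
            assert tot1[key] == pytest.approx(tot0[key], rel=1e-8)

    def test_no_negative_concentrations_in_output(self, core_traj_100):
        assert np.min(core_traj_100.states) >= 0.0

    def test_blow_up_reported_with_species(self):
        # autocatalytic growth overflows quickly at a huge rate constant
        net = toy_network([Reaction(("A",), ("A", "A"), 50.0, "binding")])
        with pytest.raises(IntegrationError) as err:
            integrate_rk4(net, {"A": 1.0}, 50.0, dt=0.5)
        assert err.value.species == "A"

    def test_oversized_step_warns(self):
        net = toy_network([Reaction(("A",), (), 10.0, "dissociation")])
        with pytest.warns(RuntimeWarning, match="stability"):
            integrate_rk4(net, {"A": 1.0}, 2.0, dt=1.0)

    def test_events_applied_at_exact_times(self):
        net = toy_network([])
        model = compile_network(net)

        def bump(y):
            y = y.copy()
            y[0] += 5.0
            return y, (1.0, "A", 5.0)

        traj = integrate_rk4(model, {"A": 1.0}, 2.0, dt=0.01,
                             events=[(1.0, bump)], record_every=0.5)
        assert traj.events == [(1.0, "A", 5.0)]
        a = traj.series("A")
        assert a[traj.times < 1.0].max() == pytest.approx(1.0)
        assert a[traj.times >= 1.0].min() == pytest.approx(6.0)


class TestSteadyStateDetection:
    def _traj(self, times, series):
        states = np.asarray(series, dtype=float)[:, None]
        return iv.Trajectory(np.asarray(times, dtype=float), states, ["A"])

    def test_constant_series_converges_at_first_window_end(self):
        t = np.linspace(0, 100, 201)
        res = detect_steady_state(self._traj(t, np.full_like(t, 7.0)), "A",
                                  rel_tol=1e-4, window=10.0)
        assert res.converged
        assert res.value == pytest.approx(7.0)
        assert res.reached_at == pytest.approx(10.0, abs=0.5)

    def test_exponential_plateau_value(self):
        t = np.linspace(0, 200, 2001)
        series = 5.0 + 20.0 * np.exp(-t / 5.0)
        res = detect_steady_state(self._traj(t, series), "A", rel_tol=1e-4,
                                  window=20.0)
        assert res.converged
        assert res.value == pytest.approx(5.0, rel=1e-3)

    def test_drifting_series_is_not_converged(self):
        t = np.linspace(0, 100, 1001)
        res = detect_steady_state(self._traj(t, 1.0 + 0.1 * t), "A",
                                  rel_tol=1e-4, window=10.0)
        assert not res.converged

    def test_window_longer_than_trajectory_rejected(self):
        t = np.linspace(0, 5, 10)
        with pytest.raises(ValueError):
            detect_steady_state(self._traj(t, np.ones_like(t)), "A",
                                window=10.0)


def test_state_vector_roundtrip(core_net):
    sv = StateVector.from_dict(core_net, {"M14": 1.5, "T2": 2.5})
    d = sv.as_dict()
    assert d["M14"] == 1.5 and d["T2"] == 2.5 and d["M2"] == 0.0
    with pytest.raises(KeyError):
        StateVector.from_dict(core_net, {"bogus": 1.0})


def test_trajectory_output_formats(core_traj_100):
    wide = core_traj_100.to_wide()
    assert list(wide.columns)[0] == "time"
    tidy = core_traj_100.to_tidy()
    assert set(tidy.columns) == {"time", "species", "concentration"}
    assert len(tidy) == (wide.shape[1] - 1) * wide.shape[0]
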