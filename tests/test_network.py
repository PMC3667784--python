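"""Species enumeration, reaction construction, deletions and shedding."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import invadosim as iv
from invadosim.network import (
    Location,
    NetworkConfigError,
    PATH_DELETION_TARGETS,
    build_core_network,
    enumerate_species,
)


class TestEnumeration:
    def test_single_pool_closed_list(self):
        names = [s.name for s in enumerate_species()]
        assert len(names) == len(set(names))
        for expected in ("M14", "T2", "M2", "M2act", "T2.M2", "T2.M2act",
                         "M14.T2", "M14.T2.M2", "M14.M14", "M14.M14.T2",
                         "M14.M14.T2.M2", "M14.T2.M14.T2",
                         "M14.T2.M14.T2.M2", "M14.T2.M2.M14.T2.M2"):
            assert expected in names
        assert len(names) == 14

    def test_ecm_variant_contains_engaged_complexes(self):
        names = [s.name for s in enumerate_species(include_ecm=True)]
        for expected in ("ECM", "M14.ECM", "M14.M14.ECM", "M14.M14.T2.ECM",
                         "M14.M14.T2.M2.ECM", "M2act.ECM"):
            assert expected in names

    def test_two_pool_variant_suffixes_membrane_species(self):
        names = [s.name for s in enumerate_species(pools="XD")]
        assert "M14X.M14X" in names
        assert "M14D" in names
        assert "M14D.T2.M14D.T2.M2" in names
        assert "M14" not in names  # bare membrane names replaced
        assert "T2" in names  # solution side unchanged

    def test_shedding_adds_scavenger_species(self):
        names = [s.name for s in enumerate_species(include_shedding=True)]
        assert "M14f" in names and "M14f.T2" in names

    def test_activity_weights(self):
        w = {s.name: s.activity_weight for s in enumerate_species()}
        assert w["M14.M14"] == 2.0
        assert w["M14"] == w["M14.M14.T2"] == w["M14.M14.T2.M2"] == 1.0
        inactive = set(w) - {"M14", "M14.M14", "M14.M14.T2", "M14.M14.T2.M2"}
        assert all(w[n] == 0.0 for n in inactive)

    def test_composition_and_location_invariants(self):
        for s in enumerate_species(include_ecm=True, include_shedding=True):
            if s.location.is_membrane:
                assert s.count("M14") >= 1
            elif not s.name.startswith("M14f"):
                assert s.count("M14") == 0

    def test_enumeration_is_deterministic(self):
        a = [s.name for s in enumerate_species(include_ecm=True, pools="XD")]
        b = [s.name for s in enumerate_species(include_ecm=True, pools="XD")]
        assert a == b


class TestCoreNetwork:
    def test_contains_t2_binding_and_reverse(self, core_net):
        labels = [r.label for r in core_net.reactions]
        assert "M14 + T2 -> M14.T2" in labels
        assert "M14.T2 -> M14 + T2" in labels

    def test_activation_releases_active_mmp2(self, core_net):
        act = [r for r in core_net.reactions if r.tag == "activation"]
        assert len(act) == 1
        assert act[0].reactants == ("M14.M14.T2.M2",)
        assert set(act[0].products) == {"M14.M14.T2", "M2act"}

    def test_composition_conserved_by_every_reaction(self, core_net):
        comp = {s.name: s.composition for s in core_net.species}
        for r in core_net.reactions:
            for monomer in ("M14", "T2"):
                lhs = sum(comp[n].get(monomer, 0) for n in r.reactants)
                rhs = sum(comp[n].get(monomer, 0) for n in r.products)
                assert lhs == rhs, r.label
            # activation converts an M2 unit to M2act; total M2 preserved
            lhs = sum(comp[n].get("M2", 0) + comp[n].get("M2act", 0)
                      for n in r.reactants)
            rhs = sum(comp[n].get("M2", 0) + comp[n].get("M2act", 0)
                      for n in r.products)
            assert lhs == rhs, r.label

    def test_at_most_bimolecular(self, core_net):
        assert all(len(r.reactants) <= 2 for r in core_net.reactions)

    def test_zero_rate_constants_freeze_the_system(self):
        import dataclasses

        p = iv.KineticParameters()
        zeros = {f.name: 0.0 for f in dataclasses.fields(p)
                 if f.name.startswith("k_")}
        net = build_core_network(dataclasses.replace(p, **zeros))
        dy = iv.mass_action_rhs(net, {"M14": 100.0, "T2": 50.0, "M2": 25.0})
        assert all(v == 0.0 for v in dy.values())

    def test_reaction_table_export_and_override_roundtrip(self, core_net,
                                                          tmp_path):
        path = tmp_path / "reactions.tsv"
        core_net.export_table(path)
        back = core_net.replace_reactions_from_table(path)
        assert len(back.reactions) == len(core_net.reactions)
        assert [r.label for r in back.reactions] == \
            [r.label for r in core_net.reactions]
        assert back.metadata["reactions_overridden"]


class TestPathDeletions:
    def test_empty_deletion_is_identity(self, core_net):
        out = iv.apply_path_deletions(core_net, set())
        assert out.species_names == core_net.species_names
        assert len(out.reactions) == len(core_net.reactions)

    def test_deleting_1_and_2_removes_double_loaded_complexes(self, core_net):
        out = iv.apply_path_deletions(core_net, {1, 2})
        assert not out.has_species("M14.T2.M2")
        assert not out.has_species("M14.T2.M2.M14.T2.M2")
        assert out.has_species("M14.T2")  # deletion 5 not requested
        # the original network is untouched
        assert core_net.has_species("M14.T2.M2")

    def test_full_deletion_leaves_only_half_inhibited_dimers(self, core_net):
        out = iv.apply_path_deletions(core_net, {1, 2, 3, 4, 5})
        t2_membrane = [s.name for s in out.species
                       if s.location.is_membrane and s.count("T2") > 0]
        assert sorted(t2_membrane) == ["M14.M14.T2", "M14.M14.T2.M2"]

    def test_idempotent_and_commutative(self, core_net):
        once = iv.apply_path_deletions(core_net, {2, 4})
        twice = iv.apply_path_deletions(once, {2, 4})
        assert once.species_names == twice.species_names
        for perm in itertools.permutations((1, 3, 5)):
            step = core_net
            for d in perm:
                step = iv.apply_path_deletions(step, {d})
            assert step.species_names == iv.apply_path_deletions(
                core_net, {1, 3, 5}).species_names

    def test_unknown_index_rejected(self, core_net):
        with pytest.raises(NetworkConfigError):
            iv.apply_path_deletions(core_net, {6})

    def test_deletion_targets_cover_all_inactive_t2_complexes(self, core_net):
        targets = set(PATH_DELETION_TARGETS.values())
        inactive = {s.name for s in core_net.species
                    if s.location.is_membrane and s.count("T2") > 0
                    and s.activity_weight == 0}
        assert targets == inactive

    def test_two_pool_deletion_removes_both_variants(self):
        net = build_core_network(pools="XD")
        out = iv.apply_path_deletions(net, {5})
        assert not out.has_species("M14X.T2")
        assert not out.has_species("M14D.T2")


class TestShedding:
    def test_negative_rate_rejected(self, core_net):
        with pytest.raises(NetworkConfigError):
            iv.add_ectodomain_shedding(core_net, -1.0)

    def test_fragment_scavenges_timp2(self, core_net):
        out = iv.add_ectodomain_shedding(core_net, 1e-4)
        assert out.has_species("M14f.T2")
        labels = [r.label for r in out.reactions]
        assert "M14f + T2 -> M14f.T2" in labels

    def test_zero_rate_reproduces_unshed_trajectories(self, params):
        base = iv.integrate_rk4(
            build_core_network(params),
            {"M14": 100.0, "T2": 100.0, "M2": 100.0}, 50.0, dt=0.01,
            record_every=1.0)
        shed0 = iv.add_ectodomain_shedding(build_core_network(params), 0.0)
        traj = iv.integrate_rk4(shed0, {"M14": 100.0, "T2": 100.0,
                                        "M2": 100.0}, 50.0, dt=0.01,
                                record_every=1.0)
        for name in base.species:
            np.testing.assert_allclose(traj.series(name), base.series(name),
                                       rtol=1e-12, atol=1e-12)

    def test_shedding_drains_membrane_enzyme(self, params):
        net = iv.add_ectodomain_shedding(build_core_network(params), 1e-3)
        traj = iv.integrate_rk4(net, {"M14": 100.0, "T2": 100.0,
                                      "M2": 100.0}, 100.0, dt=0.01,
                                record_every=10.0)
        def membrane_m14(row):
            return sum(row[traj.species.index(s.name)] * s.count("M14")
                       for s in net.species if s.location.is_membrane)
        assert membrane_m14(traj.states[-1]) < membrane_m14(traj.states[0])
        # total M14 (membrane + shed) is still conserved
        tot0 = iv.conservation_totals(net, dict(zip(traj.species,
                                                    traj.states[0])))
        tot1 = iv.conservation_totals(net, dict(zip(traj.species,
                                                    traj.states[-1])))
        assert tot1["M14"] == pytest.approx(tot0["M14"], rel=1e-8)


@given(m14=st.floats(0, 200), t2=st.floats(0, 500), m2=st.floats(0, 200))
def test_conservation_totals_are_linear(m14, t2, m2):
    net = build_core_network()
    tot = iv.conservation_totals(net, {"M14": m14, "T2": t2, "M2": m2})
    assert tot["M14"] == pytest.approx(m14)
    assert tot["T2"] == pytest.approx(t2)
    assert tot["M2"] == pytest.approx(m2)
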