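"""Flattening, rate equations, propensities and SBML round-trip."""

import numpy as np
import pytest

from procdesign.network import (
    NetworkError,
    UnsupportedRateLaw,
    export_sbml,
    flatten,
    import_sbml,
    ode_rhs,
    propensities,
)

from conftest import make_network


class TestFlatten:
    def test_reaction_count_matches_complexity_on_both_fixtures(
        self, toggle_candidates, toggle_lib, toggle_model,
        osc_candidates, osc_lib, osc_model,
    ):
        for cands, lib, model in (
            (toggle_candidates, toggle_lib, toggle_model),
            (osc_candidates, osc_lib, osc_model),
        ):
            for c in cands:
                net = flatten(c, lib, model)
                assert len(net.reactions) == c.complexity

    def test_toggle_species_are_the_eleven_instances(
        self, toggle_candidates, toggle_lib, toggle_model
    ):
        net = flatten(toggle_candidates[0], toggle_lib, toggle_model)
        assert net.species == [
            "gA", "gB", "A", "B", "S", "R", "AgB", "BgA", "SA", "RB", "AB",
        ]

    def test_oscillator_network_has_six_species_active_passive(
        self, osc_candidates, osc_lib, osc_model
    ):
        from procdesign.casestudies import oscillator_structure_label

        m1 = next(c for c in osc_candidates if oscillator_structure_label(c) == "M1")
        net = flatten(m1, osc_lib, osc_model)
        assert sorted(net.species) == [
            "A.active", "A.passive", "B.active", "B.passive", "C.active", "C.passive",
        ]
        hills = [r for r in net.reactions if r.rate.kind == "mm-cooperative"]
        assert len(hills) == 3  # the inhibition ring
        assert len(net.reactions) == 9  # + 3x2 turnover

    def test_exclusive_switch_reactions_match_fixture_encoding(
        self, toggle_candidates, toggle_lib, toggle_model
    ):
        from procdesign.casestudies import toggle_classic_structures

        net = flatten(
            toggle_classic_structures(toggle_candidates)["exclusive"],
            toggle_lib, toggle_model,
        )
        as_sets = {
            (frozenset(r.reactants), frozenset(r.products)) for r in net.reactions
        }
        # shared-operator binding: requires both sites free, keeps the own site
        assert (
            frozenset({("A", 1), ("gA", 1), ("gB", 1)}),
            frozenset({("AgB", 1), ("gA", 1)}),
        ) in as_sets
        assert (frozenset({("AgB", 1)}), frozenset({("A", 1), ("gB", 1)})) in as_sets
        assert net.free_parameters  # parametric uncertainty retained

    def test_parameter_symbols_globally_unique(self, toggle_candidates, toggle_lib, toggle_model):
        most_complex = max(
            (c for c in toggle_candidates if dict(c.decisions)["inh"] == "simple_inhibition"),
            key=lambda c: c.complexity,
        )
        net = flatten(most_complex, toggle_lib, toggle_model)
        names = [n for n, _ in net.free_parameters]
        assert len(set(names)) == len(names)
        # the two binding instances got distinct scoped symbols
        assert any("binding_a" in n for n in names)
        assert any("binding_b" in n for n in names)


class TestOdeRhs:
    def test_first_order_decay(self, decay_net):
        d = ode_rhs(decay_net, np.array([2.0]), {"k": 0.5})
        assert d == pytest.approx([-1.0])

    def test_mm_cooperative_half_saturation(self):
        from procdesign.network import MM_COOPERATIVE, RateLaw

        for n in (1.0, 2.0, 4.0):
            net = make_network(
                ["S", "P", "C"],
                [(
                    [("S", 1)], [("P", 1)],
                    RateLaw(MM_COOPERATIVE, k="k", K="K", n="n", substrate="S", catalyst="C"),
                )],
                {"k": 2.0, "K": 0.5, "n": n},
            )
            d = ode_rhs(net, np.array([1.0, 0.0, 0.5]), {"k": 2.0, "K": 0.5, "n": n})
            # catalyst at half-saturation: rate = k*[S]/2 for any n
            assert d[0] == pytest.approx(-1.0)
            assert d[1] == pytest.approx(1.0)

    def test_detailed_balance_equilibrium(self, binding_net):
        # kf*A*B = kb*C  =>  all derivatives vanish
        state = np.array([1.0, 1.0, 2.0])
        d = ode_rhs(binding_net, state, {"kf": 1.0, "kb": 0.5})
        assert np.allclose(d, 0.0)

    def test_negative_state_rejected(self, decay_net):
        with pytest.raises(NetworkError, match="negative"):
            ode_rhs(decay_net, np.array([-1.0]), {"k": 1.0})


class TestPropensities:
    def test_bimolecular(self, binding_net):
        a = propensities(binding_net, np.array([3, 4, 0]), {"kf": 0.1, "kb": 1.0})
        assert a[0] == pytest.approx(1.2)

    def test_dimerization_combinatorial_factor(self):
        net = make_network(["A", "C"], [([("A", 2)], [("C", 1)], "c")], {"c": 1.0})
        assert propensities(net, np.array([1, 0]), {"c": 1.0})[0] == 0.0
        assert propensities(net, np.array([5, 0]), {"c": 1.0})[0] == pytest.approx(10.0)

    def test_zero_counts_zero_vector(self, binding_net):
        a = propensities(binding_net, np.zeros(3, dtype=int), {"kf": 1.0, "kb": 1.0})
        assert np.all(a == 0)

    def test_hill_law_unsupported_stochastically(self):
        from procdesign.network import MM_COOPERATIVE, RateLaw

        net = make_network(
            ["S", "P"],
            [(
                [("S", 1)], [("P", 1)],
                RateLaw(MM_COOPERATIVE, k="k", K="K", n="n", substrate="S", catalyst="P"),
            )],
            {"k": 1.0, "K": 1.0, "n": 2.0},
        )
        with pytest.raises(UnsupportedRateLaw):
            propensities(net, np.array([1, 1]), {"k": 1.0, "K": 1.0, "n": 2.0})


class TestSbml:
    def test_round_trip_preserves_structure(
        self, toggle_candidates, toggle_lib, toggle_model
    ):
        from procdesign.casestudies import toggle_classic_structures

        net = flatten(
            toggle_classic_structures(toggle_candidates)["exclusive"],
            toggle_lib, toggle_model,
        )
        doc = export_sbml(net)
        assert doc.startswith("<?xml")
        assert "level3" in doc
        back = import_sbml(doc)
        assert back.species == net.species
        assert len(back.reactions) == len(net.reactions)
        assert [r.rate.kind for r in back.reactions] == [
            r.rate.kind for r in net.reactions
        ]
        assert [r.reactants for r in back.reactions] == [
            r.reactants for r in net.reactions
        ]

    def test_empty_network_valid_document(self):
        net = make_network(["A"], [], {}, initial={"A": 1.0})
        doc = export_sbml(net)
        back = import_sbml(doc)
        assert back.species == ["A"]
        assert back.reactions == []

    def test_hill_network_round_trip(self, osc_candidates, osc_lib, osc_model):
        net = flatten(osc_candidates[0], osc_lib, osc_model)
        back = import_sbml(export_sbml(net))
        assert len(back.reactions) == len(net.reactions)
        hills = [r for r in back.reactions if r.rate.kind == "mm-cooperative"]
        assert {(r.rate.substrate, r.rate.catalyst) for r in hills} == {
            ("B.active", "A.active"), ("C.active", "B.active"), ("A.active", "C.active"),
        }


class TestConservation:
    def test_mass_conserved_in_closed_binding_network(self, binding_net):
        from procdesign.simulate import SamplingGrid, simulate_ode

        grid = SamplingGrid(0.0, 10.0, np.linspace(0, 10, 101))
        traj = simulate_ode(binding_net, {"kf": 1.0, "kb": 0.5}, grid, rtol=1e-10, atol=1e-12)
        total_a = traj.get("A") + traj.get("C")
        assert np.max(np.abs(total_a - total_a[0])) < 1e-8
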