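"""Generated reaction networks: channel counts, rate keying, ODE oracle."""

from collections import Counter

import numpy as np
import pytest

from ringkmc.inhibition import InhibitionScheme
from ringkmc.network import (
    ADP,
    RateTable,
    Species,
    build_network,
    catalytic_reaction,
    ode_rhs,
    rate_key,
)
from ringkmc.rings import configuration_by_id, enumerate_ring_configurations


def channel_counts(net):
    return Counter(r.rate_name for r in net.reactions)


class TestChannelCounts:
    def test_1236_counts(self, network_1236):
        c = channel_counts(network_1236)
        assert c["k12_f"] == c["k12_r"] == 4
        assert c["k23_f"] == c["k23_r"] == 16
        assert c["k36_f"] == c["k36_r"] == 64
        assert c["kcat"] == 14
        assert len(network_1236.species_of_kind("trimer")) == 8
        assert len(network_1236.species_of_kind("hexamer")) == 14

    def test_1246_counts(self, default_rates, schemes):
        net = build_network("1246", default_rates, schemes["scheme2"])
        c = channel_counts(net)
        assert c["k24_f"] == c["k24_r"] == 16
        assert c["k46_f"] == c["k46_r"] == 128
        assert len(net.species_of_kind("tetramer")) == 16

    def test_sequential_pathway_builds(self, default_rates, schemes):
        net = build_network("123456", default_rates, schemes["scheme2"])
        c = channel_counts(net)
        assert c["k56_f"] == c["k56_r"] == 128
        assert len(net.species_of_kind("pentamer")) == 32

    def test_unknown_pathway_rejected(self, default_rates, schemes):
        with pytest.raises(ValueError):
            build_network("1356", default_rates, schemes["scheme2"])

    def test_pure_wildtype_subnetwork_collapses(self, network_1236):
        """Restricting to W-only species leaves one distinct reaction per
        step (the two attachment orientations coincide for identical
        subunits, so the channels merge)."""
        pure = [
            r for r in network_1236.reactions
            if all("M" not in s.arrangement for s in r.reactants + r.products)
        ]
        distinct = {}
        for r in pure:
            key = (tuple(sorted(s.label for s in r.reactants)),
                   tuple(sorted(s.label for s in r.products)))
            distinct.setdefault(r.rate_name, set()).add(key)
        assert len(distinct["k12_f"]) == len(distinct["k23_f"]) == len(distinct["k36_f"]) == 1
        assert len(distinct["kcat"]) == 1


class TestRateKeying:
    def test_identical_interfaces_share_rate_ref(self, default_rates, schemes):
        """WW+MM and MW+MM both create a W-M contact, hence the same rate."""
        net = build_network("1246", default_rates, schemes["scheme2"])

        def find(left, right):
            (rxn,) = [
                r for r in net.reactions
                if r.rate_name == "k24_f"
                and r.reactants == (Species("dimer", left), Species("dimer", right))
            ]
            return rxn

        a, b = find("WW", "MM"), find("MW", "MM")
        assert rate_key(a) == rate_key(b) == ("WM",)
        assert a.rate_constant == b.rate_constant

    def test_ring_closure_forms_two_interfaces(self, network_1236):
        closures = [r for r in network_1236.reactions if r.rate_name == "k36_f"]
        assert all(len(r.keys) == 2 for r in closures)
        www = Species("trimer", "WWW")
        (pure,) = [r for r in closures if r.reactants == (www, www)]
        assert rate_key(pure) == ("WW", "WW")
        assert pure.propensity_kind == "bimolecular_identical"

    def test_catalysis_has_no_interface_key(self, network_1236):
        cat = [r for r in network_1236.reactions if r.tag == "catalysis"][0]
        with pytest.raises(ValueError):
            rate_key(cat)

    def test_per_interface_rate_table(self, schemes):
        rates = RateTable(k12_f={"WW": 1.0, "WM": 2.0, "MW": 2.0, "MM": 3.0})
        net = build_network("1236", rates, schemes["scheme2"])
        by_product = {
            r.products[0].arrangement: r.rate_constant
            for r in net.reactions
            if r.rate_name == "k12_f"
        }
        assert by_product == {"WW": 1.0, "WM": 2.0, "MW": 2.0, "MM": 3.0}


class TestStructuralInvariants:
    @pytest.mark.parametrize("pathway", ["1236", "1246", "123456"])
    def test_subunit_conservation_every_reaction(self, pathway, default_rates, schemes):
        net = build_network(pathway, default_rates, schemes["scheme2"])
        for r in net.reactions:
            assert sum(s.size for s in r.reactants) == sum(s.size for s in r.products)

    @pytest.mark.parametrize("pathway", ["1236", "1246"])
    def test_every_species_consumed(self, pathway, default_rates, schemes):
        net = build_network(pathway, default_rates, schemes["scheme2"])
        consumed = {s for r in net.reactions for s in r.reactants}
        for s in net.species:
            if s.kind != "ADP":
                assert s in consumed, f"dead-end species {s.label}"

    def test_every_forward_has_reverse(self, network_1236):
        fwd = {(r.reactants, r.products, r.keys)
               for r in network_1236.reactions if r.rate_name.endswith("_f")}
        rev = {(r.products, r.reactants, r.keys)
               for r in network_1236.reactions if r.rate_name.endswith("_r")}
        assert fwd == rev

    def test_ring_splits_cover_all_opposite_interface_pairs(self, network_1236):
        """The reverse closure channels of each hexamer realize exactly the
        distinct (trimer pair, broken interfaces) splits of its necklace."""
        for cfg in enumerate_ring_configurations(6):
            seq = cfg.canonical_sequence
            brute = set()
            for i in range(6):
                rot = seq[i:] + seq[:i]
                a, b = rot[:3], rot[3:]
                brute.add((frozenset({a, b}), frozenset({a[2] + b[0], b[2] + a[0]})))
            channels = {
                (frozenset(s.arrangement for s in r.products), frozenset(r.keys))
                for r in network_1236.reactions
                if r.rate_name == "k36_r"
                and r.reactants[0].arrangement == seq
            }
            assert channels == brute

    def test_koff_zero_removes_mutant_breaking_channels(self, schemes):
        rates = RateTable(koff_mut_multiplier=0.0)
        net = build_network("1236", rates, schemes["scheme2"])
        for r in net.reactions:
            if r.rate_name.endswith("_r") and any("M" in k for k in r.keys):
                assert r.rate_constant == 0.0
            elif r.rate_name.endswith("_r"):
                assert r.rate_constant > 0.0


class TestCatalyticReaction:
    def test_pure_wildtype_ring(self, default_rates, schemes):
        r = catalytic_reaction(configuration_by_id(1), schemes["scheme2"], default_rates)
        assert r.rate_constant == pytest.approx(5.0)
        assert r.adp_yield == 6
        assert [s.kind for s in r.products[:-1]] == ["monomer"] * 6

    def test_all_mutant_ring_never_fires(self, default_rates, schemes):
        r = catalytic_reaction(configuration_by_id(14), schemes["scheme2"], default_rates)
        assert r.rate_constant == 0.0
        assert r.adp_yield == 0

    def test_mixed_ring_rate_equals_census_contribution(self, schemes):
        rates = RateTable(kcat_WW=5.0, kcat_WM=1.0)
        r = catalytic_reaction(configuration_by_id(4), schemes["scheme2"], rates)
        # (1*5 + 3*1)/4 per hexamer; times 4 ADP = the ring's turnover 8
        assert r.rate_constant == pytest.approx(2.0)
        assert r.adp_yield == 4


class TestOdeRhs:
    def test_zero_state_zero_derivative(self, network_1236):
        assert np.all(ode_rhs(np.zeros(len(network_1236.species)), network_1236) == 0)

    def test_monomer_only_dimerization_rate(self, pure_w_network):
        net = pure_w_network
        x = net.initial_state(1000, 0)
        d = net.ode_rhs(x)
        k = RateTable().k12_f
        i_w = net.index[Species("monomer", "W")]
        i_ww = net.index[Species("dimer", "WW")]
        assert d[i_ww] == pytest.approx(0.5 * k * 1000**2)
        assert d[i_w] == pytest.approx(-k * 1000**2)

    def test_subunit_conservation_along_rhs(self, network_1236):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.uniform(0, 50, len(network_1236.species))
            d = network_1236.ode_rhs(x)
            assert network_1236.subunit_size @ d == pytest.approx(0.0, abs=1e-9)

    def test_json_dump_is_complete(self, network_1236):
        dump = network_1236.to_json()
        assert len(dump["species"]) == len(network_1236.species)
        assert len(dump["reactions"]) == len(network_1236.reactions)
        assert {r["tag"] for r in dump["reactions"]} == {"assembly", "disassembly", "catalysis"}
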