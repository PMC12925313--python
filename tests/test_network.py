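"""Reference network validation, completeness scoring and pathway calls."""

import itertools

import pytest

from glycopan import network as net

TOY = {
    "metabolites": ["S", "X", "Y", "P"],
    "sources": ["S"],
    "reactions": [
        {"id": "r1", "substrate": "S", "product": "X", "genes": [["K1"]]},
        {"id": "r2", "substrate": "X", "product": "Y", "genes": [["K2"]]},
        {"id": "r3", "substrate": "Y", "product": "P", "genes": [["K3"]]},
        # short alternative route S -> X2 -> P sharing the terminal r3? no:
        {"id": "r4", "substrate": "S", "product": "Y", "genes": [["K4"]]},
    ],
    "products": {"P": "r3"},
}


class TestLoadNetwork:
    def test_minimal_chain_loads(self):
        cfg = {
            "metabolites": ["S", "X", "P"], "sources": ["S"],
            "reactions": [
                {"id": "a", "substrate": "S", "product": "X", "genes": [["K1"]]},
                {"id": "b", "substrate": "X", "product": "P", "genes": [["K2"]]},
            ],
            "products": {"P": "b"},
        }
        network = net.load_network(cfg)
        assert set(network.products) == {"P"}

    def test_missing_terminal_reaction_errors(self):
        bad = dict(TOY, products={"P": "nope"})
        with pytest.raises(net.NetworkValidationError, match="nope"):
            net.load_network(bad)

    def test_undeclared_metabolite_errors(self):
        bad = dict(TOY)
        bad["reactions"] = TOY["reactions"] + [
            {"id": "r9", "substrate": "GHOST", "product": "P", "genes": [["K9"]]}]
        with pytest.raises(net.NetworkValidationError, match="GHOST"):
            net.load_network(bad)

    def test_unreachable_product_errors(self):
        cfg = {
            "metabolites": ["S", "Q", "P"], "sources": ["S"],
            "reactions": [
                {"id": "a", "substrate": "Q", "product": "P", "genes": [["K1"]]}],
            "products": {"P": "a"},
        }
        with pytest.raises(net.NetworkValidationError, match="no route"):
            net.load_network(cfg)

    def test_bundled_reference_network_is_valid(self):
        import importlib.resources as ir

        path = ir.files("glycopan") / "data" / "nucleotide_sugar_network.yaml"
        network = net.load_network(str(path))
        assert len(network.products) >= 20
        assert {"F6P", "Ru5P", "S7P"} == network.sources


class TestReactionPresent:
    RXN = net.Reaction("r", "S", "P",
                       (frozenset({"K1"}), frozenset({"K2"})))
    COMPLEX = net.Reaction("r", "S", "P", (frozenset({"K1", "K2"}),))

    def test_or_over_isoenzymes(self):
        assert net.reaction_present(self.RXN, {"K1": 0, "K2": 1})
        assert not net.reaction_present(self.RXN, {"K1": 0, "K2": 0})

    def test_and_within_complex(self):
        assert not net.reaction_present(self.COMPLEX, {"K1": 1, "K2": 0})
        assert net.reaction_present(self.COMPLEX, {"K1": 1, "K2": 1})

    def test_missing_family_errors(self):
        with pytest.raises(KeyError, match="K2"):
            net.reaction_present(self.RXN, {"K1": 1})


class TestCompleteness:
    def test_linear_fractions(self):
        cfg = {
            "metabolites": ["S", "A", "B", "C", "P"], "sources": ["S"],
            "reactions": [
                {"id": f"r{i}", "substrate": s, "product": p, "genes": [[f"K{i}"]]}
                for i, (s, p) in enumerate(
                    [("S", "A"), ("A", "B"), ("B", "C"), ("C", "P")], 1)
            ],
            "products": {"P": "r4"},
        }
        network = net.load_network(cfg)
        full = {f"K{i}": 1 for i in range(1, 5)}
        assert net.pathway_completeness(network, "P", full) == 1.0
        assert net.pathway_completeness(network, "P", {**full, "K2": 0}) == 0.75

    def test_max_over_routes(self):
        # routes to P: S->X->Y->P (r1,r2,r3) and S->Y->P (r4,r3)
        network = net.load_network(TOY)
        row = {"K1": 1, "K2": 1, "K3": 1, "K4": 0}
        assert net.pathway_completeness(network, "P", row) == 1.0
        # short route 1/2 present, long route 2/3 present -> max 2/3
        row = {"K1": 1, "K2": 1, "K3": 0, "K4": 0}
        assert net.pathway_completeness(network, "P", row) == pytest.approx(2 / 3)

    def test_monotone_in_gene_presence(self):
        network = net.load_network(TOY)
        fams = ["K1", "K2", "K3", "K4"]
        for bits in itertools.product([0, 1], repeat=4):
            row = dict(zip(fams, bits))
            base = net.pathway_completeness(network, "P", row)
            for f in fams:
                more = {**row, f: 1}
                assert net.pathway_completeness(network, "P", more) >= base

    def test_reachability_mode(self):
        network = net.load_network(TOY)
        assert net.pathway_completeness(
            network, "P", {"K1": 0, "K2": 0, "K3": 1, "K4": 1},
            mode="reachability") == 1.0
        assert net.pathway_completeness(
            network, "P", {"K1": 1, "K2": 1, "K3": 0, "K4": 1},
            mode="reachability") == 0.0


class TestCallPathway:
    @pytest.mark.parametrize(
        "row,detected",
        [
            ({"K1": 1, "K2": 1, "K3": 0, "K4": 1}, False),  # terminal absent
            ({"K1": 0, "K2": 0, "K3": 1, "K4": 1}, True),   # short route complete
            ({"K1": 1, "K2": 0, "K3": 1, "K4": 0}, False),  # best route 2/3 < 0.75
        ],
    )
    def test_two_criteria(self, row, detected):
        network = net.load_network(TOY)
        call = net.call_pathway(network, "P", row, genome_id="g")
        assert call.detected is detected
        if call.detected:
            assert call.terminal_present
            assert call.completeness >= 0.75


def test_sugar_prevalence_strict_boundary():
    def calls(n_detected, n=61):
        return [net.PathwayCall(f"g{i}", "P", 1.0, True, i < n_detected)
                for i in range(n)]

    assert net.classify_sugar_prevalence(calls(60)).loc["P", "label"] == "core"
    assert net.classify_sugar_prevalence(calls(55)).loc["P", "label"] == "core"
    # 55/61 = 0.9016 > 0.9 but exactly 0.9 must stay accessory (strict rule)
    calls_09 = [net.PathwayCall(f"g{i}", "P", 1.0, True, i < 54)
                for i in range(60)]
    assert net.classify_sugar_prevalence(calls_09).loc["P", "label"] == "accessory"
    assert net.classify_sugar_prevalence(calls(30)).loc["P", "label"] == "accessory"
    assert net.classify_sugar_prevalence(calls(0)).loc["P", "label"] == "absent"
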