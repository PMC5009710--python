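"""GECN/EAPCN construction, EC matching, hormone-pair queries, summaries."""

import numpy as np
import pytest

from hormonet import pathway_io as pio
from hormonet.network_build import (
    CrosstalkNetwork,
    CurrencyPolicy,
    build_eapcn,
    build_gecn,
    ec_match,
    network_summary,
    shared_crosstalk_enzymes,
)
from hormonet.synthetic_data import FIXTURE_CURRENCY, SynthesisParams, generate_pathway_db

from _oracles import gecn_edges_bruteforce


class TestEcMatch:
    @pytest.mark.parametrize(
        "ec,pattern,expected",
        [
            ("2.4.1.203", "2.4.1.-", True),
            ("2.6.1.57", "2.6.1.57", True),
            ("1.14.13.93", "1.14.11.-", False),
            ("6.3.1.1", "6.3.-.-", True),
            ("6.4.1.1", "6.3.-.-", False),
            ("1.14.13.-", "1.14.13.-", True),
        ],
    )
    def test_field_wise_wildcards(self, ec, pattern, expected):
        assert ec_match(ec, pattern) is expected

    def test_malformed_ec_rejected(self):
        with pytest.raises(ValueError):
            ec_match("1.2.3", "1.2.3.-")
        with pytest.raises(ValueError):
            ec_match("1.2.3.4", "not-an-ec")


def _tiny_db(reactions):
    """Build a db from {rxn_id: (ec, substrates, products)} plus compounds."""
    db = pio.PathwayDB()
    compounds = set()
    for ec, subs, prods in reactions.values():
        compounds |= set(subs) | set(prods)
        db.enzymes.setdefault(ec, pio.Enzyme(ec=ec))
    for cid in compounds:
        db.compounds[cid] = pio.Compound(compound_id=cid, name=cid)
    for rid, (ec, subs, prods) in reactions.items():
        db.reactions[rid] = pio.Reaction(
            reaction_id=rid,
            ec_numbers=(ec,),
            substrate_ids=frozenset(subs),
            product_ids=frozenset(prods),
        )
    return db


class TestGecn:
    def test_currency_only_sharing_gives_no_edge(self):
        db = _tiny_db(
            {
                "R1": ("1.1.1.1", {"ATP", "X"}, set()),
                "R2": ("2.2.2.2", {"ATP", "Y"}, set()),
            }
        )
        net = build_gecn(db, CurrencyPolicy(currency_ids=frozenset({"ATP"})))
        assert net.graph.number_of_edges() == 0

    def test_shared_substrate_creates_edge_with_provenance(self):
        db = _tiny_db(
            {
                "R1": ("1.1.1.1", {"C"}, {"D"}),
                "R2": ("2.2.2.2", {"C"}, {"E"}),
            }
        )
        net = build_gecn(db, CurrencyPolicy(currency_ids=frozenset()))
        assert net.graph.has_edge("1.1.1.1", "2.2.2.2")
        assert net.graph.edges["1.1.1.1", "2.2.2.2"]["provenance"] == frozenset({"C"})

    def test_fixture_iaa_conjugators_share_indole_acetate(self, arabidopsis):
        db = arabidopsis[0]
        net = build_gecn(db, FIXTURE_CURRENCY)
        assert net.graph.has_edge("2.4.1.121", "6.3.-.-")
        assert "INDOLE-3-ACETATE" in net.graph.edges["2.4.1.121", "6.3.-.-"]["provenance"]

    def test_random_db_matches_bruteforce_pairwise_intersection(self, rng):
        for seed in range(8):
            params = SynthesisParams(seed=seed, n_enzymes=6, planted_route_length=3,
                                     n_compounds=12, n_pathways=3,
                                     hormone_bridge_enzymes=())
            db, _, _ = generate_pathway_db(params)
            currency = frozenset(f"CUR-{i:03d}" for i in range(params.n_currency))
            net = build_gecn(db, CurrencyPolicy(currency_ids=currency))
            expected = gecn_edges_bruteforce(db, currency)
            got = {
                tuple(sorted((u, v))): data["provenance"]
                for u, v, data in net.graph.edges(data=True)
            }
            assert got == {k: frozenset(v) for k, v in expected.items()}

    def test_simple_and_symmetric(self, arabidopsis):
        net = build_gecn(arabidopsis[0], FIXTURE_CURRENCY)
        assert all(u != v for u, v in net.graph.edges())

    def test_currency_monotonicity(self, arabidopsis):
        db = arabidopsis[0]
        small = build_gecn(db, CurrencyPolicy(currency_ids=frozenset()))
        large = build_gecn(db, FIXTURE_CURRENCY)
        assert set(large.graph.edges()) <= set(small.graph.edges())


class TestEapcn:
    def test_fixture_has_eight_hormone_nodes(self, arabidopsis):
        db, annotations = arabidopsis[0], arabidopsis[1]
        net = build_eapcn(db, annotations, FIXTURE_CURRENCY)
        assert len(net.nodes_of_kind("hormone")) == 8

    def test_empty_annotations_give_empty_network(self, arabidopsis):
        net = build_eapcn(arabidopsis[0], [], FIXTURE_CURRENCY)
        assert net.graph.number_of_nodes() == 0

    def test_unknown_pathway_is_integrity_error(self, arabidopsis):
        bad = [pio.HormoneAnnotation("auxin", "PWY-NOPE", "biosynthesis")]
        with pytest.raises(pio.IntegrityError):
            build_eapcn(arabidopsis[0], bad, FIXTURE_CURRENCY)

    def test_planted_bridge_enzyme_adjacent_to_both_hormones(self):
        params = SynthesisParams(seed=7, hormone_bridge_enzymes=((("auxin", "ethylene"), 3),))
        db, annotations, truth = generate_pathway_db(params)
        net = build_eapcn(db, annotations, CurrencyPolicy(currency_ids=frozenset()))
        for ec in truth.bridge_enzymes[("auxin", "ethylene")]:
            assert net.graph.has_edge(ec, "auxin")
            assert net.graph.has_edge(ec, "ethylene")

    def test_enzyme_edges_subset_of_gecn(self, arabidopsis):
        db, annotations = arabidopsis[0], arabidopsis[1]
        eapcn = build_eapcn(db, annotations, FIXTURE_CURRENCY)
        gecn = build_gecn(db, FIXTURE_CURRENCY)
        enzyme_edges = {
            tuple(sorted((u, v)))
            for u, v, d in eapcn.graph.edges(data=True)
            if d["relation"] == "shares_compound"
        }
        gecn_edges = {tuple(sorted(e)) for e in gecn.graph.edges()}
        assert enzyme_edges <= gecn_edges


class TestSharedCrosstalkEnzymes:
    def test_fixture_auxin_cytokinin_bridge_has_eleven_enzymes(self, arabidopsis):
        db, annotations = arabidopsis[0], arabidopsis[1]
        net = build_eapcn(db, annotations, FIXTURE_CURRENCY)
        shared = shared_crosstalk_enzymes(net, "auxin", "cytokinin")
        assert len(shared) == 11
        assert "2.4.1.12" not in shared  # carries no auxin/cytokinin membership

    def test_symmetric_in_hormone_order(self, arabidopsis):
        db, annotations = arabidopsis[0], arabidopsis[1]
        net = build_eapcn(db, annotations, FIXTURE_CURRENCY)
        assert shared_crosstalk_enzymes(net, "auxin", "cytokinin") == shared_crosstalk_enzymes(
            net, "cytokinin", "auxin"
        )

    def test_matches_neighborhood_intersection(self, arabidopsis):
        db, annotations = arabidopsis[0], arabidopsis[1]
        net = build_eapcn(db, annotations, FIXTURE_CURRENCY)
        hormones = net.nodes_of_kind("hormone")
        for i, h1 in enumerate(hormones):
            for h2 in hormones[i + 1 :]:
                expected = sorted(
                    set(net.graph.neighbors(h1)) & set(net.graph.neighbors(h2))
                    - set(hormones)
                )
                assert shared_crosstalk_enzymes(net, h1, h2) == expected

    def test_unknown_hormone_rejected(self, arabidopsis):
        db, annotations = arabidopsis[0], arabidopsis[1]
        net = build_eapcn(db, annotations, FIXTURE_CURRENCY)
        with pytest.raises(KeyError):
            shared_crosstalk_enzymes(net, "auxin", "strigolactone")


class TestNetworkSummary:
    def _net(self, edges):
        net = CrosstalkNetwork()
        for u, v in edges:
            for n in (u, v):
                if n not in net.graph:
                    net.add_node(n, kind="enzyme")
            net.add_edge(u, v, relation="shares_compound", provenance={"c"})
        return net

    def test_triangle_has_three_connected_pairs(self):
        net = self._net([("a", "b"), ("b", "c"), ("a", "c")])
        assert network_summary(net).connected_pairs == 3

    def test_two_disjoint_edges_have_two_connected_pairs(self):
        net = self._net([("a", "b"), ("c", "d")])
        summary = network_summary(net)
        assert summary.connected_pairs == 2
        assert summary.component_count == 2

    def test_random_graph_matches_reachability_bruteforce(self, rng):
        import networkx as nx

        from _oracles import random_graph

        for _ in range(20):
            graph = random_graph(rng, n_max=8)
            net = CrosstalkNetwork()
            net.graph = graph
            expected = sum(
                1
                for i, u in enumerate(sorted(graph))
                for v in sorted(graph)[i + 1 :]
                if nx.has_path(graph, u, v)
            )
            assert network_summary(net).connected_pairs == expected
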