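"""Boolean networks: parsing, dynamics and influence-graph oracle checks."""

import itertools

import numpy as np
import pytest

from scbinsim import (
    BooleanNetwork,
    async_random_walk,
    bistable_switch,
    influence_graph,
    parse_boolnet,
    star_network,
    synchronous_trace,
    tristable_switch,
)


def brute_force_influence(net: BooleanNetwork):
    """Independent oracle: plain double loop over configurations and pairs."""
    edges = set()
    n = net.n
    for bits in itertools.product((0, 1), repeat=n):
        x = np.array(bits, dtype=int)
        for j in range(n):
            if x[j] == 1:
                continue
            y = x.copy()
            y[j] = 1
            for i in range(n):
                a = net.evaluate_node(net.nodes[i], x)
                b = net.evaluate_node(net.nodes[i], y)
                if a < b:
                    edges.add((net.nodes[j], net.nodes[i], "+"))
                elif a > b:
                    edges.add((net.nodes[j], net.nodes[i], "-"))
    return edges


def random_truth_table_network(n, rng):
    nodes = [f"n{i}" for i in range(n)]
    tables = {node: rng.integers(0, 2, 2**n) for node in nodes}
    return BooleanNetwork.from_truth_table(nodes, tables)


class TestParser:
    def test_negative_feedback_loop(self):
        net = parse_boolnet("targets, factors\nA, B\nB, !A\n")
        assert (net.evaluate([0, 0]) == [0, 1]).all()
        assert (net.evaluate([1, 1]) == [1, 0]).all()

    def test_constant_function(self):
        net = parse_boolnet("targets, factors\nA, 1\n")
        assert net.evaluate([0])[0] == 1

    def test_round_trip_fixpoint(self):
        net = star_network(5)
        text = net.to_boolnet()
        again = parse_boolnet(text)
        assert again.to_boolnet() == text
        for bits in itertools.product((0, 1), repeat=net.n):
            assert (net.evaluate(bits) == again.evaluate(bits)).all()

    def test_undefined_reference_rejected(self):
        with pytest.raises(SyntaxError, match="undefined"):
            parse_boolnet("targets, factors\nA, B & C\nB, A\n")

    def test_syntax_error_reports_line(self):
        with pytest.raises(SyntaxError, match="line 3"):
            parse_boolnet("targets, factors\nA, B\nB, (A\n")

    def test_operator_precedence(self):
        net = parse_boolnet("targets, factors\nA, A | B & C\nB, B\nC, C\n")
        # & binds tighter than |
        assert net.evaluate([0, 1, 0])[0] == 0
        assert net.evaluate([0, 1, 1])[0] == 1
        assert net.evaluate([1, 0, 0])[0] == 1

    def test_truth_table_network_round_trips_via_dnf(self, rng):
        net = random_truth_table_network(3, rng)
        again = parse_boolnet(net.to_boolnet())
        for bits in itertools.product((0, 1), repeat=3):
            assert (net.evaluate(bits) == again.evaluate(bits)).all()


class TestDynamics:
    def test_evaluate_against_truth_table(self, rng):
        """AST evaluation agrees with an explicit truth-table oracle."""
        net = parse_boolnet("targets, factors\nA, (B | C) & !A\nB, A & C\nC, !B\n")
        for bits in itertools.product((0, 1), repeat=3):
            a, b, c = bits
            expected = [int((b or c) and not a), int(a and c), int(not b)]
            assert (net.evaluate(bits) == expected).all()

    def test_stability_matches_enumeration(self, rng):
        for _ in range(20):
            net = random_truth_table_network(3, rng)
            fixed = {tuple(x) for x in net.stable_states()}
            for bits in itertools.product((0, 1), repeat=3):
                assert net.is_stable(bits) == (tuple(bits) in fixed)

    def test_stable_trace_has_length_one(self):
        net = parse_boolnet("targets, factors\nA, A\nB, B\n")
        trace = async_random_walk(net, [1, 0], seed=0)
        assert len(trace) == 1

    def test_async_trace_invariant(self, rng):
        for seed in range(10):
            net = random_truth_table_network(3, rng)
            x0 = rng.integers(0, 2, 3)
            trace = async_random_walk(net, x0, max_steps=30, seed=seed)
            assert trace.is_valid(net)

    def test_async_visits_subset_of_reachable(self, rng):
        """States visited by seeded walks lie in the BFS-reachable set."""
        net = random_truth_table_network(3, rng)

        def successors(x):
            fx = net.evaluate(np.array(x))
            for i in range(3):
                if fx[i] != x[i]:
                    y = list(x)
                    y[i] = fx[i]
                    yield tuple(y)

        start = (0, 1, 0)
        reachable, frontier = {start}, [start]
        while frontier:
            nxt = []
            for x in frontier:
                for y in successors(x):
                    if y not in reachable:
                        reachable.add(y)
                        nxt.append(y)
            frontier = nxt
        for seed in range(200):
            trace = async_random_walk(net, start, max_steps=20, seed=seed)
            assert {tuple(c) for c in trace.configurations} <= reachable

    def test_synchronous_period_two_cycle(self):
        net = parse_boolnet("targets, factors\nA, B\nB, A\n")
        trace = synchronous_trace(net, [0, 1], k=4)
        states = [tuple(c) for c in trace.configurations]
        assert states == [(0, 1), (1, 0), (0, 1), (1, 0), (0, 1)]
        assert trace.is_valid(net)

    def test_synchronous_equals_iterated_evaluate(self, rng):
        net = random_truth_table_network(3, rng)
        x0 = np.array([1, 0, 1])
        trace = synchronous_trace(net, x0, k=5)
        x = x0
        for cfg in trace.configurations[1:]:
            x = net.evaluate(x)
            assert (cfg == x).all()


class TestInfluenceGraph:
    def test_definition_examples(self):
        net = parse_boolnet("targets, factors\nA, B\nB, !A\nC, A | B\n")
        edges = influence_graph(net)
        assert ("B", "A", "+") in edges
        assert ("A", "B", "-") in edges
        assert ("A", "C", "+") in edges and ("B", "C", "+") in edges
        assert ("A", "A", "+") not in edges

    def test_xor_is_non_monotone(self):
        net = parse_boolnet(
            "targets, factors\nA, (B & !C) | (!B & C)\nB, B\nC, C\n")
        edges = influence_graph(net)
        assert ("B", "A", "+") in edges and ("B", "A", "-") in edges

    def test_oracle_equivalence_random_networks(self, rng):
        """Exhaustive agreement with the brute-force oracle on random nets."""
        for _ in range(150):
            n = int(rng.integers(1, 4))
            net = random_truth_table_network(n, rng)
            assert influence_graph(net) == brute_force_influence(net)


class TestDemoModels:
    def test_star_walk_activates_monotonically(self):
        """From (tf on, genes off) genes switch on one per step until the
        all-active fixed point."""
        net = star_network(8)
        x0 = np.zeros(net.n, dtype=int)
        x0[net.nodes.index("tf")] = 1
        trace = async_random_walk(net, x0, seed=42)
        counts = [int(c.sum()) for c in trace.configurations]
        assert counts == list(range(1, net.n + 1))
        assert net.is_stable(trace.configurations[-1])
        assert trace.configurations[-1].sum() == net.n

    def test_bistable_switch_two_fates(self):
        net = bistable_switch()
        stables = {tuple(s) for s in net.stable_states()}
        on = {net.nodes[i] for s in stables for i in range(net.n) if s[i]}
        # the two mutually exclusive fates appear among the stable states
        tf8_states = [s for s in stables if s[net.nodes.index("TF8")]]
        tf9_states = [s for s in stables if s[net.nodes.index("TF9")]]
        assert tf8_states and tf9_states
        for s in tf8_states:
            assert not s[net.nodes.index("TF9")]

    def test_tristable_switch_three_fates(self):
        net = tristable_switch()
        stables = net.stable_states()
        sigs = set()
        for s in stables:
            sig = tuple(node for node, v in zip(net.nodes, s) if v
                        and node in ("A", "B", "C", "I"))
            sigs.add(sig)
        assert ("A",) in sigs
        assert ("I", "B") in sigs and ("I", "C") in sigs
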