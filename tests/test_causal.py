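import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from moadecon import causal, synth
from moadecon.network import SignedNetwork

from conftest import random_signed_graph


def brute_force_predictions(net, hypothesis, sign, delta):
    """Oracle: enumerate every simple path up to delta, keep only the
    minimum-length ones per target, and combine their sign products."""
    g = net.graph
    out = {}
    for target in g.nodes:
        if target == hypothesis:
            continue
        paths = list(
            nx.all_simple_paths(g, hypothesis, target, cutoff=delta)
        )
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        signs = set()
        for p in (p for p in paths if len(p) == shortest):
            prod = sign
            for u, v in zip(p, p[1:]):
                prod *= g[u][v]["sign"]
            signs.add(prod)
        out[target] = signs.pop() if len(signs) == 1 else 0
    return out


class TestPredictDownstream:
    def test_signed_chain(self, chain_network):
        pred = causal.predict_downstream(chain_network, "h", 1, delta=2)
        assert pred == {"a": 1, "b": -1, "c": -1}

    def test_conflicting_equal_length_paths_are_ambiguous(self, diamond_network):
        pred = causal.predict_downstream(diamond_network, "h", 1, delta=2)
        assert pred["a"] == 0
        assert pred["x"] == 1 and pred["y"] == -1

    def test_predictions_odd_in_hypothesis_sign(self, chain_network):
        plus = causal.predict_downstream(chain_network, "h", 1, 2)
        minus = causal.predict_downstream(chain_network, "h", -1, 2)
        assert minus == {k: -v for k, v in plus.items()}

    def test_layers_nest_and_agree(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            net = random_signed_graph(10, 0.25, rng)
            layers = causal.predict_layers(net, "n0", 1, 4)
            for shallow, deep in zip(layers, layers[1:]):
                assert set(shallow) <= set(deep)
                for node, state in shallow.items():
                    assert deep[node] == state

    def test_matches_brute_force_path_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(12):
            net = random_signed_graph(rng.integers(4, 9), 0.3, rng)
            for delta in (1, 2, 3):
                got = causal.predict_downstream(net, "n0", 1, delta)
                assert got == brute_force_predictions(net, "n0", 1, delta)

    def test_invalid_inputs(self, chain_network):
        with pytest.raises(ValueError):
            causal.predict_downstream(chain_network, "h", 1, 0)
        with pytest.raises(ValueError):
            causal.predict_downstream(chain_network, "nope", 1, 1)


class TestScoreHypothesis:
    def test_three_gene_worked_example(self):
        preds = {"a": 1, "b": -1, "c": 1}
        obs = {"a": 1, "b": -1, "c": -1}
        score, nc, ni, na, p = causal.score_hypothesis(preds, obs)
        assert (score, nc, ni, na) == (1, 2, 1, 0)
        assert p == pytest.approx(2 / 3)

    def test_perfect_agreement_probability(self):
        preds = {"a": 1, "b": 1, "c": -1}
        obs = dict(preds)
        score, *_, p = causal.score_hypothesis(preds, obs)
        assert score == 3
        assert p == pytest.approx(1 / 3)  # 3 distinct arrangements of {+,+,-}

    def test_all_zero_observations(self):
        score, *_, p = causal.score_hypothesis({"a": 1}, {"a": 0, "b": 0})
        assert (score, p) == (0, 1.0)

    def test_disjoint_supports(self):
        score, *_, p = causal.score_hypothesis({"a": 1}, {"b": 1})
        assert (score, p) == (0, 1.0)

    def test_ambiguous_predictions_counted(self):
        score, nc, ni, na, p = causal.score_hypothesis(
            {"a": 0, "b": 1}, {"a": 1, "b": 1}
        )
        assert na == 1 and score == 1

    def test_exact_and_monte_carlo_nulls_agree(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            nodes = [f"x{i}" for i in range(8)]
            preds = {n: int(rng.choice([-1, 1])) for n in nodes[:6]}
            obs = {n: int(rng.choice([-1, 0, 1])) for n in nodes}
            *_, p_exact = causal.score_hypothesis(preds, obs, null="exact_permutation")
            n_perm = 10_000
            *_, p_mc = causal.score_hypothesis(
                preds, obs, null="monte_carlo", n_perm=n_perm, seed=1
            )
            se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
            assert abs(p_mc - p_exact) <= max(3 * se, 1e-9)


class TestRankHypotheses:
    def test_negated_observations_equal_inverted_sign(self, chain_network):
        obs = {"a": 1, "b": -1, "c": 1}
        r1 = causal.rank_hypotheses(chain_network, obs, delta_max=2, n_perm=200)
        r2 = causal.rank_hypotheses(
            chain_network, {k: -v for k, v in obs.items()}, delta_max=2, n_perm=200
        )
        key = ["protein", "delta"]
        merged = r1.merge(r2, on=key + ["score"], suffixes=("_1", "_2"))
        flipped = merged[merged["sign_1"] == -merged["sign_2"]]
        assert len(flipped) == len(r1)

    def test_sign_flipped_network_at_depth_one(self, chain_network):
        obs = {"a": 1, "c": -1}
        r1 = causal.rank_hypotheses(chain_network, obs, delta_max=1, n_perm=200)
        r2 = causal.rank_hypotheses(
            chain_network.sign_flipped(), obs, delta_max=1, n_perm=200
        )
        m1 = r1.set_index(["protein", "sign", "delta"])["score"]
        m2 = r2.set_index(["protein", "sign", "delta"])["score"]
        for (prot, sign, delta), score in m1.items():
            assert m2[(prot, -sign, delta)] == score

    def test_empty_observation_yields_no_significant_hypotheses(self, chain_network):
        r = causal.rank_hypotheses(chain_network, {}, delta_max=2, n_perm=100)
        assert not r["significant"].any()

    def test_planted_source_regulator_ranks_first_at_every_depth(self):
        """Zero-noise recovery: with the planted regulator made a pure
        source (no incoming edges), it ranks first at its true sign for
        every path length >= the planting depth."""
        net = synth.simulate_network(60, 3, 0.3, seed=13)
        reg = "G0000"
        source_net = SignedNetwork.from_edges(
            ((u, v, s) for u, v, s in net.edges() if v != reg), nodes=net.nodes
        )
        effects = synth.planted_effects(source_net, {(reg, 1)}, depth=2)
        observed = {g: 0 for g in source_net.nodes}
        observed.update(effects)
        ranking = causal.rank_hypotheses(source_net, observed, delta_max=4, n_perm=300, seed=0)
        for delta in (2, 3, 4):
            top = ranking[ranking["delta"] == delta].iloc[0]
            assert (top["protein"], top["sign"]) == (reg, 1)


class TestConsensus:
    def test_maximum_count_wins(self):
        sig = {1: [("P1", 1)], 2: [("P1", 1), ("P2", 1)], 3: [("P1", 1)]}
        assert causal.consensus_nodes(sig) == {("P1", 1)}

    def test_ties_all_retained(self):
        sig = {1: [("P1", 1)], 2: [("P1", 1), ("P2", -1)], 3: [("P2", -1)]}
        assert causal.consensus_nodes(sig) == {("P1", 1), ("P2", -1)}

    def test_nothing_significant_gives_empty_consensus(self):
        assert causal.consensus_nodes({1: [], 2: []}) == set()


class TestReconstructSubnetwork:
    def test_only_concordant_paths_included(self, chain_network):
        # h explains a (+1) and b (-1); c is observed discordant
        observed = {"a": 1, "b": -1, "c": 1}
        sub = causal.reconstruct_subnetwork(chain_network, [("h", 1)], observed, 2)
        assert sub.explained[("h", 1)] == {"a", "b"}
        assert sub.edges() == {("h", "a", 1), ("a", "b", -1)}

    def test_union_over_consensus_nodes_no_duplicate_edges(self):
        net = SignedNetwork.from_edges(
            [("c1", "m", 1), ("c2", "m", 1), ("m", "g", 1)]
        )
        observed = {"g": 1, "m": 1}
        sub = causal.reconstruct_subnetwork(net, [("c1", 1), ("c2", 1)], observed, 3)
        assert sub.edges() == {("c1", "m", 1), ("c2", "m", 1), ("m", "g", 1)}

    def test_subnetwork_edges_subset_of_source_network(self):
        rng = np.random.default_rng(2)
        net = random_signed_graph(10, 0.3, rng)
        observed = {n: int(rng.choice([-1, 0, 1])) for n in net.nodes}
        sub = causal.reconstruct_subnetwork(net, [("n0", 1), ("n1", -1)], observed, 3)
        assert sub.edges() <= set(net.edges())


class TestPoolSetups:
    def test_min_frequency_filter(self):
        setups = {"s1": ["A", "B"], "s2": ["A"], "s3": ["A", "C"]}
        table, pooled, _ = causal.pool_setups(setups, min_frequency=2)
        assert pooled == {"A"}
        assert table.loc[table["protein"] == "A", "frequency"].iloc[0] == 3

    def test_min_frequency_one_is_union(self):
        setups = {"s1": ["A"], "s2": ["B"]}
        _, pooled, _ = causal.pool_setups(setups, min_frequency=1)
        assert pooled == {"A", "B"}

    def test_frequency_counts_every_setup(self):
        setups = {f"s{i}": [("ATF4", 1)] for i in range(8)}
        table, pooled, _ = causal.pool_setups(setups)
        assert table.loc[0, "frequency"] == 8
        assert pooled == {"ATF4"}

    def test_default_min_frequency_is_half_rounded_up(self):
        setups = {"s1": ["A", "B"], "s2": ["A"], "s3": ["A", "C"]}
        _, pooled, _ = causal.pool_setups(setups)  # ceil(3/2) = 2
        assert pooled == {"A"}

    def test_display_network_connects_pooled_regulators(self, chain_network):
        setups = {"s1": ["h", "a"], "s2": ["h", "a"]}
        _, pooled, display = causal.pool_setups(setups, network=chain_network)
        assert set(display.nodes) == {"h", "a"}
        assert list(display.edges(data="sign")) == [("h", "a", 1)]

    def test_empty_setups_rejected(self):
        with pytest.raises(ValueError):
            causal.pool_setups({})


def test_recovery_degrades_with_noise():
    """Top-1 recovery of the planted regulator is best at low residual
    noise and collapses once noise swamps the fold-change threshold."""
    import moadecon as m

    def rate(noise_sd):
        cfg = m.PipelineConfig(
            n_nodes=120, n_background_genes=400, noise_sd=noise_sd,
            n_draws_fwer=2000, n_perm_causal=150, n_perm_tf=200,
        )
        hits = 0
        for seed in range(10):
            r = m.run_pipeline(seed=seed, config=cfg)
            (reg, sign), = r.truth.planted_regulators
            top = r.causal_rankings["transcript_states"]
            top = top[top["delta"] == 2].iloc[0]
            hits += (top["protein"], top["sign"]) == (reg, sign)
        return hits / 10

    low, mid, high = rate(0.3), rate(1.0), rate(2.5)
    assert low >= mid >= high
    assert low > high


def test_consensus_subnetwork_sif_round_trip(tmp_path, chain_network):
    observed = {"a": 1, "b": -1}
    sub = causal.reconstruct_subnetwork(chain_network, [("h", 1)], observed, 2)
    path = tmp_path / "sub.sif"
    sub.to_sif(path)
    again = SignedNetwork.from_sif(path)
    assert set(again.edges()) == sub.edges()
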