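"""Upstream-regulator inference on a signed network.

Observed gene states (+1 up, -1 down, 0 unchanged) are explained by
propagating each candidate regulator's assumed sign along shortest paths
up to length 5.  The planted regulator should score highest at the
planting depth, be a consensus node across path lengths, and survive
pooling across analysis setups."""

from moadecon import causal, synth
from moadecon.pipeline import choose_regulator

net = synth.simulate_network(n_nodes=80, mean_out_degree=3, seed=3)
regulator, sign = choose_regulator(net, seed=3)
effects = synth.planted_effects(net, {(regulator, sign)}, depth=2)
observed = {g: 0 for g in net.nodes}
observed.update(effects)
print(f"planted: {regulator} (sign {sign:+d}); "
      f"{len(effects)} downstream genes observed changed")

ranking = causal.rank_hypotheses(net, observed, delta_max=5, n_perm=500, seed=0)
top = ranking[ranking["delta"] == 2].head(3)
print("\ntop hypotheses at path length 2 (score = correct - incorrect):")
print(top[["protein", "sign", "score", "n_correct", "n_incorrect", "p_value"]]
      .to_string(index=False))

consensus = causal.consensus_from_ranking(ranking)
print(f"\nconsensus nodes (significant at the most path lengths): {sorted(consensus)}")

sub = causal.reconstruct_subnetwork(net, consensus, observed, delta_max=5)
print(f"consensus subnetwork: {sub.graph.number_of_nodes()} nodes, "
      f"{sub.graph.number_of_edges()} sign-concordant edges")

# pooling hypotheses recovered by different algorithm/network setups
setups = {"setup_A": consensus, "setup_B": consensus | {("G0007", 1)}}
table, pooled, _ = causal.pool_setups(setups)
print(f"pooled regulators (recovered in >= half the setups): {sorted(pooled)}")
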