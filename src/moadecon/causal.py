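"""Causal reasoning over signed, directed protein networks.

Given discrete observed states (gene-level differential-expression signs
or discretised transcription-factor activities), every protein in the
network is tested as an upstream-regulator hypothesis: assuming the
protein is active (+1) or inhibited (-1), downstream states are
predicted by propagating the assumed sign along shortest paths, and the
hypothesis is scored by concordance with the observations.  Hypotheses
are ranked per path length, consensus nodes are extracted across path
lengths, their sign-concordant shortest-path subnetworks are
reconstructed, and hypothesis sets from multiple analysis setups are
pooled by recovery frequency.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from sympy.utilities.iterables import multiset_permutations

from .network import SignedNetwork

#: supports up to this size use exact enumeration of the permutation null
EXACT_SUPPORT_MAX = 8


@dataclass
class HypothesisScore:
    protein: str
    sign: int
    delta: int
    n_correct: int
    n_incorrect: int
    n_ambiguous: int
    p_value: float
    significant: bool

    @property
    def score(self) -> int:
        return self.n_correct - self.n_incorrect


@dataclass
class ConsensusSubnetwork:
    """Union of sign-concordant shortest paths from consensus regulators
    to the observations they explain."""

    graph: nx.DiGraph
    consensus: list[tuple[str, int]]
    explained: dict[tuple[str, int], set[str]] = field(default_factory=dict)

    def edges(self) -> set[tuple[str, str, int]]:
        return {(u, v, d["sign"]) for u, v, d in self.graph.edges(data=True)}

    def to_sif(self, path) -> None:
        from .network import SIGN_TO_RELATION

        with open(path, "w") as fh:
            for u, v, s in sorted(self.edges()):
                fh.write(f"{u}\t{SIGN_TO_RELATION[s]}\t{v}\n")


# -- sign propagation ---------------------------------------------------


def predict_layers(
    network: SignedNetwork, hypothesis: str, sign: int, delta_max: int
) -> list[dict[str, int]]:
    """Cumulative shortest-path sign predictions for delta = 1..delta_max.

    Element ``k-1`` maps every node within distance ``k`` of the
    hypothesis (the hypothesis itself excluded) to its predicted state:
    the assumed sign times the product of edge signs along a shortest
    path, or 0 when equal-length shortest paths disagree (ambiguous).
    """
    if delta_max < 1:
        raise ValueError(f"path length must be >= 1, got {delta_max}")
    if hypothesis not in network:
        raise ValueError(f"hypothesis {hypothesis!r} not in network")
    g = network.graph
    reached: dict[str, int] = {hypothesis: 0}  # node -> shortest distance
    state: dict[str, int] = {}
    frontier: dict[str, set[int]] = {hypothesis: {sign}}
    layers: list[dict[str, int]] = []
    for depth in range(1, delta_max + 1):
        nxt: dict[str, set[int]] = {}
        for u, signs in frontier.items():
            for v in g.successors(u):
                if v in reached and reached[v] < depth:
                    continue
                es = g[u][v]["sign"]
                nxt.setdefault(v, set()).update(s * es for s in signs)
        for v, signs in nxt.items():
            reached.setdefault(v, depth)
            state[v] = next(iter(signs)) if len(signs) == 1 else 0
        # ambiguous nodes propagate both signs onward
        frontier = {
            v: ({1, -1} if state[v] == 0 else {state[v]}) for v in nxt
        }
        layers.append(dict(state))
    return layers


def predict_downstream(
    network: SignedNetwork, hypothesis: str, sign: int, delta: int
) -> dict[str, int]:
    """Predicted downstream states within ``delta`` steps of a signed
    regulator hypothesis (see :func:`predict_layers`)."""
    return predict_layers(network, hypothesis, sign, delta)[-1]


# -- hypothesis scoring --------------------------------------------------


def score_hypothesis(
    predictions: Mapping[str, int],
    observed: Mapping[str, int],
    n_perm: int = 10_000,
    seed: int | None = 0,
    null: str = "auto",
    _perm_values: np.ndarray | None = None,
) -> tuple[int, int, int, int, float]:
    """Concordance score and permutation p-value for one hypothesis.

    ``observed`` maps every measured node to its state in {-1, 0, +1}
    (nodes measured as unchanged carry 0).  Over nodes with a nonzero
    prediction and a nonzero observation, agreement counts +1 and
    disagreement -1; nodes predicted ambiguous (0) with a nonzero
    observation are counted as ambiguous.  The null permutes the
    observed multiset (including the zeros) across the measured nodes
    and recomputes the score; it is enumerated exactly when at most
    ``EXACT_SUPPORT_MAX`` nodes are measured (or when
    ``null='exact_permutation'``), otherwise Monte-Carlo sampled.

    Returns ``(score, n_correct, n_incorrect, n_ambiguous, p)``.
    """
    measured = sorted(observed)
    pos = {n: i for i, n in enumerate(measured)}
    support = [n for n, p in predictions.items() if p != 0 and n in pos]
    n_ambiguous = sum(
        1 for n, p in predictions.items() if p == 0 and observed.get(n, 0) != 0
    )
    obs_all = np.array([observed[n] for n in measured])
    if not support or not obs_all.any():
        return 0, 0, 0, n_ambiguous, 1.0
    support.sort()
    pred = np.array([predictions[n] for n in support])
    obs = np.array([observed[n] for n in support])
    n_correct = int(np.sum((pred == obs) & (obs != 0)))
    n_incorrect = int(np.sum((pred == -obs) & (obs != 0)))
    score = n_correct - n_incorrect
    cols = np.array([pos[n] for n in support])

    exact = null == "exact_permutation" or (
        null == "auto" and len(measured) <= EXACT_SUPPORT_MAX
    )
    if exact:
        total = hits = 0
        for arrangement in multiset_permutations(sorted(obs_all.tolist())):
            total += 1
            if int(np.dot(pred, np.asarray(arrangement)[cols])) >= score:
                hits += 1
        p = hits / total
    else:
        if _perm_values is None:
            rng = np.random.default_rng(seed)
            order = np.argsort(rng.random((n_perm, len(measured))), axis=1)
            _perm_values = obs_all[order]
        null_scores = _perm_values[:, cols] @ pred
        p = float(np.mean(null_scores >= score))
    return score, n_correct, n_incorrect, n_ambiguous, p


def rank_hypotheses(
    network: SignedNetwork,
    observed: Mapping[str, int],
    delta_max: int = 5,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every (protein, sign, path length) hypothesis and rank.

    Both regulator signs are tested for every protein.  Rows are sorted
    by score descending, then p ascending, then protein id; a hypothesis
    is significant when p <= ``alpha``.
    """
    perm_values = None
    if len(observed) > EXACT_SUPPORT_MAX:
        # one shared permutation block: the null is a function of the
        # observed multiset only, so it can be drawn once per ranking
        rng = np.random.default_rng(seed)
        measured = sorted(observed)
        obs_all = np.array([observed[n] for n in measured])
        order = np.argsort(rng.random((n_perm, len(measured))), axis=1)
        perm_values = obs_all[order]
    rows = []
    for protein in sorted(network.nodes):
        for sign in (1, -1):
            layers = predict_layers(network, protein, sign, delta_max)
            for delta, preds in enumerate(layers, start=1):
                child = np.random.default_rng(
                    [seed, zlib.crc32(protein.encode()), sign + 1, delta]
                )
                score, nc, ni, na, p = score_hypothesis(
                    preds, observed, n_perm=n_perm, seed=child,
                    _perm_values=perm_values,
                )
                rows.append(
                    {
                        "protein": protein,
                        "sign": sign,
                        "delta": delta,
                        "score": score,
                        "n_correct": nc,
                        "n_incorrect": ni,
                        "n_ambiguous": na,
                        "p_value": p,
                        "significant": p <= alpha,
                    }
                )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["score", "p_value", "protein", "sign", "delta"],
        ascending=[False, True, True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return df


def consensus_nodes(
    significant_by_delta: Mapping[int, Iterable[tuple[str, int]]],
) -> set[tuple[str, int]]:
    """Hypotheses significant across the greatest number of path lengths.

    Ties all retained; empty when nothing is significant at any level.
    """
    counts: dict[tuple[str, int], int] = {}
    for hyps in significant_by_delta.values():
        for h in set(hyps):
            counts[h] = counts.get(h, 0) + 1
    if not counts:
        return set()
    best = max(counts.values())
    return {h for h, c in counts.items() if c == best}


def consensus_from_ranking(ranking: pd.DataFrame) -> set[tuple[str, int]]:
    """Consensus nodes from a :func:`rank_hypotheses` table."""
    sig = ranking[ranking["significant"]]
    by_delta = {
        d: list(zip(grp["protein"], grp["sign"]))
        for d, grp in sig.groupby("delta")
    }
    return consensus_nodes(by_delta)


# -- subnetwork reconstruction -------------------------------------------


def reconstruct_subnetwork(
    network: SignedNetwork,
    consensus: Iterable[tuple[str, int]],
    observed: Mapping[str, int],
    delta_max: int = 5,
) -> ConsensusSubnetwork:
    """Union of all shortest paths (<= delta_max) from each consensus
    regulator to every observation it explains concordantly."""
    g = network.graph
    sub = nx.DiGraph()
    consensus = sorted(consensus)
    explained: dict[tuple[str, int], set[str]] = {}
    for node, sign in consensus:
        preds = predict_downstream(network, node, sign, delta_max)
        targets = {
            n
            for n, p in preds.items()
            if p != 0 and observed.get(n, 0) == p
        }
        explained[(node, sign)] = targets
        if not targets:
            sub.add_node(node, role="consensus", state=sign)
            continue
        lengths = nx.single_source_shortest_path_length(g, node, cutoff=delta_max)
        sub.add_node(node, role="consensus", state=sign)
        for t in sorted(targets):
            for path in nx.all_shortest_paths(g, node, t):
                if len(path) - 1 > lengths[t]:  # pragma: no cover - defensive
                    continue
                for u, v in zip(path, path[1:]):
                    sub.add_edge(u, v, sign=g[u][v]["sign"])
            sub.nodes[t]["role"] = "explained"
            sub.nodes[t]["state"] = observed[t]
    return ConsensusSubnetwork(graph=sub, consensus=list(consensus), explained=explained)


# -- pooling across setups -------------------------------------------------


def pool_setups(
    setups: Mapping[str, Iterable[tuple[str, int] | str]],
    min_frequency: int | None = None,
    network: SignedNetwork | None = None,
) -> tuple[pd.DataFrame, set[str], nx.DiGraph | None]:
    """Pool regulator hypotheses across (algorithm x network x condition)
    setups by recovery frequency.

    Hypotheses may be bare protein ids or (protein, sign) pairs; pooling
    is by protein, with the signs recovered recorded alongside.
    ``min_frequency`` defaults to half the number of setups, rounded up.
    When a prior-knowledge ``network`` is given, the pooled regulators
    are connected by the known interactions among them for display.
    """
    if not setups:
        raise ValueError("at least one setup is required")
    if min_frequency is None:
        min_frequency = math.ceil(len(setups) / 2)
    freq: dict[str, set[str]] = {}
    signs: dict[str, set[int]] = {}
    for label, hyps in setups.items():
        seen: set[str] = set()
        for h in hyps:
            if isinstance(h, tuple):
                protein, sign = h
                signs.setdefault(protein, set()).add(sign)
            else:
                protein = h
            if protein not in seen:
                freq.setdefault(protein, set()).add(label)
                seen.add(protein)
    table = pd.DataFrame(
        {
            "protein": sorted(freq),
            "frequency": [len(freq[p]) for p in sorted(freq)],
            "setups": [",".join(sorted(freq[p])) for p in sorted(freq)],
            "signs": [
                ",".join(str(s) for s in sorted(signs.get(p, set())))
                for p in sorted(freq)
            ],
        }
    ).sort_values(["frequency", "protein"], ascending=[False, True]).reset_index(
        drop=True
    )
    pooled = {p for p in freq if len(freq[p]) >= min_frequency}
    display = None
    if network is not None:
        display = nx.DiGraph()
        display.add_nodes_from(sorted(pooled))
        for u, v, s in network.edges():
            if u in pooled and v in pooled:
                display.add_edge(u, v, sign=s)
    return table, pooled, display
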