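"""Signed directed protein-interaction networks.

The substrate for causal reasoning: a directed graph whose edges carry a
sign, +1 for activation and -1 for inhibition.  Only signed edges are
admitted; unsigned prior-knowledge edges must be filtered out before
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

#: SIF relation labels <-> edge signs
RELATION_TO_SIGN = {"activates": 1, "inhibits": -1}
SIGN_TO_RELATION = {1: "activates", -1: "inhibits"}


class NetworkError(ValueError):
    """Invalid network construction (self-loop, bad sign, sign conflict)."""


@dataclass
class SignedNetwork:
    """A directed graph with edge signs in {+1, -1}.

    Invariants enforced at construction: no self-loops, signs only +-1,
    and no pair of parallel edges of opposite sign between the same
    ordered node pair (a DiGraph holds one edge per ordered pair; an
    attempt to re-add with a conflicting sign raises).
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str, int]], nodes: Iterable[str] = ()
    ) -> "SignedNetwork":
        net = cls()
        for n in nodes:
            net.graph.add_node(n)
        for u, v, s in edges:
            net.add_edge(u, v, s)
        return net

    def add_edge(self, u: str, v: str, sign: int) -> None:
        if u == v:
            raise NetworkError(f"self-loop on {u!r} is not allowed")
        if sign not in (1, -1):
            raise NetworkError(f"edge sign must be +1 or -1, got {sign!r}")
        if self.graph.has_edge(u, v) and self.graph[u][v]["sign"] != sign:
            raise NetworkError(
                f"conflicting signs for edge {u!r}->{v!r}; opposite-sign "
                "parallel edges are disallowed"
            )
        self.graph.add_edge(u, v, sign=sign)

    # -- queries ------------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def edges(self) -> Iterator[tuple[str, str, int]]:
        for u, v, data in self.graph.edges(data=True):
            yield u, v, data["sign"]

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def sign(self, u: str, v: str) -> int:
        return self.graph[u][v]["sign"]

    def sign_flipped(self) -> "SignedNetwork":
        """Copy of the network with every edge sign inverted."""
        return SignedNetwork.from_edges(
            ((u, v, -s) for u, v, s in self.edges()), nodes=self.nodes
        )

    # -- SIF round trip ----------------------------------------------

    def to_sif(self, path: str | Path) -> None:
        """Write as SIF: ``source<TAB>relation<TAB>target`` per line."""
        with open(path, "w") as fh:
            for u, v, s in sorted(self.edges()):
                fh.write(f"{u}\t{SIGN_TO_RELATION[s]}\t{v}\n")

    @classmethod
    def from_sif(cls, path: str | Path) -> "SignedNetwork":
        """Read a SIF file, keeping only signed relations.

        Lines whose relation is not ``activates``/``inhibits`` (e.g.
        transcription-regulation mechanisms already excluded upstream)
        are dropped.
        """
        net = cls()
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise NetworkError(f"malformed SIF line: {line!r}")
                u, rel, v = parts
                if rel not in RELATION_TO_SIGN:
                    continue
                net.add_edge(u, v, RELATION_TO_SIGN[rel])
        return net
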