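"""Mixed graphs with endpoint marks, signs and stability scores.

A :class:`MixedGraph` represents either an undirected skeleton (all
endpoint marks ``circle``) or a partial ancestral graph (PAG) with
``arrow``/``tail``/``circle`` marks, as produced by constraint-based
causal discovery.  Each edge additionally carries a sign (+/-/0, the
sign of the continuous-continuous interaction parameter) and a
stability score in [0, 1] (fraction of data subsamples in which the
edge re-appears).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

CIRCLE = "circle"
ARROW = "arrow"
TAIL = "tail"
MARKS = (CIRCLE, ARROW, TAIL)


@dataclass
class Edge:
    a: str
    b: str
    mark_a: str = CIRCLE  # endpoint mark at node a
    mark_b: str = CIRCLE  # endpoint mark at node b
    sign: int = 0
    stability: float = float("nan")

    def mark_at(self, node: str) -> str:
        if node == self.a:
            return self.mark_a
        if node == self.b:
            return self.mark_b
        raise KeyError(node)

    def set_mark(self, node: str, mark: str) -> None:
        if mark not in MARKS:
            raise ValueError(f"unknown endpoint mark {mark!r}")
        if node == self.a:
            self.mark_a = mark
        elif node == self.b:
            self.mark_b = mark
        else:
            raise KeyError(node)

    def other(self, node: str) -> str:
        if node == self.a:
            return self.b
        if node == self.b:
            return self.a
        raise KeyError(node)


@dataclass
class MixedGraph:
    """At most one edge per node pair; node order is deterministic."""

    nodes: list[str] = field(default_factory=list)
    _edges: dict[tuple[str, str], Edge] = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        if a == b:
            raise ValueError("self-edges are not allowed")
        return (a, b) if a < b else (b, a)

    def add_node(self, node: str) -> None:
        if node not in self.nodes:
            self.nodes.append(node)

    def add_edge(self, a: str, b: str, mark_a: str = CIRCLE, mark_b: str = CIRCLE,
                 sign: int = 0, stability: float = float("nan")) -> Edge:
        self.add_node(a)
        self.add_node(b)
        key = self._key(a, b)
        if key == (a, b):
            edge = Edge(a, b, mark_a, mark_b, sign, stability)
        else:
            edge = Edge(b, a, mark_b, mark_a, sign, stability)
        self._edges[key] = edge
        return edge

    def remove_edge(self, a: str, b: str) -> None:
        del self._edges[self._key(a, b)]

    def has_edge(self, a: str, b: str) -> bool:
        return self._key(a, b) in self._edges

    def edge(self, a: str, b: str) -> Edge:
        return self._edges[self._key(a, b)]

    @property
    def edges(self) -> list[Edge]:
        return [self._edges[k] for k in sorted(self._edges)]

    def n_edges(self) -> int:
        return len(self._edges)

    def neighbors(self, node: str) -> list[str]:
        out = []
        for edge in self._edges.values():
            if edge.a == node:
                out.append(edge.b)
            elif edge.b == node:
                out.append(edge.a)
        return sorted(out)

    def skeleton_pairs(self) -> set[frozenset[str]]:
        return {frozenset(k) for k in self._edges}

    def copy(self) -> "MixedGraph":
        g = MixedGraph(list(self.nodes))
        for e in self.edges:
            g.add_edge(e.a, e.b, e.mark_a, e.mark_b, e.sign, e.stability)
        return g

    # --- export -------------------------------------------------------

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(
                e.a,
                e.b,
                mark_a=e.mark_a,
                mark_b=e.mark_b,
                sign=int(e.sign),
                stability=float(e.stability),
            )
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def write_sif(self, path) -> None:
        """Simple interaction format: a <relation> b, one edge per line."""
        with open(path, "w") as fh:
            for e in self.edges:
                rel = f"{e.mark_a}-{e.mark_b}"
                fh.write(f"{e.a}\t{rel}\t{e.b}\n")

    def write_edge_list(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("a\tb\tmark_a\tmark_b\tsign\tstability\n")
            for e in self.edges:
                fh.write(
                    f"{e.a}\t{e.b}\t{e.mark_a}\t{e.mark_b}\t{e.sign}\t{e.stability}\n"
                )
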