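"""Rooted admixture graphs: population-split trees with drift branch lengths
plus optional weighted admixture edges."""

from __future__ import annotations

import networkx as nx


class AdmixtureGraph:
    """Directed rooted graph of population splits.

    Tree edges parent->child carry a nonnegative drift length ``length``
    (variance of standardized allele-frequency change along the edge).  A node
    may additionally receive one admixture edge with weight ``w`` in (0, 1):
    the fraction of ancestry drawn from the admixture parent.  Leaves are the
    sampled populations; internal nodes are conventionally labeled a1, a2, ...
    """

    def __init__(self, root: str | None = None):
        self._g = nx.DiGraph()
        self.root = root
        if root is not None:
            self._g.add_node(root)

    # -- construction -----------------------------------------------------
    def add_tree_edge(self, parent: str, child: str, length: float) -> None:
        if length < 0:
            raise ValueError(f"drift length must be >= 0, got {length}")
        self._g.add_edge(parent, child, length=float(length), admixture=False)

    def add_admixture_edge(self, source: str, target: str, weight: float) -> None:
        if not 0 < weight < 1:
            raise ValueError(f"admixture weight must be in (0,1), got {weight}")
        self._g.add_edge(source, target, weight=float(weight), admixture=True)

    def copy(self) -> "AdmixtureGraph":
        out = AdmixtureGraph(self.root)
        out._g = self._g.copy()
        return out

    # -- views ------------------------------------------------------------
    @property
    def nodes(self):
        return list(self._g.nodes)

    def tree_edges(self) -> list[tuple[str, str, float]]:
        return [
            (u, v, d["length"])
            for u, v, d in self._g.edges(data=True)
            if not d.get("admixture", False)
        ]

    def admixture_edges(self) -> list[tuple[str, str, float]]:
        return [
            (u, v, d["weight"])
            for u, v, d in self._g.edges(data=True)
            if d.get("admixture", False)
        ]

    def leaves(self) -> list[str]:
        return [n for n in self._g.nodes if self._g.out_degree(n) == 0]

    def tree_parent(self, node: str) -> str | None:
        for u, _, d in self._g.in_edges(node, data=True):
            if not d.get("admixture", False):
                return u
        return None

    def admixture_parent(self, node: str) -> tuple[str, float] | None:
        for u, _, d in self._g.in_edges(node, data=True):
            if d.get("admixture", False):
                return u, d["weight"]
        return None

    def edge_length(self, parent: str, child: str) -> float:
        return self._g.edges[parent, child]["length"]

    def topological_nodes(self) -> list[str]:
        """Nodes ordered so every parent (tree or admixture) precedes its
        children."""
        return list(nx.topological_sort(self._g))

    def preorder(self) -> list[str]:
        """Nodes in depth-first preorder over tree edges from the root."""
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            children = [
                v for _, v, d in self._g.out_edges(n, data=True) if not d.get("admixture", False)
            ]
            stack.extend(reversed(sorted(children)))
        return out

    # -- checks -----------------------------------------------------------
    def validate(self) -> None:
        tree = nx.DiGraph(
            (u, v) for u, v, d in self._g.edges(data=True) if not d.get("admixture", False)
        )
        tree.add_nodes_from(self._g.nodes)
        if not nx.is_directed_acyclic_graph(self._g):
            raise ValueError("admixture graph contains a cycle")
        roots = [n for n in tree.nodes if tree.in_degree(n) == 0]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {roots}")
        if self.root is None:
            self.root = roots[0]
        elif self.root != roots[0]:
            raise ValueError(f"declared root {self.root} != structural root {roots[0]}")
        for n in tree.nodes:
            if n != self.root and tree.in_degree(n) != 1:
                raise ValueError(f"node {n} has {tree.in_degree(n)} tree parents")
            n_adx = sum(
                1 for *_, d in self._g.in_edges(n, data=True) if d.get("admixture", False)
            )
            if n_adx > 1:
                raise ValueError(f"node {n} has {n_adx} admixture parents")

    def strip_admixture(self) -> "AdmixtureGraph":
        out = AdmixtureGraph(self.root)
        for u, v, c in self.tree_edges():
            out.add_tree_edge(u, v, c)
        return out

    # -- serialization ----------------------------------------------------
    def to_newick(self) -> str:
        def rec(node: str) -> str:
            children = [
                v for _, v, d in self._g.out_edges(node, data=True)
                if not d.get("admixture", False)
            ]
            if not children:
                return node
            parts = [f"{rec(c)}:{self.edge_length(node, c):g}" for c in children]
            return "(" + ",".join(parts) + ")"

        if self.root is None:
            raise ValueError("graph has no root")
        if not nx.is_directed_acyclic_graph(self._g):
            raise ValueError("cyclic structure cannot be serialized")
        return rec(self.root) + ";"
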