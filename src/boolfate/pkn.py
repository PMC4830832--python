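"""Prior-knowledge networks: signed interaction graphs for topology training.

A prior-knowledge network (PKN) is a literature-curated hypothesis space: a
signed directed graph whose nodes are annotated by their experimental role
(stimulus, inhibited, measured, or hidden) and whose edges may be flagged
``fixed`` when the interaction is considered certain and exempt from
optimization.

Before training, the PKN is compressed: nodes that no stimulus can reach, or
from which no measured/inhibited node can be reached, are unobservable and
removed; chains of hidden single-input/single-output nodes are collapsed
into one edge whose sign is the product of the collapsed signs.  After
training, :func:`expand_network` re-inserts collapsed intermediates and adds
curated downstream targets, yielding a simulatable Boolean network.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .core import BooleanNetwork, synthesize_rules
from .rules import parse_rule

__all__ = ["PKNEdge", "PriorKnowledgeNetwork", "compress_pkn", "expand_network"]

ROLES = ("stimulus", "inhibited", "measured", "hidden")


@dataclass(frozen=True)
class PKNEdge:
    source: str
    sign: int
    target: str
    fixed: bool = False

    def __post_init__(self):
        if self.sign not in (1, -1):
            raise ValueError("edge sign must be +1 or -1")


class PriorKnowledgeNetwork:
    """Signed directed edges over role-annotated nodes."""

    def __init__(self, nodes: dict[str, str], edges: list[PKNEdge]):
        for name, role in nodes.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r} for node {name!r}")
        self.nodes = dict(nodes)
        pairs = [(e.source, e.target) for e in edges]
        if len(set(pairs)) != len(pairs):
            dupes = sorted({p for p in pairs if pairs.count(p) > 1})
            raise ValueError(f"duplicate edge(s) {dupes}")
        for e in edges:
            if e.source not in self.nodes or e.target not in self.nodes:
                raise ValueError(f"edge {e.source}->{e.target} references unknown node")
        for e in edges:
            if self.nodes[e.target] == "stimulus":
                raise ValueError(
                    f"stimulus node {e.target!r} must not have incoming edges")
        self.edges = list(edges)

    # -- role views --------------------------------------------------------

    def by_role(self, role: str) -> list[str]:
        return [n for n, r in self.nodes.items() if r == role]

    @property
    def stimuli(self) -> list[str]:
        return self.by_role("stimulus")

    @property
    def measured(self) -> list[str]:
        return self.by_role("measured")

    @property
    def inhibited(self) -> list[str]:
        return self.by_role("inhibited")

    @property
    def designated(self) -> set[str]:
        return {n for n, r in self.nodes.items() if r != "hidden"}

    def fixed_edges(self) -> list[PKNEdge]:
        return [e for e in self.edges if e.fixed]

    def optional_edges(self) -> list[PKNEdge]:
        return [e for e in self.edges if not e.fixed]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.source, e.target, sign=e.sign, fixed=e.fixed)
        return g

    def to_boolean_network(self, edges: list[PKNEdge] | None = None) -> BooleanNetwork:
        """Default-logic Boolean network (OR activators, AND NOT inhibitors)."""
        edges = self.edges if edges is None else edges
        rules = synthesize_rules([(e.source, e.sign, e.target) for e in edges])
        names = list(self.nodes)
        return BooleanNetwork(names, {n: r for n, r in rules.items() if n in names})

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_files(cls, sif_path, annotation_path) -> "PriorKnowledgeNetwork":
        """Load from SIF (source, sign, target, [fixed]) + node-role TSV.

        The SIF may carry an optional fourth column (1 = fixed edge).  The
        annotation TSV has columns ``node`` and ``role``.
        """
        edges = []
        nodes: dict[str, str] = {}
        with open(sif_path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) not in (3, 4):
                    raise ValueError(f"{sif_path}:{lineno}: expected 3 or 4 fields")
                fixed = len(parts) == 4 and parts[3].strip() == "1"
                edges.append(PKNEdge(parts[0], int(parts[1]), parts[2], fixed))
        with open(annotation_path, encoding="utf-8") as fh:
            header = None
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if header is None:
                    header = parts
                    if header[:2] != ["node", "role"]:
                        raise ValueError(
                            f"{annotation_path}:{lineno}: expected header 'node\\trole'")
                    continue
                nodes[parts[0]] = parts[1]
        for e in edges:
            nodes.setdefault(e.source, "hidden")
            nodes.setdefault(e.target, "hidden")
        return cls(nodes, edges)

    def write(self, sif_path, annotation_path) -> None:
        with open(sif_path, "w", encoding="utf-8") as fh:
            for e in self.edges:
                fh.write(f"{e.source}\t{e.sign}\t{e.target}\t{int(e.fixed)}\n")
        with open(annotation_path, "w", encoding="utf-8") as fh:
            fh.write("node\trole\n")
            for name, role in self.nodes.items():
                fh.write(f"{name}\t{role}\n")


def compress_pkn(pkn: PriorKnowledgeNetwork) -> PriorKnowledgeNetwork:
    """Remove unobservable nodes and collapse hidden linear chains.

    A node survives the observability pass if it is designated, or lies on
    some stimulus -> measured/inhibited path.  The collapse pass repeatedly
    replaces a hidden node with exactly one incoming and one outgoing edge by
    a direct edge whose sign is the product of the two signs (fixed only if
    both collapsed edges were fixed); collapse is skipped when it would
    duplicate an existing edge with a conflicting sign or create a self-loop.
    """
    if not pkn.stimuli:
        raise ValueError("PKN has no stimulus node")
    if not pkn.measured:
        raise ValueError("PKN has no measured node")
    g = pkn.graph()
    reachable: set[str] = set()
    for s in pkn.stimuli:
        reachable |= {s} | nx.descendants(g, s)
    observable: set[str] = set()
    for m in pkn.measured + pkn.inhibited:
        observable |= {m} | nx.ancestors(g, m)
    keep = (reachable & observable) | pkn.designated
    g = g.subgraph(keep).copy()

    changed = True
    while changed:
        changed = False
        for v in list(g.nodes):
            if pkn.nodes[v] != "hidden":
                continue
            ins = list(g.in_edges(v, data=True))
            outs = list(g.out_edges(v, data=True))
            if len(ins) != 1 or len(outs) != 1:
                continue
            (u, _, din), (_, w, dout) = ins[0], outs[0]
            if u == v or w == v or u == w:
                continue
            sign = din["sign"] * dout["sign"]
            if g.has_edge(u, w):
                if g.edges[u, w]["sign"] != sign:
                    continue  # conflicting parallel edge: keep the node
                g.remove_node(v)
            else:
                g.remove_node(v)
                g.add_edge(u, w, sign=sign, fixed=din["fixed"] and dout["fixed"])
            changed = True

    if not (set(g.nodes) - pkn.designated or any(
            pkn.nodes[n] == "measured" for n in g.nodes)):
        raise ValueError("network empty after compression; design is disconnected")
    nodes = {n: pkn.nodes[n] for n in g.nodes}
    edges = [PKNEdge(u, d["sign"], w, d["fixed"]) for u, w, d in g.edges(data=True)]
    return PriorKnowledgeNetwork(nodes, edges)


def expand_network(
    consensus: PriorKnowledgeNetwork,
    pkn: PriorKnowledgeNetwork,
    additions: list | None = None,
    transient_nodes: list[str] | None = None,
    arrest_node: str = "GrowthArrest",
) -> BooleanNetwork:
    """Re-expand a trained consensus into a simulatable Boolean network.

    ``additions`` may contain node names (hidden PKN intermediates to
    re-insert on collapsed edges, the inverse of compression) and/or explicit
    ``(source, sign, target)`` edges for curated downstream targets; new
    target nodes are created as needed.  ``transient_nodes`` receive negative
    autoregulation through a shared latching effect node: once a transient
    node has been active its effect latches on and permanently shuts the
    transient node off, giving on-then-off dynamics while preserving a
    fixed-point attractor.
    """
    additions = additions or []
    edges: dict[tuple[str, str], tuple[int, bool]] = {
        (e.source, e.target): (e.sign, e.fixed) for e in consensus.edges}
    nodes = dict(consensus.nodes)

    pkn_g = pkn.graph()
    for item in additions:
        if isinstance(item, str):  # re-insert a collapsed intermediate
            v = item
            if v not in pkn.nodes:
                raise ValueError(f"addition node {v!r} not in the PKN")
            restored = False
            for (a, c), (sign, fixed) in list(edges.items()):
                if pkn_g.has_edge(a, v) and pkn_g.has_edge(v, c):
                    s1 = pkn_g.edges[a, v]["sign"]
                    s2 = pkn_g.edges[v, c]["sign"]
                    if s1 * s2 != sign:
                        continue
                    del edges[(a, c)]
                    edges[(a, v)] = (s1, fixed)
                    edges[(v, c)] = (s2, fixed)
                    nodes[v] = pkn.nodes[v]
                    restored = True
                    break
            if not restored:
                raise ValueError(
                    f"no collapsed consensus edge matches intermediate {v!r}")
        else:
            src, sign, dst = item
            if (src, dst) in edges:
                raise ValueError(f"addition would duplicate edge {src}->{dst}")
            edges[(src, dst)] = (sign, False)
            nodes.setdefault(src, pkn.nodes.get(src, "hidden"))
            nodes.setdefault(dst, pkn.nodes.get(dst, "measured"))

    edge_list = [(s, sv[0], t) for (s, t), sv in edges.items()]
    rules = synthesize_rules(edge_list)
    names = list(nodes)

    if transient_nodes:
        for t in transient_nodes:
            if t not in names:
                raise ValueError(f"transient node {t!r} not in network")
        if arrest_node not in names:
            names.append(arrest_node)
        trigger = " | ".join(transient_nodes)
        rules[arrest_node] = parse_rule(f"{arrest_node} | {trigger}")
        for t in transient_nodes:
            base = rules.get(t)
            base_src = str(base) if base is not None else None
            if base_src:
                rules[t] = parse_rule(f"({base_src}) & !{arrest_node}")
            else:
                rules[t] = parse_rule(f"!{arrest_node} & {t}")

    return BooleanNetwork(names, {n: r for n, r in rules.items() if n in names})
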