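"""Rule co-occurrence networks.

Nodes are rule conditions (attribute = category); two conditions are linked
when they co-occur in at least one rule of the model. Edge weight sums the
support of the contributing rules (the number of correctly classified
children); the edge score is the best contributing rule's -log10
Bonferroni-adjusted hypergeometric p, binned into high/mid/low tertiles.
Both the weight and score definitions are pluggable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

from .dtable import Attribute
from .ruleinduce import Rule

_BIN_COLORS = {"high": "#d62728", "mid": "#ff9f4a", "low": "#9e9e9e"}


@dataclass(frozen=True)
class NetNode:
    condition: tuple[str, str]
    code: str  # display code, e.g. "V1"
    support: int


@dataclass(frozen=True)
class NetEdge:
    pair: tuple[tuple[str, str], tuple[str, str]]
    n_rules: int
    weight: int
    score: float
    score_bin: str


@dataclass
class RuleNetwork:
    phenotype: str
    target_class: str
    nodes: list[NetNode] = field(default_factory=list)
    edges: list[NetEdge] = field(default_factory=list)
    bin_bounds: tuple[float, float] | None = None

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(phenotype=self.phenotype, target_class=self.target_class)
        for n in self.nodes:
            g.add_node(f"{n.condition[0]}={n.condition[1]}", code=n.code, support=n.support)
        for e in self.edges:
            g.add_edge(
                f"{e.pair[0][0]}={e.pair[0][1]}",
                f"{e.pair[1][0]}={e.pair[1][1]}",
                n_rules=e.n_rules,
                weight=e.weight,
                score=e.score,
                score_bin=e.score_bin,
            )
        return g


def _display_code(cond: tuple[str, str], attrs: dict[str, Attribute]) -> str:
    attr, cat = cond
    a = attrs.get(attr)
    if a is not None and a.short_code:
        return f"{a.short_code}{cat}"
    return f"{attr}={cat}"


def _rule_score(rule: Rule) -> float:
    p = rule.p_adjusted if rule.p_adjusted is not None else 1.0
    return -math.log10(max(p, 1e-300))


def build_network(
    rules: list[Rule],
    phenotype: str = "decision",
    target_class: str | None = None,
    attributes: list[Attribute] | None = None,
) -> RuleNetwork:
    """Condition co-occurrence network for one phenotype and decision class."""
    if target_class is None:
        classes = {r.decision for r in rules}
        if len(classes) > 1:
            raise ValueError("rules span several classes; pass target_class")
        target_class = classes.pop() if classes else "affected"
    rules = [r for r in rules if r.decision == target_class]
    attr_map = {a.name: a for a in attributes or []}

    node_support: dict[tuple[str, str], int] = {}
    edge_rules: dict[tuple, list[Rule]] = {}
    for r in rules:
        for cond in r.conditions:
            node_support[cond] = node_support.get(cond, 0) + r.support
        for pair in combinations(sorted(r.conditions), 2):
            edge_rules.setdefault(pair, []).append(r)

    scores = {pair: max(_rule_score(r) for r in rs) for pair, rs in edge_rules.items()}
    bounds: tuple[float, float] | None = None
    if scores:
        vals = sorted(scores.values())
        q1 = vals[max(0, math.ceil(len(vals) / 3) - 1)]
        q2 = vals[max(0, math.ceil(2 * len(vals) / 3) - 1)]
        bounds = (q1, q2)

    def score_bin(s: float) -> str:
        if bounds is None:
            return "low"
        if s > bounds[1]:
            return "high"
        if s > bounds[0]:
            return "mid"
        return "low"

    nodes = [
        NetNode(condition=c, code=_display_code(c, attr_map), support=s)
        for c, s in sorted(node_support.items())
    ]
    edges = [
        NetEdge(
            pair=pair,
            n_rules=len(rs),
            weight=sum(r.support for r in rs),
            score=scores[pair],
            score_bin=score_bin(scores[pair]),
        )
        for pair, rs in sorted(edge_rules.items())
    ]
    return RuleNetwork(
        phenotype=phenotype, target_class=target_class, nodes=nodes, edges=edges,
        bin_bounds=bounds,
    )


# -- export / import -------------------------------------------------------

def export_network(net: RuleNetwork, path, format: str = "json") -> None:
    """Write the network losslessly as GraphML, JSON or an edge TSV."""
    if format == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    elif format == "json":
        payload = {
            "phenotype": net.phenotype,
            "target_class": net.target_class,
            "bin_bounds": list(net.bin_bounds) if net.bin_bounds else None,
            "nodes": [
                {"condition": list(n.condition), "code": n.code, "support": n.support}
                for n in net.nodes
            ],
            "edges": [
                {
                    "pair": [list(p) for p in e.pair],
                    "n_rules": e.n_rules,
                    "weight": e.weight,
                    "score": e.score,
                    "score_bin": e.score_bin,
                }
                for e in net.edges
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tn_rules\tweight\tscore\tscore_bin\n")
            for e in net.edges:
                fh.write(
                    f"{e.pair[0][0]}={e.pair[0][1]}\t{e.pair[1][0]}={e.pair[1][1]}"
                    f"\t{e.n_rules}\t{e.weight}\t{e.score:.6g}\t{e.score_bin}\n"
                )
    else:
        raise ValueError(f"unknown format {format!r}")


def load_network_json(path) -> RuleNetwork:
    with open(path) as fh:
        payload = json.load(fh)
    return RuleNetwork(
        phenotype=payload["phenotype"],
        target_class=payload["target_class"],
        bin_bounds=tuple(payload["bin_bounds"]) if payload["bin_bounds"] else None,
        nodes=[
            NetNode(condition=tuple(n["condition"]), code=n["code"], support=n["support"])
            for n in payload["nodes"]
        ],
        edges=[
            NetEdge(
                pair=tuple(tuple(p) for p in e["pair"]),
                n_rules=e["n_rules"],
                weight=e["weight"],
                score=e["score"],
                score_bin=e["score_bin"],
            )
            for e in payload["edges"]
        ],
    )


# -- rendering -------------------------------------------------------------

def edge_linewidths(net: RuleNetwork, max_width: float = 8.0) -> list[float]:
    """Chord widths proportional to edge weight (max weight -> max_width)."""
    if not net.edges:
        return []
    top = max(e.weight for e in net.edges)
    return [max_width * e.weight / top for e in net.edges]


def render_circular(net: RuleNetwork, path, figsize: float = 6.0) -> None:
    """Deterministic circular chord rendering.

    Nodes sit on a circle sorted by display code and category; chords are
    colored by score bin (high red, low grey) with width proportional to the
    number of correctly classified children.
    """
    from matplotlib.figure import Figure

    if not net.nodes:
        raise ValueError("cannot render an empty network")
    order = sorted(net.nodes, key=lambda n: (n.code, n.condition))
    angle = {
        n.condition: 2 * math.pi * i / len(order) for i, n in enumerate(order)
    }
    fig = Figure(figsize=(figsize, figsize))
    ax = fig.add_subplot(111)
    ax.set_aspect("equal")
    ax.axis("off")
    widths = edge_linewidths(net)
    for e, w in zip(net.edges, widths):
        x = [math.cos(angle[e.pair[0]]), math.cos(angle[e.pair[1]])]
        y = [math.sin(angle[e.pair[0]]), math.sin(angle[e.pair[1]])]
        ax.plot(x, y, lw=w, color=_BIN_COLORS[e.score_bin], alpha=0.7, zorder=1)
    for n in order:
        x, y = math.cos(angle[n.condition]), math.sin(angle[n.condition])
        ax.scatter([x], [y], s=60, color="black", zorder=2)
        ax.annotate(n.code, (1.08 * x, 1.08 * y), ha="center", va="center", fontsize=8)
    ax.set_xlim(-1.3, 1.3)
    ax.set_ylim(-1.3, 1.3)
    ax.set_title(f"{net.phenotype} ({net.target_class})")
    fig.savefig(path, dpi=150, bbox_inches="tight")
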