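"""Decision flow graphs: a layered, bipartite view of a rule set.

One node per distinct (attribute, value) literal, one node per kept
decision class, and one edge per (rule, literal) pair, annotated with the
rule id, support and coverage.  The graph makes equifinality visible:
several condition configurations converging on the same decision node are
alternative pathways to that outcome.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import networkx as nx

from .rules import RuleSet

__all__ = ["FlowGraph", "build_flow_graph", "to_dot", "parse_dot"]


@dataclass(frozen=True)
class FlowGraph:
    """A condition-literal -> decision-class graph projected from rules.

    The underlying graph is a multigraph: a literal shared by several rules
    of one class contributes one edge per rule, each annotated separately.
    """

    graph: nx.MultiDiGraph
    condition_nodes: tuple[tuple[str, object], ...]
    decision_nodes: tuple

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_flow_graph(rules: RuleSet) -> FlowGraph:
    """Project a rule set onto its decision flow graph.

    Condition nodes are ordered by (attribute order of first appearance,
    then value); decision nodes by order of appearance in the rule set.
    The edge count equals the total literal count of the rule set.
    """
    if not len(rules):
        raise ValueError("cannot build a flow graph from an empty rule set")
    attr_order: dict[str, int] = {}
    literals: dict[tuple[str, object], None] = {}
    decisions: dict = {}
    for rule in rules:
        for attr, value in rule.conditions:
            attr_order.setdefault(attr, len(attr_order))
            literals.setdefault((attr, value), None)
        decisions.setdefault(rule.decision, None)
    condition_nodes = tuple(
        sorted(literals, key=lambda lit: (attr_order[lit[0]], repr(lit[1])))
    )
    decision_nodes = tuple(decisions)

    g = nx.MultiDiGraph()
    for attr, value in condition_nodes:
        g.add_node(("cond", attr, value), layer="conditions")
    for value in decision_nodes:
        g.add_node(("dec", value), layer="decision")
    for rule_id, rule in enumerate(rules, start=1):
        for attr, value in rule.conditions:
            g.add_edge(
                ("cond", attr, value),
                ("dec", rule.decision),
                rule=rule_id,
                support=rule.support,
                coverage=rule.coverage,
            )
    return FlowGraph(
        graph=g, condition_nodes=condition_nodes, decision_nodes=decision_nodes
    )


def _quote(s: str) -> str:
    return '"' + s.replace('"', r"\"") + '"'


def to_dot(flow: FlowGraph) -> str:
    """Render the flow graph in DOT, layered left (conditions) to right."""
    lines = [
        "digraph decision_flow {",
        "  rankdir=LR;",
        "  node [shape=box, fontsize=10];",
        "  { rank=same;",
    ]
    for attr, value in flow.condition_nodes:
        lines.append(f"    {_quote(f'{attr} = {value}')};")
    lines.append("  }")
    lines.append("  { rank=same;")
    for value in flow.decision_nodes:
        lines.append(f"    {_quote(f'decision = {value}')} [shape=ellipse];")
    lines.append("  }")
    for u, v, data in flow.graph.edges(data=True):
        _, attr, value = u
        _, decision = v
        label = (
            f"r{data['rule']} s={data['support']} c={data['coverage']:.2%}"
        )
        lines.append(
            f"  {_quote(f'{attr} = {value}')} -> "
            f"{_quote(f'decision = {decision}')} [label={_quote(label)}];"
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


_NODE_RE = re.compile(r'^\s*"((?:[^"\\]|\\.)*)"\s*(\[[^\]]*\])?\s*;\s*$')
_EDGE_RE = re.compile(
    r'^\s*"((?:[^"\\]|\\.)*)"\s*->\s*"((?:[^"\\]|\\.)*)"\s*(\[[^\]]*\])?\s*;\s*$'
)


def parse_dot(text: str) -> tuple[set[str], list[tuple[str, str]]]:
    """Recover nodes and the edge list (with multiplicity) from DOT text
    produced by :func:`to_dot`.

    A deliberately small reader sufficient to round-trip the structural
    content of our own output.
    """
    nodes: set[str] = set()
    edges: list[tuple[str, str]] = []
    for line in text.splitlines():
        m = _EDGE_RE.match(line)
        if m:
            u, v = m.group(1), m.group(2)
            nodes.add(u)
            nodes.add(v)
            edges.append((u, v))
            continue
        m = _NODE_RE.match(line)
        if m:
            nodes.add(m.group(1))
    return nodes, edges
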