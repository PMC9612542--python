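"""Rules graph structures: factor/rule nodes, centralities, communities.

A kept rule set becomes a directed graph with one node per distinct
factor and one node per rule.  Each antecedent factor points into its
rule node, and the rule node points to its single consequent factor, so

* node count = #factors + #rules,
* edge count = sum over rules of (|LHS| + 1),
* every rule node has out-degree exactly 1 and in-degree |LHS|.

A factor's out-degree therefore counts the rules using it as an
antecedent and its in-degree the rules concluding in it.

Centralities:

* **closeness** C(x) = N / sum_y d(y, x) on the undirected projection,
  with the Wasserman–Faust reachable-set rescaling for disconnected
  graphs (isolated nodes score 0);
* **PageRank** in the classic unnormalized formulation
  PR(v) = (1 - d) + d * sum over in-neighbours u of PR(u) / outdeg(u),
  damping d = 0.85, iterated to a fixed point; a node with no incoming
  edges scores exactly 1 - d, and scores need not sum to 1.  Rank of
  dangling nodes is not redistributed.  A normalized variant
  (the stochastic-matrix PageRank) is available behind a flag for
  cross-checks.

Community structure uses Newman modularity Q on the undirected
projection (Q > 0.3 is the usual significance convention) with the
Blondel–Guillaume–Lambiotte–Lefebvre greedy agglomeration (Louvain).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .catalog import FactorCatalog
from .mining import AssociationRule


def build_graph(rules: list[AssociationRule]) -> nx.DiGraph:
    """Directed factor/rule graph for a kept rule set.

    Factor nodes are the item labels; rule nodes get stable identifiers
    ``R0001, R0002, ...`` in canonical rule order and carry the rule's
    support/confidence/lift as attributes.
    """
    if not rules:
        raise ValueError("empty rule list")
    g = nx.DiGraph()
    ordered = sorted(rules, key=lambda r: r.key)
    factors: list[str] = []
    for rule in ordered:
        for item in sorted(rule.lhs | {rule.rhs}):
            if item not in factors:
                factors.append(item)
    for item in sorted(factors):
        g.add_node(item, kind="factor")
    for i, rule in enumerate(ordered, start=1):
        rid = f"R{i:04d}"
        g.add_node(
            rid,
            kind="rule",
            label=rule.label(),
            support=rule.support,
            confidence=rule.confidence,
            lift=rule.lift,
        )
        for item in sorted(rule.lhs):
            g.add_edge(item, rid)
        g.add_edge(rid, rule.rhs)
    return g


def factor_nodes(g: nx.DiGraph) -> list[str]:
    return [n for n, d in g.nodes(data=True) if d.get("kind") == "factor"]


def rule_nodes(g: nx.DiGraph) -> list[str]:
    return [n for n, d in g.nodes(data=True) if d.get("kind") == "rule"]


def factor_degrees(g: nx.DiGraph) -> pd.DataFrame:
    """Per-factor in-degree (#rules concluding in it) and out-degree
    (#rules using it as antecedent)."""
    rows = [
        {"factor": n, "in_degree": g.in_degree(n), "out_degree": g.out_degree(n)}
        for n in factor_nodes(g)
    ]
    return pd.DataFrame(rows).sort_values("factor").reset_index(drop=True)


def closeness(g: nx.Graph) -> dict[str, float]:
    """Closeness C(x) = N / sum_y d(y,x), undirected, WF-rescaled.

    On a connected graph this is exactly N over the distance sum; on a
    disconnected one, distances are summed over x's component and scaled
    by (reachable - 1) / (N - 1) so small fragments do not dominate.
    Isolated nodes (and a 1-node graph) score 0.
    """
    u = g.to_undirected() if g.is_directed() else g
    n = u.number_of_nodes()
    out: dict[str, float] = {}
    for node in u.nodes:
        dist = nx.single_source_shortest_path_length(u, node)
        r = len(dist)  # includes the node itself at distance 0
        total = sum(dist.values())
        if r <= 1 or total == 0:
            out[node] = 0.0
        else:
            out[node] = (n / total) * ((r - 1) / (n - 1))
    return out


def pagerank(
    g: nx.DiGraph,
    d: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 1000,
    normalized: bool = False,
) -> dict[str, float]:
    """Unnormalized PageRank fixed point (see module docstring).

    With ``normalized=True`` the standard stochastic formulation from
    networkx (scores summing to 1, dangling rank redistributed) is
    returned instead, for cross-checking only.
    """
    if not 0 < d < 1:
        raise ValueError("damping factor must be in (0, 1)")
    if normalized:
        return nx.pagerank(g, alpha=d, tol=tol, max_iter=max_iter)
    nodes = list(g.nodes)
    pr = {v: 1.0 for v in nodes}
    out_deg = dict(g.out_degree())
    for _ in range(max_iter):
        new = {}
        for v in nodes:
            s = sum(pr[u] / out_deg[u] for u in g.predecessors(v))
            new[v] = (1.0 - d) + d * s
        residual = max(abs(new[v] - pr[v]) for v in nodes)
        pr = new
        if residual < tol:
            return pr
    raise RuntimeError(f"PageRank did not converge in {max_iter} iterations "
                       f"(residual {residual:.3e})")


@dataclass
class Partition:
    """A node -> module assignment with its modularity Q."""

    assignment: dict[str, int]
    n_modules: int
    q: float

    def communities(self) -> list[set[str]]:
        groups: dict[int, set[str]] = {}
        for node, mod in self.assignment.items():
            groups.setdefault(mod, set()).add(node)
        return [groups[k] for k in sorted(groups)]


def modularity(g: nx.Graph, partition: Partition | dict[str, int]) -> float:
    """Newman modularity Q of a partition on the undirected projection.

    Q = (1/2m) * sum_vw [A_vw - k_v k_w / 2m] delta(c_v, c_w), with m the
    undirected edge count and k the undirected degree.  Q is 0 for the
    trivial one-module partition and lies in [-1/2, 1].
    """
    assignment = partition.assignment if isinstance(partition, Partition) else partition
    u = g.to_undirected() if g.is_directed() else g
    missing = set(u.nodes) - set(assignment)
    if missing:
        raise ValueError(f"partition does not cover all nodes: {sorted(missing)[:5]}")
    groups: dict[int, set] = {}
    for node in u.nodes:
        groups.setdefault(assignment[node], set()).add(node)
    return float(nx.community.modularity(u, list(groups.values())))


def detect_communities(
    g: nx.Graph, seed: int = 0, resolution: float = 1.0
) -> Partition:
    """Louvain greedy modularity maximisation on the undirected projection.

    Deterministic under a fixed seed; modules are relabelled 0..k-1 by
    their lexicographically smallest member for stable output.
    """
    u = g.to_undirected() if g.is_directed() else g
    comms = nx.community.louvain_communities(u, seed=seed, resolution=resolution)
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    assignment = {node: i for i, c in enumerate(comms) for node in c}
    part = Partition(assignment=assignment, n_modules=len(comms), q=0.0)
    part.q = modularity(u, part)
    return part


def factor_contributions(
    g: nx.DiGraph,
    closeness_scores: dict[str, float],
    catalog: FactorCatalog,
    constructs: tuple[str, ...] = ("driver", "vehicle", "roadway", "environment", "crash"),
) -> dict[str, list[tuple[str, float]]]:
    """Within-construct contribution percentages ranked by closeness.

    For each construct, contribution(f) = 100 * C(f) / sum of C over the
    construct's factors present in the graph, sorted descending.
    Constructs with no factors in the graph are omitted.
    """
    present = set(factor_nodes(g))
    out: dict[str, list[tuple[str, float]]] = {}
    for construct in constructs:
        members = [f for f in catalog.items_of_construct(construct) if f in present]
        total = sum(closeness_scores.get(f, 0.0) for f in members)
        if not members or total == 0:
            continue
        ranked = sorted(
            ((f, 100.0 * closeness_scores.get(f, 0.0) / total) for f in members),
            key=lambda t: (-t[1], t[0]),
        )
        out[construct] = ranked
    return out


def centrality_frame(
    g: nx.DiGraph,
    closeness_scores: dict[str, float],
    pagerank_scores: dict[str, float],
    partition: Partition | None = None,
) -> pd.DataFrame:
    rows = []
    for node, data in g.nodes(data=True):
        rows.append(
            {
                "node": node,
                "kind": data.get("kind", ""),
                "in_degree": g.in_degree(node),
                "out_degree": g.out_degree(node),
                "closeness": closeness_scores.get(node),
                "pagerank": pagerank_scores.get(node),
                "module": partition.assignment.get(node) if partition else None,
            }
        )
    return pd.DataFrame(rows)


def export_graph(
    g: nx.DiGraph, path, partition: Partition | None = None
) -> None:
    """Write GraphML or GEXF (by extension) with analysis attributes."""
    h = g.copy()
    if partition is not None:
        nx.set_node_attributes(h, partition.assignment, "module")
    path = str(path)
    if path.endswith(".graphml"):
        nx.write_graphml(h, path)
    elif path.endswith(".gexf"):
        nx.write_gexf(h, path)
    else:
        raise ValueError("unsupported graph export format (use .graphml or .gexf)")
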