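"""Maximum-weight connected subgraph (MWCS) discovery.

Given mixed-sign node weights on an undirected graph, find the connected
induced subgraph maximising the weight sum — the "most significantly
deregulated gene module". The problem is NP-hard; :func:`solve_exact`
enumerates connected subgraphs with admissible branch-and-bound pruning
and is budgeted to small instances, while :func:`solve_heuristic` joins
the positive-weight nodes through a metric-closure Steiner structure and
scales to the graphs the synthetic benchmarks produce.

The empty module (score 0) is a legal optimum when every weight is
negative. No optimal module carries a negative-weight leaf, and both
solvers prune such leaves before returning.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx

logger = logging.getLogger(__name__)

DEFAULT_NODE_BUDGET = 25


@dataclass
class ModuleResult:
    """A connected node subset with its total weight and sign decomposition."""

    nodes: frozenset
    score: float
    n_positive: int
    n_negative: int
    method: str
    node_weights: dict = field(default_factory=dict)

    def jaccard(self, other: set) -> float:
        a, b = set(self.nodes), set(other)
        if not a and not b:
            return 1.0
        return len(a & b) / len(a | b)


def _result(nodes, weights, method: str) -> ModuleResult:
    nodes = frozenset(nodes)
    member_w = {v: weights[v] for v in nodes}
    return ModuleResult(
        nodes=nodes,
        score=sum(member_w.values()),
        n_positive=sum(1 for w in member_w.values() if w > 0),
        n_negative=sum(1 for w in member_w.values() if w < 0),
        method=method,
        node_weights=member_w,
    )


def _better(cand_nodes: frozenset, cand_score: float, best_nodes: frozenset, best_score: float) -> bool:
    """Deterministic tie-break: higher score, then fewer nodes, then id order."""
    if cand_score > best_score + 1e-12:
        return True
    if cand_score < best_score - 1e-12:
        return False
    if len(cand_nodes) != len(best_nodes):
        return len(cand_nodes) < len(best_nodes)
    return tuple(sorted(cand_nodes)) < tuple(sorted(best_nodes))


def prune_negative_leaves(graph: nx.Graph, weights: dict, nodes) -> frozenset:
    """Iteratively strip degree-1 nodes of negative weight.

    A negative-weight leaf never helps the objective, so removing leaves
    until fixpoint preserves both connectivity and optimality.
    """
    current = set(nodes)
    while True:
        sub = graph.subgraph(current)
        drop = [v for v in current if weights.get(v, 0.0) < 0 and sub.degree(v) <= 1]
        # keep singletons: a lone negative node is its own (suboptimal) module
        drop = [v for v in drop if len(current) > 1]
        if not drop:
            return frozenset(current)
        current.difference_update(drop)


def solve_exact(
    graph: nx.Graph, weights: dict, node_budget: int = DEFAULT_NODE_BUDGET
) -> ModuleResult:
    """Certified-optimal MWCS by connected-subgraph enumeration.

    Branch-and-bound with the admissible bound "current score plus all
    positive weights still reachable through unexcluded nodes". Refuses
    instances above ``node_budget`` nodes (exponential worst case).
    """
    n = graph.number_of_nodes()
    if n > node_budget:
        raise ValueError(
            f"{n} nodes exceeds the exact-search budget of {node_budget}; "
            "use solve_heuristic for larger instances"
        )
    order = sorted(graph.nodes)
    index = {v: i for i, v in enumerate(order)}
    best_nodes, best_score = frozenset(), 0.0

    def reachable_positive(selected: set, excluded: set) -> float:
        """Sum of positive weights reachable from `selected` avoiding `excluded`."""
        seen = set(selected)
        stack = list(selected)
        total = 0.0
        while stack:
            u = stack.pop()
            for v in graph.neighbors(u):
                if v in seen or v in excluded:
                    continue
                seen.add(v)
                if weights.get(v, 0.0) > 0:
                    total += weights[v]
                stack.append(v)
        return total

    def expand(selected: set, score: float, frontier: list, excluded: set) -> None:
        nonlocal best_nodes, best_score
        fs = frozenset(selected)
        if _better(fs, score, best_nodes, best_score):
            best_nodes, best_score = fs, score
        if not frontier:
            return
        if score + reachable_positive(selected, excluded) <= best_score - 1e-12:
            return
        v = frontier[0]
        rest = frontier[1:]
        # include v
        new_frontier = rest + [
            u
            for u in sorted(graph.neighbors(v), key=index.get)
            if u not in selected and u not in excluded and u not in rest
        ]
        selected.add(v)
        expand(selected, score + weights.get(v, 0.0), new_frontier, excluded)
        selected.remove(v)
        # exclude v
        excluded.add(v)
        expand(selected, score, rest, excluded)
        excluded.remove(v)

    for i, root in enumerate(order):
        # roots are tried in id order; earlier roots are excluded to avoid
        # re-enumerating the same subgraphs
        excluded = set(order[:i])
        expand({root}, weights.get(root, 0.0),
               [u for u in sorted(graph.neighbors(root), key=index.get) if u not in excluded],
               excluded)

    best_nodes = prune_negative_leaves(graph, weights, best_nodes) if best_nodes else best_nodes
    return _result(best_nodes, weights, "exact")


def strong_prune_tree(tree: nx.Graph, weights: dict) -> tuple[frozenset, float]:
    """Exact best-weight connected subtree of a tree (dynamic program).

    Rooting the tree anywhere, every connected subtree has a unique
    topmost node v, and the best subtree topped at v keeps exactly the
    children whose own best value is positive; one post-order pass
    therefore finds the global optimum.
    """
    if tree.number_of_nodes() == 0:
        return frozenset(), 0.0
    root = min(tree.nodes)
    parent = {root: None}
    order = []
    stack = [root]
    while stack:
        v = stack.pop()
        order.append(v)
        for u in tree.neighbors(v):
            if u not in parent:
                parent[u] = v
                stack.append(u)
    value: dict = {}
    kept_children: dict = {v: [] for v in tree.nodes}
    for v in reversed(order):
        val = weights.get(v, 0.0)
        for u in tree.neighbors(v):
            if parent.get(u) == v and value[u] > 0:
                val += value[u]
                kept_children[v].append(u)
        value[v] = val
    top = max(sorted(tree.nodes), key=lambda v: value[v])
    chosen = {top}
    stack = list(kept_children[top])
    while stack:
        v = stack.pop()
        chosen.add(v)
        stack.extend(kept_children[v])
    return frozenset(chosen), value[top]


def _local_improve(graph: nx.Graph, weights: dict, nodes) -> frozenset:
    """Greedy feasible improvement around a connected module.

    Repeatedly adds an adjacent node with positive weight, or a
    two-node chain (intermediate plus positive endpoint) with positive
    total, then re-prunes negative leaves; stops at a fixpoint. Every
    step keeps the module connected and strictly raises its score.
    """
    current = set(nodes)
    if not current:
        return frozenset()
    while True:
        gains = []
        boundary = {
            v for u in current for v in graph.neighbors(u) if v not in current
        }
        for v in sorted(boundary):
            w_v = weights.get(v, 0.0)
            if w_v > 1e-12:
                gains.append((w_v, (v,)))
            else:
                # chain v -> x where x is a positive node outside the module
                best_x = None
                for x in graph.neighbors(v):
                    if x in current or x == v:
                        continue
                    w_x = weights.get(x, 0.0)
                    if w_x + w_v > 1e-12 and (best_x is None or w_x > weights[best_x]):
                        best_x = x
                if best_x is not None:
                    gains.append((w_v + weights[best_x], (v, best_x)))
        if not gains:
            break
        gains.sort(key=lambda g: (-g[0], g[1]))
        current.update(gains[0][1])
    return prune_negative_leaves(graph, weights, current)


def solve_heuristic(graph: nx.Graph, weights: dict, seed: int = 0) -> ModuleResult:
    """Steiner-style heuristic MWCS.

    Positive nodes are joined pairwise by shortest paths under the edge
    cost max(0, -weight(entered node)); a minimum spanning structure over
    the metric closure of the positive nodes is expanded back to graph
    paths, strong pruning then extracts the exact best subtree of that
    structure (discarding positives whose connection cost exceeds their
    weight), and the result is compared against each single positive
    node.
    """
    positives = sorted(v for v in graph.nodes if weights.get(v, 0.0) > 0)
    if not positives:
        logger.warning("no positive-weight node; returning the empty module")
        return _result(frozenset(), weights, "heuristic")

    best_nodes, best_score = frozenset({positives[0]}), weights[positives[0]]
    for v in positives[1:]:
        fs = frozenset({v})
        if _better(fs, weights[v], best_nodes, best_score):
            best_nodes, best_score = fs, weights[v]

    # per-component metric-closure spanning structure over positive nodes
    cost = {v: max(0.0, -weights.get(v, 0.0)) for v in graph.nodes}
    digraph = nx.DiGraph()
    for a, b in graph.edges:
        digraph.add_edge(a, b, cost=cost[b])
        digraph.add_edge(b, a, cost=cost[a])

    for comp in nx.connected_components(graph):
        pos = [v for v in positives if v in comp]
        if len(pos) < 2:
            continue
        closure = nx.Graph()
        paths: dict[tuple, list] = {}
        for src in pos:
            dist, path = nx.single_source_dijkstra(digraph, src, weight="cost")
            for dst in pos:
                if dst <= src or dst not in dist:
                    continue
                closure.add_edge(src, dst, cost=dist[dst])
                paths[(src, dst)] = path[dst]
        union: set = set()
        for a, b in nx.minimum_spanning_edges(closure, weight="cost", data=False):
            union.update(paths[(min(a, b), max(a, b))])
        # spanning tree of the union under node-entry costs, then the exact
        # best subtree of that tree (strong pruning)
        union_graph = graph.subgraph(union).copy()
        for a, b in union_graph.edges:
            union_graph.edges[a, b]["cost"] = cost[a] + cost[b]
        tree = nx.minimum_spanning_tree(union_graph, weight="cost")
        cand, _ = strong_prune_tree(tree, weights)
        cand = _local_improve(graph, weights, cand)
        cand_score = sum(weights.get(v, 0.0) for v in cand)
        if _better(frozenset(cand), cand_score, best_nodes, best_score):
            best_nodes, best_score = frozenset(cand), cand_score

    return _result(best_nodes, weights, "heuristic")


def enumerate_connected_subsets(graph: nx.Graph, max_size: int | None = None):
    """Yield every connected node subset (for small oracle graphs)."""
    nodes = sorted(graph.nodes)
    max_size = max_size or len(nodes)
    for r in range(1, max_size + 1):
        for combo in itertools.combinations(nodes, r):
            if nx.is_connected(graph.subgraph(combo)):
                yield frozenset(combo)
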