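"""PPI hub-gene identification: centralities, rank aggregation, dense clusters.

Ten topological centralities (three local: MCC, MNC, Degree; seven global:
EPC, BottleNeck, EcCentricity, Closeness, Radiality, Betweenness, Stress)
rank the nodes of a protein-interaction graph.  The ten rankings are combined
by robust rank aggregation (RRA): each node's vector of normalized ranks is
scored by the minimum Beta order-statistic tail probability, Bonferroni-
corrected over list positions.  Independently, dense clusters are detected
with the MCODE procedure (k-core vertex weighting, seeded complex growth,
haircut) and scored as density × node count = 2E/(n−1).  The hub list is the
intersection of the RRA-filtered ranking and the cluster membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import factorial

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

CENTRALITY_METHODS = (
    "MCC",
    "MNC",
    "Degree",
    "EPC",
    "BottleNeck",
    "EcCentricity",
    "Closeness",
    "Radiality",
    "Betweenness",
    "Stress",
)


@dataclass
class CentralityRanking:
    scores: pd.DataFrame  # nodes x methods
    rankings: dict[str, list[str]]  # method -> nodes, best first

    def hub_list(self, rra: pd.DataFrame, p_max: float = 0.01) -> list[str]:
        """RRA-filtered hubs, ordered by ascending aggregated p."""
        sig = rra[rra["p"] < p_max].sort_values("p")
        return list(sig.index)


@dataclass
class MCODEResult:
    clusters: list[dict]  # {"nodes", "n_edges", "score"} sorted by score desc
    params: dict = field(default_factory=dict)

    def member_genes(self, min_score: float | None = None) -> list[str]:
        out: list[str] = []
        for c in self.clusters:
            if min_score is None or c["score"] >= min_score:
                out.extend(sorted(c["nodes"]))
        return out


def load_interaction_graph(edge_file, min_score: float = 0.4) -> nx.Graph:
    """Read a STRING-style edge list TSV into an undirected simple graph.

    Expects columns ``node_a``, ``node_b``, ``combined_score`` (header names
    flexible: the first two columns are taken as nodes, the last as score).
    Scores above 1 indicate the 0–1000 integer dialect and are divided by
    1000.  Edges below ``min_score`` and self-loops are dropped; duplicate
    pairs keep the maximum score.
    """
    df = pd.read_csv(edge_file, sep="\t")
    if df.shape[1] < 3:
        raise ValueError("edge file needs at least 3 columns: node_a, node_b, score")
    a, b, s = df.columns[0], df.columns[1], df.columns[-1]
    scores = pd.to_numeric(df[s], errors="coerce")
    if scores.isna().any():
        line = int(scores.index[scores.isna()][0]) + 2  # 1-based incl. header
        raise ValueError(f"malformed combined_score at line {line}")
    if (scores > 1.0).any():
        scores = scores / 1000.0
    g = nx.Graph()
    for u, v, w in zip(df[a].astype(str), df[b].astype(str), scores):
        if u == v or w < min_score:
            continue
        if g.has_edge(u, v):
            g[u][v]["combined_score"] = max(g[u][v]["combined_score"], float(w))
        else:
            g.add_edge(u, v, combined_score=float(w))
    return g


# ---------------------------------------------------------------------------
# centralities


def _mcc(g: nx.Graph) -> dict:
    score = dict.fromkeys(g, 0.0)
    for clique in nx.find_cliques(g):
        w = factorial(len(clique) - 1)
        for v in clique:
            score[v] += w
    return score


def _mnc(g: nx.Graph) -> dict:
    score = {}
    for v in g:
        nbrs = list(g.neighbors(v))
        if not nbrs:
            score[v] = 0.0
            continue
        sub = g.subgraph(nbrs)
        score[v] = float(max(len(c) for c in nx.connected_components(sub)))
    return score


def _epc(g: nx.Graph, n_real: int = 1000, retain: float = 0.5, seed: int = 0) -> dict:
    """Edge-percolated component: mean component size of each node over
    random edge-retention realizations."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(17,)))
    edges = list(g.edges())
    total = dict.fromkeys(g, 0.0)
    for _ in range(n_real):
        mask = rng.random(len(edges)) < retain
        h = nx.Graph()
        h.add_nodes_from(g)
        h.add_edges_from(e for e, keep in zip(edges, mask) if keep)
        for comp in nx.connected_components(h):
            size = float(len(comp))
            for v in comp:
                total[v] += size
    return {v: t / n_real for v, t in total.items()}


def _bfs_dag(g: nx.Graph, root) -> tuple[dict, dict, list]:
    """Shortest-path DAG from root: distances, path counts, BFS order."""
    dist = {root: 0}
    sigma = {root: 1.0}
    order = [root]
    frontier = [root]
    while frontier:
        nxt = []
        for u in frontier:
            for w in g.neighbors(u):
                if w not in dist:
                    dist[w] = dist[u] + 1
                    sigma[w] = 0.0
                    nxt.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
        order.extend(nxt)
        frontier = nxt
    return dist, sigma, order


def _bottleneck(g: nx.Graph) -> dict:
    """Count, per node, the rooted shortest-path structures in which it lies
    on more than |reachable|/4 of the root-to-leaf shortest paths.

    Uses the full shortest-path DAG per root (every shortest path counted),
    which makes the score invariant under node relabeling.
    """
    score = dict.fromkeys(g, 0.0)
    for root in g:
        dist, sigma, order = _bfs_dag(g, root)
        # paths from v down to any DAG leaf: 1 for leaves, else sum over succ
        down = dict.fromkeys(dist, 0.0)
        for u in reversed(order):
            succ = [w for w in g.neighbors(u) if dist.get(w) == dist[u] + 1]
            down[u] = 1.0 if not succ else sum(down[w] for w in succ)
        total_leaf_paths = down[root]
        cut = len(dist) / 4.0
        for v in dist:
            through = sigma[v] * down[v]  # root-to-leaf paths containing v
            if total_leaf_paths > 0 and through > cut:
                score[v] += 1.0
    return score


def _stress(g: nx.Graph) -> dict:
    """Number of shortest paths passing through each node (interior only)."""
    stress = dict.fromkeys(g, 0.0)
    for s in g:
        dist = {s: 0}
        sigma = {s: 1.0}
        order = [s]
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for w in g.neighbors(u):
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        sigma[w] = 0.0
                        nxt.append(w)
                    if dist[w] == dist[u] + 1:
                        sigma[w] += sigma[u]
            order.extend(nxt)
            frontier = nxt
        # q[v] = number of shortest paths from v to all strictly-downstream targets
        q = dict.fromkeys(dist, 0.0)
        for u in reversed(order):
            for w in g.neighbors(u):
                if dist.get(w) == dist[u] + 1:
                    q[u] += 1.0 + q[w]
        for v in dist:
            if v != s:
                stress[v] += sigma[v] * q[v]
    # every unordered (s, t) pair was counted from both endpoints
    return {v: x / 2.0 for v, x in stress.items()}


def _per_component(g: nx.Graph):
    for comp in nx.connected_components(g):
        yield g.subgraph(comp)


def _eccentricity_centrality(g: nx.Graph) -> dict:
    score = dict.fromkeys(g, 0.0)
    for sub in _per_component(g):
        if len(sub) == 1:
            continue
        ecc = nx.eccentricity(sub)
        for v, e in ecc.items():
            score[v] = 1.0 / e if e > 0 else 0.0
    return score


def _radiality(g: nx.Graph) -> dict:
    """Σ_w (diam + 1 − d(v, w)) / (n − 1) within each connected component."""
    score = dict.fromkeys(g, 0.0)
    for sub in _per_component(g):
        n = len(sub)
        if n == 1:
            continue
        sp = dict(nx.all_pairs_shortest_path_length(sub))
        diam = max(max(d.values()) for d in sp.values())
        for v in sub:
            score[v] = sum(diam + 1 - d for w, d in sp[v].items() if w != v) / (n - 1)
    return score


def compute_centralities(
    g: nx.Graph,
    methods: tuple[str, ...] = CENTRALITY_METHODS,
    epc_realizations: int = 1000,
    epc_retain: float = 0.5,
    seed: int = 0,
) -> CentralityRanking:
    """Score and rank every node under each requested centrality.

    Rankings are by descending score with lexicographic node-id tie-break.
    EPC is a seeded stochastic estimate; all other methods are deterministic.
    """
    if len(g) == 0:
        raise ValueError("empty graph")
    unknown = set(methods) - set(CENTRALITY_METHODS)
    if unknown:
        raise ValueError(f"unknown centrality methods: {sorted(unknown)}")
    fns = {
        "MCC": lambda: _mcc(g),
        "MNC": lambda: _mnc(g),
        "Degree": lambda: {v: float(d) for v, d in g.degree()},
        "EPC": lambda: _epc(g, epc_realizations, epc_retain, seed),
        "BottleNeck": lambda: _bottleneck(g),
        "EcCentricity": lambda: _eccentricity_centrality(g),
        "Closeness": lambda: nx.harmonic_centrality(g),
        "Radiality": lambda: _radiality(g),
        "Betweenness": lambda: nx.betweenness_centrality(g, normalized=False),
        "Stress": lambda: _stress(g),
    }
    scores = pd.DataFrame({m: pd.Series(fns[m]()) for m in methods})
    scores.index.name = "node"
    # descending score, stable lexicographic tie-break
    rankings = {
        m: list(scores[m].sort_index().sort_values(ascending=False,
                                                   kind="stable").index)
        for m in methods
    }
    return CentralityRanking(scores, rankings)


def rra_aggregate(
    rank_lists: list[list[str]], universe: list[str]
) -> pd.DataFrame:
    """Robust rank aggregation over ranked (sub)lists of a common universe.

    Each item's normalized ranks r = rank/|universe| (absent → 1) are sorted;
    rho = min over positions k of P(Beta(k, m−k+1) ≤ r_(k)), the probability
    that the k-th smallest of m uniform ranks is at most r_(k); the reported
    p is min(1, rho·m), a Bonferroni correction over the m positions.
    """
    if not universe:
        raise ValueError("empty universe")
    n = len(universe)
    m = len(rank_lists)
    r = np.ones((n, m))
    pos = {item: i for i, item in enumerate(universe)}
    for j, lst in enumerate(rank_lists):
        for rank, item in enumerate(lst, start=1):
            if item in pos:
                r[pos[item], j] = rank / n
    r.sort(axis=1)
    ks = np.arange(1, m + 1)
    tail = beta_dist.cdf(r, ks[None, :], (m - ks + 1)[None, :])
    rho = tail.min(axis=1)
    p = np.minimum(1.0, rho * m)
    return pd.DataFrame({"rho": rho, "p": p}, index=pd.Index(universe, name="node"))


# ---------------------------------------------------------------------------
# MCODE


def _core_weight(g: nx.Graph, v) -> float:
    """Highest-k-core density of v's closed neighborhood times the core number."""
    nodes = set(g.neighbors(v)) | {v}
    sub = g.subgraph(nodes)
    cores = nx.core_number(sub)
    k = max(cores.values())
    if k == 0:
        return 0.0
    core_nodes = [u for u, c in cores.items() if c >= k]
    h = sub.subgraph(core_nodes)
    n = len(h)
    density = 2.0 * h.number_of_edges() / (n * (n - 1)) if n > 1 else 0.0
    return k * density


def mcode_score(n_nodes: int, n_edges: int) -> float:
    """MCODE cluster score: density × node count = 2E/(n−1)."""
    if n_nodes < 2:
        raise ValueError("cluster score requires at least 2 nodes")
    return 2.0 * n_edges / (n_nodes - 1)


def mcode_cluster(
    g: nx.Graph,
    degree_cutoff: int = 2,
    node_score_cutoff: float = 0.2,
    k_core: int = 2,
    haircut: bool = True,
    max_depth: int = 100,
    score_min: float | None = None,
) -> MCODEResult:
    """MCODE dense-cluster detection.

    Vertex weighting uses the highest-k-core density of each closed
    neighborhood; complexes grow breadth-first from the highest-weight unseen
    seed, admitting neighbors whose weight is within ``node_score_cutoff`` of
    the seed weight, to ``max_depth``.  Grown complexes must contain a
    ``k_core``-core; ``haircut`` removes singly-connected nodes.  Clusters are
    scored 2E/(n−1) and filtered at ``score_min`` when given.
    """
    work = g.subgraph([v for v, d in g.degree() if d >= degree_cutoff]).copy()
    weight = {v: _core_weight(work, v) for v in work}
    seen: set = set()
    clusters = []
    for seed_node in sorted(work, key=lambda v: (-weight[v], v)):
        if seed_node in seen:
            continue
        members = {seed_node}
        frontier = [seed_node]
        threshold = weight[seed_node] * (1.0 - node_score_cutoff)
        depth = 0
        while frontier and depth < max_depth:
            nxt = []
            for u in frontier:
                for w in sorted(work.neighbors(u)):
                    if w in seen or w in members:
                        continue
                    if weight[w] >= threshold:
                        members.add(w)
                        nxt.append(w)
            frontier = nxt
            depth += 1
        seen |= members
        sub = work.subgraph(members).copy()
        if k_core > 0:
            cores = nx.core_number(sub) if len(sub) else {}
            if not cores or max(cores.values()) < k_core:
                continue
        if haircut:
            sub.remove_nodes_from([v for v, d in sub.degree() if d < 2])
        n = len(sub)
        if n < 2:
            continue
        clusters.append(
            {
                "nodes": set(sub.nodes()),
                "n_edges": sub.number_of_edges(),
                "score": mcode_score(n, sub.number_of_edges()),
            }
        )
    clusters.sort(key=lambda c: (-c["score"], -len(c["nodes"])))
    if score_min is not None:
        clusters = [c for c in clusters if c["score"] >= score_min]
    return MCODEResult(
        clusters,
        params={
            "degree_cutoff": degree_cutoff,
            "node_score_cutoff": node_score_cutoff,
            "k_core": k_core,
            "haircut": haircut,
            "max_depth": max_depth,
            "score_min": score_min,
        },
    )


def hub_intersection(list_a: list[str], list_b: list[str]) -> list[str]:
    """Set intersection ordered by ``list_a``'s order."""
    in_b = set(list_b)
    return [x for x in list_a if x in in_b]


def brute_force_centralities(g: nx.Graph) -> pd.DataFrame:
    """Independent all-pairs enumeration oracle for the path-based measures.

    Enumerates every shortest path explicitly (exponential; use on tiny
    graphs only) and recomputes Betweenness, Stress, Closeness, Radiality and
    EcCentricity from first principles.
    """
    nodes = sorted(g)
    out = pd.DataFrame(0.0, index=nodes, columns=["Betweenness", "Stress",
                                                  "Closeness", "Radiality",
                                                  "EcCentricity"])
    for sub in _per_component(g):
        members = sorted(sub)
        sp = {
            (s, t): list(nx.all_shortest_paths(sub, s, t))
            for s, t in combinations(members, 2)
        }
        dist = {pair: len(paths[0]) - 1 for pair, paths in sp.items()}
        diam = max(dist.values()) if dist else 0
        n = len(members)
        for v in members:
            bt = st = 0.0
            for (s, t), paths in sp.items():
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                st += through
                bt += through / len(paths)
            out.loc[v, "Betweenness"] = bt
            out.loc[v, "Stress"] = st
            dists = [dist[(min(v, w), max(v, w))] for w in members if w != v]
            out.loc[v, "Closeness"] = sum(1.0 / d for d in dists)
            if n > 1:
                out.loc[v, "Radiality"] = sum(diam + 1 - d for d in dists) / (n - 1)
                out.loc[v, "EcCentricity"] = 1.0 / max(dists)
    return out
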