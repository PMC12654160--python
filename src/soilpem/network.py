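"""Co-occurrence network inference and topology.

Edges are Spearman correlations between taxa passing |rho| > r_min and
p < p_max (raw, two-sided, t-approximation with tie handling).  Modules
come from seeded greedy multilevel modularity optimization (Louvain);
node roles follow the within-module degree z-score (Zi) and among-module
connectivity / participation coefficient (Pi):

    peripheral   Zi < 2.5, Pi < 0.62
    connector    Zi < 2.5, Pi > 0.62
    module_hub   Zi > 2.5, Pi < 0.62
    network_hub  Zi > 2.5, Pi > 0.62

Module hubs and network hubs are the putative keystone taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import FeatureTable, SampleMetadata, ValidationError

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


@dataclass
class EdgeCandidate:
    a: str
    b: str
    rho: float
    p: float


def correlation_screen(features: FeatureTable, r_min: float = 0.75,
                       p_max: float = 0.01, prevalence_min: float = 0.2,
                       positive_only: bool = False) -> list[EdgeCandidate]:
    """Spearman screen over all taxon pairs.

    By default signed edges are kept (|rho| > r_min); ``positive_only``
    restores the literal positive-threshold reading.  Taxa must be present
    in at least ``prevalence_min`` of samples; constant taxa are excluded
    (correlation undefined).
    """
    counts = features.counts
    n_samples = counts.shape[1]
    if n_samples < 5:
        raise ValidationError("need at least 5 samples for the screen")
    prevalent = (counts > 0).sum(axis=1) / n_samples >= prevalence_min
    kept = counts.loc[prevalent]
    variable = kept.std(axis=1) > 0
    kept = kept.loc[variable]
    ids = list(kept.index)
    if len(ids) < 2:
        return []
    rho, p = sps.spearmanr(kept.to_numpy().T)
    if np.ndim(rho) == 0:  # scipy collapses the 2-feature case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        p = np.array([[0.0, float(p)], [float(p), 0.0]])
    edges = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r = rho[i, j]
            keep = (r > r_min) if positive_only else (abs(r) > r_min)
            if keep and p[i, j] < p_max:
                edges.append(EdgeCandidate(ids[i], ids[j], float(r),
                                           float(p[i, j])))
    return edges


@dataclass
class CooccurrenceNetwork:
    graph: nx.Graph                      # edge attr: rho; node attr: domain
    modules: dict[str, int] = field(default_factory=dict)
    modularity: float = float("nan")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(edges: list[EdgeCandidate],
                  features: FeatureTable | None = None) -> CooccurrenceNetwork:
    """Assemble the undirected signed-weight graph from screened edges."""
    g = nx.Graph()
    for e in edges:
        if e.a == e.b:
            continue
        g.add_edge(e.a, e.b, rho=e.rho, p=e.p)
    if features is not None:
        domain = features.domain
        taxonomy = features.taxonomy
        for node in g.nodes:
            g.nodes[node]["domain"] = domain.get(node, "unknown")
            g.nodes[node]["taxonomy"] = taxonomy.get(node, "")
    return CooccurrenceNetwork(g)


def detect_modules(network: CooccurrenceNetwork, seed: int = 0
                   ) -> CooccurrenceNetwork:
    """Greedy multilevel (Louvain) module detection with a fixed seed.

    Modularity Q is the Newman-Girvan value of the detected partition on
    the unweighted graph.
    """
    g = network.graph
    if g.number_of_edges() == 0:
        raise ValidationError("cannot detect modules on an empty graph")
    communities = nx.community.louvain_communities(g, weight=None, seed=seed)
    modules = {node: idx for idx, comm in enumerate(communities)
               for node in comm}
    q = nx.community.modularity(g, communities, weight=None)
    return CooccurrenceNetwork(g, modules=modules, modularity=float(q))


def modularity_of_partition(graph: nx.Graph, modules: dict[str, int]) -> float:
    """Newman-Girvan Q of a given partition (unweighted)."""
    groups: dict[int, set] = {}
    for node, m in modules.items():
        groups.setdefault(m, set()).add(node)
    return float(nx.community.modularity(graph, list(groups.values()),
                                         weight=None))


def topology_metrics(network: CooccurrenceNetwork) -> dict:
    """Standard complexity metrics; path metrics on the largest component.

    Average degree (edges per node x 2) is the headline complexity index;
    clustering is the mean local clustering coefficient with degree <= 1
    nodes contributing zero.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValidationError("empty graph")
    n, m = g.number_of_nodes(), g.number_of_edges()
    metrics = {
        "n_nodes": n,
        "n_edges": m,
        "average_degree": 2.0 * m / n,
        "average_clustering": float(nx.average_clustering(g, count_zeros=True)),
    }
    giant = g.subgraph(max(nx.connected_components(g), key=len))
    if giant.number_of_nodes() > 1:
        metrics["average_path_length"] = float(
            nx.average_shortest_path_length(giant))
        metrics["diameter"] = float(nx.diameter(giant))
    else:
        metrics["average_path_length"] = 0.0
        metrics["diameter"] = 0.0
    if network.modules:
        metrics["modularity"] = network.modularity
    return metrics


@dataclass
class NodeTopology:
    zi: float
    pi: float
    role: str


def zi_pi(network: CooccurrenceNetwork,
          modules: dict[str, int] | None = None) -> pd.DataFrame:
    """Within-module degree z-score and participation coefficient per node.

    Zi standardizes a node's within-module degree over its module (a module
    with zero spread gives Zi = 0); Pi = 1 - sum_s (k_is / k_i)^2 over
    modules s, with Pi = 0 for isolated nodes.
    """
    g = network.graph
    modules = modules if modules is not None else network.modules
    missing = [n for n in g.nodes if n not in modules]
    if missing:
        raise ValidationError(f"nodes without module labels: {missing[:5]}")

    within = {}
    per_module_links: dict[str, dict[int, int]] = {}
    for node in g.nodes:
        own = modules[node]
        links: dict[int, int] = {}
        for nb in g.neighbors(node):
            links[modules[nb]] = links.get(modules[nb], 0) + 1
        per_module_links[node] = links
        within[node] = links.get(own, 0)

    by_module: dict[int, list[str]] = {}
    for node in g.nodes:
        by_module.setdefault(modules[node], []).append(node)

    rows = {}
    for mod, members in by_module.items():
        ks = np.array([within[n] for n in members], dtype=float)
        mean, sd = ks.mean(), ks.std(ddof=0)
        for node, k_own in zip(members, ks):
            zi = 0.0 if sd == 0 else (k_own - mean) / sd
            k_i = g.degree(node)
            if k_i == 0:
                pi = 0.0
            else:
                pi = 1.0 - sum((k / k_i) ** 2
                               for k in per_module_links[node].values())
            if zi > ZI_THRESHOLD and pi > PI_THRESHOLD:
                role = "network_hub"
            elif zi > ZI_THRESHOLD:
                role = "module_hub"
            elif pi > PI_THRESHOLD:
                role = "connector"
            else:
                role = "peripheral"
            rows[node] = {"module": mod, "zi": zi, "pi": pi, "role": role,
                          "degree": k_i}
    out = pd.DataFrame.from_dict(rows, orient="index")
    return out.loc[list(g.nodes)]


def extract_subnetwork(network: CooccurrenceNetwork, features: FeatureTable,
                       metadata: SampleMetadata, treatment: str
                       ) -> CooccurrenceNetwork:
    """Induced subgraph on taxa present (nonzero total count) in a treatment."""
    samples = metadata.samples_for(treatment)
    if not samples:
        raise ValidationError(f"no samples for treatment {treatment!r}")
    present = set(features.counts.index[
        features.counts[samples].sum(axis=1) > 0])
    nodes = [n for n in network.graph.nodes if n in present]
    sub = network.graph.subgraph(nodes).copy()
    modules = {n: m for n, m in network.modules.items() if n in present}
    return CooccurrenceNetwork(sub, modules=modules,
                               modularity=network.modularity)


def keystone_report(topologies: pd.DataFrame,
                    taxonomy: pd.Series | None = None,
                    domain: pd.Series | None = None) -> pd.DataFrame:
    """Module and network hubs, sorted by role then Zi, with phylum labels."""
    hubs = topologies[topologies["role"].isin(["network_hub", "module_hub"])]
    hubs = hubs.copy()
    if taxonomy is not None:
        import re
        def _phylum(t):
            m = re.search(r"p__([^;]*)", str(t))
            return m.group(1) if m and m.group(1) else "unclassified"
        hubs["phylum"] = [_phylum(taxonomy.get(n, "")) for n in hubs.index]
    if domain is not None:
        hubs["domain"] = [domain.get(n, "unknown") for n in hubs.index]
    role_rank = {"network_hub": 0, "module_hub": 1}
    hubs["_rank"] = hubs["role"].map(role_rank)
    hubs = hubs.sort_values(["_rank", "zi"], ascending=[True, False])
    return hubs.drop(columns="_rank")


def domain_node_percentages(network: CooccurrenceNetwork) -> dict[str, float]:
    """Share of network nodes contributed by each domain (percent)."""
    domains = [d for _, d in network.graph.nodes(data="domain", default="unknown")]
    total = len(domains)
    out: dict[str, float] = {}
    for d in sorted(set(domains)):
        out[d] = 100.0 * domains.count(d) / total
    return out


def write_edge_list(network: CooccurrenceNetwork, path) -> None:
    rows = [{"source": a, "target": b, "rho": d["rho"], "p": d["p"]}
            for a, b, d in network.graph.edges(data=True)]
    pd.DataFrame(rows, columns=["source", "target", "rho", "p"]).to_csv(
        path, sep="\t", index=False)


def write_graphml(network: CooccurrenceNetwork, path) -> None:
    g = network.graph.copy()
    for node, mod in network.modules.items():
        g.nodes[node]["module"] = mod
    nx.write_graphml(g, path)
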