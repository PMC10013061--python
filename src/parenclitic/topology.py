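"""Per-patient deviation-weighted networks and global topology indices.

Each patient's network has one node per variable that appears in at least one
reference pair and one undirected edge per pair present in the patient's
deviation profile, weighted by the deviation.  Deviations act as *distances*:
a larger deviation means a longer path and weaker physiological connectivity.

Standard weighted-graph definitions are used throughout:

* degree centrality of a node = strength, the sum of incident edge weights
  (the regression-derived network is undirected, so "in-degree" coincides
  with degree);
* characteristic path length = mean shortest-path distance over connected
  node pairs;
* diameter = largest finite shortest-path distance;
* global efficiency = mean of 1/d over all node pairs, with unreachable
  pairs contributing 0 (1/inf = 0);
* sd of centrality = sample (n-1) standard deviation of node strengths.

Edgeless graphs return 0 for every index.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .reference import ReferenceModelSet

#: Index columns emitted by :func:`topology_table`, in order.
INDEX_COLUMNS: tuple[str, ...] = (
    "mean_centrality",
    "sd_centrality",
    "char_path_length",
    "diameter",
    "global_efficiency",
)


@dataclass(frozen=True)
class TopologyIndices:
    degree_centrality: dict[str, float]
    mean_centrality: float
    sd_centrality: float
    char_path_length: float
    diameter: float
    global_efficiency: float


def build_network(
    profile: Mapping[str, float], refset: ReferenceModelSet
) -> nx.Graph:
    """Build a patient's deviation-weighted undirected network.

    Nodes are all variables covered by the reference set; pairs absent from
    the profile (missing data) leave their edge out, possibly isolating a
    node.  Variables in no reference pair are excluded entirely.
    """
    g = nx.Graph()
    g.add_nodes_from(refset.nodes)
    for pair in refset.pairs:
        w = profile.get(pair.key)
        if w is None or (isinstance(w, float) and np.isnan(w)):
            continue
        g.add_edge(pair.corr.x_var, pair.corr.y_var, weight=float(w))
    return g


def compute_topology(net: nx.Graph) -> TopologyIndices:
    """Global topology indices of a deviation-weighted network."""
    nodes = list(net.nodes)
    n = len(nodes)
    strength = {v: float(d) for v, d in net.degree(weight="weight")}
    degrees = np.array([strength[v] for v in nodes], dtype=float)
    mean_c = float(degrees.mean()) if n else 0.0
    sd_c = float(degrees.std(ddof=1)) if n > 1 else 0.0

    finite: list[float] = []
    inv_sum = 0.0
    n_pairs = n * (n - 1) // 2
    if net.number_of_edges() > 0:
        dist = dict(nx.all_pairs_dijkstra_path_length(net, weight="weight"))
        for u, v in combinations(nodes, 2):
            d = dist.get(u, {}).get(v)
            if d is not None:
                finite.append(d)
                if d > 0:
                    inv_sum += 1.0 / d
                # d == 0 can only arise from a zero-weight edge; a perfectly
                # conforming connection contributes nothing to inefficiency,
                # treated as infinite efficiency capped by convention at 0
                # contribution to keep indices finite.
    cpl = float(np.mean(finite)) if finite else 0.0
    diameter = float(np.max(finite)) if finite else 0.0
    efficiency = inv_sum / n_pairs if n_pairs else 0.0
    return TopologyIndices(
        degree_centrality=strength,
        mean_centrality=mean_c,
        sd_centrality=sd_c,
        char_path_length=cpl,
        diameter=diameter,
        global_efficiency=float(efficiency),
    )


def topology_table(profiles: pd.DataFrame, refset: ReferenceModelSet) -> pd.DataFrame:
    """Topology indices for every patient profile.

    Returns a frame indexed like ``profiles`` with one column per node degree
    (``degree_<var>``) followed by the global indices.
    """
    records = []
    for _, row in profiles.iterrows():
        net = build_network(row.to_dict(), refset)
        idx = compute_topology(net)
        rec = {f"degree_{v}": idx.degree_centrality.get(v, 0.0) for v in refset.nodes}
        rec.update(
            mean_centrality=idx.mean_centrality,
            sd_centrality=idx.sd_centrality,
            char_path_length=idx.char_path_length,
            diameter=idx.diameter,
            global_efficiency=idx.global_efficiency,
        )
        records.append(rec)
    return pd.DataFrame(records, index=profiles.index)
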