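"""Multi-source interactome integration and dense-module detection.

Edges from a scored STRING-like table and unscored curated sources are
canonicalized, thresholded (STRING combined score > 0.6 by default),
restricted to the regulated proteins, and deduplicated with source
provenance retained.  Significant kinases are mapped in as extra nodes
connected to their substrate proteins.  Dense modules are found with a
ClusterONE-style greedy search maximizing cohesiveness
``w_in / (w_in + w_bound + penalty * |members|)`` and kept when a one-sided
Mann--Whitney test of members' in-cluster vs out-of-cluster degrees is
significant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError

logger = logging.getLogger(__name__)

STRING_SCORE_MIN = 0.6


@dataclass
class IntegratedNetwork:
    """Undirected simple graph with node direction and edge provenance.

    Node attribute ``direction`` is one of up/down/kinase; edge attribute
    ``sources`` is a sorted tuple of contributing source labels.
    """

    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def copy(self) -> "IntegratedNetwork":
        return IntegratedNetwork(self.graph.copy())


@dataclass(frozen=True)
class ClusterResult:
    """A detected dense module with its cohesiveness and significance."""

    members: frozenset[str]
    cohesiveness: float
    p_value: float


@dataclass(frozen=True)
class TopologySummary:
    n_nodes: int
    n_edges: int
    mean_degree: float
    hub_nodes: tuple[str, ...]
    powerlaw_slope: float
    powerlaw_r2: float


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def merge_edge_sources(
    sources: Iterable[tuple[pd.DataFrame, str]],
    string_score_min: float = STRING_SCORE_MIN,
    allowed_nodes: Iterable[str] | None = None,
    node_directions: Mapping[str, str] | None = None,
) -> IntegratedNetwork:
    """Merge edge tables into one deduplicated undirected network.

    ``string_db``-labelled tables are thresholded at combined score
    strictly greater than ``string_score_min``; all edges are restricted to
    pairs with both endpoints in ``allowed_nodes`` (dropped edges are
    counted and logged -- no linker nodes are introduced).  Duplicate pairs
    are collapsed with their provenance unioned.
    """
    allowed = set(allowed_nodes) if allowed_nodes is not None else None
    provenance: dict[tuple[str, str], set[str]] = {}
    dropped = 0
    for table, label in sources:
        for row in table.itertuples(index=False):
            a, b = str(row.node_a), str(row.node_b)
            if a == b:
                continue
            if label == "string_db" and float(row.combined_score) <= string_score_min:
                continue
            if allowed is not None and (a not in allowed or b not in allowed):
                dropped += 1
                continue
            provenance.setdefault(_canonical(a, b), set()).add(label)
    if dropped:
        logger.info("merge_edge_sources: dropped %d edges outside allowed nodes", dropped)

    g = nx.Graph()
    for (a, b), labels in sorted(provenance.items()):
        g.add_edge(a, b, sources=tuple(sorted(labels)))
    if node_directions:
        for node in g.nodes:
            if node in node_directions:
                g.nodes[node]["direction"] = node_directions[node]
    return IntegratedNetwork(g)


def add_kinase_edges(
    network: IntegratedNetwork,
    kinase_results: Sequence,
    ksrs: pd.DataFrame,
    substrate_proteins: Mapping[str, str] | None = None,
) -> IntegratedNetwork:
    """Map significant kinases onto the network as extra nodes and edges.

    ``kinase_results`` must already be significance-filtered.  For every
    kinase, an edge (source ``ksr``) is added to each substrate protein
    already present in the network; substrates mapping outside the network
    are ignored.  ``substrate_proteins`` maps the KSR substrate identifiers
    to protein accessions (defaults to the part before the first ``|`` or
    ``:`` of the identifier).
    """
    out = network.copy()
    g = out.graph
    kinases = {r.kinase for r in kinase_results}
    if not kinases:
        return out

    def protein_of(substrate: str) -> str:
        if substrate_proteins is not None:
            return substrate_proteins.get(substrate, substrate)
        return substrate.split("|")[0].split(":")[0]

    existing = set(g.nodes)
    for row in ksrs.itertuples(index=False):
        if row.kinase not in kinases:
            continue
        target = protein_of(str(row.substrate))
        if target not in existing or target == row.kinase:
            continue
        if row.kinase not in g:
            g.add_node(row.kinase, direction="kinase")
        a, b = _canonical(str(row.kinase), target)
        if g.has_edge(a, b):
            prev = set(g.edges[a, b].get("sources", ()))
            g.edges[a, b]["sources"] = tuple(sorted(prev | {"ksr"}))
        else:
            g.add_edge(a, b, sources=("ksr",))
    return out


def topology_summary(
    network: IntegratedNetwork | nx.Graph, hub_fraction: float = 0.10
) -> TopologySummary:
    """Degree statistics, hubs, and a log-log power-law fit.

    Hubs are the top ``ceil(hub_fraction * N)`` nodes by degree with all
    degree ties at the cutoff included.  The power-law slope and r^2 come
    from least squares on log10(frequency) vs log10(degree) over degrees
    >= 1; they are NaN when fewer than two distinct degrees exist.
    """
    g = network.graph if isinstance(network, IntegratedNetwork) else network
    if g.number_of_nodes() == 0:
        raise ParameterError("empty network")
    if not 0.0 < hub_fraction <= 1.0:
        raise ParameterError("hub_fraction must lie in (0, 1]")
    n, e = g.number_of_nodes(), g.number_of_edges()
    degrees = dict(g.degree())
    ranked = sorted(degrees, key=lambda v: (-degrees[v], v))
    m = math.ceil(hub_fraction * n)
    cutoff = degrees[ranked[m - 1]]
    hubs = tuple(v for v in ranked if degrees[v] >= cutoff)

    vals = np.array([d for d in degrees.values() if d >= 1])
    slope, r2 = float("nan"), float("nan")
    if vals.size:
        uniq, freq = np.unique(vals, return_counts=True)
        if uniq.size >= 2:
            x = np.log10(uniq.astype(float))
            y = np.log10(freq.astype(float))
            slope_, intercept = np.polyfit(x, y, 1)
            fitted = slope_ * x + intercept
            ss_res = float(((y - fitted) ** 2).sum())
            ss_tot = float(((y - y.mean()) ** 2).sum())
            slope = float(slope_)
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return TopologySummary(
        n_nodes=n,
        n_edges=e,
        mean_degree=2.0 * e / n,
        hub_nodes=hubs,
        powerlaw_slope=slope,
        powerlaw_r2=r2,
    )


def _edge_partition(g: nx.Graph, members: set[str]) -> tuple[int, int]:
    w_in = 0
    w_bound = 0
    for u in members:
        for v in g.neighbors(u):
            if v in members:
                w_in += 1  # counted from both endpoints; halved below
            else:
                w_bound += 1
    return w_in // 2, w_bound


def cohesiveness(
    network: IntegratedNetwork | nx.Graph,
    members: Iterable[str],
    penalty: float = 2.0,
) -> float:
    """ClusterONE objective ``w_in / (w_in + w_bound + penalty * size)``.

    Unit edge weights; ``w_in`` counts edges inside ``members``,
    ``w_bound`` edges crossing the boundary.
    """
    g = network.graph if isinstance(network, IntegratedNetwork) else network
    mset = set(members)
    if not mset:
        raise ParameterError("members must be non-empty")
    outside = mset - set(g.nodes)
    if outside:
        raise ParameterError(f"members outside network: {sorted(outside)[:5]}")
    if penalty < 0:
        raise ParameterError("penalty must be non-negative")
    w_in, w_bound = _edge_partition(g, mset)
    denom = w_in + w_bound + penalty * len(mset)
    return w_in / denom if denom > 0 else 0.0


def _grow_cluster(g: nx.Graph, seed: str, penalty: float) -> set[str]:
    members = {seed}
    current = cohesiveness(g, members, penalty)
    for _ in range(10 * g.number_of_nodes() + 10):
        candidates: list[tuple[float, int, str, str]] = []
        boundary = {
            v for u in members for v in g.neighbors(u) if v not in members
        }
        for v in sorted(boundary):
            f = cohesiveness(g, members | {v}, penalty)
            candidates.append((f, 0, "add", v))
        if len(members) > 1:
            for u in sorted(members):
                f = cohesiveness(g, members - {u}, penalty)
                candidates.append((f, 1, "remove", u))
        if not candidates:
            break
        best = max(candidates, key=lambda c: (c[0], -c[1], c[3]))
        if best[0] <= current + 1e-12:
            break
        current = best[0]
        if best[2] == "add":
            members.add(best[3])
        else:
            members.remove(best[3])
    return members


def _match_coefficient(a: frozenset, b: frozenset) -> float:
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def _cluster_p_value(g: nx.Graph, members: frozenset[str]) -> float:
    in_degs, out_degs = [], []
    for u in members:
        nin = sum(1 for v in g.neighbors(u) if v in members)
        in_degs.append(nin)
        out_degs.append(g.degree(u) - nin)
    if len(set(in_degs) | set(out_degs)) == 1:
        return 1.0
    res = stats.mannwhitneyu(in_degs, out_degs, alternative="greater")
    return float(res.pvalue)


def find_clusters(
    network: IntegratedNetwork | nx.Graph,
    penalty: float = 2.0,
    min_size: int = 3,
    overlap_max: float = 0.8,
    p_max: float = 0.05,
) -> list[ClusterResult]:
    """Greedy cohesiveness clustering with overlap merging and significance.

    Seeds are taken in decreasing-degree order over nodes not yet assigned;
    each cluster grows by the single add/remove step that most increases
    cohesiveness until a local maximum.  Candidate clusters whose match
    coefficient ``|A&B|^2 / (|A||B|)`` exceeds ``overlap_max`` are merged,
    clusters smaller than ``min_size`` are discarded, and only clusters
    with Mann--Whitney p < ``p_max`` are reported.  Ties are broken
    lexicographically so the output is deterministic.
    """
    g = network.graph if isinstance(network, IntegratedNetwork) else network
    degrees = dict(g.degree())
    order = sorted(g.nodes, key=lambda v: (-degrees[v], v))
    assigned: set[str] = set()
    raw: list[frozenset[str]] = []
    for seed in order:
        if seed in assigned or degrees[seed] == 0:
            continue
        members = _grow_cluster(g, seed, penalty)
        raw.append(frozenset(members))
        assigned |= members

    # merge heavily overlapping candidates
    merged = True
    clusters = raw
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if _match_coefficient(clusters[i], clusters[j]) > overlap_max:
                    union = clusters[i] | clusters[j]
                    clusters = (
                        clusters[:i] + [union] + clusters[i + 1 : j] + clusters[j + 1 :]
                    )
                    merged = True
                    break
            if merged:
                break

    results = []
    for members in clusters:
        if len(members) < min_size:
            continue
        p = _cluster_p_value(g, members)
        if p < p_max:
            results.append(
                ClusterResult(
                    members=members,
                    cohesiveness=cohesiveness(g, members, penalty),
                    p_value=p,
                )
            )
    return sorted(results, key=lambda c: (-c.cohesiveness, sorted(c.members)))


def clusters_to_frame(clusters: Sequence[ClusterResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "members": [";".join(sorted(c.members)) for c in clusters],
            "size": [len(c.members) for c in clusters],
            "cohesiveness": [c.cohesiveness for c in clusters],
            "p_value": [c.p_value for c in clusters],
        }
    )


def network_to_sif_frame(network: IntegratedNetwork) -> pd.DataFrame:
    """Merged network as an edge table with a provenance column."""
    rows = [
        (a, b, ";".join(data.get("sources", ())))
        for a, b, data in sorted(network.graph.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["node_a", "node_b", "sources"])
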