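"""Isoform-level clustering, co-expression network, hubs, and
sense–antisense correlation screening.

Expression profiles (transcripts x time points, FPKM) are centred and
normalised per row, clustered with restarted k-means, and grouped into
developmental super-clusters.  The co-expression network connects
transcript pairs whose Pearson correlation reaches an edge-adjacency
threshold (default 0.9).  A node's degree of connectivity within its
super-cluster *sc* is m/n, where m is the number of its neighbors in
*sc* and n the size of *sc*; a super-cluster's connectivity is the
median over its members, and hubs are the most connected nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans

from .io import DomainHit


@dataclass(frozen=True)
class ClusterAssignment:
    transcript_id: str
    cluster_id: int
    supercluster_id: str | None = None


@dataclass(frozen=True)
class ConnectivityRecord:
    """Degree of connectivity of node x within super-cluster sc: m/n."""

    transcript_id: str
    supercluster_id: str
    m: int
    n: int

    @property
    def degree(self) -> float:
        return self.m / self.n


@dataclass(frozen=True)
class SenseAntisensePair:
    sense_id: str
    antisense_id: str
    r: float
    p_value: float
    significant: bool
    note: str = ""


def center_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Mean-center each row, then scale it to unit sum of squares.

    Constant rows become all-zero and are flagged with a warning.
    """
    if matrix.shape[1] < 2:
        raise ValueError("center_normalize requires at least 2 time points")
    centered = matrix.sub(matrix.mean(axis=1), axis=0)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    flat = norms == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant row(s) normalised to all-zero: "
            f"{matrix.index[flat].tolist()[:5]}...", stacklevel=2)
    safe = norms.replace(0, 1.0)
    return centered.div(safe, axis=0)


def kmeans_cluster(matrix: pd.DataFrame, k: int, iterations: int = 500,
                   seed: int = 0) -> list[ClusterAssignment]:
    """Euclidean k-means, best of ``iterations`` random restarts by WCSS.

    Each restart runs Lloyd's algorithm to convergence (tol 1e-6, at most
    300 sweeps).  Deterministic given ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > matrix.shape[0]:
        raise ValueError(f"k={k} exceeds the number of rows ({matrix.shape[0]})")
    km = KMeans(n_clusters=k, n_init=iterations, max_iter=300, tol=1e-6,
                random_state=seed)
    labels = km.fit_predict(matrix.values)
    return [ClusterAssignment(tid, int(lab))
            for tid, lab in zip(matrix.index, labels)]


def assign_superclusters(
    assignments: Sequence[ClusterAssignment],
    mapping: Mapping[int, str],
) -> list[ClusterAssignment]:
    """Group k-means clusters into named super-clusters.

    ``mapping`` must cover every cluster id present in ``assignments``.
    """
    missing = {a.cluster_id for a in assignments} - set(mapping)
    if missing:
        raise ValueError(f"super-cluster mapping missing cluster id(s) "
                         f"{sorted(missing)}")
    return [replace(a, supercluster_id=mapping[a.cluster_id])
            for a in assignments]


def build_network(matrix: pd.DataFrame, threshold: float = 0.9,
                  edge_rule: str = "signed_positive",
                  superclusters: Mapping[str, str] | None = None,
                  gene_ids: Mapping[str, str] | None = None) -> nx.Graph:
    """Threshold the all-pairs Pearson correlation matrix into a network.

    Under the default ``signed_positive`` rule an edge joins i and j iff
    r_ij >= threshold; under ``absolute``, iff \\|r_ij\\| >= threshold.
    Constant rows cannot carry a correlation and are excluded from edge
    formation with a warning.  Node attributes ``supercluster`` and
    ``gene_id`` are attached when mappings are supplied.
    """
    if edge_rule not in ("signed_positive", "absolute"):
        raise ValueError(f"unknown edge rule {edge_rule!r}")
    if matrix.shape[1] < 3:
        raise ValueError("build_network requires at least 3 time points")
    ids = list(matrix.index)
    values = matrix.values.astype(float)
    sd = values.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant row(s) excluded from edge "
            f"formation: {matrix.index[constant].tolist()[:5]}", stacklevel=2)

    g = nx.Graph(threshold=threshold, edge_rule=edge_rule)
    g.add_nodes_from(ids)
    ok = np.where(~constant)[0]
    if ok.size >= 2:
        corr = np.corrcoef(values[ok])
        strength = corr if edge_rule == "signed_positive" else np.abs(corr)
        ii, jj = np.where(np.triu(strength >= threshold, k=1))
        for a, b in zip(ii, jj):
            g.add_edge(ids[ok[a]], ids[ok[b]], weight=float(corr[a, b]))
    if superclusters:
        nx.set_node_attributes(
            g, {tid: sc for tid, sc in superclusters.items() if tid in g},
            "supercluster")
    if gene_ids:
        nx.set_node_attributes(
            g, {tid: gid for tid, gid in gene_ids.items() if tid in g},
            "gene_id")
    return g


def _supercluster_members(network: nx.Graph, supercluster: str) -> list[str]:
    return [n for n, d in network.nodes(data=True)
            if d.get("supercluster") == supercluster]


def degree_of_connectivity(network: nx.Graph, node: str,
                           supercluster: str) -> ConnectivityRecord:
    """m/n for one node: neighbors within the super-cluster over its size."""
    if node not in network:
        raise KeyError(f"unknown node {node!r}")
    members = _supercluster_members(network, supercluster)
    if not members:
        raise ValueError(f"super-cluster {supercluster!r} is empty")
    member_set = set(members)
    m = sum(1 for nb in network.neighbors(node) if nb in member_set)
    return ConnectivityRecord(node, supercluster, m=m, n=len(members))


def supercluster_connectivity(network: nx.Graph, supercluster: str) -> float:
    """Median degree of connectivity over the super-cluster's members."""
    members = _supercluster_members(network, supercluster)
    if not members:
        raise ValueError(f"super-cluster {supercluster!r} is empty")
    degrees = [degree_of_connectivity(network, n, supercluster).degree
               for n in members]
    return float(np.median(degrees))


def find_hubs(network: nx.Graph, supercluster: str, top_n: int = 5,
              dedupe_by_gene: bool = True) -> list[ConnectivityRecord]:
    """Most-connected nodes of a super-cluster, highest degree first.

    Ties break lexicographically on transcript id.  With
    ``dedupe_by_gene`` at most one transcript per gene survives (the
    best-ranked isoform; nodes lacking a ``gene_id`` attribute are never
    collapsed together).
    """
    members = _supercluster_members(network, supercluster)
    if not members:
        raise ValueError(f"super-cluster {supercluster!r} is empty")
    records = sorted(
        (degree_of_connectivity(network, n, supercluster) for n in members),
        key=lambda r: (-r.degree, r.transcript_id))
    if dedupe_by_gene:
        seen: set[str] = set()
        kept = []
        for r in records:
            gene = network.nodes[r.transcript_id].get("gene_id")
            if gene and gene in seen:
                continue
            if gene:
                seen.add(gene)
            kept.append(r)
        records = kept
    return records[:top_n]


def nearest_neighbors(network: nx.Graph, node: str) -> nx.Graph:
    """Induced sub-network on a node and its direct neighbors."""
    if node not in network:
        raise KeyError(f"unknown node {node!r}")
    return network.subgraph([node, *network.neighbors(node)]).copy()


def sense_antisense_screen(
    matrix: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    alpha: float = 0.05,
) -> tuple[list[SenseAntisensePair], dict]:
    """Pearson-correlate each sense–antisense pair over the time course.

    Two-sided p-values use the t transform with timepoints-2 degrees of
    freedom.  A pair is significant iff p < ``alpha``.  A pair with a
    constant member has no defined correlation and is flagged not
    significant with a reason.  Returns the per-pair records plus summary
    counts.
    """
    if matrix.shape[1] < 3:
        raise ValueError("the screen requires at least 3 time points")
    results: list[SenseAntisensePair] = []
    for sense_id, antisense_id in pairs:
        for tid in (sense_id, antisense_id):
            if tid not in matrix.index:
                raise KeyError(f"transcript {tid!r} absent from the matrix")
        x = matrix.loc[sense_id].values.astype(float)
        y = matrix.loc[antisense_id].values.astype(float)
        if x.std() == 0 or y.std() == 0:
            results.append(SenseAntisensePair(
                sense_id, antisense_id, float("nan"), 1.0, False,
                note="constant profile: correlation undefined"))
            continue
        r, p = sps.pearsonr(x, y)
        results.append(SenseAntisensePair(
            sense_id, antisense_id, float(r), float(p), bool(p < alpha)))
    n_sig = sum(r.significant for r in results)
    summary = {
        "n_pairs": len(results),
        "n_significant": n_sig,
        "fraction_significant": n_sig / len(results) if results else 0.0,
        "alpha": alpha,
    }
    return results, summary


def categorize_sv_domains(
    group: Sequence[str],
    hits: Iterable[DomainHit],
) -> str:
    """Categorise a splice-variant group by its conserved-domain composition.

    ``no_known_domain`` if any member has zero domains; else ``similar``
    when all members share identical domain-accession sets (hit counts
    may differ); else ``disparate``.
    """
    if len(group) < 2:
        raise ValueError("an SV group needs at least 2 transcripts")
    by_tid: dict[str, set[str]] = {tid: set() for tid in group}
    for h in hits:
        if h.transcript_id in by_tid:
            by_tid[h.transcript_id].add(h.domain_accession)
    domain_sets = list(by_tid.values())
    if any(not s for s in domain_sets):
        return "no_known_domain"
    if all(s == domain_sets[0] for s in domain_sets):
        return "similar"
    return "disparate"


def write_edge_list(network: nx.Graph, path) -> None:
    """Export edges as tab-separated id_a, id_b, weight."""
    rows = [{"id_a": a, "id_b": b, "weight": d.get("weight", float("nan"))}
            for a, b, d in network.edges(data=True)]
    pd.DataFrame(rows, columns=["id_a", "id_b", "weight"]
                 ).to_csv(path, sep="\t", index=False)


def write_graphml(network: nx.Graph, path) -> None:
    nx.write_graphml(network, path)
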