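"""K-shortest-path ensembles, node degeneracy and path summaries.

Communication between two residues is characterized by the ensemble of
the k shortest simple paths between their nodes (Yen's algorithm), with
path length the sum of -log|C| edge weights. Node degeneracy is the
fraction of ensemble paths containing each node; by construction the
source and sink have degeneracy 1. Among equal-length paths the ensemble
is ordered lexicographically by node-index sequence so results are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import NetworkError, ParameterError
from .network import CentralityProfile, ResidueNetwork

__all__ = [
    "PathEnsemble",
    "yen_k_shortest",
    "node_degeneracy",
    "nodes_per_path",
    "path_centrality_summary",
]

_TIE_EPS = 1e-9  # relative slack when grouping equal-length float paths


@dataclass(frozen=True)
class PathEnsemble:
    """Up to k loopless paths between a source and sink, shortest first."""

    source: int  # node positions within the network
    sink: int
    paths: tuple[tuple[int, ...], ...]
    lengths: np.ndarray
    k_requested: int

    @property
    def k_found(self) -> int:
        return len(self.paths)


def _path_length(weights: np.ndarray, path: tuple[int, ...]) -> float:
    return float(sum(weights[a, b] for a, b in zip(path, path[1:])))


def yen_k_shortest(
    network: ResidueNetwork, source: int, sink: int, k: int = 1000
) -> PathEnsemble:
    """The k shortest simple paths between two nodes.

    ``source``/``sink`` are node positions (use
    :meth:`ResidueNetwork.node_index` to translate residue labels). Paths
    are returned in non-decreasing length order with lexicographic
    tie-breaking; a disconnected pair yields an empty (flagged, not
    fatal) ensemble. When fewer than k simple paths exist the ensemble
    saturates.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    if source == sink:
        raise ParameterError("source and sink must differ")
    n = network.n_nodes
    if not (0 <= source < n and 0 <= sink < n):
        raise NetworkError("source or sink outside the network")
    g = network.to_networkx("distance")
    try:
        generator = nx.shortest_simple_paths(g, source, sink, weight="weight")
    except nx.NetworkXNoPath:
        generator = iter(())
    collected: list[tuple[float, tuple[int, ...]]] = []
    try:
        for path in generator:
            tpath = tuple(path)
            length = _path_length(network.weights, tpath)
            if len(collected) >= k:
                # keep pulling only while tied with the current k-th length
                kth = collected[k - 1][0]
                if length > kth + _TIE_EPS * max(1.0, abs(kth)):
                    break
            collected.append((length, tpath))
    except nx.NetworkXNoPath:
        pass
    collected.sort(key=lambda item: (item[0], item[1]))
    collected = collected[:k]
    return PathEnsemble(
        source=source,
        sink=sink,
        paths=tuple(p for _, p in collected),
        lengths=np.array([l for l, _ in collected]),
        k_requested=k,
    )


def node_degeneracy(ensemble: PathEnsemble, node_count: int) -> np.ndarray:
    """Fraction of ensemble paths in which each node appears.

    Divides by the number of paths found (not requested), matching the
    'percentage of pathways from the overall ensemble' reading; endpoints
    therefore always score 1.
    """
    if ensemble.k_found == 0:
        raise NetworkError("degeneracy undefined for an empty ensemble")
    counts = np.zeros(node_count)
    for path in ensemble.paths:
        counts[list(path)] += 1
    return counts / ensemble.k_found


def nodes_per_path(ensemble: PathEnsemble) -> dict:
    """Distribution of per-path node counts with mean and median."""
    if ensemble.k_found == 0:
        raise NetworkError("empty ensemble")
    counts = np.array([len(p) for p in ensemble.paths])
    return {
        "counts": counts,
        "mean": float(counts.mean()),
        "median": float(np.median(counts)),
    }


def _summary(values: np.ndarray) -> dict:
    return {
        "mean": float(np.mean(values)),
        "q1": float(np.percentile(values, 25)),
        "median": float(np.median(values)),
        "q3": float(np.percentile(values, 75)),
    }


def path_centrality_summary(
    ensemble: PathEnsemble,
    profile: CentralityProfile,
    weight_by_multiplicity: bool = False,
) -> dict:
    """Centrality of path-participating nodes vs the whole network.

    For both betweenness and eigenvector centrality, returns summary
    quartiles/means over (a) all network nodes and (b) the nodes on
    ensemble paths — each node once by default, or weighted by the number
    of paths it appears on with ``weight_by_multiplicity=True``.
    """
    if ensemble.k_found == 0:
        raise NetworkError("empty ensemble")
    n = len(profile.labels)
    for path in ensemble.paths:
        if max(path) >= n:
            raise NetworkError("ensemble contains a node missing from the profile")
    if weight_by_multiplicity:
        members = np.array([node for path in ensemble.paths for node in path])
    else:
        members = np.array(sorted({node for path in ensemble.paths for node in path}))
    return {
        "betweenness": {
            "network": _summary(profile.betweenness),
            "paths": _summary(profile.betweenness[members]),
        },
        "eigenvector": {
            "network": _summary(profile.eigenvector),
            "paths": _summary(profile.eigenvector[members]),
        },
    }
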