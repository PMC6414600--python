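"""Dynamic cross-correlation matrices and residue correlation networks.

The DCCM entry for residues i, j is the normalized scalar covariance of
their displacement vectors about the time mean,

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>),

computed after superposing the trajectory onto its initial structure over
the node selection (one C5' atom per nucleotide). Replicas are combined
into a consensus matrix; the network keeps an edge between residues i and
j only where a persistent-contact mask allows it, with

    w_ij = -log |C_ij|

as the communication "distance" (natural log by default, so |C| = 1 gives
weight 0 and |C| = 1/e gives weight 1). Shortest-path measures use these
distances, while eigenvector centrality uses the coupling strengths
|C_ij| themselves — smaller is closer for paths, bigger is stronger for
spectral importance. Both views live on the same network object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import NetworkError, UndefinedSipError, ZeroVarianceError
from .hbonds import ContactMask
from .structure_io import AtomSelection, Trajectory
from .superpose import superpose_frames

__all__ = [
    "DCCM",
    "ResidueNetwork",
    "CentralityProfile",
    "compute_dccm",
    "consensus_dccm",
    "build_network",
    "betweenness_profile",
    "eigenvector_profile",
    "centrality_profile",
    "sip",
]


@dataclass(frozen=True)
class DCCM:
    """Symmetric residue-residue correlation matrix with entries in [-1, 1]."""

    matrix: np.ndarray
    labels: tuple[int, ...]  # residue indices, one node per residue

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise NetworkError("DCCM must be square")
        if m.shape[0] != len(self.labels):
            raise NetworkError("DCCM labels must match matrix size")
        if np.max(np.abs(m - m.T)) > 1e-12:
            raise NetworkError("DCCM must be symmetric")
        if np.max(np.abs(np.diag(m) - 1.0)) > 1e-9:
            raise NetworkError("DCCM diagonal must be 1")
        if np.max(np.abs(m)) > 1.0 + 1e-9:
            raise NetworkError("DCCM entries must lie in [-1, 1]")
        object.__setattr__(self, "matrix", m)

    @property
    def n_nodes(self) -> int:
        return int(self.matrix.shape[0])


@dataclass(frozen=True)
class ResidueNetwork:
    """Contact-filtered weighted graph on residue (C5') nodes.

    ``weights[i, j]`` holds -log|C_ij| where an edge exists and +inf
    elsewhere; ``strengths`` holds |C_ij| on edges and 0 elsewhere.
    """

    labels: tuple[int, ...]
    adjacency: np.ndarray  # bool
    weights: np.ndarray  # -log|C|, +inf off-edge
    strengths: np.ndarray  # |C| on edges
    log_base: float = float(np.e)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def node_index(self, label: int) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise NetworkError(f"node {label} not in network") from None

    def to_networkx(self, weight_kind: str = "distance") -> nx.Graph:
        """Export as an undirected graph; 'distance' puts -log|C| on the
        ``weight`` attribute, 'strength' puts |C| there."""
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        for i, j in zip(ii.tolist(), jj.tolist()):
            w = self.weights[i, j] if weight_kind == "distance" else self.strengths[i, j]
            g.add_edge(i, j, weight=float(w))
        return g


@dataclass(frozen=True)
class CentralityProfile:
    """Betweenness and eigenvector centrality per node of one network."""

    labels: tuple[int, ...]
    betweenness: np.ndarray
    eigenvector: np.ndarray
    alpha: float  # reciprocal of the leading eigenvalue


def compute_dccm(
    trajectory: Trajectory,
    selection: AtomSelection,
    fit_selection: AtomSelection | None = None,
) -> DCCM:
    """DCCM of the selection after superposition onto the initial frame.

    One node per selected atom (use a C5' selection for one node per
    nucleotide). The superposition fits on the node selection by default;
    ``fit_selection`` lets callers pin the fit on a different atom set
    (e.g. a rigid core). A node with zero positional variance makes the
    correlation undefined and is rejected by name rather than silently
    assigned zero.
    """
    if trajectory.n_frames < 2:
        raise NetworkError("DCCM needs at least 2 frames")
    fit_idx = (fit_selection or selection).indices
    fitted = superpose_frames(trajectory.frames, trajectory.frames[0], fit_idx)
    coords = fitted[:, selection.indices, :]
    disp = coords - coords.mean(axis=0)
    # inner[i, j] = <dr_i . dr_j> over frames
    inner = np.einsum("fid,fjd->ij", disp, disp) / trajectory.n_frames
    var = np.diag(inner)
    bad = np.nonzero(var < 1e-15)[0]
    if bad.size:
        labels = trajectory.topology.residue_indices[selection.indices]
        raise ZeroVarianceError(
            f"zero positional variance at node(s) {labels[bad][:5].tolist()}: "
            "correlation undefined"
        )
    denom = np.sqrt(np.outer(var, var))
    c = inner / denom
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    labels = tuple(int(r) for r in trajectory.topology.residue_indices[selection.indices])
    return DCCM(c, labels)


def consensus_dccm(
    matrices: list[DCCM],
    mode: str = "mean",
    cutoff: float = 0.0,
) -> DCCM:
    """Combine replica DCCMs into one consensus matrix.

    ``mode='mean'`` (default) takes the element-wise mean. ``mode='masked'``
    keeps the mean entry only where |C| >= cutoff in *all* replicas and
    zeroes it elsewhere, a stricter consensus some network tooling uses.
    """
    if not matrices:
        raise NetworkError("no matrices to combine")
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != labels or m.matrix.shape != matrices[0].matrix.shape:
            raise NetworkError("consensus requires identical node sets")
    stack = np.array([m.matrix for m in matrices])
    mean = stack.mean(axis=0)
    if mode == "masked":
        keep = np.all(np.abs(stack) >= cutoff, axis=0)
        mean = np.where(keep, mean, 0.0)
        np.fill_diagonal(mean, 1.0)
    elif mode != "mean":
        raise NetworkError(f"unknown consensus mode {mode!r}")
    return DCCM(np.clip(mean, -1.0, 1.0), labels)


def build_network(
    dccm: DCCM,
    mask: ContactMask,
    log_base: float = float(np.e),
) -> ResidueNetwork:
    """Contact-filtered network with -log|C| edge weights.

    An edge (i, j) exists when the contact mask is true, i != j and
    |C_ij| > 0; its weight is -log|C_ij| (0 when |C| = 1), and a zero
    correlation simply yields no edge (infinite distance).
    """
    n = dccm.n_nodes
    mask_res = tuple(int(r) for r in mask.residue_indices)
    if mask_res != dccm.labels:
        raise NetworkError("contact mask residues do not match DCCM nodes")
    absc = np.abs(dccm.matrix)
    adjacency = mask.mask & (absc > 0.0)
    np.fill_diagonal(adjacency, False)
    adjacency = adjacency & adjacency.T
    weights = np.full((n, n), np.inf)
    with np.errstate(divide="ignore"):
        logs = -np.log(np.clip(absc, 0.0, 1.0)) / np.log(log_base)
    weights[adjacency] = logs[adjacency] + 0.0  # normalizes -0.0 at |C| = 1
    strengths = np.where(adjacency, absc, 0.0)
    return ResidueNetwork(
        labels=dccm.labels,
        adjacency=adjacency,
        weights=weights,
        strengths=strengths,
        log_base=log_base,
    )


def betweenness_profile(
    network: ResidueNetwork,
    normalized: bool = False,
    ordered: bool = False,
) -> np.ndarray:
    """Weighted-shortest-path betweenness centrality per node.

    Path lengths are sums of -log|C| edge weights. Each unordered node
    pair {i, j} (i, j != n) contributes sigma(i,j|n)/sigma(i,j), the
    fraction of geodesics through n; pairs in different components
    contribute zero. ``ordered=True`` doubles the raw values (sums over
    ordered pairs); ``normalized=True`` divides by the number of pairs for
    cross-size comparison.
    """
    if network.n_nodes == 0:
        raise NetworkError("empty network")
    g = network.to_networkx("distance")
    cb = nx.betweenness_centrality(g, weight="weight", normalized=normalized)
    values = np.array([cb[i] for i in range(network.n_nodes)])
    if ordered and not normalized:
        values = values * 2.0
    return values


def eigenvector_profile(network: ResidueNetwork) -> tuple[np.ndarray, float]:
    """Eigenvector centrality from the coupling-strength matrix.

    Solves A c = alpha^{-1} c for the leading eigenpair of the |C|-weighted
    adjacency restricted to the largest connected component (zeros
    elsewhere); the Perron vector is non-negative and is normalized to
    unit maximum. Returns (profile, alpha).
    """
    if network.n_nodes == 0:
        raise NetworkError("empty network")
    g = network.to_networkx("strength")
    components = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    comp = sorted(components[0])
    s = network.strengths[np.ix_(comp, comp)]
    evals, evecs = np.linalg.eigh(s)
    lead = evecs[:, -1]
    lam = float(evals[-1])
    if lam <= 0:
        raise NetworkError("leading eigenvalue not positive: no edges in component")
    if lead.sum() < 0:
        lead = -lead
    lead = np.clip(lead, 0.0, None)
    profile = np.zeros(network.n_nodes)
    profile[comp] = lead / lead.max()
    return profile, 1.0 / lam


def centrality_profile(network: ResidueNetwork, normalized_betweenness: bool = False) -> CentralityProfile:
    """Convenience bundle of both centrality measures for one network."""
    cb = betweenness_profile(network, normalized=normalized_betweenness)
    cei, alpha = eigenvector_profile(network)
    return CentralityProfile(
        labels=network.labels, betweenness=cb, eigenvector=cei, alpha=alpha
    )


def sip(profile_a: np.ndarray, profile_b: np.ndarray) -> float:
    """Square inner product between two per-node profiles.

    SIP = (w_A^T w_B)^2 / ((w_A^T w_A)(w_B^T w_B)), the squared cosine of
    the angle between the profiles: 1 for proportional vectors, 0 for
    orthogonal ones, invariant to positive rescaling of either side.
    """
    a = np.asarray(profile_a, dtype=float).ravel()
    b = np.asarray(profile_b, dtype=float).ravel()
    if a.size != b.size:
        raise UndefinedSipError("profiles have different lengths")
    aa = float(a @ a)
    bb = float(b @ b)
    if aa == 0.0 or bb == 0.0:
        raise UndefinedSipError("SIP undefined for an all-zero profile")
    ab = float(a @ b)
    return (ab * ab) / (aa * bb)
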