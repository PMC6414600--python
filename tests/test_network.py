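"""DCCM, consensus, network construction, centralities and SIP."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribodyn import (
    DCCM,
    SyntheticSpec,
    Trajectory,
    build_network,
    betweenness_profile,
    compute_dccm,
    consensus_dccm,
    contact_mask,
    eigenvector_profile,
    make_reference,
    make_trajectory,
    select_atoms,
    sip,
)
from ribodyn.errors import NetworkError, UndefinedSipError, ZeroVarianceError
from ribodyn.hbonds import ContactMask
from ribodyn.network import ResidueNetwork

from conftest import random_rigid_motion


def network_from_weights(weights: np.ndarray) -> ResidueNetwork:
    """Arbitrary weighted graph as a ResidueNetwork (inf = no edge)."""
    n = weights.shape[0]
    adjacency = np.isfinite(weights) & (weights >= 0)
    np.fill_diagonal(adjacency, False)
    w = np.where(adjacency, weights, np.inf)
    strengths = np.where(adjacency, np.exp(-np.where(adjacency, weights, 0.0)), 0.0)
    return ResidueNetwork(
        labels=tuple(range(1, n + 1)),
        adjacency=adjacency,
        weights=w,
        strengths=strengths,
    )


def random_weighted_graph(rng, n_nodes, p_edge=0.5):
    weights = np.full((n_nodes, n_nodes), np.inf)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                w = rng.uniform(0.1, 3.0)
                weights[i, j] = weights[j, i] = w
    return weights


def all_shortest_paths(weights, source, sink):
    """Exhaustive simple-path enumeration; returns (min length, paths)."""
    n = weights.shape[0]
    best = [np.inf]
    paths = []

    def walk(node, visited, length):
        if length > best[0] + 1e-12:
            return
        if node == sink:
            if length < best[0] - 1e-12:
                best[0] = length
                paths.clear()
            if abs(length - best[0]) <= 1e-12:
                paths.append(tuple(visited))
            return
        for nxt in range(n):
            if nxt not in visited and np.isfinite(weights[node, nxt]):
                walk(nxt, visited + [nxt], length + weights[node, nxt])

    walk(source, [source], 0.0)
    return best[0], paths


def brute_force_betweenness(weights):
    """Direct evaluation of the geodesic-fraction sum over unordered pairs."""
    n = weights.shape[0]
    values = np.zeros(n)
    for i, j in itertools.combinations(range(n), 2):
        length, paths = all_shortest_paths(weights, i, j)
        if not np.isfinite(length):
            continue
        sigma = len(paths)
        for node in range(n):
            if node in (i, j):
                continue
            through = sum(1 for p in paths if node in p)
            values[node] += through / sigma
    return values


def largest_component(network):
    """Largest connected component (ties by smallest node), as positions."""
    import networkx as nx

    g = network.to_networkx("strength")
    components = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    return np.array(sorted(components[0]))


def power_iteration(matrix, steps=20000):
    """Leading-eigenpair oracle. Iterates on the shifted matrix M + cI
    (same Perron vector) so bipartite spectra (lambda_min = -lambda_max)
    cannot make the iteration oscillate."""
    shift = float(np.abs(matrix).sum(axis=1).max()) + 1.0
    shifted = matrix + shift * np.eye(matrix.shape[0])
    vec = np.ones(matrix.shape[0])
    for _ in range(steps):
        nxt = shifted @ vec
        norm = np.linalg.norm(nxt)
        if norm == 0:
            return vec * 0.0, 0.0
        nxt /= norm
        if np.linalg.norm(nxt - vec) < 1e-15:
            vec = nxt
            break
        vec = nxt
    lam = float(vec @ matrix @ vec)
    return vec, lam


# --- DCCM ------------------------------------------------------------------


def anchored_two_mover_trajectory(antiphase=False, n_frames=600, seed=0):
    """Residues 5 and 6 translate identically (or in anti-phase); residues
    1-3 and 8-10 stay fixed and pin the superposition exactly."""
    spec = SyntheticSpec(n_residues=10, n_frames=n_frames, sigma=0.0, atom_jitter=0.0, seed=seed)
    reference = make_reference(spec)
    rng = np.random.default_rng(seed)
    motion = rng.normal(scale=0.5, size=(n_frames, 3))
    frames = np.repeat(reference.coords[None], n_frames, axis=0)
    for r, sign in ((5, 1.0), (6, -1.0 if antiphase else 1.0)):
        atoms = reference.atoms_of_residue(r)
        frames[:, atoms, :] += sign * motion[:, None, :]
    # nodes 4 and 7 get tiny noise so their variance is defined
    for r in (4, 7):
        atoms = reference.atoms_of_residue(r)
        frames[:, atoms, :] += rng.normal(scale=1e-4, size=(n_frames, 1, 3))
    traj = Trajectory(reference, frames)
    nodes = select_atoms(reference, "C5'", residues=range(4, 8))
    anchors = select_atoms(reference, "heavy", residues=[1, 2, 3, 8, 9, 10])
    return traj, nodes, anchors


def test_dccm_perfect_correlation():
    traj, nodes, anchors = anchored_two_mover_trajectory()
    dccm = compute_dccm(traj, nodes, fit_selection=anchors)
    assert dccm.matrix[1, 2] == pytest.approx(1.0, abs=1e-9)


def test_dccm_perfect_anticorrelation():
    traj, nodes, anchors = anchored_two_mover_trajectory(antiphase=True)
    dccm = compute_dccm(traj, nodes, fit_selection=anchors)
    assert dccm.matrix[1, 2] == pytest.approx(-1.0, abs=1e-9)


def test_dccm_independent_nodes_near_zero():
    spec = SyntheticSpec(n_residues=20, n_frames=10000, seed=42)
    reference = make_reference(spec)
    traj = make_trajectory(reference, spec)
    sel = select_atoms(reference, "C5'")
    dccm = compute_dccm(traj, sel)
    # residues 9 and 12 are independent by construction
    assert abs(dccm.matrix[8, 11]) < 0.05


def test_dccm_zero_variance_node_rejected():
    spec = SyntheticSpec(n_residues=6, n_frames=5, sigma=0.0, atom_jitter=0.0, seed=1)
    reference = make_reference(spec)
    frames = np.repeat(reference.coords[None], 5, axis=0)
    with pytest.raises(ZeroVarianceError):
        compute_dccm(Trajectory(reference, frames), select_atoms(reference, "C5'"))


def test_dccm_positive_semidefinite(small_trajectory, c5_selection):
    dccm = compute_dccm(small_trajectory, c5_selection)
    evals = np.linalg.eigvalsh(dccm.matrix)
    assert evals.min() >= -1e-8


def test_dccm_invariant_under_rigid_motion(small_trajectory, small_reference, c5_selection, rng):
    base = compute_dccm(small_trajectory, c5_selection)
    rot, shift = random_rigid_motion(rng)
    moved = Trajectory(small_reference, small_trajectory.frames @ rot.T + shift)
    again = compute_dccm(moved, c5_selection)
    np.testing.assert_allclose(again.matrix, base.matrix, atol=1e-9)


def test_planted_block_recovery_and_centrality():
    block = tuple(range(12, 19))
    spec = SyntheticSpec(
        n_residues=30,
        n_frames=10000,
        correlation_blocks=((block, 0.8),),
        seed=77,
    )
    reference = make_reference(spec)
    traj = make_trajectory(reference, spec)
    sel = select_atoms(reference, "C5'")
    dccm = compute_dccm(traj, sel)
    idx = [r - 1 for r in block]
    sub = dccm.matrix[np.ix_(idx, idx)]
    off = sub[~np.eye(len(idx), dtype=bool)]
    assert np.mean(off) == pytest.approx(0.8, abs=0.05)

    mask = contact_mask(traj)
    network = build_network(dccm, mask)
    profile, _ = eigenvector_profile(network)
    background = [r - 1 for r in range(5, 27) if r not in block]
    assert profile[idx].mean() > profile[background].mean()


# --- consensus -------------------------------------------------------------


def random_dccm(rng, n):
    a = rng.normal(size=(n, n + 3))
    c = np.corrcoef(a)
    return DCCM(np.clip((c + c.T) / 2, -1, 1), tuple(range(1, n + 1)))


def test_consensus_idempotent(rng):
    m = random_dccm(rng, 6)
    out = consensus_dccm([m, m])
    np.testing.assert_allclose(out.matrix, m.matrix, atol=1e-12)


def test_consensus_cancellation(rng):
    m = random_dccm(rng, 6)
    negated = DCCM(
        np.where(np.eye(6, dtype=bool), 1.0, -m.matrix), m.labels
    )
    out = consensus_dccm([m, negated])
    off = out.matrix[~np.eye(6, dtype=bool)]
    np.testing.assert_allclose(off, 0.0, atol=1e-12)
    np.testing.assert_allclose(np.diag(out.matrix), 1.0)


def test_consensus_matches_naive_mean(rng):
    matrices = [random_dccm(rng, 7) for _ in range(3)]
    out = consensus_dccm(matrices)
    naive = np.zeros((7, 7))
    for i in range(7):
        for j in range(7):
            naive[i, j] = np.mean([m.matrix[i, j] for m in matrices])
    np.testing.assert_allclose(out.matrix, naive, atol=1e-12)


def test_consensus_masked_mode(rng):
    m = random_dccm(rng, 5)
    weak = DCCM(np.eye(5), m.labels)  # off-diagonals zero
    out = consensus_dccm([m, weak], mode="masked", cutoff=0.1)
    off = out.matrix[~np.eye(5, dtype=bool)]
    np.testing.assert_allclose(off, 0.0, atol=1e-12)


def test_consensus_shape_mismatch(rng):
    with pytest.raises(NetworkError):
        consensus_dccm([random_dccm(rng, 5), random_dccm(rng, 6)])


# --- network construction --------------------------------------------------


def masked_all(n):
    return ContactMask(
        mask=np.ones((n, n), dtype=bool),
        residue_indices=np.arange(1, n + 1),
    )


def test_edge_weight_identities():
    c = np.eye(3)
    c[0, 1] = c[1, 0] = 1.0
    c[0, 2] = c[2, 0] = np.exp(-1.0)
    c[1, 2] = c[2, 1] = 0.5
    dccm = DCCM(c, (1, 2, 3))
    network = build_network(dccm, masked_all(3))
    assert network.weights[0, 1] == pytest.approx(0.0, abs=1e-12)
    assert network.weights[0, 2] == pytest.approx(1.0, abs=1e-12)
    assert network.weights[1, 2] == pytest.approx(0.6931471805599453, abs=1e-12)


def test_zero_correlation_gives_no_edge():
    c = np.eye(3)
    c[0, 1] = c[1, 0] = 0.0
    c[0, 2] = c[2, 0] = 0.4
    c[1, 2] = c[2, 1] = 0.4
    network = build_network(DCCM(c, (1, 2, 3)), masked_all(3))
    assert not network.adjacency[0, 1]
    assert np.isinf(network.weights[0, 1])


def test_contact_filter_blocks_edges():
    c = np.full((3, 3), 0.9)
    np.fill_diagonal(c, 1.0)
    mask = masked_all(3)
    blocked = mask.mask.copy()
    blocked[0, 2] = blocked[2, 0] = False
    network = build_network(
        DCCM(c, (1, 2, 3)),
        ContactMask(mask=blocked, residue_indices=np.arange(1, 4)),
    )
    assert network.adjacency[0, 1] and not network.adjacency[0, 2]


def test_weight_monotone_in_correlation():
    rng = np.random.default_rng(0)
    for _ in range(20):
        c1, c2 = sorted(rng.uniform(0.05, 1.0, size=2))
        assert -np.log(c2) <= -np.log(c1)


# --- betweenness -----------------------------------------------------------


def test_path_graph_betweenness():
    weights = np.full((3, 3), np.inf)
    weights[0, 1] = weights[1, 0] = 1.0
    weights[1, 2] = weights[2, 1] = 1.0
    values = betweenness_profile(network_from_weights(weights))
    np.testing.assert_allclose(values, [0.0, 1.0, 0.0])


def test_four_cycle_betweenness():
    weights = np.full((4, 4), np.inf)
    for i, j in ((0, 1), (1, 2), (2, 3), (3, 0)):
        weights[i, j] = weights[j, i] = 1.0
    values = betweenness_profile(network_from_weights(weights))
    np.testing.assert_allclose(values, 0.5)


def test_betweenness_matches_brute_force_on_random_graphs():
    rng = np.random.default_rng(99)
    for trial in range(200):
        n = int(rng.integers(3, 9))
        weights = random_weighted_graph(rng, n)
        network = network_from_weights(weights)
        values = betweenness_profile(network)
        expected = brute_force_betweenness(weights)
        np.testing.assert_allclose(values, expected, atol=1e-9)


def test_betweenness_ordered_doubles():
    weights = np.full((3, 3), np.inf)
    weights[0, 1] = weights[1, 0] = 1.0
    weights[1, 2] = weights[2, 1] = 1.0
    network = network_from_weights(weights)
    unordered = betweenness_profile(network)
    ordered = betweenness_profile(network, ordered=True)
    np.testing.assert_allclose(ordered, 2 * unordered)


# --- eigenvector centrality ------------------------------------------------


def test_two_node_symmetry():
    weights = np.full((2, 2), np.inf)
    weights[0, 1] = weights[1, 0] = 0.3
    profile, alpha = eigenvector_profile(network_from_weights(weights))
    np.testing.assert_allclose(profile, [1.0, 1.0], atol=1e-12)
    assert alpha > 0


def test_star_center_dominates():
    weights = np.full((4, 4), np.inf)
    for leaf in (1, 2, 3):
        weights[0, leaf] = weights[leaf, 0] = 0.5
    profile, _ = eigenvector_profile(network_from_weights(weights))
    assert profile[0] == pytest.approx(1.0)
    assert np.all(profile[1:] < 1.0)


def test_eigenvector_matches_power_iteration():
    rng = np.random.default_rng(7)
    for trial in range(50):
        weights = random_weighted_graph(rng, 8, p_edge=0.7)
        network = network_from_weights(weights)
        if not network.adjacency.any():
            continue  # edgeless graph: eigenvector centrality undefined
        profile, alpha = eigenvector_profile(network)
        on = largest_component(network)
        if on.size < 2:
            continue
        vec, lam = power_iteration(network.strengths[np.ix_(on, on)])
        if lam <= 1e-12:
            continue
        expected = np.abs(vec) / np.abs(vec).max()
        np.testing.assert_allclose(profile[on], expected, atol=1e-8)
        assert alpha == pytest.approx(1.0 / lam, rel=1e-8)
        off = np.setdiff1d(np.arange(network.n_nodes), on)
        np.testing.assert_array_equal(profile[off], 0.0)


def test_disconnected_component_zeros():
    weights = np.full((5, 5), np.inf)
    weights[0, 1] = weights[1, 0] = 0.2
    weights[1, 2] = weights[2, 1] = 0.2
    weights[3, 4] = weights[4, 3] = 0.2
    profile, _ = eigenvector_profile(network_from_weights(weights))
    assert profile[3] == 0.0 and profile[4] == 0.0
    assert profile[1] == pytest.approx(1.0)


# --- SIP -------------------------------------------------------------------


def test_sip_identities():
    assert sip(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0])) == pytest.approx(1.0)
    assert sip(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(0.0)
    assert sip(np.array([1.0, 2.0]), np.array([2.0, 1.0])) == pytest.approx(0.64)


def test_sip_zero_vector_rejected():
    with pytest.raises(UndefinedSipError):
        sip(np.zeros(3), np.ones(3))
    with pytest.raises(UndefinedSipError):
        sip(np.ones(3), np.ones(4))


@settings(deadline=None, derandomize=True)
@given(
    st.lists(st.floats(min_value=-10, max_value=10), min_size=2, max_size=20),
    st.floats(min_value=0.01, max_value=100.0),
    st.floats(min_value=0.01, max_value=100.0),
)
def test_sip_scale_invariance(values, scale_a, scale_b):
    a = np.array(values)
    if not np.any(np.abs(a) > 1e-6):
        a[0] = 1.0
    b = a[::-1].copy()
    base = sip(a, b)
    assert sip(scale_a * a, scale_b * b) == pytest.approx(base, rel=1e-9, abs=1e-12)
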