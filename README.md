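# ribodyn

Trajectory analysis for RNA riboswitch dynamics: substructure RMSD/RMSF,
geometric hydrogen-bond occupancy, C5′ principal component analysis, residue
correlation networks and k-shortest-path communication ensembles — with a
synthetic-trajectory generator that plants known statistics so every stage of
the pipeline can be verified quantitatively at desk scale.

## Who this is for

Groups studying ligand-dependent RNA dynamics (e.g. the thiamine-pyrophosphate
riboswitch aptamer, whose P1–P5 stems, loops and junctions respond to
metabolite binding) typically compare apo and holo simulation ensembles
through a standard chain of analyses. `ribodyn` implements that chain as a
tested, scriptable library over plain-text inputs (PDB topologies, multi-model
PDB trajectories, `name: range` substructure annotations), so the statistics
behind the usual tables and figures are reproducible and auditable.

## The analyses

- **RMSD per substructure** — each frame is least-squares superposed (Kabsch)
  onto the initial structure *using the substructure's own heavy atoms*, and
  the heavy-atom RMSD of that region is reported as mean (SD) over frames.
- **RMSF** — fluctuation about the time-average structure after fitting every
  frame to the average, per atom or aggregated per residue.
- **Hydrogen bonds** — the geometric criterion: donor–acceptor heavy-atom
  distance < 3.5 Å and D–H···A deviation from linearity ≤ 30°; occupancy is
  the percentage of frames satisfying it.
- **PCA** — eigendecomposition of the 3N×3N covariance of C5′ coordinates
  after removing rotation/translation; fractional variances, projections,
  per-PC RMSF, and complete-linkage clustering in the PC1–PC2 plane.
- **Correlation network** — the dynamic cross-correlation matrix
  C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) on C5′ nodes, filtered by a
  persistent-contact mask (heavy atoms within 4.5 Å for ≥ 75 % of frames),
  with edge weights w_ij = −log |C_ij|. Betweenness centrality
  c_B(n) = Σ_{i≠j≠n} σ(i,j|n)/σ(i,j) uses these weights as path lengths;
  eigenvector centrality solves A c = α⁻¹ c on the |C|-weighted adjacency.
  Profiles are compared across states by the square inner product
  SIP = (w_Aᵀw_B)² / ((w_Aᵀw_A)(w_Bᵀw_B)).
- **Communication paths** — Yen's k-shortest simple paths (k = 1000 by
  default) between chosen residues; node degeneracy is the fraction of
  ensemble paths containing each node.

## Worked example

Two synthetic states of a 30-residue chain: the "holo" state strengthens an
internal correlation block (0.5 → 0.8) and a long-range planted hydrogen bond
(68 % → 90 % occupancy), mimicking ligand-stabilized coupling.

```python
import numpy as np
from ribodyn import (SyntheticSpec, make_reference, make_trajectory, select_atoms,
                     compute_dccm, contact_mask, build_network, centrality_profile,
                     hbond_occupancy, yen_k_shortest, sip, fit_pca)
from ribodyn.paths import node_degeneracy

apo = SyntheticSpec(n_residues=30, n_frames=2000,
                    correlation_blocks=(((12, 13, 14, 15, 16), 0.5),),
                    hbond_schedule=(((12, "N2"), (23, "O2"), 0.68),), seed=101)
holo = SyntheticSpec(n_residues=30, n_frames=2000,
                     correlation_blocks=(((12, 13, 14, 15, 16), 0.8),),
                     hbond_schedule=(((12, "N2"), (23, "O2"), 0.90),), seed=102)

profiles = {}
for name, spec in (("apo", apo), ("holo", holo)):
    ref = make_reference(spec)
    traj = make_trajectory(ref, spec)
    nodes = select_atoms(ref, "C5'")
    dccm = compute_dccm(traj, nodes)
    mask = contact_mask(traj)                      # 4.5 A, 75% persistence
    network = build_network(dccm, mask)            # w_ij = -log|C_ij|
    profiles[name] = centrality_profile(network)
    occ = hbond_occupancy(traj, [((12, "N2"), (23, "O2"))])[0]
    model = fit_pca(traj, nodes)
    ens = yen_k_shortest(network, network.node_index(8), network.node_index(23), k=200)
    deg = node_degeneracy(ens, network.n_nodes)
    block = dccm.matrix[11:16, 11:16]
    mean_c = (block.sum() - 5) / 20
    print(f"{name}: block <C>={mean_c:.2f}  occupancy={occ.occupancy:.0f}%  "
          f"PC1 var={100*model.fractional_variance[0]:.1f}%  "
          f"paths={ens.k_found}  mean degeneracy={deg.mean():.2f}")

s = sip(profiles["apo"].betweenness, profiles["holo"].betweenness)
print(f"SIP(apo, holo) betweenness = {s:.2f}")
```

Output:

```
apo: block <C>=0.50  occupancy=68%  PC1 var=46.4%  paths=1  mean degeneracy=0.53
holo: block <C>=0.80  occupancy=90%  PC1 var=48.1%  paths=2  mean degeneracy=0.37
SIP(apo, holo) betweenness = 0.67
```

The planted block correlations and occupancies are recovered exactly at the
expected sampling precision; in the holo state the stabilized long-range
contact opens a second, shorter communication route between residues 8 and 23
(two paths instead of one), and the SIP of 0.67 quantifies how much ligand
binding reshapes the betweenness profile.

The same analyses are available from the shell:

```sh
ribodyn synth --spec examples/spec.yaml --out bundle/
ribodyn pipeline run --config examples/demo_config.yaml
ribodyn paths --traj bundle/trajectory.pdb --ref bundle/reference.pdb \
    --source 8 --sink 23 --k 1000
```

## Layout

```
src/ribodyn/
  structure_io.py   PDB/annotation I/O, selections, trajectories
  superpose.py      Kabsch superposition, RMSD series, RMSF profiles
  hbonds.py         H-bond criterion, occupancy, distances, contact masks
  pca.py            covariance PCA, projections, PC1-PC2 clustering
  network.py        DCCM, consensus, -log|C| networks, centralities, SIP
  paths.py          Yen ensembles, node degeneracy, path summaries
  synthetic.py      planted-statistics trajectory generator
  crystal.py        sequence-alignment pairing of homologous structures
  pipeline.py       multi-system orchestration + comparison reports
  cli.py            `ribodyn` command-line interface
```

See `docs/methods.md` for the statistical model behind the synthetic
generator, the numerical conventions, and known limitations.
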