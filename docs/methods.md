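# Methods

This note documents the statistical model behind `ribodyn`'s synthetic
trajectory generator, the conventions and parameters of each analysis
stage, the numerical choices that affect reproducibility, and the known
limitations of what the desk-scale tests demonstrate.

## What the synthetic generator emulates — and what it does not

The generator is a *statistical emulator* of a solvated-RNA simulation, not
a simulator: there is no force field, no integrator, no solvent, and no
temporal autocorrelation (frames are i.i.d. draws). It reproduces the
statistical structure that the downstream analyses consume:

- **Geometry.** Residues sit on an ideal helix (radius 9 Å, rise 1.5 Å,
  twist 20°/residue) and carry a small nucleotide-like template — backbone
  P/O5′/C5′/C1′, a base-like N1, a polar donor N2 with its hydrogen H21,
  and an acceptor O2. Consecutive residues are ~2.6 Å apart at closest
  approach so the 4.5 Å persistent-contact mask shows the banded structure
  of a folded chain; residues three or more apart start beyond 9 Å.
- **Correlated fluctuations.** Residue displacements follow a one-factor-
  per-block Gaussian model: inside a block with target correlation ρ, the
  displacement of residue i is σ(√ρ·z + √(1−ρ)·ε_i) with a shared 3-D
  factor z and independent ε_i, giving pairwise correlation exactly ρ.
  A two-residue block may request negative ρ through an anti-phase loading.
  Atoms move rigidly with their residue plus independent jitter
  (0.05 Å), and σ defaults to 0.5 Å — a realistic backbone fluctuation
  scale for a structured RNA at room temperature.
- **Anchors absorb the rigid component.** Least-squares superposition
  removes the best-fit rigid motion of each frame; for a generic random
  displacement field that projection is not zero, which would bias the
  recovered correlations downward by O(block/N). The generator therefore
  adds, per frame, a least-norm correction to designated anchor residues
  (three at each chain end by default) that cancels the field's net
  translation and infinitesimal rotation with respect to the C5′ nodes.
  Superposition then acts as the identity in expectation and the planted
  block correlations appear unbiased in the DCCM. The anchors' own motion
  is the compensation plus a near-zero residual (2 % of σ) — their
  statistics are ballast and are never asserted.
- **Hydrogen bonds.** A planted bond is a per-frame Bernoulli draw at the
  scheduled occupancy: when "on", the acceptor atom is placed 2.9 Å from
  the donor along the D–H axis (deviation from linearity 0°); when "off",
  at 5.0 Å. Measured occupancy therefore matches the schedule to binomial
  sampling error (±2 points at 2000 frames for occupancy 0.75).
- **Rigid-body drift.** Optional global translation (Gaussian, scale =
  amplitude in Å) plus a small random rotation (scale = amplitude/100 rad)
  per frame, drawn from a dedicated random substream so that two specs
  differing only in drift produce identical internal coordinates. Every
  superposition-based analysis must — and does — remove it exactly.

All randomness flows from the single seed recorded in the spec via
independent `SeedSequence` substreams (displacements, hydrogen bonds,
drift); a fixture bundle's manifest regenerates it bit-identically.

Because frames are independent, passing these tests shows that the
*estimators* are correct and unbiased under the planted model; it says
nothing about convergence of a real, autocorrelated MD sample, about
force-field adequacy, or about solvent/ion effects.

## Analysis conventions and defaults

| Parameter | Default | Meaning |
| --- | --- | --- |
| H-bond distance cutoff | 3.5 Å | donor–acceptor heavy-atom distance |
| H-bond angle cutoff | 30° | maximum deviation of D–H···A from linearity |
| Contact cutoff | 4.5 Å | minimum heavy-atom distance between residues |
| Contact persistence | 0.75 | fraction of frames required (inclusive, ≥) |
| Network nodes | C5′ | one backbone atom per nucleotide |
| Edge weight | −ln\|C_ij\| | natural log; configurable base |
| Path ensemble size k | 1000 | Yen's algorithm, simple paths |

- **Two reference conventions.** RMSD series use the *initial* structure as
  reference, fitting each frame on the measured region's own heavy atoms;
  RMSF and PCA superpose onto the *average* structure. Both are exposed;
  they are different statistics and are not interchangeable.
- **Angle convention.** The 30° hydrogen-bond cutoff is a maximum deviation
  from D-H-A linearity (i.e. the D-H-A angle must be ≥ 150°). The opposite
  reading would invert every occupancy; it is stated here once and tested.
- **D–A, not H–A.** The 3.5 Å cutoff applies to the two polar heavy atoms,
  with the hydrogen entering only through the angle.
- **Donor hydrogens** are inferred geometrically (nearest hydrogen of the
  same residue within 1.25 Å) because plain PDB inputs rarely carry bonds.
- **Contact distance** is the minimum heavy-atom distance between residues;
  a C5′-only alternative is available through the selection descriptor.
- **SD convention.** All reported standard deviations (RMSD tables,
  distance statistics) are population SDs (divide by n): they describe the
  sampled frames themselves, not an estimator of a larger population.
- **Covariance denominator** in PCA and DCCM is n_frames (population form),
  configurable in PCA via `ddof`.
- **Consensus matrices** are element-wise means of replica DCCMs; a
  stricter masked mode (keep an entry only where |C| clears a cutoff in
  every replica) is available.
- **Two matrices, one network.** Shortest-path measures need "smaller is
  closer" and use −log|C| distances; eigenvector centrality needs "bigger
  is stronger" and uses the |C| values on the same contact-filtered edges.
  Mixing them up silently inverts the ranking, so both live on the one
  `ResidueNetwork` object. The |C| > 0.6 filter sometimes applied when
  drawing correlation networks is an output/display filter only and never
  affects network construction.
- **Betweenness** is summed over unordered pairs and reported unnormalized;
  ordered (×2) and normalized variants are flags.
- **Eigenvector centrality** is computed on the largest connected component
  (ties broken toward the component containing the smallest node index),
  zeros elsewhere, normalized to unit maximum; an edgeless graph is an
  error rather than an all-zero profile.
- **Determinism.** Eigenvector signs are fixed by making each vector's
  largest-magnitude component positive. Equal-length paths are ordered
  lexicographically by node sequence. Complete-linkage clustering is
  delegated to `scipy.cluster.hierarchy` (the `hclust`-"complete" method),
  which is deterministic for a given input order. Node degeneracy divides
  by paths *found*, so endpoints always score 1 even when the ensemble
  saturates below k.

## Numerical choices

- Superposition uses the SVD form of the Kabsch solution with a
  determinant correction to exclude reflections; fewer than three
  non-collinear fit points is an error. Batched frame superposition stacks
  the 3×3 SVDs, so 10⁴-frame analyses run in seconds.
- The PCA average structure is obtained with two fit/recompute-mean passes,
  which makes the mean self-consistent to ~1e-8 so that projections of the
  fitting trajectory are zero-mean; full iteration to convergence is
  available behind a flag.
- DCCM entries are clipped to [−1, 1] and symmetrized against rounding; a
  node whose positional variance is below 1e-15 Å² is rejected by name
  (correlation undefined) rather than silently zeroed.
- |C| = 1 maps to edge weight exactly 0 (normalized away from −0.0);
  |C| = 0 maps to "no edge" rather than an infinite-weight edge.
- Yen ensembles keep pulling candidate paths while their length ties the
  k-th length within a 1e-9 relative slack, then sort by (length,
  lexicographic node sequence) and truncate, so float ties cannot make the
  ensemble order platform-dependent.

## Crystal-structure comparison

`crystal.compare_crystal_structures` compares two homologous RNA
structures (e.g. the bacterial and plant TPP aptamer crystal forms):
nucleotide sequences are globally aligned (match 2, mismatch −1, gap
−4/−0.5), atoms of aligned residues are matched by name, the Kabsch fit is
computed over the matched RNA heavy atoms, and RMSDs are reported for the
RNA and, under the same fit, for a ligand matched by atom name. The
structures themselves are not redistributed; the acceptance surface runs
this comparison only when the PDB files are locally present.

## Problem sizes

The test suite and acceptance script use 15–30-residue chains with up to
10⁴ frames: large enough that the stochastic tolerances (Fisher-z for
correlations, binomial for occupancies, chi-squared for variance ratios)
are a few percent, small enough that the whole pipeline is interactive.
The estimators are size-agnostic; nothing in the implementation assumes
these sizes.

## Known limitations

- The multi-model PDB trajectory format quantizes coordinates at 1e-3 Å;
  round-trip tests tolerate exactly that. Binary trajectory formats are an
  adapter hook, not core.
- Only model 1 of a PDB is accepted as a topology; altloc B+ conformers are
  discarded; mmCIF is not parsed.
- Donor/acceptor classification is name/element-based (polar N/O); there is
  no base-pair edge classification — pairs of interest are user-supplied.
- The contact mask is computed on whatever trajectory it is given; when
  replicas are combined, compute it on the concatenated trajectory (the
  pipeline does this) rather than per replica.
- Eigenvector centrality on near-disconnected networks depends on the
  component decomposition; profiles of different states are comparable only
  over a shared node set, which the pipeline enforces.
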