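# Methods

## Representation

Each protein chain is a string of spherical beads, one bead per
`granularity` consecutive residues (default 10). Bead volume is the
average volume of its residues, `V = c_vol · m_res · n_res` with
`c_vol = 1.21 Å³/Da` (the standard protein partial specific volume) and
`m_res = 110 Da` (mean residue mass); the radius is that of the equivalent
sphere, about 6.8 Å for a full 10-residue bead. Residues left over at the
C terminus form one final smaller bead rather than being redistributed, so
that residue→bead addressing stays the pure function
`bead = ⌊(residue − 1)/granularity⌋` — cross-link restraints can then be
attached without any per-chain bookkeeping. Both constants are exposed in
the topology and can be overridden.

A dimeric assembly holds two copies of every chain laid out copy-major;
while the symmetry constraint is active only copy 0 carries degrees of
freedom and copy 1 is the exact image under a proper rigid transform
(validated orthonormal, det = +1). The constraint is enforced by
construction (the image is recomputed after every accepted move), never as
an energy term.

## Scoring function

All terms act on the surface distance
`s(i,j) = ‖cᵢ − cⱼ‖ − rᵢ − rⱼ` and are dimensionless (kT units):

| term | form | default |
|---|---|---|
| connectivity | `k s²` for `s > 0`, sequence-adjacent beads | k = 1 |
| excluded volume | `k s²` for `s < 0`, all non-adjacent pairs | k = 1 |
| cross-link | `k (s* − s₀)²` for `s* > s₀`; `s*` = min over ambiguous copy assignments | k = 1, s₀ = 5 Å |
| localization | `k d²`, `d` = distance of a bead centre to its component's box (0 inside) | k = 1 |
| subcomplex | per group member, `k g²` where `g` = smallest surface distance to any other member (0 in contact) | k = 1 |

Design choices in terms the functional forms leave open:

- The connectivity harmonic is one-sided (gap only). A two-sided harmonic
  at equilibrium 0 would penalize overlap of neighbours a second time on
  top of excluded volume; with the gap-only form the two terms partition
  the pair interaction cleanly.
- The excluded-volume "intensity" multiplies a soft quadratic overlap
  penalty, the simplest form with that parameterization.
- Cross-link ambiguity is resolved per model evaluation by taking the
  minimum surface distance over all endpoint-to-copy assignments, never by
  a fixed assignment. A pair falling inside a single bead counts as
  trivially satisfied (`s = −2r`).
- Localization boxes restrain copy 0 only; copy 1 inherits its
  localization through the symmetry transform. Restraining both copies
  with the same axis-aligned box was tried and rejected: it cannot
  disambiguate intra- from inter-monomer interfaces, because the box union
  is copy-symmetric.
- The cross-link spring constant defaults to 1.0, consistent with the
  other terms; the bound, every constant, and the granularity are config
  entries.

## Sampling

Single-bead Metropolis moves (uniform displacement in a ball of radius
`max_move`, default 1 Å) on copy 0, with the symmetric image updated
before evaluating the move. Move energetics are local — only terms
touching the moved bead and its image are re-evaluated — so one step costs
O(n_beads). The inner loop is a numba kernel taking a
`numpy.random.Generator`; per-replica generators are spawned from the
master seed, execution is single-threaded, and runs are bit-for-bit
reproducible. The exact total energy is recomputed from scratch at every
exchange boundary, so floating-point drift from delta accumulation cannot
build up across a run.

Parallel tempering uses a geometric temperature ladder (`t_min = 1` to
`t_max = 3` kT; the study-scale protocol uses 34 rungs), neighbour swaps
with acceptance `min(1, exp((1/Tᵢ − 1/Tⱼ)(Eᵢ − Eⱼ)))` and alternating
even/odd pairing. An optional well-tempered-ensemble bias deposits
Gaussians (width 2, initial height 1, bias factor γ = 16) on the total
energy at exchange boundaries, with the well-tempered height decay
`exp(−V(E)/((γ−1)T))`; biased energies enter both the move acceptance and
a generalized exchange rule that reduces to the formula above when the
bias is off. The bias is disabled by default.

Initial coordinates are uniform inside each component's bounding box;
components without a box are placed uniformly in the union of all boxes by
rejection sampling. The returned ensemble holds the best-scoring snapshots
of the lowest-temperature replica (best state per inter-exchange segment,
top `top_n_keep` overall, default 1000), sorted by score.

## Ensemble analysis

- **Clustering.** Greedy neighbour-count clustering: repeatedly take the
  structure with the most neighbours within the cutoff (default 17 Å),
  remove it and its neighbours as one cluster. Ties break to the lowest
  score, then the lowest index. The pairwise metric is bead-centre RMSD
  after least-squares rigid superposition over all beads with no chain
  relabelling (the symmetric copy is a constraint, not a permutation),
  evaluated in closed form from batched 3×3 SVDs.
- **Densities.** Models are superposed onto a reference (the top cluster's
  centre) and each bead's centre is histogrammed on a common 2 Å grid,
  normalized to 1 per bead. Bead variability is the diameter of the
  half-maximum voxel set (maximum pairwise distance between voxel
  centres); the summary statistic is the fraction of beads with
  variability ≤ 3 Å.
- **Satisfaction.** A restraint is a fit when its minimum ambiguous
  surface distance is within the 10 Å cutoff — deliberately looser than
  the 5 Å restraint bound, tolerating marginal violations.
- **Contacts.** A bead pair is in contact at surface distance ≤ 5 Å
  (matching the restraint bound); sequence-adjacent pairs are excluded.
  Contacts aggregate to protein pairs and to ~100-residue macro-regions
  (N/M/C labelling, remainder residues to the C-terminal regions), each
  split intra- vs inter-monomer. For a dimer, bead-pair keys are
  canonicalized over the copy swap so contact sets are invariant to
  relabelling the two copies.
- **Jackknife.** Subsets of the restraint table (default 95%, drawn
  without replacement) are re-modelled and the conserved fraction of the
  full-data cluster-centre model's bead contacts is reported. A subset
  fraction of 1.0 re-runs the identical problem and conserves everything
  exactly, by construction.

## Docking onto the tubulin lattice

The lattice is a flat 6×6 patch of α/β-tubulin monomers (alternating
along each protofilament), each monomer a bead chain packed on a compact
cubic grid around its subunit centre. Defaults: 52 Å between
protofilaments, 40 Å between monomers along one. The patch is flat rather
than cylindrically curved — at the scale of one binding footprint the
restraint geometry at the contact face is preserved, and the flat patch
keeps the pose parameterization simple. The 20 boundary subunits are
flagged edge and never serve as restraint candidates, so the finite patch
cannot attract restraints to its rim. Complex-to-tubulin cross-links are
upper-bound harmonics on the minimum surface distance over both complex
copies × all interior subunits of the matching isoform (residue numbering
is isoform-specific; a config switch widens the ambiguity to both
isoforms).

Docking runs in two stages plus a polish: stage 1 starts the lattice at a
random orientation 100 nm away and samples rigid lattice moves
(translations ≤ 2 Å, rotations ≤ 2°) against per-bead complex moves with
the symmetry constraint on; stage 2 continues from the stage-1 optimum
with the constraint released; a final quench anneals the best state
through T = 0.3, 0.05, 0.01 with shrinking step sizes. A fraction of
rigid moves (10%) are lattice-symmetry jumps — translation by one lattice
vector or 90°/180° rotation about the lattice normal. These connect
subunit-registry basins that are separated by otherwise impassable
barriers; the proposal set is closed under inversion, so detailed balance
is preserved. Orientation is classified from the angle between the
complex's largest-variance principal axis and the protofilament axis,
folded to [0°, 90°] with a 45° class boundary (perpendicular/parallel),
plus per-terminus plus/minus-end facing from the signed axial coordinate
relative to the complex centroid. An isotropic bead cloud (top two
covariance eigenvalues within 2%) has no defined long axis and reports an
undefined class.

## Synthetic data

The generator emulates the structure of the modelling inputs, not their
biochemistry. Sequences are poly-alanine with lysine-like reactive sites
every 8th residue (about the natural lysine frequency), written as 'K' so
coverage accounting works unchanged. Toy assemblies grow bead-by-bead
(self-avoiding, group members attached within their subcomplex group) and
are compacted by shrink-and-repair projection to a radius-of-gyration
target; the default target corresponds to a moderately compact globule.
A two-fold rotation places the second copy just touching the first.
Observations: every site pair whose true minimum ambiguous surface
distance is within `d_true` (default 5 Å, the restraint bound) is detected
with probability `p_det` (default 0.7), then `⌈f_decoy · n_true⌉`
uniformly random site pairs are appended as decoys (default 1%,
distance-independent — worst-case contamination).

The reference recovery study uses a four-component dimer (140/120/80/60
residues, 40 beads per copy), boxes padded 20 Å on the two largest
components, and 2×10⁶ MC steps on 8 replicas — about one minute per seed.
Recovered-architecture metrics: satisfaction of the true UDRs at the 10 Å
cutoff and the fraction of true protein-pair contacts present in the
cluster-centre model. Contact recovery ignores the intra/inter-monomer
split because, for components without localization boxes, the monomer
assignment of an interface is exactly energy-degenerate under the
ambiguous restraints and the two-fold symmetry — both assignments occur at
identical scores, and no method could tell them apart from these data.
Decoy robustness (decoys fit worse than true links) is measured at the
5 Å restraint bound: at the 10 Å fit cutoff a converged toy accommodates
the ~1% decoy load entirely, while at the bound the separation is large
(decoys sit at the bound, true links well inside).

The docking study plants a deterministic flat-bottomed rod dimer
(two hairpin-folded chains, ~220 Å long) on a lattice of 150/140-residue
toy tubulins and reads off the contacts at the 10 Å fit span with a 15%
detection probability (giving ≈ 13–30 records, the density of a real
complex-to-tubulin dataset); the records are restrained at the same span,
so the planted pose is a true optimum. The toy's design tracks what makes
the real problem identifiable: distinct isoform lengths carry the
polarity signal, subunit dimensions are large against the ~20 Å ambiguity
reach of a single restraint, and the rod's length against the finite
patch makes misoriented poses unsatisfiable. With spherical-blob dimers,
equal isoforms, or miniature subunits, orientation recovery is provably
(and observedly) ill-posed — a caveat that applies equally to real
experiments with too-small binding footprints.

## What the synthetic studies do and do not show

Passing recovery tests demonstrates that the implementation optimizes the
intended score, that the score's optimum is the planted structure when the
data determine it, and that the analysis stages measure what they claim.
They do not demonstrate performance on real cross-linking data: real
sequences have non-uniform reactive-site density, real detection is biased
by peptide chemistry rather than Bernoulli, real decoys are not
distance-uniform, and real complexes are not exactly C2-symmetric.
Study-scale sampling (10⁸ steps, 34 replicas, 1000 retained models)
is reachable with the same configuration objects; the tests and the
acceptance script run reduced protocols (10⁵–2×10⁶ steps, 2–8 replicas)
chosen to converge their respective toy systems. One statistic scales
differently: the fraction of beads localized to ≤ 3 Å at half maximum
measures how sharply the retained ensemble concentrates at the optimum,
and a desk-scale top-1000 ensemble is thermally broad (median half-max
extents of tens of Å), so that fraction sits near zero even when the
architecture is recovered perfectly — it approaches the study-scale value
only as the retained models become many near-copies of the minimum.

## Numerical details

- Tie-breaks: clustering ties to lowest score then lowest index; the
  remainder bead is always C-terminal; box distance is 0 on the boundary.
- Degenerate inputs: empty UDR sets raise on satisfaction (fraction
  undefined); empty density maps refuse to write; a zero-size box is a
  valid harmonic tether (used by the sampler tests as an exact harmonic
  oscillator).
- Tolerances: scoring paths agree with a brute-force oracle to 1e-9
  relative; the symmetry image is exact to machine precision; PDB output
  carries 3 decimals, so round-trips are checked at 5e-4 Å.
- The MC kernel caches energies as running deltas within a segment and
  re-anchors to the exactly recomputed total at segment boundaries.
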