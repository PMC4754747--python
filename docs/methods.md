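# Methods

`dimerdyn` analyses the dissociation tendency of a protein homodimer from a
coordinate ensemble (an MD trajectory or a synthetic stand-in).  This note
describes each stage's model and assumptions, the parameters that matter,
the synthetic-data generator's ground truth, and the numerical choices made
where the design was genuinely open.

## Coordinate conventions and I/O

Coordinates are Angstrom throughout; residues are identified by
`(chain_id, author residue number)` with 1-based PDB numbering; atom order
is file order everywhere.  Insertion codes are rejected with a clear error
rather than silently reindexed — the systems this pipeline targets have
none, and silent misindexing is the worse failure mode.  The reference
ensemble dialect is multi-model PDB so that every fixture is plain text;
binary trajectory formats plug in through a registered adapter behind the
same reader contract.  Van der Waals radii come from a fixed element table
(C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80 Angstrom; default 1.70).

## Superposition and descriptors

Frames are superposed by the Kabsch algorithm (SVD of the cross-covariance
with a sign correction on the smallest singular vector to enforce a proper
rotation).  Superposition is mass-unweighted over Cα atoms — the simplest
defensible choice for a Cα-level analysis.  RMSF is taken about the
ensemble mean structure (not frame 1), the standard convention.  The RMSD
series reference is frame 0.  The inter-subunit distance is between
unweighted Cα centroids, a pairwise distance and hence rigid-motion
invariant.  Pairwise RMSD after optimal superposition is symmetric but not
a metric; no triangle inequality is assumed anywhere.

## SASA and interface detection

SASA uses the Shrake–Rupley construction with a deterministic Fibonacci
lattice on each expanded sphere (radius r_vdw + probe).  Defaults: probe
1.4 Angstrom, 960 points per atom, hydrogens excluded both as targets and
occluders.  Deterministic points make every SASA value exactly reproducible
for a fixed point count, which the regression tests and the byte-identical
rerun guarantee rely on; point count, probe and hydrogen handling are all
configurable.  A 32-point floor rejects settings below any useful accuracy.

Interface residues are defined once, from the static reference structure:
a residue belongs to the interface when its SASA computed in the complex is
more than 0.1 Angstrom² smaller than in its isolated chain.  The 0.1
Angstrom² tolerance only exists to keep numerical dust out of the set.  The
per-frame total SASA of these residues is the scalar dissociation
coordinate: a more exposed interface means a more dissociated dimer.  The
interface is deliberately not redefined per frame.

## PCA and functional mode analysis

PCA eigendecomposes the 3N×3N sample covariance of the flattened, aligned
Cα coordinates.  Modes are unit 3N displacement fields with eigenvalue
variances in Angstrom²; the sign convention (largest-magnitude component
positive) makes mode output independent of the linear-algebra backend.
Per-residue amplitude is the norm of the residue's 3-component block
(amplitudes are normalized dimer-wide: Σ amplitude² = 1 per mode), and a
residue's motion direction is that block normalized, flagged undefined
below an amplitude of 1e-6.

FMA finds the linear combination of the top-K PC modes (default K = 20)
maximally correlated with the dissociation coordinate, fitted by PLS1
regression with 10 components by default.  The fit uses the first half of
the frames and is validated on the second half; a contiguous split is used
instead of a random one because trajectory frames are autocorrelated, and
the validation-half Pearson correlation is the headline number.  Two mode
vectors are reported:

* the **regression direction** (PLS coefficient vector in PC space), whose
  projection is the maximally correlated model used for the train and
  validation PCC;
* the **ensemble-weighted collective mode**, the same coefficients with
  each PC weighted by its variance on the training half.  This is the
  displacement pattern that actually accompanies the functional change and
  is the vector used for mode comparison and per-residue amplitudes.  The
  distinction matters because regression inflates the weights of
  low-variance PCs whose tiny fluctuations happen to correlate with noise;
  the ensemble weighting removes exactly that artifact.

Mode similarity between systems is the Pearson correlation of the 3N
component vectors; a mode is projected on the top 20 PCs of another system
by that similarity, the best PC being the argmax of |PCC| with ties broken
toward the lower index.  Cross-system comparison requires the user to
supply a residue correspondence; no automatic sequence alignment is done.

One subtlety: ensemble superposition absorbs the rigid-body component of
any planted or physical displacement field.  When a recovered mode is
compared against a planted field, the field is first projected onto the
orthogonal complement of the 6-dimensional rigid-body subspace (3
translations, 3 infinitesimal rotations at the mean structure) and
renormalized; the recoverable ground truth lives in that complement.

## Residue-interaction networks

Two residues of the same chain are connected when both criteria hold
simultaneously: (i) their motion directions in the chosen PC mode are
within 45 degrees (cosine > cos 45 ≈ 0.7071, strict); (ii) at least one
heavy-atom pair is closer than 4.5 Angstrom (strict) in at least 75% of
frames (inclusive).  A residue with undefined direction fails criterion
(i).  Sequential neighbours are not excluded by default (an exclusion
window is available).  Nodes are residues with at least one edge, so
isolated residues drop out of the node count.  Networks are per chain with
intra-chain edges; an inter-chain variant is available behind a flag.

Topology summaries report node/edge counts, average degree (2E/N, asserted
as an identity) and the average local clustering coefficient
(2·triangles(v)/(deg(v)(deg(v)−1)), defined 0 for degree < 2).  Geodesics
between a perturbation residue and the interface residues are counted
exactly by BFS dynamic programming (Brandes-style sigma accumulation);
unreachable targets are flagged, never reported as length 0.

Robustness uses a frame bootstrap: each of 10 repeats draws 80% of the
frames without replacement ("choosing 80% of the frames" reads as
subsetting, not resampling with replacement), recomputes contact
occupancies on the subset, and rebuilds the network on the *same* mode —
the mode is deliberately not recomputed, isolating the contact criterion's
sampling noise.  Mean ± SD of each property across repeats is reported.
At fraction 1.0 the bootstrap provably reproduces the full network.

## Energetics

The endpoint binding-free-energy calculation itself (MM/PBSA) is out of
scope; the module consumes its outputs as delimited tables — per-frame
totals `(system, time_ns, dG_kcal_mol)` and per-residue decompositions
`(system, chain, residue, dG_kcal_mol)`.  Windowed statistics report
mean ± SD over frames up to each window end, with integer-rounded columns
for table parity.  Systems are compared with Welch's two-sample t-test on
per-frame values (the test is a documented, swappable choice; per-frame
energies are used raw, with block averaging available as an option).
P-values below 2.2e-16 are labelled "< 2.2e-16".

Key residues are selected from the per-residue difference
ΔΔG = dG_mutant − dG_wildtype: stabilizing means ΔΔG < −1 kcal/mol
(strict), sorted most negative first; destabilizing means ΔΔG > +1
kcal/mol, sorted most positive first.  The intersection of two selections
preserves the first selection's order.

## Conformational clustering

All frame pairs get a Kabsch-optimal Cα RMSD (computed via batched 3×3
cross-covariance SVDs and the singular-value identity; values at the
floating-point cancellation floor are clamped to exact zero).  Clustering
is the greedy neighbour-count scheme: the frame with the most unassigned
neighbours within the cutoff seeds a cluster of itself plus those
neighbours, ties broken toward the lowest frame label, repeated until all
frames are assigned.  The representative is the member with the smallest
mean RMSD to its cluster.  The cutoff is chosen by scanning a 0.1-Angstrom
grid upward and taking the smallest cutoff whose top-8 clusters cover more
than 90% of the frames ("smallest satisfying" is our reading of "optimal").
Top-8 coverage is checked for monotonicity over the scanned grids of the
study systems in the tests but is not hard-asserted inside the scan, since
the greedy scheme does not guarantee it for arbitrary inputs.

## Synthetic data: what is emulated, what is not

The generator emulates the statistical structure the analyses consume, not
the physics.  The toy dimer is two facing extended strands (default 24
residues per chain, Cα spacing 3.8 Angstrom, interface separation 4.0
Angstrom) with one pseudo side-chain atom per residue pointing away from
the interface, so heavy-atom contact criteria are exercised without full
chemistry.  Frames are

    x(t) = x_ref + Σ_k a_k(t)·m_k + d(t)·m_diss + ε(t)

with orthonormalized planted fields m_k (defaults: two smooth out-of-plane
sinusoidal fields with stddevs 0.8 and 0.5 Angstrom, orthogonalized against
the rigid-body subspace), a dissociation field m_diss that rigidly
translates chain B along the interface normal by d Angstrom
(d ~ Normal(0, 1.2 Angstrom)), and isotropic noise ε (stddev 0.1 Angstrom).
The dissociation coefficient is the ground truth the SASA series and FMA
must recover (their correlation exceeds 0.9 at these defaults).  Planted
contacts override the partner residue's side-chain position on a seeded
Bernoulli(occupancy) schedule, placing the pair at 3.8 or 6.5 Angstrom —
on either side of the 4.5-Angstrom criterion — lifted 80 degrees out of
the strand plane so the override creates no incidental contacts.  Each
residue may appear in at most one contact target.  One RNG stream per
generator call is seeded from the spec; the draw order (mode coefficients,
dissociation, noise, contact schedules) is fixed so adding a parameter
never shifts existing draws.

Energy tables plant stabilized/destabilized residues at ±effect_size with
Gaussian noise on the mutant table; per-frame energy series are i.i.d.
Normal draws at the study conditions of the four systems (means −181,
−202, −192, −165 kcal/mol with SDs 31, 24, 20, 29).  The default
energetics scenario plants 18 stabilized residues in the first system pair
and a destabilized set in the second sharing exactly 7 residues, matching
the reported set sizes.

What the generator does *not* emulate: force-field energetics, solvent,
secondary structure, anharmonic or state-switching dynamics, and
sequence-dependent side-chain chemistry.  Passing tests therefore
demonstrate that the estimators recover planted linear-Gaussian ground
truth under realistic noise — they do not certify behaviour on real MD
output beyond the contracts tested (formats, invariants, determinism).

## Problem sizes

The bundled end-to-end configuration uses 600 frames of the 24-residue-per
chain dimer, chosen so a full pipeline run (all eight stages, including
the 960-point SASA series) completes in well under a minute; the
recovery scenarios in the validation suite use 2000 frames, where the
planted occupancies are resolved to ±0.02 and the mode recoveries are
stable.  Clustering subsamples ensembles to at most 250 frames by even
stride before the all-pairs RMSD matrix.

## Known limitations

* Only linear correlation is considered in FMA; nonlinear dependence
  between collective motion and the dissociation coordinate is invisible
  to it (mutual-information variants are out of scope).
* The interface is fixed from the reference structure; interfaces that
  form only transiently during the trajectory are not captured.
* SASA is quadrature on a finite point set; with 960 points, per-atom
  areas carry sub-percent quadrature error (well inside the 1% oracle
  agreement the validation suite enforces).
* The GROMOS-style clustering and the "smallest satisfying cutoff" rule
  are one concrete reading of an under-specified protocol; both are
  isolated behind the operation boundary and easy to swap.
* mmCIF, altloc handling, hydrogen placement and bond perception are out
  of scope at the reader level.
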