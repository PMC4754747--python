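# dimerdyn

Trajectory analysis of protein **dimer dissociation**: why does one point
mutation make a two-chain enzyme more thermostable?  A recurring answer is
that the mutation suppresses the collective motion that pulls the two
subunits apart.  `dimerdyn` implements the complete desk-side analysis
chain for testing that hypothesis on a coordinate ensemble of a dimer
(an MD trajectory, or the bundled synthetic stand-in):

1. **Interface detection** — Shrake–Rupley solvent-accessible surface area
   (SASA); interface residues are those whose SASA drops when the two rigid
   chains associate.  The per-frame total interface SASA is the scalar
   "degree of dissociation".
2. **PCA** of the aligned Cα ensemble into orthonormal collective modes
   with variances, plus per-residue mode amplitudes and motion directions.
3. **Functional mode analysis (FMA)** — the linear combination of the top
   20 PC modes maximally correlated with the interface-SASA series, fitted
   by partial least squares on the first half of the trajectory and
   validated by the Pearson correlation (PCC) on the second half.
4. **Dynamic residue-interaction networks** — residues are linked when
   they move in the same direction in the chosen PC mode (angle < 45°)
   *and* stay in heavy-atom contact (< 4.5 Å in ≥ 75% of frames); topology
   summaries, geodesic path counts between a perturbation site and the
   interface, and a frame-bootstrap robustness protocol.
5. **Binding energetics** — per-frame and per-residue binding-free-energy
   tables (consumed as text; the MM/PBSA calculation itself is upstream):
   windowed mean ± SD, Welch tests between systems, and key-residue
   selection by ΔΔG = ΔG(mutant) − ΔG(wild type) beyond ±1 kcal/mol.
6. **Conformational clustering** by pairwise Cα RMSD with a greedy
   neighbour-count scheme; the cutoff is the smallest on a 0.1 Å grid at
   which the top 8 clusters hold > 90% of frames.

A synthetic dimer generator with *planted* ground truth (collective modes,
a dissociation mode that modulates interface SASA, Bernoulli-scheduled
contacts, planted key residues) makes every stage testable end to end
without MD output.  See `docs/methods.md` for the full model description.

## Worked example

Run the bundled synthetic pipeline (600 frames of a 48-residue toy dimer
with a planted dissociation mode):

```sh
dimerdyn run-all --seed 1 --output-dir run1
```

which logs each stage and prints the report bundle:

```json
{
 "best_pc_index": 0,
 "clustering": {"coverage_top8": 0.995, "cutoff_A": 0.4, "n_clusters": 9},
 "energetics": {"n_common": 7, "n_stabilizing": 18},
 "fma_validation_pcc": 0.9872629544685375,
 "n_interface_residues": 48,
 "network": {
  "A": {"average_clustering_coefficient": 0.0, "average_degree": 1.9166666666666667,
        "n_edges": 23, "n_nodes": 24},
  "B": {"average_clustering_coefficient": 0.0, "average_degree": 1.9166666666666667,
        "n_edges": 23, "n_nodes": 24}
 },
 "pca_variances": [18.81, 0.240, 0.136, "..."],
 "source": "synthetic"
}
```

Reading the numbers: all 48 residues of the facing-strand toy dimer bury
surface on association (`n_interface_residues`); PC1 carries almost all the
variance (18.8 Å² against 0.24 Å² for PC2) because the planted dissociation
motion dominates, and the FMA mode built from the interface-SASA series
validates with PCC ≈ 0.99 on the held-out half — the pipeline has found the
planted dissociation mode (`best_pc_index` 0).  The residue networks of the
extended strands are near-chains (24 nodes, 23 edges per chain, average
degree 2E/N ≈ 1.92, no triangles), and the energetics stage recovers the
18 planted stabilizing residues and the 7-residue common core.  Artifacts
(CSV/JSON/GraphML/PDB plus a checksummed `manifest.json` per stage) land
under `run1/`; rerunning with the same seed reproduces every file byte for
byte.

Each stage is also a library call (`detect_interface`, `pca`, `fma`,
`build_network`, `select_key_residues`, `select_cutoff`, ...) and a CLI
subcommand (`dimerdyn interface|pca|fma|network|energetics|cluster`);
stages resume from intact artifacts.

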