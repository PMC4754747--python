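"""Planted-ground-truth validation scenarios.

Each function builds a seeded synthetic scenario, runs the corresponding
pipeline stage, and measures how well the planted ground truth is
recovered, returning plain numbers.  The oracles used here (Monte-Carlo
sphere sampling for SASA, depth-first geodesic enumeration for path
counts) are independent of the implementations they check.
"""

from __future__ import annotations

import numpy as np

from .clustering import coverage_curve, gromos_cluster, pairwise_rmsd_matrix, select_cutoff
from .core import ResidueSelection, TrajectoryEnsemble, calpha_selection
from .energetics import compare_systems, select_key_residues
from .geometry import align_ensemble
from .modes import fma, pca, project_mode, remove_rigid_body
from .network import (
    bootstrap_networks,
    build_network,
    contact_occupancy,
    shortest_paths,
    summarize,
)
from .sasa import detect_interface, interface_sasa_series, sasa
from .synthetic import (
    SyntheticSpec,
    build_toy_dimer,
    dissociation_field,
    generate_energy_series,
    generate_energy_tables,
    generate_ensemble,
)

# ---------------------------------------------------------------------------
# SASA versus Monte-Carlo sphere oracle
# ---------------------------------------------------------------------------


def monte_carlo_sasa_total(coords, radii, probe=1.4, n_samples=1_000_000, seed=0):
    """Independent SASA oracle: uniform random points on each expanded
    sphere, counting the fraction outside all other expanded spheres."""
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, dtype=float)
    expanded = np.asarray(radii, dtype=float) + probe
    total = 0.0
    for i in range(len(coords)):
        v = rng.normal(size=(n_samples, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = coords[i] + expanded[i] * v
        exposed = np.ones(n_samples, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            reach = expanded[i] + expanded[j]
            if np.linalg.norm(coords[i] - coords[j]) >= reach:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            exposed &= d2 >= expanded[j] ** 2
        total += exposed.mean() * 4.0 * np.pi * expanded[i] ** 2
    return total


def sasa_oracle_benchmark(seed: int = 0, n_samples: int = 1_000_000) -> dict:
    """Shrake-Rupley SASA against the Monte-Carlo sphere oracle, plus the
    burial-is-non-negative inequality on random geometries."""
    from .core import StructureModel

    # two carbon spheres 2.0 A apart
    pair = StructureModel(
        atom_names=np.array(["CA", "CA"], dtype=object),
        elements=np.array(["C", "C"], dtype=object),
        vdw_radii=np.array([1.70, 1.70]),
        residue_indices=np.array([1, 2]),
        residue_names=np.array(["GLY", "GLY"], dtype=object),
        chain_ids=np.array(["A", "A"], dtype=object),
        reference_coordinates=np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]]),
    )
    ours_pair = sasa(pair).total
    oracle_pair = monte_carlo_sasa_total(
        pair.reference_coordinates, pair.vdw_radii, n_samples=n_samples, seed=seed
    )
    spec = SyntheticSpec(n_residues_per_chain=6, atoms_per_residue=2, n_frames=1)
    dimer = build_toy_dimer(spec)
    ours_dimer = sasa(dimer).total
    oracle_dimer = monte_carlo_sasa_total(
        dimer.reference_coordinates, dimer.vdw_radii, n_samples=n_samples, seed=seed + 1
    )
    rng = np.random.default_rng(seed + 2)
    atoms_a = np.where(dimer.chain_ids == "A")[0]
    atoms_b = np.where(dimer.chain_ids == "B")[0]
    violations = 0
    for _ in range(100):
        coords = dimer.reference_coordinates + rng.normal(
            scale=2.0, size=(dimer.n_atoms, 3)
        )
        total = sasa(dimer, coordinates=coords, n_points=240).total
        iso = (
            sasa(dimer, coordinates=coords, atom_subset=atoms_a, n_points=240).total
            + sasa(dimer, coordinates=coords, atom_subset=atoms_b, n_points=240).total
        )
        if total > iso + 1e-9:
            violations += 1
    return {
        "two_sphere_rel_err_pct": 100.0 * abs(ours_pair - oracle_pair) / oracle_pair,
        "toy_dimer_rel_err_pct": 100.0 * abs(ours_dimer - oracle_dimer) / oracle_dimer,
        "burial_violations": violations,
    }


# ---------------------------------------------------------------------------
# PCA / FMA recovery of the planted dissociation mode
# ---------------------------------------------------------------------------


def fma_recovery_benchmark(seed: int = 0, n_frames: int = 2000) -> dict:
    """Recovery of the planted dissociation mode by PCA and FMA on a
    synthetic dimer ensemble whose interface SASA is modulated by the mode."""
    spec = SyntheticSpec(n_frames=n_frames, seed=seed)
    model = build_toy_dimer(spec)
    traj, coeffs = generate_ensemble(model, spec)
    iface = detect_interface(model)
    series = interface_sasa_series(traj, iface)
    d = coeffs["dissociation"].to_numpy()
    sasa_diss_pcc = float(np.corrcoef(d, series)[0, 1])

    aligned = align_ensemble(traj)
    modes = pca(aligned, k=20)
    ca = calpha_selection(model)
    planted = remove_rigid_body(
        dissociation_field(model)[ca].ravel(), model.reference_coordinates[ca]
    )
    projection = project_mode(planted, modes, top_k=20)
    pca_cos = abs(float(np.dot(planted, modes.modes[projection.best_index])))

    functional = fma(aligned, modes, series)
    fma_cos = abs(float(np.dot(planted, functional.mode)))

    rng = np.random.default_rng(seed + 1)
    snr5 = d + rng.normal(scale=d.std() / 5.0, size=len(d))
    functional_snr5 = fma(aligned, modes, snr5)
    return {
        "sasa_dissociation_pcc": sasa_diss_pcc,
        "pca_planted_mode_abs_cos": pca_cos,
        "fma_planted_mode_abs_cos": fma_cos,
        "fma_validation_pcc_sasa": functional.validation_pcc,
        "fma_validation_pcc_snr5": functional_snr5.validation_pcc,
    }


# ---------------------------------------------------------------------------
# Network recovery of a planted edge set
# ---------------------------------------------------------------------------


def _network_scenario(seed: int, n_frames: int = 2000):
    """Six planted contacts (occupancy 0.6/0.8/1.0 crossed with motion
    angles 20/70 degrees) on chain A of a 24-residue-per-chain dimer."""
    from .modes import ModeSet

    pairs = [
        (("A", 1), ("A", 13), 0.6, 20.0),
        (("A", 3), ("A", 15), 0.8, 20.0),
        (("A", 5), ("A", 17), 1.0, 20.0),
        (("A", 7), ("A", 19), 0.6, 70.0),
        (("A", 9), ("A", 21), 0.8, 70.0),
        (("A", 11), ("A", 23), 1.0, 70.0),
    ]
    spec = SyntheticSpec(
        n_residues_per_chain=24,
        n_frames=n_frames,
        planted_modes=[],
        dissociation_amplitude_stddev=0.0,
        noise_stddev=0.05,
        contact_targets=[(a, b, q) for a, b, q, _ in pairs],
        seed=seed,
    )
    model = build_toy_dimer(spec)
    traj, _ = generate_ensemble(model, spec)
    residues = model.residues()
    vec = np.zeros(3 * len(residues))
    for ref, partner, _, angle in pairs:
        theta = np.deg2rad(angle)
        vec[3 * residues.index(ref) : 3 * residues.index(ref) + 2] = [1.0, 0.0]
        vec[3 * residues.index(partner) : 3 * residues.index(partner) + 2] = [
            np.cos(theta),
            np.sin(theta),
        ]
    vec /= np.linalg.norm(vec)
    ca = calpha_selection(model)
    modeset = ModeSet(
        atom_indices=ca,
        residue_keys=residues,
        mean_structure=model.reference_coordinates[ca],
        modes=vec[None, :],
        variances=np.array([1.0]),
    )
    expected = {
        tuple(sorted([a, b]))
        for a, b, q, angle in pairs
        if q >= 0.75 and angle < 45.0
    }
    return model, traj, modeset, expected


def network_recovery_benchmark(seed: int = 0, n_frames: int = 2000) -> dict:
    model, traj, modeset, expected = _network_scenario(seed, n_frames)
    occ = contact_occupancy(traj)
    nets = build_network(modeset, 0, occ)
    recovered = {
        tuple(sorted(e)) for net in nets for e in net.graph.edges
    }
    full_summary = {
        n.chain_id: summarize(n) for n in nets if n.graph.number_of_nodes()
    }
    boot = bootstrap_networks(traj, modeset, 0, fraction=1.0, repeats=3, seed=seed)
    boot_identical = all(
        boot.mean[c]["n_edges"] == s.n_edges and boot.sd[c]["n_edges"] == 0.0
        for c, s in full_summary.items()
    )

    def edge_count(occ_thr, angle_thr):
        return sum(
            n.graph.number_of_edges()
            for n in build_network(
                modeset, 0, occ,
                angle_threshold=angle_thr, occupancy_threshold=occ_thr,
            )
        )

    monotone_occ = all(
        edge_count(a, 45.0) >= edge_count(b, 45.0)
        for a, b in zip((0.5, 0.75, 0.9), (0.75, 0.9, 1.0))
    )
    monotone_angle = all(
        edge_count(0.5, a) >= edge_count(0.5, b)
        for a, b in zip((80.0, 45.0, 25.0), (45.0, 25.0, 10.0))
    )
    return {
        "planted_edges": len(expected),
        "recovered_edges": len(recovered),
        "recovery_exact": float(recovered == expected),
        "bootstrap_full_fraction_identical": float(boot_identical),
        "edge_count_monotone": float(monotone_occ and monotone_angle),
    }


# ---------------------------------------------------------------------------
# Geodesic counts versus brute-force enumeration
# ---------------------------------------------------------------------------


def _enumerate_geodesics(adj: dict, source, target, max_len: int) -> list:
    """Depth-first enumeration of all simple shortest paths up to max_len."""
    best: list[list] = []
    best_len = max_len + 1

    def extend(path):
        nonlocal best, best_len
        node = path[-1]
        if node == target:
            if len(path) - 1 < best_len:
                best_len = len(path) - 1
                best = [list(path)]
            elif len(path) - 1 == best_len:
                best.append(list(path))
            return
        if len(path) - 1 >= best_len:
            return
        for nxt in adj[node]:
            if nxt not in path:
                path.append(nxt)
                extend(path)
                path.pop()

    extend([source])
    return best


def path_count_benchmark(seed: int = 0, n_graphs: int = 20) -> dict:
    """Geodesic lengths/counts versus exhaustive enumeration on random
    12-node graphs (paths up to length 6)."""
    import networkx as nx
    from .network import ResidueNetwork

    rng = np.random.default_rng(seed)
    checked = 0
    matched = 0
    for g_idx in range(n_graphs):
        g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(10_000)))
        mapping = {n: ("A", n + 1) for n in g.nodes}
        relabeled = nx.relabel_nodes(g, mapping)
        net = ResidueNetwork(chain_id="A", graph=relabeled, parameters={})
        nodes = sorted(relabeled.nodes)
        connected = [n for n in nodes if relabeled.degree(n) > 0]
        if len(connected) < 2:
            continue
        source = connected[0]
        targets = ResidueSelection([n for n in nodes if n != source])
        report = shortest_paths(net, source, targets)
        adj = {n: sorted(relabeled.neighbors(n)) for n in relabeled.nodes}
        for target in targets:
            geodesics = _enumerate_geodesics(adj, source, target, max_len=6)
            checked += 1
            if not geodesics:
                ok = report.lengths[target] is None or report.lengths[target] > 6
            else:
                ok = (
                    report.lengths[target] == len(geodesics[0]) - 1
                    and report.n_paths[target] == len(geodesics)
                )
            matched += bool(ok)
    return {"pairs_checked": checked, "match_fraction": matched / checked}


# ---------------------------------------------------------------------------
# Energetics recovery and Welch-test calibration
# ---------------------------------------------------------------------------


def energetics_benchmark(seed: int = 0, n_null: int = 1000) -> dict:
    spec = SyntheticSpec(n_frames=1)
    model = build_toy_dimer(spec)
    residues = ResidueSelection(model.residues())
    stabilized = set(residues.entries[2:20])  # 18 planted residues
    wt, mut = generate_energy_tables(
        residues, stabilized, set(), effect_size=2.0, noise=0.0, seed=seed
    )
    noiseless = select_key_residues(wt, mut, threshold=1.0)
    noiseless_exact = set(noiseless.selection.entries) == stabilized

    hits = 0
    for s in range(10):
        wt, mut = generate_energy_tables(
            residues, stabilized, set(), effect_size=2.0, noise=0.2, seed=seed + 100 + s
        )
        sel = select_key_residues(wt, mut, threshold=1.0)
        hits += set(sel.selection.entries) == stabilized

    rng = np.random.default_rng(seed + 1)
    rejections = 0
    for _ in range(n_null):
        a = generate_energy_series("a", 0.0, 1.0, n_frames=30, seed=int(rng.integers(2**31)))
        b = generate_energy_series("b", 0.0, 1.0, n_frames=30, seed=int(rng.integers(2**31)))
        if compare_systems(a, b).p_value < 0.05:
            rejections += 1

    effect = compare_systems(
        generate_energy_series("hBBCK", -181.0, 31.0, n_frames=1000, seed=seed + 7),
        generate_energy_series("BP36L", -202.0, 24.0, n_frames=1000, seed=seed + 8),
    )
    return {
        "noiseless_recovery_exact": float(noiseless_exact),
        "noisy_recovery_rate": hits / 10.0,
        "welch_type1_error": rejections / n_null,
        "planted_effect_p_below_1e7": float(effect.p_value < 1e-7),
        "planted_effect_mean_difference": effect.mean_difference,
    }


# ---------------------------------------------------------------------------
# Clustering recovery
# ---------------------------------------------------------------------------


def clustering_benchmark(seed: int = 0, per_group: int = 40) -> dict:
    """Two planted conformer groups separated by ~10 A pairwise RMSD with
    ~1 A within-group spread, clustered at a 3 A cutoff."""
    spec = SyntheticSpec(n_residues_per_chain=8, atoms_per_residue=1, n_frames=1)
    model = build_toy_dimer(spec)
    ref = model.reference_coordinates
    pattern = np.zeros_like(ref)
    pattern[:, 2] = np.where(np.arange(len(ref)) % 2 == 0, 1.0, -1.0)
    rng = np.random.default_rng(seed)
    frames = []
    for center in (0.0, 10.0):
        for _ in range(per_group):
            frames.append(
                ref + center * pattern + rng.normal(scale=1.0 / 2.45, size=ref.shape)
            )
    traj = TrajectoryEnsemble(model=model, frames=np.stack(frames))
    matrix = pairwise_rmsd_matrix(traj)
    result = gromos_cluster(matrix, 3.0)
    groups = [set(range(per_group)), set(range(per_group, 2 * per_group))]
    exact = len(result.clusters) == 2 and all(
        set(c) in groups for c in result.clusters
    )
    cutoffs = np.arange(0.5, matrix.max() + 0.5, 0.5)
    curve = coverage_curve(matrix, cutoffs)
    monotone = all(a <= b + 1e-12 for a, b in zip(curve, curve[1:]))
    selected = select_cutoff(matrix)
    return {
        "two_groups_recovered_exact": float(exact),
        "coverage_monotone": float(monotone),
        "selected_cutoff_A": selected.cutoff,
        "selected_coverage_top8": selected.coverage_top8,
    }


# ---------------------------------------------------------------------------
# End-to-end determinism
# ---------------------------------------------------------------------------


def determinism_benchmark(seed: int, workdir) -> dict:
    """Run the bundled synthetic pipeline twice with one seed and compare
    every output file byte for byte."""
    import filecmp
    from pathlib import Path

    from .pipeline import PipelineConfig, run_pipeline

    workdir = Path(workdir)
    dirs = []
    for name in ("run_a", "run_b"):
        config = PipelineConfig.from_dict(
            {"seed": seed, "output_dir": str(workdir / name)}
        )
        run_pipeline(config, resume=False)
        dirs.append(workdir / name)
    mismatches = []
    files_a = sorted(p.relative_to(dirs[0]) for p in dirs[0].rglob("*") if p.is_file())
    files_b = sorted(p.relative_to(dirs[1]) for p in dirs[1].rglob("*") if p.is_file())
    if files_a != files_b:
        mismatches.append("file lists differ")
    for rel in files_a:
        if not filecmp.cmp(dirs[0] / rel, dirs[1] / rel, shallow=False):
            mismatches.append(str(rel))
    return {
        "n_files_compared": len(files_a),
        "byte_identical": float(not mismatches),
    }
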