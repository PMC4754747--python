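"""End-to-end pipeline: synthetic data -> interface -> PCA -> FMA ->
amplitudes -> networks (+ bootstrap, paths) -> energetics -> clustering.

Every stage writes its artifacts (PDB / CSV / JSON / GraphML) plus a
``manifest.json`` recording the stage parameters and SHA-256 checksums of
inputs and outputs, under ``<output_dir>/<stage>/``.  Stages are
independently resumable: when a stage's manifest matches the requested
parameters and its outputs are intact, the stage is reloaded from disk
instead of recomputed.  All randomness derives from the single configured
seed via fixed per-stage offsets.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    align_ensemble,
    chain_center_distance,
    common_key_residues,
    compare_systems,
    detect_interface,
    fma,
    interface_sasa_series,
    pca,
    pairwise_rmsd_matrix,
    project_mode,
    read_ensemble,
    read_structure,
    residue_amplitude,
    residue_direction,
    rmsd_series,
    rmsf_profile,
    select_cutoff,
    select_key_residues,
    shortest_paths,
    summarize,
    windowed_stats,
    write_ensemble,
    write_structure,
)
from .core import ResidueSelection, TrajectoryEnsemble, ValidationError
from .energetics import (
    read_energy_series,
    read_energy_table,
    write_energy_series,
    write_energy_table,
)
from .modes import ModeSet
from .network import bootstrap_networks, build_network, contact_frames, occupancy_from_frames
from .sasa import InterfaceSet
from .synthetic import (
    DEFAULT_ENERGY_SYSTEMS,
    SyntheticSpec,
    build_toy_dimer,
    generate_energy_series,
    generate_energy_tables,
    generate_ensemble,
)

log = logging.getLogger("dimerdyn")

_STAGE_SEED_OFFSETS = {
    "simulate": 0,
    "bootstrap": 1,
    "energy_series": 2,  # +2..+5 for the four systems
    "energy_tables": 10,  # +10, +11 for the two pairs
}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_DEFAULT_CONFIG = {
    "seed": 0,
    "output_dir": "dimerdyn_run",
    "synthetic": {
        "n_residues_per_chain": 24,
        "atoms_per_residue": 2,
        "n_frames": 600,
        "dissociation_amplitude_stddev": 1.2,
        "noise_stddev": 0.1,
        "contact_targets": [],
    },
    "input": {"topology": None, "ensemble": None},
    "interface": {"probe_radius": 1.4, "n_points": 960, "tolerance": 0.1},
    "pca": {"n_modes": 20},
    "fma": {"n_components": 10, "top_k": 20},
    "network": {
        "distance_threshold": 4.5,
        "occupancy_threshold": 0.75,
        "angle_threshold": 45.0,
        "mode_index": None,  # None = best PC from the FMA projection
        "exclude_sequence_window": 0,
        "bootstrap_fraction": 0.8,
        "bootstrap_repeats": 10,
        "path_source": None,  # [chain, residue]; None = chain A midpoint
    },
    "energetics": {
        "n_frames": 1000,
        "windows_ns": [80.0, 90.0, 100.0],
        "effect_size": 2.0,
        "noise": 0.2,
        "threshold": 1.0,
        "n_stabilized": 18,
        "n_common": 7,
    },
    "clustering": {
        "top_n": 8,
        "coverage": 0.90,
        "grid_step": 0.1,
        "max_frames": 250,
    },
}


def _merge_validate(defaults: dict, user: dict, path: str = "") -> dict:
    out = {}
    for key, default in defaults.items():
        if isinstance(default, dict) and key in ("synthetic", "input", "interface",
                                                 "pca", "fma", "network",
                                                 "energetics", "clustering"):
            out[key] = _merge_validate(default, user.get(key, {}) or {}, f"{path}{key}.")
        else:
            out[key] = user.get(key, default)
    unknown = set(user) - set(defaults)
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(path + k for k in unknown)}")
    return out


@dataclass
class PipelineConfig:
    data: dict = field(default_factory=lambda: json.loads(json.dumps(_DEFAULT_CONFIG)))

    @classmethod
    def from_dict(cls, user: dict) -> "PipelineConfig":
        cfg = cls(data=_merge_validate(_DEFAULT_CONFIG, user or {}))
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def __getitem__(self, key: str):
        return self.data[key]

    def validate(self) -> None:
        d = self.data
        if not isinstance(d["seed"], int) or d["seed"] < 0:
            raise ValidationError("seed must be a non-negative integer")
        net = d["network"]
        if not (0.0 < net["occupancy_threshold"] <= 1.0):
            raise ValidationError("network.occupancy_threshold must be in (0, 1]")
        if not (0.0 < net["angle_threshold"] < 180.0):
            raise ValidationError("network.angle_threshold must be in (0, 180)")
        if net["distance_threshold"] <= 0:
            raise ValidationError("network.distance_threshold must be positive")
        if not (0.0 < net["bootstrap_fraction"] <= 1.0):
            raise ValidationError("network.bootstrap_fraction must be in (0, 1]")
        if net["bootstrap_repeats"] < 1:
            raise ValidationError("network.bootstrap_repeats must be >= 1")
        iface = d["interface"]
        if iface["probe_radius"] <= 0 or iface["n_points"] < 32:
            raise ValidationError("interface probe/n_points out of range")
        clus = d["clustering"]
        if not (0.0 < clus["coverage"] < 1.0) or clus["grid_step"] <= 0:
            raise ValidationError("clustering coverage/grid_step out of range")
        if d["energetics"]["n_common"] > d["energetics"]["n_stabilized"]:
            raise ValidationError("energetics.n_common cannot exceed n_stabilized")

    def synthetic_spec(self) -> SyntheticSpec:
        s = self.data["synthetic"]
        return SyntheticSpec(
            n_residues_per_chain=s["n_residues_per_chain"],
            atoms_per_residue=s["atoms_per_residue"],
            n_frames=s["n_frames"],
            dissociation_amplitude_stddev=s["dissociation_amplitude_stddev"],
            noise_stddev=s["noise_stddev"],
            contact_targets=[
                ((a[0], int(a[1])), (b[0], int(b[1])), float(q))
                for a, b, q in s["contact_targets"]
            ],
            seed=self.data["seed"] + _STAGE_SEED_OFFSETS["simulate"],
        )


# ---------------------------------------------------------------------------
# Manifest helpers
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _write_manifest(stage_dir: Path, stage: str, params: dict, inputs: list, outputs: list) -> None:
    manifest = {
        "stage": stage,
        "parameters": params,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
        "outputs": {Path(p).name: _sha256(Path(p)) for p in outputs},
    }
    _write_json(stage_dir / "manifest.json", manifest)


def _stage_is_current(stage_dir: Path, params: dict) -> bool:
    mpath = stage_dir / "manifest.json"
    if not mpath.exists():
        return False
    try:
        manifest = json.loads(mpath.read_text())
    except json.JSONDecodeError:
        return False
    if json.loads(json.dumps(params)) != manifest.get("parameters"):
        return False
    for name, digest in manifest.get("outputs", {}).items():
        out = stage_dir / name
        if not out.exists() or _sha256(out) != digest:
            return False
    return True


def _res_key(res: tuple) -> str:
    return f"{res[0]}:{res[1]}"


def _parse_res_key(key: str) -> tuple:
    chain, res = key.split(":")
    return (chain, int(res))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(config: PipelineConfig, outdir: Path, resume: bool):
    """Write (or reload) the synthetic topology, ensemble and ground truth."""
    stage_dir = outdir / "simulate"
    stage_dir.mkdir(parents=True, exist_ok=True)
    spec = config.synthetic_spec()
    params = {"spec": spec.to_json()}
    topo_path = stage_dir / "topology.pdb"
    ens_path = stage_dir / "ensemble.pdb"
    coeff_path = stage_dir / "coefficients.csv"
    spec_path = stage_dir / "spec.json"
    if resume and _stage_is_current(stage_dir, params):
        log.info("simulate: reusing existing artifacts")
        model = read_structure(str(topo_path))
        traj = read_ensemble(model, str(ens_path))
        coeffs = pd.read_csv(coeff_path)
        return model, traj, coeffs
    log.info("simulate: generating toy dimer ensemble (%d frames)", spec.n_frames)
    model = build_toy_dimer(spec)
    traj, coeffs = generate_ensemble(model, spec)
    write_structure(model, str(topo_path))
    write_ensemble(traj, str(ens_path))
    coeffs.to_csv(coeff_path, index=False)
    _write_json(spec_path, spec.to_json())
    _write_manifest(stage_dir, "simulate", params, [], [topo_path, ens_path, coeff_path, spec_path])
    # Round-trip through the PDB fixed-width format so downstream numbers are
    # identical whether the ensemble is recomputed or reloaded.
    model = read_structure(str(topo_path))
    traj = read_ensemble(model, str(ens_path))
    return model, traj, coeffs


def stage_geometry(config: PipelineConfig, outdir: Path, traj: TrajectoryEnsemble, resume: bool):
    stage_dir = outdir / "geometry"
    stage_dir.mkdir(parents=True, exist_ok=True)
    params = {"selection": "calpha", "reference": "first_frame"}
    outputs = [stage_dir / n for n in ("rmsd.csv", "rmsf.csv", "center_distance.csv")]
    aligned = align_ensemble(traj, reference="first_frame")
    if not (resume and _stage_is_current(stage_dir, params)):
        log.info("geometry: RMSD / RMSF / center distance")
        rmsd = rmsd_series(traj)
        pd.DataFrame({"frame": traj.frame_labels, "rmsd_A": rmsd}).to_csv(outputs[0], index=False)
        residues, rmsf = rmsf_profile(aligned)
        pd.DataFrame(
            {
                "chain": [c for c, _ in residues],
                "residue": [r for _, r in residues],
                "rmsf_A": rmsf,
            }
        ).to_csv(outputs[1], index=False)
        chains = traj.model.chains
        dist = chain_center_distance(traj, chains[0], chains[1])
        pd.DataFrame({"frame": traj.frame_labels, "distance_A": dist}).to_csv(outputs[2], index=False)
        _write_manifest(stage_dir, "geometry", params, [], outputs)
    return aligned


def stage_interface(config: PipelineConfig, outdir: Path, model, traj, resume: bool):
    stage_dir = outdir / "interface"
    stage_dir.mkdir(parents=True, exist_ok=True)
    p = config["interface"]
    params = dict(p)
    res_path = stage_dir / "interface_residues.csv"
    series_path = stage_dir / "sasa_series.csv"
    if resume and _stage_is_current(stage_dir, params):
        log.info("interface: reusing existing artifacts")
        df = pd.read_csv(res_path)
        residues = ResidueSelection(list(zip(df["chain"], df["residue"])))
        iface = InterfaceSet(
            residues=residues,
            delta_sasa={
                (str(c), int(r)): float(d)
                for c, r, d in zip(df["chain"], df["residue"], df["delta_sasa_A2"])
            },
        )
        series = pd.read_csv(series_path)["interface_sasa_A2"].to_numpy()
        return iface, series
    log.info("interface: SASA-loss interface detection + per-frame series")
    chains = model.chains
    iface = detect_interface(
        model,
        chain_pair=(chains[0], chains[1]),
        tolerance=p["tolerance"],
        probe_radius=p["probe_radius"],
        n_points=p["n_points"],
    )
    pd.DataFrame(
        {
            "chain": [c for c, _ in iface.residues],
            "residue": [r for _, r in iface.residues],
            "delta_sasa_A2": [iface.delta_sasa[k] for k in iface.residues],
        }
    ).to_csv(res_path, index=False)
    series = interface_sasa_series(
        traj, iface, probe_radius=p["probe_radius"], n_points=p["n_points"]
    )
    pd.DataFrame({"frame": traj.frame_labels, "interface_sasa_A2": series}).to_csv(
        series_path, index=False
    )
    _write_manifest(stage_dir, "interface", params, [], [res_path, series_path])
    return iface, series


def stage_pca(config: PipelineConfig, outdir: Path, aligned, resume: bool) -> ModeSet:
    stage_dir = outdir / "pca"
    stage_dir.mkdir(parents=True, exist_ok=True)
    params = dict(config["pca"])
    modes_path = stage_dir / "modes.csv"
    var_path = stage_dir / "variances.csv"
    mean_path = stage_dir / "mean_structure.csv"
    if resume and _stage_is_current(stage_dir, params):
        log.info("pca: reusing existing artifacts")
        return _load_modeset(aligned, modes_path, var_path, mean_path)
    log.info("pca: %d modes of the Calpha covariance", params["n_modes"])
    modeset = pca(aligned, k=params["n_modes"])
    rows = []
    for k in range(modeset.n_modes):
        vecs = modeset.modes[k].reshape(-1, 3)
        for (chain, res), (x, y, z) in zip(modeset.residue_keys, vecs):
            rows.append({"mode": k, "chain": chain, "residue": res, "x": x, "y": y, "z": z})
    pd.DataFrame(rows).to_csv(modes_path, index=False)
    pd.DataFrame(
        {"mode": np.arange(modeset.n_modes), "variance_A2": modeset.variances}
    ).to_csv(var_path, index=False)
    pd.DataFrame(
        {
            "chain": [c for c, _ in modeset.residue_keys],
            "residue": [r for _, r in modeset.residue_keys],
            "x": modeset.mean_structure[:, 0],
            "y": modeset.mean_structure[:, 1],
            "z": modeset.mean_structure[:, 2],
        }
    ).to_csv(mean_path, index=False)
    _write_manifest(stage_dir, "pca", params, [], [modes_path, var_path, mean_path])
    return modeset


def _load_modeset(aligned, modes_path, var_path, mean_path) -> ModeSet:
    modes_df = pd.read_csv(modes_path)
    var_df = pd.read_csv(var_path)
    mean_df = pd.read_csv(mean_path)
    from .core import select as _select

    sel = _select(aligned.model, "calpha")
    residue_keys = [
        (str(aligned.model.chain_ids[i]), int(aligned.model.residue_indices[i]))
        for i in sel
    ]
    n_modes = int(modes_df["mode"].max()) + 1
    modes = np.stack(
        [
            modes_df[modes_df["mode"] == k][["x", "y", "z"]].to_numpy().ravel()
            for k in range(n_modes)
        ]
    )
    # Written at CSV precision; restore exact unit norm / orthogonality.
    modes, _ = np.linalg.qr(modes.T)
    modes = modes.T
    from .modes import _fix_mode_signs

    modes = _fix_mode_signs(modes)
    return ModeSet(
        atom_indices=sel,
        residue_keys=residue_keys,
        mean_structure=mean_df[["x", "y", "z"]].to_numpy(),
        modes=modes,
        variances=var_df["variance_A2"].to_numpy(),
    )


def stage_fma(config: PipelineConfig, outdir: Path, aligned, modeset: ModeSet, series, resume: bool):
    stage_dir = outdir / "fma"
    stage_dir.mkdir(parents=True, exist_ok=True)
    params = dict(config["fma"])
    report_path = stage_dir / "fma_report.json"
    mode_path = stage_dir / "fma_mode.csv"
    amp_path = stage_dir / "amplitudes.csv"
    log.info("fma: PLS functional mode vs interface SASA")
    functional = fma(
        aligned,
        modeset,
        series,
        n_components=params["n_components"],
        top_k=params["top_k"],
    )
    projection = project_mode(functional.mode, modeset, top_k=params["top_k"])
    best = projection.best_index
    report = {
        "train_pcc": functional.train_pcc,
        "validation_pcc": functional.validation_pcc,
        "pc_coefficients": functional.pc_coefficients.tolist(),
        "regression_coefficients": functional.regression_coefficients.tolist(),
        "projection_pccs": projection.pccs.tolist(),
        "best_pc_index": best,
        "best_pc_pcc": projection.best_pcc,
    }
    _write_json(report_path, report)
    vecs = functional.mode.reshape(-1, 3)
    pd.DataFrame(
        {
            "chain": [c for c, _ in modeset.residue_keys],
            "residue": [r for _, r in modeset.residue_keys],
            "x": vecs[:, 0],
            "y": vecs[:, 1],
            "z": vecs[:, 2],
        }
    ).to_csv(mode_path, index=False)
    # Per-residue amplitude table: the best PC mode vs the functional mode,
    # with the cosine between the residue's directions in the two.
    rows = []
    for key in modeset.residue_keys:
        amp_pc = residue_amplitude(modeset, best, key)
        block = functional.mode.reshape(-1, 3)[modeset.residue_keys.index(key)]
        amp_fm = float(np.linalg.norm(block))
        d_pc = residue_direction(modeset, best, key)
        cosine = ""
        if d_pc is not None and amp_fm >= 1e-6:
            cosine = float(np.dot(d_pc, block / amp_fm))
        rows.append(
            {
                "chain": key[0],
                "residue": key[1],
                "amplitude_best_pc": amp_pc,
                "amplitude_functional_mode": amp_fm,
                "direction_cosine": cosine,
            }
        )
    pd.DataFrame(rows).to_csv(amp_path, index=False)
    _write_manifest(stage_dir, "fma", params, [], [report_path, mode_path, amp_path])
    return functional, projection


def stage_network(config: PipelineConfig, outdir: Path, traj, modeset: ModeSet,
                  mode_index: int, targets: ResidueSelection, resume: bool):
    stage_dir = outdir / "network"
    stage_dir.mkdir(parents=True, exist_ok=True)
    p = config["network"]
    params = dict(p) | {"resolved_mode_index": mode_index}
    log.info("network: contacts + mode-direction networks (mode %d)", mode_index)
    cf = contact_frames(traj, distance=p["distance_threshold"])
    occ = occupancy_from_frames(cf)
    nets = build_network(
        modeset,
        mode_index,
        occ,
        angle_threshold=p["angle_threshold"],
        occupancy_threshold=p["occupancy_threshold"],
        exclude_sequence_window=p["exclude_sequence_window"],
    )
    outputs = []
    summaries = {}
    import networkx as nx

    for net in nets:
        edge_path = stage_dir / f"edges_{net.chain_id}.csv"
        rows = [
            {
                "chain": net.chain_id,
                "res_i": a[1],
                "res_j": b[1],
                "occupancy": net.graph.edges[a, b]["occupancy"],
                "direction_cosine": net.graph.edges[a, b]["direction_cosine"],
            }
            for a, b in net.graph.edges
        ]
        pd.DataFrame(rows).to_csv(edge_path, index=False)
        outputs.append(edge_path)
        if net.graph.number_of_nodes():
            s = summarize(net)
            summaries[net.chain_id] = {
                "n_nodes": s.n_nodes,
                "n_edges": s.n_edges,
                "average_degree": s.average_degree,
                "average_clustering_coefficient": s.average_clustering_coefficient,
            }
            gml_path = stage_dir / f"network_{net.chain_id}.graphml"
            relabel = {n: _res_key(n) for n in net.graph.nodes}
            nx.write_graphml(nx.relabel_nodes(net.graph, relabel), gml_path)
            outputs.append(gml_path)
    summary_path = stage_dir / "summary.json"
    _write_json(summary_path, summaries)
    outputs.append(summary_path)

    boot = bootstrap_networks(
        traj,
        modeset,
        mode_index,
        fraction=p["bootstrap_fraction"],
        repeats=p["bootstrap_repeats"],
        seed=config["seed"] + _STAGE_SEED_OFFSETS["bootstrap"],
        distance=p["distance_threshold"],
        angle_threshold=p["angle_threshold"],
        occupancy_threshold=p["occupancy_threshold"],
        exclude_sequence_window=p["exclude_sequence_window"],
        precomputed_contacts=cf,
    )
    boot_path = stage_dir / "bootstrap.json"
    _write_json(boot_path, {"mean": boot.mean, "sd": boot.sd})
    outputs.append(boot_path)

    source = p["path_source"]
    if source is None:
        chain0 = traj.model.chains[0]
        chain_res = [r for c, r in traj.model.residues() if c == chain0]
        source = (chain0, chain_res[len(chain_res) // 2])
    else:
        source = (str(source[0]), int(source[1]))
    paths_path = stage_dir / "paths.json"
    try:
        report = shortest_paths(nets, source, targets)
        _write_json(
            paths_path,
            {
                "source": _res_key(report.source),
                "targets": {
                    _res_key(t): {
                        "length": report.lengths[t],
                        "n_shortest_paths": report.n_paths[t],
                        "example": (
                            [_res_key(r) for r in report.example_paths[t]]
                            if report.example_paths[t]
                            else None
                        ),
                    }
                    for t in report.targets
                },
            },
        )
    except ValidationError as exc:
        _write_json(paths_path, {"error": str(exc)})
        report = None
    outputs.append(paths_path)
    _write_manifest(stage_dir, "network", params, [], outputs)
    return nets, summaries, boot, report


def stage_energetics(config: PipelineConfig, outdir: Path, model, resume: bool):
    stage_dir = outdir / "energetics"
    stage_dir.mkdir(parents=True, exist_ok=True)
    p = config["energetics"]
    params = dict(p)
    seed = config["seed"]
    log.info("energetics: windowed stats, Welch tests, key residues")
    series = {}
    outputs = []
    for i, (system, (mean, sd)) in enumerate(DEFAULT_ENERGY_SYSTEMS.items()):
        s = generate_energy_series(
            system,
            mean,
            sd,
            n_frames=p["n_frames"],
            seed=seed + _STAGE_SEED_OFFSETS["energy_series"] + i,
        )
        path = stage_dir / f"series_{system}.csv"
        write_energy_series(s, str(path))
        series[system] = read_energy_series(str(path))
        outputs.append(path)

    report: dict = {"windowed": {}, "comparisons": {}}
    for system, s in series.items():
        stats_df = windowed_stats(s, p["windows_ns"])
        report["windowed"][system] = stats_df.to_dict(orient="records")
    for a, b in (("hBBCK", "BP36L"), ("hMMCK", "ML36P")):
        cmp_res = compare_systems(series[a], series[b])
        report["comparisons"][f"{a}_vs_{b}"] = {
            "mean_difference": cmp_res.mean_difference,
            "t_statistic": cmp_res.t_statistic,
            "p_value": cmp_res.p_value,
            "p_label": cmp_res.p_label,
        }

    # Per-residue tables: two wild-type/mutant pairs whose key-residue sets
    # share a planted common core.
    residues = ResidueSelection(model.residues())
    n_stab = p["n_stabilized"]
    n_common = p["n_common"]
    universe = residues.entries
    stabilized = set(universe[1 : 1 + n_stab])
    common = set(universe[1 : 1 + n_common])
    extra = set(universe[1 + n_stab : 1 + n_stab + 4])
    destabilized_second = common | extra
    pair1 = generate_energy_tables(
        residues,
        stabilized,
        set(),
        effect_size=p["effect_size"],
        noise=p["noise"],
        seed=seed + _STAGE_SEED_OFFSETS["energy_tables"],
        wt_id="hBBCK",
        mut_id="BP36L",
    )
    pair2 = generate_energy_tables(
        residues,
        set(),
        destabilized_second,
        effect_size=p["effect_size"],
        noise=p["noise"],
        seed=seed + _STAGE_SEED_OFFSETS["energy_tables"] + 1,
        wt_id="hMMCK",
        mut_id="ML36P",
    )
    for table in (*pair1, *pair2):
        path = stage_dir / f"table_{table.system_id}.csv"
        write_energy_table(table, str(path))
        outputs.append(path)
    pair1 = tuple(
        read_energy_table(str(stage_dir / f"table_{t.system_id}.csv")) for t in pair1
    )
    pair2 = tuple(
        read_energy_table(str(stage_dir / f"table_{t.system_id}.csv")) for t in pair2
    )
    key_stab = select_key_residues(*pair1, threshold=p["threshold"], direction="stabilizing")
    key_destab = select_key_residues(*pair2, threshold=p["threshold"], direction="destabilizing")
    common_sel = common_key_residues(key_stab, key_destab)
    report["key_residues"] = {
        "stabilizing": [
            {"residue": _res_key(r), "ddG": key_stab.ddG[r]} for r in key_stab.selection
        ],
        "destabilizing": [
            {"residue": _res_key(r), "ddG": key_destab.ddG[r]}
            for r in key_destab.selection
        ],
        "common": [_res_key(r) for r in common_sel],
    }
    report_path = stage_dir / "report.json"
    _write_json(report_path, report)
    outputs.append(report_path)
    _write_manifest(stage_dir, "energetics", params, [], outputs)
    return report, common_sel


def stage_cluster(config: PipelineConfig, outdir: Path, traj, resume: bool):
    stage_dir = outdir / "cluster"
    stage_dir.mkdir(parents=True, exist_ok=True)
    p = config["clustering"]
    params = dict(p)
    log.info("cluster: pairwise-RMSD conformational clustering")
    stride = max(1, int(np.ceil(traj.n_frames / p["max_frames"])))
    sub = TrajectoryEnsemble(
        model=traj.model,
        frames=traj.frames[::stride],
        frame_labels=traj.frame_labels[::stride],
        aligned=traj.aligned,
    )
    matrix = pairwise_rmsd_matrix(sub)
    result = select_cutoff(
        matrix,
        top_n=p["top_n"],
        coverage=p["coverage"],
        grid_step=p["grid_step"],
        frame_labels=sub.frame_labels,
    )
    clusters_path = stage_dir / "clusters.json"
    _write_json(
        clusters_path,
        {
            "cutoff_A": result.cutoff,
            "n_clusters": len(result.clusters),
            "sizes": result.sizes,
            "coverage_top8": result.coverage_top8,
            "representatives": result.representatives,
            "clusters": result.clusters,
            "stride": stride,
        },
    )
    rep_path = stage_dir / "representatives.pdb"
    label_to_pos = {int(l): i for i, l in enumerate(sub.frame_labels)}
    rep_frames = sub.frames[[label_to_pos[r] for r in result.representatives]]
    write_ensemble(
        TrajectoryEnsemble(
            model=traj.model,
            frames=rep_frames,
            frame_labels=np.array(result.representatives),
            aligned=traj.aligned,
        ),
        str(rep_path),
    )
    _write_manifest(stage_dir, "cluster", params, [], [clusters_path, rep_path])
    return result


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

STAGES = ("simulate", "geometry", "interface", "pca", "fma", "network",
          "energetics", "cluster")


def run_pipeline(
    config: PipelineConfig, upto: str = "cluster", resume: bool = True
) -> dict:
    """Run the pipeline through stage ``upto`` and return a report bundle."""
    if upto not in STAGES:
        raise ValidationError(f"unknown stage {upto!r}")
    outdir = Path(config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"output_dir": str(outdir)}
    last = STAGES.index(upto)

    def _wants(stage: str) -> bool:
        return STAGES.index(stage) <= last

    try:
        if config["input"]["topology"]:
            model = read_structure(config["input"]["topology"])
            traj = read_ensemble(model, config["input"]["ensemble"])
            bundle["source"] = "user input"
        else:
            model, traj, _ = stage_simulate(config, outdir, resume)
            bundle["source"] = "synthetic"
        if not _wants("geometry"):
            return bundle
        aligned = stage_geometry(config, outdir, traj, resume)
        if not _wants("interface"):
            return bundle
        iface, series = stage_interface(config, outdir, model, traj, resume)
        bundle["n_interface_residues"] = len(iface.residues)
        if not _wants("pca"):
            return bundle
        modeset = stage_pca(config, outdir, aligned, resume)
        bundle["pca_variances"] = modeset.variances.tolist()
        if not _wants("fma"):
            return bundle
        functional, projection = stage_fma(config, outdir, aligned, modeset, series, resume)
        bundle["fma_validation_pcc"] = functional.validation_pcc
        bundle["best_pc_index"] = projection.best_index
        if not _wants("network"):
            return bundle
        if not _wants("energetics"):
            mode_index = (
                config["network"]["mode_index"]
                if config["network"]["mode_index"] is not None
                else projection.best_index
            )
            targets = ResidueSelection([])
            stage_network(config, outdir, traj, modeset, mode_index, targets, resume)
            return bundle
        report, common_sel = stage_energetics(config, outdir, model, resume)
        bundle["energetics"] = {
            "n_stabilizing": len(report["key_residues"]["stabilizing"]),
            "n_common": len(report["key_residues"]["common"]),
        }
        mode_index = (
            config["network"]["mode_index"]
            if config["network"]["mode_index"] is not None
            else projection.best_index
        )
        nets, summaries, boot, path_report = stage_network(
            config, outdir, traj, modeset, mode_index, common_sel, resume
        )
        bundle["network"] = summaries
        if not _wants("cluster"):
            return bundle
        cluster = stage_cluster(config, outdir, traj, resume)
        bundle["clustering"] = {
            "cutoff_A": cluster.cutoff,
            "n_clusters": len(cluster.clusters),
            "coverage_top8": cluster.coverage_top8,
        }
    except ValidationError:
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc
    return bundle


def simulate_to_disk(config: PipelineConfig) -> dict:
    """The ``simulate`` subcommand: write the synthetic dataset and its
    ground truth (plus the energetics tables) to disk."""
    outdir = Path(config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    model, traj, coeffs = stage_simulate(config, outdir, resume=False)
    stage_energetics(config, outdir, model, resume=False)
    return {"output_dir": str(outdir), "n_frames": traj.n_frames}
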