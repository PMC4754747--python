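"""Solvent accessible surface area (Shrake-Rupley) and interface detection.

The SASA of an atom is the fraction of deterministic, quasi-uniform sphere
points (a Fibonacci lattice on the expanded sphere of radius r_vdw + probe)
not buried inside any neighbouring atom's expanded sphere, times the full
sphere area.  Deterministic points make every SASA value exactly
reproducible for a fixed point count.

The dimer interface is detected on the static reference structure as the
set of residues whose SASA decreases when the two rigid chains are
associated, compared with each chain in isolation.  The per-frame total
SASA of those residues is the scalar "degree of dissociation" series driving
the functional mode analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import (
    ResidueSelection,
    StructureModel,
    TrajectoryEnsemble,
    ValidationError,
)


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (Fibonacci lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i  # golden angle increments
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class SasaResult:
    per_atom: np.ndarray  # Angstrom^2, aligned with the atom subset used
    atom_indices: np.ndarray  # model atom indices the values refer to
    per_residue: dict  # (chain_id, residue_index) -> Angstrom^2
    total: float  # Angstrom^2


def _resolve_atoms(model: StructureModel, include_hydrogens: bool) -> np.ndarray:
    if include_hydrogens:
        return np.arange(model.n_atoms)
    return np.where(np.array([e != "H" for e in model.elements]))[0]


def sasa(
    model: StructureModel,
    coordinates: np.ndarray | None = None,
    atom_subset: np.ndarray | None = None,
    probe_radius: float = 1.4,
    n_points: int = 960,
    include_hydrogens: bool = False,
) -> SasaResult:
    """Shrake-Rupley SASA of ``atom_subset`` (default: all heavy atoms).

    Atoms outside the subset do not occlude; the subset defines the molecule
    whose surface is measured.  ``coordinates`` defaults to the model's
    reference coordinates.
    """
    if n_points < 32:
        raise ValidationError("n_points < 32 is below the accuracy floor")
    coords = (
        np.asarray(coordinates, dtype=float)
        if coordinates is not None
        else model.reference_coordinates
    )
    if coords.shape != (model.n_atoms, 3):
        raise ValidationError("coordinates must match the model's atom count")
    atoms = (
        np.asarray(atom_subset, dtype=int)
        if atom_subset is not None
        else _resolve_atoms(model, include_hydrogens)
    )
    pts = sphere_points(n_points)
    sub_coords = coords[atoms]
    radii = model.vdw_radii[atoms] + probe_radius
    tree = cKDTree(sub_coords)
    max_r = radii.max()
    per_atom = np.empty(len(atoms))
    for k in range(len(atoms)):
        center = sub_coords[k]
        r_k = radii[k]
        neigh = tree.query_ball_point(center, r_k + max_r)
        neigh = [j for j in neigh if j != k]
        surface = center + r_k * pts
        if neigh:
            ncoords = sub_coords[neigh]
            nradii = radii[neigh]
            close = np.linalg.norm(ncoords - center, axis=1) < r_k + nradii
            ncoords = ncoords[close]
            nradii = nradii[close]
        if neigh and len(ncoords):
            d2 = (
                (surface[:, None, :] - ncoords[None, :, :]) ** 2
            ).sum(axis=2)
            buried = (d2 < (nradii**2)[None, :]).any(axis=1)
            exposed = np.count_nonzero(~buried)
        else:
            exposed = n_points
        per_atom[k] = (exposed / n_points) * 4.0 * np.pi * r_k**2
    per_residue: dict[tuple[str, int], float] = {}
    for k, i in enumerate(atoms):
        key = (str(model.chain_ids[i]), int(model.residue_indices[i]))
        per_residue[key] = per_residue.get(key, 0.0) + per_atom[k]
    return SasaResult(
        per_atom=per_atom,
        atom_indices=atoms,
        per_residue=per_residue,
        total=float(per_atom.sum()),
    )


@dataclass
class InterfaceSet:
    residues: ResidueSelection
    delta_sasa: dict  # (chain, residue) -> Angstrom^2 buried on association


def detect_interface(
    model: StructureModel,
    chain_pair: tuple[str, str] = ("A", "B"),
    tolerance: float = 0.1,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> InterfaceSet:
    """Interface residues of the static structure: residues whose SASA drops
    by more than ``tolerance`` Angstrom^2 when the two rigid chains associate.
    """
    chain_a, chain_b = chain_pair
    for c in chain_pair:
        if c not in model.chains:
            raise ValidationError(f"chain {c!r} not in model")
    heavy = _resolve_atoms(model, include_hydrogens=False)
    in_pair = np.array(
        [model.chain_ids[i] in (chain_a, chain_b) for i in heavy]
    )
    pair_atoms = heavy[in_pair]
    complex_sasa = sasa(
        model, atom_subset=pair_atoms, probe_radius=probe_radius, n_points=n_points
    )
    delta: dict[tuple[str, int], float] = {}
    for chain in chain_pair:
        chain_atoms = pair_atoms[
            np.array([model.chain_ids[i] == chain for i in pair_atoms])
        ]
        isolated = sasa(
            model,
            atom_subset=chain_atoms,
            probe_radius=probe_radius,
            n_points=n_points,
        )
        for key, iso_val in isolated.per_residue.items():
            d = iso_val - complex_sasa.per_residue[key]
            if d > tolerance:
                delta[key] = d
    if not delta:
        warnings.warn("no interface residues detected (chains do not touch)")
    ordered = [r for r in model.residues() if r in delta]
    return InterfaceSet(
        residues=ResidueSelection(ordered),
        delta_sasa={k: delta[k] for k in ordered},
    )


def interface_sasa_series(
    traj: TrajectoryEnsemble,
    interface: InterfaceSet,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-frame total SASA (Angstrom^2) of the interface residues in the
    complex — the scalar dissociation coordinate for the functional mode
    analysis (larger SASA = more exposed interface = more dissociated).
    """
    if len(interface.residues) == 0:
        raise ValidationError("interface set is empty")
    model = traj.model
    members = set(interface.residues.entries)
    series = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        result = sasa(
            model,
            coordinates=traj.frames[t],
            probe_radius=probe_radius,
            n_points=n_points,
        )
        series[t] = sum(
            v for k, v in result.per_residue.items() if k in members
        )
    return series
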