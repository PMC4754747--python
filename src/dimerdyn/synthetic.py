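"""Synthetic dimer ensembles with planted ground truth.

The generator emulates the statistical structure of an MD ensemble of a
two-chain protein at desk scale: a toy dimer of two facing extended strands
(one Cα plus pseudo side-chain atoms per residue), Gaussian-weighted
orthonormal collective modes, one planted "dissociation" mode that rigidly
translates chain B away from chain A along the interface normal (and hence
modulates the interface SASA), isotropic thermal noise, and residue-residue
contacts switched across the contact-distance threshold by a seeded
Bernoulli schedule so that contact occupancies are controllable.

Randomness: one ``numpy`` Generator per call, seeded from ``spec.seed``.
Draw order is fixed and documented in :func:`generate_ensemble` so adding a
parameter never silently shifts existing draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .core import (
    ResidueSelection,
    StructureModel,
    TrajectoryEnsemble,
    ValidationError,
)
from .energetics import EnergySeries, EnergyTable

#: toy-geometry constants (Angstrom)
CA_SPACING = 3.8  # along the strand (x axis)
INTERFACE_SEPARATION = 4.0  # between facing Cα rows (y axis)
SIDECHAIN_OFFSET = np.array([0.0, 1.2, 0.8])  # away from the interface
CONTACT_DISTANCE = 3.8  # planted pair distance in contact frames
NO_CONTACT_DISTANCE = 6.5  # planted pair distance otherwise
CONTACT_ELEVATION_DEG = 80.0  # lift planted contacts out of the strand plane


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dimer dataset.

    ``planted_modes`` entries are (displacement_field, stddev) with the field
    shaped (A, 3); ``None`` uses two smooth sinusoidal out-of-plane fields
    with stddevs 0.8 and 0.5 Angstrom.  ``contact_targets`` entries are
    ((chain, residue), (chain, residue), occupancy).
    """

    n_residues_per_chain: int = 24
    atoms_per_residue: int = 2
    n_frames: int = 2000
    planted_modes: list | None = None
    dissociation_amplitude_stddev: float = 1.2
    noise_stddev: float = 0.1
    contact_targets: list = dc_field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.n_residues_per_chain < 4:
            raise ValidationError("need at least 4 residues per chain")
        if self.atoms_per_residue < 1:
            raise ValidationError("need at least one atom per residue")
        if self.n_frames < 1:
            raise ValidationError("need at least one frame")
        if self.dissociation_amplitude_stddev < 0 or self.noise_stddev < 0:
            raise ValidationError("stddevs must be non-negative")
        seen: set = set()
        for a, b, q in self.contact_targets:
            if not (0.0 <= q <= 1.0):
                raise ValidationError("contact occupancy must be in [0, 1]")
            ka, kb = (str(a[0]), int(a[1])), (str(b[0]), int(b[1]))
            if ka == kb:
                raise ValidationError("contact target must join two residues")
            for k in (ka, kb):
                if k in seen:
                    raise ValidationError(
                        f"residue {k} appears in more than one contact target"
                    )
                seen.add(k)
        if self.contact_targets and self.atoms_per_residue < 2:
            raise ValidationError(
                "contact planting needs a pseudo side-chain atom per residue"
            )

    def to_json(self) -> dict:
        return {
            "n_residues_per_chain": self.n_residues_per_chain,
            "atoms_per_residue": self.atoms_per_residue,
            "n_frames": self.n_frames,
            "planted_modes": (
                None
                if self.planted_modes is None
                else [
                    {"field": np.asarray(f).tolist(), "stddev": float(s)}
                    for f, s in self.planted_modes
                ]
            ),
            "dissociation_amplitude_stddev": self.dissociation_amplitude_stddev,
            "noise_stddev": self.noise_stddev,
            "contact_targets": [
                [[str(a[0]), int(a[1])], [str(b[0]), int(b[1])], float(q)]
                for a, b, q in self.contact_targets
            ],
            "seed": self.seed,
        }

    @classmethod
    def from_json(cls, data: dict) -> "SyntheticSpec":
        modes = data.get("planted_modes")
        if modes is not None:
            modes = [
                (np.asarray(m["field"], dtype=float), float(m["stddev"]))
                for m in modes
            ]
        return cls(
            n_residues_per_chain=int(data["n_residues_per_chain"]),
            atoms_per_residue=int(data["atoms_per_residue"]),
            n_frames=int(data["n_frames"]),
            planted_modes=modes,
            dissociation_amplitude_stddev=float(
                data["dissociation_amplitude_stddev"]
            ),
            noise_stddev=float(data["noise_stddev"]),
            contact_targets=[
                ((a[0], int(a[1])), (b[0], int(b[1])), float(q))
                for a, b, q in data.get("contact_targets", [])
            ],
            seed=int(data["seed"]),
        )


# ---------------------------------------------------------------------------
# Toy dimer geometry
# ---------------------------------------------------------------------------


def build_toy_dimer(spec: SyntheticSpec) -> StructureModel:
    """Two facing extended strands, chains A and B, 4.0 Angstrom apart.

    Residue i of each chain sits at x = (i-1) * 3.8 Angstrom; chain A's Cα
    row is at y = 0 and chain B's at y = +4.0, so facing Cα pairs are
    exactly 4.0 Angstrom apart.  Pseudo side-chain atoms point away from
    the interface at fixed offsets.  Deterministic for a fixed spec.
    """
    spec.validate()
    n = spec.n_residues_per_chain
    names, elements, radii, res_idx, res_names, chain_ids, coords = (
        [], [], [], [], [], [], []
    )
    for chain, y_ca, sc_sign in (("A", 0.0, -1.0), ("B", INTERFACE_SEPARATION, 1.0)):
        for i in range(n):
            x = i * CA_SPACING
            ca = np.array([x, y_ca, 0.0])
            positions = [ca]
            atom_names = ["CA"]
            for k in range(1, spec.atoms_per_residue):
                offset = SIDECHAIN_OFFSET + np.array([0.0, 1.0, 0.0]) * (k - 1)
                positions.append(ca + np.array([0.0, sc_sign * offset[1], offset[2]]))
                atom_names.append(f"CB{k}")
            for name, pos in zip(atom_names, positions):
                names.append(name)
                elements.append("C")
                radii.append(1.70)
                res_idx.append(i + 1)
                res_names.append("ALA")
                chain_ids.append(chain)
                coords.append(pos)
    return StructureModel(
        atom_names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        vdw_radii=np.array(radii, dtype=float),
        residue_indices=np.array(res_idx, dtype=int),
        residue_names=np.array(res_names, dtype=object),
        chain_ids=np.array(chain_ids, dtype=object),
        reference_coordinates=np.array(coords, dtype=float),
    )


# ---------------------------------------------------------------------------
# Planted displacement fields
# ---------------------------------------------------------------------------


def dissociation_field(model: StructureModel, chain: str = "B") -> np.ndarray:
    """Displacement field (A x 3) translating one chain by one Angstrom per
    unit coefficient along the interface normal (+y): the planted
    dissociation motion."""
    field = np.zeros((model.n_atoms, 3))
    field[model.chain_ids == chain, 1] = 1.0
    return field


def default_planted_fields(model: StructureModel) -> list:
    """Two smooth out-of-plane (z) sinusoidal residue-level fields,
    orthogonalized against rigid-body motion and each other, with stddevs
    0.8 and 0.5 Angstrom."""
    from .modes import rigid_body_basis

    residues = model.residues()
    n_res = len(residues)
    res_of_atom = np.array(
        [
            residues.index((str(c), int(r)))
            for c, r in zip(model.chain_ids, model.residue_indices)
        ]
    )
    phases = (np.arange(n_res) + 0.5) / n_res
    profiles = [np.sin(2 * np.pi * phases), np.cos(4 * np.pi * phases)]
    rigid = rigid_body_basis(model.reference_coordinates)
    fields = []
    basis = [row for row in rigid]
    for profile in profiles:
        f = np.zeros((model.n_atoms, 3))
        f[:, 2] = profile[res_of_atom]
        flat = f.ravel()
        for b in basis:
            flat = flat - b * np.dot(b, flat)
        flat = flat / np.linalg.norm(flat)
        basis.append(flat)
        fields.append(flat.reshape(model.n_atoms, 3))
    return [(fields[0], 0.8), (fields[1], 0.5)]


def _orthonormalize(fields: list[np.ndarray]) -> np.ndarray:
    """Gram-Schmidt over flattened fields; error when near-degenerate."""
    flats = [np.asarray(f, dtype=float).ravel() for f in fields]
    flats = [f / np.linalg.norm(f) for f in flats]
    for i in range(len(flats)):
        for j in range(i + 1, len(flats)):
            if abs(np.dot(flats[i], flats[j])) > 0.99:
                raise ValidationError(
                    f"planted fields {i} and {j} are near-degenerate"
                )
    out = []
    for f in flats:
        for g in out:
            f = f - g * np.dot(g, f)
        norm = np.linalg.norm(f)
        if norm < 1e-8:
            raise ValidationError("planted fields are linearly dependent")
        out.append(f / norm)
    return np.array(out)


# ---------------------------------------------------------------------------
# Ensemble generation
# ---------------------------------------------------------------------------


def generate_ensemble(
    model: StructureModel, spec: SyntheticSpec
) -> tuple[TrajectoryEnsemble, pd.DataFrame]:
    """Sample frames around the reference structure.

    frame_t = reference + sum_k a_k(t) m_k + d(t) m_diss + eps(t), with
    a_k ~ Normal(0, stddev_k) along each (re-orthonormalized) planted field,
    d ~ Normal(0, dissociation stddev) along the rigid chain-B translation
    (d is the physical translation in Angstrom), and eps i.i.d.
    Normal(0, noise) per coordinate.  Planted contacts then override the
    partner residue's side-chain position on a Bernoulli(occupancy)
    schedule, placing the planted atom pair at 3.8 (contact) or 6.5
    (no contact) Angstrom, on either side of the 4.5 Angstrom criterion.

    RNG draw order (one seeded stream): (1) mode coefficients (F x K);
    (2) dissociation coefficients (F); (3) coordinate noise (F x A x 3);
    (4) one uniform series (F) per contact target, in list order.

    Returns the ensemble (aligned=False) and the per-frame planted
    coefficients (columns ``mode_<k>`` and ``dissociation``, plus the
    contact indicator columns ``contact_<i>``).
    """
    spec.validate()
    planted = (
        spec.planted_modes
        if spec.planted_modes is not None
        else default_planted_fields(model)
    )
    for f, _ in planted:
        if np.asarray(f).shape != (model.n_atoms, 3):
            raise ValidationError("planted field shape must match the model")
    stddevs = np.array([s for _, s in planted], dtype=float)
    if np.any(stddevs < 0):
        raise ValidationError("mode stddevs must be non-negative")
    fields = (
        _orthonormalize([f for f, _ in planted])
        if planted
        else np.zeros((0, model.n_atoms * 3))
    )
    diss = dissociation_field(model).ravel()

    rng = np.random.default_rng(spec.seed)
    f_count, k_count = spec.n_frames, len(planted)
    a = rng.normal(0.0, 1.0, size=(f_count, k_count)) * stddevs[None, :]
    d = rng.normal(0.0, spec.dissociation_amplitude_stddev, size=f_count)
    eps = rng.normal(0.0, spec.noise_stddev, size=(f_count, model.n_atoms, 3))
    schedules = [
        rng.uniform(size=f_count) < q for _, _, q in spec.contact_targets
    ]

    ref = model.reference_coordinates.ravel()
    frames = (
        ref[None, :]
        + a @ fields
        + d[:, None] * diss[None, :]
    ).reshape(f_count, model.n_atoms, 3) + eps

    elev = np.deg2rad(CONTACT_ELEVATION_DEG)
    for idx, ((res_a, res_b, _), schedule) in enumerate(
        zip(spec.contact_targets, schedules)
    ):
        sc_a = model.atom_indices_of_residue(str(res_a[0]), int(res_a[1]))[1]
        sc_b = model.atom_indices_of_residue(str(res_b[0]), int(res_b[1]))[1]
        home_a = model.reference_coordinates[sc_a]
        home_b = model.reference_coordinates[sc_b]
        u = home_b - home_a
        norm = np.linalg.norm(u)
        u = u / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
        # Lift the placement direction out of the strand plane so the
        # planted pair is the only contact the override creates.
        direction = np.cos(elev) * u + np.sin(elev) * np.array([0.0, 0.0, 1.0])
        direction /= np.linalg.norm(direction)
        dist = np.where(schedule, CONTACT_DISTANCE, NO_CONTACT_DISTANCE)
        frames[:, sc_b, :] = frames[:, sc_a, :] + dist[:, None] * direction[None, :]

    coeffs = pd.DataFrame(
        {f"mode_{k}": a[:, k] for k in range(k_count)}
        | {"dissociation": d}
        | {f"contact_{i}": s.astype(int) for i, s in enumerate(schedules)}
    )
    coeffs.insert(0, "frame", np.arange(f_count))
    traj = TrajectoryEnsemble(model=model, frames=frames, aligned=False)
    return traj, coeffs


# ---------------------------------------------------------------------------
# Energy tables and series
# ---------------------------------------------------------------------------


def generate_energy_tables(
    residues: ResidueSelection,
    planted_stabilized: set,
    planted_destabilized: set,
    effect_size: float = 2.0,
    noise: float = 0.2,
    seed: int = 0,
    wt_id: str = "wildtype",
    mut_id: str = "mutant",
    baseline: float = -1.0,
) -> tuple[EnergyTable, EnergyTable]:
    """Per-residue binding-energy tables for a wild-type / mutant pair.

    The mutant-minus-wildtype difference is centered at ``-effect_size``
    for planted stabilized residues, ``+effect_size`` for destabilized
    ones, and 0 elsewhere, plus Normal(0, noise) on every residue.
    """
    stabilized = {(str(c), int(r)) for c, r in planted_stabilized}
    destabilized = {(str(c), int(r)) for c, r in planted_destabilized}
    if stabilized & destabilized:
        raise ValidationError("planted sets must be disjoint")
    universe = set(residues.entries)
    for s in (stabilized, destabilized):
        if not s.issubset(universe):
            raise ValidationError("planted sets must be subsets of the residues")
    rng = np.random.default_rng(seed)
    wt = {res: baseline for res in residues}
    mut = {}
    for res in residues:
        if res in stabilized:
            center = -effect_size
        elif res in destabilized:
            center = effect_size
        else:
            center = 0.0
        mut[res] = wt[res] + center + rng.normal(0.0, noise)
    return (
        EnergyTable(system_id=wt_id, per_residue_dG=wt),
        EnergyTable(system_id=mut_id, per_residue_dG=mut),
    )


def generate_energy_series(
    system_id: str,
    mean: float,
    sd: float,
    n_frames: int = 1000,
    t_start: float = 0.1,
    dt: float = 0.1,
    seed: int = 0,
) -> EnergySeries:
    """I.i.d. Normal(mean, sd) per-frame binding energies with a uniform
    time grid (ns) — the stand-in for an MM/PBSA per-frame output table."""
    rng = np.random.default_rng(seed)
    times = t_start + dt * np.arange(n_frames)
    return EnergySeries(
        system_id=system_id,
        per_frame_dG=rng.normal(mean, sd, size=n_frames),
        frame_times=times,
    )


#: per-frame binding-energy study conditions (mean, SD in kcal/mol) of the
#: four simulated systems: wild-type brain-type CK, its P36L mutant,
#: wild-type muscle-type CK, its L36P mutant.
DEFAULT_ENERGY_SYSTEMS = {
    "hBBCK": (-181.0, 31.0),
    "BP36L": (-202.0, 24.0),
    "hMMCK": (-192.0, 20.0),
    "ML36P": (-165.0, 29.0),
}
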