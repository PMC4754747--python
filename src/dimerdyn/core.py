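"""Core domain types and structure / ensemble I/O.

The package represents a dimeric protein as a :class:`StructureModel`
(atom identities plus reference coordinates) and a coordinate ensemble as a
:class:`TrajectoryEnsemble` (F frames over the same atoms).  All coordinates
are in Angstrom, residue numbering is 1-based as in PDB files, and atom order
is file order everywhere.

PDB parsing and writing is delegated to biotite; this module adds the
validation the rest of the pipeline relies on (unique residue identity per
chain, rejection of insertion codes, van der Waals radius assignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile


class ValidationError(ValueError):
    """Input violates a structural contract of the pipeline."""


class ParseError(ValueError):
    """A file could not be parsed as the requested dialect."""


#: van der Waals radii in Angstrom by element symbol.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}
DEFAULT_VDW_RADIUS = 1.70


def element_from_atom_name(name: str) -> str:
    """Infer the element symbol from a PDB atom name (e.g. ``CA`` -> ``C``)."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise ParseError(f"cannot infer element from atom name {name!r}")
    return stripped[0].upper()


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.strip().upper(), DEFAULT_VDW_RADIUS)


@dataclass(frozen=True)
class AtomRecord:
    atom_id: int
    name: str
    element: str
    vdw_radius: float
    residue_index: int
    residue_name: str
    chain_id: str


@dataclass
class StructureModel:
    """Atom identities plus one set of reference coordinates.

    Parallel arrays of length A (number of atoms); ``reference_coordinates``
    has shape (A, 3) in Angstrom.
    """

    atom_names: np.ndarray
    elements: np.ndarray
    vdw_radii: np.ndarray
    residue_indices: np.ndarray
    residue_names: np.ndarray
    chain_ids: np.ndarray
    reference_coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.reference_coordinates = np.asarray(
            self.reference_coordinates, dtype=float
        )
        if self.reference_coordinates.shape != (self.n_atoms, 3):
            raise ValidationError(
                "reference_coordinates must have shape (n_atoms, 3)"
            )
        if np.any(self.vdw_radii <= 0):
            raise ValidationError("all van der Waals radii must be positive")
        self._validate_residue_order()

    def _validate_residue_order(self) -> None:
        seen_atoms: set[tuple[str, int, str]] = set()
        last_res: dict[str, int] = {}
        for i in range(self.n_atoms):
            chain = str(self.chain_ids[i])
            res = int(self.residue_indices[i])
            key = (chain, res, str(self.atom_names[i]))
            if key in seen_atoms:
                raise ValidationError(
                    f"duplicate atom {key[2]!r} in residue {chain}:{res}"
                )
            seen_atoms.add(key)
            if chain in last_res and res < last_res[chain]:
                raise ValidationError(
                    f"residue indices not increasing in chain {chain} "
                    f"({res} after {last_res[chain]})"
                )
            last_res[chain] = res

    # -- basic queries -----------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for c in self.chain_ids:
            if c not in out:
                out.append(str(c))
        return out

    def residues(self) -> list[tuple[str, int]]:
        """All (chain_id, residue_index) pairs in file order."""
        out: list[tuple[str, int]] = []
        for c, r in zip(self.chain_ids, self.residue_indices):
            key = (str(c), int(r))
            if not out or out[-1] != key:
                if key in out:
                    raise ValidationError(f"non-contiguous residue {key}")
                out.append(key)
        return out

    def atoms(self) -> Iterator[AtomRecord]:
        for i in range(self.n_atoms):
            yield AtomRecord(
                atom_id=i,
                name=str(self.atom_names[i]),
                element=str(self.elements[i]),
                vdw_radius=float(self.vdw_radii[i]),
                residue_index=int(self.residue_indices[i]),
                residue_name=str(self.residue_names[i]),
                chain_id=str(self.chain_ids[i]),
            )

    def atom_indices_of_residue(self, chain_id: str, residue_index: int) -> np.ndarray:
        mask = (self.chain_ids == chain_id) & (self.residue_indices == residue_index)
        idx = np.where(mask)[0]
        if idx.size == 0:
            raise ValidationError(
                f"residue {chain_id}:{residue_index} not in model"
            )
        return idx

    def with_coordinates(self, coords: np.ndarray) -> "StructureModel":
        return replace(self, reference_coordinates=np.asarray(coords, dtype=float))


@dataclass
class TrajectoryEnsemble:
    """F frames x A atoms x 3 coordinates sharing one :class:`StructureModel`."""

    model: StructureModel
    frames: np.ndarray
    frame_labels: np.ndarray | None = None
    aligned: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (self.model.n_atoms, 3):
            raise ValidationError(
                "frames must have shape (F, n_atoms, 3) matching the model"
            )
        if self.n_frames < 1:
            raise ValidationError("ensemble needs at least one frame")
        if self.frame_labels is None:
            self.frame_labels = np.arange(self.n_frames)
        self.frame_labels = np.asarray(self.frame_labels, dtype=int)
        if len(self.frame_labels) != self.n_frames:
            raise ValidationError("frame_labels length must equal frame count")
        if len(np.unique(self.frame_labels)) != self.n_frames:
            raise ValidationError("frame_labels must be unique")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class ResidueSelection:
    """Ordered unique list of (chain_id, residue_index) pairs."""

    entries: list[tuple[str, int]]

    def __post_init__(self) -> None:
        entries = [(str(c), int(r)) for c, r in self.entries]
        if len(set(entries)) != len(entries):
            raise ValidationError("residue selection entries must be unique")
        self.entries = entries

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.entries)

    def __contains__(self, item: object) -> bool:
        return item in self.entries

    def validate_against(self, model: StructureModel) -> None:
        known = set(model.residues())
        missing = [e for e in self.entries if e not in known]
        if missing:
            raise ValidationError(f"residues not in model: {missing}")

    def to_json(self) -> list[list]:
        return [[c, r] for c, r in self.entries]

    @classmethod
    def from_json(cls, data: Sequence[Sequence]) -> "ResidueSelection":
        return cls([(str(c), int(r)) for c, r in data])


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------


def _model_from_atom_array(array: struc.AtomArray, path: str) -> StructureModel:
    if np.any(array.ins_code != ""):
        bad = np.where(array.ins_code != "")[0][0]
        raise ValidationError(
            f"{path}: insertion codes are not supported "
            f"(atom {bad + 1}, residue {array.chain_id[bad]}:{array.res_id[bad]})"
        )
    elements = []
    for el, name in zip(array.element, array.atom_name):
        el = str(el).strip()
        elements.append(el.upper() if el else element_from_atom_name(str(name)))
    elements = np.array(elements, dtype=object)
    radii = np.array([vdw_radius(el) for el in elements], dtype=float)
    return StructureModel(
        atom_names=np.array([str(n) for n in array.atom_name], dtype=object),
        elements=elements,
        vdw_radii=radii,
        residue_indices=np.asarray(array.res_id, dtype=int),
        residue_names=np.array([str(n) for n in array.res_name], dtype=object),
        chain_ids=np.array([str(c) for c in array.chain_id], dtype=object),
        reference_coordinates=np.asarray(array.coord, dtype=float),
    )


def read_structure(path: str, dialect: str = "pdb") -> StructureModel:
    """Read a (single-model) PDB file into a :class:`StructureModel`.

    The first model of a multi-model file provides the reference
    coordinates.  The element column is used when present; otherwise the
    element is inferred from the atom name.
    """
    if dialect != "pdb":
        raise ValidationError(f"unknown structure dialect {dialect!r}")
    try:
        pdb_file = PDBFile.read(path)
        array = pdb_file.get_structure(model=1)
    except ValidationError:
        raise
    except Exception as exc:  # biotite raises various error types
        raise ParseError(f"{path}: not parseable as PDB: {exc}") from exc
    if array.array_length() == 0:
        raise ParseError(f"{path}: no ATOM records")
    return _model_from_atom_array(array, path)


def _atom_array_from_model(
    model: StructureModel, coords: np.ndarray
) -> struc.AtomArray:
    array = struc.AtomArray(model.n_atoms)
    array.coord = np.asarray(coords, dtype=np.float32)
    array.chain_id = np.array([str(c) for c in model.chain_ids], dtype="U4")
    array.res_id = np.asarray(model.residue_indices, dtype=int)
    array.res_name = np.array([str(n) for n in model.residue_names], dtype="U5")
    array.atom_name = np.array([str(n) for n in model.atom_names], dtype="U6")
    array.element = np.array([str(e) for e in model.elements], dtype="U2")
    array.hetero = np.zeros(model.n_atoms, dtype=bool)
    return array


def write_structure(model: StructureModel, path: str) -> None:
    pdb_file = PDBFile()
    pdb_file.set_structure(_atom_array_from_model(model, model.reference_coordinates))
    pdb_file.write(path)


def read_ensemble(
    topology: StructureModel, path: str, dialect: str = "multi-model-pdb"
) -> TrajectoryEnsemble:
    """Read a multi-model PDB into a :class:`TrajectoryEnsemble`.

    Every MODEL block must contain exactly the topology's atoms in the
    topology's order.  ``dialect="adapter"`` is reserved for user-registered
    binary-format adapters (see :func:`register_ensemble_adapter`).
    """
    if dialect == "adapter":
        raise ValidationError(
            "no ensemble adapter registered; use register_ensemble_adapter()"
        )
    if dialect != "multi-model-pdb":
        raise ValidationError(f"unknown ensemble dialect {dialect!r}")
    try:
        pdb_file = PDBFile.read(path)
        n_models = pdb_file.get_model_count()
    except Exception as exc:
        raise ParseError(f"{path}: not parseable as PDB: {exc}") from exc
    try:
        stack = pdb_file.get_structure()
        coords = np.asarray(stack.coord, dtype=float)
        if coords.ndim == 2:
            coords = coords[None, :, :]
    except Exception:
        # Uneven atom counts across models: find and name the offender.
        for i in range(1, n_models + 1):
            arr = pdb_file.get_structure(model=i)
            if arr.array_length() != topology.n_atoms:
                raise ValidationError(
                    f"{path}: frame {i - 1} has {arr.array_length()} atoms, "
                    f"expected {topology.n_atoms}"
                )
        raise
    if coords.shape[1] != topology.n_atoms:
        raise ValidationError(
            f"{path}: frames have {coords.shape[1]} atoms, "
            f"expected {topology.n_atoms}"
        )
    return TrajectoryEnsemble(model=topology, frames=coords, aligned=False)


_ENSEMBLE_ADAPTERS: dict[str, object] = {}


def register_ensemble_adapter(name: str, reader) -> None:
    """Register a callable ``reader(topology, path) -> TrajectoryEnsemble``
    for a binary trajectory format, addressable as ``dialect=name``."""
    _ENSEMBLE_ADAPTERS[name] = reader


def read_ensemble_via_adapter(
    topology: StructureModel, path: str, name: str
) -> TrajectoryEnsemble:
    if name not in _ENSEMBLE_ADAPTERS:
        raise ValidationError(f"no ensemble adapter named {name!r}")
    return _ENSEMBLE_ADAPTERS[name](topology, path)


def write_ensemble(traj: TrajectoryEnsemble, path: str) -> None:
    """Write an ensemble as a multi-model PDB."""
    model = traj.model
    stack = struc.AtomArrayStack(traj.n_frames, model.n_atoms)
    template = _atom_array_from_model(model, model.reference_coordinates)
    for category in template.get_annotation_categories():
        stack.set_annotation(category, template.get_annotation(category))
    stack.coord = np.asarray(traj.frames, dtype=np.float32)
    pdb_file = PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(path)


# ---------------------------------------------------------------------------
# Atom selection
# ---------------------------------------------------------------------------


def select(model: StructureModel, expression: str) -> np.ndarray:
    """Resolve a selection expression to atom indices in model order.

    Expressions: ``calpha`` (atoms named CA), ``heavy`` (element != H),
    ``chain:<id>``, ``residues:<chain:res,chain:res,...>``.
    """
    names = np.array([str(n).strip() for n in model.atom_names])
    if expression == "calpha":
        return np.where(names == "CA")[0]
    if expression == "heavy":
        return np.where(np.array([e != "H" for e in model.elements]))[0]
    if expression.startswith("chain:"):
        chain = expression.split(":", 1)[1]
        if chain not in model.chains:
            raise ValidationError(f"chain {chain!r} not in model")
        return np.where(model.chain_ids == chain)[0]
    if expression.startswith("residues:"):
        spec = expression.split(":", 1)[1]
        entries = []
        for token in spec.split(","):
            chain, res = token.strip().split(":")
            entries.append((chain, int(res)))
        sel = ResidueSelection(entries)
        sel.validate_against(model)
        keys = set(sel.entries)
        return np.where(
            [
                (str(c), int(r)) in keys
                for c, r in zip(model.chain_ids, model.residue_indices)
            ]
        )[0]
    raise ValidationError(f"unknown selection expression {expression!r}")


def calpha_selection(model: StructureModel) -> np.ndarray:
    return select(model, "calpha")
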