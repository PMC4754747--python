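import numpy as np
import pytest

from dimerdyn.core import StructureModel
from dimerdyn.synthetic import SyntheticSpec, build_toy_dimer, generate_ensemble


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """A small dimer (8 residues/chain, Cα + side chain) for fast tests."""
    return SyntheticSpec(
        n_residues_per_chain=8,
        atoms_per_residue=2,
        n_frames=200,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_model(small_spec) -> StructureModel:
    return build_toy_dimer(small_spec)


@pytest.fixture(scope="session")
def small_ensemble(small_spec, small_model):
    traj, coeffs = generate_ensemble(small_model, small_spec)
    return traj, coeffs


def make_ca_model(n_residues: int, chains=("A",), spacing: float = 3.8) -> StructureModel:
    """Minimal Cα-only model for mode / geometry tests."""
    names, elements, radii, res_idx, res_names, chain_ids, coords = (
        [], [], [], [], [], [], []
    )
    for ci, chain in enumerate(chains):
        for i in range(n_residues):
            names.append("CA")
            elements.append("C")
            radii.append(1.70)
            res_idx.append(i + 1)
            res_names.append("GLY")
            chain_ids.append(chain)
            coords.append([i * spacing, 4.0 * ci, 0.1 * (i % 3)])
    return StructureModel(
        atom_names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        vdw_radii=np.array(radii, dtype=float),
        residue_indices=np.array(res_idx, dtype=int),
        residue_names=np.array(res_names, dtype=object),
        chain_ids=np.array(chain_ids, dtype=object),
        reference_coordinates=np.array(coords, dtype=float),
    )
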