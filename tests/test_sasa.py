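import numpy as np
import pytest

from dimerdyn.core import StructureModel, TrajectoryEnsemble, ValidationError
from dimerdyn.sasa import detect_interface, interface_sasa_series, sasa, sphere_points


def carbon_model(coords):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return StructureModel(
        atom_names=np.array(["CA"] * n, dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        vdw_radii=np.full(n, 1.70),
        residue_indices=np.arange(1, n + 1),
        residue_names=np.array(["GLY"] * n, dtype=object),
        chain_ids=np.array(["A"] * n, dtype=object),
        reference_coordinates=coords,
    )


def monte_carlo_sasa(coords, radii, probe=1.4, n_samples=100_000, seed=0):
    """Independent SASA oracle: uniform random points on each expanded
    sphere, rejecting points inside any other expanded sphere."""
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, dtype=float)
    expanded = np.asarray(radii) + probe
    total = 0.0
    per_atom = []
    for i in range(len(coords)):
        v = rng.normal(size=(n_samples, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = coords[i] + expanded[i] * v
        exposed = np.ones(n_samples, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            exposed &= d2 >= expanded[j] ** 2
        area = exposed.mean() * 4.0 * np.pi * expanded[i] ** 2
        per_atom.append(area)
        total += area
    return total, np.array(per_atom)


def two_sphere_exact(r, d, probe=1.4):
    """Closed-form SASA of two equal spheres: each loses a spherical cap of
    height h = R - d/2 where R = r + probe."""
    R = r + probe
    if d >= 2 * R:
        return 2 * 4 * np.pi * R**2
    h = R - d / 2.0
    cap = 2 * np.pi * R * h
    return 2 * (4 * np.pi * R**2 - cap)


class TestSasa:
    def test_isolated_carbon_closed_form(self):
        model = carbon_model([[0.0, 0.0, 0.0]])
        result = sasa(model)
        expected = 4 * np.pi * (1.70 + 1.4) ** 2
        assert result.total == pytest.approx(expected, abs=1e-3)
        assert result.total == pytest.approx(120.762, abs=1e-3)

    def test_disjoint_spheres_additive(self):
        model = carbon_model([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]])
        single = 4 * np.pi * (1.70 + 1.4) ** 2
        assert sasa(model).total == pytest.approx(2 * single, abs=1e-6)

    def test_two_spheres_match_oracles(self):
        model = carbon_model([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        result = sasa(model)
        exact = two_sphere_exact(1.70, 2.0)
        mc, _ = monte_carlo_sasa(model.reference_coordinates, model.vdw_radii)
        assert result.total == pytest.approx(exact, rel=0.01)
        assert result.total == pytest.approx(mc, rel=0.01)

    def test_monotone_burial_over_distance_sweep(self):
        totals = [
            sasa(carbon_model([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])).total
            for d in np.linspace(0.2, 6.5, 25)
        ]
        assert all(a <= b + 1e-9 for a, b in zip(totals, totals[1:]))

    def test_agrees_with_biotite_on_random_cluster(self):
        # independent Shrake-Rupley implementation as cross-check
        import biotite.structure as struc

        rng = np.random.default_rng(3)
        coords = rng.normal(scale=2.5, size=(12, 3))
        model = carbon_model(coords)
        ours = sasa(model, n_points=2000)
        arr = struc.AtomArray(12)
        arr.coord = coords.astype(np.float32)
        arr.chain_id = np.array(["A"] * 12)
        arr.res_id = np.arange(1, 13)
        arr.res_name = np.array(["GLY"] * 12)
        arr.atom_name = np.array(["CA"] * 12)
        arr.element = np.array(["C"] * 12)
        theirs = struc.sasa(
            arr, probe_radius=1.4, point_number=2000, vdw_radii=np.full(12, 1.70)
        )
        assert ours.total == pytest.approx(float(theirs.sum()), rel=0.01)

    def test_point_floor_rejected(self):
        model = carbon_model([[0.0, 0.0, 0.0]])
        with pytest.raises(ValidationError):
            sasa(model, n_points=16)

    def test_sphere_points_unit_norm(self):
        pts = sphere_points(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)

    def test_per_residue_sums_to_total(self, small_model):
        result = sasa(small_model)
        assert sum(result.per_residue.values()) == pytest.approx(
            result.total, abs=1e-6
        )


class TestInterface:
    def test_separated_chains_empty(self, small_model):
        coords = small_model.reference_coordinates.copy()
        coords[small_model.chain_ids == "B"] += [0.0, 100.0, 0.0]
        far = small_model.with_coordinates(coords)
        with pytest.warns(UserWarning, match="no interface"):
            iface = detect_interface(far)
        assert len(iface.residues) == 0

    def test_toy_dimer_facing_residues(self, small_model):
        # every residue of the facing-strand toy dimer touches the interface
        iface = detect_interface(small_model)
        assert set(iface.residues.entries) == set(small_model.residues())
        assert all(v > 0.1 for v in iface.delta_sasa.values())

    def test_delta_sasa_against_mc_oracle(self, small_model):
        iface = detect_interface(small_model)
        key = ("A", 4)
        atoms_a = np.where(small_model.chain_ids == "A")[0]
        res_atoms = small_model.atom_indices_of_residue(*key)
        _, per_atom_complex = monte_carlo_sasa(
            small_model.reference_coordinates, small_model.vdw_radii, n_samples=40_000
        )
        _, per_atom_iso = monte_carlo_sasa(
            small_model.reference_coordinates[atoms_a],
            small_model.vdw_radii[atoms_a],
            n_samples=40_000,
        )
        iso = sum(per_atom_iso[list(atoms_a).index(i)] for i in res_atoms)
        cpx = sum(per_atom_complex[i] for i in res_atoms)
        assert iface.delta_sasa[key] == pytest.approx(iso - cpx, rel=0.05, abs=0.5)

    def test_large_tolerance_empties_interface(self, small_model):
        with pytest.warns(UserWarning):
            iface = detect_interface(small_model, tolerance=1e6)
        assert len(iface.residues) == 0


class TestInterfaceSeries:
    def test_constant_ensemble_constant_series(self, small_model):
        frames = np.stack([small_model.reference_coordinates] * 3)
        traj = TrajectoryEnsemble(model=small_model, frames=frames)
        iface = detect_interface(small_model)
        series = interface_sasa_series(traj, iface, n_points=240)
        np.testing.assert_allclose(series, series[0], atol=1e-9)

    def test_translated_chain_raises_series(self, small_model):
        ref = small_model.reference_coordinates
        apart = ref.copy()
        apart[small_model.chain_ids == "B"] += [0.0, 10.0, 0.0]
        traj = TrajectoryEnsemble(model=small_model, frames=np.stack([ref, apart]))
        iface = detect_interface(small_model)
        series = interface_sasa_series(traj, iface)
        assert series[1] > series[0]
        # oracle check on both geometries
        members = set(iface.residues.entries)
        for t, coords in enumerate([ref, apart]):
            _, per_atom = monte_carlo_sasa(
                coords, small_model.vdw_radii, n_samples=40_000
            )
            oracle = sum(
                per_atom[i]
                for i in range(small_model.n_atoms)
                if (
                    str(small_model.chain_ids[i]),
                    int(small_model.residue_indices[i]),
                )
                in members
            )
            assert series[t] == pytest.approx(oracle, rel=0.01)

    def test_complex_never_exceeds_chain_sum(self, small_model):
        # burial is non-negative for arbitrary geometry
        rng = np.random.default_rng(12)
        atoms_a = np.where(small_model.chain_ids == "A")[0]
        atoms_b = np.where(small_model.chain_ids == "B")[0]
        for _ in range(10):
            coords = small_model.reference_coordinates + rng.normal(
                scale=1.5, size=(small_model.n_atoms, 3)
            )
            total = sasa(small_model, coordinates=coords, n_points=240).total
            iso = (
                sasa(small_model, coordinates=coords, atom_subset=atoms_a, n_points=240).total
                + sasa(small_model, coordinates=coords, atom_subset=atoms_b, n_points=240).total
            )
            assert total <= iso + 1e-9
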