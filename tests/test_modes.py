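import numpy as np
import pytest

from dimerdyn.core import TrajectoryEnsemble, ValidationError
from dimerdyn.geometry import align_ensemble
from dimerdyn.modes import (
    ModeSet,
    direction_cosine,
    fma,
    mode_similarity,
    pca,
    project_frames,
    project_mode,
    remove_rigid_body,
    residue_amplitude,
    residue_direction,
)
from dimerdyn.synthetic import (
    SyntheticSpec,
    build_toy_dimer,
    default_planted_fields,
    generate_ensemble,
)

from conftest import make_ca_model


def make_modeset(model, vectors, variances=None):
    """ModeSet over the Cα atoms of a Cα-only model from raw vectors."""
    from dimerdyn.core import calpha_selection

    sel = calpha_selection(model)
    vectors = np.asarray(vectors, dtype=float)
    vectors = vectors / np.linalg.norm(vectors, axis=1, keepdims=True)
    if variances is None:
        variances = np.arange(len(vectors), 0, -1, dtype=float)
    return ModeSet(
        atom_indices=sel,
        residue_keys=[
            (str(model.chain_ids[i]), int(model.residue_indices[i])) for i in sel
        ],
        mean_structure=model.reference_coordinates[sel],
        modes=vectors,
        variances=np.asarray(variances, dtype=float),
    )


def planted_ensemble(n_frames=400, seed=0, noise=0.0, stddevs=(1.0,)):
    spec = SyntheticSpec(
        n_residues_per_chain=6,
        atoms_per_residue=1,
        n_frames=n_frames,
        dissociation_amplitude_stddev=0.0,
        noise_stddev=noise,
        seed=seed,
    )
    model = build_toy_dimer(spec)
    fields = default_planted_fields(model)
    spec.planted_modes = [(fields[k][0], s) for k, s in enumerate(stddevs)]
    traj, coeffs = generate_ensemble(model, spec)
    return model, spec, traj, coeffs


class TestPca:
    def test_recovers_planted_field(self):
        model, spec, traj, _ = planted_ensemble(noise=0.0)
        aligned = align_ensemble(traj)
        ms = pca(aligned, k=1)
        field = spec.planted_modes[0][0].ravel()
        eff = remove_rigid_body(field, model.reference_coordinates)
        assert abs(np.dot(ms.modes[0], eff)) > 0.999
        assert ms.variances[0] == pytest.approx(1.0, rel=0.15)

    def test_constant_ensemble_degenerate(self):
        model = make_ca_model(6)
        frames = np.stack([model.reference_coordinates] * 10)
        traj = TrajectoryEnsemble(model=model, frames=frames, aligned=True)
        with pytest.raises(ValidationError, match="degenerate"):
            pca(traj)

    def test_unaligned_rejected(self):
        model, _, traj, _ = planted_ensemble(n_frames=20)
        with pytest.raises(ValidationError):
            pca(traj)

    def test_variance_ratio_of_two_planted_fields(self):
        # stddevs 2 and 1 plant variances in ratio 4:1
        _, _, traj, _ = planted_ensemble(
            n_frames=5000, seed=4, noise=0.0, stddevs=(2.0, 1.0)
        )
        aligned = align_ensemble(traj)
        ms = pca(aligned, k=2)
        ratio = ms.variances[0] / ms.variances[1]
        assert ratio == pytest.approx(4.0, rel=0.10)

    def test_reconstruction_from_all_modes(self):
        _, _, traj, _ = planted_ensemble(n_frames=200, seed=5, noise=0.05)
        aligned = align_ensemble(traj)
        ms = pca(aligned)  # all positive-variance modes
        x = project_frames(aligned, ms)
        from dimerdyn.core import calpha_selection

        sel = calpha_selection(aligned.model)
        centered = (
            aligned.frames[:, sel].reshape(aligned.n_frames, -1)
            - ms.mean_structure.ravel()
        )
        back = x @ ms.modes
        np.testing.assert_allclose(back, centered, atol=1e-6)


class TestResidueAmplitudes:
    def test_delta_mode(self):
        model = make_ca_model(4)
        vec = np.zeros(12)
        vec[0] = 1.0  # residue 1 moves along x only
        ms = make_modeset(model, [vec])
        assert residue_amplitude(ms, 0, ("A", 1)) == pytest.approx(1.0)
        for r in (2, 3, 4):
            assert residue_amplitude(ms, 0, ("A", r)) == pytest.approx(0.0)
        assert residue_direction(ms, 0, ("A", 2)) is None

    def test_amplitudes_square_sum_to_one(self):
        model = make_ca_model(5)
        rng = np.random.default_rng(0)
        ms = make_modeset(model, [rng.normal(size=15)])
        total = sum(
            residue_amplitude(ms, 0, ("A", r)) ** 2 for r in range(1, 6)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_amplitudes_match_block_norms(self):
        model = make_ca_model(5)
        rng = np.random.default_rng(1)
        vec = rng.normal(size=15)
        ms = make_modeset(model, [vec])
        unit = vec / np.linalg.norm(vec)
        for r in range(1, 6):
            block = unit[3 * (r - 1) : 3 * r]
            assert residue_amplitude(ms, 0, ("A", r)) == pytest.approx(
                np.linalg.norm(block), abs=1e-12
            )

    def test_missing_residue_raises(self):
        model = make_ca_model(4)
        ms = make_modeset(model, [np.ones(12)])
        with pytest.raises(ValidationError):
            residue_amplitude(ms, 0, ("A", 99))


class TestDirectionCosine:
    def test_identical_and_negated(self):
        # compare the same mode index across two systems' mode sets
        model = make_ca_model(4)
        rng = np.random.default_rng(2)
        vec = rng.normal(size=12)
        ms_a = make_modeset(model, [vec], variances=[2.0])
        ms_b = make_modeset(model, [-vec], variances=[1.0])
        for r in range(1, 5):
            assert direction_cosine(ms_a, 0, ms_a, 0, ("A", r)) == pytest.approx(1.0)
            assert direction_cosine(ms_a, 0, ms_b, 0, ("A", r)) == pytest.approx(-1.0)

    def test_matches_dot_product_oracle(self):
        model = make_ca_model(4)
        rng = np.random.default_rng(3)
        va, vb = rng.normal(size=12), rng.normal(size=12)
        ms_a = make_modeset(model, [va], variances=[2.0])
        ms_b = make_modeset(model, [vb], variances=[1.0])
        ua = va / np.linalg.norm(va)
        ub = vb / np.linalg.norm(vb)
        for r in range(1, 5):
            a = ua[3 * (r - 1) : 3 * r]
            b = ub[3 * (r - 1) : 3 * r]
            expected = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
            assert direction_cosine(ms_a, 0, ms_b, 0, ("A", r)) == pytest.approx(
                expected, abs=1e-12
            )


class TestSimilarityProjection:
    def test_self_similarity(self):
        rng = np.random.default_rng(4)
        vec = rng.normal(size=30)
        assert mode_similarity(vec, vec) == pytest.approx(1.0)

    def test_orthogonal_zero_mean_modes_uncorrelated(self):
        vec = np.zeros(30)
        vec[0], vec[1] = 1.0, -1.0
        other = np.zeros(30)
        other[2], other[3] = 1.0, -1.0
        assert mode_similarity(vec, other) == pytest.approx(0.0, abs=1e-6)

    def test_planted_mode_projects_onto_own_pc(self):
        model, spec, traj, _ = planted_ensemble(n_frames=600, seed=6, noise=0.05)
        aligned = align_ensemble(traj)
        ms = pca(aligned, k=6)
        field = spec.planted_modes[0][0].ravel()
        eff = remove_rigid_body(field, model.reference_coordinates)
        proj = project_mode(eff, ms, top_k=6)
        assert proj.best_index == 0
        assert abs(proj.best_pcc) > 0.95

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError):
            mode_similarity(np.ones(6), np.ones(9))


class TestFma:
    def test_noiseless_linear_function(self):
        _, _, traj, _ = planted_ensemble(n_frames=200, seed=7, noise=0.02,
                                         stddevs=(1.0, 0.5))
        aligned = align_ensemble(traj)
        ms = pca(aligned, k=4)
        y = project_frames(aligned, ms)[:, 1]  # exact projection on PC2
        fm = fma(aligned, ms, y, n_components=4, top_k=4)
        assert fm.train_pcc == pytest.approx(1.0, abs=1e-6)
        assert fm.validation_pcc == pytest.approx(1.0, abs=1e-6)
        assert abs(np.dot(fm.mode, ms.modes[1])) > 0.999

    def test_pure_noise_function_does_not_validate(self):
        # permutation-style null: a function independent of the coordinates
        # must not produce a validating mode
        _, _, traj, _ = planted_ensemble(n_frames=2000, seed=8, noise=0.05)
        aligned = align_ensemble(traj)
        ms = pca(aligned, k=10)
        worst = 0.0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            y = rng.normal(size=traj.n_frames)
            fm = fma(aligned, ms, y, n_components=5, top_k=10)
            worst = max(worst, abs(fm.validation_pcc))
        assert worst < 0.2

    def test_noisy_function_validates_at_snr_5(self):
        for seed in range(10):
            _, _, traj, coeffs = planted_ensemble(n_frames=600, seed=20 + seed,
                                                  noise=0.05)
            aligned = align_ensemble(traj)
            ms = pca(aligned, k=6)
            signal = coeffs["mode_0"].to_numpy()
            rng = np.random.default_rng(seed)
            y = signal + rng.normal(scale=signal.std() / 5.0, size=len(signal))
            fm = fma(aligned, ms, y, n_components=4, top_k=6)
            assert fm.validation_pcc > 0.8

    def test_constant_function_rejected(self):
        _, _, traj, _ = planted_ensemble(n_frames=50, seed=9, noise=0.05)
        aligned = align_ensemble(traj)
        ms = pca(aligned, k=4)
        with pytest.raises(ValidationError, match="zero-variance"):
            fma(aligned, ms, np.ones(traj.n_frames))

    def test_pcc_invariant_under_affine_function_rescaling(self):
        _, _, traj, coeffs = planted_ensemble(n_frames=300, seed=10, noise=0.05)
        aligned = align_ensemble(traj)
        ms = pca(aligned, k=4)
        y = coeffs["mode_0"].to_numpy()
        fm1 = fma(aligned, ms, y, n_components=3, top_k=4)
        fm2 = fma(aligned, ms, 7.5 * y + 123.0, n_components=3, top_k=4)
        assert fm1.train_pcc == pytest.approx(fm2.train_pcc, abs=1e-9)
        assert fm1.validation_pcc == pytest.approx(fm2.validation_pcc, abs=1e-9)
        np.testing.assert_allclose(fm1.mode, fm2.mode, atol=1e-9)


class TestModeSetInvariants:
    def test_unit_norm_and_orthogonality_enforced(self):
        model = make_ca_model(4)
        bad = np.ones((1, 12))
        with pytest.raises(ValidationError):
            ModeSet(
                atom_indices=np.arange(4),
                residue_keys=[("A", r) for r in range(1, 5)],
                mean_structure=model.reference_coordinates,
                modes=bad,
                variances=np.array([1.0]),
            )

    def test_pca_sign_convention_deterministic(self):
        _, _, traj, _ = planted_ensemble(n_frames=100, seed=11, noise=0.05)
        aligned = align_ensemble(traj)
        a = pca(aligned, k=3)
        b = pca(aligned, k=3)
        np.testing.assert_array_equal(a.modes, b.modes)
        for k in range(3):
            i = np.argmax(np.abs(a.modes[k]))
            assert a.modes[k, i] > 0
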