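"""Collective motion modes: PCA of the Cα ensemble and functional mode
analysis (FMA).

PCA eigendecomposes the 3N x 3N sample covariance of the flattened, aligned
Cα coordinates; each PC mode is a unit 3N displacement field and its
eigenvalue the variance (Angstrom^2) along it.  FMA finds the linear
combination of the top-K PC modes maximally correlated with a scalar
per-frame functional quantity (here: total interface SASA), fitted by
partial least squares (PLS1) on the first half of the trajectory and
validated on the second half.

Sign convention: the largest-magnitude component of every PC mode is made
positive, so mode-level outputs are deterministic across linear-algebra
backends.  The FMA mode direction is fixed by the regression itself (the
training-half correlation is non-negative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from .core import StructureModel, TrajectoryEnsemble, ValidationError


@dataclass
class ModeSet:
    """Orthonormal collective-motion vectors over Cα atoms."""

    atom_indices: np.ndarray  # Cα atom indices into the model
    residue_keys: list  # (chain_id, residue_index) per Cα atom
    mean_structure: np.ndarray  # N x 3 Angstrom
    modes: np.ndarray  # K x 3N unit vectors
    variances: np.ndarray  # K eigenvalues, Angstrom^2, descending

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.modes, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValidationError("modes must have unit norm")
        gram = self.modes @ self.modes.T
        if not np.allclose(gram, np.eye(len(self.modes)), atol=1e-8):
            raise ValidationError("modes must be mutually orthogonal")
        if np.any(np.diff(self.variances) > 1e-12) or np.any(self.variances < -1e-12):
            raise ValidationError("variances must be non-negative and descending")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_indices)

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]

    def residue_block(self, mode_index: int, residue: tuple) -> np.ndarray:
        key = (str(residue[0]), int(residue[1]))
        try:
            pos = self.residue_keys.index(key)
        except ValueError:
            raise ValidationError(f"residue {key} has no Cα in the mode set")
        return self.modes[mode_index, 3 * pos : 3 * pos + 3]


def _fix_mode_signs(modes: np.ndarray) -> np.ndarray:
    out = modes.copy()
    for k in range(out.shape[0]):
        i = np.argmax(np.abs(out[k]))
        if out[k, i] < 0:
            out[k] = -out[k]
    return out


def pca(
    traj: TrajectoryEnsemble, selection: str = "calpha", k: int | None = None
) -> ModeSet:
    """PCA of the aligned Cα coordinate fluctuations.

    Returns the top ``k`` modes (default: all with positive variance).
    """
    if not traj.aligned:
        raise ValidationError("PCA requires an aligned ensemble")
    from .core import select as _select

    sel = _select(traj.model, selection)
    coords = traj.frames[:, sel].reshape(traj.n_frames, -1)  # F x 3N
    if k is not None and traj.n_frames <= k:
        raise ValidationError("need more frames than requested modes")
    mean = coords.mean(axis=0)
    centered = coords - mean
    cov = centered.T @ centered / (traj.n_frames - 1 if traj.n_frames > 1 else 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    if evals[0] <= 1e-12:
        raise ValidationError("degenerate covariance: ensemble has no variance")
    n_keep = k if k is not None else int(np.count_nonzero(evals > 1e-12))
    modes = _fix_mode_signs(evecs[:, :n_keep].T)
    model = traj.model
    residue_keys = [
        (str(model.chain_ids[i]), int(model.residue_indices[i])) for i in sel
    ]
    return ModeSet(
        atom_indices=sel,
        residue_keys=residue_keys,
        mean_structure=mean.reshape(-1, 3),
        modes=modes,
        variances=evals[:n_keep],
    )


# ---------------------------------------------------------------------------
# Per-residue amplitude and direction within a mode
# ---------------------------------------------------------------------------

AMPLITUDE_FLOOR = 1e-6


def residue_amplitude(modes: ModeSet, mode_index: int, residue: tuple) -> float:
    """Norm of the residue's 3-component block of the (unit) mode.

    Amplitudes satisfy sum over residues of amplitude^2 = 1 per mode.
    """
    return float(np.linalg.norm(modes.residue_block(mode_index, residue)))


def residue_direction(
    modes: ModeSet, mode_index: int, residue: tuple
) -> np.ndarray | None:
    """Unit motion direction of the residue in the mode, or None when the
    amplitude is below the defined-direction floor."""
    block = modes.residue_block(mode_index, residue)
    norm = np.linalg.norm(block)
    if norm < AMPLITUDE_FLOOR:
        return None
    return block / norm


def direction_cosine(
    modes_a: ModeSet,
    mode_index_a: int,
    modes_b: ModeSet,
    mode_index_b: int,
    residue: tuple,
) -> float | None:
    """Cosine of the angle between a residue's motion directions in two
    modes; None when either direction is undefined."""
    da = residue_direction(modes_a, mode_index_a, residue)
    db = residue_direction(modes_b, mode_index_b, residue)
    if da is None or db is None:
        return None
    return float(np.clip(np.dot(da, db), -1.0, 1.0))


# ---------------------------------------------------------------------------
# Mode similarity and projection
# ---------------------------------------------------------------------------


def mode_similarity(mode_a: np.ndarray, mode_b: np.ndarray) -> float:
    """Pearson correlation coefficient between two 3N mode vectors."""
    mode_a = np.asarray(mode_a, dtype=float).ravel()
    mode_b = np.asarray(mode_b, dtype=float).ravel()
    if mode_a.shape != mode_b.shape:
        raise ValidationError("mode vectors must have equal dimension")
    return float(stats.pearsonr(mode_a, mode_b)[0])


@dataclass
class ModeProjection:
    pccs: np.ndarray  # per-PC Pearson correlations
    best_index: int  # argmax of |PCC|, ties toward lower index
    best_pcc: float


def project_mode(
    mode: np.ndarray, modes: ModeSet, top_k: int = 20
) -> ModeProjection:
    """Correlate a mode vector with each of the top-K PC modes and report the
    best-matching PC."""
    top_k = min(top_k, modes.n_modes)
    pccs = np.array(
        [mode_similarity(mode, modes.modes[k]) for k in range(top_k)]
    )
    best = int(np.argmax(np.abs(pccs)))  # argmax takes the first maximum
    return ModeProjection(pccs=pccs, best_index=best, best_pcc=float(pccs[best]))


# ---------------------------------------------------------------------------
# Functional mode analysis
# ---------------------------------------------------------------------------


@dataclass
class FunctionalMode:
    """Result of a functional mode analysis.

    ``mode`` is the ensemble-weighted collective mode: the displacement
    pattern whose motion accompanies changes of the function, i.e. the
    back-projection of the PLS weights with each PC weighted by its
    variance along the trajectory.  ``pc_coefficients`` are the weights
    reproducing ``mode`` from the PC modes.  ``regression_coefficients``
    are the raw PLS regression weights in PC space; the projection
    ``X @ regression_coefficients`` is the maximally correlated model whose
    Pearson correlation with the function is reported as ``train_pcc`` /
    ``validation_pcc``.
    """

    mode: np.ndarray  # 3N unit vector (ensemble-weighted collective mode)
    pc_coefficients: np.ndarray  # weights over the top-K PC modes for `mode`
    regression_coefficients: np.ndarray  # PLS model weights in PC space
    train_pcc: float
    validation_pcc: float


def project_frames(traj: TrajectoryEnsemble, modes: ModeSet) -> np.ndarray:
    """Project the centered Cα coordinates of every frame onto the PC modes
    (F x K matrix of mode coordinates, Angstrom)."""
    coords = traj.frames[:, modes.atom_indices].reshape(traj.n_frames, -1)
    centered = coords - modes.mean_structure.ravel()
    return centered @ modes.modes.T


def fma(
    traj: TrajectoryEnsemble,
    modes: ModeSet,
    function_series: np.ndarray,
    n_components: int = 10,
    top_k: int = 20,
    split: str = "halves",
) -> FunctionalMode:
    """Functional mode analysis: the linear combination of the top-K PC modes
    maximally correlated with ``function_series``, by PLS1 regression.

    The fit uses the first half of the frames; the Pearson correlation
    between mode projection and function is reported for both halves
    (``train_pcc`` / ``validation_pcc``).  A contiguous split respects the
    temporal autocorrelation of trajectory data.
    """
    if not traj.aligned:
        raise ValidationError("FMA requires an aligned ensemble")
    y = np.asarray(function_series, dtype=float)
    if y.shape[0] != traj.n_frames:
        raise ValidationError("function series length must equal frame count")
    if np.std(y) < 1e-12:
        raise ValidationError("zero-variance function")
    if split != "halves":
        raise ValidationError(f"unknown split scheme {split!r}")
    top_k = min(top_k, modes.n_modes)
    x = project_frames(traj, modes)[:, :top_k]
    n_components = min(n_components, top_k)
    half = traj.n_frames // 2
    if half < 2 or traj.n_frames - half < 2:
        raise ValidationError("need at least 4 frames for a half split")
    x_train, y_train = x[:half], y[:half]
    x_valid, y_valid = x[half:], y[half:]
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(x_train, y_train)
    coef = np.asarray(pls.coef_, dtype=float).ravel()  # weights in PC space
    proj_train = x_train @ coef
    proj_valid = x_valid @ coef
    train_pcc = float(stats.pearsonr(proj_train, y_train)[0])
    validation_pcc = float(stats.pearsonr(proj_valid, y_valid)[0])
    # Ensemble-weighted collective mode: weight each PC by its variance on
    # the training half, so the mode describes the motion pattern that
    # actually accompanies the functional change rather than the
    # variance-inflated regression direction.
    var_train = x_train.var(axis=0, ddof=1)
    weights = coef * var_train
    mode = weights @ modes.modes[:top_k]
    norm = np.linalg.norm(mode)
    if norm < 1e-12:
        raise ValidationError("PLS produced a null mode")
    return FunctionalMode(
        mode=mode / norm,
        pc_coefficients=weights / norm,
        regression_coefficients=coef,
        train_pcc=train_pcc,
        validation_pcc=validation_pcc,
    )


# ---------------------------------------------------------------------------
# Rigid-body subspace helpers
# ---------------------------------------------------------------------------


def rigid_body_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis (6 x 3N) of infinitesimal rigid-body motions
    (3 translations, 3 rotations about the centroid) at a structure.

    Ensemble superposition removes exactly this subspace from any planted
    displacement field, so recovered modes live in its orthogonal complement.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    centered = coords - coords.mean(axis=0)
    basis = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = 1.0
        basis.append(t.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        basis.append(np.cross(e, centered).ravel())
    basis = np.array(basis)
    q, r = np.linalg.qr(basis.T)
    keep = np.abs(np.diag(r)) > 1e-10
    return q.T[keep]


def remove_rigid_body(field: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Project a 3N displacement field onto the complement of the rigid-body
    subspace at ``coords`` and renormalize."""
    field = np.asarray(field, dtype=float).ravel().copy()
    basis = rigid_body_basis(coords)
    field -= basis.T @ (basis @ field)
    norm = np.linalg.norm(field)
    if norm < 1e-12:
        raise ValidationError("field is purely rigid-body motion")
    return field / norm
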