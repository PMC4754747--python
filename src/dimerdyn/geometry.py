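"""Superposition and basic structural descriptors.

Kabsch superposition (SVD with proper-rotation sign correction), ensemble
alignment on the Cα selection, and the standard descriptors: per-frame RMSD,
per-residue RMSF about the ensemble mean, and the inter-subunit
centroid-distance series.  Superposition is mass-unweighted over Cα atoms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    ResidueSelection,
    StructureModel,
    TrajectoryEnsemble,
    ValidationError,
    calpha_selection,
)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # 3-vector, Angstrom
    rmsd: float  # Angstrom

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    """Rigid transform (proper rotation + translation) minimizing the RMSD of
    ``mobile`` onto ``target``.

    Both inputs are N x 3 with N >= 3 and must not be collinear.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValidationError("mobile and target must both be N x 3")
    n = mobile.shape[0]
    if n < 3:
        raise ValidationError("superposition needs at least 3 points")
    mob_center = mobile.mean(axis=0)
    tgt_center = target.mean(axis=0)
    p = mobile - mob_center
    q = target - tgt_center
    # Degeneracy: all points collinear leaves a free rotation axis.
    if np.linalg.matrix_rank(p, tol=1e-8) < 2:
        raise ValidationError("degenerate (collinear) point set")
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    rotated = p @ rotation.T
    rmsd = float(np.sqrt(np.mean(np.sum((rotated - q) ** 2, axis=1))))
    translation = tgt_center - rotation @ mob_center
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd)


def _superpose_frames(
    frames: np.ndarray, sel: np.ndarray, reference_sel: np.ndarray
) -> np.ndarray:
    out = np.empty_like(frames)
    for t in range(frames.shape[0]):
        fit = kabsch_superpose(frames[t, sel], reference_sel)
        out[t] = fit.apply(frames[t])
    return out


def align_ensemble(
    traj: TrajectoryEnsemble,
    selection: str = "calpha",
    reference: str = "first_frame",
    tol: float = 1e-6,
    max_iter: int = 100,
) -> TrajectoryEnsemble:
    """Superpose every frame on a common reference via the Cα selection.

    ``reference="first_frame"`` fits all frames onto frame 0;
    ``reference="mean_iterative"`` alternates (align onto current mean,
    recompute mean) until the mean moves by less than ``tol`` Angstrom RMS
    or ``max_iter`` iterations.
    """
    if traj.aligned:
        raise ValidationError("ensemble already aligned")
    from .core import select as _select

    sel = _select(traj.model, selection)
    if sel.size < 3:
        raise ValidationError("alignment selection has fewer than 3 atoms")
    frames = np.array(traj.frames, dtype=float)
    if reference == "first_frame":
        frames = _superpose_frames(frames, sel, frames[0, sel])
    elif reference == "mean_iterative":
        ref = frames[0, sel].copy()
        for _ in range(max_iter):
            frames = _superpose_frames(frames, sel, ref)
            new_ref = frames[:, sel].mean(axis=0)
            shift = np.sqrt(np.mean(np.sum((new_ref - ref) ** 2, axis=1)))
            ref = new_ref
            if shift < tol:
                break
    else:
        raise ValidationError(f"unknown alignment reference {reference!r}")
    return TrajectoryEnsemble(
        model=traj.model,
        frames=frames,
        frame_labels=traj.frame_labels.copy(),
        aligned=True,
    )


def rmsd_series(
    traj: TrajectoryEnsemble,
    selection: str = "calpha",
    reference_frame: int = 0,
) -> np.ndarray:
    """Per-frame Kabsch-optimal RMSD (Angstrom) to a reference frame."""
    from .core import select as _select

    sel = _select(traj.model, selection)
    ref = traj.frames[reference_frame, sel]
    return np.array(
        [kabsch_superpose(traj.frames[t, sel], ref).rmsd for t in range(traj.n_frames)]
    )


def rmsf_profile(
    traj: TrajectoryEnsemble, selection: str = "calpha"
) -> tuple[ResidueSelection, np.ndarray]:
    """Per-residue RMSF (Angstrom) about the ensemble mean structure.

    Requires an aligned ensemble.  Returns the residue selection (one entry
    per selected atom, in model order) and the matching RMSF values.
    """
    if not traj.aligned:
        raise ValidationError("RMSF requires an aligned ensemble")
    from .core import select as _select

    sel = _select(traj.model, selection)
    if traj.n_frames == 1:
        warnings.warn("single-frame ensemble: RMSF is identically zero")
    coords = traj.frames[:, sel]  # F x n x 3
    mean = coords.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    model = traj.model
    residues = ResidueSelection(
        [
            (str(model.chain_ids[i]), int(model.residue_indices[i]))
            for i in sel
        ]
    )
    return residues, rmsf


def chain_center_distance(
    traj: TrajectoryEnsemble, chain_a: str, chain_b: str
) -> np.ndarray:
    """Per-frame distance between the unweighted Cα centroids of two chains.

    A pairwise distance is rigid-motion invariant, so aligned and unaligned
    ensembles give identical series.
    """
    model = traj.model
    ca = calpha_selection(model)
    sel_a = ca[np.array([model.chain_ids[i] == chain_a for i in ca])]
    sel_b = ca[np.array([model.chain_ids[i] == chain_b for i in ca])]
    if sel_a.size == 0 or sel_b.size == 0:
        raise ValidationError("both chains need Cα atoms")
    centers_a = traj.frames[:, sel_a].mean(axis=1)
    centers_b = traj.frames[:, sel_b].mean(axis=1)
    return np.linalg.norm(centers_a - centers_b, axis=1)
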