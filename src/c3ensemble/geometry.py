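"""Rigid-body superposition and trimer-specific geometric observables.

The central construction is the per-frame trimer frame: the C3 symmetry axis
is taken as the unit normal of the plane through the three monomer-core
centers of mass, and the reference plane passes through the center of mass
of all core atoms, perpendicular to that axis.  Signed loop protrusion is
the axial coordinate of a reporter atom (Calpha of the loop-tip residue by
convention) in that frame: positive values point away from the ligand face,
i.e. toward the putative downstream-partner interface.

All observables here are invariant under global roto-translations applied
uniformly per frame; superposition-based quantities (RMSF, RMSD) remove
such motion explicitly, plane-based quantities (protrusion) are covariant
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .io import EnsembleTrajectory

__all__ = [
    "TrimerFrame",
    "ProtrusionSeries",
    "kabsch_superpose",
    "c3_frame",
    "trimer_frames",
    "protrusion_distances",
    "radius_of_gyration",
    "rmsf_profile",
    "rmsd_timeseries",
    "equilibration_trim",
]


@dataclass
class TrimerFrame:
    """Per-frame C3 reference frame: unit axis, plane origin, monomer COMs."""

    axis: np.ndarray
    origin: np.ndarray
    monomer_core_coms: np.ndarray  # (3, 3)


@dataclass
class ProtrusionSeries:
    """Signed reporter-to-plane distances, shape (n_frames, 3), in Angstrom."""

    values: np.ndarray
    reporter: tuple[int, str]
    monomers: tuple[str, str, str] = ("A", "B", "C")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise ValueError("protrusion values must have shape (n_frames, 3)")

    @property
    def monomer_averaged(self) -> np.ndarray:
        """Per-frame mean over the three monomers."""
        return self.values.mean(axis=1)


def _check_not_collinear(coords: np.ndarray, what: str) -> None:
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if len(s) < 2 or s[1] <= 1e-8 * max(s[0], 1.0):
        raise ValueError(f"{what}: selected atoms are collinear or degenerate")


def kabsch_superpose(
    mobile_coords: np.ndarray, reference_coords: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper-rotation superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the RMSD to the
    reference over the given atoms.
    """
    mob = np.asarray(mobile_coords, dtype=float)
    ref = np.asarray(reference_coords, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    if mob.shape[0] < 3:
        raise ValueError("superposition requires at least 3 atoms")
    _check_not_collinear(ref, "reference")
    _check_not_collinear(mob, "mobile")
    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - ref_c, mob - mob_c)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    moved = mob @ R.T + t
    rmsd = float(np.sqrt(((moved - ref) ** 2).sum(axis=1).mean()))
    return R, t, rmsd


def _monomer_core_indices(
    traj: EnsembleTrajectory, core_selection: np.ndarray
) -> list[np.ndarray]:
    mono = traj.atoms["monomer_id"].to_numpy()
    labels = traj.monomer_ids[:3]
    out = []
    for m in labels:
        idx = core_selection[mono[core_selection] == m]
        if idx.size == 0:
            raise ValueError(f"core selection empty in monomer {m}")
        out.append(idx)
    return out


def trimer_frames(
    traj: EnsembleTrajectory,
    core_selection: np.ndarray,
    orientation_selection: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized C3 frames for every frame.

    Returns ``(axes, origins, monomer_coms)`` with shapes (n, 3), (n, 3) and
    (n, 3, 3).  The axis sign is fixed so that the orientation selection
    (the ligand face) has a negative axial coordinate.
    """
    if len(orientation_selection) == 0:
        raise ValueError("orientation_selection must be non-empty")
    per_mono = _monomer_core_indices(traj, np.asarray(core_selection))
    coms = np.stack([traj.coords[:, idx, :].mean(axis=1) for idx in per_mono], axis=1)
    v1 = coms[:, 1] - coms[:, 0]
    v2 = coms[:, 2] - coms[:, 0]
    normals = np.cross(v1, v2)
    norms = np.linalg.norm(normals, axis=1)
    if np.any(norms <= 1e-8):
        bad = int(np.argmax(norms <= 1e-8))
        raise ValueError(f"monomer core centers of mass collinear in frame {bad}")
    axes = normals / norms[:, None]
    origins = traj.coords[:, np.asarray(core_selection), :].mean(axis=1)
    orient_com = traj.coords[:, np.asarray(orientation_selection), :].mean(axis=1)
    proj = np.einsum("ij,ij->i", orient_com - origins, axes)
    axes = np.where(proj[:, None] > 0, -axes, axes)
    return axes, origins, coms


def c3_frame(
    traj: EnsembleTrajectory,
    frame_index: int,
    core_selection: np.ndarray,
    orientation_selection: np.ndarray,
) -> TrimerFrame:
    """C3 frame of a single trajectory frame (see :func:`trimer_frames`)."""
    sub = traj.slice_frames(slice(frame_index, frame_index + 1))
    axes, origins, coms = trimer_frames(sub, core_selection, orientation_selection)
    return TrimerFrame(axis=axes[0], origin=origins[0], monomer_core_coms=coms[0])


def protrusion_distances(
    traj: EnsembleTrajectory,
    reporter: tuple[int, str],
    core_selection: np.ndarray,
    orientation_selection: np.ndarray,
) -> ProtrusionSeries:
    """Signed axial distance of the reporter atom from the core plane.

    ``reporter`` is (residue_number, atom_name); it must be present once in
    each of the three monomers.
    """
    res_num, atom_name = reporter
    labels = traj.monomer_ids[:3]
    rep_idx = []
    for m in labels:
        idx = traj.select(monomer=m, residues=[res_num], atoms=atom_name)
        if idx.size != 1:
            raise ValueError(
                f"reporter atom {atom_name} of residue {res_num} not found "
                f"exactly once in monomer {m} (found {idx.size})"
            )
        rep_idx.append(int(idx[0]))
    axes, origins, _ = trimer_frames(traj, core_selection, orientation_selection)
    rep = traj.coords[:, rep_idx, :]  # (n, 3, 3)
    values = np.einsum("nmj,nj->nm", rep - origins[:, None, :], axes)
    return ProtrusionSeries(values=values, reporter=reporter, monomers=tuple(labels))


def radius_of_gyration(
    traj: EnsembleTrajectory,
    selection: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame radius of gyration over the selection (uniform weights
    by default; pass per-atom masses for mass weighting)."""
    idx = np.arange(traj.n_atoms) if selection is None else np.asarray(selection)
    if idx.size == 0:
        raise ValueError("empty selection")
    x = traj.coords[:, idx, :]
    if weights is None:
        w = np.ones(idx.size)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (idx.size,):
            raise ValueError("weights must match selection size")
    w = w / w.sum()
    com = np.einsum("nij,i->nj", x, w)
    d2 = ((x - com[:, None, :]) ** 2).sum(axis=2)
    return np.sqrt(np.einsum("ni,i->n", d2, w))


def _superpose_all(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Superpose every frame of (n, a, 3) onto the (a, 3) reference."""
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        R, t, _ = kabsch_superpose(coords[f], reference)
        out[f] = coords[f] @ R.T + t
    return out


def rmsf_profile(
    traj: EnsembleTrajectory,
    selection: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
):
    """Per-atom RMSF about the iteratively refined average structure.

    Frames are superposed onto the running mean structure until the mean
    shifts by less than ``tol`` Angstrom (max-norm); the RMSF of atom i is
    then sqrt(<|r_i - <r_i>|^2>).  Returns a DataFrame with the selected
    atoms' identity columns and an ``rmsf`` column.
    """
    import pandas as pd

    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    idx = np.arange(traj.n_atoms) if selection is None else np.asarray(selection)
    x = traj.coords[:, idx, :].copy()
    mean = x[0].copy()
    for _ in range(max_iter):
        x = _superpose_all(x, mean)
        new_mean = x.mean(axis=0)
        shift = np.abs(new_mean - mean).max()
        mean = new_mean
        if shift < tol:
            break
    else:
        raise RuntimeError(
            f"average-structure superposition did not converge within {max_iter} iterations"
        )
    rmsf = np.sqrt(((x - mean) ** 2).sum(axis=2).mean(axis=0))
    out = traj.atoms.iloc[idx].reset_index(drop=True).copy()
    out["rmsf"] = rmsf
    return out


def rmsd_timeseries(
    traj: EnsembleTrajectory,
    selection: np.ndarray | None = None,
    reference_frame: int = 0,
) -> np.ndarray:
    """Per-frame minimized RMSD to a reference frame (default: first)."""
    idx = np.arange(traj.n_atoms) if selection is None else np.asarray(selection)
    ref = traj.coords[reference_frame, idx, :]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, _, out[f] = kabsch_superpose(traj.coords[f, idx, :], ref)
    return out


def equilibration_trim(
    traj: EnsembleTrajectory,
    t_cut: float | None = None,
    fraction: float = 0.1,
) -> EnsembleTrajectory:
    """Drop the equilibration segment at the start of a trajectory.

    With frame times present, frames with time < ``t_cut`` ns (default
    100 ns) are removed; without times, the first ``fraction`` of frames is
    dropped.
    """
    if traj.times is not None:
        cut = 100.0 if t_cut is None else float(t_cut)
        span = traj.times.max() - traj.times.min()
        if cut - traj.times.min() >= span:
            raise ValueError(
                f"t_cut={cut} ns >= trajectory span ({span} ns); nothing would remain"
            )
        keep = np.nonzero(traj.times >= cut)[0]
    else:
        if t_cut is not None:
            raise ValueError("t_cut given but trajectory has no frame times")
        n_drop = int(round(fraction * traj.n_frames))
        if n_drop >= traj.n_frames:
            raise ValueError("trim fraction would remove every frame")
        keep = np.arange(n_drop, traj.n_frames)
    return traj.slice_frames(keep)
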