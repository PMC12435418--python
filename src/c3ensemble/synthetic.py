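"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline (geometry, clustering, avidity
statistics, contact persistence, NMR fitting) has a parameter-recovery test
against data produced here, so no external trajectories or spectra are
needed.

The trimer generator emulates a C3-symmetric receptor: a rigid pseudo-atom
core of three identical monomers related by 120-degree rotations, each
carrying a long anchored loop built as a fixed-bond-length pseudo-Calpha
chain whose tip (the reporter residue) protrudes along the symmetry axis.
The reporter's signed axial position is drawn from a two-state mixture: a
"latched" (directed) state with a controllable Normal(mean, sd) marginal,
emulating the stem being pinned by transient contacts to the ligand site,
and an unlatched state sampling a broad centered distribution, emulating
the freely reorienting stem of the ligand-free form.  Inter-loop coupling
is imposed through an equicorrelated Gaussian copula on the three draws.

Default monomer layout (residue numbers, all pseudo-atoms named CA):
1-40 core ring, 41-44 orientation pad on the ligand face (negative axial
side), 66-96 loop with the reporter at residue 81.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .io import EnsembleTrajectory, ShiftTable
from .nmr import (
    DispersionCurve,
    RelaxationSeries,
    carver_richards_r2eff,
    dw_ppm_to_rad,
    rex_from_parameters,
)

__all__ = [
    "TrimerSpec",
    "GroundTruth",
    "generate_trimer_ensemble",
    "generate_shift_tables",
    "generate_dispersion_set",
    "generate_relaxation_set",
    "generate_contact_trajectory",
    "default_selections",
    "BOND_LENGTH",
]

#: Fixed pseudo-bond length of the Calpha-like loop chain, Angstrom.
BOND_LENGTH = 3.8

CORE_RESIDUES = 40
ORIENT_RESIDUES = (41, 42, 43, 44)
LOOP_START = 66
REPORTER_RESIDUE = 81


@dataclass
class TrimerSpec:
    """Parameters of the synthetic trimer ensemble.

    ``loop_bias_mean``/``loop_bias_sd`` set the reporter's axial marginal in
    the latched (directed) state; ``latch_prob`` is the per-frame, per-loop
    probability of that state; the unlatched state samples
    Normal(``random_state_mean``, ``random_state_sd``).  ``inter_loop_corr``
    couples the three monomers' Gaussian draws (equicorrelation, must be
    >= -0.5 for a valid 3x3 correlation matrix).
    """

    n_frames: int = 1000
    n_loop_residues: int = 31
    core_radius: float = 15.0
    loop_bias_mean: float = 16.0
    loop_bias_sd: float = 3.0
    latch_prob: float = 1.0
    inter_loop_corr: float = 0.0
    jitter_sd: float = 0.0
    apply_global_motion: bool = False
    seed: int = 0
    random_state_mean: float = 6.0
    random_state_sd: float = 6.0
    frame_dt_ns: float | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0.0 <= self.latch_prob <= 1.0:
            raise ValueError("latch_prob must be in [0, 1]")
        if self.loop_bias_sd < 0 or self.jitter_sd < 0 or self.random_state_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not -0.5 <= self.inter_loop_corr <= 1.0:
            raise ValueError(
                "inter_loop_corr must be in [-0.5, 1]: the 3-monomer "
                "equicorrelation matrix is not positive semidefinite below -0.5"
            )
        if self.n_loop_residues < 3:
            raise ValueError("loop needs at least 3 residues")


@dataclass
class GroundTruth:
    """Planted truth accompanying a generated dataset."""

    protrusions: np.ndarray | None = None  # (n_frames, 3) Angstrom
    latch_states: np.ndarray | None = None  # (n_frames, 3) bool
    forward_probability: pd.DataFrame | None = None  # threshold grid -> p
    hbond_present: np.ndarray | None = None  # (n_frames,) bool
    parameters: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {}
        if self.protrusions is not None:
            payload["protrusions"] = self.protrusions.tolist()
        if self.latch_states is not None:
            payload["latch_states"] = self.latch_states.astype(int).tolist()
        if self.hbond_present is not None:
            payload["hbond_present"] = self.hbond_present.astype(int).tolist()
        if self.forward_probability is not None:
            payload["forward_probability"] = self.forward_probability.to_dict("list")
        payload["parameters"] = self.parameters
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def default_selections(traj: EnsembleTrajectory) -> dict[str, np.ndarray]:
    """Core / orientation / loop selections for generator-built trimers."""
    return {
        "core": traj.select(residues=(1, CORE_RESIDUES)),
        "orientation": traj.select(residues=(ORIENT_RESIDUES[0], ORIENT_RESIDUES[-1])),
        "loop": traj.select(residues=(LOOP_START, LOOP_START + 30)),
    }


def _monomer_core_template(core_radius: float) -> tuple[np.ndarray, list[int]]:
    """Rigid core arc of one monomer plus the orientation pad, around +x.

    Returns (coords, residue_numbers); the trimer is built by rotating this
    template by 0/120/240 degrees about z.  The full-core center of mass
    sits on the z axis at z=0 by symmetry.
    """
    coords = []
    resnum = []
    arc = np.linspace(-np.pi / 3 + 0.15, np.pi / 3 - 0.15, CORE_RESIDUES)
    z_wave = 4.0 * np.sin(np.linspace(0, 3 * np.pi, CORE_RESIDUES))
    z_wave -= z_wave.mean()  # core plane sits exactly at z = 0
    r_wave = core_radius + 1.5 * np.cos(np.linspace(0, 2 * np.pi, CORE_RESIDUES))
    for i, (phi, z, r) in enumerate(zip(arc, z_wave, r_wave), start=1):
        coords.append([r * np.cos(phi), r * np.sin(phi), z])
        resnum.append(i)
    # orientation pad: the ligand face, on the negative axial side
    for k, res in enumerate(ORIENT_RESIDUES):
        coords.append([0.6 * core_radius, (k - 1.5) * 2.0, -8.0])
        resnum.append(res)
    return np.asarray(coords, dtype=float), resnum


def _loop_path(
    anchor_a: np.ndarray,
    anchor_b: np.ndarray,
    tip: np.ndarray,
    n_residues: int,
    rng: np.random.Generator,
    wobble_sd: float = 0.6,
) -> np.ndarray:
    """Fixed-bond-length chain from anchor_a through tip to anchor_b.

    Points are spaced evenly along the two-segment polyline and pushed out
    perpendicular in an alternating sawtooth so each pseudo-bond has length
    close to BOND_LENGTH (exact on straight segments, approximate at the
    kink); a small random wobble decorrelates non-tip atoms between frames.
    The tip atom itself is placed exactly at ``tip``.
    """
    n_half = n_residues // 2
    seg1 = np.linalg.norm(tip - anchor_a)
    seg2 = np.linalg.norm(anchor_b - tip)
    if seg1 < 1e-9 or seg2 < 1e-9:
        raise ValueError("non-constructible loop geometry: tip coincides with an anchor")
    total = seg1 + seg2
    spacing = total / (n_residues - 1)
    if spacing > BOND_LENGTH:
        raise ValueError(
            f"loop too short to span anchors: {n_residues} residues need "
            f"{spacing:.2f} A spacing > bond length {BOND_LENGTH} A"
        )
    # arc-length positions along the polyline
    s = np.linspace(0.0, total, n_residues)
    pts = np.empty((n_residues, 3))
    u1 = (tip - anchor_a) / seg1
    u2 = (anchor_b - tip) / seg2
    for i, si in enumerate(s):
        if si <= seg1:
            pts[i] = anchor_a + u1 * si
        else:
            pts[i] = tip + u2 * (si - seg1)
    # alternating perpendicular sawtooth restoring the bond length
    amp = 0.5 * np.sqrt(max(BOND_LENGTH**2 - spacing**2, 0.0))
    normal = np.cross(u1, u2)
    if np.linalg.norm(normal) < 1e-8:
        helper = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(u1, helper)) > 0.9:
            helper = np.array([1.0, 0.0, 0.0])
        normal = np.cross(u1, helper)
    normal = normal / np.linalg.norm(normal)
    signs = np.where(np.arange(n_residues) % 2 == 0, 1.0, -1.0)
    offsets = signs[:, None] * amp * normal
    offsets += rng.normal(0.0, wobble_sd, size=(n_residues, 3))
    offsets[0] = offsets[-1] = 0.0  # anchors stay put
    tip_index = n_half
    offsets[tip_index] = 0.0  # reporter exactly at the drawn position
    return pts + offsets


def _sample_protrusions(spec: TrimerSpec, rng: np.random.Generator):
    """Draw per-frame per-monomer axial tip positions and latch states."""
    n = spec.n_frames
    rho = spec.inter_loop_corr
    cov = np.full((3, 3), rho) + (1.0 - rho) * np.eye(3)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(3))
    z = rng.standard_normal((n, 3)) @ chol.T
    latched = rng.random((n, 3)) < spec.latch_prob
    mean = np.where(latched, spec.loop_bias_mean, spec.random_state_mean)
    sd = np.where(latched, spec.loop_bias_sd, spec.random_state_sd)
    return mean + sd * z, latched


def generate_trimer_ensemble(spec: TrimerSpec) -> tuple[EnsembleTrajectory, GroundTruth]:
    """Build a C3-symmetric pseudo-atom trimer ensemble with known truth.

    Identical specs (including seed) give bit-identical trajectories.  The
    ground truth records the exact pre-jitter axial reporter positions.
    """
    rng = np.random.default_rng(spec.seed)
    core_template, core_resnum = _monomer_core_template(spec.core_radius)
    rotations = [
        Rotation.from_euler("z", ang, degrees=True).as_matrix()
        for ang in (0.0, 120.0, 240.0)
    ]
    protrusions, latched = _sample_protrusions(spec, rng)

    loop_resnums = list(range(LOOP_START, LOOP_START + spec.n_loop_residues))
    tip_index = spec.n_loop_residues // 2
    reporter_residue = loop_resnums[tip_index]

    # anchors at the top rim of the core template (start and end of the arc)
    anchor_a0 = core_template[0] + np.array([0.0, 0.0, 3.0])
    anchor_b0 = core_template[CORE_RESIDUES - 1] + np.array([0.0, 0.0, 3.0])
    tip_radius = 0.45 * spec.core_radius

    atoms_rows = []
    for m_idx, label in enumerate("ABC"):
        for res in core_resnum:
            atoms_rows.append((label, res, "GLY", "CA"))
        for res in loop_resnums:
            atoms_rows.append((label, res, "GLY", "CA"))
    atoms = pd.DataFrame(atoms_rows, columns=["monomer_id", "residue_number", "residue_name", "atom_name"])

    n_per_mono = len(core_resnum) + spec.n_loop_residues
    coords = np.empty((spec.n_frames, 3 * n_per_mono, 3))
    for f in range(spec.n_frames):
        frame_parts = []
        for m_idx, R in enumerate(rotations):
            tip_local = np.array(
                [tip_radius, 0.0, protrusions[f, m_idx]]
            )
            loop = _loop_path(
                anchor_a0, anchor_b0, tip_local, spec.n_loop_residues, rng
            )
            mono = np.vstack([core_template, loop])
            frame_parts.append(mono @ R.T)
        frame = np.vstack(frame_parts)
        if spec.jitter_sd > 0:
            frame = frame + rng.normal(0.0, spec.jitter_sd, size=frame.shape)
        if spec.apply_global_motion:
            Rg = Rotation.random(random_state=rng).as_matrix()
            tg = rng.uniform(-50.0, 50.0, size=3)
            frame = frame @ Rg.T + tg
        coords[f] = frame

    times = (
        np.arange(spec.n_frames) * spec.frame_dt_ns
        if spec.frame_dt_ns is not None
        else None
    )
    traj = EnsembleTrajectory(coords, atoms, times)
    thresholds = np.arange(0.0, 30.5, 0.5)
    if spec.loop_bias_sd > 0 or spec.latch_prob < 1.0:
        from scipy.stats import norm

        p_lat = (
            1.0 - norm.cdf(thresholds, spec.loop_bias_mean, max(spec.loop_bias_sd, 1e-12))
            if spec.loop_bias_sd > 0
            else (thresholds <= spec.loop_bias_mean).astype(float)
        )
        p_unl = 1.0 - norm.cdf(
            thresholds, spec.random_state_mean, max(spec.random_state_sd, 1e-12)
        )
        p_fwd = spec.latch_prob * p_lat + (1.0 - spec.latch_prob) * p_unl
    else:
        p_fwd = (thresholds <= spec.loop_bias_mean).astype(float)
    truth = GroundTruth(
        protrusions=protrusions,
        latch_states=latched,
        forward_probability=pd.DataFrame(
            {"threshold": thresholds, "p_forward": p_fwd}
        ),
        parameters={
            "spec": asdict(spec),
            "reporter_residue": reporter_residue,
        },
    )
    return traj, truth


def generate_shift_tables(
    n_residues: int,
    perturbed_set: Sequence[int],
    dh: float,
    dn: float,
    seed: int = 0,
) -> tuple[ShiftTable, ShiftTable, GroundTruth]:
    """Two-state shift tables: holo equals apo except (dh, dn) on the
    amide H/N of the perturbed residues."""
    perturbed = set(int(r) for r in perturbed_set)
    if not perturbed <= set(range(1, n_residues + 1)):
        raise ValueError("perturbed_set must be a subset of residue indices")
    rng = np.random.default_rng(seed)
    centers = {"H": (8.3, 0.5), "N": (119.0, 4.0), "C": (176.0, 1.8), "CA": (56.0, 3.0), "CB": (33.0, 4.5)}
    rows = []
    for res in range(1, n_residues + 1):
        for atom, (mu, sd) in centers.items():
            rows.append((res, "ALA", atom, float(rng.normal(mu, sd))))
    apo_df = pd.DataFrame(rows, columns=["residue_number", "residue_name", "atom_name", "shift"])
    holo_df = apo_df.copy()
    mask_h = holo_df["residue_number"].isin(perturbed) & (holo_df["atom_name"] == "H")
    mask_n = holo_df["residue_number"].isin(perturbed) & (holo_df["atom_name"] == "N")
    holo_df.loc[mask_h, "shift"] += dh
    holo_df.loc[mask_n, "shift"] += dn
    truth = GroundTruth(
        parameters={
            "perturbed_residues": sorted(perturbed),
            "dh_ppm": dh,
            "dn_ppm": dn,
            "expected_csp_ppm": float(np.sqrt(dh**2 + (0.14 * dn) ** 2)),
        }
    )
    return (
        ShiftTable(apo_df, label="apo"),
        ShiftTable(holo_df, label="holo"),
        truth,
    )


def generate_dispersion_set(
    r20: float,
    kex: float,
    pb: float,
    dw_ppm: float,
    field_mhz: float,
    nu_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[DispersionCurve, GroundTruth]:
    """CPMG dispersion curve from the two-site closed form plus noise.

    The planted truth stores the analytic Rex of the noiseless curve.
    """
    if kex <= 0:
        raise ValueError("kex must be > 0")
    if not 0.0 <= pb < 0.5:
        raise ValueError("pb must be in [0, 0.5)")
    nu = np.asarray(nu_grid, dtype=float)
    if np.any(nu <= 0) or np.any(np.diff(nu) <= 0):
        raise ValueError("nu grid must be positive ascending")
    rng = np.random.default_rng(seed)
    if pb == 0.0:
        clean = np.full_like(nu, r20)
        rex = 0.0
    else:
        dw_rad = dw_ppm_to_rad(dw_ppm, field_mhz)
        clean = carver_richards_r2eff(nu, r20, kex, pb, dw_rad)
        rex = rex_from_parameters(kex, pb, dw_rad)
    noisy = clean + rng.normal(0.0, noise_sd, size=nu.shape)
    errors = np.full(nu.shape, noise_sd) if noise_sd > 0 else None
    curve = DispersionCurve(nu_hz=nu, r2eff=noisy, field_mhz=field_mhz, errors=errors)
    truth = GroundTruth(
        parameters={
            "r20": r20,
            "kex": kex,
            "pb": pb,
            "dw_ppm": dw_ppm,
            "field_mhz": field_mhz,
            "rex": rex,
            "noise_sd": noise_sd,
            "noiseless": clean.tolist(),
        }
    )
    return curve, truth


def generate_relaxation_set(
    rate: float,
    i0: float,
    delays: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> RelaxationSeries:
    """Exponential decay ``I(t) = I0 exp(-rate t)`` plus Gaussian noise."""
    if rate <= 0:
        raise ValueError("rate must be > 0")
    t = np.asarray(delays, dtype=float)
    if t.size == 0:
        raise ValueError("delay list must be non-empty")
    if np.any(t < 0):
        raise ValueError("delays must be >= 0")
    rng = np.random.default_rng(seed)
    y = i0 * np.exp(-rate * t) + rng.normal(0.0, noise_sd, size=t.shape)
    errors = np.full(t.shape, noise_sd) if noise_sd > 0 else None
    return RelaxationSeries(delays=t, intensities=y, errors=errors, label=f"rate={rate}")


def generate_contact_trajectory(
    occupancy_fraction: float,
    n_frames: int,
    seed: int = 0,
) -> tuple[EnsembleTrajectory, GroundTruth]:
    """Donor/hydrogen/acceptor fixture with an exactly planted H-bond occupancy.

    In ``round(occupancy_fraction * n_frames)`` frames the acceptor oxygen
    sits 2.9 A from the donor nitrogen on the N-H axis (ideal linear bond);
    in the remaining frames it is displaced to 6.5 A, violating any common
    distance criterion.
    """
    if not 0.0 <= occupancy_fraction <= 1.0:
        raise ValueError("occupancy_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_on = int(round(occupancy_fraction * n_frames))
    present = np.zeros(n_frames, dtype=bool)
    present[rng.permutation(n_frames)[:n_on]] = True

    # donor residue GLN 9 (N, H, CA) and acceptor residue GLY 95 (O, CA),
    # echoing a loop-latch amide contact; three chains for trimer validity
    atoms = pd.DataFrame(
        [
            ("A", 9, "GLN", "N"),
            ("A", 9, "GLN", "H"),
            ("A", 9, "GLN", "CA"),
            ("A", 95, "GLY", "O"),
            ("A", 95, "GLY", "CA"),
            ("B", 9, "GLN", "CA"),
            ("C", 9, "GLN", "CA"),
        ],
        columns=["monomer_id", "residue_number", "residue_name", "atom_name"],
    )
    n_atoms = len(atoms)
    coords = np.zeros((n_frames, n_atoms, 3))
    donor_n = np.array([0.0, 0.0, 0.0])
    donor_h = np.array([1.0, 0.0, 0.0])  # N-H along +x, 1.0 A
    donor_ca = np.array([-1.5, 0.0, 0.0])
    acceptor_on = np.array([2.9, 0.0, 0.0])  # linear N-H...O
    acceptor_off = np.array([0.0, 6.5, 0.0])
    for f in range(n_frames):
        acc = acceptor_on if present[f] else acceptor_off
        coords[f, 0] = donor_n
        coords[f, 1] = donor_h
        coords[f, 2] = donor_ca
        coords[f, 3] = acc
        coords[f, 4] = acc + np.array([1.5, 0.0, 0.0])
        coords[f, 5] = np.array([20.0, 0.0, 0.0])
        coords[f, 6] = np.array([0.0, 20.0, 0.0])
    traj = EnsembleTrajectory(coords, atoms)
    truth = GroundTruth(
        hbond_present=present,
        parameters={
            "occupancy_fraction": occupancy_fraction,
            "planted_occurrence_pct": 100.0 * n_on / n_frames,
        },
    )
    return traj, truth
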