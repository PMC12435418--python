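"""Residue-pair minimum-distance maps, apo-holo difference maps, and
hydrogen-bond / salt-bridge occupancy with persistence filtering.

Contact maps aggregate the per-frame minimum heavy-atom distance between
residue pairs (ensemble mean by default; the per-frame matrix is available
for other aggregations).  H-bonds use a geometric criterion — donor-acceptor
distance and donor-hydrogen-acceptor angle — with occurrence expressed as
the percentage of frames in which the criterion holds.  "Persistent"
contacts are those strictly above an occurrence threshold (10% by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EnsembleTrajectory

__all__ = [
    "ContactMap",
    "HBondRecord",
    "min_distance_map",
    "difference_map",
    "hbond_occurrence",
    "persistent_contacts",
    "salt_bridge_occurrence",
    "DEFAULT_HBOND_CRITERIA",
]

#: Common MD-analysis convention: donor-acceptor <= 3.5 A, D-H-A >= 150 deg.
DEFAULT_HBOND_CRITERIA = {"d_da_max": 3.5, "angle_dha_min": 150.0}

#: Charged-group nitrogen/oxygen minimum distance for salt bridges, A.
SALT_BRIDGE_CUTOFF = 4.0

PairKey = tuple[str, int, str, int]


@dataclass
class ContactMap:
    """Residue-pair keyed mean minimum heavy-atom distances.

    ``table`` columns: monomer_i, residue_i, monomer_j, residue_j,
    mean_min_distance (A).  Pairs are stored once with the canonical
    ordering (monomer, residue) ascending; lookups are symmetric.
    """

    table: pd.DataFrame
    scope: str = "all"
    per_frame: np.ndarray | None = field(default=None, repr=False)

    def get(self, mono_i: str, res_i: int, mono_j: str, res_j: int) -> float:
        a, b = sorted([(mono_i, res_i), (mono_j, res_j)])
        sel = self.table[
            (self.table["monomer_i"] == a[0])
            & (self.table["residue_i"] == a[1])
            & (self.table["monomer_j"] == b[0])
            & (self.table["residue_j"] == b[1])
        ]
        if sel.empty:
            raise KeyError(f"pair {a}-{b} not in map")
        return float(sel["mean_min_distance"].iloc[0])


def _heavy_mask(atoms: pd.DataFrame) -> np.ndarray:
    return ~atoms["atom_name"].str.startswith("H").to_numpy()


def _residue_groups(traj: EnsembleTrajectory, atom_indices: np.ndarray):
    atoms = traj.atoms.iloc[atom_indices]
    groups = {}
    for (mono, res), sub in atoms.groupby(["monomer_id", "residue_number"], sort=True):
        groups[(mono, int(res))] = atom_indices[
            np.isin(atom_indices, sub.index.to_numpy())
        ]
    return groups


def min_distance_map(
    traj: EnsembleTrajectory,
    pair_scope: str = "all",
    selection: np.ndarray | None = None,
) -> ContactMap:
    """Mean (over frames) of per-frame minimum heavy-atom distances.

    ``pair_scope``: "intra" (same monomer), "inter" (different monomers) or
    "all".  The per-frame minima are kept on the result for alternative
    aggregations.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    if pair_scope not in ("intra", "inter", "all"):
        raise ValueError(f"unknown pair scope {pair_scope!r}")
    idx = np.arange(traj.n_atoms) if selection is None else np.asarray(selection)
    idx = idx[_heavy_mask(traj.atoms)[idx]]
    groups = _residue_groups(traj, idx)
    keys = sorted(groups)
    pairs = []
    for i, ki in enumerate(keys):
        for kj in keys[i + 1 :]:
            same = ki[0] == kj[0]
            if pair_scope == "intra" and not same:
                continue
            if pair_scope == "inter" and same:
                continue
            pairs.append((ki, kj))
    if not pairs:
        raise ValueError(f"scope {pair_scope!r} selects no residue pairs")
    per_frame = np.empty((traj.n_frames, len(pairs)))
    for p, (ki, kj) in enumerate(pairs):
        xi = traj.coords[:, groups[ki], :]
        xj = traj.coords[:, groups[kj], :]
        d = np.linalg.norm(xi[:, :, None, :] - xj[:, None, :, :], axis=3)
        per_frame[:, p] = d.min(axis=(1, 2))
    table = pd.DataFrame(
        {
            "monomer_i": [ki[0] for ki, _ in pairs],
            "residue_i": [ki[1] for ki, _ in pairs],
            "monomer_j": [kj[0] for _, kj in pairs],
            "residue_j": [kj[1] for _, kj in pairs],
            "mean_min_distance": per_frame.mean(axis=0),
        }
    )
    return ContactMap(table=table, scope=pair_scope, per_frame=per_frame)


def difference_map(map_a: ContactMap, map_b: ContactMap) -> pd.DataFrame:
    """Signed per-pair difference A - B (negative: closer in A).

    Outer join over the two pair universes; pairs present in only one map
    carry NaN differences and are flagged.  Disjoint maps are an error.
    """
    keys = ["monomer_i", "residue_i", "monomer_j", "residue_j"]
    merged = map_a.table.merge(
        map_b.table, on=keys, how="outer", suffixes=("_a", "_b"), indicator=True
    )
    if not (merged["_merge"] == "both").any():
        raise ValueError("contact maps share no residue pairs")
    merged["delta"] = merged["mean_min_distance_a"] - merged["mean_min_distance_b"]
    merged["missing"] = merged["_merge"] != "both"
    return merged[keys + ["delta", "missing"]]


@dataclass
class HBondRecord:
    """A donor(-H)-acceptor candidate with per-frame presence flags."""

    donor: tuple[str, int, str]
    hydrogen: tuple[str, int, str] | None
    acceptor: tuple[str, int, str]
    criteria: dict
    presence: np.ndarray
    occurrence: float  # percent of frames

    def __post_init__(self) -> None:
        if not 0.0 <= self.occurrence <= 100.0:
            raise ValueError("occurrence must be a percentage in [0, 100]")


def _polar_atoms(traj: EnsembleTrajectory):
    names = traj.atoms["atom_name"]
    heavy_no = names.str.startswith("N").to_numpy()
    heavy_o = names.str.startswith("O").to_numpy()
    hydro = names.str.startswith("H").to_numpy()
    return np.nonzero(heavy_no | heavy_o)[0], np.nonzero(hydro)[0]


def _attached_hydrogens(
    traj: EnsembleTrajectory, polar_idx: np.ndarray, hydro_idx: np.ndarray
) -> dict[int, list[int]]:
    """Map donor heavy atom -> bonded hydrogens (<= 1.25 A in frame 0,
    same residue)."""
    out: dict[int, list[int]] = {}
    if hydro_idx.size == 0:
        return out
    atoms = traj.atoms
    x0 = traj.coords[0]
    for d in polar_idx:
        same_res = (
            (atoms["monomer_id"] == atoms["monomer_id"].iloc[d])
            & (atoms["residue_number"] == atoms["residue_number"].iloc[d])
        ).to_numpy()
        cand = hydro_idx[same_res[hydro_idx]]
        if cand.size == 0:
            continue
        dist = np.linalg.norm(x0[cand] - x0[d], axis=1)
        bonded = cand[dist <= 1.25].tolist()
        if bonded:
            out[int(d)] = bonded
    return out


def _atom_id(traj: EnsembleTrajectory, i: int) -> tuple[str, int, str]:
    row = traj.atoms.iloc[i]
    return (row["monomer_id"], int(row["residue_number"]), row["atom_name"])


def hbond_occurrence(
    traj: EnsembleTrajectory,
    d_da_max: float = DEFAULT_HBOND_CRITERIA["d_da_max"],
    angle_dha_min: float = DEFAULT_HBOND_CRITERIA["angle_dha_min"],
    heavy_only: bool = False,
) -> list[HBondRecord]:
    """Per-frame H-bond detection over all donor/acceptor candidates.

    Donors are N/O atoms with a covalently attached hydrogen (bond inferred
    from frame-0 geometry); acceptors are any N/O atoms outside the donor's
    residue.  A bond is present in a frame when distance(D, A) <= d_da_max
    and angle(D-H-A) >= angle_dha_min.  Without hydrogens in the topology,
    an error instructs the distance-only ``heavy_only`` mode, which is
    flagged in the records' criteria.
    """
    polar_idx, hydro_idx = _polar_atoms(traj)
    donors = _attached_hydrogens(traj, polar_idx, hydro_idx)
    criteria = {
        "d_da_max": d_da_max,
        "angle_dha_min": angle_dha_min,
        "heavy_only": heavy_only,
    }
    if not donors and not heavy_only:
        raise ValueError(
            "no hydrogens attached to polar atoms in the topology; rerun "
            "with heavy_only=True for a distance-only criterion"
        )
    records: list[HBondRecord] = []
    donor_items = (
        donors.items() if not heavy_only else [(int(d), [None]) for d in polar_idx]
    )
    atoms = traj.atoms
    for d, hydrogens in donor_items:
        d_res = (atoms["monomer_id"].iloc[d], int(atoms["residue_number"].iloc[d]))
        for a in polar_idx:
            if int(a) == int(d):
                continue
            a_res = (atoms["monomer_id"].iloc[a], int(atoms["residue_number"].iloc[a]))
            if a_res == d_res:
                continue
            dist = np.linalg.norm(traj.coords[:, a, :] - traj.coords[:, d, :], axis=1)
            for h in hydrogens:
                if h is None:
                    present = dist <= d_da_max
                else:
                    v1 = traj.coords[:, d, :] - traj.coords[:, h, :]
                    v2 = traj.coords[:, a, :] - traj.coords[:, h, :]
                    cosang = np.einsum("ij,ij->i", v1, v2) / (
                        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
                    )
                    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                    present = (dist <= d_da_max) & (angle >= angle_dha_min)
                records.append(
                    HBondRecord(
                        donor=_atom_id(traj, d),
                        hydrogen=None if h is None else _atom_id(traj, h),
                        acceptor=_atom_id(traj, int(a)),
                        criteria=criteria,
                        presence=present,
                        occurrence=float(100.0 * present.mean()),
                    )
                )
    return records


def persistent_contacts(
    records: list[HBondRecord], min_occurrence: float = 10.0
) -> list[HBondRecord]:
    """Contacts with occurrence strictly above the threshold (percent),
    sorted by occurrence descending."""
    kept = [r for r in records if r.occurrence > min_occurrence]
    return sorted(kept, key=lambda r: -r.occurrence)


POSITIVE_RESIDUES = ("ARG", "LYS", "HIS")
NEGATIVE_RESIDUES = ("ASP", "GLU")


def salt_bridge_occurrence(
    traj: EnsembleTrajectory, d_max: float = SALT_BRIDGE_CUTOFF
) -> list[HBondRecord]:
    """Salt bridges as a contact subclass: charged-group N (Arg/Lys/His
    sidechain) to charged-group O (Asp/Glu sidechain) minimum distance
    <= ``d_max`` per frame."""
    atoms = traj.atoms
    pos = np.nonzero(
        atoms["residue_name"].isin(POSITIVE_RESIDUES).to_numpy()
        & atoms["atom_name"].str.match(r"N[HZE]").to_numpy()
    )[0]
    neg = np.nonzero(
        atoms["residue_name"].isin(NEGATIVE_RESIDUES).to_numpy()
        & atoms["atom_name"].str.match(r"O[ED]").to_numpy()
    )[0]
    criteria = {"d_da_max": d_max, "kind": "salt_bridge"}
    # group by residue, take the per-frame minimum over the charged groups
    records: list[HBondRecord] = []
    pos_res = sorted({(atoms["monomer_id"].iloc[i], int(atoms["residue_number"].iloc[i])) for i in pos})
    neg_res = sorted({(atoms["monomer_id"].iloc[i], int(atoms["residue_number"].iloc[i])) for i in neg})
    for pr in pos_res:
        pi = [i for i in pos if (atoms["monomer_id"].iloc[i], int(atoms["residue_number"].iloc[i])) == pr]
        for nr in neg_res:
            ni = [i for i in neg if (atoms["monomer_id"].iloc[i], int(atoms["residue_number"].iloc[i])) == nr]
            d = np.linalg.norm(
                traj.coords[:, pi, None, :] - traj.coords[:, None, ni, :], axis=3
            ).min(axis=(1, 2))
            present = d <= d_max
            records.append(
                HBondRecord(
                    donor=(pr[0], pr[1], "sidechain-N"),
                    hydrogen=None,
                    acceptor=(nr[0], nr[1], "sidechain-O"),
                    criteria=criteria,
                    presence=present,
                    occurrence=float(100.0 * present.mean()),
                )
            )
    return records
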