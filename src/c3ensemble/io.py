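"""Ensemble and shift-table I/O.

Reads multi-model PDB trajectories into :class:`EnsembleTrajectory`, chemical
shift tables from CSV or NMR-STAR v3 ``Atom_chem_shift`` loops into
:class:`ShiftTable`, and writes deterministic TSV/JSON result bundles.

Residue numbering is 1-based at the file boundary, as in PDB and NMR-STAR;
internal atom indices are 0-based numpy indices.
"""

from __future__ import annotations

import json
import shlex
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EnsembleTrajectory",
    "ShiftTable",
    "read_trajectory",
    "write_trajectory",
    "read_shift_table",
    "write_shift_table_csv",
    "write_results",
    "count_shifts",
    "count_assigned_residues",
    "DEFAULT_SHIFT_ATOMS",
]

#: Backbone shift types retained by default: amide proton/nitrogen, carbonyl
#: carbon (stored as "C" per PDB/NMR-STAR convention), and Calpha/Cbeta.
DEFAULT_SHIFT_ATOMS = ("H", "N", "C", "CA", "CB")

ATOM_COLUMNS = ["monomer_id", "residue_number", "residue_name", "atom_name"]


@dataclass
class EnsembleTrajectory:
    """A conformational ensemble of a (pseudo-)molecular system.

    Parameters
    ----------
    coords
        Coordinates in Angstrom, shape ``(n_frames, n_atoms, 3)``.
    atoms
        Atom table with columns ``monomer_id`` (chain label, 'A'/'B'/'C' for
        the trimer), ``residue_number`` (1-based), ``residue_name``,
        ``atom_name``; one row per atom, aligned with the coordinate axis.
    times
        Optional per-frame times in ns (ascending).
    """

    coords: np.ndarray
    atoms: pd.DataFrame
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(
                f"coords must have shape (n_frames, n_atoms, 3), got {self.coords.shape}"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValueError(f"atom table missing columns {missing}")
        if len(self.atoms) != self.coords.shape[1]:
            raise ValueError(
                f"atom table has {len(self.atoms)} rows but coords have "
                f"{self.coords.shape[1]} atoms"
            )
        self.atoms = self.atoms.reset_index(drop=True)
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (self.coords.shape[0],):
                raise ValueError("times must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def monomer_ids(self) -> list[str]:
        """Monomer labels in order of first appearance."""
        return list(dict.fromkeys(self.atoms["monomer_id"]))

    def select(
        self,
        monomer: str | None = None,
        residues: Sequence[int] | tuple[int, int] | None = None,
        atoms: str | Iterable[str] | None = None,
    ) -> np.ndarray:
        """Return 0-based atom indices matching the criteria.

        ``residues`` may be an inclusive ``(lo, hi)`` range or an explicit
        list of residue numbers.
        """
        mask = np.ones(self.n_atoms, dtype=bool)
        if monomer is not None:
            mask &= (self.atoms["monomer_id"] == monomer).to_numpy()
        if residues is not None:
            res = self.atoms["residue_number"].to_numpy()
            if isinstance(residues, tuple) and len(residues) == 2:
                mask &= (res >= residues[0]) & (res <= residues[1])
            else:
                mask &= np.isin(res, list(residues))
        if atoms is not None:
            if isinstance(atoms, str):
                atoms = [atoms]
            mask &= self.atoms["atom_name"].isin(list(atoms)).to_numpy()
        return np.nonzero(mask)[0]

    def slice_frames(self, frame_indices: np.ndarray | slice) -> "EnsembleTrajectory":
        times = self.times[frame_indices] if self.times is not None else None
        return EnsembleTrajectory(self.coords[frame_indices], self.atoms.copy(), times)

    def subset_atoms(self, atom_indices: np.ndarray) -> "EnsembleTrajectory":
        times = None if self.times is None else self.times.copy()
        return EnsembleTrajectory(
            self.coords[:, atom_indices, :],
            self.atoms.iloc[atom_indices].reset_index(drop=True),
            times,
        )


@dataclass
class ShiftTable:
    """Chemical-shift table for one state (apo or holo).

    ``entries`` has columns ``residue_number``, ``residue_name``,
    ``atom_name``, ``shift`` (ppm); at most one row per (residue, atom).
    """

    entries: pd.DataFrame
    label: str = ""
    accession: str = ""

    def __post_init__(self) -> None:
        required = ["residue_number", "residue_name", "atom_name", "shift"]
        missing = [c for c in required if c not in self.entries.columns]
        if missing:
            raise ValueError(f"shift table missing columns {missing}")
        ent = self.entries.reset_index(drop=True)
        dup = ent.duplicated(subset=["residue_number", "atom_name"], keep=False)
        if dup.any():
            rows = ent.loc[dup, ["residue_number", "atom_name"]]
            raise ValueError(
                "duplicate (residue, atom) shift rows: "
                + ", ".join(f"{r.residue_number}/{r.atom_name}" for r in rows.itertuples())
            )
        if not np.isfinite(ent["shift"].to_numpy(dtype=float)).all():
            raise ValueError("shift values must be finite")
        self.entries = ent

    def get(self, residue_number: int, atom_name: str) -> float | None:
        sel = self.entries[
            (self.entries["residue_number"] == residue_number)
            & (self.entries["atom_name"] == atom_name)
        ]
        if sel.empty:
            return None
        return float(sel["shift"].iloc[0])


# ---------------------------------------------------------------------------
# trajectory I/O (multi-model PDB via biotite)
# ---------------------------------------------------------------------------


def _model_atom_counts(lines: Sequence[str]) -> list[int]:
    """Count ATOM/HETATM records per MODEL block (single block if no MODEL)."""
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    for line in lines:
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            in_model = True
            current = 0
        elif rec == "ENDMDL":
            counts.append(current)
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            current += 1
    if not saw_model:
        counts = [current]
    elif in_model:  # unterminated final MODEL
        counts.append(current)
    return counts


def read_trajectory(path: str | Path, topology_path: str | Path | None = None) -> EnsembleTrajectory:
    """Read a multi-model PDB file as an ensemble.

    The first three distinct chain identifiers are mapped to monomers
    'A', 'B', 'C' in order of appearance; further chains (e.g. a ligand)
    keep their own label.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    pdb = PDBFile.read(str(path))
    counts = _model_atom_counts(pdb.lines)
    if len(set(counts)) > 1:
        bad = next(i for i, c in enumerate(counts, start=1) if c != counts[0])
        raise ValueError(
            f"inconsistent atom counts across models: model {bad} has "
            f"{counts[bad - 1]} atoms, model 1 has {counts[0]}"
        )
    stack = pdb.get_structure(model=None)
    coords = np.asarray(stack.coord, dtype=float)
    chains = list(stack.chain_id)
    order = list(dict.fromkeys(chains))
    if len(order) < 3:
        raise ValueError(
            f"trimer trajectory requires >= 3 chains, found {len(order)}: {order}"
        )
    mapping = {c: lbl for c, lbl in zip(order[:3], "ABC")}
    monomer = [mapping.get(c, c) for c in chains]
    atoms = pd.DataFrame(
        {
            "monomer_id": monomer,
            "residue_number": np.asarray(stack.res_id, dtype=int),
            "residue_name": list(stack.res_name),
            "atom_name": list(stack.atom_name),
        }
    )
    return EnsembleTrajectory(coords, atoms)


def write_trajectory(traj: EnsembleTrajectory, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB file (coordinates to 0.001 A)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_atoms = traj.n_atoms
    arr = struc.AtomArray(n_atoms)
    arr.chain_id = np.array([str(m)[:4] for m in traj.atoms["monomer_id"]])
    arr.res_id = traj.atoms["residue_number"].to_numpy(dtype=int)
    arr.res_name = traj.atoms["residue_name"].to_numpy(dtype=str)
    arr.atom_name = traj.atoms["atom_name"].to_numpy(dtype=str)
    elements = [
        (a[:1] if a[:1].isalpha() else a[1:2]) or "C" for a in traj.atoms["atom_name"]
    ]
    arr.element = np.array([e.upper() for e in elements])
    stack = struc.AtomArrayStack(traj.n_frames, n_atoms)
    for ann in ("chain_id", "res_id", "res_name", "atom_name", "element"):
        stack.set_annotation(ann, arr.get_annotation(ann))
    stack.coord = traj.coords.astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# shift-table I/O
# ---------------------------------------------------------------------------


def _read_nmrstar_shift_rows(path: Path) -> pd.DataFrame:
    """Extract the Atom_chem_shift loop from an NMR-STAR v3 file.

    Minimal reader for the deposited-shift use case: finds the ``loop_``
    whose tags belong to the ``_Atom_chem_shift`` category and parses its
    whitespace-separated rows (quoted values handled) until ``stop_``.
    """
    text = path.read_text()
    lines = text.splitlines()
    i = 0
    n = len(lines)
    while i < n:
        if lines[i].strip() == "loop_":
            tags: list[str] = []
            j = i + 1
            while j < n and lines[j].strip().startswith("_"):
                tags.append(lines[j].strip())
                j += 1
            if tags and tags[0].startswith("_Atom_chem_shift."):
                columns = [t.split(".", 1)[1] for t in tags]
                rows: list[list[str]] = []
                while j < n:
                    s = lines[j].strip()
                    if s == "stop_":
                        break
                    if s and not s.startswith("#"):
                        rows.append(shlex.split(s))
                    j += 1
                df = pd.DataFrame(rows, columns=columns[: len(rows[0])] if rows else columns)
                return df
            i = j
        else:
            i += 1
    raise ValueError(f"no _Atom_chem_shift loop found in {path}")


def read_shift_table(
    path: str | Path,
    format: str | None = None,
    keep_atoms: Sequence[str] = DEFAULT_SHIFT_ATOMS,
    label: str = "",
) -> ShiftTable:
    """Read a chemical-shift table from CSV or NMR-STAR.

    Only atoms in ``keep_atoms`` (default H, N, C, CA, CB) are retained;
    rows with other atom names trigger a warning and are skipped.
    CSV columns: ``residue_number, residue_name, atom_name, shift``.
    """
    path = Path(path)
    if format is None:
        format = "nmrstar" if path.suffix.lower() in (".str", ".star") else "csv"
    if format == "csv":
        df = pd.read_csv(path)
        required = {"residue_number", "residue_name", "atom_name", "shift"}
        if not required.issubset(df.columns):
            raise ValueError(f"CSV shift table must have columns {sorted(required)}")
        accession = ""
    elif format == "nmrstar":
        raw = _read_nmrstar_shift_rows(path)
        res_col = "Comp_index_ID" if "Comp_index_ID" in raw.columns else "Seq_ID"
        df = pd.DataFrame(
            {
                "residue_number": raw[res_col].astype(int),
                "residue_name": raw["Comp_ID"],
                "atom_name": raw["Atom_ID"],
                "shift": raw["Val"].astype(float),
            }
        )
        accession = str(raw["Entry_ID"].iloc[0]) if "Entry_ID" in raw.columns and len(raw) else ""
    else:
        raise ValueError(f"unknown shift table format: {format!r}")

    keep = set(keep_atoms)
    unknown = sorted(set(df["atom_name"]) - keep)
    if unknown:
        warnings.warn(
            f"skipping {sum(df['atom_name'].isin(unknown))} shift rows with "
            f"atom names outside {sorted(keep)}: {unknown}",
            stacklevel=2,
        )
    df = df[df["atom_name"].isin(keep)].reset_index(drop=True)
    return ShiftTable(df, label=label, accession=accession)


def write_shift_table_csv(table: ShiftTable, path: str | Path) -> None:
    cols = ["residue_number", "residue_name", "atom_name", "shift"]
    table.entries[cols].to_csv(path, index=False)


def count_shifts(table: ShiftTable) -> int:
    """Number of retained shifts (one per (residue, atom) pair)."""
    return len(table.entries)


def count_assigned_residues(table: ShiftTable, require_all: bool = False) -> int:
    """Number of residues with assigned shifts.

    Two conventions: with ``require_all=False`` (default) a residue counts if
    it carries at least one retained shift; with ``require_all=True`` it must
    carry all five backbone shift types.
    """
    grouped = table.entries.groupby("residue_number")["atom_name"].agg(set)
    if require_all:
        full = set(DEFAULT_SHIFT_ATOMS)
        return int(sum(full <= s for s in grouped))
    return int(len(grouped))


# ---------------------------------------------------------------------------
# result bundles
# ---------------------------------------------------------------------------


def write_results(
    tables: Mapping[str, pd.DataFrame],
    path_prefix: str | Path,
    summaries: Mapping[str, Any] | None = None,
    timestamp: str | None = None,
) -> list[Path]:
    """Write result tables as TSV and summaries as JSON.

    Output is byte-deterministic for identical input; a timestamp is only
    included when explicitly passed, so reruns hash identically by default.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in tables.items():
        out = prefix.parent / f"{prefix.name}{name}.tsv"
        df.to_csv(out, sep="\t", index=False, float_format="%.6g")
        written.append(out)
    if summaries is not None:
        payload = dict(summaries)
        if timestamp is not None:
            payload["timestamp"] = timestamp
        out = prefix.parent / f"{prefix.name}summary.json"
        out.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n")
        written.append(out)
    return written


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_protrusion_table(path: str | Path) -> pd.DataFrame:
    """Read back a protrusion TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")
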