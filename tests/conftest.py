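import numpy as np
import pandas as pd
import pytest

from c3ensemble import synthetic
from c3ensemble.io import EnsembleTrajectory


@pytest.fixture(scope="session")
def rigid_trimer():
    """Latched, noise-free trimer: every loop tip exactly 16 A forward."""
    spec = synthetic.TrimerSpec(
        n_frames=10, loop_bias_mean=16.0, loop_bias_sd=0.0, latch_prob=1.0, seed=42
    )
    traj, truth = synthetic.generate_trimer_ensemble(spec)
    return traj, truth


@pytest.fixture(scope="session")
def wobbly_trimer():
    """Mixed-latch trimer with spread, for distributional tests."""
    spec = synthetic.TrimerSpec(
        n_frames=200, loop_bias_mean=14.0, loop_bias_sd=3.0, latch_prob=0.7, seed=7
    )
    return synthetic.generate_trimer_ensemble(spec)


@pytest.fixture()
def tiny_traj():
    """Hand-built 2-frame, 3-chain toy used by geometry/IO edge cases."""
    atoms = pd.DataFrame(
        {
            "monomer_id": ["A", "A", "B", "B", "C", "C"],
            "residue_number": [1, 2, 1, 2, 1, 2],
            "residue_name": ["GLY"] * 6,
            "atom_name": ["CA", "CB"] * 3,
        }
    )
    rng = np.random.default_rng(0)
    coords = rng.normal(size=(2, 6, 3)) * 5.0
    return EnsembleTrajectory(coords, atoms)


def synthetic_nmrstar(path, n_residues=10, extra_ha_rows=0):
    """Write a small synthetic NMR-STAR v3 file with an Atom_chem_shift loop.

    Synthetic stand-in for a deposited shift list; layout mirrors the
    Atom_chem_shift loop of real depositions.
    """
    rng = np.random.default_rng(1)
    lines = [
        "data_synthetic_entry",
        "",
        "save_assigned_chemical_shifts",
        "   _Assigned_chem_shift_list.Sf_category   assigned_chemical_shifts",
        "",
        "   loop_",
        "      _Atom_chem_shift.ID",
        "      _Atom_chem_shift.Comp_index_ID",
        "      _Atom_chem_shift.Comp_ID",
        "      _Atom_chem_shift.Atom_ID",
        "      _Atom_chem_shift.Val",
        "",
    ]
    i = 1
    atom_shifts = {"H": 8.3, "N": 119.0, "C": 176.0, "CA": 56.0, "CB": 33.0}
    for res in range(1, n_residues + 1):
        for atom, mu in atom_shifts.items():
            val = mu + rng.normal(0, 0.5)
            lines.append(f"      {i} {res} ALA {atom} {val:.3f}")
            i += 1
    for k in range(extra_ha_rows):
        lines.append(f"      {i} {k + 1} ALA HA {4.3 + 0.01 * k:.3f}")
        i += 1
    lines += ["   stop_", "save_", ""]
    path.write_text("\n".join(lines))
    return path
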