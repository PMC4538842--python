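import numpy as np
import pytest

import topotraj as tt


def write_pdb(path, records):
    """Write minimal ATOM records; each record is
    (serial, name, resname, chain, resnum, x, y, z, occ, altloc, element)."""
    lines = []
    for serial, name, resname, chain, resnum, x, y, z, occ, altloc, element in records:
        lines.append(
            f"ATOM  {serial:>5d} {name:<4s}{altloc:1s}{resname:<3s} {chain:1s}"
            f"{resnum:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00"
            f"          {element:>2s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def tiny_pdb(tmp_path):
    """One glycine with three atoms."""
    return write_pdb(
        tmp_path / "tiny.pdb",
        [
            (1, " N  ", "GLY", "A", 1, 0.0, 0.0, 0.0, 1.0, " ", "N"),
            (2, " CA ", "GLY", "A", 1, 1.45, 0.0, 0.0, 1.0, " ", "C"),
            (3, " C  ", "GLY", "A", 1, 2.0, 1.3, 0.0, 1.0, " ", "C"),
        ],
    )


@pytest.fixture
def straight_duplex():
    traj, pairing = tt.build_duplex(tt.DuplexRecipe.uniform(12))
    frames = tt.assign_base_frames(traj.coords[0], traj.topology, pairing)
    return traj, pairing, frames


def random_rigid_motion(rng):
    from scipy.spatial.transform import Rotation

    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return R, t


def pseudo_ca_topology(n_atoms):
    return tt.Topology.from_residue_table(
        [("P", "GLY", i + 1, tt.AMINO_ACID, [("CA", "C")]) for i in range(n_atoms)]
    )
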