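"""Data model and I/O for topology-bearing MD trajectories.

The containers here are deliberately small: a :class:`Topology` mapping
chains → residues → atoms, a :class:`Trajectory` holding per-frame
coordinates in Å, and a :class:`TimeSeries` for scalar per-frame
observables (distances, helical parameters, RMSD, dihedrals).  All
downstream analyses — religation geometry, helical-form transitions,
contact maps and correlated motions — are expressed in terms of these
three types plus selections.

Conventions: coordinates are in Å, time in ps, author (PDB) residue
numbering is preserved everywhere; the signed nucleotide labels used to
discuss the cleavage site (−1/+1 etc.) live only in
:class:`NucleotideLabelMap`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

AMINO_ACID = "amino-acid"
NUCLEOTIDE = "nucleotide"
OTHER = "other"

__all__ = [
    "AMINO_ACID",
    "NUCLEOTIDE",
    "OTHER",
    "Residue",
    "Topology",
    "Trajectory",
    "SelectionSpec",
    "NucleotideLabelMap",
    "TimeSeries",
    "load_structure",
    "load_trajectory",
    "write_trajectory",
    "pair_distance_series",
    "moving_average",
]


@dataclass(frozen=True)
class Residue:
    """One residue record with author-assigned numbering."""

    name: str
    number: int
    chain_id: str
    kind: str = OTHER
    icode: str = ""

    def __post_init__(self):
        if self.kind not in (AMINO_ACID, NUCLEOTIDE, OTHER):
            raise ValueError(f"unknown residue kind {self.kind!r}")


class Topology:
    """Chains, residues and atoms of one molecular system.

    Atoms are indexed contiguously from 0 and grouped by residue; every
    atom belongs to exactly one residue and every residue to exactly one
    chain, in file order.
    """

    def __init__(
        self,
        chain_ids: Sequence[str],
        residues: Sequence[Residue],
        atom_names: Sequence[str],
        atom_elements: Sequence[str],
        atom_residue: Sequence[int],
    ):
        self.chain_ids = list(chain_ids)
        self.residues = list(residues)
        self.atom_names = list(atom_names)
        self.atom_elements = [e.upper() for e in atom_elements]
        self.atom_residue = np.asarray(atom_residue, dtype=int)
        if not (len(self.atom_names) == len(self.atom_elements) == len(self.atom_residue)):
            raise ValueError("atom arrays must have equal length")
        if self.atom_residue.size and (
            self.atom_residue.min() < 0 or self.atom_residue.max() >= len(self.residues)
        ):
            raise ValueError("atom_residue indexes outside the residue list")
        # atoms of one residue must be stored contiguously
        if self.atom_residue.size and np.any(np.diff(self.atom_residue) < 0):
            raise ValueError("atoms must be grouped by residue in order")
        known = set(self.chain_ids)
        for r in self.residues:
            if r.chain_id not in known:
                raise ValueError(f"residue {r} references unknown chain {r.chain_id!r}")
        # residue -> atom index ranges
        self._res_start = np.searchsorted(self.atom_residue, np.arange(len(self.residues)))
        self._res_stop = np.searchsorted(
            self.atom_residue, np.arange(len(self.residues)), side="right"
        )

    # -- sizes ---------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    # -- lookups -------------------------------------------------------
    def residue_atoms(self, res_index: int) -> np.ndarray:
        """Atom indices of one residue, in storage order."""
        return np.arange(self._res_start[res_index], self._res_stop[res_index])

    def heavy_atoms(self, res_index: int) -> np.ndarray:
        idx = self.residue_atoms(res_index)
        return idx[[self.atom_elements[i] != "H" for i in idx]]

    def find_residue(self, chain_id: str, number: int, icode: str = "") -> int:
        for i, r in enumerate(self.residues):
            if r.chain_id == chain_id and r.number == number and r.icode == icode:
                return i
        raise KeyError(f"no residue {number}{icode} in chain {chain_id!r}")

    def find_atom(self, chain_id: str, number: int, atom_name: str) -> int:
        ri = self.find_residue(chain_id, number)
        for i in self.residue_atoms(ri):
            if self.atom_names[i] == atom_name:
                return int(i)
        raise KeyError(f"no atom {atom_name!r} in {chain_id}:{number}")

    def chain_residues(self, chain_id: str) -> list[int]:
        return [i for i, r in enumerate(self.residues) if r.chain_id == chain_id]

    # -- construction helper ------------------------------------------
    @classmethod
    def from_residue_table(
        cls,
        table: Iterable[tuple[str, str, int, str, Sequence[tuple[str, str]]]],
    ) -> "Topology":
        """Build a topology from ``(chain, resname, resnum, kind, atoms)`` rows,
        where ``atoms`` is a sequence of ``(atom_name, element)``."""
        chain_ids: list[str] = []
        residues: list[Residue] = []
        names: list[str] = []
        elements: list[str] = []
        owner: list[int] = []
        for chain_id, resname, resnum, kind, atoms in table:
            if chain_id not in chain_ids:
                chain_ids.append(chain_id)
            ri = len(residues)
            residues.append(Residue(resname, resnum, chain_id, kind))
            for aname, elem in atoms:
                names.append(aname)
                elements.append(elem)
                owner.append(ri)
        return cls(chain_ids, residues, names, elements, owner)


@dataclass
class Trajectory:
    """Ordered coordinate frames (Å) bound to a :class:`Topology`.

    ``frame_interval`` is the time between stored frames in ps.
    """

    topology: Topology
    coords: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame has {self.coords.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0 ps")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]


@dataclass(frozen=True)
class SelectionSpec:
    """Declarative atom selection resolving to an ordered index list.

    All fields combine conjunctively; ``None`` means "no constraint".
    ``resnums`` is either an inclusive ``(lo, hi)`` range or an explicit
    collection of author residue numbers.
    """

    chain: str | None = None
    resnums: tuple[int, int] | frozenset[int] | None = None
    atom_names: frozenset[str] | None = None
    kind: str | None = None

    @staticmethod
    def ca(chain: str | None = None) -> "SelectionSpec":
        """Protein Cα atoms."""
        return SelectionSpec(chain=chain, atom_names=frozenset({"CA"}), kind=AMINO_ACID)

    @staticmethod
    def c5prime(chain: str | None = None) -> "SelectionSpec":
        """DNA C5′ atoms."""
        return SelectionSpec(chain=chain, atom_names=frozenset({"C5'"}), kind=NUCLEOTIDE)

    def _match_residue(self, r: Residue) -> bool:
        if self.chain is not None and r.chain_id != self.chain:
            return False
        if self.kind is not None and r.kind != self.kind:
            return False
        if self.resnums is not None:
            if isinstance(self.resnums, tuple):
                lo, hi = self.resnums
                if not (lo <= r.number <= hi):
                    return False
            elif r.number not in self.resnums:
                return False
        return True

    def resolve(self, topology: Topology, require: bool = True) -> np.ndarray:
        """Ordered atom indices matching this selection.

        With ``require`` (default) an empty result raises, because every
        use site in the analyses needs at least one atom.
        """
        out: list[int] = []
        for ri, r in enumerate(topology.residues):
            if not self._match_residue(r):
                continue
            for ai in topology.residue_atoms(ri):
                if self.atom_names is not None and topology.atom_names[ai] not in self.atom_names:
                    continue
                out.append(int(ai))
        if require and not out:
            raise ValueError(f"selection {self} matched no atoms")
        return np.asarray(out, dtype=int)


class NucleotideLabelMap:
    """Bijection between author residue numbers and signed nucleotide labels.

    The gate-DNA nucleotides are discussed with signed labels counted
    away from the scissile phosphate: −10…−1 on the 5′ side and +1…+10
    on the 3′ side of each strand (0 is skipped).  The scissile step is
    the −1/+1 step: religation re-forms the O3′(−1)—P(+1) bond.
    """

    def __init__(self, strand_maps: dict[str, dict[int, int]]):
        if len(strand_maps) != 2:
            raise ValueError("both strands must be covered")
        self._by_label: dict[str, dict[int, int]] = {}
        self._by_resnum: dict[str, dict[int, int]] = {}
        for strand, mapping in strand_maps.items():
            if any(lbl == 0 for lbl in mapping):
                raise ValueError("labels skip 0")
            if len(set(mapping.values())) != len(mapping):
                raise ValueError(f"label map for strand {strand!r} is not bijective")
            self._by_label[strand] = dict(mapping)
            self._by_resnum[strand] = {v: k for k, v in mapping.items()}

    @property
    def strands(self) -> list[str]:
        return list(self._by_label)

    def resnum(self, strand: str, label: int) -> int:
        return self._by_label[strand][label]

    def label_of(self, strand: str, resnum: int) -> int:
        return self._by_resnum[strand][resnum]

    def labels(self, strand: str) -> list[int]:
        return sorted(self._by_label[strand])

    def scissile_pair(self, strand: str) -> tuple[int, int]:
        """Residue numbers of the −1 and +1 nucleotides of one strand."""
        return self.resnum(strand, -1), self.resnum(strand, +1)


@dataclass
class TimeSeries:
    """Scalar observable per frame with units and a time step in ps."""

    values: np.ndarray
    frame_interval: float = 1.0
    label: str = ""
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 1:
            raise ValueError("a TimeSeries holds at least one value")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0 ps")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.frame_interval

    def moving_average(self, window: int) -> "TimeSeries":
        return moving_average(self, window)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": np.arange(self.values.size), "time_ps": self.times, "value": self.values}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# structure / trajectory I/O
# ---------------------------------------------------------------------------


def _prescan_pdb(path: Path) -> None:
    """Fail early with a line number on malformed or duplicated records."""
    serials: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ValueError(f"{path}: unparseable coordinate record at line {lineno}")
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: unparseable coordinates at line {lineno}"
                ) from exc
            serial = line[6:11].strip()
            if serial in serials:
                raise ValueError(f"{path}: duplicate atom serial {serial} at line {lineno}")
            serials.add(serial)


def _residue_kind(resname: str) -> str:
    import gemmi

    info = gemmi.find_tabulated_residue(resname)
    if info is not None:
        if info.is_amino_acid():
            return AMINO_ACID
        if info.is_nucleic_acid():
            return NUCLEOTIDE
    return OTHER


def load_structure(
    path: str | Path, include_hetero: bool = False
) -> tuple[Topology, Trajectory]:
    """Read a PDB file into a topology plus a single-frame trajectory.

    Only the first model is used.  For atoms with alternate locations
    the highest-occupancy altloc is kept (ties go to the first
    encountered).  By default only polymer residues (amino acids and
    nucleotides) are retained; ``include_hetero`` keeps everything else
    (ligands, ions, water) as kind ``"other"``.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_pdb(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except Exception as exc:  # pragma: no cover - gemmi error text varies
        raise ValueError(f"{path}: PDB parse error: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models in file")
    model = st[0]

    chain_ids: list[str] = []
    residues: list[Residue] = []
    names: list[str] = []
    elements: list[str] = []
    owner: list[int] = []
    xyz: list[tuple[float, float, float]] = []
    for chain in model:
        for res in chain:
            kind = _residue_kind(res.name)
            if kind == OTHER and not include_hetero:
                continue
            # altloc: keep highest occupancy per atom name, tie -> first
            chosen: dict[str, "gemmi.Atom"] = {}
            for atom in res:
                prev = chosen.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    chosen[atom.name] = atom
            if not chosen:
                continue
            if chain.name not in chain_ids:
                chain_ids.append(chain.name)
            ri = len(residues)
            residues.append(
                Residue(res.name, res.seqid.num, chain.name, kind, (res.seqid.icode or "").strip())
            )
            for atom in res:  # preserve file order among the kept altlocs
                if chosen[atom.name] is not atom:
                    continue
                names.append(atom.name)
                elements.append(atom.element.name.upper())
                owner.append(ri)
                xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
    if not residues:
        raise ValueError(f"{path}: no polymer residues found")
    top = Topology(chain_ids, residues, names, elements, owner)
    traj = Trajectory(top, np.asarray(xyz, dtype=float)[None, :, :], frame_interval=1.0)
    return top, traj


def _read_xyz(path: Path) -> np.ndarray:
    frames: list[np.ndarray] = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"{path}: bad atom count at line {i + 1}") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path}: truncated frame starting at line {i + 1}")
        coords = np.array([row.split()[1:4] for row in block], dtype=float)
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return np.stack(frames)


def _write_xyz(traj: Trajectory, path: Path) -> None:
    top = traj.topology
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{top.n_atoms}\n")
            fh.write(f"frame {f} t={f * traj.frame_interval:.3f} ps\n")
            for a in range(top.n_atoms):
                x, y, z = traj.coords[f, a]
                fh.write(f"{top.atom_elements[a]:<2s} {x:15.8f} {y:15.8f} {z:15.8f}\n")


def load_trajectory(
    topology: Topology, path: str | Path, frame_interval: float = 1.0
) -> Trajectory:
    """Read a coordinate trajectory (``.dcd`` binary or multi-frame ``.xyz``).

    The file's atom count must equal the topology's.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".xyz":
        coords = _read_xyz(path)
    elif suffix == ".dcd":
        from mdtraj.formats import DCDTrajectoryFile

        with DCDTrajectoryFile(str(path)) as fh:
            coords, _, _ = fh.read()
        coords = np.asarray(coords, dtype=float)
    else:
        raise ValueError(f"unsupported trajectory format {suffix!r} (use .dcd or .xyz)")
    if coords.shape[1] != topology.n_atoms:
        raise ValueError(
            f"trajectory has {coords.shape[1]} atoms but topology has {topology.n_atoms}"
        )
    return Trajectory(topology, coords, frame_interval)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as ``.dcd`` or plain-text ``.xyz`` by suffix."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".xyz":
        _write_xyz(traj, path)
    elif suffix == ".dcd":
        from mdtraj.formats import DCDTrajectoryFile

        with DCDTrajectoryFile(str(path), "w") as fh:
            fh.write(traj.coords.astype(np.float32))
    else:
        raise ValueError(f"unsupported trajectory format {suffix!r} (use .dcd or .xyz)")


# ---------------------------------------------------------------------------
# per-frame observables
# ---------------------------------------------------------------------------


def pair_distance_series(traj: Trajectory, atom_a: int, atom_b: int) -> TimeSeries:
    """Euclidean distance between two atoms per frame, in Å."""
    if atom_a == atom_b:
        raise ValueError("atom_a and atom_b must differ")
    n = traj.topology.n_atoms
    for idx in (atom_a, atom_b):
        if not 0 <= idx < n:
            raise IndexError(f"atom index {idx} outside topology (n_atoms={n})")
    d = np.linalg.norm(traj.coords[:, atom_a] - traj.coords[:, atom_b], axis=1)
    return TimeSeries(d, traj.frame_interval, label=f"d({atom_a},{atom_b})", units="A")


def moving_average(series: TimeSeries, window: int) -> TimeSeries:
    """Trailing-window arithmetic mean; output length is n − window + 1."""
    if window < 1:
        raise ValueError("window must be ≥ 1")
    n = len(series)
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    kernel = np.ones(window) / window
    smoothed = np.convolve(series.values, kernel, mode="valid")
    return TimeSeries(
        smoothed,
        series.frame_interval,
        label=f"{series.label} (ma{window})" if series.label else f"ma{window}",
        units=series.units,
    )
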