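"""Protein-conformation probes: superposition RMSD, dimeric-arrangement
RMSD, pseudo-dihedrals and clustering-based reference selection.

The DNA-gate closure of the dimeric enzyme is followed with a handful
of geometric probes: the RMSD of one winged-helix domain (WHD) after
pre-aligning its counterpart (reporting on the dimeric arrangement
rather than internal deformation), the Cα pseudo-dihedral over the
Gln789/Glu777 pairs of the two protomers, and inter-protomer Cα
distances such as Ile872–Ile872 (plain ``pair_distance_series`` calls
parameterized by the domain annotation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation

from .core import AMINO_ACID, SelectionSpec, Topology, TimeSeries, Trajectory

__all__ = [
    "DomainAnnotation",
    "TOP2B_DOMAINS",
    "SuperpositionResult",
    "superpose",
    "interdomain_rmsd",
    "pseudo_dihedral",
    "cluster_reference",
]

# functional regions of the human topoisomerase IIβ cleavage core
# (author residue numbering, identical in both protomers)
TOP2B_DOMAINS: dict[str, tuple[int, int] | frozenset[int]] = {
    "linker": (659, 681),              # helix-bundle linker preceding WHD
    "intercalating": (870, 880),       # DNA-intercalating motif around Ile872
    "catalytic_tyr": frozenset({821}),
    "edxd": frozenset({477, 557, 559}),  # Mg2+-binding acidic triad of TOPRIM
    "rgkiln": (503, 508),              # DNA backbone-binding region
    "b_alpha4_start": frozenset({563}),
    "gln789": frozenset({789}),
    "glu777": frozenset({777}),
    "ile872": frozenset({872}),
}


@dataclass
class DomainAnnotation:
    """Named residue ranges shared by both protomers.

    ``domains`` maps a region name to an inclusive ``(lo, hi)`` author
    residue-number range or an explicit residue-number set; ``chains``
    names the two protomers.
    """

    chains: tuple[str, str]
    domains: dict[str, tuple[int, int] | frozenset[int]] = field(
        default_factory=lambda: dict(TOP2B_DOMAINS)
    )

    def selection(
        self, name: str, chain: str, atom_names: frozenset[str] = frozenset({"CA"})
    ) -> SelectionSpec:
        if chain not in self.chains:
            raise KeyError(f"chain {chain!r} is not an annotated protomer")
        rng = self.domains[name]
        resnums = rng if isinstance(rng, frozenset) else tuple(rng)
        return SelectionSpec(chain=chain, resnums=resnums, atom_names=atom_names, kind=AMINO_ACID)

    def probe_atom(self, topology: Topology, name: str, chain: str) -> int:
        """Cα atom index of a single-residue probe (e.g. Ile872)."""
        (idx,) = self.selection(name, chain).resolve(topology)
        return int(idx)


@dataclass
class SuperpositionResult:
    """Least-squares rigid fit: ``fitted = rotation @ mobile + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _resolve(selection, topology: Topology) -> np.ndarray:
    if isinstance(selection, SelectionSpec):
        return selection.resolve(topology)
    return np.asarray(selection, dtype=int)


def superpose(
    mobile: np.ndarray, reference: np.ndarray, selection: np.ndarray | None = None
) -> SuperpositionResult:
    """Optimal (Kabsch) rigid-body fit of ``mobile`` onto ``reference``.

    With ``selection`` the fit and the RMSD are computed over those
    atom indices of both coordinate sets.  The rotation is proper.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if selection is not None:
        selection = np.asarray(selection, dtype=int)
        mobile = mobile[selection]
        reference = reference[selection]
    if mobile.shape != reference.shape:
        raise ValueError(
            f"selected atom counts differ: {mobile.shape[0]} vs {reference.shape[0]}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atoms for a superposition")
    mob_mean = mobile.mean(axis=0)
    ref_mean = reference.mean(axis=0)
    mob_c = mobile - mob_mean
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise ValueError("selection is degenerate (collinear or coincident atoms)")
    rot, rssd = Rotation.align_vectors(reference - ref_mean, mob_c)
    R = rot.as_matrix()
    t = ref_mean - R @ mob_mean
    return SuperpositionResult(R, t, float(rssd / np.sqrt(n)), n)


def interdomain_rmsd(
    traj: Trajectory,
    reference: np.ndarray,
    prealign_selection,
    compare_selection,
) -> TimeSeries:
    """Dimeric-arrangement RMSD: pre-align one selection, compare another.

    Per frame, the frame is fitted to the reference on
    ``prealign_selection`` (e.g. the WHD of protomer A) and the RMSD is
    then evaluated over ``compare_selection`` (e.g. the WHD of protomer
    B) *without refitting*, so relative inter-domain motion is reported
    rather than internal deformation.
    """
    top = traj.topology
    pre = _resolve(prealign_selection, top)
    cmp_ = _resolve(compare_selection, top)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (top.n_atoms, 3):
        raise ValueError("reference must provide coordinates for the full topology")
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        fit = superpose(traj.coords[f], reference, pre)
        moved = fit.apply(traj.coords[f][cmp_])
        values[f] = float(np.sqrt(np.mean(np.sum((moved - reference[cmp_]) ** 2, axis=1))))
    return TimeSeries(values, traj.frame_interval, label="interdomain RMSD", units="A")


def pseudo_dihedral(traj: Trajectory, atoms: Sequence[int]) -> TimeSeries:
    """Signed torsion of four atoms per frame, degrees in (−180°, 180°].

    IUPAC sign convention: looking from the second atom toward the
    third, a clockwise rotation of the far bond is positive.  Frames
    with a collinear inner triple have no defined torsion and are
    reported as NaN (the single sanctioned missing-value case).
    """
    atoms = list(atoms)
    if len(atoms) != 4 or len(set(atoms)) != 4:
        raise ValueError("need four distinct atom indices")
    p = traj.coords[:, atoms, :]
    b1 = p[:, 1] - p[:, 0]
    b2 = p[:, 2] - p[:, 1]
    b3 = p[:, 3] - p[:, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    x = np.sum(n1 * n2, axis=1)
    y = np.sum(np.cross(n1, n2) * b2 / np.where(b2n > 0, b2n, 1.0)[:, None], axis=1)
    ang = np.degrees(np.arctan2(y, x))
    bad = (np.linalg.norm(n1, axis=1) < 1e-10) | (np.linalg.norm(n2, axis=1) < 1e-10)
    ang = np.where(bad, np.nan, ang)
    ang = np.where(np.isclose(ang, -180.0), 180.0, ang)
    return TimeSeries(ang, traj.frame_interval, label="pseudo-dihedral", units="deg")


def _pairwise_rmsd(coords: np.ndarray) -> np.ndarray:
    """All-pair RMSD of pre-aligned coordinate sets (T, n, 3)."""
    T = coords.shape[0]
    flat = coords.reshape(T, -1)
    d2 = (
        np.sum(flat**2, axis=1)[:, None]
        + np.sum(flat**2, axis=1)[None, :]
        - 2 * flat @ flat.T
    )
    d2 = np.clip(d2, 0.0, None) / coords.shape[1]
    return np.sqrt(d2)


def cluster_reference(
    traj: Trajectory, selection, min_fraction: float = 0.4
) -> int:
    """Reference-frame index by average-linkage clustering.

    All frames are superposed to frame 0 on the selection, pairwise
    RMSDs feed an average-linkage tree, and the tree is cut at the
    finest level whose most populated cluster still holds at least
    ``min_fraction`` of the frames (falling back to the top-level
    2-cluster split).  The medoid of the most populated cluster is
    returned; ties go to the cluster with the lower internal mean RMSD
    and then to the lower frame index.  Deterministic for fixed input.
    """
    top = traj.topology
    sel = _resolve(selection, top)
    T = traj.n_frames
    if T < 2:
        raise ValueError("need at least two frames to cluster")
    aligned = np.empty((T, sel.size, 3))
    ref = traj.coords[0]
    for f in range(T):
        fit = superpose(traj.coords[f], ref, sel)
        aligned[f] = fit.apply(traj.coords[f][sel])
    dm = _pairwise_rmsd(aligned)
    if np.allclose(dm, 0.0):
        return 0
    Z = linkage(squareform(dm, checks=False), method="average")
    chosen = fcluster(Z, 2, criterion="maxclust")
    for k in range(T, 1, -1):
        labels = fcluster(Z, k, criterion="maxclust")
        counts = np.bincount(labels)
        if counts.max() >= min_fraction * T:
            chosen = labels
            break
    counts = np.bincount(chosen)
    best_size = counts.max()
    candidates = [c for c in np.nonzero(counts == best_size)[0] if c > 0]

    def cluster_key(c: int) -> tuple[float, int]:
        members = np.nonzero(chosen == c)[0]
        sub = dm[np.ix_(members, members)]
        internal = float(sub.sum() / max(members.size * (members.size - 1), 1))
        return internal, int(members.min())

    winner = min(candidates, key=cluster_key)
    members = np.nonzero(chosen == winner)[0]
    sums = dm[np.ix_(members, members)].sum(axis=1)
    return int(members[int(np.argmin(sums))])
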