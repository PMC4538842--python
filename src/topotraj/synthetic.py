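"""Synthetic trajectory generators.

Each generator is the documented inverse (or statistical oracle) of
exactly one analysis operation, so the whole pipeline is exercisable
without any structure download:

* :func:`build_duplex` composes mid-step frame transforms that
  :func:`topotraj.nucleic.step_parameters` decomposes — a rebuilt duplex
  returns its step-parameter schedule exactly.
* :func:`build_bent_duplex` accumulates planar Roll so the total turn is
  a known bending angle.
* :func:`sample_correlated_ensemble` draws Gaussian frames with a
  prescribed covariance, the closed-form oracle for the generalized
  correlation coefficient.
* :func:`build_distance_schedule_fixture` places two residues so their
  minimum heavy-atom distance follows a prescribed per-frame schedule
  (oracle for religation-event counting and contact shells).
* :func:`random_walk_trajectory` produces the diffusive regime in which
  the cosine content of the first principal component approaches 1.

Fixtures are geometric, not physical: no force field, no solvent.
All randomness flows through explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import basegeom
from .core import AMINO_ACID, NUCLEOTIDE, Topology, Trajectory
from .nucleic import _FLIP, compose_step

__all__ = [
    "DuplexRecipe",
    "EnsembleRecipe",
    "build_duplex",
    "build_bent_duplex",
    "sample_correlated_ensemble",
    "isotropic_correlation_cov",
    "block_correlation_matrix",
    "build_distance_schedule_fixture",
    "random_walk_trajectory",
]


def _element_of(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


# ---------------------------------------------------------------------------
# duplex builders
# ---------------------------------------------------------------------------


@dataclass
class DuplexRecipe:
    """Prescription for a duplex: per-step helical parameters plus
    optional per-base-pair x-offsets.

    ``steps`` holds one dict of the six step parameters per step
    (missing keys default to 0, except ``rise`` which must be given and
    positive).  ``sequence`` is strand I read 5′→3′; strand II is the
    reverse complement.  ``x_offsets`` displaces each base-pair origin
    along its own x-axis (used to emulate the A-form axis displacement);
    note that non-uniform offsets feed back into the measured Slide.
    """

    n_bp: int
    steps: Sequence[dict[str, float]]
    sequence: str | None = None
    x_offsets: Sequence[float] | None = None
    labels: Sequence[str] | None = None

    def __post_init__(self):
        if self.n_bp < 2:
            raise ValueError("a duplex needs at least 2 base pairs")
        if len(self.steps) != self.n_bp - 1:
            raise ValueError(
                f"schedule has {len(self.steps)} steps but n_bp−1 = {self.n_bp - 1}"
            )
        for i, s in enumerate(self.steps):
            if s.get("rise", 0.0) <= 0:
                raise ValueError(f"step {i}: Rise must be > 0 for a stacked duplex")
        if self.sequence is None:
            self.sequence = ("GC" * self.n_bp)[: self.n_bp]
        if len(self.sequence) != self.n_bp:
            raise ValueError("sequence length must equal n_bp")
        for c in self.sequence:
            basegeom.base_code(c)
        if self.x_offsets is not None and len(self.x_offsets) != self.n_bp:
            raise ValueError("x_offsets must give one value per base pair")
        if self.labels is not None and len(self.labels) != self.n_bp:
            raise ValueError("labels must give one value per base pair")

    @staticmethod
    def uniform(
        n_bp: int,
        twist: float = 36.0,
        rise: float = 3.4,
        slide: float = 0.0,
        roll: float = 0.0,
        tilt: float = 0.0,
        shift: float = 0.0,
        **kwargs,
    ) -> "DuplexRecipe":
        step = {
            "shift": shift,
            "slide": slide,
            "rise": rise,
            "tilt": tilt,
            "roll": roll,
            "twist": twist,
        }
        return DuplexRecipe(n_bp, [dict(step) for _ in range(n_bp - 1)], **kwargs)


def build_duplex(recipe: DuplexRecipe) -> tuple[Trajectory, list[tuple[int, int]]]:
    """Single-frame duplex whose step parameters equal the recipe.

    Base-pair frames are generated by composing the mid-step transform
    for each scheduled step, starting from the identity frame at the
    origin; base atoms are then placed from the idealized reference
    geometry (complementary bases flipped about the pair x-axis).
    Returns the trajectory plus the strand-I/strand-II residue pairing
    list, ordered 5′→3′ along strand I.
    """
    n = recipe.n_bp
    R = np.eye(3)
    o = np.zeros(3)
    frames = [(R, o)]
    for step in recipe.steps:
        R, o = compose_step(R, o, step)
        frames.append((R, o))
    if recipe.x_offsets is not None:
        frames = [
            (R, o + off * R[:, 0]) for (R, o), off in zip(frames, recipe.x_offsets)
        ]

    codes_i = [basegeom.base_code(c) for c in recipe.sequence]
    codes_j = [basegeom.COMPLEMENT[c] for c in codes_i]

    rows = []
    coords: list[np.ndarray] = []
    # strand I, 5'→3'
    for k, code in enumerate(codes_i):
        names = basegeom.all_atom_names(code)
        rows.append(("I", "D" + code, k + 1, NUCLEOTIDE, [(a, _element_of(a)) for a in names]))
        Rk, ok = frames[k]
        coords.append(basegeom.all_coords(code) @ Rk.T + ok)
    # strand II in its own 5'→3' order = reverse pair order
    for m, k in enumerate(reversed(range(n))):
        code = codes_j[k]
        names = basegeom.all_atom_names(code)
        rows.append(("J", "D" + code, m + 1, NUCLEOTIDE, [(a, _element_of(a)) for a in names]))
        Rk, ok = frames[k]
        coords.append(basegeom.all_coords(code) @ (Rk @ _FLIP).T + ok)

    top = Topology.from_residue_table(rows)
    xyz = np.concatenate(coords, axis=0)[None, :, :]
    traj = Trajectory(top, xyz, frame_interval=1.0)
    pairing = [(k, n + (n - 1 - k)) for k in range(n)]
    return traj, pairing


def build_bent_duplex(
    total_bend: float, n_bp: int = 20, rise: float = 3.4
) -> tuple[Trajectory, list[tuple[int, int]]]:
    """Coplanar duplex bent by a prescribed total angle (degrees).

    The bend is built from uniform Roll increments summing to
    ``total_bend``, placed on the internal steps only (the first and
    last step stay straight, mimicking unbent terminal pairs), with
    zero Twist so all increments share one bending plane.  Measuring
    the bending angle over either the whole axis or the internal
    n_bp − 2 pairs therefore recovers ``total_bend``.
    """
    if not 0 <= total_bend <= 180:
        raise ValueError("total_bend must lie in [0°, 180°]")
    if n_bp < 4:
        raise ValueError("need at least 4 bp to hold internal bend steps")
    n_steps = n_bp - 1
    per_step = total_bend / (n_steps - 2)
    steps = []
    for i in range(n_steps):
        roll = per_step if 0 < i < n_steps - 1 else 0.0
        steps.append({"rise": rise, "twist": 0.0, "roll": roll})
    return build_duplex(DuplexRecipe(n_bp, steps))


# ---------------------------------------------------------------------------
# correlated Gaussian ensembles
# ---------------------------------------------------------------------------


def isotropic_correlation_cov(rho: np.ndarray, var: float = 1.0) -> np.ndarray:
    """3N×3N covariance with per-axis correlation ``rho[i, j]`` between
    atoms i and j and no cross-axis coupling (the closed-form model in
    which the generalized correlation coefficient equals |ρ|)."""
    rho = np.asarray(rho, dtype=float)
    n = rho.shape[0]
    if rho.shape != (n, n) or not np.allclose(rho, rho.T):
        raise ValueError("rho must be a symmetric square matrix")
    cov = np.zeros((3 * n, 3 * n))
    for axis in range(3):
        cov[axis::3, axis::3] = var * rho
    return cov


def block_correlation_matrix(
    n_atoms: int, groups: Sequence[Sequence[int]], rho_within: float, rho_between: float = 0.0
) -> np.ndarray:
    """Atom-level correlation matrix with planted correlated groups."""
    rho = np.full((n_atoms, n_atoms), rho_between, dtype=float)
    for g in groups:
        g = list(g)
        for i in g:
            for j in g:
                rho[i, j] = rho_within
    np.fill_diagonal(rho, 1.0)
    return rho


@dataclass
class EnsembleRecipe:
    """Prescription for a Gaussian conformational ensemble.

    ``covariance`` is the full 3N×3N target (must be positive
    semidefinite); ``kinds`` marks each pseudo-atom ``"protein"`` (a Cα
    stand-in) or ``"dna"`` (a C5′ stand-in) so selections and network
    partitions work on the result.  The seed is mandatory: identical
    recipes produce bit-identical trajectories.
    """

    n_atoms: int
    n_frames: int
    seed: int
    covariance: np.ndarray | None = None
    mean: np.ndarray | None = None
    kinds: Sequence[str] | None = None

    def __post_init__(self):
        if self.n_atoms < 1 or self.n_frames < 1:
            raise ValueError("n_atoms and n_frames must be ≥ 1")
        if self.covariance is None:
            self.covariance = np.eye(3 * self.n_atoms)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.covariance.shape != (3 * self.n_atoms, 3 * self.n_atoms):
            raise ValueError("covariance must be 3N×3N")
        if self.mean is None:
            self.mean = np.column_stack(
                [10.0 * np.arange(self.n_atoms), np.zeros(self.n_atoms), np.zeros(self.n_atoms)]
            )
        self.mean = np.asarray(self.mean, dtype=float).reshape(self.n_atoms, 3)
        if self.kinds is None:
            self.kinds = ["protein"] * self.n_atoms
        if len(self.kinds) != self.n_atoms:
            raise ValueError("kinds must give one entry per atom")


def _ensemble_topology(kinds: Sequence[str]) -> Topology:
    rows = []
    for i, kind in enumerate(kinds):
        if kind == "protein":
            rows.append(("P", "GLY", i + 1, AMINO_ACID, [("CA", "C")]))
        elif kind == "dna":
            rows.append(("D", "DA", i + 1, NUCLEOTIDE, [("C5'", "C")]))
        else:
            raise ValueError(f"unknown pseudo-atom kind {kind!r}")
    return Topology.from_residue_table(rows)


def sample_correlated_ensemble(recipe: EnsembleRecipe) -> Trajectory:
    """Frames drawn from N(mean, covariance) via a symmetric factor of
    the target covariance; raises if the target is not PSD."""
    cov = recipe.covariance
    w, V = np.linalg.eigh(0.5 * (cov + cov.T))
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ValueError(f"target covariance is not PSD (λmin = {w.min():.3g})")
    factor = V * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(recipe.seed)
    z = rng.standard_normal((recipe.n_frames, 3 * recipe.n_atoms))
    frames = z @ factor.T + recipe.mean.ravel()
    top = _ensemble_topology(recipe.kinds)
    return Trajectory(top, frames.reshape(recipe.n_frames, recipe.n_atoms, 3))


# ---------------------------------------------------------------------------
# distance schedules and random walks
# ---------------------------------------------------------------------------


def build_distance_schedule_fixture(
    schedule: Sequence[float],
    contact_atoms: tuple[str, str] = ("C", "P"),
    res_names: tuple[str, str] = ("GLY", "DA"),
    kinds: tuple[str, str] = (AMINO_ACID, NUCLEOTIDE),
    frame_interval: float = 1.0,
) -> Trajectory:
    """Two-residue trajectory whose minimum heavy-atom distance per
    frame equals the given schedule (Å).

    The first residue's contact atom sits at the origin with two
    padding atoms behind it (x < 0); the second residue's contact atom
    sits at ``(d, 0, 0)`` with padding beyond, so the closest pair is
    always the two named contact atoms.  This makes the generator the
    exact inverse of ``pair_distance_series`` and of the contact-shell
    measurement.
    """
    schedule = np.asarray(schedule, dtype=float)
    if schedule.size < 1:
        raise ValueError("schedule must be non-empty")
    if np.any(schedule <= 0):
        raise ValueError("schedule distances must be > 0 Å")
    name_a, name_b = contact_atoms
    atoms_a = [(name_a, _element_of(name_a)), ("CB1", "C"), ("CB2", "C")]
    atoms_b = [(name_b, _element_of(name_b)), ("CB1", "C"), ("CB2", "C")]
    top = Topology.from_residue_table(
        [
            ("A", res_names[0], 1, kinds[0], atoms_a),
            ("B", res_names[1], 1, kinds[1], atoms_b),
        ]
    )
    base_a = np.array([[0.0, 0.0, 0.0], [-1.3, 0.6, 0.0], [-1.1, -0.9, 0.4]])
    base_b = np.array([[0.0, 0.0, 0.0], [1.3, 0.6, 0.0], [1.1, -0.9, 0.4]])
    coords = np.empty((schedule.size, 6, 3))
    for f, d in enumerate(schedule):
        coords[f, :3] = base_a
        coords[f, 3:] = base_b + np.array([d, 0.0, 0.0])
    return Trajectory(top, coords, frame_interval)


def random_walk_trajectory(
    n_atoms: int, n_frames: int, step_sigma: float, seed: int
) -> Trajectory:
    """Independent Gaussian random walk per atom coordinate: the
    diffusive regime in which PC-1 projections look like half-period
    cosines (cosine content → 1, i.e. unconverged sampling)."""
    if n_frames < 10:
        raise ValueError("need at least 10 frames for a meaningful walk")
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n_frames, n_atoms, 3)) * step_sigma
    coords = np.cumsum(steps, axis=0)
    top = _ensemble_topology(["protein"] * n_atoms)
    return Trajectory(top, coords)
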