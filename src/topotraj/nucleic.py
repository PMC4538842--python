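"""Nucleic-acid conformation: base-pair frames, step parameters,
curvilinear helical axis, x-displacement, bending and A/B form.

The B→A transformation of the gate-DNA in the topoisomerase II cleavage
complex shows up most clearly in two descriptors: Slide (the
inter-base-pair shear along the long pair axis) and x-displacement (the
offset of each base pair from the curvilinear helical axis, along the
pair's major-groove direction).  Canonical fibre values are ≈ −1.5 Å /
−4.2 Å for A-DNA and ≈ 0 / 0 for B-DNA, so jointly they discriminate
the two forms and expose B–A–B partitions along the duplex.

Conventions.  Base frames follow the standard reference frame (origin
in the pair plane, x toward the major groove, y along the long pair
axis, z the stacking normal).  Step parameters use the symmetric
mid-step frame construction: both pair triads are rotated halfway about
their hinge axis, the twist is measured between the resulting y axes,
and the translation (Shift, Slide, Rise) is the origin displacement
expressed in the mid frame.  The builder in :mod:`topotraj.synthetic`
applies the exact inverse of this decomposition, which every round-trip
test relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import make_interp_spline, make_smoothing_spline
from scipy.spatial.transform import Rotation

from . import basegeom
from .core import Topology, Trajectory, TimeSeries

__all__ = [
    "BasePairFrame",
    "HelicalAxis",
    "FormThresholds",
    "FormClassification",
    "STEP_PARAMETERS",
    "assign_base_frames",
    "step_parameters",
    "fit_helical_axis",
    "x_displacement",
    "bending_angle",
    "classify_form",
    "parameter_series",
]

STEP_PARAMETERS = ("shift", "slide", "rise", "tilt", "roll", "twist")

# flip about the base x-axis: maps the complementary base's frame onto
# the pair frame orientation (y and z reverse)
_FLIP = np.diag([1.0, -1.0, -1.0])


# ---------------------------------------------------------------------------
# small rotation helpers
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalize a near-zero vector")
    return v / n


def _rot(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    return Rotation.from_rotvec(_unit(axis) * angle_rad).as_matrix()


def _signed_angle(a: np.ndarray, b: np.ndarray, about: np.ndarray) -> float:
    """Angle rotating ``a`` onto ``b`` about ``about`` (radians, signed)."""
    return float(np.arctan2(np.dot(about, np.cross(a, b)), np.dot(a, b)))


def _check_triad(triad: np.ndarray, tol: float = 1e-8) -> None:
    if not np.allclose(triad.T @ triad, np.eye(3), atol=tol):
        raise ValueError("base-pair triad is not orthonormal")
    if np.linalg.det(triad) < 0:
        raise ValueError("base-pair triad is left-handed")


@dataclass
class BasePairFrame:
    """Origin and orthonormal right-handed triad of one base pair.

    ``triad`` holds the unit axes as columns (x, y, z).
    """

    origin: np.ndarray
    triad: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.triad = np.asarray(self.triad, dtype=float).reshape(3, 3)
        _check_triad(self.triad)

    @property
    def x(self) -> np.ndarray:
        return self.triad[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.triad[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.triad[:, 2]


# ---------------------------------------------------------------------------
# base-frame assignment
# ---------------------------------------------------------------------------


def _fit_base_frame(
    obs: np.ndarray, ref: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid fit of reference base geometry onto observed
    ring atoms; returns ``(R, t)`` with ``obs ≈ R @ ref + t``."""
    obs_mean = obs.mean(axis=0)
    ref_mean = ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(obs - obs_mean, ref - ref_mean)
    R = rot.as_matrix()
    t = obs_mean - R @ ref_mean
    return R, t


def _residue_base_frame(
    coords: np.ndarray, topology: Topology, res_index: int
) -> tuple[np.ndarray, np.ndarray]:
    res = topology.residues[res_index]
    code = basegeom.base_code(res.name)
    names = basegeom.ring_atom_names(code)
    idx = []
    present = {topology.atom_names[a]: a for a in topology.residue_atoms(res_index)}
    for name in names:
        if name not in present:
            raise ValueError(
                f"residue {res.chain_id}:{res.number} ({res.name}) is missing "
                f"ring atom {name!r}"
            )
        idx.append(present[name])
    return _fit_base_frame(coords[idx], basegeom.ring_coords(code))


def assign_base_frames(
    frame_coords: np.ndarray,
    topology: Topology,
    pairing: Sequence[tuple[int, int]],
    labels: Sequence[str] | None = None,
) -> list[BasePairFrame]:
    """Base-pair frames for one coordinate frame.

    ``pairing`` lists residue-index pairs ``(strand-I residue,
    complementary residue)``, ordered 5′→3′ along strand I.  Each base
    frame is fitted from its ring atoms to the embedded idealized
    geometry; the complementary base's frame is flipped about its
    x-axis and the pair frame is the rotation average of the two, with
    the origin at the midpoint of the two base origins.
    """
    frame_coords = np.asarray(frame_coords, dtype=float)
    out: list[BasePairFrame] = []
    for k, (ri, rj) in enumerate(pairing):
        R1, t1 = _residue_base_frame(frame_coords, topology, ri)
        R2, t2 = _residue_base_frame(frame_coords, topology, rj)
        R2f = R2 @ _FLIP
        mean_rot = Rotation.from_matrix(np.stack([R1, R2f])).mean().as_matrix()
        origin = 0.5 * (t1 + t2)
        label = labels[k] if labels is not None else f"bp{k}"
        out.append(BasePairFrame(origin, mean_rot, label))
    return out


# ---------------------------------------------------------------------------
# step parameters (mid-step frame decomposition)
# ---------------------------------------------------------------------------


def _step_between(
    R1: np.ndarray, o1: np.ndarray, R2: np.ndarray, o2: np.ndarray
) -> tuple[dict[str, float], np.ndarray, np.ndarray]:
    """Six step parameters plus the mid-step frame ``(Rm, om)``."""
    z1, z2 = R1[:, 2], R2[:, 2]
    cross = np.cross(z1, z2)
    sin_g = np.linalg.norm(cross)
    gamma = float(np.arctan2(sin_g, np.clip(np.dot(z1, z2), -1.0, 1.0)))
    if sin_g < 1e-12:
        R1p, R2p = R1, R2
        hinge = None
    else:
        hinge = cross / sin_g
        R1p = _rot(hinge, +gamma / 2) @ R1
        R2p = _rot(hinge, -gamma / 2) @ R2
    zm = _unit(R1p[:, 2] + R2p[:, 2])
    twist = _signed_angle(R1p[:, 1], R2p[:, 1], zm)
    ym = _unit(R1p[:, 1] + R2p[:, 1])
    ym = _unit(ym - np.dot(ym, zm) * zm)
    xm = np.cross(ym, zm)
    Rm = np.column_stack([xm, ym, zm])
    om = 0.5 * (o1 + o2)
    shift, slide, rise = Rm.T @ (o2 - o1)
    if hinge is None:
        roll = tilt = 0.0
    else:
        phi = _signed_angle(hinge, ym, zm)
        roll = gamma * np.cos(phi)
        tilt = gamma * np.sin(phi)
    params = {
        "shift": float(shift),
        "slide": float(slide),
        "rise": float(rise),
        "tilt": float(np.degrees(tilt)),
        "roll": float(np.degrees(roll)),
        "twist": float(np.degrees(twist)),
    }
    return params, Rm, om


def compose_step(
    R1: np.ndarray, o1: np.ndarray, params: dict[str, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Exact inverse of the mid-step decomposition: the next pair frame
    from the previous one plus six step parameters (Å / degrees)."""
    tilt = np.radians(params.get("tilt", 0.0))
    roll = np.radians(params.get("roll", 0.0))
    twist = np.radians(params.get("twist", 0.0))
    gamma = float(np.hypot(roll, tilt))
    phi = float(np.arctan2(tilt, roll))
    zhat = np.array([0.0, 0.0, 1.0])
    h_loc = np.array([np.sin(phi), np.cos(phi), 0.0])
    half_bend = _rot(h_loc, gamma / 2) if gamma > 0 else np.eye(3)
    half_twist = _rot(zhat, twist / 2)
    # R1 = Rm @ half_bend.T @ half_twist.T  =>  Rm = R1 @ half_twist @ half_bend
    Rm = R1 @ half_twist @ half_bend
    R2 = Rm @ half_bend @ half_twist
    disp = np.array(
        [params.get("shift", 0.0), params.get("slide", 0.0), params.get("rise", 0.0)]
    )
    o2 = o1 + Rm @ disp
    return R2, o2


def step_parameters(bp_frames: Sequence[BasePairFrame]) -> pd.DataFrame:
    """Six step parameters for each consecutive base-pair step.

    Returns a DataFrame with one row per step (n_bp − 1 rows), columns
    ``shift, slide, rise`` (Å) and ``tilt, roll, twist`` (degrees),
    indexed by ``"<label_i>/<label_i+1>"``.
    """
    if len(bp_frames) < 2:
        raise ValueError("need at least two base-pair frames for a step")
    rows, index = [], []
    for a, b in zip(bp_frames[:-1], bp_frames[1:]):
        _check_triad(a.triad)
        _check_triad(b.triad)
        params, _, _ = _step_between(a.triad, a.origin, b.triad, b.origin)
        rows.append(params)
        index.append(f"{a.label}/{b.label}")
    return pd.DataFrame(rows, index=index, columns=list(STEP_PARAMETERS))


# ---------------------------------------------------------------------------
# curvilinear helical axis
# ---------------------------------------------------------------------------


@dataclass
class HelicalAxis:
    """Curvilinear helical axis: one point and unit tangent per base pair."""

    points: np.ndarray
    tangents: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.tangents = np.asarray(self.tangents, dtype=float)
        if self.points.shape != self.tangents.shape or self.points.ndim != 2:
            raise ValueError("points and tangents must both be (n_bp, 3)")
        norms = np.linalg.norm(self.tangents, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("tangents must be unit vectors")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def _step_screw_center(
    R1: np.ndarray, o1: np.ndarray, R2: np.ndarray, o2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Helical centre and axis direction of one step's screw transform.

    The rigid motion carrying pair frame i onto i+1 is a screw; for a
    predominantly helical step (screw axis within 60° of the stacking
    normal) its axis point, chosen level with the step midpoint, is the
    local helical centre the curvilinear axis is threaded through.  For
    a transverse screw — rotation dominated by bending, as in a
    twist-free rolled step, where the screw axis is the bending hinge —
    the step midpoint of the pair origins is used instead, so the axis
    follows the duplex rather than collapsing onto the bending centre.
    """
    Q = R2 @ R1.T
    d = o2 - Q @ o1
    rotvec = Rotation.from_matrix(Q).as_rotvec()
    angle = np.linalg.norm(rotvec)
    mid = 0.5 * (o1 + o2)
    zm = _unit(R1[:, 2] + R2[:, 2])

    def _translation_dir() -> np.ndarray:
        t = o2 - o1
        return _unit(t) if np.linalg.norm(t) > 1e-12 else zm

    if angle < 1e-8:
        # pure translation: axis along the displacement
        return mid, _translation_dir()
    u = rotvec / angle
    if np.dot(u, zm) < 0:
        u = -u
    if np.dot(u, zm) < 0.5:
        return mid, _translation_dir()
    d_perp = d - np.dot(d, u) * u
    p0, *_ = np.linalg.lstsq(np.eye(3) - Q, d_perp, rcond=None)
    # slide the axis point along u to sit level with the step midpoint
    return p0 + np.dot(mid - p0, u) * u, u


def fit_helical_axis(
    bp_frames: Sequence[BasePairFrame], smoothing: float = 0.0
) -> HelicalAxis:
    """Curvilinear axis through the per-step helical centres.

    A cubic spline (interpolating by default; ``smoothing`` > 0 selects
    a penalised smoothing spline for noisy per-frame data) is threaded
    through the screw-axis centres of consecutive steps, parameterised
    by step index, and evaluated at every base-pair position; tangents
    come from the analytic spline derivative.
    """
    n = len(bp_frames)
    if n < 3:
        raise ValueError("need at least three base pairs to fit an axis")
    centers, dirs = [], []
    for a, b in zip(bp_frames[:-1], bp_frames[1:]):
        c, u = _step_screw_center(a.triad, a.origin, b.triad, b.origin)
        centers.append(c)
        dirs.append(u)
    centers = np.asarray(centers)
    s_centers = np.arange(n - 1) + 0.5
    s_eval = np.arange(n, dtype=float)
    if len(centers) == 1:  # unreachable for n >= 3, kept for safety
        u = dirs[0]
        pts = centers[0] + np.outer(s_eval - s_centers[0], u)
        return HelicalAxis(pts, np.tile(u, (n, 1)))
    k = min(3, len(centers) - 1)
    if smoothing > 0 and len(centers) > 3:
        spl = make_smoothing_spline(s_centers, centers, lam=smoothing)
    else:
        spl = make_interp_spline(s_centers, centers, k=k)
    der = spl.derivative()
    pts = np.asarray(spl(s_eval), dtype=float)
    tans = np.asarray(der(s_eval), dtype=float)
    tans = tans / np.linalg.norm(tans, axis=1, keepdims=True)
    return HelicalAxis(pts, tans)


def x_displacement(
    bp_frames: Sequence[BasePairFrame], axis: HelicalAxis
) -> pd.DataFrame:
    """Signed offset of every base pair from the helical axis along its
    major-groove (x) direction, perpendicular to the local tangent.

    Returns a DataFrame with one ``xdisp`` column (Å), one row per bp.
    """
    if axis.n_points != len(bp_frames):
        raise ValueError("axis must come from the same base-pair list")
    rows, index = [], []
    for k, bp in enumerate(bp_frames):
        t = axis.tangents[k]
        d = bp.origin - axis.points[k]
        d_perp = d - np.dot(d, t) * t
        xeff = bp.x - np.dot(bp.x, t) * t
        nx = np.linalg.norm(xeff)
        xd = 0.0 if nx < 1e-8 else float(np.dot(d_perp, xeff / nx))
        rows.append(xd)
        index.append(bp.label)
    return pd.DataFrame({"xdisp": rows}, index=index)


def bending_angle(
    axis: HelicalAxis,
    bp_range: tuple[int, int] | None = None,
    end_window: int = 1,
) -> float:
    """Total bending angle of (part of) the helical axis, in degrees.

    The bend is the angle between the mean tangent of the first
    ``end_window`` base pairs and the mean tangent of the last
    ``end_window`` base pairs of the restricted axis; with the default
    window of 1 this is simply the angle between the terminal tangents,
    which recovers the full accumulated turn of a uniform arc.
    ``bp_range`` is an inclusive index pair, e.g. ``(1, n-2)`` for the
    internal n−2 base pairs.
    """
    if bp_range is None:
        lo, hi = 0, axis.n_points - 1
    else:
        lo, hi = bp_range
    if lo < 0 or hi >= axis.n_points or hi - lo + 1 < 3:
        raise ValueError(f"bp_range ({lo}, {hi}) invalid for axis of {axis.n_points} points")
    if end_window < 1 or 2 * end_window > hi - lo + 1:
        raise ValueError("end_window too large for the selected range")
    t1 = _unit(axis.tangents[lo : lo + end_window].mean(axis=0))
    t2 = _unit(axis.tangents[hi - end_window + 1 : hi + 1].mean(axis=0))
    ang = np.degrees(np.arctan2(np.linalg.norm(np.cross(t1, t2)), np.dot(t1, t2)))
    return float(ang)


# ---------------------------------------------------------------------------
# A/B form classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FormThresholds:
    """Slide / x-displacement cutoffs separating A- and B-form steps.

    Defaults interpolate between the canonical fibre values
    (A: Slide ≈ −1.5 Å, x-disp ≈ −4.2 Å; B: ≈ 0 / 0 Å): a step is A
    when both descriptors sit on the A side of the inner cutoffs, B
    when both sit on the B side, otherwise intermediate.
    """

    a_slide: float = -0.8
    a_xdisp: float = -1.8
    b_slide: float = -0.4
    b_xdisp: float = -1.0


@dataclass
class FormClassification:
    """Per-step A/B/intermediate labels plus contiguous-run segmentation.

    ``runs`` lists ``(label, start_step, end_step)`` with inclusive
    bounds, partitioning all steps.
    """

    labels: list[str]
    runs: list[tuple[str, int, int]]


def _runs_of(labels: Sequence[str]) -> list[tuple[str, int, int]]:
    runs: list[tuple[str, int, int]] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((labels[start], start, i - 1))
            start = i
    return runs


def classify_form(
    step_table: pd.DataFrame,
    axis_table: pd.DataFrame,
    thresholds: FormThresholds | None = None,
    min_run_length: int = 2,
) -> FormClassification:
    """Label each step A/B/intermediate from Slide and x-displacement.

    The per-step x-displacement is the mean of the two flanking base
    pairs' values.  Runs shorter than ``min_run_length`` are absorbed
    into the preceding run (the first run absorbs forward), so boundary
    ties resolve to the earlier run.
    """
    thr = thresholds or FormThresholds()
    slides = step_table["slide"].to_numpy()
    xd = axis_table["xdisp"].to_numpy()
    if len(xd) != len(slides) + 1:
        raise ValueError("axis table must cover one more base pair than steps")
    step_xd = 0.5 * (xd[:-1] + xd[1:])
    labels = []
    for s, x in zip(slides, step_xd):
        if s <= thr.a_slide and x <= thr.a_xdisp:
            labels.append("A")
        elif s >= thr.b_slide and x >= thr.b_xdisp:
            labels.append("B")
        else:
            labels.append("intermediate")
    runs = _runs_of(labels)
    while len(runs) > 1:
        lengths = [end - start + 1 for _, start, end in runs]
        short = next((i for i, L in enumerate(lengths) if L < min_run_length), None)
        if short is None:
            break
        absorb = short - 1 if short > 0 else 1
        lab = runs[absorb][0]
        _, s0, e0 = runs[short]
        for j in range(s0, e0 + 1):
            labels[j] = lab
        runs = _runs_of(labels)
    return FormClassification(labels, runs)


# ---------------------------------------------------------------------------
# per-frame parameter time series
# ---------------------------------------------------------------------------


def parameter_series(
    traj: Trajectory,
    pairing: Sequence[tuple[int, int]],
    which: str,
    locus: int | str,
    labels: Sequence[str] | None = None,
) -> TimeSeries:
    """Time series of one helical parameter at one step or base pair.

    ``which`` is a step parameter name or ``"xdisp"``; ``locus`` is a
    step/bp index or, when ``labels`` is given, a label such as
    ``"+3/+4"`` (step) or ``"+3"`` (base pair).
    """
    which = which.lower()
    if which not in STEP_PARAMETERS and which != "xdisp":
        raise ValueError(f"unknown parameter {which!r}")
    values = []
    for f in range(traj.n_frames):
        frames = assign_base_frames(traj.coords[f], traj.topology, pairing, labels)
        if which == "xdisp":
            axis = fit_helical_axis(frames)
            table = x_displacement(frames, axis)
        else:
            table = step_parameters(frames)
        if isinstance(locus, str):
            if locus not in table.index:
                raise KeyError(f"locus {locus!r} not in {list(table.index)}")
            row = table.loc[locus]
        else:
            if not 0 <= locus < len(table):
                raise IndexError(f"locus {locus} outside table of {len(table)} rows")
            row = table.iloc[locus]
        values.append(float(row[which] if which != "xdisp" else row["xdisp"]))
    units = "A" if which in ("shift", "slide", "rise", "xdisp") else "deg"
    return TimeSeries(
        np.asarray(values), traj.frame_interval, label=f"{which}@{locus}", units=units
    )
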