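"""Scissile-site geometry and strand-asymmetry statistics.

Type II topoisomerases cleave both strands of the gate-DNA, leaving the
catalytic tyrosine bonded to each 5′ terminus.  Religation re-forms the
O3′(−1)—P(+1) phosphodiester bond, which is geometrically feasible once
the two atoms approach ≈3 Å (the reference distance adopted here, the
O—P separation at which nucleophilic attack has been modelled
successfully).  This module measures that distance per frame, counts
religation-compliant excursions against the reference, and tests
whether the two strands approach asymmetrically with an unbalanced
two-way ANOVA (strand group × trajectory).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import NucleotideLabelMap, TimeSeries, Topology, Trajectory, pair_distance_series

__all__ = [
    "ScissileSite",
    "ReligationCriterion",
    "ReligationSummary",
    "AnovaTable",
    "scissile_distance_series",
    "religation_events",
    "assign_strand_groups",
    "strand_asymmetry_anova",
]


@dataclass(frozen=True)
class ScissileSite:
    """O3′ of the −1 nucleotide and P of the +1 nucleotide of one strand."""

    strand: str
    o3_atom: int
    p_atom: int

    @classmethod
    def from_labels(
        cls, topology: Topology, labels: NucleotideLabelMap, strand: str
    ) -> "ScissileSite":
        """Resolve the scissile pair through the signed nucleotide labels."""
        res_m1, res_p1 = labels.scissile_pair(strand)
        try:
            o3 = topology.find_atom(strand, res_m1, "O3'")
        except KeyError as exc:
            raise ValueError(
                f"cannot resolve O3' of nucleotide −1 (residue {res_m1}) on strand "
                f"{strand!r}: {exc}"
            ) from exc
        try:
            p = topology.find_atom(strand, res_p1, "P")
        except KeyError as exc:
            raise ValueError(
                f"cannot resolve P of nucleotide +1 (residue {res_p1}) on strand "
                f"{strand!r}: {exc}"
            ) from exc
        return cls(strand, o3, p)


@dataclass(frozen=True)
class ReligationCriterion:
    """Religation-compliant reference distance in Å (default 3.0)."""

    reference_distance: float = 3.0

    def __post_init__(self):
        if self.reference_distance <= 0:
            raise ValueError("reference distance must be > 0 Å")


@dataclass
class ReligationSummary:
    """Accounting of religation-compliant frames in one distance series."""

    n_frames_below: int
    fraction_below: float
    min_distance: float
    first_crossing_frame: int | None
    n_crossings: int


def scissile_distance_series(traj: Trajectory, site: ScissileSite) -> TimeSeries:
    """O3′(−1)—P(+1) distance per frame for one strand, in Å."""
    n = traj.topology.n_atoms
    for name, idx in (("O3'(-1)", site.o3_atom), ("P(+1)", site.p_atom)):
        if not 0 <= idx < n:
            raise ValueError(f"scissile atom {name} (index {idx}) is missing from the topology")
    series = pair_distance_series(traj, site.o3_atom, site.p_atom)
    series.label = f"O3'(-1)-P(+1) strand {site.strand}"
    return series


def religation_events(
    series: TimeSeries, criterion: ReligationCriterion | None = None
) -> ReligationSummary:
    """Count frames at or below the religation reference distance.

    A "crossing" is an entry into the compliant region (a run of frames
    ≤ reference counts once; a series that starts compliant counts its
    initial run).
    """
    crit = criterion or ReligationCriterion()
    below = series.values <= crit.reference_distance
    n_below = int(below.sum())
    first = int(np.argmax(below)) if n_below else None
    entries = np.diff(np.concatenate([[False], below]).astype(int)) == 1
    return ReligationSummary(
        n_frames_below=n_below,
        fraction_below=n_below / len(series),
        min_distance=float(series.values.min()),
        first_crossing_frame=first,
        n_crossings=int(entries.sum()),
    )


def assign_strand_groups(
    per_trajectory: Mapping[str, Mapping[str, TimeSeries | np.ndarray]],
) -> list[tuple[str, str, np.ndarray]]:
    """Per-trajectory strand grouping by mean scissile distance.

    For each trajectory the strand with the smaller average distance is
    assigned to the ``"smaller"`` group and the other to ``"larger"``;
    exact ties are broken by strand id (lexicographically first →
    smaller).  Returns observation tuples ready for
    :func:`strand_asymmetry_anova`.
    """
    out: list[tuple[str, str, np.ndarray]] = []
    for traj_id, strands in per_trajectory.items():
        if len(strands) != 2:
            raise ValueError(f"trajectory {traj_id!r} must provide exactly two strands")
        items = []
        for strand_id in sorted(strands):
            v = strands[strand_id]
            values = v.values if isinstance(v, TimeSeries) else np.asarray(v, dtype=float)
            items.append((float(values.mean()), strand_id, values))
        items.sort(key=lambda t: (t[0], t[1]))
        out.append((traj_id, "smaller", items[0][2]))
        out.append((traj_id, "larger", items[1][2]))
    return out


@dataclass
class AnovaTable:
    """Two-way main-effects ANOVA with Type-II sums of squares.

    ``table`` has rows ``strand_group``, ``trajectory`` and
    ``residual`` with columns ``sum_sq``, ``df``, ``F`` and ``p``.  The
    significance gate follows the analysis convention of p < 0.001.
    """

    table: pd.DataFrame
    alpha: float = 0.001

    def significant(self, factor: str) -> bool:
        return bool(self.table.loc[factor, "p"] < self.alpha)


def strand_asymmetry_anova(
    observations: Iterable[tuple[str, str, Sequence[float]]],
    stride: int = 1,
) -> AnovaTable:
    """Unbalanced two-way fixed-effects ANOVA on pooled distances.

    ``observations`` are ``(trajectory_id, strand_group, values)``
    tuples; groups are typically the per-trajectory smaller/larger-mean
    strands from :func:`assign_strand_groups`.  Main effects only,
    Type-II sums of squares.  Observations are individual frames with
    no autocorrelation correction; ``stride`` optionally subsamples
    each series to thin serial dependence.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if stride < 1:
        raise ValueError("stride must be ≥ 1")
    rows = []
    for traj_id, group, values in observations:
        for v in np.asarray(values, dtype=float).ravel()[::stride]:
            rows.append({"trajectory": str(traj_id), "group": str(group), "value": v})
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no observations supplied")
    for factor in ("trajectory", "group"):
        if df[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} has a single level")
    fit = smf.ols("value ~ C(group) + C(trajectory)", data=df).fit()
    raw = sm.stats.anova_lm(fit, typ=2)
    total_ss = float(((df["value"] - df["value"].mean()) ** 2).sum())
    out = pd.DataFrame(
        {
            "sum_sq": [
                raw.loc["C(group)", "sum_sq"],
                raw.loc["C(trajectory)", "sum_sq"],
                raw.loc["Residual", "sum_sq"],
            ],
            "df": [
                raw.loc["C(group)", "df"],
                raw.loc["C(trajectory)", "df"],
                raw.loc["Residual", "df"],
            ],
            "F": [raw.loc["C(group)", "F"], raw.loc["C(trajectory)", "F"], np.nan],
            "p": [
                raw.loc["C(group)", "PR(>F)"],
                raw.loc["C(trajectory)", "PR(>F)"],
                np.nan,
            ],
        },
        index=["strand_group", "trajectory", "residual"],
    )
    # a factor explaining nothing is reported as F = 0, p = 1 even when
    # the residual variance is also zero (degenerate constant data)
    for factor in ("strand_group", "trajectory"):
        if out.loc[factor, "sum_sq"] <= 1e-12 * max(total_ss, 1.0):
            out.loc[factor, ["F", "p"]] = [0.0, 1.0]
    return AnovaTable(out)
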