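# Methods

This note documents the models and conventions implemented in
`topotraj`, the defaults that matter, the design choices made where the
design was genuinely open, and what the synthetic generators do and do
not emulate.

## Data model

Coordinates are in Å and time in ps throughout.  Author (PDB) residue
numbering is preserved everywhere; the signed nucleotide labels used
around the cleavage site (−10…−1, +1…+10 per strand, skipping 0) live
only in `NucleotideLabelMap`, which keeps the bijection explicit and
avoids silent renumbering.  Structures are read from PDB via gemmi:
only the first model is used, the highest-occupancy alternate location
is kept per atom (ties to the first encountered), hydrogens are
retained if present, and non-polymer residues (water, ions, ligands)
are dropped unless requested — distance-based analyses then operate on
heavy atoms.  Trajectories are read/written as DCD (binary, via
mdtraj's raw DCD reader) or as plain multi-frame XYZ so that fixtures
stay human-writable.  Frames are assumed pre-imaged; no periodic-box
handling is performed, as the analyses concern a solute.

## Religation geometry

The religation-compliant reference distance defaults to 3.0 Å — the
O3′(−1)—P(+1) separation at which phosphodiester re-formation is
geometrically feasible (nucleophilic-attack geometries modelled in the
3.1–3.5 Å range motivate the round value; it is a parameter of
`ReligationCriterion`).  `religation_events` counts frames at or below
the reference, the minimum approach, the first compliant frame and the
number of distinct compliant excursions.

Strand asymmetry uses a two-way fixed-effects ANOVA with main effects
only.  For each trajectory the strand with the smaller mean distance is
assigned to one group (ties broken by strand id, which makes the
grouping deterministic), the trajectory index is the second factor, and
the design is unbalanced because trajectories differ in length.  The
paper-style analysis names no sum-of-squares type; Type-II is used
because it is the standard choice for unbalanced main-effects models
and reduces to the classical decomposition when the design is balanced.
Observations are individual frames with no autocorrelation correction;
a `stride` parameter thins the series when serial dependence is a
concern.  Significance is gated at p < 0.001.  Degenerate all-constant
input (zero factor SS and zero residual SS) is reported as F = 0,
p = 1 rather than NaN.

## Nucleic-acid conformation

**Base frames.**  Each base carries an embedded idealized geometry in
the standard nucleic-acid reference frame (origin in the pair plane,
x toward the major groove, y along the long pair axis, z the stacking
normal).  The observed ring atoms are fitted to this geometry by a
least-squares rigid fit; the complementary base's frame is flipped
about its x-axis and the pair frame is the quaternion average of the
two rotations with the origin at the midpoint.  Builder and analyzer
share the same embedded table, which makes them exact inverses.

**Step parameters.**  The symmetric mid-step construction: the two pair
triads are rotated halfway toward each other about the hinge
(z₁ × z₂), Twist is the signed angle between the resulting y axes, the
mid frame is the bisector frame, (Shift, Slide, Rise) is the origin
displacement expressed in the mid frame, and (Tilt, Roll) decompose the
bending angle by the hinge phase.  The builder applies the exact
algebraic inverse, so rebuild→measure round trips recover arbitrary
physical schedules to 1e−6 (tested over |Slide| ≤ 3 Å,
Twist ∈ [20°, 45°], Rise ∈ [2.5, 4] Å).  This is the standard mid-step
convention, not a re-implementation of any particular program's
internals; agreement with other tools is expected at the ~0.1 Å / few
degree level.

**Curvilinear axis.**  Each step's rigid motion is decomposed as a
screw; for predominantly helical steps (screw axis within 60° of the
stacking normal) the axis point level with the step midpoint is the
local helical centre.  When the screw is transverse — rotation
dominated by bending, as in a twist-free rolled step whose screw axis
is the bending hinge — the step midpoint of the pair origins is used
instead, so the axis follows the duplex rather than collapsing onto
the bending centre.  A cubic spline (interpolating by default; a
`smoothing` parameter enables the penalised variant for noisy
per-frame data) is threaded through the centres and evaluated at every
base-pair position; tangents come from the analytic derivative.

**x-displacement** is the signed component of (pair origin − axis
point) along the pair's x-axis, both projected perpendicular to the
local tangent.  It is invariant under global rigid motion and recovers
constructed offsets to ±0.05 Å on interior pairs.

**Bending angle** is the angle between the mean tangents of the two
terminal segments of the (optionally restricted) axis.  The end window
defaults to a single base pair — i.e. the terminal tangents — because
a wider window systematically under-reports a uniform arc by about one
step's turn per end (≈5° on a 140° bend over 28 bp); `end_window` is
exposed for noisy data where averaging is preferable.

**Form classification.**  The analysis gives no A/B thresholds, so the
defaults interpolate between the canonical fibre values (A: Slide
≈ −1.5 Å, x-disp ≈ −4.2 Å; B: ≈ 0/0): a step is A when
Slide ≤ −0.8 Å *and* x-disp ≤ −1.8 Å, B when Slide ≥ −0.4 Å *and*
x-disp ≥ −1.0 Å, otherwise intermediate.  Per-step x-disp is the mean
of the flanking pairs.  Runs shorter than the minimum run length
(default 2) are absorbed into the preceding run, so boundary ties
resolve to the earlier compartment.  All constants sit in
`FormThresholds`.

The cleaved duplex is treated as geometrically paired throughout: the
−1/+1 step exists even when the backbone is cut, so its parameters are
computed from the flanking pair frames like any other step.

## Protein conformation

Superposition is the proper-rotation least-squares (Kabsch) fit;
selections need ≥3 non-collinear atoms.  The dimeric-arrangement probe
fits one selection (e.g. the winged-helix domain of protomer A) and
evaluates RMSD over another (the WHD of protomer B) *without*
refitting, so it reports relative inter-domain motion, not internal
deformation.  Pseudo-dihedrals follow the IUPAC sign convention and
agree numerically with mdtraj; a collinear inner triple has no defined
torsion and yields NaN for that frame — the one sanctioned missing
value in a `TimeSeries`.

The "well-folded" fitting mask is user-supplied residue ranges (no
secondary-structure assignment dependency), which keeps runs
reproducible.  Reference-frame selection superposes all frames to
frame 0 on the selection, builds an average-linkage tree on pairwise
RMSD, and cuts it at the finest level whose most populated cluster
still holds ≥40% of frames (a plain 2-cluster cut would trivially
always satisfy the fraction, so the finest qualifying cut is used to
get tight clusters); the medoid of the most populated cluster is
returned, with ties broken by lower within-cluster mean RMSD and then
lower frame index.  `TOP2B_DOMAINS` records the functional regions of
the human topoisomerase IIβ cleavage core (linker 659–681,
intercalating motif 870–880, catalytic Tyr821, the E•DxD metal-binding
triad 477/557/559, the RGKILN region 503–508, helix B′α4 start 563 and
the Gln789/Glu777/Ile872 probes) for both protomers.

## Contacts

The residue–nucleotide distance is the minimum heavy-atom–heavy-atom
distance (hydrogens excluded by default because crystal-derived inputs
lack them; a flag includes them).  f₃.₅ and f₅.₀ are frame fractions
within 3.5 Å and 5.0 Å; f₅.₀ is cumulative — only then does an
inner-shell frame score (2/3) + (1/3) = 1 as the weighting requires.
Cutoffs and weights are configurable (`ShellConfig`) and an optional
frame range mirrors production-window analyses.  A residue pair is
in-cis when the residue's protomer is the one whose catalytic tyrosine
is covalently bonded to the strand at hand, in-trans otherwise.

## Correlated motions

Covariance PCA uses the coordinates exactly as stored (*nofit*) by
default, on the assumption that rigid-body motion was removed upstream
by the reference alignment; a fit selection is available.  Cosine
content is computed with midpoint time sampling, which makes the
definitional limits exact in the discrete setting (an exact
half-period cosine scores 1, a constant scores 0).  A run is reported
"adequately sampled" when c₁ ≤ 0.5 — the diffusive regime produces
c₁ near 1, and 0.5 is this package's documented gate for
"sufficiently small".

Mutual information is the Gaussian ("linear") estimator
I = ½ ln(det C_X · det C_Y / det C_XY) on 3-D displacement variables
(d is a parameter, default 3); the nonparametric k-NN estimator is out
of scope.  Each covariance receives a tiny ridge
(1e−10 · trace/dim on the diagonal) before the determinant, and the
exact finite-sample expectation of each log-determinant is subtracted
(a Bartlett-type digamma correction, on by default).  Without the
correction the plug-in estimator has an O(d²/n) positive bias that
reports spurious r ≈ 0.02–0.03 for independent atoms even at 5000
frames; with it, independent pairs land at 0 up to sampling noise and
the closed-form identity r = |ρ| for isotropic per-axis Gaussian
correlation is recovered within 0.03 at n = 5000.  Negative corrected
MI (sampling noise) is clamped to 0; r values within 1e−12 of unity
report exactly 1.  Networks keep edges with r ≥ threshold (0.7 and 0.8
are the conventional choices), report protein–DNA edge counts and
named domain-pair counts, and are monotone in the threshold by
construction.

## Synthetic generators

Every generator is the documented inverse or statistical oracle of one
analysis: duplexes from step schedules (exact inverse of the step
decomposition), planar bent duplexes (roll increments summing to the
target angle placed on the internal steps only, with straight terminal
steps, so both full-axis and internal-window measurements recover the
constructed bend), Gaussian ensembles from a prescribed PSD covariance
(closed-form oracle for generalized correlation), two-residue distance
schedules (inverse of the distance and contact-shell measurements),
and Gaussian random walks (the diffusive cosine-content regime).
Fixtures are geometric, not physical: no force field, no solvent, no
sequence-dependent energetics, minimal residues where only distances
matter.  Passing tests therefore demonstrate the correctness of the
measurement machinery and statistics, not force-field realism; real
trajectories add noise, autocorrelation and conformational
heterogeneity that the generators deliberately omit.  All randomness
flows through explicit integer seeds; identical recipe + seed is
bit-identical.

## Problem sizes and determinism

The test and acceptance workloads are desk-scale by design: duplexes of
2–30 bp, ensembles of 2–20 pseudo-atoms over 10³–10⁴ frames, 100-seed
replicate sweeps.  Statistical recovery tests (generalized correlation,
ANOVA power, cosine-content flagging) use fixed seeds and tolerances
derived from their closed-form oracles.

## Known limitations

* Step parameters follow the standard mid-step convention; programs
  with different axis definitions will differ at the ~0.1 Å / few
  degree level, and curvilinear bends carry a few degrees of
  convention tolerance.
* The transverse-screw fallback in the axis construction switches
  definitions at a 60° threshold; duplexes with steps near that
  boundary (comparable twist and roll magnitudes) get a mixed axis.
* The Gaussian MI estimator only captures linear dependence; strongly
  non-Gaussian coupled motions are under-reported.
* No groove geometry, backbone torsions, sugar puckers, hydrogen-bond
  criteria or buried-surface areas; no free-energy or reaction
  modelling.
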