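# Methods

## Data model and kinematics

The empirical input is a per-frame table of tracked individuals (`frame,
id, x, y, vx, vy`) at a known frame rate inside a rectangular tank.  Units
are centimetres and seconds; frame indices are 0-based and the time of
frame *f* is *f*/fps.  Headings are the unit velocity vectors.  A fish
whose speed falls below a floor (default 1e-6 cm/s, a machine-noise guard
only) keeps its most recent valid heading; a fish that has never moved has
no heading and is excluded from order-parameter sums for that frame.  The
carry-forward rule keeps the effective group size stable through brief
stalls; exclusion would be the plausible alternative and is obtained by
setting the floor to zero and filtering on `valid`.

Missing fish are simply absent — identities need not persist, and every
per-frame statistic normalises by the individuals actually present.  Rows
with non-finite fields are dropped at load time and counted in the load
report.

## Order parameters and smoothing

Polarization is the norm of the mean unit heading; rotation is the norm of
the mean normalised angular momentum about the group's centre of mass
(unweighted mean position of all recorded fish; fish exactly at the centre
contribute zero but still count in *N*).  Positive signed rotation is
counter-clockwise.  Both series are smoothed with a centred moving average
of 30 frames (1 s at 30 fps) before classification.  Two numerical
choices:

* the centred window needs an odd span, so an even request widens by one
  frame; at the series edges the window truncates *symmetrically* so no
  phase shift is introduced;
* the rotation magnitude is smoothed from its own magnitude series rather
  than taken as the absolute smoothed signed series, so a brief handedness
  flip inside a mill does not masquerade as a drop in rotational order.
  The signed series is smoothed separately for handedness statistics.

Local polarization restricts the sum to a disc around a focal fish,
default radius 15.6 cm (about three body lengths at the 5.2 cm golden-
shiner body length; the radius is configurable and 1–3 BL variants are
supported).  The radial decomposition of the mill uses six concentric
shells about the group centre; the outer radius *R* is the median
centre-distance of the five most peripheral fish, each shell is *R*/6 wide
and the outermost shell also absorbs fish beyond *R*.  Shell rotation uses
the full-group centre (there is only one physically meaningful centre);
window averages are occupancy-weighted.

## State machine

With threshold *k* = 0.35 (configurable, 0 < *k* < 0.5 keeps the regions
disjoint): polarized iff O_p > 1−k and O_r < k; milling iff O_p < k and
O_r > 1−k; swarm iff both < k; everything else — including exact
threshold values, since the inequalities are strict — is the transition
band.  A *completed transition* is a change of state among S/P/M
regardless of intervening transition-band frames; an excursion into T that
returns to its source state is not a transition.  A direct frame-to-frame
state change without any T frame (possible after smoothing) counts.

Frames with undefined order parameters are gaps.  Gaps of at most 1 s
flanked by the same state are bridged (the gap frames are excluded from
duration accounting); longer gaps split visits and break transition
pairing, since what happened during a long dropout is unknown.  The
transition-zone completion statistic counts only T visits strictly longer
than 1 s that are flanked by states on both sides.  Milling handedness is
the sign of the mean smoothed signed rotation over each milling visit; an
exactly zero mean (a probability-zero event) is tie-broken to
counter-clockwise and logged.

## Geometry

The group area is a 2D alpha shape: Delaunay triangles with circumradius
at most the probe radius (default one body length, 5.2 cm) are kept and
their union taken; the probe radius going to infinity recovers the convex
hull, and fish in no kept triangle count as singleton components.  The
packing fraction is N × body area / area with body area defaulting to
3.38 cm² (a 5.2 cm × 0.65 cm body; the 8:1 aspect follows the pixel
footprint of a tracked shiner).  Both the probe radius and the body area
are calibration parameters; any constant body area rescales the packing
fraction uniformly, so state-dependent density *patterns* do not depend on
it.  Boundary distance is from the group centre of mass to the nearest of
the four walls.

## Phase-space maps

All maps live on the unit square with O_r on the first axis and O_p on
the second, divided into 30 × 30 bins (half-open except the last, which is
closed so 1.0 belongs to the final bin).  Bins supported by fewer than
`min_count` samples (100 for occupancy/mean maps, 20 for transition maps)
are masked and never interpolated from.  Display refinement to 300 × 300
interpolates linearly between unmasked bin centres and never extrapolates
beyond supported bins.  Transition paths are resampled to a common length
(100 points) in normalised time, averaged pointwise, and differentiated
with forward differences; difference vectors are binned by their starting
point.  Bilinear interpolation and forward differencing are choices made
where the procedure was genuinely open.

## Zonal model

The simulator is the constant-speed zonal model: three concentric,
non-overlapping behavioural zones (repulsion within radius 1, orientation
to 3, attraction to 15, model units), a 270° field of perception whose
90° blind cone hides neighbours in *every* zone (a fish cannot react to
what it cannot see), Gaussian noise of 0.2 rad applied to the desired
direction before a turn-limit clamp of 60° per unit time (6° per 0.1-time
step), synchronous updates, and no boundary.  Repulsion overrides
everything; otherwise the normalised orientation and attraction terms are
averaged when both neighbour sets are non-empty.  The orientation term
excludes the focal agent's own heading.  We verified empirically that
weighting the two social terms by neighbour count instead of normalising
them lets attraction swamp orientation in groups of 150+ and collapses the
milling regime entirely, so the normalised-average rule is used.

The model is three-dimensional by default (spherical zones), with the
planar variant available via `dimension=2`.  The dimensionality matters:
in 2D the large-N, high-speed regime spuriously favours polarized motion
and the milling/polarized bistability at intermediate N disappears, while
the 3D model reproduces the structure the model family is known for —
milling fraction growing with group size at high speed and a clear
milling/polarized bimodality for groups around 150.  Agents start
uniformly placed in a ball of the attraction radius with uniform random
headings (the ball guarantees initial connectivity at every group size);
each replicate of the speed sweep (speeds 0.1–4.1 in steps of 0.1) runs
2500 steps and records the final-step order parameters, using the 3D
generalisations |mean heading| and |mean r̂ × û|.  Per-replicate seeds
derive deterministically from a base seed via `SeedSequence` spawn keys.
The inner force loop is numba-compiled; semantics are identical to the
pure-Python formulation.

Known limitation: with these parameters the model does not reproduce two
features sometimes attributed to it.  First, at very low speed (0.1) the
2500-step endpoint is a dense, partially aligned blob (median O_p ≈ 0.6
for 150 agents) rather than a fully disordered swarm — heading alignment
in this model is speed-independent, so slow dense groups still order, and
the low-speed disorder seen elsewhere plausibly reflects an unequilibrated
contraction transient from a more extended start.  Second, the polarized
branch at N = 300 does not vanish across the whole high-speed band: we
measure ~12% polarized endpoints at speed 3.0 (and an all-polarized window
near speed 2.0), although milling is clearly dominant.  Both are recorded
as failing assertions in the acceptance tests rather than papered over.

## Synthetic data

Three generator tiers calibrate and test the pipeline:

* **Archetype frames** realise each state exactly: a common heading
  (O_p = 1), tangential concentric rings of one handedness (rotation
  magnitude 1), or uniform disorder (both order parameters ~ N^(−1/2)).
* **Scripted order-parameter series** dwell at per-state anchor points —
  P (0.85, 0.10), M (0.10, 0.85), S (0.15, 0.15) in (O_p, O_r), the
  centres of the empirically occupied regions — with Gaussian
  fluctuations (default sd 0.02) and 2-s linear ramps between anchors.
  Ground-truth labels come from classifying the noiseless series, so ramp
  frames outside the source region are truthfully T.
* **Bounded-tank schools** realise a script as positions: polarized
  segments translate a jittered disc at 10 cm/s and reflect off the walls,
  milling segments rotate ring layouts about the group centre at 10 cm/s
  mean tangential speed, swarm segments wiggle at 60% spacing and ~2 cm/s
  (slow and dense, as in real shoals).  During a ramp the outgoing and
  incoming motion patterns both keep evolving and positions are
  smoothstep-blended between them, with incoming pattern slots matched to
  the outgoing configuration by optimal assignment so the morph
  displacement stays small; this carries the order-parameter path
  diagonally through the transition band instead of collapsing through
  disorder and creating spurious extra transitions.  Velocities are
  central differences of positions, so derived headings are consistent
  with the motion.

What the generators do *not* emulate: tracking-error structure, identity
swaps, individual behavioural variability, wall-following, or any
interaction dynamics — trajectories are kinematic patterns, not simulated
fish.  Tests passing on them therefore validate the *measurement chain*
(order parameters → smoothing → segmentation → statistics), not any claim
about real shoals.

## Problem sizes used in the test suite

The suite exercises the simulator at the full 2500-step protocol with
32 replicates per group size for N ≤ 150 and 24 for N = 300 at one fixed
high speed (3.0), plus 24 low-speed replicates — enough for the
qualitative regime assertions while keeping the whole suite within a few
minutes on one CPU.  Scripted-shoal fixtures use 40–60 fish and 60–120 s
scripts.  The full 500-replicate, 41-speed campaign is available through
`shoalstates sweep` and `sweep_and_phase`.
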