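# Methods

## The scientific problem

An observer translating through a rigid world experiences radially
expanding optic flow whose singularity — the focus of expansion (FoE) —
marks the direction of travel (heading).  Independently moving objects
corrupt this field: they carry their own radial pattern (an approaching
object's flow expands from a point *opposite* its direction of motion),
they occlude the most informative background region when they cross the
future path, and motion contrast at a trailing edge can mimic a focus of
expansion (a "pseudo FoE").  Human heading judgments under these conditions
are biased by only a few degrees and evolve smoothly in time.  The package
implements three heading models against which that robustness can be
studied:

* **competitive dynamics** — a dynamical model of the magnocellular
  pathway (retina → LGN → V1 → MT+ → MSTd) whose MSTd stage is a recurrent
  competitive field of heading templates that integrates optic flow over
  time;
* **motion pooling** — a per-frame match of the flow field against
  center-weighted radial templates;
* **differential motion** — the same template match applied to a field of
  opponent difference vectors that respond to speed discontinuities
  (motion parallax).

## Stimuli

Each trial simulates 1.5 s (45 frames at 30 frames/s) of straight-ahead
translation at 200 cm/s toward two frontoparallel planes of 3000 random
dots each, initially 800 and 1000 cm away; the two depths provide the
motion parallax the differential-motion model requires.  A moving
rectangular object (150 × 150 cm, 320 dots) starts left of the path and
moves rightward along one row of the condition table (lateral offset,
depth, speed, trajectory angle).

Trajectory-angle conventions (the printed table is not self-consistent, so
each row is read so that its defining property holds):

* **Approach rows (positive angle)** are world-frame velocities measured
  from the observer's line of travel.  With object and observer speeds
  equal this places the object-region FoE at exactly half the trajectory
  angle (the half-angle identity `atan(sin θ / (1 + cos θ)) = θ/2`), i.e.
  7.5° and 35° for the 15° and 70° approaches, on the side opposite the
  object's lateral motion.
* **Fixed-depth** clamps the object's world depth-rate to the observer's
  speed, so relative depth is constant; the lateral speed is
  `speed · sin |angle|`.
* **Retreating rows (negative angle)** are observer-relative velocities,
  which makes the object recede in depth throughout the trial.

The camera is an ideal pinhole with a 100° horizontal field of view (wide
enough to contain every trajectory, matching the field size quoted for the
illustrative wide-field display).  Analytic flow is the exact projected
per-dot displacement with z-buffered occlusion by the opaque object (and by
the optional textureless "blank" occluder, which hides dots but emits
none).  Dots leaving the field are not replenished during a 1.5 s trial.
Rendered frames splat each visible dot as a small Gaussian at sub-pixel
position (white on black, clipped to [0, 1]).

What the generator does **not** emulate: eye rotations or curved paths
(flow is purely translational), photometric realism, finite dot lifetime,
and sensor noise.  Passing tests therefore speak to the models' geometric
and dynamical behavior, not to their robustness against photometric
nuisances; the video route (below) partially addresses the latter.

## Shunting dynamics

Every neural layer obeys a membrane-style shunting equation
`dx/dt = ε(−x + (1 − x)E − xI)`, which bounds activity in [0, 1] and
implements divisive normalization.  Recurrent signals pass through the
faster-than-linear sigmoid `f(w; f₀) = w²/(w² + f₀²)` (half-maximum at
`f₀`) after a firing threshold `g(w; Γ) = [w − Γ]⁺`; this combination
produces soft winner-take-all competition.

Two printed layer equations cannot work as written and are replaced by the
standard forms (the printed forms remain available behind flags):

* the LGN transmitter gate `dZ/dt = ε(1 − R − λRZ)` grows without bound at
  zero drive, contradicting recovery "to full capacity"; the default is the
  habituative form `dZ/dt = ε((1 − Z) − λRZ)`;
* the MT equation `dM/dt = −M(1 − M)·input` is non-increasing on (0, 1) and
  could never excite MT; the default is `dM/dt = −M + (1 − M)·input`,
  consistent with every other layer.

**Integration.**  The public primitive is forward Euler with an enforced
stability bound `dt·ε·(1 + E + I) ≤ 1`.  The model itself integrates its
layers with an exponential update (exact for drives held constant over the
step, unconditionally stable and bounded), one sub-step per frame; the MSTd
field, the stiffest layer, takes two half-steps per frame.  Doubling the
sub-step count changes terminal heading estimates by less than 0.1° (only
isolated mid-trial frames can flip by one grid node near decision
boundaries).

**Time constants.**  Printed rates are used where given (LGN drive
2 s⁻¹, gate 0.01 s⁻¹, V1 simple cells 5 s⁻¹).  The V1-complex, MT and MSTd
equations carry no explicit rate.  V1-complex and MT use 30 s⁻¹ (fast
sensory stages that track the stimulus within a frame; MSTd is described as
several-fold slower than its inputs).  MSTd uses ε = 2 s⁻¹: with typical
total drive `1 + E + I ≈ 4–8` its effective decay constant
`1/(ε(1 + E + I))` is of the order of the 81 ms MSTd decay reported in the
physiology, while the *network-level* competition — the behaviorally
relevant timescale — unfolds over several hundred milliseconds, as the
heading-error buildup curves require.

## Motion detection

V1 simple cells are correlation (Reichardt-style) detectors over LGN
signals: channel (speed *s* ∈ {1, 2, 3} px/frame, direction *d* ∈ 8)
sums the current signal with the previous frame's signal displaced
opposite *d* by every offset of length ≤ *s* along the ray, thresholds at
0.45, squares, and averages over active offsets (diagonal contributions
scaled by *s*, as specified).  Complex cells pool simple-cell energy
anisotropically along the preferred direction (elongation ratio 15; the
unspecified absolute cross-axis width defaults to radius/3), are inhibited
by the orthogonal pooling, by other directions' recurrent activity, and by
direction-discrepant MT feedback (Gaussian σ = 0.5 px, radius 3s) — the
net-suppressive loop that prevents runaway inter-areal feedback and
resolves the aperture problem over frames.  MT pools complex output over a
larger elongated field; its output collapses speeds, pools collinearly
(radius 2 on the heading grid), thresholds at 10⁻³ and squares.

**Input routes.**  The full image-computable route (retina → LGN →
correlation detectors) drives the pathway from rendered or user-supplied
grayscale video.  For the dot-world experiments at reduced resolution the
analytic flow field drives the same speed/direction channels directly:
rectified-cosine direction tuning (broad, like the simple cells), and
speed tuning that mirrors the offset-inclusive detector — channel *s*
responds from one channel unit up to *s* units, ramping below one unit and
cutting off above its own preferred speed.  The cutoff matters: motion
faster than the largest correlation offset is *invisible* to the detector,
and that blindness to very fast near-object flow is part of the model's
robustness in the retreating and pseudo-FoE displays.  The drive amplitude
(`flow_gain = 6`) is a free constant calibrated once so that the static
two-plane display produces mid-range activity at every stage.

## Heading estimation (MSTd)

Templates are ideal unit-length radial fields, one expansion and one
contraction template per node of a grid spacing 6 px (reference scale),
decomposed into the 8 direction channels by rectified cosine projection
and center-weighted by a Gaussian around the preferred singularity.  The
weighting is nearly full-field (σ = 160 px at reference scale), consistent
with MSTd receptive fields that span much of the visual field; narrow
weighting makes the match track local dot-density fluctuations instead of
global radial structure.  The match is normalized per template by the
in-grid template energy (one unit vector per location) and scaled by a
bottom-up gain (`v_gain = 0.3`), a free constant placing the peak match
just above the 0.3 firing threshold so that competition operates in its
intended regime.

MSTd units compete across 2D space and across polarity.  The off-surround
is implemented as network-wide mean-field inhibition with gain 20: every
unit receives the mean recurrent signal of all other units of both
polarities.  A literal local Gaussian window (σ 10, radius 7 grid units)
is implemented and available (`surround_gain`), but at the working grid
resolution it produced winner lattices and border artifacts for every gain
tried — a normalized neighborhood average can never outweigh the saturated
self-excitation of a weakly supported unit, while the raw weighted sum
oscillates and favors border units with cropped neighborhoods.  The
mean-field form matches the generic recurrent competitive field (inhibition
by the total activity of all competitors) and keeps the suppression
uniform, so the surviving units are exactly the best supported ones.

The heading estimate is the preferred azimuth of the most active
expansion-tuned unit on the horizontal cross-section through the true
heading (ties go to the node nearer the image center; a silent
cross-section yields a no-estimate sentinel, not 0°).  The population
variance is the activity-weighted positional variance (deg²) of the
expansion units over the full 2D template space; a 1D cross-section
variant exists.  The lesioned variant drops every recurrent term, leaving
pure leaky integration of the match.

## Baselines

Both baselines share the center-weighted radial match: a template at every
2nd pixel scores the Gaussian-weighted mean cosine between local motion
direction and the radial direction from its FoE (support-normalized, so
dot density is not confused with motion structure).  Pooling width is
25 px for motion pooling and 19 px for differential motion (the printed
overrides).  The differential front end filters rectified directional
speed with 7×7 odd-symmetric Gabor lobes displaced along each direction;
the rectified lobe difference points the difference vector toward the
faster surface.  Uniform (parallax-free) flow yields no opponent response
and the model reports the no-estimate sentinel with a warning.  Baselines
are frame-independent; the temporal-smoothing control applies a causal
3/6/9-frame moving average to their per-frame template maps only.

The video route feeds the baselines Horn–Schunck flow (classic
global-smoothness estimator, Jacobi iterations, implemented in-package and
validated against the rigid-shift oracle), while the competitive model
consumes the frames directly.

## Resolution presets and problem sizes

Pixel-denominated constants are defined at a 320-px-wide reference display
(the video resolution; the dot-display resolution is not stated).  The
default **desk** preset runs at 129 × 97 px with every such constant
scaled by ρ = 129/320 ≈ 0.40: template grid every 2 px (≈ 2.8°/node at
100° field), speed-channel unit 0.40 px/frame, pooling σ 10.1/7.7 px,
baseline grid every 1 px.  Odd image dimensions keep the grid exactly
mirror-symmetric, and left-right mirroring of a stimulus negates the
signed error to machine precision.  A 45-frame competitive trial takes a
few seconds on one CPU; the full study (25-trial ensembles of six
conditions plus baselines) runs in roughly ten minutes.  The **paper**
preset (321 × 241 px, grid 6 px, MT grids 1/2/3 px) is provided for
larger-scale runs.

Ensembles use 25 trials differing only in the dot-placement seed
(`base_seed + trial index`); the test suite uses 8-trial ensembles of the
same protocol for speed.

## Experiment metrics

Signed error is positive when the estimate deviates in the direction of
object motion (objects always move rightward).  Crossing epochs are
computed from geometry: "during" frames are those in which the object's
lateral extent contains the observer's path.  The peak bias is the
extremal mean signed error over the crossing epoch (over the whole trial
for conditions that never cross); the variance plateau time is the first
frame whose across-seed mean population variance is within 5% of the
terminal value.

## Known limitations

* At desk scale the 70°-approach bias comes out *positive* (the occlusion
  asymmetry — the object hides the left background — outweighs the pull of
  the object's own FoE at −35°), where the reported bias is negative.
* The stationary pseudo-FoE display drags the estimate by ~5–8° late in
  the trial instead of < 2°: once the object occludes the heading region
  its own expansion pattern is the strongest radial structure, and with
  mean-field competition an established heading peak cannot locally
  out-inhibit it.  The blank-occluder variant does reduce the bias, as in
  the reference data.
* The population-variance statistic is range-compressed: subthreshold
  units retain a match-driven pedestal that dominates the activity-weighted
  variance, so the curve moves by only a few percent and the
  5%-of-terminal plateau criterion triggers almost immediately rather than
  near 500 ms.
* The lesioned model's fixed-depth/retreating biases share the intact
  model's sign here, because at desk scale the instantaneous match itself
  already carries the occlusion-asymmetry bias.
* The retreating-object peak bias is larger than reported (the early
  trial, when the large near object occludes much of the left field,
  produces a strong rightward transient before competition engages).

These are properties of this implementation at the desk operating point;
they are exercised (and visible) in the acceptance test suite rather than
hidden.
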