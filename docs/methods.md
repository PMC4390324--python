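# Methods

## Kinematic model

Each finger is a serial chain of four rigid bones.  Segment frames follow
the convention +x radial (the flexion axis), +y proximal along the bone,
+z dorsal; every phalanx frame has its origin at the bone's proximal joint
centre, so the middle-phalanx frame origin is the PIP centre and segment
lengths are the distances between consecutive joint centres.  The MCP joint
is a universal joint — ab/adduction about the parent z axis followed by
flexion about the rotated x axis — and PIP/DIP are revolute flexion
joints.  Ranges of motion: MCP flexion 0–90°, MCP ab/adduction 0–30°, PIP
0–90°, DIP 0–50°, with 0° full extension, flexion and abduction positive.
The rotation order at a universal joint is a modelling choice (the two
orders differ only at combined large angles); ab/adduction-first matches
the common two-DOF gimbal convention and is isolated in one function
(`joint_rotation`) if it ever needs to be flipped.

Angles are degrees at every interface and radians internally.

### Dimensions

Index-finger phalanx lengths (proximal 42.60, middle 25.10, distal
19.10 mm) come from the packaged anthropometry table.  Two kinds of
dimensions are *not* tabulated anywhere and use documented placeholder
defaults chosen from generic 50th-percentile hand proportions, consistent
with the coordinate ranges of the packaged attachment tables:

* phalanx lengths for the middle, ring and little fingers
  (`DEFAULT_DIMENSIONS`),
* the distance from the mid-metacarpal frame origin to the MCP centre
  (`DEFAULT_METACARPAL_OFFSETS`; half a generic metacarpal length).

Both are constructor arguments of `build_finger_chain`.  No quantitative
result in the test suite or acceptance script depends on them; they only
enter the qualitative sign/trend regressions.

## Muscle paths and wrapping

A muscle path is an ordered list of attachment *pairs*, one pair per
crossed joint (proximal point on the joint's parent bone or more proximal,
distal point on the child bone), which is also how the packaged attachment
tables are organized.  Ten muscles per finger are modelled: the extrinsic
FDP, FDS and EDC, the intrinsic interossei (RI, UI) and lumbrical (LU),
and the extensor-mechanism bands TE, ES, RB and UB.

Each joint carries one wrap cylinder along its flexion axis, fixed to the
parent bone, radius a quarter of the joint's dorsopalmar thickness
(index values 17.08 / 7.31 / 4.95 mm at MCP / PIP / DIP; other fingers
scaled by the proximal-phalanx length ratio).  A quarter thickness
approximates the bone radius at the neck where tendons actually ride; a
half-thickness cylinder (the full joint head) would contain several of the
packaged intrinsic attachment points and make the tangent construction
ill-posed.  The radius scale and the full cylinder set are config-exposed
(`default_wrap_set(radius_scale=...)`, or pass any `WrapCylinder` dict).

A pair's straight segment wraps when its chord penetrates the cylinder
(closest approach to the axis < radius, with the crossing between the
endpoints and both endpoints outside the cylinder).  The path is then
routed around the cylinder's configured side — palmar for the flexors
(FDP, FDS, RI, UI, LU), dorsal for the extensors and bands — even when the
chord grazes marginally on the opposite side of the axis, which restores
the pulley-like behaviour of e.g. the palmar interosseous whose chord
crosses a fraction of a millimetre dorsal to the MCP axis in mid-range
postures.  The shortest route is tangent line – arc – tangent line in the
plane perpendicular to the axis; the axial coordinate varies linearly with
planar arc length (the unrolled-cylinder geodesic), so the wrapped length
is `sqrt(Lp² + h²)` with `Lp` the planar path length and `h` the axial
offset.  Ab/adduction has no wrap geometry of its own: ab/adduction moment
arms are evaluated on the straight chord.

Engagement transitions make moment-arm curves piecewise smooth; the
`validate=True` flag of `moment_arm` warns when the partial-velocity and
finite-difference values disagree by more than 0.01 mm, which brackets the
transition band.

## Moment arms

The partial-velocity implementation sums, over the straight elements of
the resolved path, `û · (v(P₁) − v(P₀))`, where `v` is the rigid-body
partial velocity `ω̂ × (P − c)` of the bone each point rides on (zero for
bones proximal to the coordinate).  Wrap contact points ride on the bone
the cylinder is fixed to and arc lengths are rigid-invariant, so arcs
contribute nothing — for a locally shortest path the sliding terms vanish
(envelope theorem), making this exactly `−∂L/∂q`.  The independent
cross-check is the central-difference tendon excursion
`−[L(q+h) − L(q−h)]/2h` with h = 10⁻⁴ rad; the two agree to better than
10⁻⁶ mm away from engagement transitions (the finite-difference
truncation error reaches ~10⁻⁷ mm on strongly curved configurations).
Two exact limits are tested: a fully wrapped tendon in the axial plane of
its attachments has moment arm exactly the cylinder radius, and isometric
scaling of all geometry by s scales every moment arm by exactly s.

Sign convention: positive = flexion (muscle shortens as flexion increases)
or abduction moment arm.

## Attachment optimization

One pair x = (proximal xyz, distal xyz) is freed.  The objective is the
summed RMS error between target and model flexion moment-arm curves over
an m = 100 point grid covering the RoM; at MCP an inequality constraint
holds the ab/adduction moment arm during the flexion sweep within
ε = 2.5 mm (extrinsic) or 1.7 mm (intrinsic) of the target.  When the
ab/adduction target is tabulated on the flexion grid the constraint is
pointwise; an experimental-style curve tabulated over the ab/adduction
range is reduced to its mean level, since ab/adduction moment arms depend
strongly on the (unreported) flexion posture at which they were measured.
The constraint is enforced by an exterior quadratic penalty
`1e4·max(0, g−ε)²` during the search plus a hard feasibility flag on the
returned candidates; bounds are enforced by clipping every iterate.

Bounds are the skin-surface box around each bone: the dorsopalmar
half-extent is half the scaled skin joint thickness, the radioulnar extent
reuses the same value (widths are not tabulated), and the box spans the
segment length with a joint-thickness margin.  A bone-surface *lower*
bound is deliberately not imposed: real attachment sites hug the bone
(several packaged points lie within 2.5 mm of the segment axis), so any
exclusion cylinder wide enough to matter would exclude the ground truth;
bone non-penetration is the wrap cylinders' job.

The search is Corana-style adaptive Simulated Annealing (t0 = 10, cooling
0.85, 20 moves per coordinate per step adjustment, 5 adjustments per
temperature, per-coordinate steps adapted toward 50% acceptance,
termination when f changes < 10⁻⁴ over 4 temperatures, 40-temperature
cap) refined by Hooke–Jeeves pattern search (initial step 1 mm, halving to
10⁻³ mm, with a stagnation guard that halves the step when a full
explore/pattern cycle gains less than 10⁻¹⁰ relative — the classic
zig-zag pathology when the step is about twice the distance to the
optimum).  Each of the 26 starts gets an independent RNG stream derived
from the problem seed, so runs are bit-reproducible.  Scaled-down runs
(tests, acceptance script, `--max-temps/--t0` on the CLI) lower the
starting temperature to 1.0 and cap at 12 temperatures with 10 moves per
coordinate: a truncated schedule at t0 = 10 is still in its random-walk
phase when it stops, whereas cooling further recovers the same optima at a
fifth of the cost.

Candidate selection follows the anatomical rule: among feasible candidates
whose worst point-distance to the measured pair is within 28% of the
middle-phalanx length (7.03 mm for the index), pick the largest radius of
curvature (smoothest path), computed as the smallest circumradius over
successive attachment triples of the whole muscle path; otherwise pick the
candidate nearest the measured pair; ties fall back to the objective.
Collinear triples have infinite radius (a straight tendon is smoothest).

The fit frees one pair at a time.  Moment arms at a joint depend only on
the pair straddling it (points on bones that move rigidly together
contribute nothing), so the summed-over-joints objective decouples and
fitting pair-by-pair loses nothing for two-point pairs.

## Synthetic targets and what recovery shows

`generate_synthetic_targets` evaluates the model on known ("true")
attachments — one flexion curve per crossed joint, plus the ab/adduction
moment arm over the flexion sweep at MCP — and adds i.i.d. Gaussian noise
(seeded; SD 0 or 0.5 mm in the packaged experiments, the latter matching
the order of reported inter-specimen moment-arm variability).  Recovery
experiments use the index FDS pair at MCP.  With zero noise the pipeline
reaches objective RMS < 0.1 mm and every coordinate within the 7.03 mm
anatomical threshold; with 0.5 mm noise the final RMS settles near
0.5 mm (the noise floor of fitting 100 noisy points with 6 parameters).
These experiments validate the optimizer against a known answer under the
model's own geometry; they do not show that the simple two-point,
single-cylinder geometry reproduces a real finger's moment-arm curves,
only that attachments consistent with a given curve are found and ranked
sensibly.

## Known limitations

* The packaged reference tables contain internal inconsistencies: for 26
  of the 103 printed per-point distances, recomputing the Euclidean
  distance from the printed coordinate columns disagrees with the printed
  distance by more than the 0.05 mm print rounding (three cells by more
  than 2 mm).  The tables are stored verbatim and the discrepancy is
  surfaced, not patched; the overall mean distance (4.68 mm recomputed,
  4.77 mm printed) is unaffected at the headline 4.9 mm level.
* Two-point pairs with a single wrap cylinder reproduce the signs of the
  reference mean moment arms at every joint of every finger, but not
  strict monotonicity: UI's flexion moment arm at the little-finger MCP
  declines by ~1 mm over the upper range, and several intrinsics show
  0.01–0.09 mm local dips near wrap transitions.  Reproducing monotone
  curves would require the via-point and wrap geometry of the original
  model, which is not published.
* Exact reproduction of the reference mean moment arms is out of reach for
  the same reason; they serve as sign/ordering regressions only.
* Wrap cylinders are infinite and axis-aligned with the flexion axis;
  ab/adduction wrapping and joint translations are not modelled.
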