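# Methods

`glenofdk` simulates glenohumeral (GH) translation during scapular-plane
abduction–adduction by solving, at every motion frame, a quasi-static force
equilibrium over the three translational degrees of freedom of the GH joint
(force-dependent kinematics, FDK).  This note records the model, the
numerical machinery, the choices made where the design was open, and what
the synthetic data can and cannot say about real shoulders.

## Coordinate conventions and kinematics

All computation happens in the **glenoid frame**: x anterior, y superior,
z lateral (from the glenoid cavity toward the humerus); gravity acts along
−y.  The frame is constructed from the glenoid rim (origin at the rim
centroid, y from the inferior to the superior rim landmark, z along the
outward cap normal) and for the default fixture coincides with the world
frame by construction.

Primary kinematics are prescribed: elevation θ(t) follows a raised-cosine
0 → peak → 0 profile per cycle (continuously differentiable across cycle
boundaries; default three 4-s cycles to 30°, sampled at 5 Hz → 61 frames).
Elevation is a ball rotation about the nominal head centre; the elevation
plane is the scapular plane, taken 30° anterior of the coronal plane.  The
scapula is held fixed over 0°–30° (setting phase of the scapulohumeral
rhythm; a configurable plane offset and axial-rotation DOF exist for
calibration poses and sensitivity use).  Secondary kinematics are the
translation u = (AP, IS, lateral) of the head centre, bounded by ‖u‖ ≤ 10 mm.

The arm is a single rigid segment (upper arm plus extended forearm/hand,
thumb-forward): length 0.40 × body height from GH centre to hand, mass 5 %
of body mass, COM at 45 % of arm length — standard anthropometric
fractions; elbow motion is irrelevant to the task.  Trials are quasi-static:
inertial terms are dropped from both the torque balance and the residual.

## Articular geometry and elastic-foundation contact

The glenoid is a concave spherical cap (radius 27 mm, half-angle 35°), the
labrum a compliant band extending the cap rim by 4 mm of arc (deepening the
socket), the humeral head a sphere of radius 25 mm (icosphere, 5120 facets).
At the neutral pose the head is internally tangent to the glenoid sphere
with a 0.5 mm clearance at the deepest point — the configuration the
ligament calibration is performed in, so that seating the head under load
(≈ 0.7 mm medial translation) perturbs the calibrated strains only mildly.

Contact force follows the elastic-foundation law: magnitude =
pressure module × penetration volume, with moduli 9.3 × 10⁹ N/m³
(bone-on-bone) and 0.11 × 10⁹ N/m³ (head-on-labrum); the two wrenches add.
The foundation is discretised on the slave (head) mesh: each slave vertex is
projected onto the master surface by an exact nearest-point query (cKDTree
candidate culling + point-triangle projection — no ray casting, which grazes
badly on near-congruent caps) and signed along the master normal; a facet's
depth is the mean of its three clamped vertex depths and its column
cross-section is the facet area projected onto the master normal.  Vertex
(rather than centroid) sampling matters: centroids of a sphere mesh lie
inside the sphere, biasing depths low by several percent.  Against the
spherical-cap closed form V = πh²(3R−h)/3 (sphere R = 25 mm on a plane,
h = 1 mm) the discretisation is accurate to 0.3 % at the default mesh and
converges with refinement.  Facets whose outward normal does not oppose the
local master normal (the far side of the head) and depths beyond 5 mm are
rejected as non-physical.  The resultant direction is the depth-weighted
average of master normals; the moment is taken about the centre of pressure.

## Ligaments

Four ligament systems are discretised into 17 springs: superior GH (2),
middle GH (2), inferior GH (8, split 3/2/3 across its anterior / posterior /
inferior portions — the anterior and posterior bands being the mechanically
dominant structures), coracohumeral (5).  Bundle stiffnesses (N per unit
strain): 550, 375, 582 / 320 / 388, 1099.  The published stiffness is a
bundle property, split equally across the bundle's springs.

Tension is slack / quadratic-toe / linear in engineering strain ε:
T = 0 for ε ≤ 0, k ε²/(2ε_t) for 0 < ε ≤ ε_t, k (ε − ε_t/2) beyond, with
toe extent ε_t = 0.03 — the external curve source prints no parameters, so a
standard C¹ piecewise form was adopted.  Springs route around the humeral
head as a single spherical wrapping obstacle; the shortest
tangent–arc–tangent path has a closed form, and the net pull on the humerus
acts along the scapula-side departing segment.

Slack lengths are not material constants: per spring,
L₀ = L(calibration pose)/(1 + ε_ref), where each bundle's reference pose and
strain are (abduction, axial rotation, strain): superior (0°, 20° ER, 9 %),
middle (0°, 0°, 7 %), inferior-anterior (60°, 50° ER, 11 %),
inferior-posterior (60°, 30° ER, 10 %), inferior-inferior (60°, 80° IR,
10 %), coracohumeral (0°, 0°, 5 %).  Calibration is per spring at u = 0 and
round-trips exactly by construction.  Whether the original calibration was
per spring or per bundle is not documented; per-spring was chosen as the
only variant that reproduces the reference strain for every element.

Attachment sites are generic landmarks on the scaled geometry.  Two
placements were revised during validation, on anatomical grounds: the
inferior and posterior IGHL insertions sit close to the humeral long axis
(an early, more off-axis placement made the Table-pose axial rotations
shorten these bundles, leaving them spuriously taut by +28 % during low
elevation, where anatomically — and in reported trial behaviour — they hang
slack); and the infraspinatus inserts high on the greater tuberosity so it
retains an abduction moment arm and participates throughout elevation, as
the posterior cuff does in vivo.  With the final geometry, at neutral the
middle GH (7 %) and coracohumeral (5 %) ligaments are taut, the inferior
capsule is slack (−18 to −35 %), and the inferior/posterior IGHL portions
carry no load below ≈ 20° elevation.

## Muscles

Sixteen muscles spanning the GH joint are discretised into 118 line
elements; the per-muscle allocation (deltoid 12/12/12, supraspinatus 6,
infraspinatus 12, subscapularis 12, teres minor 6, teres major 6, pectoralis
major 5/5/5, latissimus dorsi 12, coracobrachialis 3, biceps 2/2, triceps
long 6) spreads each muscle across its attachment footprint, with the
deltoid parts and the large cuff muscles carrying the biggest counts.
Nominal strength F₀ = 55 N/cm² × PCSA, scaled by body mass and divided
equally over elements; PCSA fractions follow published anatomy (deltoid
25 cm² total, subscapularis 13, infraspinatus 9.5, supraspinatus 6, …).

Instantaneous strength is Hill-type: S = tear · F₀ · f_L(l̃) · f_V(ṽ) with a
quadratic force-length bump on l̃ ∈ [0.5, 1.5] peaking at 1 and a clipped
force-velocity curve (f_V(0) = 1, eccentric plateau 1.4); the trials are
quasi-static so f_V ≡ 1.  The operating range is calibrated per element by
sweeping path length over the full shoulder range of motion (0–180°
elevation, elevation planes −30° to 90°, axial −70° to 90°): the excursion
midpoint maps to l̃ = 1 and the excursion spans l̃ ∈ [0.6, 1.4] through an
affine span normalisation l̃ = 1 + 0.4 (L − L_mid)/L_half.  The affine rule
(rather than plain division by an optimal length) keeps every element inside
the force-length support at every reachable pose and handles zero-excursion
elements (l̃ ≡ 1); it mirrors operating-range matching in which each muscle
uses a consistent fraction of its curve.  Tears multiply strength per
muscle: 1 intact, 0.5 partial-thickness, 0 full-thickness (torn elements
produce no force at all — no separate passive fibre force is modelled, since
passive joint stability is carried by the ligaments and contact).

Moment arms come from tendon excursion: central differences of wrapped path
length under ±0.25° virtual rotations about the three glenoid-frame axes
through the current head centre.  This keeps torque and path geometry
consistent and avoids analytic special cases at wrap onset.

## Recruitment and the stability cone

Per frame, element forces minimise the cubic criterion Σ (fᵢ/Nᵢ)³ subject to
moment balance about the three GH rotational axes (torque demand from
gravity, ligaments and contact at the current pose), fᵢ ≥ 0, and the
glenoid stability constraint: the required joint reaction — the force the
joint must supply after muscles, ligaments and gravity — must point through
the glenoid cavity.  The cone is linearised into 8 planar facets through the
glenoid rim with apex at the nominal head centre, and coexists with the
deformable contact: the cone acts inside recruitment on the required
reaction, while the elastic foundation supplies that reaction in the
translational residual.  Nᵢ normalises the objective but does not hard-cap
the force, the convention of polynomial recruitment criteria (the
strength-weighted optimum follows fᵢ ∝ Nᵢ^{3/2}).  Elements with zero
strength are removed before solving — the objective is undefined at N = 0.

The program is convex and is solved with SLSQP in activation variables
x = f/N (an order of magnitude better conditioned than raw forces),
ftol 10⁻¹⁰, warm-started across outer iterations and frames.  Degenerate
moment-balance rows (axes with no actuator authority, which arise in
reduced test problems) are dropped when their demand is zero and flagged
infeasible otherwise.  If the optimiser fails, an LP feasibility certificate
distinguishes genuine infeasibility (reported with the violated constraint)
from numerical failure.  Verified against brute-force grid search (≤ 1 %
objective) and the N^{3/2} closed form.

## FDK outer loop

For each frame, u is updated by a damped quasi-Newton iteration on the
residual R(u) = F_muscle + F_lig + F_contact + F_gravity:

- Jacobian: forward differences (step 10 µm) with muscle forces frozen —
  the stiff part of ∂R/∂u is the contact/ligament response, and freezing
  recruitment quarters the number of inner solves; Broyden rank-1 updates
  between full refreshes (every 10 iterations) absorb the neglected
  recruitment coupling.
- Steps are clipped to 0.5 mm, backtracked up to 4 halvings, and u is
  clamped to the ±10 mm box.  When the Jacobian is singular along the
  residual (no restoring stiffness — e.g. an unopposed superior pull), the
  head drifts along the net force at the step limit, which is how superior
  escape is reached and flagged (`failure_mode="superior_escape"` once the
  superior component hits the bound).
- Convergence: ‖R‖₂ < 10 N (Euclidean norm; the threshold is the model's
  published acceptance value), typically 2–5 iterations per frame with
  warm starts, ≈ 15 for the cold first frame.

A trial marks frames individually; recruitment infeasibility inside a frame
is recorded (`recruitment_infeasible`) without aborting the trial, and a
trial with > 20 % unconverged frames is marked failed with partial results
retained.  The **default** model runs the same recruitment with u ≡ 0 and
no ligament or contact terms: the ideal joint supplies the required reaction
directly, and its translations are identically zero.

Reported joint reactions are the force on the scapula (= −(required
reaction on the humerus)), decomposed as compressive (+ pressing the head
into the glenoid), AP shear (anterior +) and IS shear (superior +).  Only
converged frames enter summary statistics; per-cycle maxima of |IS| and
|AP| are averaged across cycles.

## The synthetic-data generator

`make_fixture` emulates the study conditions — near-congruent spherical
articular surfaces with a compliant labrum rim, the 16/118 actuator set, the
2/2/8/5 ligament discretisation, 0°–30° three-cycle motion, 0–3 kg handheld
loads — for a reference subject (1.75 m, 75 kg) with seed-controlled ~1 mm
Gaussian jitter on soft-tissue attachments standing in for between-subject
variability.  `synth_fluoro_translations` produces a fluoroscopy-like
measured series: inferior-anterior drift proportional to elevation with a
prescribed |IS| amplitude (1.4 mm and 1.1 mm at 0 and 2 kg reproduce the
uniplanar-fluoroscopy scale) plus Gaussian measurement noise.

What the generator does **not** emulate: real bony morphology (no retroversion,
inclination, or non-sphericity), cartilage, subject-specific attachment
anatomy or ligament laxity, scapulohumeral rhythm, soft-tissue wrapping
beyond a single sphere, and any physiologic coupling between the measured
series and the mechanics (the fluoroscopy-like series is a stylised
reference signal, not an output of the model).  Passing tests therefore
demonstrate internal consistency — equilibrium below threshold, calibration
round trips, directional responses to tears and loads, force magnitudes in
the physiological envelope — not agreement with any real cohort.

## Numerical choices and degenerate inputs

Moment-arm differencing step 0.25°; outer FD step 10 µm; recruitment
ftol 10⁻¹⁰ with torque residual reported relative to demand (< 10⁻⁶ at
converged frames); contact depth cap 5 mm; degenerate (zero-area) slave
facets are dropped with a logged count; collinear rim points, endpoints
inside the wrap sphere, uncalibrated bundles and invalid anthropometrics
raise typed errors naming the offending field.  Ties in the backtracking
line search keep the first (longest) step.  All angles are degrees at
interfaces and radians internally.

## Problem sizes

Default trials: 61 frames (3 × 4 s cycles at 5 Hz); the load and tear
batteries in `analysis/` use single-cycle 21-frame trials — the solver is
deterministic and warm-started, so repeated cycles duplicate the first to
within micrometres.  Meshes: glenoid 1488, labrum 576, head 5120 facets.
A full three-cycle FDK trial runs in ≈ 15 s on one CPU; the complete test
suite in ≈ 90 s.

## Known limitations and observed behaviour

- The healthy joint force at 30° (≈ 300 N total, ≈ 260 N compressive at
  0 kg) lies inside the in-vivo instrumented-prosthesis envelope, and the
  FDK compressive force exceeds the spherical-joint model's by ≈ 45 N; but
  shear fractions are constrained by the 8-facet cone and should not be
  over-interpreted component by component.
- A 50 % supraspinatus strength reduction reduces its peak force to ≈ 47 %
  of healthy, not to the interior-optimum 35 %: weakening a muscle raises
  the shadow price of the demands it serves, partially restoring its share.
- In this synthetic subject, |IS| translation maxima grow mildly with
  handheld load (1.2 → 1.9 mm at 0 → 3 kg) as the head seats under rising
  compression; real shoulders, with their co-contraction strategies and
  individual morphology, need not follow this pattern.
- Trial-time ligament strains stay near their calibration values; in-vivo
  imaging reports substantially larger mid-range elongations for the middle
  GH ligament, so absolute ligament forces here are conservative.
- No cartilage layer, no friction, no capsule continuum, no ligament
  failure criterion; the stability cone's facet count and the labrum band
  height are declared constants, not fitted quantities.
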