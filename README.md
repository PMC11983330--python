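# glenofdk

A desk-scale musculoskeletal shoulder simulator that computes **glenohumeral
(GH) translations with force-dependent kinematics (FDK)**: instead of pinning
the humeral head to an ideal ball-and-socket joint, the three translational
degrees of freedom of the GH joint are solved per frame from the quasi-static
equilibrium of muscle, ligament, articular-contact and external forces.  The
package is aimed at shoulder biomechanists who want to study how bony
congruence, the labrum, the GH/coracohumeral ligaments and rotator-cuff (RC)
muscle forces interact to stabilise the humeral head — and how partial or
full RC tears disturb that balance — without access to subject-specific
imaging: every input (articular surfaces, a 16-muscle/118-element actuator
set, 17 ligament springs, motion, loads, fluoroscopy-like reference
translations) is generated synthetically.

## The model

For each frame of a prescribed 0°–30° scapular-plane abduction–adduction
motion with a handheld load, two nested problems are solved.

**Muscle recruitment (inner).**  Element forces f minimise the cubic
polynomial criterion

    min Σᵢ (fᵢ / Nᵢ)³   s.t.   A f = b,   f ≥ 0,   joint reaction inside the stability cone

where A holds tendon-excursion moment arms about the three GH rotational
axes, b is the torque demand from gravity, ligaments and contact, and
Nᵢ = tear · F₀ · f_L(l̃) · f_V(ṽ) is the instantaneous Hill-type strength
(quasi-static trials use ṽ = 0).  The stability cone — an 8-facet
linearisation of the cone from the head centre through the glenoid rim —
requires the joint reaction to point through the glenoid cavity, which
forces physiological cuff co-contraction.  RC tears scale N: 0.5 for a
partial-thickness tear, 0 (inactivated) for a full-thickness tear.

**FDK equilibrium (outer).**  The GH translation u (anterior–posterior,
inferior–superior, lateral) is driven by a damped quasi-Newton iteration
until the net translational force on the humerus,

    R(u) = F_muscle + F_ligament + F_contact + F_gravity,

falls below a 10 N residual threshold.  Contact between the humeral head
and the glenoid/labrum surfaces uses an elastic-foundation law: the contact
force magnitude is the penetration volume times a pressure module
(9.3 × 10⁹ N/m³ bone-on-bone, 0.11 × 10⁹ N/m³ head-on-labrum), directed
along the depth-weighted master-surface normals.  Ligament bundles are
tension-only springs with a quadratic toe region and a linear elastic
region; their slack lengths are calibrated so that reference arm positions
reproduce published strains (e.g. middle GH 7 % and coracohumeral 5 % at
0° abduction / 0° axial rotation).  A **default** mode locks u ≡ 0 (the
conventional spherical-joint model, stability cone only) for paired
comparisons.

## Worked example

```python
import glenofdk as g
from glenofdk.fixtures import make_loadcases, make_motion
from glenofdk.solver import simulate_trial
from glenofdk.reporting import reaction_at_max_elevation, summarize_translations

fx = g.default_fixture(seed=0)                      # calibrated synthetic shoulder
profile = make_motion(peak=30, n_cycles=1, frame_rate=5.0)
lc = make_loadcases(fx.anthropometrics)[0]          # 0 kg handheld

trial = simulate_trial(fx, profile, lc, mode="fdk")
print(f"converged {len(trial.converged_frames)}/{len(trial.frames)} frames")

r = reaction_at_max_elevation(trial, fx.glenoid_frame)
print(f"joint reaction at {r['elevation_deg']:.0f} deg: "
      f"compressive {r['compressive_n']:.1f} N, "
      f"AP {r['ap_shear_n']:+.1f} N, IS {r['is_shear_n']:+.1f} N "
      f"(total {r['total_n']:.1f} N)")

s = summarize_translations(trial)
print(f"max |IS| translation {s.max_abs_is_mm:.2f} mm, max |AP| {s.max_abs_ap_mm:.2f} mm")
```

prints

```
converged 21/21 frames
joint reaction at 30 deg: compressive 260.1 N, AP -95.9 N, IS +109.2 N (total 297.9 N)
max |IS| translation 1.19 mm, max |AP| 1.26 mm
```

Every frame reaches force equilibrium below the 10 N threshold.  At peak
elevation the joint is compressed with 260 N — the total reaction of 298 N
falls inside the 200–400 N range measured in vivo with instrumented
prostheses at 30° abduction — and the humeral head wanders about a
millimetre in the glenoid plane, the scale seen in dynamic fluoroscopy.

## Analysis scripts

Numbered drivers under `analysis/` rerun the full study on the synthetic
subject and write their tables to `results/` (large per-frame output goes to
`scratch/`):

| script | what it does |
|---|---|
| `01_build_fixture.py` | builds/calibrates the fixture; ligament calibration table |
| `02_fdk_vs_default.py` | healthy 0 kg: FDK vs spherical-joint model, 3 cycles |
| `03_weight_battery.py` | 0–3 kg loads: joint compression and translation maxima |
| `04_tear_comparison.py` | healthy / partial / full supraspinatus tear battery |

A thin CLI wraps the same library calls: `glenofdk fixtures-make`,
`glenofdk run --config run.yaml`, `glenofdk batch --weights 0,1,2,3`,
`glenofdk compare`.

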