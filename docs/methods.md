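# Methods

## Problem setting

The package consumes per-frame 3D joint coordinates produced by monocular
human-pose-estimation backends and outputs joint-angle trajectories of a
humanoid skeleton. Three stages run in order: region-of-interest (ROI)
selection/tracking over object-detector records, link-length-based outlier
detection and correction, and per-frame inverse kinematics by global
optimization. Each stage is usable on its own.

## Coordinate conventions

Right-handed frame, origin at the pelvis center (midpoint of the hips),
+y up, +x toward the subject's anatomical left, +z toward the camera.
Trajectories are either metric (meters, pelvis-centered) or pixel-valued
(image frame); pixel link lengths are converted to centimeters via the
subject's pixel height and an assumed stature (defaults 175 cm male /
160 cm female population averages).

Anatomical rotation planes: sagittal θ (about x), coronal φ (about z),
transverse ψ (about y). Multi-DoF joints compose intrinsically in the
order sagittal → coronal → transverse, i.e. R = Rx(θ)·Rz(φ)·Ry(ψ); the
body orientation applies as Ry(ψ_bd)·Rz(φ_bd)·Rx(θ_bd) ahead of both
kinematic trees. All rotations are right-handed about their axes; with
the subject facing the camera, positive knee flexion moves the ankle away
from the camera and positive elbow flexion does the same for the wrist.
These composition orders and polarities are package conventions — the
skeleton could be parameterized many ways — and every consumer of the
angle files should treat them as the definition.

## ROI selection and tracking

First frame: drop detections below the confidence threshold (default 0.5),
drop non-person labels, keep the largest-area survivor. If nothing
survives, the threshold is halved and the selection retried down to a
floor of 0.05, below which the frame is declared subject-free. Later
frames: among person boxes, keep the argmax of confidence + IoU with the
previous selection. Boxes are half-open pixel rectangles so shared edges
are not double-counted; IoU is intersection/union with the 0/0 → 0
convention. Ties keep the first candidate in input order (determinism).
Frames with no person box hold the previous box for up to `max_gap`
(default 5) consecutive frames, then the track is declared lost.

## Outlier detection and correction

Ten links are monitored: shoulder line, pelvis line, and left/right upper
arm, lower arm, thigh, shin. Real limb lengths change smoothly with
perspective during motion; identity switches and misdetections produce
step changes. The detector differentiates each link-length series per
frame and flags a frame when any |Δlength| exceeds a threshold, default
10 cm/frame at 30 fps and scaled by 30/fps at other rates (the same
physical motion produces smaller per-frame steps at higher frame rates).
Flagged frames within `merge_gap` (default 2) frames merge into segments.
A segment where ≥ `switch_link_count` (default 4) links trigger on the
same frame is classed as a left/right switch — switches affect the whole
body, so all joints are corrected; otherwise it is a misdetection and only
the joints of the triggering links are corrected.

Correction replaces every affected coordinate in the segment with the mean
of the last clean frame before and the first clean frame after the segment
(at a sequence boundary the single available neighbor is replicated). A
running median filter (default window 5, odd; edges use a shrunken window)
then suppresses residual frame-to-frame jitter. The median filter is
implemented directly because the shrink-at-edges semantics is part of the
contract; library edge modes pad instead.

Known blind spot, by construction: a full-body switch of a bilaterally
symmetric pose changes no coordinates, hence no link lengths, and cannot
be detected. The threshold rule also cannot see corruptions whose induced
length change stays below threshold (e.g. a displacement nearly
perpendicular to a short link). The synthetic corruption generator can
produce both cases, which is how these limits are demonstrated rather than
hidden.

## Humanoid model

Two kinematic trees root at the pelvis center: pelvis → hips → knees →
ankles, and pelvis → (3-DoF waist at the pelvis center) → shoulder center
→ shoulders → elbows → wrists. The 26 joint DoF are: body orientation
(θ, φ, ψ), waist (θ, φ, ψ), neck (φ, ψ), shoulders (θ, φ, ψ × 2), elbows
(θ × 2), hips (θ, φ, ψ × 2), knees (θ × 2), ankles (θ × 2). The pose
vector optimized per frame has 21 entries: the size factor γ plus 20
angles (3 body + 17 joint angles); the remaining 6 DoF (neck pair, hip
transverse pair, ankle pair) are held at zero because wrists and ankles
are modelled as chain endpoints and the head is not among the compared
joints, leaving those rotations unobservable from the 12 fitted joints.

Link lengths default to standard anthropometric fractions of stature
(thigh 0.245, shin 0.246, upper arm 0.186, lower arm 0.146, trunk 0.288,
shoulder width 0.259, hip width 0.191; stature default 175 cm); every
length is individually overridable. γ multiplies all link lengths,
absorbing camera distance; its bounds are [0.5, 2.0]. Angle bounds default
to physiological ranges (knee [0°, 150°], shoulder sagittal [−60°, 180°],
etc.) and are configurable per variable.

### Identifiability

Because the body sagittal rotation Rx(θ_bd) is adjacent to the waist and
hip sagittal rotations in both trees, and the hips lie on the x axis
through the origin, the map (θ_bd, θ_ws, θ_hp^l, θ_hp^r) →
(θ_bd + δ, θ_ws − δ, θ_hp^l − δ, θ_hp^r − δ) leaves every joint position
exactly unchanged while δ keeps all four in bounds: θ_bd is a gauge
freedom, and only the sums θ_bd + θ_ws and θ_bd + θ_hp are identifiable
from positions. Similarly, the axial shoulder rotation ψ_sh is
unobservable when the elbow is straight (the lower arm lies on the
rotation axis) and weakly observable when slightly bent. Tests and
reported errors use medians across variables, which these flat directions
cannot dominate; users reading individual θ_bd/θ_ws/ψ_sh tracks should
keep the gauge in mind.

## uDEAS optimizer

Each variable is a binary row; a row of length d with integer value v
decodes to lo + (hi−lo)(v + 0.5)/2^d — the midpoint of one of 2^d equal
cells, strictly inside the bounds. This midpoint rule is the package's
decoding convention.

A *session* visits each variable once:

- **BSS** (bisectional search): append one bit — evaluate the two
  half-cell children, keep the better (ties keep the lower "0" child); the
  winning side sets the UDS direction.
- **UDS** (unidirectional search): step the row's integer value ±1 at
  fixed length, accepting while the cost strictly decreases; stops at the
  first non-improvement or range clamp. M = accepted steps.
- A row already at maximum length gets a same-depth neighbor probe plus
  UDS instead, so late sessions keep polishing; the local search ends when
  all rows are at maximum length and a full session brings no improvement.

The cost-sensitivity score of variable i in session j is

S(v_i^j) = ( |L_l − L_r| / |v_l − v_r|  +  Σ_{k=1..M} |L_{k−1} − L_k| /
|v_{k−1} − v_k| ) / (M + 1)

over its BSS pair and accepted UDS steps. With ordering "sensitivity"
(default) the next session visits variables in descending S; the first
session is always sequential. Ties break by variable index.

The global scheme is multistart: `restarts` (default 5) independent local
searches from random depth-`initial_depth` (default 2) matrices, seeded
deterministically; the best evaluated point across all evaluations is
returned, making the reported best cost monotone non-increasing within a
local search even when a BSS deepening lands on a worse cell midpoint.
Default maximum depth 12 gives a grid of (hi−lo)/4096 per variable
(≈ 0.06° on a 240° range).

## Pose fitting

The per-frame cost is the MPJPE over the 12 canonical joints between the
measured frame (re-centered to its pelvis midpoint) and the model's
forward kinematics; exact overlap gives zero. Because 21-dimensional
coordinate descent converges slowly along the correlated trunk/limb
valleys from arbitrary starts, `fit_frame` seeds the first restart with a
closed-form geometric estimate: γ from measured/spec link-length ratios,
body yaw/roll from the hip line (θ_bd gauge-fixed, then shifted so the
compensated sagittal angles fit their bounds), waist from trunk and
shoulder-line directions, hip/shoulder swing angles from limb directions
in their parent frames (both swing-decomposition branches tried, the one
reproducing the elbow and wrist better kept), knee/elbow flexion and
axial shoulder rotation from the distal segments. The remaining restarts
are random, preserving the multistart global scheme. In sequences each
frame warm-starts from the previous frame's solution (disableable); warm
starts are encoded at depth max_depth − 4 so the search can still refine
them, a compromise between keeping the information and freezing the row.

## Synthetic motion generator

Motion scripts assign each pose variable a sinusoid (amplitude, period,
phase, offset, degrees); defaults `rowing`, `back_chest` and `arm_leg`
emulate gym-style exercises with amplitudes of 10–60° and periods of
2–2.5 s at 30 fps, all inside the default bounds, plus `still`. Rendering
through the same forward kinematics yields exactly realizable targets, so
noiseless recovery error isolates optimizer behaviour. Corruptions:
left/right switches over frame segments (full-body or named pairs —
partial switches create cross-body links and large length jumps),
misdetection displacements of single joints, and Gaussian jitter (typical
σ 2–5 mm). Jitter is noise, not an outlier, and is excluded from the truth
mask. What this generator does not emulate: camera projection and depth
ambiguity, correlated (non-white) estimation noise, soft-tissue and
clothing artifacts, and backend-specific bias — so passing tests
demonstrate correctness of the algorithms under their stated model, not
end-to-end accuracy on real video.

## Numerical and design notes

- Tie-breaks everywhere are "first in input order" / "lower child" for
  determinism; identical seeds and configs reproduce identical histories.
- Problem sizes in the shipped checks: 20 random poses for recovery
  (depth 12, 5 restarts), 15 corruption trials for detector quality,
  12-frame sequences end-to-end; chosen to characterize behaviour while
  keeping a full run in minutes on one CPU.
- Degenerate inputs: zero-area boxes are legal (IoU 0); segments touching
  the sequence boundary replicate their single neighbor; a segment
  covering the whole sequence is an error; pixel trajectories without
  detections fall back to the vertical coordinate span for the subject's
  pixel height.
- The HybrIK-29 landmark map follows the SMPL joint ordering convention;
  the backend's own choice is undocumented, so the map is user-overridable.
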