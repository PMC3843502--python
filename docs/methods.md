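# Methods

`toewalk` simulates toe walking (equinus gait) with a planar eight-segment
biped under a two-level feedback control strategy, and reproduces the
"inhibitory casting" experiment in silico: a family of toe-walking gait
patterns is generated by gradually shrinking the ankle components of the
walking-premise parameter set and letting the closed loop settle at each
stage.

## The mechanical model

The biped is a sagittal-plane linkage of eight rigid segments — left and
right foot, shank and thigh, plus a pelvis and a torso segment — all
hinged at a common hip point.  Generalized coordinates are the planar hip
position and the eight *absolute* segment orientations
(counter-clockwise from the world vertical), `q ∈ R¹⁰`.  Seven joint
torques act on the relative joint angles (two hips, two knees, two ankles,
pelvis–torso) through a constant actuation matrix `B`; the three remaining
degrees of freedom (planar position + overall orientation) are unactuated,
as they must be for a legged system.

Support-phase dynamics follow the constrained Lagrangian form

    M(q) q̈ + C(q, q̇) q̇ + G(q) = B u + Γᵀ λ,     Γ q̇ = 0

where each ground contact is a *toe point* pinned to a world anchor (two
holonomic constraints; single support: 1 contact / 8 DOF, double support:
2 contacts / 6 DOF).  With absolute angles the Lagrangian terms have a
closed form in `cos/sin(θⱼ − θₖ)` with constant mass-moment matrices, so
the equations of motion are assembled exactly (no symbolic runtime
dependency) and are verified in the test-suite against a
numerical-Lagrangian oracle and, for 1–2 link reductions, against closed
forms and an independently derived symbolic model.

Touchdown is a rigid, perfectly plastic impact: positions are unchanged
and the post-impact velocity solves the impulsive KKT system that zeroes
the velocity of every active contact point; kinetic energy never
increases (tested over 1000 random states).  Take-off is impulse-free
constraint removal.  λ is reported as the force exerted on the biped *by*
the ground (vertical component ≥ 0 during valid contact).

### Anthropometry

No anthropometry is prescribed by the premise-parameter family itself,
so the defaults are a standard gait-analysis anthropometric table (mass fractions, COM offsets and radii of gyration per segment)
scaled to a configured body mass and stature, with every value
overridable in the model configuration.  Two defaults deserve comment:

* **Stature 1.60 m (mass 40 kg).**  The premise parameter sets are given
  in absolute centimetres (virtual-leg lengths up to 83.6 cm with ankle
  components of 5.6–9.4 cm).  A model whose thigh+shank is shorter than
  ~0.79 m cannot reach those lengths without driving the swing knee
  through its straight-knee singularity, where the leg-length control
  direction is lost.  At 1.60 m stature with thigh = shank = 0.26·H the
  leg workspace covers the whole family with a safe singularity margin.
* **Foot (ankle→toe-contact) segment 0.07·H ≈ 11 cm.**  The ankle
  component of the virtual leg is the projection of the toe→ankle vector
  onto the toe→hip axis.  For the printed components (5.6–9.4 cm) to
  correspond to an equinus (plantarflexed) foot, the toe-contact lever
  must be ~11 cm; a longer lever would force a dorsiflexed foot posture.

`L_leg,nominal` defaults to thigh + shank + 0.45·foot — the toe–hip
distance with the leg extended at the reference toe-walking ankle
posture.

## Virtual legs and the phase variable

The virtual stance/swing leg is the segment from a toe tip to the hip;
its length decomposes into an ankle component (projection of toe→ankle
onto the virtual-leg axis) and the knee component (remainder).  The
virtual-leg angle is measured from the vertical, **positive when the hip
is ahead of the toe**; with this sign the stance angle `q_st,v` increases
monotonically through stance — which is what makes it usable as the
phase variable — and the step-geometry relation

    L_step,d = 2 v_d / cad_d = (x_st − x_sw)|SS-start + 2 L_leg,nominal sin(q_st,v,d)

closes with a positive arcsin.  (Self-consistency of this relation shows
that `2 v_d / cad_d` is the *swing-toe travel per swing*, i.e. the stride
length, with cadence counted in steps per second.)

## Within-step control

Seven single-support outputs (gait premises) are zeroed by input–output
feedback linearization: inter-leg symmetry (`q_st,v + q_sw,v`, relaxed
from its take-off value by a fast exponential weight), swing-foot
clearance, stance virtual-leg length, pelvis angle, torso angle, and both
ankle components.  The last five are fourth-order polynomials in the
phase variable, each pinned by five conditions: value and slope at the
phase start taken from the take-off state (position/velocity continuity),
a user value at mid-phase (s = 0.5), and a user value and slope at the
phase end.  The 14 free conditions form the control-parameter set ζ; the
end slope of the stance-leg length is not free — the between-step
controller owns it.  Time-slopes are converted to phase-slopes through
the phase rate `ṡ = q̇_st,v / Δq` (take-off rate for start slopes, the
previous step's end-of-stance rate for end slopes).

The clearance reference is `z_sw,d = k1 · L_leg,nominal · b(s)` with
`b(s) = 16 s²(1−s)² + γ s²(1−s)` (γ = 1, k1 = 0.05): zero height and
slope at lift-off, a ~4 cm mid-swing peak, and a *transversal* descent at
s = 1 so the swing toe crosses the ground with finite speed exactly when
the phase variable reaches its touchdown target.  A symmetric bump would
graze the ground with zero vertical velocity — an event a crossing
detector cannot fire on (and with nothing for the plastic impact to
absorb); the descent term makes the hybrid event well posed.

In double support only six independent outputs exist (6 DOF); each
premise relaxes exponentially from an anchor (the double-support start
value for the symmetry row, the ζ end values for the rest).  Torques come
from the Moore–Penrose pseudoinverse of the 6×7 decoupling matrix — the
minimum-norm torque achieving the prescribed output accelerations.

The linearizing law needs the output Jacobian and the `L_f²h` bias term
exactly; these are computed with a small second-order forward-mode
differential type (each kinematic quantity carries value, time rate,
gradient and velocity-product bias), so the closed loop satisfies
`ÿ = −K_D ẏ − K_P y` to ~1e−13 (tested by substitution into the
constrained dynamics).

### Gains

`K_P = ω² I`, `K_D = 2ω I` (critically damped) per phase with
ω_ss = 20 s⁻¹ and **ω_ds = 0.5 s⁻¹**.  The asymmetric choice is
deliberate: the plastic impact leaves the double-support outputs with a
rate error of ~2 rad/s (the hip keeps moving while both feet are
pinned), and correcting it on a time scale shorter than the
double-support phase pitches the load onto the leading foot so hard that
the trailing leg unloads instantly — the double support collapses to
zero duration for any ω_ds ≳ 1.  At ω_ds = 0.5 the double support lasts
~4–5 % of the gait cycle per side, matching the clinical band layout,
and the deferred symmetry correction then happens at single-support
start, producing the characteristic hip-moment burst of this control
structure.  Exponential weight rates: w_ss = 20 s⁻¹ (asymmetry removed
within ~0.05 s of lift-off), w_ds = 0.1 s⁻¹ (the double-support anchors
creep by <0.5 % during the ~40 ms phase).

## Between-step control

Once per step the gait velocity is measured as hip travel over step
duration and the stance-leg end-lengthening velocity (push-off proxy) is
updated:

    L̇_st,v,end ← L̇_st,v,end + k_p (v_d − v) + k_d (v_prev − v)

with k_p = 0.2, k_d = 0.05 (m·s⁻¹ per m·s⁻¹).  Walking slower than
desired strengthens the next push-off.  The touchdown target
`q_st,v,d = arcsin[(L_step,d − (x_st − x_sw))/(2 L_leg,nominal)]` is
recomputed each step from the actual toe positions at single-support
start.

## Hybrid execution

Phases are integrated with RK45 (rtol 1e−7, atol 1e−9, max step 10 ms)
with root-located events: touchdown when the swing-toe height crosses
zero downward (enabled after a phase guard s > 0.25 so the just-lifted
toe cannot retrigger), take-off when the trailing-leg vertical contact
force crosses zero from above, plus fall events (hip below 0.45
L_leg,nominal, phase-variable reversal, event timeout).  Every fall is a
structured error carrying step index, phase and time.  Records are
sampled at 1 kHz; torques and ground reactions are recomputed on demand
from the stored control context, so long runs keep scalar step summaries
only.

A documented static-start routine poses the model at a single-support
start (stance toe planted, swing toe grounded behind, legs at the
nominal splay, premise-consistent posture) with joint rates solved by
constrained least squares so the stance toe is stationary, the hip moves
at the target speed and the symmetry output starts at rest.  The first
steps are transient; the settle criterion — the sample standard
deviation of the last N = 10 step velocities below ε = 0.01 m/s —
gates every schedule stage.  Cold starts settle in ~30 steps; parameter
transitions in ~10.

Schedules sub-divide every change between consecutive ζ columns into
m = 5 equal increments and settle at each one (the destabilization-free
gradual-transition regime).  The packaged schedule runs ~225 steps in
about two minutes on one CPU; the sustained-stability check continues
walking at the final set to >500 gait cycles (~1000 steps).

## Post-processing

A gait cycle for one leg spans its two consecutive steps (stance step +
swing step).  Joint moments are filtered with a zero-phase
forward-backward fourth-order Butterworth at 5 Hz (zero phase is the
gait-analysis convention; the filter itself is defined only by its order
and cutoff), then everything is resampled to the 101-point 0–100 % gait-cycle
grid with double-support/single-support/swing bands in % GC.  Clinical
sign conventions: hip and knee flexion positive, ankle dorsiflexion
positive; moments as hip flexion +, knee extension +, ankle plantar
flexion +, both raw and mass-normalized.  Scalar descriptors: peak stance
knee flexion, peak stance ankle plantar flexion, double-support fraction,
gait velocity, the two ankle plantar-flexion moment peaks (early/mid
stance 0–40 % GC and push-off 40–50 % GC) and the peak knee extension
moment.

## What the simulated experiment shows — and does not

With the default model, running the packaged five-column schedule yields
five settled gaits at the target velocity, all with the principal
toe-walking signature: toe-only contact, stance-phase ankle plantar
flexion, flexed knee and hip, a double-teeth ankle plantar-flexion
moment, and a pronounced knee extension moment.  Along the schedule the
stance ankle plantar flexion normalizes (peak ~27° → ~17°), the
push-off ankle moment peak grows (≈25 → ≈35 N·m, monotone over the
first four sets with a small final dip that mirrors the parameter
table's own partial reversal of the last ankle end-length), and the knee
extension moment decreases.

The knee *peak* behaves differently from the clinical expectation
(initial knee flexion falling from roughly 60° to below 40° after
casting): it is
dominated by an early-stance crouch (~10–15 % GC) whose size is set by
impact geometry — after touchdown the stance leg inevitably shortens as
the hip advances toward the planted toe — and is therefore nearly
independent of the parameter sets (~61–69° across the family).  The
premise-driven mid-stance knee flexion does decrease monotonically with
the ankle shortening (~57° → ~45°), which is exactly the geometric
mechanism the intervention encodes (constant virtual-leg length with a
shorter ankle component extends the knee), but with this model's
(necessarily guessed) segment geometry the crouch caps the stance peak
above 40°.  Other self-consistent segment-parameter and gain choices may
shrink the crouch further, but none of the ranges scanned here (leg and
foot lengths, double-support bandwidths per output row, target speed and
cadence) brings the peak below the mid-stance premise-driven value while
keeping a finite double support and a stable gait.

## Limitations

Sagittal plane only; toe-point contact (no heel-toe rollover); rigid
ground; torque actuators, not muscles; no joint limits (feasibility is
maintained by the premise parameters staying inside the leg workspace);
gait velocities well below ~0.9 m/s stall the double-support weight
transfer under the default double-support weights (the trailing-leg load
never reaches zero), so the default operating point is 1.0 m/s at 2.2
steps/s.  All simulated falls terminate runs with structured diagnostics
rather than exceptions from the integrator.
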