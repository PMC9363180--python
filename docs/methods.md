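# Methods

## Muscle–tendon model

Each of the four hip muscles (iliopsoas, rectus femoris, gluteus
maximus, hamstring — the last lumping semitendinosus, semimembranosus
and the long head of biceps femoris) is a Hill-type muscle–tendon unit:
a contractile element whose force is
F_CE = F_max·a·f_L(L̃)·f_V(Ṽ), a parallel elastic element engaging above
optimal fiber length, and a series elastic tendon carrying
F_T = (F_CE + F_PEE)·cos α.  Normalizations: fiber length by the optimal
fiber length L0m, fiber velocity by V_max (shortening positive), tendon
strain by the slack length, forces by F_max.

The active and passive force–length curves each admit two algebraic
readings; the package defaults to the forms that satisfy the physical
anchors below and exposes the alternatives as `CurveConfig` switches:

* `active_fl_form="peak-at-optimum"` (default): exp(−|(L̃^0.87 − 1)/0.39|^3.19),
  which has its unit peak exactly at L̃ = 1, as a curve normalized by the
  optimal fiber length must.  The alternative reading
  (`"peak-shifted"`, L̃/0.87 in place of L̃^0.87) peaks at 0.87.
* `passive_fl_form="offset"` (default): 0.0238·(e^{5.3(L̃−1)} − 1) above
  L̃ = 1, rising from exactly zero at its onset; `"no-offset"` drops the
  −1 and jumps to 0.0238 at onset.
* The eccentric force–velocity denominator constant is 30.24
  (`fv_lengthening_const`); branch continuity at v = 0 holds for any
  value.

The tendon is a linear curve reaching F_max at 3.3% strain
(`tendon_strain_at_fmax`), chosen because the inverse analysis requires
an invertible tendon law and 3.3% is the conventional strain-at-F_max
of stiff lower-limb tendons.  A slack tendon carries no force.

Metabolic power is P_ME = a·F_max·V_max·f_ME(Ṽ) with the two-branch
empirical rate factor (0.23 − 0.16·e^{−8Ṽ} shortening; 0.01 − 0.11Ṽ +
0.06·e^{23Ṽ} lengthening; both 0.07 at Ṽ = 0), integrated by the
trapezoid rule over the cycle.

## Hip geometry

The model is sagittal-plane only: the third coordinate of the pelvis
attachment points is dropped.  Defaults describe a 170 cm / 70 kg
subject: thigh link 0.434 m, single-joint insertion 0.210 m, and the
per-muscle attachment coordinates, moment-arm lengths, PCSA and
pennation shipped in `data/default_anthropometry.yaml`.  The hamstring
origin is a package default (an ischial-tuberosity-like coordinate),
since only the hamstring's moment arms are anatomically specified in
that set.
F_max defaults to σ·PCSA with σ = 55 N/cm² (mid-range literature
specific tension); V_max defaults to 10·L0m per second.  Default optimal
fiber length is 45% of the neutral-pose MTU length and tendon slack
length the remaining 55%, so at δ = η = 0 each fiber sits at optimum
with the tendon just slack.  Pennation defaults to 0 (fusiform
simplification); the measured pennations are retained in the
anthropometry for use when that simplification is switched off.

MTU lengths are origin-to-insertion distances over the planar two-link
chain (hip flexion δ rotates the thigh, knee flexion η swings the shank
backwards).  Biarticular muscles (rectus femoris, hamstring) insert
beyond the knee and depend on both angles; monoarticular lengths are
exactly invariant to η.  The straight-line path is a deliberate
simplification — it has no patellar wrapping, so the knee-angle
dependence of the rectus femoris length is qualitative only.

Joint moments use M = F_MUT·U(β) with U(β) = r·sin(β_eff) clamped to
[0, r].  The β1..β6 are calibration constants; by default each muscle's
β_eff varies affinely with its joint angle around the calibrated value
(slope `kappa_hip` = 1, sign chosen so flexor and extensor lines of
action rotate oppositely; biarticular muscles add a knee term scaled by
`kappa_knee` = 0.5 through the sine of their second β).  This is the
minimal extension that lets moment arms vary over the cycle;
`constant_beta=True` reproduces the constant-arm reading.  The net
moment convention is physiological (flexors positive, extensors
negative, flexion-positive δ); an alternate fixed index-sign
convention (+rectus +hamstring − gluteus − iliopsoas) is available as
`convention="literal"`.  The joint-level passive moment M_p is disabled
by default, so calibration attributes all moment to muscles unless the
user parameterizes it; when enabled it is a double-exponential
restoring moment outside a neutral band.

## Forward solve

Given kinematics and measured activations, each sample's fiber/tendon
split solves f_SEE(ε) = (a·f_L·f_V + f_PEE)·cos α.  In normalized form
this balance involves neither F_max nor the m/n scalings, and the β
angles only enter moment arms — so the fiber/tendon solution is
computed once per gait cycle (`solve_mtu_kinetics`) and any candidate
H = [β1..β6, m, n] is evaluated against it at negligible cost.

The balance is solved by vectorized bisection on fiber length (the
residual brackets a sign change between vanishing fiber length and a
slack tendon).  Fiber velocity must equal the periodic central
difference of the fiber-length trace; that fixed point is reached by a
short damped Picard warm-up followed by Anderson-accelerated iteration,
because plain relaxation oscillates for the long-tendon hamstring (the
steep eccentric force–velocity slope, 0.8·(1 + 30.24) near v = 0,
against a compliant tendon gives the Picard map a spectral radius near
one).  Tolerances: velocity consistency 1e−7 m/s; force-balance
residual 1e−8·F_max (the final bisection runs at the converged velocity,
so the achieved residual is at machine precision).

## Calibration

**Stage 1 (H).**  Objective: body-mass-normalized RMSE between the model
net moment and the reference hip moment; bounds β1 ∈ [12°, 120°],
β2, β6 ∈ [12°, 145°],
β3 ∈ [60°, 180°], β4, β5 ∈ [35°, 165°], m, n ∈ [0.5, 1.5].  The default
optimizer is an in-house real-coded GA (population 60, 150 generations,
tournament selection, blend crossover, per-gene gaussian mutation with
probability 1/9, elitism 2, fixed seed), followed by a bounded
least-squares polish (scipy TRF) on the per-sample residuals.  The
polish matters: the RMSE surface has a curved, shallow valley along
which the force scalings trade off against the β angles, and the GA
alone stops with m biased by several hundredths at RMSE below 1e−3
Nm/kg, while the least-squares step descends to the exact minimum.
scipy's differential evolution is available with `method="de"`.  RMSE
is reported both raw (Nm) and normalized (Nm/kg); r² is the squared
Pearson correlation by default (a curve-similarity reading), with the
coefficient of determination as a flag.

**Stage 2 (I).**  For each muscle independently, the stage-1 tendon
force trace is inverted through the tendon curve to fiber kinematics;
activation is back-solved sample by sample; candidate optimal fiber
lengths on a 201-point grid over [0.6, 1.4]·L0m (refined by repeated
grid trisection; the final step is the reported search resolution) are
filtered by feasibility 0 ≤ b(t) ≤ 1.  Three selection objectives:

* `"match"` (default): minimize the RMS difference between reconstructed
  and measured activations.  This is the criterion the calibrated model
  is judged by (per-muscle activation r²/RMSE against the measured
  curves) and the only objective that recovers the generating fiber
  length on model-consistent data.
* `"min-bmin"`: minimize the cycle-minimum activation.  Because passive
  fiber force grows as L0m shrinks, this objective provably selects the
  smallest feasible fiber length — the point where passive force just
  covers the lowest-demand sample — systematically below the generating
  value; it is retained as the literal minimum-activation objective.
* `"max-margin"`: maximize the distance of the trace from both bounds.

## Synthetic gait

The generator emulates one normal walking cycle on a uniform 101-point
grid over 0–100% GC with a 1.1 s cycle (both are package defaults, not
claims about any particular dataset).
Hip angle: two half-sine segments pinned to the extension window
(default 30–65% GC, −12° peak extension, +30° peak flexion), so δ < 0
exactly and only inside the window — a piecewise construction chosen
over a truncated Fourier series because the window-sign property is
exact by construction.  Knee angle: two positive bumps (15° stance, 60°
swing).  Hip moment: biphasic, extensor-negative in early stance and
flexor-positive around 52% GC, peak scale 50 Nm.  Activations: gaussian
bursts in circular phase at physiological timings (gluteus maximus 10%,
hamstring 3%, iliopsoas 58%, rectus femoris 62% GC; peaks 0.45–0.6) on
a 0.02 tonic floor.  Optional multiplicative gaussian noise applies to
the hip-moment channel only, preserving periodicity.  All channels are
periodic to machine precision and deterministic for a fixed seed (one
`numpy` Generator per call; no global state).

What the generator does **not** emulate: measured inter-subject
variability, EMG noise and crosstalk, non-sagittal kinematics,
double-support asymmetries, and any correlation structure between
moment and activation errors.  Passing tests on this input demonstrates
the correctness and internal consistency of the pipeline, not the
fidelity of the model to any particular subject.

`generate_from_model` replaces the moment channel with the forward
model's output at known parameters, giving ground truth for the
recovery experiments; by construction the recovery experiments are
self-consistent (stage 1 fits with the same nominal fiber lengths used
to generate).

## EET assistance analysis

The spring engages only in extension: M_J = J·|δ| for δ < 0, else 0
(flexion-assisting).  With M_T the unassisted flexor-group moment:
M_Re = max(M_T − M_J, 0) and M_Ex = min(M_T − M_J, 0), one expression
with complementary branches, both defined and continuous at the switch.
The flexor demand M_Re and the extensor demand (baseline + |M_Ex|) are
split within each group in proportion to the muscle's unassisted share
at the same sample (moment-arm ratio where a group's baseline vanishes);
the additive update form is exact at zero stiffness, so J = 0
reproduces the baseline bit for bit.  Forces are recovered through the
moment arms as baseline-anchored deltas (finite where the calibrated
arm vanishes, floored at 1 mm); activations are re-back-solved and
reported unclipped (values above 1 flag infeasible demand; metabolic
integration clips to [0, 1]).

MDC (muscle moment distribution coefficient) is defined here as the
within-group share of the time-integrated absolute
moment over a window (default: the spring-engaged window; any window
and the full cycle are available), which is unit-free, lies in [0, 1],
and sums to 1 per group.  Work components integrate F·V over the cycle
at the MTU, fiber, and tendon levels (MTU = fiber + tendon by the
series decomposition; a periodic elastic tendon nets ≈ 0 J), plus the
hip-joint work ∫M_bio·δ̇ dt and a **knee proxy** — biarticular muscle
force times knee-level moment arms times knee velocity — reported in
place of a knee-joint work the model cannot compute without knee muscle
mechanics.  The default sweep is J ∈ {0, 50, 100, 150, 200, 250, 300,
350, 400, 500, 600, 800} Nm/rad.

## Problem sizes and numerical defaults

One gait cycle of 101 samples; GA 60×150 with least-squares polish
(test-time calibrations use a 24×30 GA, which the polish compensates);
the acceptance script uses a 40×60 GA.  Stage-2 grid: 201 points plus
three 41-point refinement rounds.  Bisection: 52 iterations on the full
bracket, 30 when warm-started.  All tolerances as given above.

## Known limitations

* Planar geometry with straight-line muscle paths; no wrapping surfaces
  or via points, so biarticular knee coupling is qualitative.
* No excitation→activation dynamics, fatigue, or history dependence.
* The β-affine moment-arm model is a one-parameter-per-joint-angle
  approximation of the true arm-angle relationship.
* Activation-driven inverse analysis only: no forward dynamics, ground
  reaction forces, or balance constraints.
* The knee work entry is a proxy, and the joint-level passive moment is
  disabled unless parameterized by the user.
* Reported assisted activations can exceed 1 at high stiffness; the
  package reports rather than redistributes such infeasible demand.
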