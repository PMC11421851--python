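# Methods

## Model overview and assumptions

The package treats motor cortex as a generic input-driven dynamical system:
an N-unit recurrent rate network whose readout drives an effector, with all
task knowledge carried by an exogenous input trajectory `u(t)` chosen by an
optimal controller. Nothing in the network (weights, readout, baseline) is
tuned for the task; preparation, when it appears, is purely a property of
the optimal control solution. The delay duration is assumed known to the
controller (the objective is deterministic); stochastic-delay variants are
out of scope.

Time is in milliseconds throughout the neural dynamics; the effector halves
of the state (joint angles/velocities, or the toy output) integrate in SI
seconds. The full trial spans `[−Δprep, T]` with the go cue at t = 0, and
inputs are allowed over the whole window.

## Plants

**Inhibition-stabilized network (ISN).** Excitatory columns (80% of units)
are sparse (connection probability 0.2) with log-normal weights
(σ_ln = 1, mean-one shape, 1/√N scale); inhibitory columns are denser
(probability 0.4) and initialized to balance the mean excitatory input per
row. The whole matrix is rescaled so the initial spectral abscissa equals
`exc_scale` (default 2.5 — a strongly coupled, linearly unstable starting
point roughly 3× beyond the stability line). Inhibitory entries are then
optimized by gradient descent on the squared H2 norm of the shifted system
`A = W − sI` (gradient `2QP` from the controllability/observability
Gramians, backtracking line search, nonpositivity projection, fixed
sparsity pattern) until the spectral abscissa of `W` falls below 0.8.
The shift sits a margin of 0.1 above the current abscissa: on N=100
fixtures this small margin both converges fastest and best preserves the
network's transient amplification (peak energy amplification ~150 versus
~90 at margin 0.3), which is the point of stabilizing by reshaping
inhibition rather than uniformly weakening the coupling. "Spectral
abscissa" here means max Re eig(W), so the continuous-time dynamics
(−I + W)/τ are stable whenever it is below 1.

**Baseline.** Target resting rates are drawn Gaussian (5 ± 5 Hz), rectified
at zero, and iteratively rescaled so the sample moments match as closely as
rectification allows; `h = (I − W) r*` then makes `x* = r*` an exact fixed
point under the rectified-linear nonlinearity.

**Readout.** Entries are zero-mean Gaussian. Two scale conventions are
implemented: the default σ_C = 0.05/√N, under which independent 30 Hz rate
fluctuations at N = 200 decode to torques of s.d. ≈ 1.5 N·m, and a
`convention="literal"` alternative σ_C = 0.05/N. The two differ by √N and
the source material is internally inconsistent about which is meant; we
note that the literal scale pushes the optimally controlled network into a
~20 Hz movement-epoch rate regime (versus ~2 Hz for the default) at the
price of a lower preparation index. Torques are read out from rate
*deviations*, `m = C(r − r*)`: with the raw readout `C r` the baseline
torque is nonzero and the arm drifts about a centimeter during the delay,
so the deviation convention is the only one in which rest is an equilibrium
of the coupled network–arm system.

**Two-unit motifs and ensembles.** The feedforward motif `W = [[0,0],[w,0]]`
(source unit 0 feeding sink unit 1) and oscillatory motif
`W = [[0,−w],[w,0]]` use the identity nonlinearity and a unit-norm 1D
readout at angle θ_C. Unstructured ensembles: i.i.d. Gaussian entries with
s.d. R/√N (circular-law radius R ≤ 0.99), skew-symmetrized versions
(R ≤ 5), and diagonally shifted skew matrices (+λI, λ ≤ 0.8).

## Effectors

The planar two-link arm uses the standard rigid-body form
`m = M(θ)θ̈ + X(θ,θ̇) + Bθ̇` with L₁ = L₂ = 0.30 m, I₁ = 0.025,
I₂ = 0.045 kg·m², M₁ = 1.4, M₂ = 1.0 kg, D₂ = 0.16 m and symmetric joint
friction B = [[0.05, 0.025],[0.025, 0.05]] N·m·s; no gravity, no joint
limits. The initial posture is unstated in the source; we place the hand at
(0, 0.30) m in shoulder coordinates via the elbow-down inverse-kinematics
branch, with the 8 radial targets on a 12 cm circle converted to joint
angles on the same branch (both configurable). The toy effector is a 1D
double integrator driven directly by the readout, ÿ = Cx.

## Cost functionals

All objectives share the urgency-weighted target term (weight t²/T²),
a delay-epoch stillness term, and a quadratic effort term, each normalized
by the movement duration (and the effort term additionally by the unit
count) so weights are comparable across tasks. Defaults follow the
parameter table: single reaches α_null = 1, α_effort = 5·10⁻⁷, Δprep =
300 ms, T = 900 ms; toy task α_effort = 10⁻⁵, Δprep = 500 ms, T = 2000 ms,
y* = 20; sequences α_null = 10, α_pause = 100, first-reach window 300 ms,
pause 600 ms (double) or 6 ms (compound), T = 1400 ms (the printed 1406 ms
rounded to the 10 ms solver grid). The sequence objective restarts the
second target's urgency clock when the enforced hold ends; its extra terms
reuse the single-reach normalization so the printed weights keep their
meaning. The stillness term uses the torque for the arm task and the output
acceleration for the toy task, exactly as specified. Discretization: stage
costs are Riemann sums at the solver step, the go-cue sample belongs to the
movement epoch, and the final sample contributes the terminal target term.

## Trajectory optimizer

Standard iLQR with Gauss–Newton cost expansions. The dynamics are Euler
maps at dt = 10 ms for the high-dimensional arm task (τ/15) and dt = 1 ms
for the 2D toy task; inputs enter only the neural block with constant gain
dt/τ, which the backward pass exploits. Regularization is applied through
the value function (μ added to V_xx), with the schedule ×2 up / ÷1.6 down
on [10⁻⁹, 10⁹]; a failed Cholesky of the control Hessian raises μ and
retries, never fails silently. The forward pass backtracks over step
lengths 1, ½, …, 2⁻¹⁰ and accepts any strict cost decrease; convergence is
declared when the expected improvement or the realized relative decrease
falls below 10⁻⁶. The rectified-linear derivative at exactly zero uses the
inactive side (0); u_init = 0 ("no control"), and seeds never enter the
solver. The toy problem is exactly linear-quadratic, so the optimizer
reaches the global optimum in one accepted iteration; the exactness of the
backward pass is tested against an independent finite-horizon Riccati
recursion at 10⁻⁸ relative cost.

## Preparation metrics

The preparation index is the ratio of summed squared input norms, delay
epoch over movement epoch (epochs split at t = 0, go-cue sample counted as
movement); it is undefined (explicit error) if the movement epoch carries
no input. Gramian summaries use the identity-nonlinearity linearization
A = (−I + W)/τ, with B = I: α divides the nullspace-restricted trace of Q
by the nullspace dimension and β divides the readout-restricted trace of P
by the readout dimension (the printed divisors N−2 and 2 generalized to
N−k and k for k-output readouts). The α/β → preparation-index model is an
ordinary least-squares fit on z-scored predictors with five-fold
cross-validated R², plus single-predictor ablations; transfer to other
network families applies the ISN-trained fit without refitting.

## Subspace analysis

Trial-averaged rates are soft-normalized (divisor = range + 5 Hz) and
mean-centered across conditions at each time bin (per-time centering is the
default; the covariance convention is configurable). Preparatory activity
is the 300 ms before delay end; movement activity the 300 ms starting 50 ms
after the go cue. The two six-dimensional bases maximize the sum of
normalized captured variances subject to mutual orthogonality, optimized by
projected gradient ascent on the joint Stiefel frame (QR retraction,
adaptive step, spectral initialization plus 10 random restarts, best
objective kept); the normalizers Z(d) are top-d eigenvalue sums of the
epoch covariances. Occupancy is the across-condition variance of projected
activity summed over basis dimensions, optionally peak-normalized per
curve. Movement onset is the first hand-speed crossing of 5% of peak speed
plus a 120 ms lag. Subspaces for the sequence analyses are fitted on single
reaches plus the first reaches of double sequences only.

## Problem sizes

The test suite exercises the full default plant (N = 200, 8 targets,
delays 0 and 300 ms) once per session and reuses those solutions for the
cost, preparation and subspace checks; sequences use two target pairs in
both double and compound variants. The α/β sweep runs N = 48 ISNs over a
3 × 3 grid of coupling strengths (1.5, 2.5, 3.5) and time constants (100,
150, 200 ms) with two seeds each, two targets per network, plus six
transfer networks — a deliberately reduced rendition of the full ensemble
study whose size is recorded in the output tables. The acceptance script
solves the full 2D motif grid exactly and the N = 200 task for three
network seeds × 8 targets at the 300 ms plateau onset.

## What the generator emulates, and limits

The synthetic networks reproduce the *stated* construction: Dale's law,
sparse log-normal excitation, optimized inhibition to abscissa < 0.8,
5 ± 5 Hz baselines, random readouts, and the printed task hyperparameters.
They do not reproduce unprinted details of the original ensemble — the
exact initial weight variance, inhibitory density, and readout scale
convention — and several headline magnitudes are sensitive to exactly
those details. In our reconstruction the qualitative structure is robust
(source-readout motifs do not prepare, sink-readout and oscillatory motifs
do; sink readouts are ~1.5× cheaper; the ISN's preparation index rises with
delay and plateaus beyond ~300 ms while total cost falls; preparatory
occupancy peaks before each movement of a sequence), but the plateau level
of the preparation index, the motif index magnitudes, and the captured-
variance fractions differ from the originally reported values (see the
acceptance outputs for the numbers this code actually produces). Passing
tests therefore certify the method and the qualitative phenomena, not
agreement with any particular recorded dataset.

A specific numerical caveat: with a purely quadratic effort penalty and no
input-smoothness term, the optimal input develops a near-impulsive
output-null "charging" component in the last few solver steps before the
go cue. The preparation index of the high-dimensional task then depends on
how this near-impulse straddles the epoch boundary and is therefore
sensitive to the discretization step (we measure roughly 0.3 / 0.8 / 1.1 at
dt = 5 / 10 / 15 ms for the default plant) and correspondingly insensitive
to the network time constant and connectivity family. All reported
high-dimensional indices use the package default dt = 10 ms. The 2D toy
task does not share this fragility (its indices move by ~10% between
dt = 1 and 2 ms).

Other known limitations: no muscle model or sensory feedback; no joint
limits; quadratic input penalties only (no input-derivative penalty); the
optimizer finds local optima (global only in the linear-quadratic toy
task); and movement-onset detection assumes a unimodal speed rise per
reach.
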