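# Methods

## Model

`xbridge` simulates the chemo-mechanical cycle of skeletal-muscle myosin II
heads interacting with an actin filament. Each available head sees one
binding site per 36-nm actin target-zone repeat; the head–site offset x is
distributed uniformly over the repeat, and a head attached in state j
exerts the linear elastic force k_s (x − x_j), where x_j is the position of
that state's free-energy minimum and k_s = 2.8 pN/nm is the cross-bridge
stiffness. Heads are independent of one another except through the shared
filament position.

The cycle has seven states. Five are attached — the pre-power-stroke state
AMDP_PP, the Pi-release state AMDP_PiR, the low- and high-force ADP states
AMD_L and AMD_H flanking the main power stroke (first sub-stroke
d1 = x11 − x2), and the lumped rigor/ADP state AM/AMD reached by a second
sub-stroke (d2 = x2 − x3) that confers strain sensitivity to ADP release —
and two are detached (MT after ATP-induced detachment, MDP after the
recovery stroke and hydrolysis). The weakly bound first encounter state
carries no free-energy drop and is absorbed into MDP.

Attached-state free energies are harmonic wells,
G_j(x) = G_j^min + k_s (x − x_j)² / (2 kBT), with successive minima dropping
by ΔG_on, ΔG_PiR, ln(KC/[Pi]), ΔG_AMDL−AMDH and ΔG_AMDH−AMD along the
cycle; detached states are flat, with MT sitting ln(K3) above MDP. Every
reversible transition obeys detailed balance against these diagrams:
log(k_fwd/k_rev) equals the free-energy gap at every x (a property-tested
invariant, tolerance 1e-9 kBT). Strain-dependent forms: attachment uses a
transition state halfway into the well (strain/ (4 kBT) exponents); entry
into the Pi-release state uses half-stiffness strain terms; the power
stroke and the second sub-stroke have constant reverse rates (2000 s⁻¹)
with forward rates fixed by detailed balance; Pi release is
strain-insensitive with reverse rate kP+ [Pi]/KC; ATP-induced detachment
saturates hyperbolically in [MgATP] with k2(x) growing as
exp(k_s |x − x3| x_crit / kBT). For numerical stability every rate is
clamped to [1e-6, 1e5] s⁻¹ for isometric work and [1e-6, 1e6] s⁻¹ during
shortening. The AM/AMD → MT step is irreversible because [MgADP] = 0.

Two published reverse-rate conventions are internally inconsistent with
detailed balance; the package implements the consistent forms and keeps the
literal ones behind flags (`as_printed`, `use_x1`) purely to document the
discrepancy. kBT is always derived from the solution temperature
(0.0138065 pN nm/K), never fixed at 4 pN nm.

## Parameter sets and modifiers

Presets ship as YAML under `xbridge/data/`: a *standard* 30 °C set
(x1 = 7.2, x11 = 6.7, x2 = 1.0, x3 = 0 nm; ΔG split 14/2 kBT;
kon′ = 130 s⁻¹) and an *optimized* set (x1 = x11 = 0, x2 = −5.5,
x3 = −7.7 nm, i.e. d2 enlarged from 1.0 to 2.2 nm; split 12/4 kBT;
kon′ = 325 s⁻¹) at 30/22/15/5 °C, the colder columns scaling kon′, the
hydrolysis sum and ratio, k2, the Pi-release-entry prefactor and
ΔG_AMDL−AMDH. Only differences of x positions enter any formula, so each
preset carries its own origin.

Modifiers are sparse field overrides encoding drug mechanisms: amrinone
(ΔG_AMDH−AMD reduced to 25%), blebbistatin (kPr′ 3000 → 5 s⁻¹), omecamtiv
mecarbil (ΔG_PiR 1 → 6 kBT, ΔG_AMDL−AMDH → 0), and [MgATP] changes. Scan
helpers (`set_x2`, `set_dG_split`, `set_kon`, `scan_grid`) build parameter
grids for sub-stroke and energy-split sensitivity studies; every derived
set is re-validated (positivity, x1 ≥ x11 ≥ x2 ≥ x3).

## Steady-state backend

At sliding velocity v the conditional state probabilities p_j(x) obey
v dp/dx = Qᵀ(x) p over one 36-nm repeat with periodic boundary conditions
(a head leaving the window at the low-x end re-enters, in the same state,
at the next site). At v = 0 each offset is an independent Markov chain and
p(x) is the null-space vector of the local generator.

The sliding equation is integrated by interval-wise matrix exponentials of
the generator evaluated at interval midpoints (default step 0.1 nm).
Because each factor expm(Qᵀ h/v) is a stochastic matrix, the scheme is
unconditionally stable, exactly conservative and positivity-preserving no
matter how stiff the capped rates make the problem, and the periodic
steady state is obtained *without shooting iterations* as the eigenvector
of the one-period propagator at eigenvalue 1. Accuracy is second order in
the step; halving the step moves V0 by well under 1% (tested).

Observables average over the repeat: mean force per available head uses
the numerator window [x3 − 9, x3 + 14] nm over the 36-nm denominator (the
conventional reduction; `window="full"` integrates the whole period, which
differs only near V0 where dragged heads cross the window's lower edge,
by ~2% in V0), and the ATP turnover per head is the probability flux
through the detachment step (equal, at steady state, to the hydrolysis-step
flux — a tested identity). V0 is found by bracketing bisection of the mean
force in v (tolerance 1–5 nm/s).

## Monte Carlo backend

Finite ensembles are simulated with the Gillespie algorithm: exponential
waiting times in the total propensity, events chosen proportionally to
propensity, propensities being the clamped rate functions at each head's
current strain. Heads start detached, equilibrated between MT and MDP
(odds 1 : K3), at uniform random offsets.

Three run modes:

* **isometric** — the filament is fixed, so heads are statistically
  independent and are simulated head-by-head with no approximation.
* **ramp** — after an isometric equilibration (default 0.5 s, insensitive
  to doubling) the filament position decreases at constant velocity. Heads
  remain independent because X(t) is prescribed; propensities are frozen
  over displacements ≤ 0.1 nm, with null events when the drawn waiting
  time overshoots. Rate caps switch from isometric to shortening at ramp
  onset; detached heads re-wrap modulo 36 nm.
* **unloaded** — after every transition the filament is repositioned so
  the total elastic force is exactly zero (closed form for explicit
  kinetics, bracketed bisection when the rapid-equilibrium node makes the
  force locally non-affine; residual < 1e-11 pN at every sample). All
  heads' propensities are refreshed whenever the filament has moved 0.05 nm
  since the last full refresh. The unloaded velocity is the fitted slope
  of X(t) over the recorded window.

Two treatments of the very fast main power stroke are available. The
default simulates AMD_L and AMD_H explicitly with the same capped rates
the steady-state backend integrates; at N = 3000 the two backends then
agree to better than 2% in force per head and V0 and within run-to-run
intervals along the FV curve (random head placement alone leaves a
~2%/√runs between-run spread even at N = 3000). The optional
rapid-equilibrium node (`lump_powerstroke=True`) collapses the pair into
one state whose split is the fast-equilibrium ratio of the *capped*
forward/backward rates and whose exits are split-weighted; it removes the
fastest events but slightly over-weights AMD_H during rapid sliding, where
the true population lags its local equilibrium (~4% force bias at
intermediate velocities). The published small-ensemble results this
package reproduces were generated with the lumped treatment, so the canned
protocols use it.

Between-run variability of the attached-head count at fixed N follows
Bin(N, p) with p ≈ 5/36 (one ~5-nm favourable stretch per repeat);
`binomial_attachment_stats` gives the exact moments and the
√(Np/(1−p)) signal-to-noise ratio, and a chi-square test confirms the law
on simulated runs.

## Canned protocols

`isometric_force_ensemble` reproduces the small-ensemble isometric force
assay: N drawn uniformly per run from a small range (e.g. 16–19 or 33–39),
0.5 s equilibration, 1.0 s of sampling at 25 ms (40 samples/run), grand
mean of run means with a 95% t-interval.

`small_ensemble_fv` reproduces the ~100-head FV assay: V0 from three
unloaded runs; the isometric point from ten runs; loaded points from
iso-velocity ramps at {5, 12, 22, 35, 50, 65, 80}% of the measured V0, two
runs each, ramp amplitude max(36 nm, 0.1 s × v) with ~31 samples per ramp;
*all* ramp samples are averaged, so the isometric-to-shortening transient
is part of the assay definition. The Hill hyperbola is fitted to the
loaded points plus the unloaded (F = 0) point, excluding the isometric
point. Ramp amplitude/duration per velocity is the one genuinely open
protocol choice; at ≤ 0.1 mM MgATP the ATP-limited detachment stretches
the post-onset relaxation over ~80 nm of sliding, so with one-repeat ramps
the low-[MgATP] curvature ratio is transient-inflated relative to a
steady-state reduction (discarding the first two repeats instead
reproduces the low-[MgATP] behaviour but under-curves the physiological
conditions; no single amplitude choice matches all three published
conditions simultaneously).

What the stochastic generator emulates: single-site target zones, rigid
filaments, independent single heads, uniform offsets. What it does not:
multiple accessible sites per target zone, filament compliance,
two-headed/inter-head cooperativity, viscous damping — so quantitative
agreement of a passing test speaks to the model as specified, not to every
feature of a real gliding assay.

## Hill-equation analysis

`HillModel` fits (F + a)(V + b) = b(F0* + a) by least squares with
residuals in velocity (velocity as the response; force is the controlled
coordinate in these assays; force residuals are available), positivity
enforced by log-parameterisation, initialised at a = 0.25 max F,
b = 0.25 max V, F0* = measured F0. Windows: all points, forces below
0.8 F0, or excluding the isometric point. Derived quantities: V0 = bF0*/a
(an exact identity of the result object), curvature ratio a/F0* (smaller =
more curved) and deviation ratio F0*/F0. A fit is flagged degenerate when
a/F0* > 5 or the Jacobian is rank-deficient — the behaviour of near-linear
FV data from very small (≲ 20-head) ensembles, which do not yield a usable
hyperbola. `power_curve` reports P = F·V with a local quadratic refinement
of the discrete maximum.

## Numerical and degenerate-input choices

* Generator rows sum to zero to machine precision; stationary solves
  reject generators without a one-dimensional null space.
* The detached-only limit (kon′ → 0) makes the generator reducible; the
  physically relevant distribution is the long-time limit from the
  detached start (tests march the master equation explicitly).
* Unloaded runs with no attached head hold the filament until the next
  attachment.
* Ramps shorter than one 36-nm repeat warn: head-placement noise then does
  not average out within a run.
* Identical seed + configuration reproduces trajectories bit-for-bit; all
  multi-run protocols derive per-run seeds from one root seed.

## Known limitations

Linear cross-bridge elasticity only (the non-linear alternative would
mainly raise V0); a single actin site per repeat (real target zones may
offer ~2, roughly doubling attached counts at a given N); no transient
(length-step) analysis; the absolute V0 of the standard parameter set sits
below the fast-muscle experimental range, consistent with the linear
elasticity assumption; amplitude details of the published ramp protocol
are unprinted, so the low-[MgATP] curvature ratio depends on a
reconstruction choice (see above).
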