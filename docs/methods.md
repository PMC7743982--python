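# Methods

## Model formalism and conventions

The package analyses piece-wise linear differential-equation (PLDE)
systems with state-dependent switching. Amounts are molecule counts;
first-order rates are s⁻¹ and production rates molecules·s⁻¹ (the bundled
model's source table prints production constants as s⁻¹; we read them as
molecules·s⁻¹, the only dimensionally consistent choice, and record that
reading in the field descriptions). The stress intensity `R` is
dimensionless (a.u.), constant within a run, and scales flagged
first-order rates by `(1+R)`.

**Threshold convention.** A switching variable is 1 exactly *at* its
threshold (`Z = 1 ⇔ x ≥ θ`). Every component — domain labelling, event
relabelling, region side conditions ("above" includes the threshold,
"below" is strict) — uses this single convention.

**Generic schema.** Any number of variables and thresholds is supported;
the bundled module's 12-domain structure (2×3×2) is derived from its four
thresholds, not hard-coded. Rate terms are restricted to production,
first-order loss and paired mass transfers; the transfer-pairing check
guarantees transport moves mass instead of creating it, which yields the
reduction identity d(M+N)/dt = p₂* − d₂(1+R)(M+N) used as a test oracle.
Model validation also enforces that every resolved coefficient stays
positive in every domain (for the bundled model this encodes k₁₀ > k₁₁:
PTEN throttles transport but cannot reverse it).

## Closed-form propagation

Within a domain, `x(t) = x* + e^{At}(x₀ − x*)`. The runtime path uses the
spectral decomposition of `A` (vectorised over time), falling back to the
exponential of the augmented homogeneous system `[[A, b], [0, 0]]` when
`A` is singular or its eigenvector matrix is ill-conditioned (condition
number above 1e10). The fallback has no special cases, so repeated or
collided eigenvalues degrade nothing. The bundled module's per-variable
textbook solution (scalar exponentials for p53 and PTEN, a
variation-of-parameters bi-exponential for the MDM2 pair) is kept in the
test suite as an independent oracle, not as the runtime path, so the
engine stays model-agnostic; agreement is verified to 1e-12 relative and
against adaptive integration at rtol 1e-12 to 1e-8 relative.

## Switching times and event location

Variables whose within-domain dynamics are scalar first-order get the
logarithmic crossing time, with the four-case analysis: starting at the
focal point (never), focal point exactly on the threshold (approached but
never crossed, reported as "never" with a distinguishing tag), opposite
sides (finite log-formula time), same side (never). Equality in these
case tests uses relative tolerance 1e-12.

The general crossing search samples the closed-form trajectory at a step
of 1/20 of the fastest relaxation time, brackets the first sign change,
and polishes the root with Brent's method to 1e-6 s. A trajectory within
1e-9 relative of its focal point with no sign change is declared
non-crossing. A sampled search can in principle miss a sub-step grazing
double crossing; for the bundled module the monitored scalar variables
are monotone within a domain and the bi-exponential has at most one
interior extremum several sampling steps wide, so the step is adequate by
construction.

## Hybrid simulation

Between events the state follows the exact closed form; at an event the
state is advanced exactly onto the threshold, the crossed variable is set
to θ bit-exactly, and the domain label is recomputed (≥ convention). No
hysteresis band is used. Degenerate situations are resolved by *probing*
the closed-form solution at small times (10⁻⁶ to 1 sampling step): a
state sitting on a threshold joins the side its flow actually enters.
If that zero-advance resolution revisits a domain, the point is a
singular corner where the one-sided flows circulate — a stationary point
in the Filippov sense — and the simulator holds it, unless the two
one-sided normal velocities push into the threshold from both sides with
finite magnitude, which is genuine sliding and raises a chattering
diagnostic naming the threshold (sliding dynamics are deliberately not
regularised or implemented; the bundled module's trajectories cross
transversally). An event-storm guard (default 10³ switches per simulated
second) backs this up.

Default output cadence is 600 s plus all event instants, matching
multi-day horizons with ~10⁴–10⁵ s oscillation periods.

## Oscillation detection

The first min(50 % of the run, 5·10⁶ s) is discarded as transient (the
slowest relaxation rate of the bundled module is d₃ = 3·10⁻⁵ s⁻¹, so this
covers dozens of relaxation times). Classification: *fixed point* if every
post-transient relative amplitude is below 10⁻³; *limit cycle* if at least
five intervals between successive upward crossings of the reference
threshold agree within 1 % (the period is their mean); otherwise
*undecided* — never a forced classification. The reference threshold
defaults to the p53 threshold θ_P, on which both oscillation-organising
singular points sit; exact event times are used for the crossings when
available, interpolated samples otherwise.

## Stationary analysis

**Transition graph.** One directed edge per domain, to the domain holding
its focal point; self-containing domains are sinks (RSP candidates),
directed cycles are limit-cycle candidates; a focal point landing exactly
on a threshold flags the node instead of guessing an edge.

**RSP ranges.** Existence in `R` is computed numerically — a 0.001 grid
scan of "focal point inside its domain" (vectorised batched solves of the
stress-affine system) with every boundary refined by bisection to 1e-6 —
and displayed rounded to 4 decimals. The closed-form quadratic roots of
the focal-N condition serve as independent test oracles, to 1e-4. The
numeric-first design keeps the module model-agnostic: nothing assumes the
rational structure of the bundled model.

**Δ-regions and SSPs.** All faces are enumerated: every choice of 1..k
pinned thresholds (at most one per variable) crossed with every
consistent side assignment of the remaining thresholds; no
production/degradation-only pre-screening is applied because transport
invalidates its assumptions. For one region at one stress, the
steady-state algebra (pinned variables at their thresholds, their
switching values singular unknowns in [0, 1], unpinned steady states
unknown) is solved with a hybrid Powell root finder — the system is
bilinear when a pinned switch multiplies an unpinned amount, so a linear
solve would not cover it — from a focal-point-informed initial guess,
with per-equation residuals accepted below 1e-8 of the largest term
magnitude. An SSP is reported iff all singular values lie in [0, 1]
(tolerance 1e-9) and all side conditions hold. SSP stress ranges use the
same 0.001-grid-plus-bisection scan with warm-started continuation.
Interval endpoints carry explicit open/closed flags determined by
evaluating the predicate at the refined endpoint.

The three-threshold crossing of the bundled model deserves a note: the
PTEN equation pins the singular Z_P at 0.6858 for all stress, and the
transport switching value then bounds existence; the package's scan gives
≈ [0.706, 7.703] a.u. for this face. This face's point is also the one
that never organises observable oscillations (probes are captured by the
other attractors).

**Stability.** Classified empirically, as is standard for these systems:
perturbed simulations (default 1 % of each variable's nearest threshold,
fixed seed) must all settle on a limit cycle straddling the SSP's pinned
thresholds for "stable"; capture by other stationary behaviour gives
"unstable"; anything else "numeric-undecided". No Filippov/first-return
analytic stability theory is implemented.

## Bifurcation sweeps

For each grid stress the analytic candidates are computed first, then
probed: an RSP from a 1 % offset (t = 4·10⁵ s, must relax back), an SSP
from a 1 % offset (default t = 1.5·10⁶ s — roughly 15–70 cycle periods,
half discarded as transient — must sustain a limit cycle straddling its
pinned thresholds and respecting its side conditions, e.g. PTEN staying
above θ_T for the high-PTEN cycle). The nominal initial condition is
probed additionally when nothing else survives. Branches are stitched
across adjacent grid points by attractor identity; undecided points leave
gaps. The default grid step in `R` is 0.01, which is also the resolution
at which the high-PTEN cycle's numeric onset (0.95 a.u.) is defined; the
probe times above are the package's default problem sizes and were chosen
so that classification is transient-free, not tuned per target.

The nonlinear sweep finds steady states by root solving from several
seeded starts, probes their stability by integration, matches branches
across grid points by log-amount proximity (within a factor ~3), and
probes oscillation from the nominal initial state.

## The nonlinear comparison model

The smooth counterpart uses Hill production (exponent 4 in p53) and a
saturating transport factor (quadratic in PTEN). The printed
half-saturation constants (k̃₂ = 10⁻⁵ "mol⁴", k̃₃ = 1.5·10⁻⁵ "mol²") are
stored verbatim as defaults but are dimensionally inconsistent with
molecule-count states: both saturation factors are then pinned at their
limits, and the system has no finite steady state (p53 grows without
bound). The package therefore also ships a documented `rescaled` preset
that reads the printed magnitudes at the 10⁵-molecule scale
(k̃₂ = (10⁵)⁴, k̃₃ = (1.5·10⁵)²); with it the unstressed steady state
lands within 2 % of the nominal initial condition, which strongly
suggests this is the intended scale. Under the rescaled preset the smooth
model's oscillations are damped at every stress we probed (the steady
state stays linearly stable through the oscillatory window of the
switching model), so only the qualitative steady-branch structure — not a
sustained oscillatory branch — is reproduced; dynamic nonlinear tests use
the rescaled preset and assert only these qualitative facts.

## Synthetic fixtures

The stratified fixture generator draws states uniformly inside each
domain's bounding box (within a decade of the outermost thresholds,
round-robin over all 12 domains) and stress values cycling through the
module's qualitative regime windows. It emulates coverage of the discrete
state-space structure, not biological variability: passing the
oracle-equivalence suites shows the algebra and the engine agree
everywhere in state space, and says nothing about noise robustness or
parameter misspecification in real data.

## Known limitations

* No sliding-mode (Filippov) dynamics: trajectories that genuinely slide
  abort with a diagnostic rather than being regularised.
* Time-varying stress schedules, delays and stochastic switching are out
  of scope.
* Existence ranges are numeric (grid + bisection); no symbolic ranges for
  arbitrary models.
* The nonlinear baseline is qualitative only, for the scale reasons
  above.
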