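# pldesys

Analysis toolkit for **piece-wise linear differential-equation (PLDE)
models with state-dependent switching** — the Glass-type formalism used to
describe gene regulatory networks with threshold logic — bundled with a
fully analysed instance: the **p53–MDM2–PTEN regulatory module**.

## Who this is for

Systems biologists and modellers who want the analytical advantages of
switching systems over nonlinear ODEs: closed-form solutions inside each
threshold-delimited domain, exact equilibrium enumeration, and cheap,
exhaustive bifurcation analysis — while keeping a model description
(production / degradation / transport rates plus low/medium/high
thresholds) that maps directly onto quantitative biology.

## The model class

A PLDE model tracks molecular amounts `x` whose rate laws are affine
within each *domain* of state space. Domains are delimited by thresholds
`θ`; each threshold carries a binary switching variable

    Z = 0  for x < θ,    Z = 1  for x ≥ θ,

and every rate coefficient is affine in the `Z`s, so inside one domain

    dx/dt = A x + b,     x(t) = x* + e^{At}(x₀ − x*),   x* = −A⁻¹ b.

`x*` is the domain's **focal point**. A focal point inside its own domain
is a **regular stationary point** (RSP, always asymptotically stable). A
**singular stationary point** (SSP) sits on thresholds: the pinned
switching variables take fractional values in [0, 1] that balance the flow
exactly on the crossing; SSPs organise the limit-cycle oscillations of the
switched system. An external stress intensity `R ≥ 0` scales selected
degradation rates by `(1+R)` and serves as the bifurcation parameter.

The bundled module has four species — nuclear p53 (`P`), cytoplasmic MDM2
(`M`), nuclear MDM2 (`N`), PTEN (`T`) — four thresholds (θ_P, θ_N1, θ_N2,
θ_T) and therefore 2×3×2 = 12 domains. MDM2 ubiquitinates p53 (negative
feedback); p53 above θ_P boosts MDM2 and PTEN production; PTEN above θ_T
blocks MDM2 nuclear import (positive feedback); stress accelerates MDM2
degradation. A smooth nonlinear counterpart (Hill-type production,
saturating transport) ships as a comparison baseline.

## What the toolkit computes

* `model` / `configio` — declarative model definitions (YAML round-trip
  safe), domain labelling `{z_P z_N z_T}`, per-domain affine systems.
* `analytic` — exact closed-form flows (spectral, with matrix-exponential
  fallback), focal points, analytic switching times with the four-case
  crossing analysis, numeric crossing times.
* `simulate` — event-driven hybrid simulation (exact between events, root
  polished event location, chattering diagnostics), stiff integration of
  the nonlinear model, limit-cycle / fixed-point classification.
* `stationary` — domain transition graphs, RSP enumeration with
  stress-existence ranges, exhaustive Δ-region scan for SSPs, singular
  switching-value algebra, empirical stability classification.
* `bifurcation` — stress sweeps with analytically seeded attractor
  probing, branch stitching, coexistence (multistability) reports.

## Worked example

The resting state of the unstressed module, its stress window, and the
oscillation-organising singular point:

```
$ pldesys rsp --model p53 --stress 0
RSP {020} [stable]  P=33558.96653637144 (33558.9665)  M=14656.48854961832 (14656.4885)
N=159888.9659958362 (159888.9660)  T=17240.0 (17240.0000)

$ pldesys rsp --model p53 --range --domain 020
{020}: [0.0000, 0.8635)

$ pldesys ssp --model p53 --region "tP,tN2,T<tT" --stress 2
SSP Delta(theta_P, M, theta_N2, T<theta_T)  P=45000.0  M=22000.0  N=80000.0  T=27338.5694
singular switching values: Z_P=0.0837  Z_N2=0.3224
```

Reading: without stress the module rests at low p53 (≈3.4·10⁴ molecules)
and high nuclear MDM2 (≈1.6·10⁵), and this resting point exists only for
stress below 0.8635 a.u. At stress 2 a.u. a singular stationary point sits
on the crossing of θ_P and θ_N2 with PTEN low; the fractional switching
values (Z_P = 0.084, Z_N2 = 0.3224) certify it, and trajectories near it
oscillate — p53 pulses around its threshold:

```
$ pldesys simulate --model p53 --stress 1.0 --init "45450,776000,80800,135000" \
      --t-end 1500000 --out out/
classification: limit-cycle, period 100828.6 s
```

Other subcommands: `validate`, `focal`, `graph` (DOT transition graphs),
`bifurcate` (branch tables and the three-panel diagram), `nonlinear`,
`compare`.

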