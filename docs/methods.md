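# Methods

## Scope and data model

`combosurf` quantifies the interaction of two drugs from a checkerboard
viability experiment: a full grid of concentration pairs including the
single-agent rows/columns and a double-vehicle well, with replicate
readings per well. Signals are normalized to the mean vehicle signal, so
viability 1.0 means untreated growth and inhibition is
`100·(1 − viability)` percentage points. Concentrations are nanomolar
throughout. Negative normalized values (possible after background
subtraction) are clipped to zero with a logged warning; the clip count
is tracked in the synthetic generator to keep the noise model honest
(< 1% of wells at default noise).

## Single-agent curves

Each marginal follows a four-parameter log-logistic (Hill) curve
`E(d) = e_zero + (e_inf − e_zero)·(d/ec50)^h/(1+(d/ec50)^h)` with
`e_inf ≤ e_zero`, fitted to all replicate points jointly (replicates are
not averaged first, preserving the error structure for diagnostics) by
bounded nonlinear least squares (`scipy.optimize.least_squares`, trf).
The zero dose enters the objective exactly as `e_zero` — no pseudo-dose,
which would bias `ec50`; a pseudo-dose one decade below the smallest
nonzero dose is used for log-axis plotting only. `ec50` is optimized as
log10. Fits are multi-started from a data-driven heuristic (anchors at
the curve extremes, midpoint-nearest dose, slope 1) plus scrambled-Sobol
draws over the bounds; 16 restarts by default, early-stopped when the
residual sum of squares is numerically zero. Default box:
`e_zero ∈ [0.8, 1.2]`, `e_inf ∈ [0, 1]`, `ec50` within
[min_dose/10, max_dose·10], `h ∈ [0.2, 10]` — wide enough for published
cytotoxicity assays. A series whose mean viabilities span < 0.05 is
flagged degenerate (flat curve): no parameters, no ec50, and downstream
metrics are marked accordingly. Iso-effect doses come from the
closed-form inversion; a target effect outside the open interval
`(e_inf, e_zero)` is *not available* — this reachability check, applied
within the tested range only, is what later gates the combination index.

## The interaction surface

The combination model is an implicit Loewe-interaction (Greco-style)
surface. At dose pair `(dA, dB)` the predicted viability `E` solves

    dA/DA(E) + dB/DB(E) + α·dA·dB / sqrt(PA(E)·PB(E)·ec50_a·ec50_b) = 1

with nine parameters: shared `e_zero`; two marginal triples
`(e_inf, ec50, h)`; the interaction coefficient `α`; and a combined
asymptote `e_inf_ab ≤ min(e_inf_a, e_inf_b)`. `DA/DB` are the marginal
inverse-Hill dose functions, taken as +∞ (vanishing term) for effects
deeper than the marginal asymptote. `PA/PB` are the same inversions with
`e_inf_ab` in place of the marginal asymptote: they keep the interaction
term alive below both marginal asymptotes, so a synergistic combination
can approach `e_inf_ab` even when neither single agent passes its own
plateau — the behaviour needed for combinations rescuing a <50%
single-agent responder.

Two design choices deserve comment:

* **Geometric-mean interaction scaling.** The interaction denominator is
  `sqrt(PA·PB·ec50_a·ec50_b)` (the classical Greco convention) rather
  than the plain product `PA·PB`. With the product, the cross term is of
  strictly higher order than the marginal terms near zero effect and the
  implicit equation loses its root for *any* α < 0; the geometric mean
  keeps all terms of comparable order, so moderate antagonism is well
  posed. When `e_inf_ab` equals both marginal asymptotes the equation
  is exactly Greco's model; on the 50% level with full-range unit-slope
  marginals the two scalings coincide (the closed-form minimum CI at
  α = 3 is exactly 2/3 under both).
* **Root policy.** For α ≥ 0 the left-hand side is monotone increasing
  in `E` and diverges at `e_zero`, so the root is unique and found by
  vectorized bisection (48 halvings of the unit-span bracket, interval
  ≈ 4e−15). For α < 0 the gap can cross zero twice; the physical root —
  the branch continuously connected to the additive solution — is the
  lowest crossing, located by a 64-point ascending scan before
  bisection. Strong antagonism at deep doses leaves no root at all
  (Greco's documented breakdown); prediction then raises an error naming
  the dose pair, and the fit objective converts that into a finite
  penalty so the optimizer retreats into the solvable region. The
  practical consequence: antagonistic designs should span a few ec50
  multiples, not the 100× grids suitable for synergy.

On any iso-effect contour the equation is *linear in `dB` given `dA`*,
which gives closed-form isoboles, an exactly additive α = 0 null
(CI ≡ 1 to machine precision — the package's key self-check), and a
quadratic closed form for the equipotent-ray crossing.

Surface fitting is unweighted joint least squares over all wells (no
variance model is assumed), initialized from the single-agent axis fits
with α = 0, with additional restarts jittering the marginals and
resampling `(α, u)` from a Sobol sequence; ec50s are log10-parameterized
and the ninth coordinate is `u ∈ [0, 1]` with
`e_inf_ab = u·min(e_inf_a, e_inf_b)`, enforcing the asymptote ordering
inside a plain box. Default α box: [−5, 100]. On noiseless 8×8 boards
the fit recovers all nine generating parameters to ≈1e−10 relative
error; under 5% multiplicative noise the interaction sign at |α| = 2 is
recovered in ≥95/100 simulations.

## Synergy metrics

**Combination index.** `CI = dA/D_A50 + dB/D_B50` for a combination
achieving 50% viability. CI is *not available* when either marginal
fails to reach 50% viability within the tested range (no extrapolation)
or the fitted surface never crosses 50% inside the tested rectangle.
The headline CI is evaluated where the equipotent ray
(`dA/D_A50 = dB/D_B50`) crosses the fitted 50% isobole: it is exactly 1
under Loewe additivity, < 1 for synergy and > 1 for antagonism. The
minimum of `dA/D_A50 + dB/D_B50` over the whole contour (the most
favorable tested combination, polished by a bounded 1-D search) is
computed and serialized alongside (`ci_min_isobole`); note the contour's
axis intercepts always score exactly 1, so this minimum is capped at 1
and can only evidence synergy, never antagonism — the reason it is not
the headline. If antagonism pushes the equipotent crossing outside the
tested rectangle, the contour minimum stands in, flagged in
diagnostics.

**Nonlinear blending.** Each drug's dose is scaled by its maximum tested
concentration; along the anti-diagonal ray of fixed total scaled dose
(default 1.0) with mixture fraction `x`, the statistic is
`max over interior x of inhibition(x)` minus the better endpoint
inhibition, in percentage points — a 101-point sweep polished by a
bounded 1-D maximizer, matching a 10,001-point exhaustive sweep to
< 0.1. By construction this quantity is non-negative up to solver
tolerance (the interior supremum dominates the endpoints by continuity),
so strongly negative blending values can enter classification only as
externally supplied numbers (e.g. a published table), not from this
pipeline; this is a known limitation of the ray construction chosen.

**Classification.** With a CI available: CI < 0.7 → synergy, CI > 1.3 →
subadditivity, the closed interval [0.7, 1.3] → additivity; the CI
decides even when the blending value alone would say otherwise. Without
a CI: blending > 20 → synergy, < −20 → subadditivity ("antagonism" is
accepted as a synonym), [−20, 20] → additivity. Boundary values fall in
additivity in both scales. These thresholds and the precedence rule
reproduce the packaged 15-cell-line reference panel 15/15, including the
row where blending 19.6 alone would misclassify but CI 0.41 governs.

## Synthetic data

The generator exists to give every pipeline stage a ground truth. A
board is `predict_surface(truth, dA, dB)` plus noise per well —
multiplicative lognormal with σ = 0.05 by default (a typical
luminescence-assay CV; an additive-Gaussian option is retained for
boundary testing) — clipped at zero. Default designs are 9-dose half-log
grids per drug plus vehicle, duplicate wells, reaching 100× each ec50
for the null/synergy presets (deep enough to pin the asymptotes) and
~3.2× for the antagonism preset (the well-posed region, and the range
antagonism checkerboards are realistically run over). Presets:
`loewe-null` (α = 0), `synergy` (α = 5, both agents reaching 80%
inhibition), `antagonism` (α = −0.5). All generators are pure functions
of (spec, seed); identical inputs are byte-identical.

What the generator does *not* emulate: plate spatial artifacts (edge
effects, drift), cell-line-specific curve shapes, signal-dependent
heteroscedasticity, and pipetting serial-dilution error correlation.
Passing tests therefore demonstrate correctness of the estimators under
a clean error model, not robustness to plate pathology.

Additional fixtures: a Bliss-independence board (combination viability =
product of marginals) as a robustness null — read through this Loewe
pipeline with equal-potency unit-slope marginals it scores
CI = 2(√2 − 1) ≈ 0.83, the known Loewe-reads-Bliss bias, verified
against the closed form; a resistance pair (two Hill curves differing
only in ec50, defaults 53 nM vs 20 μM on a grid capped at 10 μM) that
exercises the CI-NA/blending-fallback path; and an exponential-growth
xenograft cohort whose ground-truth T/C% has a closed form.

## Ancillary formulas

Caliper tumor volume `length × width² × 0.5` (mm³, width ≤ length
enforced); treated-over-control percentage
`100 × mean(per-animal treated volume change)/mean(control change)` —
group means of per-animal changes, animals missing either endpoint
excluded with a logged count, control change ≤ 0 returning NA with a
warning; and qPCR relative expression `2^−ΔΔCt` with the standard sign
convention (ΔCt = Ct_target − Ct_reference, ΔΔCt = treated − control).

## Numerical choices and study sizes

Bisection tolerance ~4e−15 in effect units; closed-form contours satisfy
the surface equation to machine precision; classification thresholds are
configurable (`RunConfig`) with the published defaults. The validation
studies use: 50 random α = 0 surfaces for the Loewe-null property; 20
random surfaces against 2000²-grid and 10,001-point oracles; 50
noiseless boards for parameter recovery; 100 boards per arm for the
Monte-Carlo label calibration, run with a lean fit profile (6 Hill
restarts, 2 surface restarts, marginal-informed initialization) that
matches the headline profile's answers on these designs. All study
randomness flows from a single seed.

## Known limitations

The exact published nine-parameter surface this stands in for is cited
in the source literature only by reference; the parameterization here is
a documented, testable choice isolated behind the predict/fit interface
so an alternative is a drop-in. The blending statistic cannot go
strongly negative (above). Strong antagonism on deep grids is outside
the model's solvable region. Confidence intervals on CI/blending (e.g.
by well-level bootstrap) are not provided.
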