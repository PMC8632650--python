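# Methods

## Scoring model and DSB accounting

A metaphase enters analysis only when all 46 centromeres are visible;
incomplete spreads are removed before any tallying so that lost
chromosomes cannot be mistaken for deletions. Aberration classes follow
the telomere/centromere-staining taxonomy: dicentrics, centric rings,
acentric rings, and acentric fragments with four (`ace_4tel`), two
(`ace_2tel`) or zero (`ace_0tel`) telomere signals, plus telomere
deletions.

DSB weights per scored event: dicentric or centric ring = 2 (this
absorbs the accompanying four-telomere fragment), terminal deletion = 1,
interstitial deletion = 2, telomere deletion = 1. Two points were open
to interpretation and are resolved as package design choices:

* **Excess four-telomere fragments.** One `ace_4tel` is expected per
  dicentric/ring. Fragments beyond `n_dic + n_cring` — counted at the
  tally level, since scoring is aggregated per dose — are treated as
  fusion events without a visible dicentric and scored 2 DSB each.
* **Acentric rings** carry no conventional weight; ring formation
  requires two breaks, so the default weight is 2, exposed as
  `acentric_ring_dsb_weight` for laboratories using another convention.

DSB totals are computed on tallies; a single-cell tally gives the
per-record value, and the computation is additive over tallies whenever
`ace_4tel ≤ dic + cring` in each part.

The F-ratio is reported as centric rings per dicentric (≈ 0.05 in
healthy European donors). The inverse reading circulates in the
literature; this package always returns rings/dicentrics.

## Calibration fit

The endpoint count at dose point *i* is modelled Poisson with mean
`n_i (C + α D_i + β D_i²)` — identity link on the per-cell yield with
cells scored as exposure, which matches the additive quadratic yield
form. C, α, β are constrained non-negative (the convention for physical
yields). The likelihood is maximized directly with a bounded
quasi-Newton solver (L-BFGS-B, analytic gradient); coefficients landing
on the boundary are fixed at exactly 0 and the remaining parameters
refit (profile refit). Because bounded line searches can stall at a
boundary optimum with a pessimistic status flag, first-order (KKT)
optimality is verified explicitly — interior gradient ≈ 0, boundary
gradient ≥ 0, at relative tolerance 1e-6 — and a derivative-free
Nelder–Mead polish rescues premature terminations; convergence control
is a relative log-likelihood change below 1e-10 within a 100-iteration
cap per solve. Fitting operates on per-dose aggregates; per-cell records
aggregate first (the Poisson likelihood is identical).

Covariance is the inverse expected Fisher information over the free
parameters, times the Pearson dispersion estimate χ²/df **floored at
1.0** so that apparent underdispersion can never shrink the standard
errors. Clipped coefficients get SE 0 and zero covariance rows. An
all-zero count table returns the degenerate flat fit (C = α = β = 0)
with a `degenerate` flag rather than an error.

Statsmodels' identity-link Poisson GLM reproduces these estimates on
interior-solution data and serves as an independent cross-check in the
test suite; it is not used in the implementation because its IRLS
weights divide by the mean, which is exactly 0 at dose 0 when C sits on
the boundary.

## Dispersion diagnostics

For per-cell counts (N cells, X total events): sample variance with
denominator N − 1, dispersion index σ²/Ȳ, and

    u = (σ²/Ȳ − 1) · sqrt((N − 1) / (2 (1 − 1/X)))

approximately standard normal under Poisson sampling; |u| > 1.96 flags a
5% two-sided departure. u is reported as undefined (None), not a number,
when X < 2. The false-alarm rate stays in the nominal band down to
λ = 0.1 with N = 200 (where X ≈ 20).

## Exact Poisson intervals and Merkle dose bounds

Count uncertainty uses Garwood chi-square bounds:
`lower = ½ χ²((1−γ)/2; 2x)` (0 at x = 0), `upper = ½ χ²(1−(1−γ)/2; 2x+2)`.
These are deliberately conservative (coverage ≥ nominal).

Dose estimation inverts the curve in closed form (non-negative quadratic
root; `(y−C)/α` when β = 0; 0 Gy for yields at or below background). The
Merkle bounds intersect two envelopes: the lower dose bound solves
`Y(D) + z·SE(D) = lower count limit / n`, the upper bound solves
`Y(D) − z·SE(D) = upper count limit / n`, with `SE(D) = sqrt(vᵀ V v)`,
v = (1, D, D²), by the delta method. Roots are located by a 256-panel
scan plus Brent refinement on [0, D_max] (default 10 Gy; estimates above
4 Gy attach an extrapolation warning). An unsolvable lower bound clamps
to 0; an unsolvable upper bound reports D_max with an open-interval
flag. The split between the two confidence levels is left open by the
procedure itself; both default to 95%, independently configurable, which
in simulation gives joint dose-interval coverage well above 90% (typically
≈ 99%, the count interval's conservatism dominating). No partial-body or
protracted-exposure correction is applied.

## Group comparison

The default two-group test is the exact conditional Poisson-rate test:
given the total count, the first group's count is binomial with the
cell-share as success probability. It remains exact at zero counts —
the regime of spontaneous-background comparisons, e.g. 6 dicentrics in
5,200 cells against 0 in 12,450 gives p = (5200/17650)⁶ ≈ 6.5 × 10⁻⁴.
Two-sided p-values aggregate outcomes by minimum likelihood (doubling
the smaller tail is selectable). The Kruskal–Wallis test (tie-corrected,
chi-square approximation) is provided for per-cell distributions at a
matched dose, and a 2-df Wald contrast on (α, β) with pooled covariance
compares fitted curves. Endpoints are reported raw, without
multiple-testing correction.

## Synthetic cohorts

The generator emulates the study design the analysis assumes: doses
{0, 0.5, 1, 2, 4} Gy, 200 cells per dose by default (two slides of
~100), per-cell class counts Poisson at the class's LQ yield, and
overdispersion only at 4 Gy (default 1.3), implemented as gamma-mixed
Poisson with variance = dispersion × mean. Each dicentric/ring is
accompanied deterministically by one four-telomere fragment (an
independence mode exists for stress testing). Optional features, off by
default: a fraction of non-analyzable (≠ 46 centromere) cells, and a
per-donor lognormal frailty on yields for future inter-individual work.

Group presets carry the published dicentric (α, β) exactly. Since no
class-wise breakdown was published, the ring yield is the
(dicentrics+rings) row minus the dicentrics row, floored at 0, and the
residual DSB yield — DSB row minus twice the (dicentrics+rings) row,
floored at 0 — is split 50/25/25 in DSB units between terminal
deletions, interstitial deletions and telomere deletions. Backgrounds:
African groups have C = 0 for dicentrics and rings with a residual DSB
background of 0.0017 per cell split the same way; the Caucasian preset
adds C = 6/5200 for dicentrics and reuses the same residual acentric
background, for which no published figure exists. A few published rows
are mutually inconsistent (a dicentrics α above the dicentrics+rings α;
a DSB β below twice the dicentrics+rings β; two (α, β) covariances
larger in magnitude than the product of their printed SEs, so those
blocks are not positive semi-definite); the presets floor at 0 and keep
the printed values verbatim, and the inconsistent covariance blocks are
used only for ratio and contrast checks, never for envelope propagation.

What the generator does **not** emulate: inter-laboratory scoring
variation, donor age/sex structure, misclassification of aberration
classes, and any correlation between classes beyond the
fragment-pairing rule. Passing tests therefore demonstrate statistical
correctness of the pipeline under the assumed sampling model, not
robustness to real-world scoring artefacts.

## Problem sizes and numerical defaults

Simulation-based checks use: 200 cohorts × 5 doses × 2,000 cells for
parameter recovery and Wald coverage; 20 random ≤ 5-point instances for
the brute-force likelihood cross-check (1e-4 relative agreement); 1,000
replicates of N = 200 at λ ∈ {0.1, 0.5, 1.6} for u-statistic
calibration; 500 replicates × 500 cells at each of 0.5/1/2/4 Gy for
Merkle coverage; 40 seeds × 5,200 cells for the background emulation.
These sizes give Monte-Carlo standard errors comfortably inside the
assertion bands while keeping the full suite fast. File outputs round
floats to 6 significant digits; in-memory values keep full precision.
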