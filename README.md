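# cytodose

Cytogenetic biological dosimetry from telomere/centromere-stained
metaphases: aberration scoring and double-strand-break (DSB) accounting,
quasi-Poisson linear-quadratic calibration of dose-response curves, dose
estimation with Merkle uncertainty bounds, and between-group comparison
of radiation response.

## Who this is for

Biodosimetry laboratories and radiation-cytogenetics researchers who
score unstable chromosomal aberrations — dicentric chromosomes, centric
rings, acentric fragments classified by their telomere signals — in
peripheral blood lymphocytes, and need to (i) build a calibration curve
from *in vitro* irradiations, (ii) estimate an absorbed dose from a field
sample, and (iii) test whether two donor populations respond differently.
A synthetic cohort generator reproduces the statistical structure of such
studies (doses 0–4 Gy, ~200 cells per dose, Poisson counts with optional
overdispersion at 4 Gy, group-specific yields), so the whole pipeline is
testable without access to raw score sheets.

## The model

Only metaphases with all 46 centromeres are analyzed. Telomere/centromere
staining lets each aberration class be translated into the DSB count that
produced it: a dicentric or centric ring (with its accompanying
four-telomere fragment) is 2 DSB; an excess four-telomere fragment 2; a
terminal deletion (two telomere signals) 1; an interstitial deletion (no
signals) 2; a telomere deletion 1.

The per-cell yield of an endpoint (dicentrics; dicentrics + rings; total
DSB) follows the linear-quadratic form

    Y(D) = C + αD + βD²

For a dose point with *n* cells the count is Poisson with mean *n*·Y(D).
Coefficients are maximum-likelihood estimates constrained ≥ 0, with
standard errors and the (C, α, β) covariance matrix scaled by a Pearson
quasi-Poisson dispersion estimate. Per-cell distributions are checked
with the dispersion index σ²/Ȳ and the Papworth u statistic. Dose
estimation inverts the curve at the observed yield and brackets it by
Merkle's procedure: the exact (Garwood) Poisson interval of the count
intersected with the curve's ±z·SE(D) confidence envelope from the fit's
covariance matrix. Groups are compared by an exact conditional
Poisson-rate test, a Kruskal–Wallis test on per-cell counts, or a Wald
contrast on fitted (α, β).

## Worked example

Simulate a Senegalese-donor calibration cohort (2,000 cells per dose at
0, 0.5, 1, 2, 4 Gy), fit the dicentric curve, and estimate the dose of a
fresh sample with 130 dicentrics in 200 cells:

```sh
cytodose simulate --preset senegal_africa --cells 2000 --seed 42 --out scores.csv
cytodose calibrate --scores scores.csv --endpoint dicentrics --out-prefix senegal
cytodose estimate --curve senegal_dicentrics.curve.json --count 130 --cells 200 --out est.json
```

The calibration summary (`senegal_summary.csv`) from this exact run:

```
group_id,endpoint,C,alpha,se_alpha,beta,se_beta,alpha_beta_ratio,cov_alpha_beta,dispersion_scale
senegal_africa,dicentrics,0,0.176901,0.00969334,0.0575407,0.0034043,3.07,-2.90002e-05,1
```

The fitted α = 0.177 ± 0.010 Gy⁻¹ and β = 0.0575 ± 0.0034 Gy⁻² recover
the generating yields (α = 0.168, β = 0.061) within their standard
errors; C = 0 reflects the dicentric-free African background. The
estimate step prints

```
dicentrics: 130/200 cells -> 2.159 Gy (95/95 bounds 1.851-2.484)
```

an observed yield of 0.65 dicentrics/cell inverted through the curve,
with Merkle 95/95 bounds combining the count's exact Poisson interval
and the curve envelope. `cytodose compare` and `cytodose dsb` expose the
group tests and the DSB breakdown on the same file contracts.

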