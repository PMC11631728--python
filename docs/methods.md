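# Methods

## Survival model

The Poisson-threshold model treats a dose D (Gy) as drawing a number of
"unit damages" n from a Poisson distribution with mean αD; a cell with n
damages survives with probability βⁿ for n ≤ m and dies for n > m:

    SF(D) = e^(−αD) · Σ_{n=0}^{m} (βαD)ⁿ / n!

* **α** (Gy⁻¹, > 0): mean unit damages per Gy — the "ability to damage".
  What a unit damage corresponds to physically (one or several lesions) is
  left uninterpreted; only the Poisson count matters computationally.
* **β** (dimensionless, [0, 1]): probability that one unit damage is
  repaired and the cell survives — the "ability to repair".
* **m** (integer ≥ 0, default 5): damage count above which repair fails.
  m = 0 collapses to e^(−αD) and m → ∞ to e^(−α(1−β)D), both log-linear in
  dose, so a finite intermediate m is required for curvature; m in 3–6
  fits clonogenic data comparably and 5 is the fixed default. The
  evaluator takes m as an argument so the limiting cases are testable.

Evaluation accumulates the m+1 series terms iteratively
(term_{n+1} = term_n · βαD/(n+1)) and multiplies by e^(−αD). Double
precision is exact at assay dose scales (αD ≲ 700); no log-space machinery
is used. With β = 1 the expression is exactly the Poisson CDF at m, which
the tests use as an independent oracle (scipy.stats.poisson).

Goodness of fit is the root-mean-square percentage error,
RMSPE = sqrt(mean(((P−O)/O)²)), because survival fractions span ~1 to
10⁻³ and relative error weights the tail correctly. Zero-dose points are
excluded from fitting by the dataset accessor, keeping the statistic pure.

## Multi-curve fitting

For one cell line, (α_x, β_x) are first fitted to the pooled photon
points and then held fixed; the proton curves at LETs L_i share the four
coefficients of the linear relations

    α_p = (a_α + b_α·L) · α_x,   β_p = (a_β − b_β·L) · β_x

and MCF minimises the **unweighted sum of per-dataset RMSPE** (curves with
more dose points are not up-weighted). Inside the forward model β_p is
clamped to [0, 1] so the optimiser can explore steep b_β without invalid
curves; clamping events are logged and recorded. The optimiser is bounded
L-BFGS-B from a fixed multi-start grid (intercepts {0.8, 1.0, 1.2},
slopes {0, 0.01, 0.03}); all 81 starts are screened by objective value and
the best five polished, ties broken by start order, which makes results
exactly reproducible without any randomness. Bounds: intercepts
(10⁻³, 5), slopes [0, 1]; single-curve fits use α ∈ (0, 20] Gy⁻¹,
β ∈ [0, 1] (LQ: both in [0, 20]).

The deterioration index Det = RMSPE_MCF / (RMSPE_best + 0.05) compares
each curve's constrained fit with its own unconstrained best fit; the
0.05 floor keeps Det meaningful when the best fit is already excellent.
Flags: ok (≤ 1.25, visually undetectable), acceptable (≤ 2), suspicious
(≤ 4), outlier (> 4); thresholds configurable. Outlier exclusion is a
deliberate manual step — the package flags, it does not automatically
re-fit with outliers dropped.

The single-variable refit holds (a_α, b_α, a_β) at their cross-cell-line
averages (1.12, 0.0019, 0.99) and refits b_β alone (bounded scalar
minimisation), giving the cell-dependent slope b_β^#; a through-origin
least-squares regression (slope = Σxy/Σx², no intercept by construction,
unweighted) of b_β^# on α_x yields the comprehensive-model coefficient
0.013. Cross-line means use the sample (n−1) standard deviation.

## RBE calculation

RBE at photon dose-per-fraction D is D/D_p where SF_p(D_p) = SF_x(D).
The reference dose is the **photon** dose; this convention is what
reproduces the extreme-LET worked value (~12.7). The dose solve brackets
[0, D_max] with D_max grown geometrically from 10 Gy (error above 10⁴ Gy)
and refines with Brent's method; defaults guarantee |ΔSF| ≤ 1e-9, with the
internal bracket tolerance tightened below the nominal 1e-8 Gy because on
steep curves the SF tolerance is the binding one. At high LET the
extrapolated β_p crosses zero and is clamped at 0 with a flag (clamping,
not truncating the curve, is what the worked example requires); raw
β_p > 1 is clamped to 1.

## Synthetic data

`synthetic` generates families with the structure the fitting assumes:
one photon curve from (α_x, β_x) plus one proton curve per LET from the
linear relations. Defaults define the reference study conditions: dose
grid {1..8} Gy (a typical 8-point assay), LET set {1.1, 4.0, 7.0, 11.9,
18.0, 22.6} keV/µm (the pristine-beam range of the densest published
fibroblast series), photon truth α_x = 2.34 Gy⁻¹, β_x = 0.75 with
response (1.12, 0.0019, 0.99, 0.033) — an AG01522-like line. Noise is
multiplicative lognormal, SF_obs = SF_true · exp(σZ − σ²/2): mean-one,
strictly positive (survival data are log-scale), with σ = 0.066 matching
the ~6.6% average RMSPE scatter of published clonogenic fits. The real
error structure of colony counts (replicate statistics, plating
efficiency) is not emulated, so passing recovery tests shows estimator
correctness under the assumed noise model, not robustness to assay
artefacts. Each dataset draws from an independent spawned child of the
seed, so families are bit-reproducible.

A per-dataset LET bias mislabels the *recorded* LET while generating the
curve at the true LET — the distal-edge SOBP error mode. Biasing an
interior LET (e.g. 11.9 → 7.1 keV/µm at −40%) makes that curve the
family's maximum-Det member, well above 4. A caveat the tests document:
when the −40% bias is applied to the *highest* LET of the family, the
mislabelled curve's relative errors under the consistent fit are so large
(observed SF far below prediction) that the summed-RMSPE objective bends
the whole fit toward the outlier, and the *majority* of curves acquire
large Det instead — consistent with the diagnostic rule that many large
Det values signal a broken linear relation rather than one bad curve.

## Problem sizes

Recovery tests use families of 6 LETs × 8 doses; the consistency ladder
runs 20 seeds at σ ∈ {0.10, 0.05, 0} (60 MCF runs, ~30 s total), chosen
as the smallest replication that separates the RMSE levels cleanly.

## Known limitations

* The linear LET relations are calibrated on LET ≲ 30 keV/µm; LET 83 is an
  extrapolation (β_p clamped at 0) and is reported as such.
* Single scalar LET per curve; SOBP beams mix LET spectra, which is
  precisely why their distal-edge datasets appear as outliers.
* No uncertainty quantification on fitted coefficients (point estimates
  only), no dose-rate/oxygen/cell-cycle effects, no fractionation (BED)
  arithmetic.
* Eligibility screening encodes source-specific exclusions only as an
  explicit publication blacklist; it cannot infer them from the data.
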