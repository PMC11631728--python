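# protonrbe

Proton therapy is planned with a constant relative biological effectiveness
(RBE) of 1.1, even though the biological effect per Gy rises steeply with
linear energy transfer (LET), falls with dose per fraction, and differs
between cell types. `protonrbe` implements a semi-empirical proton RBE
model derived from published clonogenic survival data: a Poisson-threshold
cell-survival model, shared-parameter **multi-curve fitting (MCF)** of the
LET dependence of its parameters, a **deterioration index** for spotting
survival curves whose nominal LET is wrong, and an iterative
isoeffective-dose RBE calculator. It is aimed at medical physicists and
radiobiologists who work with clonogenic assay data (e.g. exports from the
Particle Irradiation Data Ensemble, PIDE) or need LET/dose/cell-dependent
RBE estimates.

## The model

Radiation dose D (Gy) produces *n* "unit damages" with Poisson probability
P(n) = (αD)ⁿ/n! · e^(−αD), where α is the mean number of damages per Gy. A
cell with one damage repairs it and survives with probability β; n damages
are repaired independently (βⁿ), and more than m = 5 damages are lethal.
Hence

    SF(D) = e^(−αD) · Σ_{n=0}^{m} (βαD)ⁿ / n!

Unlike the empirical linear-quadratic (LQ) model, α ("ability to damage")
and β ("ability to repair") have mechanistic LET dependences, assumed
linear relative to the photon values (α_x, β_x) of the same cell line:

    α_p = (a_α + b_α·LET) · α_x        β_p = (a_β − b_β·LET) · β_x

MCF fits all survival curves of one cell line simultaneously over
(a_α, b_α, a_β, b_β), minimising the summed root-mean-square percentage
error (RMSPE). Per curve, the deterioration index
Det = RMSPE_MCF / (RMSPE_best + 0.05) flags experimental outliers
(Det > 4). Pooling cell lines gives the comprehensive model

    α_p = (1.12 + 0.0019·LET) · α_x    β_p = (0.99 − 0.013·α_x·LET) · β_x

and RBE at photon dose D is D / D_p, where D_p solves
SF_p(D_p) = SF_x(D).

## Worked example

The largest proton LET is ~83 keV/µm. For a radiosensitive cell line
(α_x = 2.5 Gy⁻¹, β_x = 0.9) at 0.5 Gy/fraction:

```sh
$ protonrbe rbe --alpha-x 2.5 --beta-x 0.9 --let 83 --dose 0.5
RBE         = 12.7
proton dose = 0.03947 Gy
matched SF  = 0.88154
alpha_p     = 3.19425 /Gy
beta_p      = 0.00000  (clamped)
```

The photon exposure of 0.5 Gy leaves SF = 0.88154; at LET 83 the
extrapolated repair parameter β_p is negative and is clamped to 0 (no
repair), so only 0.0395 Gy of protons produces the same survival — an RBE
of 12.7. At a clinical LET of ~10 keV/µm and 2 Gy/fraction the same
machinery gives RBE ≈ 1.9.

A full pipeline on synthetic data with known ground truth:

```sh
$ protonrbe simulate --seed 42 --out synth.csv
wrote 7 datasets to synth.csv
$ protonrbe mcf --data synth.csv
SYN-FIB: (a_alpha, b_alpha, a_beta, b_beta) = (1.11, 0.0015, 0.97, 0.033); alpha_x = 2.351, beta_x = 0.755; sum RMSPE = 0.3999
  SYN-FIB/synthetic/pristine/LET=1.1: RMSPE = 0.0898, best = 0.0890, Det = 0.65 [ok]
  ...
```

The simulated family was generated with (1.12, 0.0019, 0.99, 0.033) and
6.6% lognormal noise; MCF recovers (1.11, 0.0015, 0.97, 0.033). Other
subcommands: `fit` (per-curve best fits, Poisson or LQ), `filter`
(data-eligibility screens), `rbe-curves` (RBE tables over a grid),
`report` (filter → MCF per cell line → cross-line summary).

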