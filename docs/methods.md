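# Methods

This note documents the models, parameter choices and numerical decisions
behind `ovodyn`, and what the synthetic-data tests do and do not establish
about field data.

## Stereology

### The packing-density equation

Oocytes of phase *i* are modelled as prolate spheroids with axes
(L, S, S). With the per-profile diameter defined as OD = (L+S)/2 and the
shape factor k = L/S, the spheroid volume is

    v = (π/6)·L·S² = (π/6)·OD³·8k/(1+k)³   [µm³]

One gram of ovary of specific gravity ρ_o occupies 1/ρ_o cm³, of which the
fraction V_V is oocytes of phase *i*. Dividing occupied volume by
per-oocyte volume (converted by 10¹² µm³/cm³) gives

    OPD_i = V_Vi · (1/ρ_o) · (1+k)³/(8k) · (6/π)·10¹² / cOD_vi³

whose base-10 logarithm is the implemented equation with the constant
C = log10((6/π)·10¹²) = 12.28100…, printed as 12.28. The logarithm base is
forced by that constant: no other base reproduces 12.28 for µm diameters
and g cm⁻³ gravities. `constant_mode="printed"` (default) reproduces
published numbers; `"exact"` is used by the oracle tests. The two modes
differ by the fixed factor 10^(12.28100−12.28) ≈ 1.0023 for every input.

### Diameters, shape, shrinkage

* The volume-based diameter OD_v = (Σ OD³/n)^(1/3) is the diameter of the
  sphere of mean volume; it is ≥ the arithmetic mean (power-mean
  inequality) and is the right summary because the equation divides by a
  volume. Three through-the-nucleus profiles per phase suffice because
  within-phase diameter variance is kept low by the fine phase scheme.
* k is computed per profile and averaged per phase/female (the alternative,
  k from averaged axes, differs only at second order).
* Histology-scale diameters are multiplied by a shrinkage correction to
  return to the formalin-preserved scale. **The default 1.11 (~10% linear
  shrinkage, typical of resin embedding) is a documented stand-in** — the
  appropriate factor is protocol-specific and should be set in
  configuration whenever known.
* Specific gravity: 1.020 g cm⁻³ for maturing ovaries (IMR stages 3–5),
  1.047 for spawning/spent/recovering (6–8), as determined by whole-ovary
  submersion; juveniles have no defined value and raise an error.
  `specific_gravity_from_submersion` implements the direct weight/volume
  estimate.
* PVO1 is excluded from packing densities (too few grid hits to quantify),
  as are hydrated oocytes (irregular after dehydration). Phases with zero
  volume fraction yield OPD = 0 rather than an error so spent ovaries
  process cleanly; a phase with grid hits but no axis measurements is a
  data error and raises.

## Spawning staging

The oocyte ratio OR = ΣPVO/Σ(VO+FOM) is computed on cleaned wholemount
diameters (window 100–1100 µm: smaller oocytes wash out during staining,
and the follicle layer detaches above ~1150 µm). The PVO/developing split
is purely diametric (default 230 µm); cortical alveoli oocytes count as
developing. Rule-table bins are closed on their upper end (OR ≤ 1 → ORC1,
≤ 3 → ORC2, ≤ 15 → ORC3, else ORC4); ORC0 (prespawning) is assigned only
from the biometry record's flag, never from OR, because prespawning fish
have no defined OR range. A helper derives a candidate flag from capture
month, but the stored flag is authoritative.

### The Gamma/Gaussian mixture

`fit_gamma_gaussian_mixture` maximises w·Gamma + (1−w)·Normal by EM:

* initialisation at the empirical-density minimum between 150 and 400 µm,
  method-of-moments per side; requires n ≥ 50 with ≥ 10 points per side;
* gamma M-step by weighted maximum likelihood (digamma root-find), normal
  M-step in closed form; log-likelihood asserted non-decreasing every
  iteration; tolerance 1e-6, max 500 iterations (non-convergence returns
  `converged=False` with a warning; a collapsing weight raises
  "unimodal data");
* the threshold is the smallest diameter between the gamma mode and the
  normal mean where the posterior probability of the normal component
  reaches 0.5 — the weighted-density crossing; outer crossings are ignored.

Fits are windowed to diameters ≤ 500 µm in the pipeline: the threshold
lives between the PVO bulk and the first developing mode, and ovaries
holding several advanced cohorts (vitellogenic through final maturation,
roughly 280–950 µm) make a single Gaussian upper component unidentifiable.
Thresholds are fitted per female and summarised across females with a
t-interval, reflecting genuine between-female variation; a pooled fit is a
single function call on the concatenated sample if wanted.

**Known behaviour:** against a multi-phase truth the two-component model is
structurally misspecified, and its threshold sits systematically below the
exact crossing of the PVO and developing densities (by ~25 µm under the
default synthetic conditions). This mirrors what the estimator does on real
ovaries, where statistically fitted thresholds fall below histologically
established landmarks; the histological landmark, not the mixture fit,
should define the counting bound.

Smoothed size distributions use a Gaussian kernel (Silverman bandwidth by
default, overridable), renormalised to integrate to 1 on the 100–1100 µm
grid.

## Biometrics

The length–weight power fit is OLS on log10–log10 axes; no back-transform
bias correction is applied, matching the ratio convention of relative
condition K_n = W/(a·TL^b), which is self-centring (median ≈ 1) on its
fitting sample. GSI_TL = 10⁴·OW/TL^b uses the pooled fitted exponent by
default (override available). Lengths are cm and weights g throughout;
the functions reject non-positive lengths rather than absorbing unit
mistakes.

## Recruitment calculus

* RF cells are means with normal-approximation 95% CIs (±1.96 SE); n = 1
  cells are flagged, not bootstrapped.
* De novo influx = mean RF_PVO4c(ORC0) − mean RF_PVO4c(ORC4); its SE
  combines the cell SEs in quadrature. A negative influx (the determinate
  signature) is reported with a warning, never clamped. No atresia
  adjustment is applied; atresia volume fractions are reported separately
  so users can judge whether one is needed.
* The prespawning aggregate is the mean over ORC0 females of per-female RF
  sums PVO4c→GVBD (per-female sums first, then the mean — the paired
  convention used throughout).
* Batch number = (aggregate + influx)/batch fecundity, rounded to the
  nearest integer and reported with the unrounded ratio.
* Threshold sensitivity compares per-female sums PVO4a→GVBD vs
  PVO4c→GVBD among actively spawning females (ORC1–3): prespawning and
  spent fish hold little beyond PVOs and would dominate the percent
  reduction; fish with only the legacy-side phases drop out of the
  pairing.

## The synthetic generator

The generator emulates a cohort sampled across a spawning cycle:

* Each female draws a latent stage ORC0–4 (default probabilities 0.30,
  0.125, 0.125, 0.15, 0.30 — a prespawning-heavy winter sample plus a long
  spent tail). Per-phase truth is a relative-fecundity trajectory indexed
  by stage: flat PVO2/PVO3 reservoirs (2600/2000 oocytes g⁻¹ body),
  a PVO4c pool declining 200 → 40 (programmed influx 160, prespawning
  PVO4c→GVBD aggregate 528), and dome-shaped CA/VO waves that drain to
  near zero when spent. Between-female lognormal noise has CV 0.20
  (deviates clipped at ±2.5σ to keep ovaries physically packable).
* True packing densities follow from opd = RF/(OW/W), with the
  ovary-to-body ratio set by stage (0.06, 0.12, 0.09, 0.06, 0.02) so the
  length-based gonadosomatic index declines through spawning.
* Wholemount observation draws 400 diameters per female, multinomially over
  phases weighted by density × detection; PVO detection is 0.10 versus 1.0
  for developing phases (small oocytes hide under large ones), which is
  what places observed oocyte ratios in the rule-table bands. Within-phase
  wholemount diameters are truncated normals with CV 0.15 (the wholemount
  channel sweeps a growth continuum binned into phases, so its size
  distributions are smooth); histology profiles use CV 0.05 (selected
  through-the-nucleus sections of a tight phase).
* Histology observation inverts the packing-density equation exactly —
  including the normal third moment E[OD³] = µ³+3µσ², so the cubic-mean
  diameter estimator is unbiased — to expected volume fractions, draws one
  500-point multinomial grid per female with OTHERS absorbing the residual
  probability, and three axis pairs per present phase at the histology
  scale (formalin diameter ÷ 1.11). Structures (POFs, α atresia) appear
  with small stage-dependent probabilities.
* Identical (config, seed) pairs give byte-identical tables; a
  configuration whose expected volume fractions exceed 0.95 is rejected as
  an overpacked ovary.

Phase diameter means (110, 140, 185, 210, 230 µm for PVO2–PVO4c; 280–950
µm for CA–GVBD) are anchored to the published landmarks; per-phase
variances are assumptions, not measured values. One deliberate departure
from published magnitude wording: early-PVO densities of "millions per
gram" are geometrically impossible at 110–140 µm diameters (a million
110 µm spheres occupy ~0.7 cm³), so the generator realises the quoted
decade *ordering* (reservoir ≫ late PVO ≫ developing) at feasible absolute
levels (~10⁴–10⁵ g⁻¹).

### What passing tests show — and don't

The closed-loop tests demonstrate that the estimators are correctly
implemented and statistically well behaved *under the generator's
assumptions*: multinomial grid sampling, normal diameter laws, exact
inverse volume fractions, perfectly known stage labels for ORC0. They do
not establish field performance where sections are anisotropic, phases are
misannotated, shrinkage varies between ovaries, or sampling is spatially
clustered. Field-scale quantities that depend on specimen data (the
observed threshold value, year-specific sensitivity percentages, the
field length–weight exponent) are reproduced qualitatively, not asserted
numerically.

## Numerical conventions

* Base-10 logarithms throughout the packing-density chain; V_V = 0 yields
  a −∞ log-density sentinel and linear OPD 0.
* EM determinism: the fit is a deterministic function of the data; the
  `seed` argument is reserved for stochastic restarts (none currently).
* Degenerate inputs: all-equal diameters get a fixed 10 µm kernel in the
  smoothed distribution; two-point length–weight fits are rejected (n ≥ 3
  required); juvenile maturity stages have no specific gravity.
* Batch counts are invariant to expressing fecundities per kg instead of
  per g when the batch fecundity is expressed in the same unit.

## Problem sizes

Default test and demonstration cohorts use 150 females (one 500-point grid
and three axis profiles each, 400 wholemount diameters), 50-replicate
mixture-recovery experiments at n = 2000, and a few hundred replicate
grids for the unbiasedness checks — sizes chosen so the whole suite runs
in well under a minute while keeping Monte-Carlo error far below the
tolerances being asserted.
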