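# ovodyn

Quantitative analysis of oocyte recruitment dynamics in serial-spawning
teleosts: stereological oocyte packing densities, wholemount spawning-stage
classification, and the de novo recruitment calculus that separates
indeterminate from determinate fecundity.

## The problem

Egg-production methods for estimating spawning stock biomass need to know a
stock's *fecundity type*: whether the season's egg number is fixed before
spawning (determinate) or topped up by de novo recruitment of new oocytes
during spawning (indeterminate). The classical diagnostic — presence or
absence of a gap (hiatus) between previtellogenic (PVO) and vitellogenic
(VO) oocytes in the oocyte size frequency distribution — is unreliable.
`ovodyn` implements a fully quantitative alternative built on two
instruments:

1. **Oocyte packing density (OPD).** From a Weibel-grid point count of a
   histological section, the Delesse principle gives each oocyte phase's
   volume fraction `V_V`, and the packing-density equation converts it to
   oocytes per gram of ovary:

   ```
   log10 OPD_i = log10[ V_Vi · (1/ρ_o) · (1+k_i)³ / (8·k_i) ]
                 + 12.28 − 3·log10(cOD_vi)
   ```

   with ovary specific gravity `ρ_o` (g cm⁻³), profile shape factor
   `k = L/S`, shrinkage-corrected volume-based diameter `cOD_v` (µm), and
   12.28 = log10((6/π)·10¹²) the µm³→cm³ unit constant. The shape term
   follows exactly from modelling oocytes as prolate spheroids (axes
   L, S, S) with OD = (L+S)/2.

2. **Ultrametric spawning staging.** From wholemount diameters, the oocyte
   ratio `OR = ΣPVO / Σ(VO+FOM)` (diameter split at 230 µm) is binned into
   oocyte-ratio categories ORC0–4 (prespawning → spent). A two-component
   Gamma + Gaussian mixture, fitted per female by EM, estimates the
   PVO/developing diameter threshold when no hiatus exists.

Packing densities become fecundities via `NO_i = OPD_i × OW`,
`RF_i = NO_i / W` (oocytes per g body weight) and
`RF_TL,i = 100 · NO_i / TL^b`. The decline of the most advanced PVO phase
(PVO4c) from prespawning (ORC0) to spent (ORC4) measures the **de novo
influx**; added to the prespawning standing stock (RF summed PVO4c→GVBD)
and divided by a batch fecundity it yields the number of egg batches a
typical female produces. A 185 µm vs 230 µm lower-threshold sensitivity
quantifies how much legacy fecundity protocols overcount.

Because field specimens are rarely available, the package ships a seeded
synthetic-ovary generator (`ovodyn.synthetic`) with complete ground truth —
per-female phase densities, latent spawning stage, programmed influx — and
simulators for both observation channels (wholemount detection bias,
multinomial grid counts, histological shrinkage), so every stage of the
pipeline is testable end to end.

## Worked example

Generate a 150-female synthetic cohort and run the full pipeline:

```sh
ovodyn simulate --out demo --seed 42
ovodyn run --females demo/females.csv --wholemount demo/wholemount.csv \
           --hits demo/histology_hits.csv --axes demo/histology_axes.csv \
           --out demo/out
```

The report printed to stdout (and written to `demo/out/report.md`) includes:

```
## Mixture threshold

Mean PVO/developing diameter threshold over 21 fitted females: 181.3 um
(95% CI 178.1-184.6 um).

## Recruitment

- prespawning (ORC0) aggregate RF (PVO4c-GVBD, per-female sums then mean): 530.7 oocytes g^-1 body weight
- de novo influx (PVO4c, ORC0 minus ORC4): 172.5 +/- 24.9 oocytes g^-1
- total potential RF: 703.2 oocytes g^-1

| batch fecundity (oocytes g^-1) | batches (ratio) | batches (rounded) |
|---|---|---|
| 40 | 17.58 | 18 |
| 30 | 23.44 | 23 |
| 34 | 20.68 | 21 |

## Threshold sensitivity (legacy vs revised lower phase bound)

 year  mean_pct_reduction  n
 2019           28.918734 68
```

Reading it: the cohort was generated with a programmed PVO4c influx of 160
oocytes g⁻¹ and a prespawning PVO4c→GVBD aggregate of 528; the pipeline
recovers 172.5 ± 24.9 and 530.7 from the simulated histology and wholemount
observations alone. The fitted diameter threshold (181 µm) sits below the
histological 230 µm landmark — the known downward displacement of the
two-component approximation. Moving the lower counting bound from PVO4a
(185 µm) to PVO4c (230 µm) reduces aggregated relative fecundity by ~29%
in actively spawning females. With a batch fecundity of 40 oocytes g⁻¹ the
standard female produces ~18 batches.

The same stages are available individually (`ovodyn ultrametric`,
`ovodyn stereology`, `ovodyn biometrics`, `ovodyn recruit`) and as library
functions; see `docs/methods.md` for the model details and assumptions.

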