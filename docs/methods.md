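# Methods

This note documents the statistical procedures implemented in
`effluxsig`, the design decisions taken where the underlying assay
protocol leaves the analysis open, and what the synthetic-data generator
does and does not emulate.

## Data model and normalization

The unit of analysis is a wide peak-area table: samples × metabolites of
non-negative areas from targeted LC-MS quantitation, annotated with a
treated/control (or KO/WT) group per sample. Missing cells are kept as
missing, never imputed to zero; they are excluded from normalization
denominators and propagated.

Total-sum normalization divides each sample's areas by that sample's
summed area over the quantified *cellular* analytes. The spiked
instrument-control analyte (an olomoucine spike at constant
concentration) is excluded from the denominator and dropped from the
normalized matrix: it is added after extraction and tracks the
instrument, not the cell, so including it would dilute every biological
proportion by an arbitrary constant. Normalizing twice is rejected
rather than silently ignored. Instrument QC is the control analyte's CV
across samples on the raw areas (n−1 denominator), with a default
acceptance bound of 0.20 — the assay monitors the spike but publishes no
bound, so this is a package default. Monolayer QC keeps wells with TEER
strictly above 1000 Ω·cm².

## OPLS-DA

For a binary class vector `y` the model is deterministic and needs no
iterative NIPALS: the PLS weight vector has the closed form `w ∝ Xᵀy`.
Orthogonal components are extracted first (Trygg–Wold construction: the
orthogonal weight is the predictive loading minus its projection on `w`),
each deflated from X, and one predictive component is then fit on the
deflated matrix. By construction every orthogonal score vector is exactly
orthogonal to the predictive scores. Defaults: unit-variance scaling
after mean centering (the usual choice for metabolomics; pareto and
center-only are available), one predictive component (binary problem),
orthogonal components selected by cross-validation.

Cross-validation uses venetian-blind fold assignment over a seeded
sample permutation, 7 folds by default, deterministic given the seed.
`Q² = 1 − PRESS/SS(y)`; the number of orthogonal components is the
smallest k whose Q² is within 0.01 of the best over 0..max_k (default
max 2). Degenerate folds whose training split loses a class predict the
training mean.

Permutation validation refits the entire pipeline — including component
selection — under random relabelings and reports
`p = (1 + #{Q²_perm ≥ Q²_obs}) / (n_perm + 1)` (add-one correction;
default 99 permutations). Measured on null tables (12 × 20) the test
rejects at p < 0.05 in ≈ 4–5% of simulations, i.e. it holds its nominal
size.

### VIP

With a single predictive component the variable-importance formula
reduces to `VIP_j = √p · |w_j| / ‖w‖`, so mean(VIP²) = 1 exactly — an
algebraic identity the test suite asserts on every fit. The signature
threshold VIP > 0.75 is strict.

### Outlier diagnostics

DModX is the per-sample residual standard deviation relative to the
pooled model residual sd computed with the sample itself left out. The
leave-one-out form matters at n ≈ 12: a gross outlier contributes most of
the pooled residual variance and would otherwise shrink its own distance
below the critical value. DModX² is referred to an
F(K−A, (N−A−2)(K−A)) quantile.

Hotelling's T² combines predictive and orthogonal scores. For *training*
scores the variance estimate contains the tested sample, so T² is
bounded by (N−1)²/N and follows (N−1)²/N · Beta(A/2, (N−A−1)/2) exactly
— the familiar F form applies only to new observations and is
unattainable for training samples at small N and strict alpha (at
N = 12 the F-form 99.9% critical is ≈ 19.7 while the largest possible
training T² is ≈ 10.1). The beta form is therefore used for the ellipse.

Diagnostics are reported at alpha 0.05 (the conventional 95% ellipse:
about one sample in twenty sits outside by chance and deserves
inspection, not deletion), while automatic elimination uses alpha 0.001
and iterates fit → flag → drop (default 3 rounds), never reducing a
class below 3 samples. On simulated tables with a 10% outlier rate this
removes only planted outliers in 46/50 runs, catches 67/74 of them, and
touches 2/50 clean tables.

## Per-metabolite statistics and signatures

Percent change is `100 · (mean_T − mean_C)/mean_C` on normalized areas;
a zero control mean marks the metabolite undefined rather than dropping
it. Significance is the unpaired two-sided Mann–Whitney test — exact by
enumeration when both groups have ≤ 8 tie-free observations, otherwise
the normal approximation with midrank tie correction and continuity
correction — with the usual star tiers at 0.05/0.01/0.001/0.0001 and no
multiplicity correction gating anything (a Benjamini–Hochberg column is
emitted for reference only).

A metabolite enters a transporter's consensus signature iff VIP > 0.75
and its percent change has the same nonzero sign in **every** supplied
experiment (each inhibitor and the knockout). Requiring the bar in all
experiments, rather than in a designated main inhibitor plus KO only, is
a deliberate choice: at 6 + 6 replicates a null metabolite exceeds
VIP 0.75 in a single model with probability ≈ 0.25, so any two-experiment
rule admits several chance members per run, while the four-experiment
consensus with sign agreement suppresses them (measured false-positive
expectation ≪ 1 per derivation) and matches the biological intent —
changes reproducible across chemically unrelated inhibitors and a
genetic knockout are transporter effects, not compound effects.
Direction conflicts are excluded with a logged reason; the result is
independent of experiment order.

Dose–response checks use Spearman rank correlation of percent change
against dose, with an exact two-sided p by full permutation enumeration
for ≤ 8 dose levels (a constant series is reported as rho = 0, p = 1).

## Inhibition score and classification

The score is the plain signed sum of signature-member percent changes;
decreases count negatively and no expected direction is folded in, which
is what makes the BCRP band negative. Bands follow the published
wording: Pgp strict (> 600), MRP2 inclusive (300–600), BCRP strict
(< 0). Flags are independent — the bands genuinely overlap (Pgp and MRP2
share arginine, threonine and pantothenate) and no precedence is
imposed. Signature members missing from a panel are skipped and
reported; a score over fewer than half the members is refused. Scores
are invariant to any per-sample global scaling of raw areas (the
normalization and ratio structure cancel it), and replicate experiments
are classified individually.

## Transport arithmetic

`Papp = (dQ/dt · Vr)/(C0 · A)` with dQ/dt the least-squares slope of
receiver concentration vs time over the sink-condition window (points
with receiver < 10% of C0; all points if fewer than three qualify);
µM/s · mL / (µM · cm²) reduces to cm/s. A negative fitted slope beyond
tolerance returns 0 with a warning. Default geometry: insert area
0.11 cm², apical volume 0.1 mL, basolateral 0.3 mL. Efflux ratio is
Papp(B→A)/Papp(A→B), undefined (error) at zero denominator; inhibitor
effect is the signed percent reduction of the ratio.

## The synthetic-data generator

The generator emulates the *statistical* structure the analysis relies
on, not the chromatography:

* per-metabolite log-normal baselines whose medians span 3.5 decades
  (log10 medians uniform on [4.0, 7.5]);
* signature metabolites drawn as low-to-mid-abundance analytes (log10
  medians on [4.3, 5.3]), as in real targeted panels where a few
  high-abundance species dominate the summed signal — planted effects
  therefore perturb the total-sum denominator only mildly;
* a per-sample multiplicative size factor (CV 10%) standing in for
  extraction-volume/cell-count variation, which total-sum normalization
  removes exactly;
* multiplicative log-normal replicate noise, default CV 10% (typical
  targeted LC-MS precision); peak areas are positive and
  heteroscedastic, so noise is multiplicative, not additive;
* planted fold-change effects applied to treated samples **before** the
  size factor, so normalized data carry the effect; defaults 1.6 for
  increased and 0.6 for decreased metabolites — calibration choices, the
  assay reports direction but not per-metabolite magnitudes;
* outlier samples (default rate 0.05) whose metabolites each receive a
  log-normal distortion with σ = ln 5 (a "typical 5×" per-analyte
  distortion). A *uniform* 5× factor would be removed exactly by
  total-sum normalization and be undetectable by construction, so the
  distortion is per-metabolite;
* a spiked control analyte at constant area with 1% CV, unaffected by
  size factors or outlier distortion (it is added post-extraction).

Default design: 6 replicates per group, 80 cellular analytes per panel
(the packaged signature metabolites plus deterministic fillers
`analyte_NNN`), three inhibitor experiments plus one knockout per
signature derivation, dose series with per-dose attenuation applied on
the log-fold scale (`fold^attenuation`). Everything is reproducible
bit-for-bit from (scenario, panel size, seed).

What passing tests on this generator show — and what they do not: the
pipeline recovers planted signatures and score bands under realistic
noise, size-factor and outlier contamination; they do not establish
performance against correlated metabolite networks, batch drift,
censored/missing low-abundance peaks, or matrix effects, none of which
the generator models.

## Problem sizes and numerical choices

Simulation-backed checks use 25 runs (signature recovery), 50 runs
(score bands and specificity) and 200 runs (permutation-test size) at
the default 12-sample, 80-analyte scale; these sizes keep the full suite
to a few minutes while leaving binomial margins interpretable. Fit
tolerances: rank guards at 1e-12, orthogonality asserted at 1e-8,
normalized row sums at 1e-9. Fold assignment, permutations and every
generator draw go through seeded `numpy` generators; identical seeds
reproduce identical outputs everywhere.

## Known limitations

* Binary designs only — one predictive component; no multi-class OPLS-DA
  or O2-PLS.
* The consensus rule treats all supplied experiments as gating; there is
  no weighting by experiment quality (Q²).
* The BCRP band (< 0) flags noise-level negative scores, as the vehicle
  example shows; it indicates *an interaction* rather than inhibition
  specifically.
* Papp assumes sink conditions and linear uptake; no mass-balance or
  recovery accounting, and no fluorescence calibration.
* The score does not average replicate experiments before
  classification; replicates are reported individually with their mean
  available downstream.
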