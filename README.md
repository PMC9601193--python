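# effluxsig

Metabolomic flagging of efflux-transporter inhibitors in the routine
Caco-2 permeability assay.

## The problem

Caco-2 monolayers on transwell filters are the standard in-vitro model of
intestinal drug permeability. The assay readily identifies *substrates*
of the apical efflux transporters P-glycoprotein (Pgp/ABCB1), BCRP
(ABCG2) and MRP2 (ABCC2), but flagging *inhibitors* — the other half of a
transporter-mediated drug–drug interaction — normally requires separate,
dedicated experiments. Inhibiting an efflux pump, however, also changes
the cell's intracellular metabolite pool, because the transporters export
endogenous metabolites too. `effluxsig` implements the analysis that
turns that observation into a screen: targeted LC-MS peak areas from the
cells of an ordinary permeability experiment are normalized, modelled,
reduced to per-transporter metabolite signatures, and summarised as an
inhibition score with published classification bands.

The package is aimed at DMPK/metabolomics analysts. It is a library first
(see `examples/`), with a thin `effluxsig` CLI for manifest-driven runs.

## The method

For one treated-vs-control experiment (≥ 6 replicates per group):

1. **Normalization.** Each sample's peak areas are divided by its total
   quantified analyte area (the spiked instrument-control analyte is
   excluded), removing extraction and loading variation.
2. **OPLS-DA.** A discriminant model with one predictive component and
   cross-validated selection of orthogonal components; fit quality is
   reported as R²X, R²Y and Q², validated by label permutation. Outlying
   samples (DModX, Hotelling's T²) are flagged and eliminated.
3. **VIP + consensus signature.** A metabolite joins a transporter's
   signature only with VIP > 0.75 and a consistent direction of change in
   every supporting experiment (three chemically distinct inhibitors and
   the transporter knockout).
4. **Percent change and score.** Per metabolite *m*,
   `Δ_m = 100 · (mean_treated − mean_control) / mean_control` on
   normalized areas (unpaired Mann–Whitney per metabolite); the
   transporter's **inhibition score** is `S = Σ_{m ∈ signature} Δ_m`,
   signed. Classification bands: Pgp interaction `S > 600`, MRP2
   interaction `300 ≤ S ≤ 600`, BCRP interaction `S < 0`.

Packaged reference signatures: 11 Pgp metabolites (all increased), 4 BCRP
metabolites (glutamate, hypoxanthine, xanthine decreased; pantothenate
increased), 9 MRP2 metabolites (acetylcarnitine decreased, the rest
increased).

Transwell arithmetic is included as the functional QC arm:
`Papp = (dQ/dt · Vr) / (C0 · A)` in cm/s and the efflux ratio
`Papp(B→A)/Papp(A→B)`, plus TEER monolayer filtering (> 1000 Ω·cm²).

A seeded synthetic-data generator (`effluxsig.simulate`) emulates the
statistical structure of the peak-area tables — log-normal baselines over
3.5 decades, per-sample size factors, multiplicative replicate noise,
planted fold-change effects, occasional outlier samples and a spiked
control analyte — so the whole pipeline is testable without any
instrument data.

## Worked example

```python
from effluxsig import (analyze_experiment, builtin_scenarios,
                       generate_peak_table, inhibition_score,
                       reference_signatures)

table, truth = generate_peak_table(builtin_scenarios()["pgp_inhibitor"], seed=1)
analysis = analyze_experiment(table)
score = inhibition_score(analysis.percent_changes, reference_signatures()["pgp"])
print(analysis.model.r2y, analysis.q2, score.score)
```

Running `python examples/04_score_and_classify.py` prints:

```
compound                pgp     mrp2     bcrp  flags
pgp_inhibitor         687.9    180.2     56.3  pgp
mrp2_inhibitor        192.8    448.0     56.4  mrp2
bcrp_inhibitor         77.3     64.8    -63.8  bcrp
vehicle                19.1      6.6     -1.1  bcrp
```

Each simulated inhibitor lands in its own transporter's band (687.9 > 600
for Pgp; 448.0 in 300–600 for MRP2; −63.8 < 0 for BCRP) and the vehicle
triggers neither the Pgp nor the MRP2 band. The vehicle's spurious BCRP
flag illustrates why a "score below zero" band cannot distinguish weak
interactions from noise. The other examples cover simulation and
normalization, OPLS-DA/VIP, signature derivation, transwell permeability
and dose–response trends; the CLI mirrors them
(`effluxsig simulate|normalize|opls|signature|score|transport|run`).

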