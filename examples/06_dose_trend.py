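"""Concentration-dependence of signature-metabolite changes.

Simulates an inhibitor dose series with attenuated effects at low doses
and tests each planted metabolite's percent change for a monotone trend
across doses (Spearman rank correlation, exact small-n p-value).
"""

from effluxsig import Scenario, analyze_experiment, concentration_trend, generate_dose_series

scenario = Scenario(
    name="zosuquidar_titration",
    transporter="pgp",
    role="inhibitor",
    effects={"methionine": 1.6, "nicotinamide": 1.6, "pantothenate": 1.6},
    noise_cv=0.05,
    outlier_rate=0.0,
    dose_series=[(0.37, 0.25), (1.1, 0.5), (3.3, 0.75), (10.0, 1.0)],  # µM
)

series = generate_dose_series(scenario, seed=2)
tables = [analyze_experiment(table).percent_changes for _, table, _ in series]
doses = [dose for dose, _, _ in series]

print("dose (µM):", doses)
for met in scenario.effects:
    changes = [t.percent_change(met) for t in tables]
    rho, p = concentration_trend(tables, met, doses=doses)
    print(f"{met:<14s} changes: "
          + " ".join(f"{c:+6.1f}%" for c in changes)
          + f"   rho={rho:+.2f} p={p:.3f}")
# rho = +1 across four doses (p = 1/12) says the metabolite rises strictly
# with inhibitor concentration — the dose-response fingerprint expected of
# a genuine transporter-mediated effect.
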