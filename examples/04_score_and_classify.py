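"""Score simulated compounds against the packaged transporter signatures.

The inhibition score for a transporter is the sum of the signed percent
changes of its signature metabolites. Published bands: Pgp interaction
> 600, MRP2 interaction 300-600, BCRP interaction < 0.
"""

from effluxsig import (
    analyze_experiment,
    builtin_scenarios,
    generate_peak_table,
    reference_signatures,
    score_report,
)

scenarios = ["pgp_inhibitor", "mrp2_inhibitor", "bcrp_inhibitor", "vehicle"]
experiments = []
for name in scenarios:
    table, _ = generate_peak_table(builtin_scenarios()[name], seed=1)
    experiments.append((analyze_experiment(table).percent_changes, name))

reports = score_report(experiments, reference_signatures())
print(f"{'compound':<18s} {'pgp':>8s} {'mrp2':>8s} {'bcrp':>8s}  flags")
for r in reports:
    flags = ",".join(t for t, f in r.flags.items() if f) or "-"
    print(f"{r.compound:<18s} {r.scores['pgp']:8.1f} {r.scores['mrp2']:8.1f} "
          f"{r.scores['bcrp']:8.1f}  {flags}")
# Each inhibitor scenario should flag only its own transporter; the
# vehicle should flag neither Pgp nor MRP2 (the BCRP band, being "score
# below zero", cannot separate weak interactions from noise).
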