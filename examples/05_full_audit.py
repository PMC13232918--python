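"""Run the complete data-quality audit and write the JSON report.

Every check — validation, averaging, difference summaries, digit
preference, the dBP=62 spike and both threshold tests — over every stratum
(cohort x measure x raw/averaged, plus pooled).
"""

from bpqc import SimConfig, run_audit, simulate_cohort, write_audit_report

vt = simulate_cohort(
    SimConfig(n_visits=1500, theta0=0.15, theta5=0.05, pi62=0.3,
              phi_avoid=0.3, mu_sbp=125.0, seed=51)
)
report = run_audit(vt, seed=51)
write_audit_report(report, "audit_report.json")

dp = report["digit_preference"]["raw/sbp/pooled"]
sp = report["spike_artifact"]["dbp=62/pooled"]
seg = report["threshold_behavior"]["raw/sbp@140/pooled"]
print(f"visits kept: {report['validation']['n_visits_kept']}")
print(f"raw sBP terminal-0: {100*dp['prop0']:.1f}% (p={dp['p0']:.2g})")
print(f"dBP=62 raw {100*sp['prop_raw']:.2f}% vs averaged {100*sp['prop_avg']:.2f}%, "
      f"RR {sp['rr']:.2f}")
print(f"sBP@140: {seg['direction']} (LRT p={seg['p_value']:.2g})")
print("full report written to audit_report.json")
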