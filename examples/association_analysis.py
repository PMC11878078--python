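"""Carriage-vs-resistance association statistics on a synthetic cohort.

Simulates a full-size cohort (25 patients x 3 isolates, 4 lytic
phages), takes the latent outcome grid as the resistance matrix, and
computes the association report: carrier/non-carrier contingency with
Fisher and chi-square, conditional probabilities, per-system
differential probability dPR, and the defense-system-count regression.
"""

from pfresist import (
    ResistanceMatrix,
    SimulationConfig,
    association_report,
    simulate_cohort,
    simulate_interaction_outcomes,
)

config = SimulationConfig(seed=3)
cohort, truth = simulate_cohort(config)
truth = simulate_interaction_outcomes(cohort, truth, config)
matrix = ResistanceMatrix(data=truth.outcome)

report = association_report(matrix, cohort)

inter = report["interactions"]
print(f"{inter['total']} interactions: {inter['resistant']} R, {inter['sensitive']} S")
print(f"contingency (carrier R/S, non-carrier R/S): {report['contingency']}")
print(f"Fisher two-sided p: {report['fisher_p']:.3g}")
print(f"chi-square: {report['chi2']['statistic']:.2f} (p = {report['chi2']['p_value']:.3g})")

cond = report["conditional_probabilities"]
print(f"P(Pf|R) = {cond['p_pf_given_r']:.3f}   P(Pf|S) = {cond['p_pf_given_s']:.3f}")

print("\nper-system dPR (carrier interactions only, default orientation):")
for row in report["dpr"]:
    if row["defined"]:
        print(f"  {row['system']:<12} dPR = {row['dpr']:+.2f} "
              f"over {row['n_carrier_interactions']:>3} interactions")
    else:
        print(f"  {row['system']:<12} undefined (no carrier interactions)")

reg = report["regression"]
print(f"\nsystems-vs-resistance OLS: slope {reg['slope']:.3f}, "
      f"r^2 = {reg['r_squared']:.3f}, p = {reg['p_value']:.3g}")

# dPR = +1 means every interaction of the system's carriers was
# resistant; 0 means an even split; negative values would indicate
# association with sensitivity.
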