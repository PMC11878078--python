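"""Simulate a small cohort and recover phenotypes from raw curves.

Generates an 8-patient synthetic cohort (triplicate spot grades and
OD600 growth curves per isolate x phage pair), runs the two-stage
infection caller on the raw data, and compares the resulting R/S
matrix against the generator's latent truth. Under the default noise
level the caller should recover the truth essentially perfectly.
"""

from pfresist import (
    SimulationConfig,
    build_resistance_matrix,
    call_interaction,
    simulate_all,
)

config = SimulationConfig(n_patients=8, seed=11)
result = simulate_all(config)

calls = []
for (iso_id, phage_id), well in result.curves.items():
    infected = [c for c in well if c.condition == "infected"]
    control = [c for c in well if c.condition == "control"]
    calls.append(
        call_interaction(iso_id, phage_id, result.spots[(iso_id, phage_id)],
                         infected, control)
    )

matrix = build_resistance_matrix(calls)
total, n_r, n_s = matrix.counts()
print(f"{total} interactions: {n_r} resistant, {n_s} sensitive")

agree = sum(
    matrix.cell(iso, ph) == result.truth.outcome.at[iso, ph]
    for iso in matrix.isolate_ids
    for ph in matrix.phage_ids
)
print(f"calls matching latent truth: {agree}/{total}")

# Each sensitive call required a positive triplicate spot AND a
# significant OD drop inside the control's exponential window; spot
# positives without growth suppression stay resistant.
spot_only = [c for c in calls if c.spot_positive and c.final == "R"]
print(f"spot-positive but non-productive (called R): {len(spot_only)}")
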