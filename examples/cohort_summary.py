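"""Summarize the packaged cohort and Pf-phage catalog.

Loads the packaged 75-isolate cystic-fibrosis cohort and its 12-phage
Pf catalog, then prints the carriage summaries a cohort paper would
report: prophage genome count, carrier split, per-patient carriage
histogram, prevalence, per-system prevalence across phages, and the
attB insertion-site distribution.
"""

from pfresist import (
    attb_distribution,
    count_pf_carriers,
    count_pf_genomes,
    distinct_complete_systems,
    load_table1_cohort,
    patient_carriage_histogram,
    pf_prevalence_percent,
    system_prevalence,
)

cohort = load_table1_cohort()
carriers, noncarriers = count_pf_carriers(cohort)

print(f"isolates: {cohort.n_isolates} from {cohort.n_patients} patients")
print(f"Pf prophage genomes: {count_pf_genomes(cohort)}")
print(f"carriers / non-carriers: {carriers} / {noncarriers}")
print(f"patients by carried isolates: {patient_carriage_histogram(cohort)}")
print(f"prevalence (genomes per 100 isolates): {pf_prevalence_percent(cohort):.1f}%")
print(f"prevalence (carrier isolates):         {pf_prevalence_percent(cohort, 'carriers'):.1f}%")

print(f"\ncatalog: {len(cohort.catalog)} Pf phages")
for sp in system_prevalence(cohort.catalog):
    print(f"  {sp.system_name:<12} in {sp.n_phages:>2}/12 phages "
          f"({100 * sp.fraction_of_phages:.0f}%)")
summary = distinct_complete_systems(cohort.catalog)
print(f"{len(summary.systems)} distinct complete systems; "
      f"{summary.n_phages_carrying} phages carry at least one")

for weighting in ("per_phage", "per_isolate"):
    dist = attb_distribution(cohort.catalog, weighting)
    print(f"attB sites {weighting}: {dist.counts} of {dist.total}")

# The genome count exceeds the carrier count because three isolates
# carry two prophages each; dividing genomes (42) by isolates (75)
# gives the 56% prevalence, carriers/isolates the more conservative 52%.
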