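"""Worked differential-probability example: an exclusive resistant system.

Builds a toy carrier set in which exactly two isolates carry the
Avs-encoding phage (PfAC11) and resist all four lytic phages, while
the other carriers' phages never encode Avs. Under the default
orientation, dPR(Avs) = P(R|Avs) - P(S|Avs) = 1: every interaction of
an Avs carrier was resistant.
"""

import pandas as pd

from pfresist import (
    Cohort,
    Isolate,
    ResistanceMatrix,
    differential_probability,
    load_table2_catalog,
)

catalog = load_table2_catalog()
by_id = {p.id: p for p in catalog}

carriage = {
    "avs-1": "PfAC11",
    "avs-2": "PfAC11",
    "other-1": "PfAC01",
    "other-2": "PfAC05",
}
outcomes = {
    "avs-1": "RRRR",
    "avs-2": "RRRR",
    "other-1": "RRSS",
    "other-2": "SSSS",
}

isolates = tuple(
    Isolate(
        id=iso_id,
        patient_id=iso_id,
        pf_ids=(pf_id,),
        n_genome_systems=len(by_id[pf_id].system_names),
        genome_system_names=by_id[pf_id].system_names,
    )
    for iso_id, pf_id in carriage.items()
)
cohort = Cohort(isolates=isolates, catalog=tuple(catalog))
matrix = ResistanceMatrix(
    data=pd.DataFrame(
        [list(outcomes[i]) for i in carriage],
        index=pd.Index(list(carriage), name="isolate_id"),
        columns=["DCL-PA6", "DCL-PA6a", "PAC2", "PAC8"],
    )
)

for r in differential_probability(matrix, cohort):
    status = f"{r.dpr:+.2f}" if r.defined else "undefined"
    print(f"{r.system_name:<10} dPR = {status:<10} "
          f"(n = {r.n_carrier_interactions} carrier interactions)")

# Avs reaches the maximum dPR of +1 because its 8 carrier interactions
# are all resistant; systems shared with sensitive carriers score lower.
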