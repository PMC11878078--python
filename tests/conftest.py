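import pytest

from pfresist import (
    Cohort,
    Isolate,
    SimulationConfig,
    load_table1_cohort,
    load_table2_catalog,
    simulate_cohort,
    simulate_interaction_outcomes,
)


@pytest.fixture(scope="session")
def catalog():
    return load_table2_catalog()


@pytest.fixture(scope="session")
def table1(catalog):
    return load_table1_cohort()


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated cohort with latent outcomes."""
    config = SimulationConfig(n_patients=8, seed=7)
    cohort, truth = simulate_cohort(config)
    truth = simulate_interaction_outcomes(cohort, truth, config)
    return config, cohort, truth


def make_carrier_cohort(catalog, spec):
    """Build a toy all-carrier cohort.

    ``spec`` maps isolate id -> catalog phage id; every isolate carries
    exactly that one phage and exactly its payload systems.
    """
    by_id = {p.id: p for p in catalog}
    isolates = []
    for iso_id, pf_id in spec.items():
        payload = frozenset(s.name for s in by_id[pf_id].systems)
        isolates.append(
            Isolate(
                id=iso_id,
                patient_id=iso_id.split("-")[0],
                st="1",
                pf_ids=(pf_id,),
                n_genome_systems=len(payload),
                genome_system_names=payload,
            )
        )
    return Cohort(isolates=tuple(isolates), catalog=tuple(catalog))
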