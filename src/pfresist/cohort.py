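"""Domain model for a clinical isolate cohort and its Pf prophage catalog.

A cohort is a set of *Pseudomonas aeruginosa* isolates sampled from
patients (here, chronic cystic-fibrosis patients, several isolates per
patient). Each isolate may carry one or more integrated filamentous Pf
prophages; each catalogued Pf phage carries a payload of anti-phage
defense systems in its accessory genome (plus PfsE in the core genome).
The counting operations in this module summarize carriage the way such
cohorts are usually reported: total prophage genomes, carrier /
non-carrier isolate counts, the per-patient carriage histogram, and
prevalence.
"""

from __future__ import annotations

import warnings
from collections import Counter
from typing import Literal

from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import InputError, ReferentialError

Strategy = Literal["abi", "restriction", "ta", "sie", "unknown"]
AttBSite = Literal["tRNA-Met", "tRNA-Gly", "tRNA-Sec"]

#: Defense strategy of each system known to occur on a Pf phage.
#: Systems absent from this lookup are classified "unknown".
STRATEGY_LOOKUP: dict[str, Strategy] = {
    "PfsE": "sie",
    "Retron": "abi",
    "Kiwa": "abi",
    "Gabija": "abi",
    "Avs": "abi",
    "TA-typeII": "ta",
    "ShosTA": "ta",
    "IetAS": "ta",
    "AbiEii toxin": "abi",
    "Cytosine methyltransferase": "restriction",
}


class DefenseSystemAnnotation(BaseModel):
    """One anti-phage defense system annotated on a Pf phage genome.

    ``complete=False`` marks a lone protein from a clustered system
    (e.g. an orphan AbiEii toxin); incomplete systems are stored but
    excluded from differential-probability statistics by default.
    """

    model_config = {"frozen": True}

    name: str = Field(min_length=1)
    strategy: Strategy = "unknown"
    complete: bool = True


def annotate_system(name: str, complete: bool = True) -> DefenseSystemAnnotation:
    """Build an annotation, resolving the strategy from the fixed lookup."""
    return DefenseSystemAnnotation(
        name=name, strategy=STRATEGY_LOOKUP.get(name, "unknown"), complete=complete
    )


class PfPhage(BaseModel):
    """One catalogued Pf phage (a group of near-identical prophage genomes)."""

    id: str = Field(min_length=1)
    n_isolates: int = Field(ge=1)
    n_patients: int = Field(ge=1)
    st_list: str = ""
    genbank: str = ""
    attb_site: AttBSite
    genome_size: int = Field(gt=0)
    n_cds: int = Field(ge=0)
    n_core_cds: int = Field(ge=0)
    n_accessory_cds: int = Field(ge=0)
    systems: tuple[DefenseSystemAnnotation, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "PfPhage":
        if self.n_core_cds + self.n_accessory_cds != self.n_cds:
            raise ValueError(
                f"{self.id}: core ({self.n_core_cds}) + accessory "
                f"({self.n_accessory_cds}) CDS != total ({self.n_cds})"
            )
        if self.n_isolates < self.n_patients:
            raise ValueError(f"{self.id}: n_isolates < n_patients")
        # Pf genomes cluster tightly around 10-14 kb; an outlier is
        # suspicious but not impossible, so warn rather than reject.
        if not 10_000 <= self.genome_size <= 15_000:
            warnings.warn(
                f"{self.id}: genome size {self.genome_size} bp outside the "
                "typical Pf range [10000, 15000]",
                stacklevel=2,
            )
        return self

    @property
    def complete_system_names(self) -> frozenset[str]:
        return frozenset(s.name for s in self.systems if s.complete)

    @property
    def system_names(self) -> frozenset[str]:
        return frozenset(s.name for s in self.systems)


class Isolate(BaseModel):
    """One clinical isolate with its Pf carriage and defense repertoire.

    ``n_genome_systems`` is the whole-genome count of anti-phage defense
    systems; it must be at least the number of distinct systems
    contributed by the carried Pf phages.
    """

    id: str = Field(min_length=1)
    patient_id: str = Field(min_length=1)
    st: str = ""
    pf_ids: tuple[str, ...] = ()
    pf_isolate_names: tuple[str, ...] = ()
    n_genome_systems: int = Field(default=0, ge=0)
    genome_system_names: frozenset[str] = frozenset()

    @property
    def is_carrier(self) -> bool:
        return len(self.pf_ids) > 0


class Cohort(BaseModel):
    """A validated collection of isolates plus the Pf phage catalog."""

    isolates: tuple[Isolate, ...] = ()
    catalog: tuple[PfPhage, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "Cohort":
        ids = [iso.id for iso in self.isolates]
        dupes = [i for i, n in Counter(ids).items() if n > 1]
        if dupes:
            raise ValueError(f"duplicate isolate ids: {sorted(dupes)}")
        known = {p.id for p in self.catalog}
        for iso in self.isolates:
            missing = [p for p in iso.pf_ids if p not in known]
            if missing:
                raise ValueError(
                    f"isolate {iso.id} references unknown Pf phage(s) {missing}"
                )
            contributed = self.pf_system_names(iso)
            if iso.n_genome_systems < len(contributed):
                raise ValueError(
                    f"isolate {iso.id}: n_genome_systems ({iso.n_genome_systems}) "
                    f"< systems contributed by carried Pf phages ({len(contributed)})"
                )
        return self

    # -- lookups ---------------------------------------------------------

    def phage(self, pf_id: str) -> PfPhage:
        for p in self.catalog:
            if p.id == pf_id:
                return p
        raise ReferentialError(f"unknown Pf phage id {pf_id!r}")

    def isolate(self, isolate_id: str) -> Isolate:
        for iso in self.isolates:
            if iso.id == isolate_id:
                return iso
        raise ReferentialError(f"unknown isolate id {isolate_id!r}")

    def pf_system_names(self, isolate: Isolate, complete_only: bool = False) -> frozenset[str]:
        """Distinct defense-system names contributed by an isolate's Pf phages."""
        by_id = {p.id: p for p in self.catalog}
        names: set[str] = set()
        for pf_id in isolate.pf_ids:
            phage = by_id[pf_id]
            names |= phage.complete_system_names if complete_only else phage.system_names
        return frozenset(names)

    def by_patient(self) -> dict[str, list[Isolate]]:
        groups: dict[str, list[Isolate]] = {}
        for iso in self.isolates:
            groups.setdefault(iso.patient_id, []).append(iso)
        return groups

    @property
    def n_isolates(self) -> int:
        return len(self.isolates)

    @property
    def n_patients(self) -> int:
        return len({iso.patient_id for iso in self.isolates})

    def carriers(self) -> list[Isolate]:
        return [iso for iso in self.isolates if iso.is_carrier]

    def noncarriers(self) -> list[Isolate]:
        return [iso for iso in self.isolates if not iso.is_carrier]


# -- counting operations -------------------------------------------------


def count_pf_genomes(cohort: Cohort) -> int:
    """Total number of Pf prophage genomes, summed over isolates.

    An isolate carrying two distinct prophages contributes two.
    """
    return sum(len(iso.pf_ids) for iso in cohort.isolates)


def count_pf_carriers(cohort: Cohort) -> tuple[int, int]:
    """(carrier, non-carrier) isolate counts; the two always sum to n_isolates."""
    carriers = sum(1 for iso in cohort.isolates if iso.is_carrier)
    return carriers, cohort.n_isolates - carriers


def patient_carriage_histogram(cohort: Cohort) -> dict:
    """Number of patients by how many of their isolates carry a Pf phage.

    When every patient contributed the same number of isolates the keys
    are integer carried-isolate counts (e.g. ``{3: 10, 2: 3, 1: 3, 0: 9}``
    for triplet sampling). With unequal sampling depth the histogram
    degrades gracefully to the categories ``"all"``, ``"some"``, ``"none"``.
    """
    groups = cohort.by_patient()
    sizes = {len(v) for v in groups.values()}
    hist: Counter = Counter()
    for isolates in groups.values():
        carried = sum(1 for iso in isolates if iso.is_carrier)
        if len(sizes) <= 1:
            hist[carried] += 1
        elif carried == len(isolates):
            hist["all"] += 1
        elif carried == 0:
            hist["none"] += 1
        else:
            hist["some"] += 1
    return dict(hist)


def pf_prevalence_percent(
    cohort: Cohort, basis: Literal["genomes", "carriers"] = "genomes"
) -> float:
    """Pf prevalence as a percentage of isolates.

    ``basis="genomes"`` (default) divides the number of Pf genomes by the
    number of isolates; with multi-carriage this can exceed the carrier
    fraction (and can exceed 100). ``basis="carriers"`` divides carrier
    isolates by all isolates.
    """
    if cohort.n_isolates == 0:
        raise InputError("prevalence undefined for an empty cohort")
    if basis == "genomes":
        return 100.0 * count_pf_genomes(cohort) / cohort.n_isolates
    return 100.0 * count_pf_carriers(cohort)[0] / cohort.n_isolates
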