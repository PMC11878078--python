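"""Queries over the Pf phage catalog.

Covers the three summaries usually reported for a prophage catalog —
per-system prevalence across phages, the distribution of attB
(tRNA) insertion sites, and a keyword classifier assigning annotated
CDS products to the conserved core genome (replication, structure,
integration) or the variable accessory genome (defense systems, morons,
hypotheticals).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Literal, Sequence

from .cohort import AttBSite, PfPhage
from .errors import InputError

logger = logging.getLogger(__name__)

ATTB_SITES: tuple[AttBSite, ...] = ("tRNA-Met", "tRNA-Gly", "tRNA-Sec")


@dataclass(frozen=True)
class SystemPrevalence:
    """How many catalog phages carry a given defense system."""

    system_name: str
    n_phages: int
    fraction_of_phages: float


@dataclass(frozen=True)
class AttBDistribution:
    """attB insertion-site counts, weighted per phage or per isolate."""

    weighting: Literal["per_phage", "per_isolate"]
    counts: dict[AttBSite, int]
    fractions: dict[AttBSite, float]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def system_prevalence(
    catalog: Sequence[PfPhage], include_incomplete: bool = False
) -> list[SystemPrevalence]:
    """Prevalence of each defense system across the catalog.

    Each phage counts at most once per system name. Incomplete systems
    (orphan proteins of clustered systems) are skipped unless
    ``include_incomplete`` is set. Sorted by descending count, then name.
    """
    if not catalog:
        raise InputError("system prevalence undefined for an empty catalog")
    counts: Counter = Counter()
    for phage in catalog:
        names = phage.system_names if include_incomplete else phage.complete_system_names
        counts.update(names)
    n = len(catalog)
    return [
        SystemPrevalence(name, k, k / n)
        for name, k in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


@dataclass(frozen=True)
class CompleteSystemSummary:
    systems: frozenset[str]
    n_phages_carrying: int


def distinct_complete_systems(catalog: Sequence[PfPhage]) -> CompleteSystemSummary:
    """Distinct complete defense systems and the phages that carry any."""
    names: set[str] = set()
    n_carrying = 0
    for phage in catalog:
        complete = phage.complete_system_names
        names |= complete
        if complete:
            n_carrying += 1
    return CompleteSystemSummary(frozenset(names), n_carrying)


def attb_distribution(
    catalog: Sequence[PfPhage],
    weighting: Literal["per_phage", "per_isolate"] = "per_phage",
) -> AttBDistribution:
    """Distribution of tRNA attB insertion sites across the catalog.

    ``per_phage`` counts each catalog entry once; ``per_isolate`` weights
    each entry by the number of isolates (prophage genomes) it groups.
    """
    if not catalog:
        raise InputError("attB distribution undefined for an empty catalog")
    counts: dict[AttBSite, int] = {site: 0 for site in ATTB_SITES}
    for phage in catalog:
        counts[phage.attb_site] += phage.n_isolates if weighting == "per_isolate" else 1
    total = sum(counts.values())
    fractions = {site: (c / total if total else 0.0) for site, c in counts.items()}
    return AttBDistribution(weighting=weighting, counts=counts, fractions=fractions)


# Core-genome gene products of integrative Pf phages (the Pf4-like
# replication/structure/integration module), matched case-insensitively
# by keyword with common annotation synonyms.
_CORE_KEYWORDS: dict[str, tuple[str, ...]] = {
    "repressor": ("c repressor", "pf4r", "repressor c protein"),
    "excisionase": ("excisionase", "xisf4"),
    "ssdna-binding": (
        "single-stranded dna binding",
        "single stranded dna binding",
        "ssdna-binding",
        "ssb protein",
    ),
    "major-coat": ("major coat protein", "coab"),
    "minor-coat": ("minor coat protein", "coaa"),
    "zot": ("zot",),
    "replication-initiator": ("replication initiation", "replication initiator"),
    "integrase": ("integrase", "intf"),
}

# Annotations that contain a core keyword but are accessory-genome
# regulators, not the core gene itself (e.g. "excisionase negative
# regulator", Arc-family lysis/lysogeny repressors).
_ACCESSORY_OVERRIDES: tuple[str, ...] = ("negative regulator", "arc family")


def classify_cds_role(product_description: str) -> Literal["core", "accessory"]:
    """Classify an annotated CDS product as core or accessory genome.

    A description matching any core-gene keyword (repressor/pf4r,
    excisionase XisF4, ssDNA-binding protein, coat proteins CoaA/CoaB,
    Zot domain, replication initiator, integrase IntF) is core; anything
    else — defense systems, hypotheticals, Arc-family regulators — is
    accessory. Matching is case-insensitive and order-independent.
    """
    if not product_description or not product_description.strip():
        raise InputError("empty CDS product description")
    text = product_description.lower()
    if any(override in text for override in _ACCESSORY_OVERRIDES):
        return "accessory"
    for keywords in _CORE_KEYWORDS.values():
        if any(kw in text for kw in keywords):
            return "core"
    logger.debug("unrecognized CDS product %r classified accessory", product_description)
    return "accessory"
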