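"""Association statistics linking Pf carriage and defense systems to resistance.

The analysis unit is the *interaction*: one isolate challenged with one
lytic phage, classified Resistant (R) or Sensitive (S). For a cohort of
75 isolates and 4 phages that is a grid of 300 interactions. The module
provides:

* the carrier/non-carrier x R/S contingency table with Fisher's exact
  and chi-square tests;
* conditional probabilities P(Pf|R), P(nPf|R), P(Pf|S), P(nPf|S);
* the per-system differential probability dPR, computed among
  Pf-carrier interactions only. The default orientation contrasts
  outcomes given the system, dPR = P(R|DF) - P(S|DF), which equals
  2f - 1 where f is the resistant fraction of the system's carrier
  interactions; the alternative orientation contrasts system carriage
  given the outcome, dPR = P(DF|R) - P(DF|S);
* an ordinary least-squares fit of per-isolate resistant-phage count on
  defense-system count.

Isolate-level (rather than interaction-level) variants of the carriage
statistics are exposed behind ``unit="isolate"``, where an isolate
counts as resistant when it resists every phage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .calling import ResistanceMatrix
from .cohort import Cohort, PfPhage
from .errors import InputError, ReferentialError

Orientation = Literal["outcome_given_system", "system_given_outcome"]
Unit = Literal["interaction", "isolate"]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = {Pf carrier, non-carrier}, columns = {R, S}."""

    a: int  # carrier, resistant
    b: int  # carrier, sensitive
    c: int  # non-carrier, resistant
    d: int  # non-carrier, sensitive

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InputError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row_margins(self) -> tuple[int, int]:
        return self.a + self.b, self.c + self.d

    @property
    def col_margins(self) -> tuple[int, int]:
        return self.a + self.c, self.b + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def _resistant_isolate(matrix: ResistanceMatrix, isolate_id: str) -> bool:
    """Isolate-level collapse: resistant iff resistant to every phage."""
    row = matrix.data.loc[isolate_id]
    return bool((row == "R").all())


def carriage_contingency(
    matrix: ResistanceMatrix, cohort: Cohort, unit: Unit = "interaction"
) -> ContingencyTable2x2:
    """Cross-tabulate Pf carriage against the R/S outcome."""
    by_id = {iso.id: iso for iso in cohort.isolates}
    a = b = c = d = 0
    for isolate_id in matrix.isolate_ids:
        if isolate_id not in by_id:
            raise ReferentialError(f"matrix isolate {isolate_id!r} absent from cohort")
        carrier = by_id[isolate_id].is_carrier
        if unit == "isolate":
            outcomes = ["R" if _resistant_isolate(matrix, isolate_id) else "S"]
        else:
            outcomes = [matrix.cell(isolate_id, ph) for ph in matrix.phage_ids]
        for outcome in outcomes:
            if carrier and outcome == "R":
                a += 1
            elif carrier:
                b += 1
            elif outcome == "R":
                c += 1
            else:
                d += 1
    return ContingencyTable2x2(a, b, c, d)


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p (point-probability rule).

    Sums hypergeometric point probabilities of all tables with the
    observed margins that are no more probable than the observed one.
    """
    if table.total == 0:
        raise InputError("Fisher test undefined for an all-zero table")
    return float(sps.fisher_exact(table.as_array(), alternative="two-sided")[1])


def chi_square(table: ContingencyTable2x2, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 table, 1 degree of freedom."""
    if table.total == 0:
        raise InputError("chi-square undefined for an empty table")
    if 0 in table.row_margins or 0 in table.col_margins:
        raise InputError("chi-square degenerate: a table margin is zero")
    res = sps.chi2_contingency(table.as_array(), correction=yates)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ConditionalProbabilities:
    """P(carriage | outcome) over interactions; complements sum to 1.

    A conditional is ``None`` (and the matching ``defined_given_*`` flag
    False) when no interaction with that outcome exists.
    """

    p_pf_given_r: Optional[float]
    p_npf_given_r: Optional[float]
    p_pf_given_s: Optional[float]
    p_npf_given_s: Optional[float]
    n_resistant: int
    n_sensitive: int

    @property
    def defined_given_r(self) -> bool:
        return self.p_pf_given_r is not None

    @property
    def defined_given_s(self) -> bool:
        return self.p_pf_given_s is not None


def conditional_probabilities(
    matrix: ResistanceMatrix, cohort: Cohort, unit: Unit = "interaction"
) -> ConditionalProbabilities:
    """P(Pf|R), P(nPf|R), P(Pf|S), P(nPf|S) from the contingency counts."""
    t = carriage_contingency(matrix, cohort, unit=unit)
    n_r = t.a + t.c
    n_s = t.b + t.d
    p_pf_r = t.a / n_r if n_r else None
    p_pf_s = t.b / n_s if n_s else None
    return ConditionalProbabilities(
        p_pf_given_r=p_pf_r,
        p_npf_given_r=(1.0 - p_pf_r) if p_pf_r is not None else None,
        p_pf_given_s=p_pf_s,
        p_npf_given_s=(1.0 - p_pf_s) if p_pf_s is not None else None,
        n_resistant=n_r,
        n_sensitive=n_s,
    )


@dataclass(frozen=True)
class DPRResult:
    """Differential probability of one defense system.

    ``defined`` is False (and ``dpr`` None) when the conditioning side
    is empty: no carrier interaction involves the system under the
    default orientation, or there is no R or no S carrier interaction
    under the literal orientation. ``p_value`` is a per-system Fisher
    exact p on the system x outcome table among carrier interactions;
    ``q_value`` is only filled when Benjamini-Hochberg adjustment is
    requested.
    """

    system_name: str
    orientation: Orientation
    dpr: Optional[float]
    n_carrier_interactions: int
    defined: bool
    p_value: Optional[float] = None
    q_value: Optional[float] = None


def differential_probability(
    matrix: ResistanceMatrix,
    cohort: Cohort,
    catalog: Sequence[PfPhage] | None = None,
    orientation: Orientation = "outcome_given_system",
    include_incomplete: bool = False,
    adjust: Literal["none", "bh"] = "none",
) -> list[DPRResult]:
    """Per-system differential probability among Pf-carrier interactions.

    An interaction belongs to system DF when its isolate carries a Pf
    phage encoding DF. Under ``outcome_given_system`` (default),
    dPR = P(R|DF) - P(S|DF) over DF interactions; under
    ``system_given_outcome`` (the formula as usually printed),
    dPR = P(DF|R) - P(DF|S) over all carrier interactions. Either way
    dPR is in [-1, 1]. Incomplete systems are excluded by default.
    """
    if catalog is None:
        catalog = cohort.catalog
    if orientation not in ("outcome_given_system", "system_given_outcome"):
        raise InputError(f"unknown dPR orientation {orientation!r}")
    by_id = {iso.id: iso for iso in cohort.isolates}
    for isolate_id in matrix.isolate_ids:
        if isolate_id not in by_id:
            raise ReferentialError(f"matrix isolate {isolate_id!r} absent from cohort")

    system_names: list[str] = []
    for phage in catalog:
        for s in phage.systems:
            if (s.complete or include_incomplete) and s.name not in system_names:
                system_names.append(s.name)
    system_names.sort()

    # Carrier interactions with their outcome and per-isolate Pf systems.
    interactions: list[tuple[frozenset[str], str]] = []
    for isolate_id in matrix.isolate_ids:
        iso = by_id[isolate_id]
        if not iso.is_carrier:
            continue
        carried = cohort.pf_system_names(iso, complete_only=not include_incomplete)
        for ph in matrix.phage_ids:
            interactions.append((carried, matrix.cell(isolate_id, ph)))
    n_r_total = sum(1 for _, o in interactions if o == "R")
    n_s_total = len(interactions) - n_r_total

    results: list[DPRResult] = []
    for name in system_names:
        n_r = sum(1 for carried, o in interactions if name in carried and o == "R")
        n_s = sum(1 for carried, o in interactions if name in carried and o == "S")
        n_df = n_r + n_s
        if orientation == "outcome_given_system":
            defined = n_df > 0
            dpr = (n_r - n_s) / n_df if defined else None
        else:
            defined = n_r_total > 0 and n_s_total > 0
            dpr = (n_r / n_r_total - n_s / n_s_total) if defined else None
        p_value = None
        if n_df and len(interactions) > n_df:
            p_value = float(
                sps.fisher_exact(
                    [[n_r, n_s], [n_r_total - n_r, n_s_total - n_s]]
                )[1]
            )
        results.append(
            DPRResult(
                system_name=name,
                orientation=orientation,
                dpr=dpr,
                n_carrier_interactions=n_df,
                defined=defined,
                p_value=p_value,
            )
        )

    if adjust == "bh":
        idx = [i for i, r in enumerate(results) if r.p_value is not None]
        if idx:
            qs = sps.false_discovery_control([results[i].p_value for i in idx])
            for i, q in zip(idx, qs):
                r = results[i]
                results[i] = DPRResult(
                    system_name=r.system_name,
                    orientation=r.orientation,
                    dpr=r.dpr,
                    n_carrier_interactions=r.n_carrier_interactions,
                    defined=r.defined,
                    p_value=r.p_value,
                    q_value=float(q),
                )
    return results


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def ols_systems_vs_resistance(
    points: Sequence[tuple[float, float]]
) -> RegressionFit:
    """OLS of resistant-phage count on defense-system count per isolate.

    r^2 = 1 - SSres/SStot; the two-sided slope p comes from the t
    distribution with n - 2 degrees of freedom.
    """
    if len(points) < 3:
        raise InputError("regression needs at least 3 points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise InputError("degenerate design: x is constant")
    res = sps.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(points),
    )


def regression_points(
    matrix: ResistanceMatrix, cohort: Cohort
) -> list[tuple[int, int]]:
    """(n_genome_systems, n_resistant_phages) per isolate in the matrix."""
    by_id = {iso.id: iso for iso in cohort.isolates}
    pts = []
    for isolate_id in matrix.isolate_ids:
        if isolate_id not in by_id:
            raise ReferentialError(f"matrix isolate {isolate_id!r} absent from cohort")
        n_res = int((matrix.data.loc[isolate_id] == "R").sum())
        pts.append((by_id[isolate_id].n_genome_systems, n_res))
    return pts


def association_report(
    matrix: ResistanceMatrix,
    cohort: Cohort,
    orientation: Orientation = "outcome_given_system",
    include_incomplete: bool = False,
    adjust: Literal["none", "bh"] = "none",
) -> dict:
    """One JSON-serializable report with every association statistic.

    Fisher is the headline p-value; chi-square (no continuity
    correction) is reported alongside. The regression is skipped (null)
    when the design is degenerate.
    """
    table = carriage_contingency(matrix, cohort)
    cond = conditional_probabilities(matrix, cohort)
    dpr = differential_probability(
        matrix,
        cohort,
        orientation=orientation,
        include_incomplete=include_incomplete,
        adjust=adjust,
    )
    try:
        chi2_stat, chi2_p = chi_square(table)
        chi2 = {"statistic": chi2_stat, "p_value": chi2_p}
    except InputError:
        chi2 = None
    try:
        fit = ols_systems_vs_resistance(regression_points(matrix, cohort))
        regression = {
            "slope": fit.slope,
            "intercept": fit.intercept,
            "r_squared": fit.r_squared,
            "p_value": fit.p_value,
            "n": fit.n,
        }
    except InputError:
        regression = None
    total, n_r, n_s = matrix.counts()
    return {
        "interactions": {"total": total, "resistant": n_r, "sensitive": n_s},
        "contingency": {
            "carrier_resistant": table.a,
            "carrier_sensitive": table.b,
            "noncarrier_resistant": table.c,
            "noncarrier_sensitive": table.d,
        },
        "fisher_p": fisher_exact_two_sided(table),
        "chi2": chi2,
        "conditional_probabilities": {
            "p_pf_given_r": cond.p_pf_given_r,
            "p_npf_given_r": cond.p_npf_given_r,
            "p_pf_given_s": cond.p_pf_given_s,
            "p_npf_given_s": cond.p_npf_given_s,
        },
        "dpr": [
            {
                "system": r.system_name,
                "orientation": r.orientation,
                "dpr": r.dpr,
                "n_carrier_interactions": r.n_carrier_interactions,
                "defined": r.defined,
                "p_value": r.p_value,
                "q_value": r.q_value,
            }
            for r in dpr
        ],
        "regression": regression,
    }
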