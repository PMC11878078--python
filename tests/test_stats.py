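"""Association statistics vs independent brute-force oracles."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pfresist import (
    Cohort,
    ContingencyTable2x2,
    Isolate,
    ResistanceMatrix,
    carriage_contingency,
    chi_square,
    conditional_probabilities,
    differential_probability,
    fisher_exact_two_sided,
    ols_systems_vs_resistance,
)
from pfresist.errors import InputError, ReferentialError

from conftest import make_carrier_cohort

PHAGES = ["phA", "phB", "phC", "phD"]


def matrix_from(outcomes: dict[str, str]) -> ResistanceMatrix:
    """{isolate: 'RRSS'} -> matrix over the four standard phages."""
    data = pd.DataFrame(
        [list(calls) for calls in outcomes.values()],
        index=pd.Index(list(outcomes), name="isolate_id"),
        columns=PHAGES[: len(next(iter(outcomes.values())))],
    )
    return ResistanceMatrix(data=data)


def mixed_cohort(catalog, n_carriers, n_noncarriers, pf_id="PfAC03"):
    payload = frozenset(
        s.name for p in catalog if p.id == pf_id for s in p.systems
    )
    isolates = [
        Isolate(id=f"c{k}", patient_id=f"pc{k}", pf_ids=(pf_id,),
                n_genome_systems=len(payload), genome_system_names=payload)
        for k in range(n_carriers)
    ] + [
        Isolate(id=f"n{k}", patient_id=f"pn{k}", n_genome_systems=0)
        for k in range(n_noncarriers)
    ]
    return Cohort(isolates=tuple(isolates), catalog=tuple(catalog))


def fisher_enumeration(a, b, c, d):
    """Exact two-sided Fisher p: enumerate all tables with the observed
    margins, summing hypergeometric point probabilities <= the observed
    one (point-probability rule, exact rational arithmetic)."""
    r1, r2, c1 = a + b, c + d, a + c
    denom = math.comb(r1 + r2, c1)
    p_obs = Fraction(math.comb(r1, a) * math.comb(r2, c1 - a), denom)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), denom)
        if p <= p_obs:
            total += p
    return float(total)


def ols_normal_equations(x, y):
    """Brute-force simple OLS via the normal equations."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    ssres = float((resid**2).sum())
    sstot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ssres / sstot
    se = math.sqrt(ssres / (n - 2) / sxx)
    t = slope / se
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return slope, intercept, r2, p


class TestContingency:
    def test_row_margins_from_carrier_counts(self, catalog):
        cohort = mixed_cohort(catalog, 39, 36)
        outcomes = {iso.id: "RRRR" for iso in cohort.isolates}
        table = carriage_contingency(matrix_from(outcomes), cohort)
        assert table.row_margins == (156, 144)

    def test_all_resistant_empty_sensitive_margin(self, catalog):
        cohort = mixed_cohort(catalog, 2, 2)
        table = carriage_contingency(
            matrix_from({iso.id: "RRRR" for iso in cohort.isolates}), cohort
        )
        assert table.col_margins == (16, 0)

    def test_matches_brute_force_pair_enumeration(self, catalog):
        rng = np.random.default_rng(11)
        cohort = mixed_cohort(catalog, 5, 6)
        outcomes = {
            iso.id: "".join(rng.choice(["R", "S"], 4)) for iso in cohort.isolates
        }
        table = carriage_contingency(matrix_from(outcomes), cohort)
        expected = [0, 0, 0, 0]  # a, b, c, d by naive loop
        for iso in cohort.isolates:
            for call in outcomes[iso.id]:
                idx = (0 if call == "R" else 1) + (0 if iso.is_carrier else 2)
                expected[idx] += 1
        assert (table.a, table.b, table.c, table.d) == tuple(expected)

    def test_unknown_isolate_is_referential_error(self, catalog):
        cohort = mixed_cohort(catalog, 1, 1)
        with pytest.raises(ReferentialError):
            carriage_contingency(matrix_from({"ghost": "RRRR"}), cohort)

    def test_negative_count_rejected(self):
        with pytest.raises(InputError):
            ContingencyTable2x2(-1, 0, 0, 0)


class TestFisher:
    def test_hand_enumerated_table(self):
        # margins (4,4|4,4): C(8,4)=70 tables; tables at least as extreme
        # as [[3,1],[1,3]] sum to 34/70
        assert fisher_exact_two_sided(ContingencyTable2x2(3, 1, 1, 3)) == pytest.approx(
            34 / 70
        )

    def test_symmetric_table_p_is_one(self):
        assert fisher_exact_two_sided(ContingencyTable2x2(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_zero_margin_p_is_one(self):
        assert fisher_exact_two_sided(ContingencyTable2x2(3, 0, 2, 0)) == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(InputError):
            fisher_exact_two_sided(ContingencyTable2x2(0, 0, 0, 0))

    @settings(derandomize=True, deadline=None, max_examples=60)
    @given(st.tuples(*[st.integers(0, 12)] * 4))
    def test_matches_exhaustive_enumeration(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        p = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
        assert p == pytest.approx(fisher_enumeration(a, b, c, d), abs=1e-10)


class TestChiSquare:
    def test_balanced_table_statistic_zero(self):
        stat, p = chi_square(ContingencyTable2x2(10, 10, 10, 10))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # E = 12.5 in all cells: sum (O-E)^2/E = 4 * 56.25/12.5 = 18
        stat, _ = chi_square(ContingencyTable2x2(20, 5, 5, 20))
        assert stat == pytest.approx(18.0)

    def test_yates_never_exceeds_uncorrected(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            a, b, c, d = rng.integers(1, 30, 4)
            plain, _ = chi_square(ContingencyTable2x2(a, b, c, d))
            corrected, _ = chi_square(ContingencyTable2x2(a, b, c, d), yates=True)
            assert corrected <= plain + 1e-12

    def test_swapping_rows_and_columns_invariant(self):
        stat1, _ = chi_square(ContingencyTable2x2(8, 3, 2, 9))
        stat2, _ = chi_square(ContingencyTable2x2(9, 2, 3, 8))
        assert stat1 == pytest.approx(stat2)

    def test_zero_margin_rejected(self):
        with pytest.raises(InputError):
            chi_square(ContingencyTable2x2(3, 0, 2, 0))


class TestConditionalProbabilities:
    def test_perfect_separation(self, catalog):
        cohort = mixed_cohort(catalog, 2, 2)
        outcomes = {"c0": "RRRR", "c1": "RRRR", "n0": "SSSS", "n1": "SSSS"}
        cond = conditional_probabilities(matrix_from(outcomes), cohort)
        assert cond.p_pf_given_r == pytest.approx(1.0)
        assert cond.p_pf_given_s == pytest.approx(0.0)

    def test_hand_arithmetic_on_study_scale_matrix(self, catalog):
        # carriers: 31 all-R + 8 all-S -> 124 R of 156; non-carriers:
        # 23 all-R + 13 all-S -> 92 R of 144; P(Pf|R) = 124/216
        cohort = mixed_cohort(catalog, 39, 36)
        outcomes = {f"c{k}": ("RRRR" if k < 31 else "SSSS") for k in range(39)}
        outcomes |= {f"n{k}": ("RRRR" if k < 23 else "SSSS") for k in range(36)}
        cond = conditional_probabilities(matrix_from(outcomes), cohort)
        assert cond.n_resistant == 216
        assert cond.p_pf_given_r == pytest.approx(124 / 216)
        assert cond.p_pf_given_s == pytest.approx(32 / 84)

    def test_complements_sum_to_one(self, catalog):
        rng = np.random.default_rng(3)
        cohort = mixed_cohort(catalog, 4, 4)
        outcomes = {
            iso.id: "".join(rng.choice(["R", "S"], 4)) for iso in cohort.isolates
        }
        cond = conditional_probabilities(matrix_from(outcomes), cohort)
        if cond.defined_given_r:
            assert cond.p_pf_given_r + cond.p_npf_given_r == pytest.approx(1.0)
        if cond.defined_given_s:
            assert cond.p_pf_given_s + cond.p_npf_given_s == pytest.approx(1.0)

    def test_undefined_side_flagged(self, catalog):
        cohort = mixed_cohort(catalog, 1, 1)
        cond = conditional_probabilities(
            matrix_from({"c0": "RRRR", "n0": "RRRR"}), cohort
        )
        assert not cond.defined_given_s
        assert cond.p_pf_given_s is None


class TestDifferentialProbability:
    def test_avs_pattern_reaches_one(self, catalog):
        """Two Avs-carrying isolates resistant to all four phages, Avs
        absent from every other carrier: dPR(Avs) = 1."""
        cohort = make_carrier_cohort(
            catalog,
            {"11-a": "PfAC11", "11-b": "PfAC11", "01-a": "PfAC01", "05-a": "PfAC05"},
        )
        outcomes = {"11-a": "RRRR", "11-b": "RRRR", "01-a": "RRSS", "05-a": "SSSS"}
        results = {
            r.system_name: r
            for r in differential_probability(matrix_from(outcomes), cohort)
        }
        assert results["Avs"].dpr == pytest.approx(1.0)
        assert results["Avs"].n_carrier_interactions == 8

    def test_balanced_system_is_zero(self, catalog):
        cohort = make_carrier_cohort(catalog, {"a": "PfAC11", "b": "PfAC11"})
        results = differential_probability(
            matrix_from({"a": "RRSS", "b": "RSRS"}), cohort
        )
        by_name = {r.system_name: r.dpr for r in results}
        assert by_name["Avs"] == pytest.approx(0.0)

    def test_identity_dpr_equals_two_f_minus_one(self, catalog):
        rng = np.random.default_rng(21)
        cohort = make_carrier_cohort(
            catalog, {f"i{k}": pf for k, pf in enumerate(
                ["PfAC01", "PfAC02a", "PfAC02b", "PfAC05", "PfAC08", "PfAC11"])}
        )
        outcomes = {
            iso.id: "".join(rng.choice(["R", "S"], 4)) for iso in cohort.isolates
        }
        matrix = matrix_from(outcomes)
        for r in differential_probability(matrix, cohort):
            if not r.defined:
                continue
            n_r = sum(
                outcomes[iso.id].count("R")
                for iso in cohort.isolates
                if r.system_name in cohort.pf_system_names(iso, complete_only=True)
            )
            f = n_r / r.n_carrier_interactions
            assert r.dpr == pytest.approx(2 * f - 1)

    def test_both_orientations_match_exhaustive_count(self, catalog):
        rng = np.random.default_rng(8)
        spec = {f"i{k}": pf for k, pf in enumerate(
            ["PfAC01", "PfAC02b", "PfAC03", "PfAC08", "PfAC11", "PfAC16"])}
        cohort = make_carrier_cohort(catalog, spec)
        outcomes = {iso: "".join(rng.choice(["R", "S"], 4)) for iso in spec}
        matrix = matrix_from(outcomes)
        # naive enumeration of conditional frequencies
        inter = [
            (set(cohort.pf_system_names(cohort.isolate(iso), complete_only=True)), o)
            for iso in spec
            for o in outcomes[iso]
        ]
        n_r_tot = sum(1 for _, o in inter if o == "R")
        n_s_tot = len(inter) - n_r_tot
        for orientation in ("outcome_given_system", "system_given_outcome"):
            for r in differential_probability(matrix, cohort, orientation=orientation):
                n_r = sum(1 for s, o in inter if r.system_name in s and o == "R")
                n_s = sum(1 for s, o in inter if r.system_name in s and o == "S")
                if orientation == "outcome_given_system":
                    expected = (n_r - n_s) / (n_r + n_s) if n_r + n_s else None
                else:
                    expected = n_r / n_r_tot - n_s / n_s_tot
                if expected is None:
                    assert not r.defined
                else:
                    assert r.dpr == pytest.approx(expected)

    def test_incomplete_systems_excluded_by_default(self, catalog):
        cohort = make_carrier_cohort(catalog, {"a": "PfAC13"})
        results = differential_probability(matrix_from({"a": "RRRR"}), cohort)
        names = {r.system_name for r in results}
        assert "AbiEii toxin" not in names
        with_inc = differential_probability(
            matrix_from({"a": "RRRR"}), cohort, include_incomplete=True
        )
        assert "AbiEii toxin" in {r.system_name for r in with_inc}

    def test_absent_system_flagged_undefined(self, catalog):
        cohort = make_carrier_cohort(catalog, {"a": "PfAC01"})
        results = {r.system_name: r for r in
                   differential_probability(matrix_from({"a": "RRRR"}), cohort)}
        assert not results["Avs"].defined
        assert results["Avs"].dpr is None

    def test_isolate_permutation_invariance(self, catalog):
        rng = np.random.default_rng(31)
        spec = {f"i{k}": "PfAC02a" for k in range(4)} | {"x": "PfAC11"}
        cohort = make_carrier_cohort(catalog, spec)
        outcomes = {iso: "".join(rng.choice(["R", "S"], 4)) for iso in spec}
        forward = differential_probability(matrix_from(outcomes), cohort)
        shuffled = matrix_from(dict(reversed(list(outcomes.items()))))
        backward = differential_probability(shuffled, cohort)
        assert forward == backward


class TestRegression:
    def test_perfect_line(self):
        fit = ols_systems_vs_resistance([(1, 2), (2, 4), (3, 6)])
        assert fit.slope == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_flat_relationship(self):
        fit = ols_systems_vs_resistance([(0, 0), (1, 1), (2, 0)])
        assert fit.slope == pytest.approx(0.0)
        assert fit.r_squared == pytest.approx(0.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(5, 15))
            x = rng.integers(0, 20, n).astype(float)
            if np.ptp(x) == 0:
                x[0] += 1
            y = 0.3 * x + rng.normal(0, 1.0, n)
            fit = ols_systems_vs_resistance(list(zip(x, y)))
            slope, intercept, r2, p = ols_normal_equations(x, y)
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, abs=1e-10)
            assert fit.r_squared == pytest.approx(r2, abs=1e-10)
            assert fit.p_value == pytest.approx(p, abs=1e-10)

    def test_constant_x_rejected(self):
        with pytest.raises(InputError):
            ols_systems_vs_resistance([(2, 1), (2, 2), (2, 3)])

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError):
            ols_systems_vs_resistance([(1, 1), (2, 2)])
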