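"""Disproportionality statistics against independently coded oracles."""

import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from faerspv import (
    ContingencyTable,
    SignalStats,
    analyze_tables,
    apply_signal_rule,
    bcpnn_ic,
    build_cohort,
    build_tables,
    compute_signal_stats,
    deduplicate,
    prr_chi2,
    ror_ci,
    standardize_drugs,
)
from faerspv.synthetic_faers import SyntheticConfig, generate


# --- independent formula oracles (coded separately from the package) --------


def oracle_ror(a, b, c, d):
    ror = a * d / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, ror * math.exp(-1.96 * se), ror * math.exp(1.96 * se)


def oracle_prr(a, b, c, d):
    return (a / (a + b)) / (c / (c + d))


def oracle_ic(a, b, c, d):
    n11, n1, n_1, n = a, a + b, a + c, a + b + c + d
    a1 = b1 = 1.0
    al = be = 2.0
    g11 = 1.0
    g = g11 * (n + al) * (n + be) / ((n1 + a1) * (n_1 + b1))
    e = math.log2((n11 + g11) * (n + al) * (n + be) / ((n + g) * (n1 + a1) * (n_1 + b1)))
    v = (1 / math.log(2)) ** 2 * (
        (n - n11 + g - g11) / ((n11 + g11) * (1 + n + g))
        + (n - n1 + al - a1) / ((n1 + a1) * (1 + n + al))
        + (n - n_1 + be - b1) / ((n_1 + b1) * (1 + n + be))
    )
    return e, e - 1.96 * math.sqrt(v)


class TestWorkedExamples:
    def test_symmetric_table_is_null(self):
        t = ContingencyTable(10, 10, 10, 10)
        ror, lo, hi = ror_ci(t)
        assert ror == 1.0 and lo < 1.0 < hi
        prr, chi2 = prr_chi2(t)
        assert prr == 1.0 and chi2 == 0.0

    def test_worked_2x2_example(self):
        # values frozen from the closed forms evaluated before implementation
        t = ContingencyTable(10, 90, 100, 9900)
        ror, lo, hi = ror_ci(t)
        assert ror == pytest.approx(11.0, abs=0)
        assert lo == pytest.approx(5.559514928894626, rel=1e-12)
        assert hi == pytest.approx(21.76448872744693, rel=1e-12)
        prr, chi2 = prr_chi2(t)
        assert prr == pytest.approx(10.0, abs=0)
        assert chi2 == pytest.approx(74.44717444717445, rel=1e-12)

    def test_unit_table_ci_is_exp_pm_392(self):
        ror, lo, hi = ror_ci(ContingencyTable(1, 1, 1, 1))
        assert ror == 1.0
        assert lo == pytest.approx(math.exp(-3.92), rel=1e-12)  # se = 2
        assert hi == pytest.approx(math.exp(3.92), rel=1e-12)

    def test_ic_shrinks_toward_zero(self):
        ic, ic_lo = bcpnn_ic(ContingencyTable(10, 90, 100, 9900))
        assert ic == pytest.approx(2.382489137316143, rel=1e-12)
        assert ic < math.log2(10 * 10100 / (100 * 110))  # unshrunk log2 O/E = 3.199
        assert ic_lo < ic

    def test_ic_independence_limit(self):
        ic, _ = bcpnn_ic(ContingencyTable(1000, 99000, 9000, 891000))
        assert abs(ic) < 0.02

    def test_ic_negative_when_observed_below_expected(self):
        ic, _ = bcpnn_ic(ContingencyTable(0, 100, 100, 9800))
        assert ic < 0

    def test_yates_correction_reduces_chi2(self):
        t = ContingencyTable(10, 90, 100, 9900)
        assert prr_chi2(t, continuity=True)[1] == pytest.approx(66.3269408044408, rel=1e-10)


class TestOracleEquivalence:
    def test_1000_random_tables_match_oracles_to_1e10(self):
        rng = np.random.default_rng(0)
        cells = rng.integers(1, 501, size=(1000, 4))
        for a, b, c, d in cells:
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            ror, lo, hi = ror_ci(t)
            o_ror, o_lo, o_hi = oracle_ror(a, b, c, d)
            assert ror == pytest.approx(o_ror, rel=1e-10)
            assert lo == pytest.approx(o_lo, rel=1e-10)
            assert hi == pytest.approx(o_hi, rel=1e-10)
            prr, chi2 = prr_chi2(t)
            assert prr == pytest.approx(oracle_prr(a, b, c, d), rel=1e-10)
            ic, ic_lo = bcpnn_ic(t)
            o_ic, o_lo2 = oracle_ic(a, b, c, d)
            assert ic == pytest.approx(o_ic, rel=1e-10, abs=1e-12)
            assert ic_lo == pytest.approx(o_lo2, rel=1e-10, abs=1e-12)

    def test_chi2_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(1)
        for a, b, c, d in rng.integers(1, 501, size=(100, 4)):
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            expected = chi2_contingency([[a, b], [c, d]], correction=False)[0]
            assert prr_chi2(t)[1] == pytest.approx(expected, rel=1e-10)


class TestAlgebraicProperties:
    def test_transposition_leaves_ror_chi2_unchanged(self):
        rng = np.random.default_rng(2)
        for a, b, c, d in rng.integers(1, 300, size=(50, 4)):
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            tt = ContingencyTable(int(a), int(c), int(b), int(d))  # transpose
            assert ror_ci(t)[0] == pytest.approx(ror_ci(tt)[0], rel=1e-12)
            assert prr_chi2(t)[1] == pytest.approx(prr_chi2(tt)[1], rel=1e-12)

    def test_row_swap_inverts_ror(self):
        t = ContingencyTable(10, 90, 100, 9900)
        swapped = ContingencyTable(100, 9900, 10, 90)
        assert ror_ci(swapped)[0] == pytest.approx(1 / ror_ci(t)[0], rel=1e-12)

    def test_scaling_doubles_chi2_keeps_prr(self):
        t = ContingencyTable(10, 90, 100, 9900)
        t2 = ContingencyTable(20, 180, 200, 19800)
        prr1, chi1 = prr_chi2(t)
        prr2, chi2 = prr_chi2(t2)
        assert prr2 == pytest.approx(prr1, rel=1e-12)
        assert chi2 == pytest.approx(2 * chi1, rel=1e-12)

    def test_monotone_in_a_with_fixed_margins(self):
        base = ContingencyTable(10, 90, 100, 9900)
        prev = compute_signal_stats(base)
        for a in range(11, 40):
            t = ContingencyTable(a, 100 - a, 110 - a, 9890 + a)
            cur = compute_signal_stats(t)
            assert cur.ror >= prev.ror and cur.prr >= prev.prr and cur.ic >= prev.ic
            prev = cur

    def test_ic_limit_is_log2_observed_over_expected(self):
        a, b, c, d = 10, 90, 100, 9900
        target = math.log2(a * (a + b + c + d) / ((a + b) * (a + c)))
        k = 10**6
        ic, _ = bcpnn_ic(ContingencyTable(a * k, b * k, c * k, d * k))
        assert ic == pytest.approx(target, abs=1e-4)


class TestZeroCellPolicy:
    def test_zero_cell_gets_haldane_correction(self):
        s = compute_signal_stats(ContingencyTable(5, 0, 3, 100))
        assert s.zero_cell_corrected
        assert s.ror == pytest.approx((5.5 * 100.5) / (0.5 * 3.5), rel=1e-12)

    def test_zero_margin_yields_missing_with_reason(self):
        s = compute_signal_stats(ContingencyTable(0, 0, 5, 5))
        assert s.ror is None and s.prr is None and s.reason == "zero_margin"
        assert s.ic is not None  # the Bayesian estimate stays defined
        assert not apply_signal_rule([s])[0].is_signal


def _stats(a=100, ror_lo=1.5, prr=3.0, chi2=5.0, ic_lo=0.5):
    t = ContingencyTable(a, max(1000 - a, 1), 100, 9900)
    return SignalStats(table=t, ror=ror_lo * 2, ror_lo=ror_lo, ror_hi=ror_lo * 4,
                       prr=prr, chi2=chi2, ic=ic_lo + 1, ic_lo=ic_lo)


class TestSignalRule:
    @pytest.mark.parametrize("a_ok", [True, False])
    @pytest.mark.parametrize("ror_ok", [True, False])
    @pytest.mark.parametrize("prr_ok", [True, False])
    @pytest.mark.parametrize("ic_ok", [True, False])
    def test_truth_table(self, a_ok, ror_ok, prr_ok, ic_ok):
        s = _stats(
            a=3 if a_ok else 2,
            ror_lo=1.5 if ror_ok else 1.0,
            prr=3.0 if prr_ok else 2.0,
            chi2=5.0 if prr_ok else 4.0,
            ic_lo=0.5 if ic_ok else 0.0,
        )
        assert apply_signal_rule([s])[0].is_signal == (a_ok and ror_ok and prr_ok and ic_ok)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"a": 3},          # boundary a = 3 passes
            {"ror_lo": 1.0 + 1e-9},
            {"prr": 2.0 + 1e-9},
            {"chi2": 4.0 + 1e-9},
            {"ic_lo": 1e-9},
        ],
    )
    def test_just_above_boundaries_pass(self, kwargs):
        assert apply_signal_rule([_stats(**kwargs)])[0].is_signal

    @pytest.mark.parametrize("field", ["ror_lo", "prr", "chi2", "ic_lo"])
    def test_missing_component_fails(self, field):
        s = _stats()
        setattr(s, field, None)
        assert not apply_signal_rule([s])[0].is_signal

    def test_published_somnolence_row_is_a_signal(self):
        # report count 2556 with ROR CI lower bound 10.11 and the other
        # criteria comfortably met reproduces the published signal verdict
        s = _stats(a=2556, ror_lo=10.11, prr=10.0, chi2=1000.0, ic_lo=2.0)
        assert apply_signal_rule([s])[0].is_signal


class TestBuildTables:
    def test_multiple_pts_count_once_each_and_soc_dedup(self, mock_meddra, drug_dictionary):
        from conftest import make_report

        reports = standardize_drugs(
            [
                make_report("1", drugs=[("PS", "ZYRTEC")], reactions={"SOMNOLENCE", "PRURITUS"}),
                make_report("2", drugs=[("PS", "ZYRTEC")], reactions={"SOMNOLENCE", "HEADACHE"}),
                make_report("3", drugs=[("PS", "CLARITIN")], reactions={"SOMNOLENCE"}),
            ],
            drug_dictionary,
        )
        cohort = build_cohort(reports, "cetirizine", dictionary=drug_dictionary)
        pt_tables = {t.event: t for t in build_tables(cohort, "PT", mock_meddra)}
        assert pt_tables["SOMNOLENCE"].a == 2 and pt_tables["PRURITUS"].a == 1
        assert all(t.a + t.b == 2 and t.c + t.d == 1 for t in pt_tables.values())
        # report 2 has two PTs in the nervous-system SOC; it contributes 1
        soc_tables = {t.event: t for t in build_tables(cohort, "SOC", mock_meddra)}
        assert soc_tables["NERVOUS SYSTEM DISORDERS"].a == 2

    def test_empty_exposed_returns_empty_list(self, mock_meddra, drug_dictionary):
        from faerspv import Cohort

        cohort = Cohort("cetirizine", [], [])
        assert build_tables(cohort, "PT", mock_meddra) == []

    def test_counts_match_brute_force_on_generated_cohort(self, ):
        cfg = SyntheticConfig(n_reports=2000, n_drugs=6, n_pts=15, seed=9,
                              planted_signals={("ingredient02", "PT 005"): 5.0})
        reports, _ = generate(cfg)
        deduped = deduplicate(reports)
        standardize_drugs(deduped, cfg.drug_dictionary())
        cohort = build_cohort(deduped, "ingredient02", dictionary=cfg.drug_dictionary())
        for t in build_tables(cohort, "PT", cfg.meddra()):
            a = sum(1 for r in cohort.exposed if t.event in r.reactions)
            c = sum(1 for r in cohort.background if t.event in r.reactions)
            assert (t.a, t.b, t.c, t.d) == (a, len(cohort.exposed) - a, c, len(cohort.background) - c)
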