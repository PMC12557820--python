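"""Disproportionality statistics: closed forms, oracles and criteria."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import digamma
from scipy.stats import gamma as gamma_dist
from scipy.stats import nbinom

from pvsignals.signals import (BcpnnPriors, ContingencyTable, MgpsHyper,
                               SignalCriteria, SignalStats, bcpnn_stats,
                               build_contingency, contingency_tables,
                               drug_event_cells, evaluate_criteria, mgps_cell,
                               mgps_fit, prr_stats, ror_stats)

CT = ContingencyTable


# --- independent oracle: direct transcription of the defining formulas ----

def oracle_ror(a, b, c, d):
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (ror, math.exp(math.log(ror) - 1.96 * se),
            math.exp(math.log(ror) + 1.96 * se))


def oracle_prr_chi2(a, b, c, d, yates):
    n = a + b + c + d
    prr = (a / (a + b)) / (c / (c + d))
    num = abs(a * d - b * c) - (n / 2 if yates else 0)
    num = max(num, 0.0)
    chi2 = n * num ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return prr, chi2


def oracle_ic(a, b, c, d):
    n = a + b + c + d
    a1 = b1 = g11 = 1.0
    al = be = 2.0
    row, col = a + b, a + c
    g = g11 * (n + al) * (n + be) / ((row + a1) * (col + b1))
    ic = math.log2((a + g11) * (n + al) * (n + be)
                   / ((n + g) * (row + a1) * (col + b1)))
    v = (1 / math.log(2) ** 2) * (
        (n - a + g - g11) / ((a + g11) * (1 + n + g))
        + (n - row + al - a1) / ((row + a1) * (1 + n + al))
        + (n - col + be - b1) / ((col + b1) * (1 + n + be)))
    return ic, ic - 2 * math.sqrt(v)


class TestRor:
    @pytest.mark.parametrize("cells, want", [
        ((53, 90, 164, 1494), (5.36, 3.68, 7.81)),   # 2x2 cross-product
        ((10, 90, 100, 900), (1.00, None, None)),    # proportional table
        ((5, 95, 50, 9850), (10.37, 4.05, 26.58)),   # hand evaluation
    ])
    def test_known_values(self, cells, want):
        ror, lo, hi, reason = ror_stats(CT(*cells))
        assert reason is None
        assert round(ror, 2) == want[0]
        if want[1] is not None:
            assert round(lo, 2) == want[1]
            assert round(hi, 2) == want[2]

    def test_zero_cell_undefined_with_reason(self):
        ror, lo, hi, reason = ror_stats(CT(0, 10, 5, 100))
        assert ror is None and "zero cell" in reason

    def test_haldane_correction_optional(self):
        ror, lo, hi, reason = ror_stats(CT(0, 10, 5, 100), correction=True)
        assert reason is None and ror > 0


class TestPrr:
    def test_independence(self):
        prr, chi2, _ = prr_stats(CT(10, 90, 100, 900), yates=False)
        assert prr == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0)

    def test_hand_evaluation_with_and_without_yates(self):
        prr, chi2, _ = prr_stats(CT(5, 95, 50, 9850), yates=False)
        assert round(prr, 2) == 9.90 and round(chi2, 2) == 36.57
        _, chi2y, _ = prr_stats(CT(5, 95, 50, 9850), yates=True)
        assert round(chi2y, 2) == 28.81

    def test_zero_numerator_valid(self):
        prr, chi2, reason = prr_stats(CT(0, 100, 50, 9850))
        assert prr == 0.0 and reason is None

    def test_zero_comparator_undefined(self):
        prr, chi2, reason = prr_stats(CT(5, 95, 0, 9850))
        assert prr is None and "c = 0" in reason

    def test_yates_floor_at_zero(self):
        # tiny imbalance: |ad-bc| < N/2 must floor the statistic at 0
        prr, chi2, _ = prr_stats(CT(1, 9, 10, 91), yates=True)
        assert chi2 == 0.0


class TestBcpnn:
    def test_independence_table_near_zero(self):
        ic, _ = bcpnn_stats(CT(100, 900, 9900, 89100))
        assert abs(ic) < 0.01

    def test_zero_count_finite_negative(self):
        ic, ic025 = bcpnn_stats(CT(0, 20, 50, 500))
        assert math.isfinite(ic) and ic < 0
        assert math.isfinite(ic025)

    @given(a=st.integers(0, 500), b=st.integers(1, 5000),
           c=st.integers(1, 5000), d=st.integers(1, 50000))
    @settings(max_examples=200, deadline=None)
    def test_lower_bound_strictly_below_point(self, a, b, c, d):
        ic, ic025 = bcpnn_stats(CT(a, b, c, d))
        assert ic025 < ic

    def test_asymptotic_observed_over_expected(self):
        """Priors wash out: IC → log2 of the raw relative reporting ratio."""
        a, row, col, n = 20_000, 100_000, 1_000_000, 10_000_000
        t = CT(a, row - a, col - a, n - row - col + a)
        rr = n * a / (row * col)
        ic, _ = bcpnn_stats(t)
        assert ic == pytest.approx(math.log2(rr), abs=0.01)


class TestClosedFormOracles:
    def test_thousand_random_tables_agree_to_1e10(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            a, b, c, d = (int(v) for v in rng.integers(1, 2000, 4))
            t = CT(a, b, c, d)
            ror, lo, hi, _ = ror_stats(t)
            oro, olo, ohi = oracle_ror(a, b, c, d)
            for got, want in ((ror, oro), (lo, olo), (hi, ohi)):
                assert math.isclose(got, want, rel_tol=1e-10, abs_tol=1e-10)
            for yates in (False, True):
                prr, chi2, _ = prr_stats(t, yates=yates)
                oprr, ochi = oracle_prr_chi2(a, b, c, d, yates)
                assert math.isclose(prr, oprr, rel_tol=1e-10, abs_tol=1e-10)
                assert math.isclose(chi2, ochi, rel_tol=1e-10, abs_tol=1e-10)
            ic, ic025 = bcpnn_stats(t)
            oic, oic025 = oracle_ic(a, b, c, d)
            assert math.isclose(ic, oic, rel_tol=1e-10, abs_tol=1e-10)
            assert math.isclose(ic025, oic025, rel_tol=1e-10, abs_tol=1e-10)

    def test_ror_prr_agree_in_rare_event_limit(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            a = int(rng.integers(1, 30))
            b = int(rng.integers(5000, 20000))
            c = int(rng.integers(1, 30))
            d = int(rng.integers(100_000, 200_000))
            ror, _, _, _ = ror_stats(CT(a, b, c, d))
            prr, _, _ = prr_stats(CT(a, b, c, d), yates=False)
            assert abs(ror / prr - 1) < 0.01


class TestMgpsCell:
    H_EQUAL = MgpsHyper(1.0, 1.0, 1.0, 1.0, 0.5)

    class _T:
        """Synthetic cell with a = 10 and independence expectation E = 2."""
        a, n = 10, 220
        expected = 2.0

    def test_identical_components_reduce_to_single_gamma(self):
        # posterior Gamma(11, rate 3): EBGM = exp(psi(11) - ln 3) = 3.50
        ebgm, ebgm05, reason = mgps_cell(self._T, self.H_EQUAL)
        assert reason is None
        assert ebgm == pytest.approx(math.exp(digamma(11) - math.log(3)),
                                     rel=1e-9)
        assert round(ebgm, 2) == 3.50
        # chi2_{22} 5th percentile / (2*3)
        want05 = gamma_dist(11, scale=1 / 3).ppf(0.05)
        assert ebgm05 == pytest.approx(want05, abs=1e-6)
        assert round(ebgm05, 2) == 2.06

    def test_degenerate_weight_collapses_to_first_component(self):
        h = MgpsHyper(0.7, 0.3, 5.0, 2.0, 1.0 - 1e-12)
        ebgm, ebgm05, _ = mgps_cell(self._T, h)
        a, E = self._T.a, self._T.expected
        assert ebgm == pytest.approx(
            math.exp(digamma(h.a1 + a) - math.log(h.b1 + E)), rel=1e-9)
        assert ebgm05 == pytest.approx(
            gamma_dist(h.a1 + a, scale=1 / (h.b1 + E)).ppf(0.05), abs=1e-6)

    @given(a=st.integers(0, 200), e=st.floats(0.1, 100.0))
    @settings(max_examples=100, deadline=None)
    def test_quantile_below_geometric_mean(self, a, e):
        t = type("T", (), {"a": a, "n": 1000, "expected": e})
        ebgm, ebgm05, _ = mgps_cell(t, MgpsHyper(0.2, 0.1, 2.0, 4.0, 1 / 3))
        assert 0 < ebgm05 < ebgm

    def test_posterior_matches_numeric_integration_oracle(self):
        """EBGM/EBGM05 vs quadrature on the explicit posterior mixture."""
        h = MgpsHyper(0.3, 0.2, 3.0, 2.5, 0.4)
        for a, E in [(0, 1.0), (3, 0.7), (10, 2.0), (50, 60.0), (25, 5.0)]:
            t = type("T", (), {"a": a, "n": 10_000, "expected": E})
            ebgm, ebgm05, _ = mgps_cell(t, h)
            # posterior weight from the two negative-binomial marginals
            p1, p2 = h.b1 / (h.b1 + E), h.b2 / (h.b2 + E)
            m1 = h.w * nbinom.pmf(a, h.a1, p1)
            m2 = (1 - h.w) * nbinom.pmf(a, h.a2, p2)
            q = m1 / (m1 + m2)
            g1 = gamma_dist(h.a1 + a, scale=1 / (h.b1 + E))
            g2 = gamma_dist(h.a2 + a, scale=1 / (h.b2 + E))

            def dens(x):
                return q * g1.pdf(x) + (1 - q) * g2.pdf(x)

            hi = max(g1.ppf(1 - 1e-12), g2.ppf(1 - 1e-12))
            mean_log, _ = quad(lambda x: math.log(x) * dens(x), 0, hi,
                               limit=200)
            assert ebgm == pytest.approx(math.exp(mean_log), abs=1e-6,
                                         rel=1e-6)

            def cdf(x):
                v, _ = quad(dens, 0, x, limit=200)
                return v

            want05 = brentq(lambda x: cdf(x) - 0.05, 1e-12, hi, xtol=1e-10)
            assert ebgm05 == pytest.approx(want05, abs=1e-6, rel=1e-6)


class TestMgpsFit:
    def test_single_cell_rejected(self):
        with pytest.raises(ValueError, match="at least two"):
            mgps_fit([3.0], [1.0])

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(ValueError):
            mgps_fit([1.0, 2.0], [1.0, 0.0])

    def test_recovers_single_gamma_prior(self):
        """w→1 boundary: dominant component within 10% at 10,000 cells."""
        rng = np.random.default_rng(0)
        n = 10_000
        E = np.exp(rng.uniform(np.log(0.5), np.log(50), n))
        lam = rng.gamma(2.0, 1 / 2.0, n)
        a = rng.poisson(lam * E).astype(float)
        h = mgps_fit(a, E)
        shape, rate = (h.a1, h.b1) if h.w >= 0.5 else (h.a2, h.b2)
        assert abs(shape - 2.0) / 2.0 < 0.10
        assert abs(rate - 2.0) / 2.0 < 0.10

    def test_recovers_mixture_weight(self):
        """Well-separated components: w within ±0.05 at 10,000 cells."""
        rng = np.random.default_rng(7)
        n = 10_000
        E = np.exp(rng.uniform(np.log(0.5), np.log(50), n))
        comp = rng.random(n) < 0.7
        lam = np.where(comp, rng.gamma(0.5, 1 / 0.5, n),
                       rng.gamma(20.0, 1 / 2.0, n))
        a = rng.poisson(lam * E).astype(float)
        h = mgps_fit(a, E)
        # identify components by their prior mean
        if h.a1 / h.b1 < h.a2 / h.b2:
            w_low = h.w
        else:
            w_low = 1 - h.w
        assert abs(w_low - 0.7) < 0.05

    def test_shrinkage_toward_null(self):
        """EBGM stays between 1 and a/E for elevated cells on null data."""
        rng = np.random.default_rng(5)
        n = 5_000
        E = np.exp(rng.uniform(np.log(1.0), np.log(30), n))
        lam = rng.gamma(2.0, 1 / 2.0, n)  # prior mean 1 (null)
        a = rng.poisson(lam * E).astype(float)
        h = mgps_fit(a, E)
        checked = 0
        for ai, Ei in zip(a, E):
            if ai >= 10 and ai / Ei >= 2.0:
                t = type("T", (), {"a": ai, "n": 10 ** 6, "expected": Ei})
                ebgm, _, _ = mgps_cell(t, h)
                assert 1.0 < ebgm < ai / Ei
                checked += 1
        assert checked > 10


class TestContingency:
    def test_hand_tally_on_toy_database(self, toy_reports):
        t = build_contingency(toy_reports, "NAUSEA", ["X"])
        assert (t.a, t.b, t.c, t.d) == (2, 2, 1, 3)
        t2 = build_contingency(toy_reports, "RASH", ["X"])
        assert (t2.a, t2.b, t2.c, t2.d) == (1, 3, 2, 2)

    def test_target_total_equals_a_plus_b(self, toy_reports):
        cells = contingency_tables(toy_reports, ["X"])
        assert ((cells["a"] + cells["b"]) == 4).all()
        assert ((cells["c"] + cells["d"]) == 4).all()

    def test_exclusive_term_is_degenerate(self):
        from conftest import make_report_set
        rs = make_report_set([
            {"primaryid": "1", "drugs": [("X", "PS")], "pts": ["ODDEVENT"]},
            {"primaryid": "2", "drugs": [("Y", "PS")], "pts": ["NAUSEA"]},
        ])
        t = build_contingency(rs, "ODDEVENT", ["X"])
        assert t.c == 0 and t.degenerate

    def test_unknown_term_warns_zero_table(self, toy_reports):
        with pytest.warns(UserWarning, match="absent"):
            t = build_contingency(toy_reports, "NO SUCH TERM", ["X"])
        assert t.a == 0 and t.a + t.b == 4

    def test_soc_level_counts_pairs_not_reports(self, toy_reports, ):
        from pvsignals.ingest import MeddraMap, map_pt_to_soc
        m = MeddraMap({"HEADACHE": "S1", "NAUSEA": "S1", "RASH": "S2"})
        rs = map_pt_to_soc(toy_reports, m)
        t = build_contingency(rs, "S1", ["X"], level="SOC")
        # X pairs in S1: r1 contributes 2 PTs, r2 one -> a = 3
        assert (t.a, t.b) == (3, 1)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            CT(-1, 2, 3, 4)

    def test_planted_pair_count_within_binomial_error(self, small_bundle):
        from pvsignals.ingest import bundle_to_reports
        from pvsignals.synthetic import SimConfig, plant_association
        rs = bundle_to_reports(small_bundle)
        cfg = SimConfig()  # catalogue defaults used by the fixture
        p0 = {pt: p for pt, _, p in cfg.event_catalog}[
            "HEPATIC FUNCTION ABNORMAL"]
        orr = {pt: o for _, pt, o in cfg.planted_signals}[
            "HEPATIC FUNCTION ABNORMAL"]
        p1 = plant_association(p0, orr)
        t = build_contingency(rs, "HEPATIC FUNCTION ABNORMAL", ["AVACOPAN"])
        n_target = len(set(
            small_bundle.drug.loc[
                (small_bundle.drug.role_cod == "PS")
                & (small_bundle.drug.drugname == "AVACOPAN"),
                "primaryid"]))
        se = math.sqrt(n_target * p1 * (1 - p1))
        assert abs(t.a - n_target * p1) < 4 * se + 1


class TestCriteria:
    def _stats(self, **kw):
        s = SignalStats(term="T", level="PT", n=kw.pop("n"),
                        table=CT(1, 1, 1, 1))
        for k, v in kw.items():
            setattr(s, k, v)
        return s

    def test_all_four_positive_matches_validated_signal(self):
        # hepatobiliary SOC-level row of a validated association
        s = self._stats(n=296, ror=5.05, ror_lo=4.49, ror_hi=5.67, prr=4.88,
                        chi2=918.77, ic=2.28, ic025=2.11, ebgm=4.87,
                        ebgm05=4.42)
        out = evaluate_criteria(s)
        assert out.all_four_positive and out.n_positive == 4
        assert not out.small_count_caution

    def test_null_row_negative(self):
        s = self._stats(n=1194, ror=0.92, ror_lo=0.86, ror_hi=0.98, prr=0.93,
                        chi2=7.45, ic=-0.1, ic025=-0.19, ebgm=0.93,
                        ebgm05=0.88)
        out = evaluate_criteria(s)
        assert not out.all_four_positive
        assert not out.ror_pos and not out.bcpnn_pos

    def test_minimum_count_rule_beats_huge_ror(self):
        s = self._stats(n=2, ror=400.0, ror_lo=50.0, ror_hi=3000.0, prr=400.0,
                        chi2=500.0, ic=5.0, ic025=3.0, ebgm=300.0,
                        ebgm05=50.0)
        out = evaluate_criteria(s)
        assert not out.ror_pos and not out.prr_pos
        assert out.bcpnn_pos and out.mgps_pos  # count rule is ROR/PRR-only
        assert out.small_count_caution

    def test_absent_statistics_count_negative(self):
        s = self._stats(n=50)
        out = evaluate_criteria(s)
        assert out.n_positive == 0 and not out.all_four_positive

    def test_thresholds_configurable(self):
        s = self._stats(n=5, ror=3.0, ror_lo=1.5, ror_hi=6.0, prr=3.0,
                        chi2=5.0, ic=1.0, ic025=0.5, ebgm=3.0, ebgm05=1.5)
        strict = SignalCriteria(ebgm05_gt=2.0)
        loose = SignalCriteria(ebgm05_gt=1.0)
        assert not evaluate_criteria(s, strict).mgps_pos
        assert evaluate_criteria(s, loose).mgps_pos


def test_drug_event_cells_margins(toy_reports):
    cells = drug_event_cells(toy_reports).set_index(["drugname", "pt"])
    assert cells["a"].sum() == 8  # total (report, PT) pairs
    assert (cells["E"] > 0).all()
    # hand check: drug X / NAUSEA has a=2 and E = (4 X-pairs)(3 NAUSEA)/8
    row = cells.loc[("X", "NAUSEA")]
    assert row["a"] == 2 and row["E"] == pytest.approx(4 * 3 / 8)
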