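"""Frequency summaries, age curves, Poisson intervals, the D/ND ratio."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from comornet import reference
from comornet.cohort import Stratum, StratumSpec, age_strata, diabetic_patient_ids
from comornet.stats import (
    comorbidity_curve,
    dn_ratio,
    meta_coprescription_profile,
    morbidity_curve,
    poisson_ci,
    selected_groups_share,
    summarize_by_type,
    summarize_group_by_type,
)


def frame(rows):
    df = pd.DataFrame(
        rows,
        columns=["patient_id", "age", "sex", "date", "rx_type", "rx_code", "icd9_code"],
    )
    df["date"] = pd.to_datetime(df["date"])
    return df


class TestTypeSummary:
    def test_published_counts_reproduce_printed_percents(self):
        s = summarize_by_type(
            counts=reference.TYPE_COUNTS,
            n_patients=reference.N_PATIENTS,
            window_years=reference.WINDOW_YEARS,
        )
        rounded = {t: round(p, 1) for t, p in s.percents.items()}
        assert rounded == {
            "Drug": 51.9,
            "Laboratory Test": 37.4,
            "Procedures": 6.1,
            "Rehab": 0.5,
            "Referral": 3.8,
            "Hospital": 0.3,
        }
        assert s.per_patient_per_year["All"] == pytest.approx(10.51, abs=0.005)

    def test_single_type_is_hundred_percent(self):
        s = summarize_by_type(
            frame([("P1", 50, "M", "2005-01-01", "Drug", "R", "401.9")]),
            n_patients=1,
            window_years=1.0,
        )
        assert s.percents["Drug"] == pytest.approx(100.0)
        assert s.percents["Rehab"] == pytest.approx(0.0)

    def test_zero_patients_with_records_rejected(self):
        with pytest.raises(ValueError):
            summarize_by_type(counts={"Drug": 5}, n_patients=0, window_years=1.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 10_000), min_size=6, max_size=6))
    def test_conservation(self, counts):
        from comornet.records import RX_TYPES

        s = summarize_by_type(
            counts=dict(zip(RX_TYPES, counts)), n_patients=100, window_years=2.0
        )
        assert sum(s.counts.values()) == s.total
        if s.total:
            assert sum(s.percents.values()) == pytest.approx(100.0)


class TestGroupSummaries:
    def test_row_percentages(self):
        rows = [("P1", 50, "M", "2005-01-01", "Drug", "R", "401.9")] * 7
        rows += [("P1", 50, "M", "2005-01-01", "Laboratory Test", "R", "401.9")] * 3
        out = summarize_group_by_type(frame(rows))
        assert len(out) == 1
        row = out.iloc[0]
        assert row["group"] == "CIRC" and row["count"] == 10
        assert row["Drug %"] == pytest.approx(70.0)
        assert row["Laboratory Test %"] == pytest.approx(30.0)

    def test_empty_input_gives_empty_table(self):
        assert len(summarize_group_by_type(frame([]))) == 0

    def test_counts_are_conserved_across_groups(self, small_dataset):
        _, recs = small_dataset
        out = summarize_group_by_type(recs)
        assert out["count"].sum() == len(recs)
        row_pct = out.filter(like="%").sum(axis=1)
        assert np.allclose(row_pct, 100.0)

    def test_thirteen_clinical_groups_share(self):
        share = selected_groups_share(
            counts=reference.GROUP_COUNTS,
            groups=reference.CLINICAL_GROUPS_13,
            total=reference.TOTAL_PRESCRIPTIONS,
        )
        assert round(100 * share) == 81

    def test_all_groups_share_is_one(self):
        from comornet.icd9 import GROUPS

        assert selected_groups_share(counts=reference.GROUP_COUNTS, groups=GROUPS) == 1.0
        assert selected_groups_share(counts=reference.GROUP_COUNTS, groups=()) == 0.0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            selected_groups_share(counts=reference.GROUP_COUNTS, groups=("XXXX",))


class TestCurves:
    def test_morbidity_value_is_records_per_patient(self):
        rows = [("P%d" % i, 50, "M", "2005-01-01", "Drug", "R", "401.9") for i in range(10)]
        rows += [("P0", 50, "M", "2005-02-01", "Drug", "R", "401.9")] * 140
        strata = age_strata(frame(rows))
        curve = morbidity_curve(strata)
        assert len(curve) == 1  # empty classes omitted, not zero
        assert curve.iloc[0]["value"] == pytest.approx(15.0)

    def test_comorbidity_value_is_twice_links_per_patient(self):
        rows = []
        for i in range(3):
            rows.append((f"P{i}", 50, "M", "2005-01-01", "Drug", "R", "401.9"))
        rows += [("P0", 50, "M", "2005-03-01", "Drug", "R", "401.9"),
                 ("P0", 50, "M", "2005-03-01", "Drug", "R", "250.00")] * 1
        rows += [("P1", 50, "M", "2005-03-02", "Drug", "R", "401.9"),
                 ("P1", 50, "M", "2005-03-02", "Drug", "R", "250.00")]
        rows += [("P2", 50, "M", "2005-03-03", "Drug", "R", "401.9"),
                 ("P2", 50, "M", "2005-03-03", "Drug", "R", "250.00")]
        strata = age_strata(frame(rows))
        curve = comorbidity_curve(strata)
        # single edge of weight 3 among 3 patients -> 2 * 3 / 3
        assert curve.iloc[0]["value"] == pytest.approx(2.0)

    def test_comorbidity_curve_matches_network_strengths(self, small_dataset):
        """Curve values equal the sum of normalized node strengths."""
        from comornet.network import network_from_frame

        _, recs = small_dataset
        strata = age_strata(recs)
        curve = comorbidity_curve(strata).set_index("age_class")["value"]
        for s in strata:
            if s.n_patients == 0:
                continue
            net = network_from_frame(s.records, s.n_patients).normalize()
            assert curve[s.spec.age_class] == pytest.approx(
                sum(net.strengths().values())
            )


class TestMetaProfile:
    def d_nd(self, rows_d, rows_nd):
        return (
            Stratum(spec=StratumSpec(diabetes="D"), records=frame(rows_d)),
            Stratum(spec=StratumSpec(diabetes="ND"), records=frame(rows_nd)),
        )

    def test_rates_divide_by_patient_denominator(self):
        rows_d = []
        for day in range(1, 11):
            rows_d += [
                ("PD1" if day <= 5 else "PD2", 60, "M", f"2005-01-{day:02d}", "Drug", "R", "401.9"),
                ("PD1" if day <= 5 else "PD2", 60, "M", f"2005-01-{day:02d}", "Drug", "R", "250.00"),
            ]
        rows_nd = [("PN1", 60, "M", "2005-01-01", "Drug", "R", "401.9")]
        sd, snd = self.d_nd(rows_d, rows_nd)
        prof = meta_coprescription_profile(sd, snd).set_index("group")
        assert prof.loc["CIRC", "count_D"] == 10
        assert prof.loc["CIRC", "rate_D"] == pytest.approx(5.0)
        assert prof.loc["CIRC", "rate_ND"] == 0.0

    def test_group_without_meta_coevents_has_zero_rate(self):
        sd, snd = self.d_nd(
            [("PD1", 60, "M", "2005-01-01", "Drug", "R", "486")],
            [("PN1", 60, "M", "2005-01-01", "Drug", "R", "486")],
        )
        prof = meta_coprescription_profile(sd, snd, groups=("RESP",)).set_index("group")
        assert prof.loc["RESP", "count_D"] == 0
        assert prof.loc["RESP", "count_ND"] == 0


class TestPoissonCI:
    def test_zero_count_interval(self):
        lo, hi = poisson_ci(0, 0.95)
        assert lo == 0.0
        assert hi == pytest.approx(-math.log(0.025), rel=1e-6)  # 3.6889

    def test_matches_chi_square_formulation(self):
        """Independent oracle: the same interval via chi-square quantiles."""
        for k in (1, 7, 100, 412):
            lo, hi = poisson_ci(k, 0.95)
            assert lo == pytest.approx(scipy.stats.chi2.ppf(0.025, 2 * k) / 2)
            assert hi == pytest.approx(scipy.stats.chi2.ppf(0.975, 2 * k + 2) / 2)

    def test_known_interval_k100(self):
        lo, hi = poisson_ci(100, 0.95)
        assert lo == pytest.approx(81.36, abs=0.01)
        assert hi == pytest.approx(121.63, abs=0.01)

    def test_nesting_99_contains_95(self):
        for k in list(range(0, 50)) + [100, 250, 500, 1000]:
            lo95, hi95 = poisson_ci(k, 0.95)
            lo99, hi99 = poisson_ci(k, 0.99)
            assert lo99 <= lo95 and hi99 >= hi95

    def test_normal_approximation_available(self):
        lo, hi = poisson_ci(100, 0.95, method="normal")
        assert lo == pytest.approx(100 - 1.96 * 10, abs=0.05)
        assert hi == pytest.approx(100 + 1.96 * 10, abs=0.05)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            poisson_ci(-1)
        with pytest.raises(ValueError):
            poisson_ci(3, level=1.2)


class TestDnRatio:
    def test_point_estimate_arithmetic(self):
        est = dn_ratio(100, 10, 10, 10)
        assert est.ratio == pytest.approx(10.0)
        assert est.rate_D == pytest.approx(10.0)

    def test_equal_rates_ci_straddles_one(self):
        est = dn_ratio(50, 100, 50, 100)
        assert est.ratio == pytest.approx(1.0)
        assert est.ci[0] < 1.0 < est.ci[1]

    def test_ratio_within_its_interval(self):
        for cd, cnd in [(5, 50), (80, 20), (1, 1), (300, 7)]:
            est = dn_ratio(cd, 40, cnd, 160)
            assert est.ci[0] <= est.ratio <= est.ci[1]

    def test_scaling_preserves_ratio_and_narrows_ci(self):
        small = dn_ratio(30, 10, 20, 40)
        big = dn_ratio(300, 100, 200, 400)
        assert big.ratio == pytest.approx(small.ratio)
        assert big.ci[1] - big.ci[0] < small.ci[1] - small.ci[0]

    def test_zero_nd_count_gives_one_sided_bound(self):
        est = dn_ratio(10, 5, 0, 5)
        assert math.isinf(est.ratio)
        assert est.ci[0] > 0 and math.isinf(est.ci[1])

    def test_interval_has_nominal_coverage_for_poisson_counts(self, rng):
        """Simulated Poisson pair with true ratio 4: the exact conditional
        interval covers the truth at >= the nominal rate."""
        true_ratio, hits, n_rep = 4.0, 0, 400
        for _ in range(n_rep):
            cd = rng.poisson(40.0)   # n_D=10, rate 4
            cnd = rng.poisson(20.0)  # n_ND=20, rate 1
            est = dn_ratio(int(cd), 10, int(cnd), 20)
            if est.ci[0] <= true_ratio <= est.ci[1]:
                hits += 1
        assert hits / n_rep >= 0.93
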