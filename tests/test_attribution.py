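"""PARF arithmetic, component contributions, overlap adjustment, aggregation."""

import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from hipimpact import (
    AdjustmentInput,
    adjustment_factor,
    aggregate,
    decompose,
    factor_contribution,
    medication_contribution,
    osteoporosis_rate,
    parf,
    risk_component,
    share_of_total,
)

prevalences = st.floats(0.0, 1.0)
rrs = st.floats(0.05, 20.0)


class TestParf:
    @pytest.mark.parametrize(
        "p, rr, expected",
        [
            (0.168, 1.3, 0.04798),
            (0.552, 0.66, -0.23104),
            (0.0, 2.5, 0.0),
            (0.4, 1.0, 0.0),
        ],
    )
    def test_values(self, p, rr, expected):
        assert parf(p, rr) == pytest.approx(expected, abs=5e-6)

    @given(p=st.floats(0.001, 1.0), rr=rrs)
    def test_sign_flips_with_reciprocal_rr(self, p, rr):
        assume(abs(rr - 1.0) > 1e-3)
        a, b = parf(p, rr), parf(p, 1.0 / rr)
        assert a * b < 0

    @given(
        p1=prevalences,
        p2=prevalences,
        rr=rrs,
    )
    def test_strictly_monotone_in_prevalence(self, p1, p2, rr):
        assume(abs(rr - 1.0) > 1e-3 and abs(p1 - p2) > 1e-6)
        lo, hi = min(p1, p2), max(p1, p2)
        diff = parf(hi, rr) - parf(lo, rr)
        assert diff > 0 if rr > 1 else diff < 0

    def test_degenerate_denominator_rejected(self):
        # P(RR-1)+1 underflows to 0 at full prevalence and vanishing RR
        with pytest.raises(ValueError, match="invalid PARF"):
            parf(1.0, 1e-20)


class TestFactorContribution:
    @pytest.mark.parametrize(
        "ne, p_by, p_ey, rr, expected, tol",
        [
            (7391, 0.168, 0.217, 1.3, 97.1, 0.1),
            (7391, 0.051, 0.069, 0.5, -70.7, 0.1),
            (5000, 0.3, 0.3, 1.8, 0.0, 1e-12),
        ],
    )
    def test_values(self, ne, p_by, p_ey, rr, expected, tol):
        assert factor_contribution(ne, p_by, p_ey, rr) == pytest.approx(
            expected, abs=tol
        )

    @given(
        ne=st.floats(0.0, 1e5),
        scale=st.floats(0.1, 10.0),
        p_by=prevalences,
        p_ey=prevalences,
        rr=rrs,
    )
    def test_linear_in_expected_count(self, ne, scale, p_by, p_ey, rr):
        base = factor_contribution(ne, p_by, p_ey, rr)
        assert factor_contribution(ne * scale, p_by, p_ey, rr) == pytest.approx(
            base * scale, rel=1e-9, abs=1e-9
        )

    @given(ne=st.floats(1.0, 1e5), p_by=prevalences, p_ey=prevalences, rr=rrs)
    def test_reversing_years_flips_sign_exactly(self, ne, p_by, p_ey, rr):
        forward = factor_contribution(ne, p_by, p_ey, rr)
        backward = factor_contribution(ne, p_ey, p_by, rr)
        assert forward == -backward


class TestMedicationOps:
    @pytest.mark.parametrize(
        "pop_rate, rr, expected",
        [(10.12, 6.4, 64.768), (6.5, 6.4, 41.60), (7.7, 1.0, 7.7)],
    )
    def test_osteoporosis_rate(self, pop_rate, rr, expected):
        assert osteoporosis_rate(pop_rate, rr) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize(
        "users, rrr, r_op, expected",
        [
            (100_000, 0.53, 64.77, -343.3),
            (50_000, 0.0, 64.77, 0.0),
            (0, 0.53, 64.77, 0.0),
        ],
    )
    def test_medication_contribution_is_prevented(self, users, rrr, r_op, expected):
        assert medication_contribution(users, rrr, r_op) == pytest.approx(
            expected, abs=0.05
        )


class TestAdjustmentFactor:
    @pytest.mark.parametrize(
        "mags, expected",
        [
            ([0.3], 1.0),
            ([0.1, 0.2], 0.28 / 0.30),
            ([0.5, 0.5, 0.5], 0.875 / 1.5),
        ],
    )
    def test_values(self, mags, expected):
        res = adjustment_factor(AdjustmentInput(risk_magnitudes=mags))
        assert res.af == pytest.approx(expected, rel=1e-12)

    def test_all_zero_continuity(self):
        res = adjustment_factor(AdjustmentInput(risk_magnitudes=[0.0, 0.0]))
        assert res.af == 1.0
        assert "continuity" in res.note

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            adjustment_factor(AdjustmentInput(risk_magnitudes=[]))

    @given(mags=st.lists(st.floats(0.0, 0.95), min_size=1, max_size=8))
    def test_af_at_most_one(self, mags):
        assert adjustment_factor(AdjustmentInput(risk_magnitudes=mags)).af <= 1.0 + 1e-12

    @given(
        mags=st.lists(st.floats(0.0, 0.95), min_size=1, max_size=6),
        extra=st.floats(0.01, 0.95),
    )
    def test_af_non_increasing_as_factors_appended(self, mags, extra):
        before = adjustment_factor(AdjustmentInput(risk_magnitudes=mags)).af
        after = adjustment_factor(AdjustmentInput(risk_magnitudes=mags + [extra])).af
        assert after <= before + 1e-12

    @given(mags=st.lists(st.floats(0.01, 0.95), min_size=2, max_size=6))
    def test_af_below_one_with_two_nonzero(self, mags):
        assert adjustment_factor(AdjustmentInput(risk_magnitudes=mags)).af < 1.0


class TestAggregation:
    def test_risk_component(self):
        af = adjustment_factor(AdjustmentInput(risk_magnitudes=[0.1, 0.2])).af
        assert risk_component([100, 200], af) == pytest.approx(280.0, rel=1e-12)
        assert risk_component([100, -50], 1.0) == 50
        assert risk_component([], 0.7) == 0

    @pytest.mark.parametrize(
        "med, risk, drugs, excess, modeled, pct_1dp",
        [
            (-733, 4376, 644, 4760, 4287, 90.1),
            (0, 0, 0, 100, 0, 0.0),
            (-100, 200, 0, 100, 100, 100.0),
        ],
    )
    def test_aggregate(self, med, risk, drugs, excess, modeled, pct_1dp):
        nx, pct = aggregate(med, risk, drugs, excess)
        assert nx == modeled
        assert round(pct, 1) == pct_1dp

    def test_zero_excess_rejected(self):
        with pytest.raises(ValueError):
            aggregate(1, 2, 3, 0)

    @pytest.mark.parametrize(
        "nx, excess, share_1dp",
        [(1750, 4760, 36.8), (0, 4760, 0.0), (-733, 4760, -15.4)],
    )
    def test_share_of_total(self, nx, excess, share_1dp):
        assert round(share_of_total(nx, excess), 1) == share_1dp


class TestConservation:
    def test_modeled_equals_adjusted_rows_plus_medication(self, romania):
        res = decompose(romania, track="equations")
        af = res.adjustment.af
        rows = af * sum(c.nx for c in res.contributions) + res.nx_med
        assert res.nx_modeled == pytest.approx(rows, rel=1e-9)

    def test_component_identity_on_published_track(self, romania):
        res = decompose(romania, track="published")
        assert res.nx_modeled == pytest.approx(
            res.nx_med + res.nx_risk + res.nx_drugs, rel=1e-12
        )
        assert res.adjustment is not None and not res.adjustment.applied
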