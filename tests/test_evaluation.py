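"""Agreement/bias statistics: examples, oracles, and invariants.

The MSEP decomposition and CCC are checked against independent oracles:
a brute-force mean-squared-residual computation for the additive
identity, and closed-form/hand-computed values for CCC.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from equide.dataset import Dataset
from equide.energy import NS_EQUATION, ZK_EQUATION
from equide.evaluation import (
    PairedSeries,
    bias_regression,
    ccc,
    evaluate_equation,
    msep_decomposition,
    pearson,
    r_squared,
    residual_nutrient_correlations,
    residuals,
    rmsep,
    sd_band_summary,
)
from equide.synthetic import SyntheticConfig, generate_feeds


def series(obs, pred):
    return PairedSeries(np.asarray(obs, float), np.asarray(pred, float))


# paired series with non-degenerate variance on both sides
paired_st = st.integers(4, 40).flatmap(
    lambda n: st.tuples(
        hnp.arrays(np.float64, n, elements=st.floats(-1e3, 1e3, width=64)),
        hnp.arrays(np.float64, n, elements=st.floats(-1e3, 1e3, width=64)),
    )
).filter(lambda op: op[0].std() > 1e-6 and op[1].std() > 1e-6)


class TestBasics:
    def test_residual_sign_convention(self):
        ps = series([2, 4, 5], [3, 3, 5])
        assert residuals(ps).tolist() == [-1, 1, 0]

    def test_series_validation(self):
        with pytest.raises(ValueError):
            series([1, 2], [1, 2])
        with pytest.raises(ValueError):
            series([1, 2, np.nan], [1, 2, 3])
        with pytest.raises(ValueError):
            PairedSeries(np.array([1.0, 2, 3]), np.array([1.0, 2]))

    def test_pearson_exact_lines(self):
        x = np.arange(5.0)
        assert pearson(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_pearson_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1, 1, 1], [1, 2, 3])

    def test_r_squared(self):
        ps = series([1, 2, 3, 4], [1, 2, 3, 4])
        assert r_squared(ps) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            r_squared(series([1, 2, 3], [5, 5, 5]))

    def test_rmsep(self):
        assert rmsep(series([1, 2, 3], [1, 2, 3])) == 0.0
        assert rmsep(series([2, 4, 2, 4], [3, 3, 3, 3])) == pytest.approx(1.0)


class TestCcc:
    def test_perfect_agreement(self):
        assert ccc(series([1, 2, 3], [1, 2, 3])) == pytest.approx(1.0)

    def test_perfect_discordance(self):
        # cov = -2/3, variances 2/3, no mean shift
        assert ccc(series([1, 2, 3], [3, 2, 1])) == pytest.approx(-1.0)

    def test_both_constant_rejected(self):
        with pytest.raises(ValueError):
            ccc(series([5, 5, 5], [7, 7, 7]))

    @given(paired_st)
    @settings(max_examples=100, derandomize=True)
    def test_never_exceeds_absolute_correlation(self, op):
        o, p = op
        ps = PairedSeries(o, p)
        r, _ = pearson(o, p)
        assert ccc(ps) <= abs(r) + 1e-9

    @given(paired_st)
    @settings(max_examples=100, derandomize=True)
    def test_equals_r_when_moments_match(self, op):
        o, p = op
        # rescale p to share mean and SD with o: CCC collapses to r
        p2 = (p - p.mean()) / p.std() * o.std() + o.mean()
        ps = PairedSeries(o, p2)
        r, _ = pearson(o, p2)
        assert ccc(ps) == pytest.approx(r, abs=1e-9)

    @given(paired_st)
    @settings(max_examples=100, derandomize=True)
    def test_unity_only_for_exact_agreement(self, op):
        o, _ = op
        assert ccc(PairedSeries(o, o.copy())) == pytest.approx(1.0)
        # any mean shift of one SD caps CCC at 2/3
        shifted = PairedSeries(o, o + o.std())
        assert ccc(shifted) == pytest.approx(2.0 / 3.0, abs=1e-9)


class TestBiasRegression:
    def test_zero_residuals(self):
        ps = series([1, 2, 3, 4], [1, 2, 3, 4])
        b = bias_regression(ps)
        assert b.intercept == pytest.approx(0.0, abs=1e-12)
        assert b.slope == pytest.approx(0.0, abs=1e-12)

    def test_pure_mean_bias(self):
        o = np.array([10.0, 20, 30, 40])
        b = bias_regression(PairedSeries(o, o + 50))
        assert b.intercept == pytest.approx(-50.0)
        assert b.slope == pytest.approx(0.0, abs=1e-12)

    def test_constant_predictions_rejected(self):
        with pytest.raises(ValueError):
            bias_regression(series([1, 2, 3, 4], [2, 2, 2, 2]))

    def test_needs_four_points(self):
        with pytest.raises(ValueError):
            bias_regression(series([1, 2, 3], [1, 2, 4]))

    def test_parameter_recovery_within_two_se(self):
        """e = a + b (p - pbar) + noise must be recovered by the fit."""
        rng = np.random.default_rng(42)
        p = rng.uniform(2000, 3500, 300)
        a, b = 40.0, 0.15
        e = a + b * (p - p.mean()) + rng.normal(0, 60, p.size)
        ps = PairedSeries(p + e, p)
        fit = bias_regression(ps)
        assert abs(fit.intercept - a) < 2 * fit.se_intercept
        assert abs(fit.slope - b) < 2 * fit.se_slope
        assert fit.p_slope < 0.01


class TestMsepDecomposition:
    def test_translation_case(self):
        o = np.array([10.0, 20, 30, 40])
        d = msep_decomposition(PairedSeries(o, o + 5))
        assert d.ect == pytest.approx(25.0)
        assert d.er == pytest.approx(0.0, abs=1e-12)
        assert d.ed == pytest.approx(0.0, abs=1e-12)
        assert d.pct_ect == pytest.approx(100.0)

    def test_zero_msep_percentages_undefined(self):
        d = msep_decomposition(series([1, 2, 3], [1, 2, 3]))
        assert d.msep == 0.0
        assert d.pct_ect is None and d.pct_er is None and d.pct_ed is None

    @given(paired_st)
    @settings(max_examples=150, derandomize=True)
    def test_identity_against_brute_force_oracle(self, op):
        """ECT + ER + ED must equal the directly computed mean squared residual."""
        o, p = op
        d = msep_decomposition(PairedSeries(o, p))
        brute = float(np.mean((o - p) ** 2))  # independent oracle
        assert d.ect + d.er + d.ed == pytest.approx(brute, rel=1e-9, abs=1e-9)
        assert d.msep == pytest.approx(brute, rel=1e-12, abs=1e-12)
        assert d.msep == pytest.approx(rmsep(PairedSeries(o, p)) ** 2, rel=1e-9, abs=1e-9)
        # percentage identity cancels catastrophically when MSEP is tiny
        # relative to the data scale; only assert it away from that regime
        scale = max(1.0, float(o.var() + p.var()))
        if d.msep > 1e-9 * scale:
            assert d.pct_ect + d.pct_er + d.pct_ed == pytest.approx(100.0, abs=1e-4)

    @given(paired_st, st.floats(-500, 500))
    @settings(max_examples=100, derandomize=True)
    def test_translation_moves_only_central_tendency(self, op, c):
        o, p = op
        d0 = msep_decomposition(PairedSeries(o, p))
        d1 = msep_decomposition(PairedSeries(o, p + c))
        assert d1.ect == pytest.approx((p.mean() + c - o.mean()) ** 2, rel=1e-6, abs=1e-6)
        assert d1.er == pytest.approx(d0.er, rel=1e-9, abs=1e-9)
        assert d1.ed == pytest.approx(d0.ed, rel=1e-9, abs=1e-9)

    @given(paired_st, st.floats(0.1, 5.0))
    @settings(max_examples=100, derandomize=True)
    def test_positive_scaling_preserves_random_error(self, op, k):
        # scaling predictions by k > 0 leaves r, hence ED, unchanged
        o, p = op
        d0 = msep_decomposition(PairedSeries(o, p))
        d1 = msep_decomposition(PairedSeries(o, k * p))
        assert d1.ed == pytest.approx(d0.ed, rel=1e-7, abs=1e-7)


class TestDatasetLevel:
    def test_statistics_invariant_to_record_order(self, table1):
        rev = Dataset(tuple(reversed(table1.records)), name="rev")
        for eq in (NS_EQUATION, ZK_EQUATION):
            a = evaluate_equation(table1, eq)
            b = evaluate_equation(rev, eq)
            assert a.r2 == pytest.approx(b.r2)
            assert a.rmsep == pytest.approx(b.rmsep)
            assert a.ccc == pytest.approx(b.ccc)
            assert a.decomposition.pct_er == pytest.approx(b.decomposition.pct_er)
            assert a.bias.slope == pytest.approx(b.bias.slope)

    def test_exact_predictions_give_perfect_scores(self):
        # observed DE set exactly to the NS prediction for each feed
        from equide.dataset import FeedRecord
        from equide.energy import predict_de

        base = generate_feeds(SyntheticConfig(n=12, seed=3))
        recs = tuple(
            FeedRecord(
                id=r.id, source=r.source, kind=r.kind, composition=r.composition,
                digestible=None, de_observed=predict_de(r.composition, NS_EQUATION),
            )
            for r in base
        )
        res = evaluate_equation(Dataset(recs, "exact"), NS_EQUATION)
        assert res.r2 == pytest.approx(1.0)
        assert res.rmsep == pytest.approx(0.0, abs=1e-9)
        assert res.ccc == pytest.approx(1.0)
        assert res.decomposition.ect == pytest.approx(0.0, abs=1e-9)
        assert res.decomposition.er == pytest.approx(0.0, abs=1e-9)
        assert res.decomposition.ed == pytest.approx(0.0, abs=1e-9)

    def test_fixture_low_de_feed_is_overpredicted(self, table1):
        res = evaluate_equation(table1, NS_EQUATION)
        i = [r.id for r in table1].index(13)
        assert res.residuals[i] == pytest.approx(-373, abs=5)

    def test_sd_band_all_equal_observed(self):
        from equide.dataset import FeedRecord, ProximateComposition

        comp = ProximateComposition(10, 20, 55, 3)
        recs = tuple(
            FeedRecord(id=i, source="x", kind="mixed diet",
                       composition=comp, de_observed=2500.0)
            for i in range(1, 5)
        )
        summary = sd_band_summary(Dataset(recs, "flat"), [2400, 2450, 2500, 2550])
        assert summary.bands["within"]["count"] == 4
        assert summary.bands["below"]["count"] == 0
        assert summary.bands["above"]["count"] == 0

    def test_sd_band_edges_on_fixture(self, table1):
        from equide.energy import predict_dataset

        summary = sd_band_summary(table1, predict_dataset(table1, NS_EQUATION))
        assert summary.lower_edge == pytest.approx(2599.78 - 491.97, abs=0.5)
        assert summary.upper_edge == pytest.approx(2599.78 + 491.97, abs=0.5)
        total = sum(summary.bands[k]["count"] for k in ("below", "within", "above"))
        assert total == 32

    def test_residual_correlation_table_shape(self, table1):
        table = residual_nutrient_correlations(table1, ZK_EQUATION)
        rows = {(row["x"], row["y"]): row for row in table}
        assert rows[("residual", "cf")]["n"] == 32
        assert rows[("residual", "cf")]["r"] == pytest.approx(-0.66, abs=0.01)
        assert rows[("cf", "dcp")]["n"] == 24
        assert rows[("cf", "dcp")]["r"] < -0.7  # strong negative, as computed

    def test_zero_residuals_correlation_is_an_error(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([0, 0, 0, 0], [1, 2, 3, 4])
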