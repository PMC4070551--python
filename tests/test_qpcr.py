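import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from regwire.errors import ConfigurationError, DataValidationError
from regwire.qpcr import (
    aggregate_triplicates,
    efficiency_from_curve,
    lin_ccc,
    normalize_and_test,
    platform_correlation,
    reference_stability,
    relative_quantity,
)


class TestRelativeQuantity:
    def test_calibrator_has_quantity_one(self):
        cp = pd.Series({"s1": 22.0, "s2": 25.0, "s3": 24.0})
        qty = relative_quantity(cp, slope=-3.3219280948873623)
        assert qty["s1"] == pytest.approx(1.0)
        assert ((qty > 0) & (qty <= 1)).all()

    def test_later_crossing_means_smaller_quantity(self):
        # one full log10 later (3.3219 cycles at 100% efficiency) -> 0.1
        cp = pd.Series({"cal": 20.0, "low": 23.3219280948873623})
        qty = relative_quantity(cp, slope=-3.3219280948873623)
        assert qty["low"] == pytest.approx(0.1)

    def test_doubling_dilution_series_halves_quantities(self):
        slope = -3.3219280948873623
        cp = pd.Series({f"s{i}": 20.0 + i for i in range(5)})
        qty = relative_quantity(cp, slope)
        assert qty.to_numpy() == pytest.approx(0.5 ** np.arange(5))

    def test_shift_invariance(self):
        cp = pd.Series({"a": 21.3, "b": 24.8, "c": 23.1})
        q1 = relative_quantity(cp, -3.5)
        q2 = relative_quantity(cp + 4.2, -3.5)
        assert q1.to_numpy() == pytest.approx(q2.to_numpy())

    def test_positive_slope_rejected(self):
        with pytest.raises(ConfigurationError):
            relative_quantity(pd.Series({"a": 20.0}), slope=3.3)

    def test_missing_cp_excluded_with_warning(self):
        cp = pd.Series({"a": 20.0, "b": np.nan, "c": 22.0})
        with pytest.warns(UserWarning, match="b"):
            qty = relative_quantity(cp, -3.32)
        assert list(qty.index) == ["a", "c"]


class TestEfficiencyFromCurve:
    def test_perfect_doubling_gives_100_percent(self):
        pts = [(x, 30.0 - 3.3219280948873623 * x) for x in (0, 1, 2, 3)]
        slope, eff = efficiency_from_curve(pts)
        assert slope == pytest.approx(-3.3219280948873623)
        assert eff == pytest.approx(100.0)

    def test_slope_minus_3_8_formula_value(self):
        # (10**(1/3.8) - 1) * 100 = 83.298 (direct arithmetic)
        pts = [(x, 28.0 - 3.8 * x) for x in (0, 1, 2, 3)]
        _, eff = efficiency_from_curve(pts)
        assert eff == pytest.approx(83.29807108, rel=1e-8)

    def test_two_points_rejected(self):
        with pytest.raises(DataValidationError):
            efficiency_from_curve([(0, 30.0), (1, 26.7)])

    def test_narrow_dilution_span_rejected(self):
        pts = [(0.0, 30.0), (0.5, 28.3), (1.0, 26.7)]
        with pytest.raises(DataValidationError, match="span"):
            efficiency_from_curve(pts)


class TestReferenceStability:
    def test_proportional_candidates_have_zero_m(self):
        q = pd.DataFrame(
            {"s1": [1.0, 2.0], "s2": [0.5, 1.0], "s3": [0.25, 0.5]},
            index=["g1", "g2"],
        )
        res = reference_stability(q)
        assert res.m.to_numpy() == pytest.approx([0.0, 0.0])

    def test_noisy_candidate_ranks_last(self):
        rng = np.random.default_rng(0)
        n = 10
        stable = np.full(n, 0.8)
        q = pd.DataFrame(
            [stable, stable * 0.5, stable * rng.uniform(0.3, 1.6, n)],
            index=["g1", "g2", "noisy"],
            columns=[f"s{i}" for i in range(n)],
        )
        res = reference_stability(q)
        assert res.m["noisy"] == res.m.max()
        assert set(res.selected) == {"g1", "g2"}

    def test_normalization_factor_is_geometric_mean(self):
        q = pd.DataFrame(
            {"s1": [4.0, 9.0], "s2": [1.0, 1.0]}, index=["g1", "g2"]
        )
        res = reference_stability(q)
        assert res.normalization_factors["s1"] == pytest.approx(6.0)
        assert res.normalization_factors["s2"] == pytest.approx(1.0)

    def test_zero_quantity_rejected(self):
        q = pd.DataFrame({"s1": [0.0, 1.0], "s2": [1.0, 1.0]}, index=["a", "b"])
        with pytest.raises(DataValidationError):
            reference_stability(q)


class TestNormalizeAndTest:
    def design(self, n=4):
        idx = [f"s{i}" for i in range(2 * n)]
        return pd.DataFrame(
            {"group": ["A"] * n + ["B"] * n, "series": 1},
            index=pd.Index(idx, name="sample_id"),
        )

    def test_identical_groups_ratio_one_p_one(self):
        design = self.design()
        qty = pd.Series(0.5, index=design.index)
        nf = pd.Series(1.0, index=design.index)
        res = normalize_and_test(qty, nf, design, ("A", "B"))
        assert res["ratio"] == pytest.approx(1.0)
        assert res["p_value"] == 1.0

    def test_unit_normalization_factor_is_identity(self):
        design = self.design()
        rng = np.random.default_rng(1)
        qty = pd.Series(rng.uniform(0.1, 1, len(design)), index=design.index)
        nf = pd.Series(1.0, index=design.index)
        res = normalize_and_test(qty, nf, design, ("A", "B"))
        pd.testing.assert_series_equal(res["normalized"], qty)

    def test_planted_twofold_difference_recovered(self):
        design = self.design(n=10)
        rng = np.random.default_rng(2)
        base = rng.normal(0.4, 0.01, 20)
        base[10:] *= 2.0
        qty = pd.Series(base, index=design.index)
        nf = pd.Series(1.0, index=design.index)
        res = normalize_and_test(qty, nf, design, ("A", "B"))
        assert res["ratio"] == pytest.approx(2.0, abs=0.1)
        assert res["p_value"] < 0.05


class TestPlatformAgreement:
    def test_identical_vectors_r_one(self):
        x = np.array([1.0, 2.0, 3.5, 4.0])
        r, p = platform_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_antiproportional_vectors_r_minus_one(self):
        x = np.array([1.0, 2.0, 3.5, 4.0])
        r, _ = platform_correlation(x, -2 * x + 1)
        assert r == pytest.approx(-1.0)

    def test_ccc_perfect_agreement(self):
        x = [0.3, 1.2, 2.5, 4.0]
        assert lin_ccc(x, x).ccc == pytest.approx(1.0)

    def test_ccc_hand_evaluated_case(self):
        # x=(1,2,3,4), y=(1.5,2,2.5,5): CCC = 2.75/3.125 = 0.88 by hand
        res = lin_ccc([1, 2, 3, 4], [1.5, 2, 2.5, 5])
        assert res.ccc == pytest.approx(0.88)

    def test_ccc_symmetric(self):
        x, y = [1.0, 2.0, 4.0], [1.2, 2.5, 3.3]
        assert lin_ccc(x, y).ccc == pytest.approx(lin_ccc(y, x).ccc)

    def test_ccc_zero_denominator_rejected(self):
        with pytest.raises(DataValidationError):
            lin_ccc([2.0, 2.0], [2.0, 2.0])

    def test_ccc_length_mismatch_rejected(self):
        with pytest.raises(DataValidationError):
            lin_ccc([1.0, 2.0], [1.0])

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=12),
        st.integers(0, 10_000),
    )
    def test_ccc_never_exceeds_pearson_magnitude(self, xs, seed):
        x = np.asarray(xs)
        rng = np.random.default_rng(seed)
        y = rng.uniform(-50, 50, len(x))
        if x.std() == 0 or y.std() == 0:
            return
        r = np.corrcoef(x, y)[0, 1]
        assert abs(lin_ccc(x, y).ccc) <= abs(r) + 1e-9


def test_triplicate_aggregation_warns_on_noisy_replicates():
    cp = pd.DataFrame(
        {
            "gene": ["g"] * 6,
            "sample": ["s1"] * 3 + ["s2"] * 3,
            "replicate": [1, 2, 3] * 2,
            "cp": [20.0, 20.1, 19.9, 22.0, 23.5, 24.9],
        }
    )
    with pytest.warns(UserWarning, match="s2"):
        means = aggregate_triplicates(cp)
    assert means.loc["g", "s1"] == pytest.approx(20.0)
    assert means.loc["g", "s2"] == pytest.approx(23.466666, rel=1e-5)
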