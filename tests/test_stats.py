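"""Validation statistics against hand-computed and textbook formulas."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from foodscale.errors import StatsError
from foodscale.stats import (
    PairedSample,
    class_accuracy,
    one_sample_t,
    paired_t,
    pearson,
    validate_pairs,
)


class TestPairedT:
    def test_identical_vectors_no_difference(self):
        s = PairedSample(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        res = paired_t(s)
        assert res.statistic == 0.0
        assert res.pvalue == 1.0
        assert res.degenerate

    def test_constant_nonzero_difference_flagged(self):
        s = PairedSample(np.array([2.0, 3.0, 4.0, 5.0]), np.array([1.0, 2.0, 3.0, 4.0]))
        res = paired_t(s)
        assert res.degenerate
        assert math.isnan(res.statistic)

    def test_hand_computed_example(self):
        # d = (-1,-1,-2,-2): mean -1.5, sd 0.5774, t = -5.196
        s = PairedSample(np.array([1.0, 2.0, 3.0, 4.0]), np.array([2.0, 3.0, 5.0, 6.0]))
        res = paired_t(s)
        assert res.mean == pytest.approx(-1.5)
        assert res.sd == pytest.approx(0.5774, abs=1e-4)
        assert res.statistic == pytest.approx(-5.196, abs=1e-3)

    def test_equals_one_sample_t_on_differences(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert paired_t(PairedSample(x, y)) == one_sample_t(x - y, 0.0)

    def test_short_sample_rejected(self):
        with pytest.raises(StatsError):
            PairedSample(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestOneSampleT:
    def test_all_zero_differences(self):
        res = one_sample_t([0.0, 0.0, 0.0])
        assert res.mean == 0.0 and res.degenerate

    def test_symmetric_sample_t_zero(self):
        res = one_sample_t([-1.0, 0.0, 1.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # mean 3, sd 1.5811, t = 3 / (1.5811/sqrt(5)) = 4.243
        res = one_sample_t([1.0, 2.0, 3.0, 4.0, 5.0], mu0=0.0)
        assert res.statistic == pytest.approx(4.243, abs=1e-3)

    @settings(derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10_000))
    def test_matches_textbook_formula(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=int(rng.integers(5, 30)))
        res = one_sample_t(v)
        mean, sd, n = v.mean(), v.std(ddof=1), len(v)
        t = mean / (sd / math.sqrt(n))
        from scipy.stats import t as tdist

        p = 2 * tdist.sf(abs(t), df=n - 1)
        assert res.statistic == pytest.approx(t, rel=1e-9)
        assert res.pvalue == pytest.approx(p, rel=1e-9)


class TestPearson:
    def test_exact_positive_line(self):
        s = PairedSample(np.array([1.0, 2.0, 3.0]), np.array([3.0, 5.0, 7.0]))
        assert pearson(s).r == pytest.approx(1.0)

    def test_exact_negative_line(self):
        s = PairedSample(np.array([1.0, 2.0, 3.0]), np.array([7.0, 5.0, 3.0]))
        assert pearson(s).r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # cov = 1.5, sx = 1, sy: r = 3/sqrt(2*42/9) = 0.9820
        s = PairedSample(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0]))
        assert pearson(s).r == pytest.approx(0.9820, abs=1e-4)

    def test_zero_variance_rejected(self):
        s = PairedSample(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(StatsError):
            pearson(s)

    @settings(derandomize=True, max_examples=50)
    @given(
        b=st.floats(min_value=-5, max_value=5).filter(lambda v: abs(v) > 1e-3),
        a=st.floats(min_value=-10, max_value=10),
    )
    def test_affine_map_gives_sign_of_slope(self, a, b):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        s = PairedSample(x, a + b * x)
        assert pearson(s).r == pytest.approx(math.copysign(1.0, b), rel=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10_000))
    def test_matches_textbook_formula(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=15), rng.normal(size=15)
        r = pearson(PairedSample(x, y)).r
        manual = ((x - x.mean()) * (y - y.mean())).sum() / math.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(manual, rel=1e-9)


class TestClassAccuracy:
    def test_nine_of_ten(self):
        t = ["a"] * 10
        p = ["a"] * 9 + ["b"]
        table = class_accuracy(t, p)
        assert table.per_class["a"] == (10, pytest.approx(90.0))

    def test_all_correct(self):
        t = ["a", "b", "a", "b"]
        table = class_accuracy(t, t)
        assert all(acc == 100.0 for _, acc in table.per_class.values())
        assert table.overall_accuracy == 100.0

    def test_two_class_overall(self):
        t = ["a", "a", "a", "a", "b", "b"]
        p = ["a", "a", "a", "x", "b", "x"]
        table = class_accuracy(t, p)
        assert table.per_class["a"] == (4, pytest.approx(75.0))
        assert table.per_class["b"] == (2, pytest.approx(50.0))
        assert table.overall_accuracy == pytest.approx(100 * 4 / 6)
        assert table.overall_n == sum(n for n, _ in table.per_class.values())

    def test_class_map_aggregation(self):
        t = ["pea", "steak", "pea"]
        p = ["pea", "steak", "corn"]
        table = class_accuracy(t, p, class_map={"pea": "veg", "steak": "meat"})
        assert table.per_class["veg"] == (2, pytest.approx(50.0))

    def test_empty_rejected(self):
        with pytest.raises(StatsError):
            class_accuracy([], [])


class TestValidatePairs:
    def test_report_fields_consistent(self):
        rng = np.random.default_rng(4)
        measured = rng.uniform(50, 300, size=30)
        estimated = measured + rng.normal(0, 2, size=30)
        rep = validate_pairs(estimated, measured)
        assert rep.n == 30
        assert rep.mean_diff == pytest.approx((estimated - measured).mean())
        assert 0 <= rep.p_value <= 1
        assert rep.pearson_r > 0.99
        assert rep.pearson_r_squared == pytest.approx(rep.pearson_r**2)

    def test_json_export(self, tmp_path):
        rep = validate_pairs([1.0, 2.0, 3.5], [1.1, 2.2, 3.0])
        path = tmp_path / "report.json"
        rep.to_json(path)
        import json

        assert json.loads(path.read_text())["n"] == 3
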