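import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import colorquant.evalstats as ev
from colorquant.exceptions import ContractError, DegenerateInputError


finite_floats = st.floats(-1e4, 1e4, allow_nan=False)


class TestNmae:
    def test_perfect_agreement(self):
        assert ev.nmae([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 10.0) == 0.0

    def test_hand_arithmetic(self):
        assert ev.nmae([12.0, 14.0], [10.0, 10.0], 20.0) == pytest.approx(15.0)

    def test_scale_invariance(self):
        est = np.array([1.0, 5.0, 9.0])
        act = np.array([2.0, 4.0, 8.0])
        assert ev.nmae(est, act, 10.0) == pytest.approx(
            ev.nmae(3 * est, 3 * act, 30.0))

    @given(st.lists(st.tuples(finite_floats, finite_floats), min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=100)
    def test_matches_bruteforce(self, pairs):
        est = [p[0] for p in pairs]
        act = [p[1] for p in pairs]
        expected = 100.0 * sum(abs(e - a) for e, a in pairs) / len(pairs) / 50.0
        assert ev.nmae(est, act, 50.0) == pytest.approx(expected)

    def test_zero_range_rejected(self):
        with pytest.raises(DegenerateInputError):
            ev.nmae([1.0], [1.0], 0.0)


class TestCv:
    def test_constant_vector(self):
        assert ev.coefficient_of_variation([5.0, 5.0, 5.0]) == 0.0

    def test_two_point_example(self):
        # sample sd sqrt(2), mean 3
        assert ev.coefficient_of_variation([2.0, 4.0]) == pytest.approx(47.14, abs=0.01)

    @given(st.lists(st.floats(1.0, 1e3), min_size=2, max_size=20),
           st.floats(0.1, 10.0))
    @settings(derandomize=True, max_examples=100)
    def test_scale_invariance_and_bruteforce(self, values, scale):
        cv = ev.coefficient_of_variation(values)
        assert cv == pytest.approx(ev.coefficient_of_variation(
            [scale * v for v in values]), rel=1e-9)
        mean = sum(values) / len(values)
        sd = (sum((v - mean) ** 2 for v in values) / (len(values) - 1)) ** 0.5
        assert cv == pytest.approx(100.0 * sd / mean)

    def test_zero_mean_rejected(self):
        with pytest.raises(DegenerateInputError):
            ev.coefficient_of_variation([-1.0, 1.0])


class TestEstimatedVsActual:
    def test_identity_line(self):
        act = np.array([1.0, 2.0, 3.0, 4.0])
        slope, intercept, r2 = ev.fit_estimated_vs_actual(act, act)
        assert (slope, intercept, r2) == pytest.approx((1.0, 0.0, 1.0))

    def test_exact_affine(self):
        act = np.array([1.0, 2.0, 3.0, 4.0])
        slope, intercept, r2 = ev.fit_estimated_vs_actual(2 * act + 5, act)
        assert (slope, intercept, r2) == pytest.approx((2.0, 5.0, 1.0))

    def test_slope_approaches_one_as_noise_vanishes(self):
        rng = np.random.default_rng(0)
        act = np.tile(np.arange(1.0, 9.0), 20)
        slopes = []
        for noise in (1.0, 0.01):
            est = act + rng.normal(0, noise, act.size)
            slope, _, _ = ev.fit_estimated_vs_actual(est, act)
            # closed-form least squares as the oracle
            expected = (np.cov(act, est)[0, 1] / np.var(act, ddof=1))
            assert slope == pytest.approx(expected)
            slopes.append(abs(slope - 1.0))
        assert slopes[1] < slopes[0]

    def test_degenerate_actuals_rejected(self):
        with pytest.raises(Exception):
            ev.fit_estimated_vs_actual([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestEvaluate:
    def test_report_fields(self):
        act = np.repeat([0.0, 10.0, 20.0], 5)
        rng = np.random.default_rng(1)
        est = act + rng.normal(0, 0.1, act.size)
        report = ev.evaluate(est, act, value_range=20.0)
        assert report.n_pixels == 15
        assert report.nmae_percent == pytest.approx(ev.nmae(est, act, 20.0))
        assert 0.9 < report.r_squared <= 1.0
        assert len(report.per_level) == 3
        assert set(report.to_dict()) >= {"nmae_percent", "r_squared", "slope",
                                         "intercept", "per_level"}


class TestPca:
    def test_two_perfectly_correlated_variables(self):
        x = np.linspace(0, 1, 30)
        result = ev.pca_profile(np.column_stack([x, 2 * x + 1]))
        np.testing.assert_allclose(result.eigenvalues, [2.0, 0.0], atol=1e-12)
        assert result.n_retained == 1
        assert result.explained_percent[0] == pytest.approx(100.0)

    def test_eigenvalue_sum_is_variable_count(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(40, 7))
        result = ev.pca_profile(data)
        assert result.eigenvalues.sum() == pytest.approx(7.0)
        np.testing.assert_allclose(
            result.explained_percent, 100.0 * result.eigenvalues / 7.0)

    def test_loadings_bounded_and_communalities(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(60, 2))
        data = base @ rng.normal(size=(2, 6)) + 0.1 * rng.normal(size=(60, 6))
        result = ev.pca_profile(pd.DataFrame(data, columns=list("abcdef")))
        load = result.loadings.to_numpy()
        assert np.all(np.abs(load) <= 1.0 + 1e-9)
        assert np.all((load**2).sum(axis=1) <= 1.0 + 1e-9)
        assert list(result.loadings.index) == list("abcdef")

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"a": rng.normal(size=20),
                           "b": rng.normal(size=20),
                           "flat": np.ones(20)})
        with pytest.warns(UserWarning):
            result = ev.pca_profile(df)
        assert result.dropped == ("flat",)
        assert result.n_variables == 2

    def test_too_few_rows_rejected(self):
        with pytest.raises(DegenerateInputError):
            ev.pca_profile(np.ones((1, 3)))

    def test_full_pipeline_retains_few_components(self, cod_study):
        """The 83 channels are derived from three base responses, so the
        correlation structure should collapse to a handful of retained
        components rather than anything near 83."""
        with np.errstate(all="ignore"):
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = ev.pca_profile(
                    pd.DataFrame(cod_study.train.features(),
                                 columns=list(cod_study.train.channel_names)))
        assert 1 <= result.n_retained <= 15
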