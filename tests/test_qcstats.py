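"""Distribution analytics: spreadsheet moments, density histograms, rates."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from eiqc.qcstats import (
    fraction_in_range,
    histogram,
    reject_rate,
    summarize,
    tracking_series,
)
from eiqc.records import filter_records
from eiqc.simulate import generate, institution_scenario
from tests.conftest import make_dataset


def brute_force_moments(values):
    """Independent plain-Python evaluation of the spreadsheet estimators."""
    n = len(values)
    mean = sum(values) / n
    s = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    z3 = sum(((v - mean) / s) ** 3 for v in values)
    z4 = sum(((v - mean) / s) ** 4 for v in values)
    skew = n / ((n - 1) * (n - 2)) * z3
    kurt = n * (n + 1) / ((n - 1) * (n - 2) * (n - 3)) * z4 - 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    return mean, s, skew, kurt


class TestSummarize:
    def test_constant_sample_moments_absent(self):
        s = summarize([1400, 1400, 1400, 1400])
        assert s.mean_ei == 1400 and s.median_ei == 1400 and s.sd_ei == 0
        assert s.skewness is None and s.excess_kurtosis is None  # zero SD

    def test_symmetric_ramp(self):
        s = summarize(range(1, 11))
        assert s.skewness == pytest.approx(0.0, abs=1e-12)
        assert s.excess_kurtosis == pytest.approx(-1.2, abs=1e-9)

    def test_even_n_median_is_midpoint(self):
        assert summarize([1, 2, 3, 4]).median_ei == 2.5

    @pytest.mark.parametrize("n", [5, 17, 256])
    def test_matches_brute_force_and_pandas(self, n):
        rng = np.random.default_rng(n)
        x = rng.normal(1500, 200, n)
        s = summarize(x)
        mean, sd, skew, kurt = brute_force_moments(list(x))
        assert s.mean_ei == pytest.approx(mean, rel=1e-9)
        assert s.sd_ei == pytest.approx(sd, rel=1e-9)
        assert s.skewness == pytest.approx(skew, rel=1e-9)
        assert s.excess_kurtosis == pytest.approx(kurt, rel=1e-9)
        # pandas implements the same sample-corrected estimators
        ser = pd.Series(x)
        assert s.skewness == pytest.approx(float(ser.skew()), rel=1e-9)
        assert s.excess_kurtosis == pytest.approx(float(ser.kurt()), rel=1e-9)

    def test_small_n_fields_absent(self):
        assert summarize([5.0]).sd_ei is None
        s2 = summarize([5.0, 7.0])
        assert s2.sd_ei is not None and s2.skewness is None
        s3 = summarize([5.0, 7.0, 9.0])
        assert s3.skewness is not None and s3.excess_kurtosis is None

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            summarize([])

    def test_generated_mean_within_three_standard_errors(self):
        cfg = institution_scenario("A1", 2014, "abdomen", seed=2)
        ds, manifest = generate(cfg)
        s = summarize(ds.eis(accepted_only=False))
        mu = manifest.mixture_mean("A1", "abdomen")
        sigma = manifest.mixture_sd("A1", "abdomen")
        assert s.n == 2262
        assert abs(s.mean_ei - mu) <= 3 * sigma / math.sqrt(s.n)

    def test_single_component_shape_vanishes_at_large_n(self):
        rng = np.random.default_rng(0)
        s = summarize(rng.normal(1400, 150, 100_000))
        assert abs(s.skewness) < 0.05 and abs(s.excess_kurtosis) < 0.05


class TestHistogram:
    def test_single_value(self):
        h = histogram([1400.0], bin_width=50)
        assert h.area == pytest.approx(1.0, abs=1e-12)
        nonzero = h.densities[h.densities > 0]
        assert len(nonzero) == 1 and nonzero[0] == pytest.approx(1 / 50)

    @given(
        st.lists(st.floats(min_value=0, max_value=3500), min_size=1, max_size=300),
        st.sampled_from([25.0, 50.0, 150.0]),
    )
    @settings(max_examples=100, derandomize=True)
    def test_area_is_unity(self, values, width):
        h = histogram(values, bin_width=width)
        assert h.area == pytest.approx(1.0, abs=1e-9)
        assert (h.densities >= 0).all()

    def test_out_of_range_clipped_and_counted(self):
        h = histogram([400.0, 1400.0, 3000.0], bin_width=50, range=(500, 2600))
        assert h.clipped_low == 1 and h.clipped_high == 1
        assert h.area == pytest.approx(1.0, abs=1e-12)
        assert h.densities[0] > 0 and h.densities[-1] > 0

    def test_modal_bins_near_mixture_means(self):
        rng = np.random.default_rng(42)
        comp = rng.random(1000) < 0.5
        x = np.where(comp, rng.normal(1300, 60, 1000), rng.normal(1900, 60, 1000))
        h = histogram(x, bin_width=50)
        centers = (h.bin_edges[:-1] + h.bin_edges[1:]) / 2
        left = h.densities.copy()
        left[centers > 1600] = 0
        right = h.densities.copy()
        right[centers <= 1600] = 0
        assert abs(centers[left.argmax()] - 1300) <= 75
        assert abs(centers[right.argmax()] - 1900) <= 75

    def test_errors(self):
        with pytest.raises(ValueError):
            histogram([], bin_width=50)
        with pytest.raises(ValueError):
            histogram([1400.0], bin_width=0)


class TestFractionInRange:
    def test_all_on_target(self):
        assert fraction_in_range([1400] * 7, 1400, 300) == 1.0

    def test_boundaries_inclusive(self):
        assert fraction_in_range([1099, 1100, 1700, 1701], 1400, 300) == 0.5

    def test_matches_analytic_mixture_mass(self):
        rng = np.random.default_rng(123)
        n = 10_000
        comp = rng.random(n) < 0.9
        x = np.where(comp, rng.normal(1400, 150, n), rng.normal(1800, 100, n))
        # closed-form mass of the mixture in 1400 ± 300
        expected = 0.9 * (norm.cdf(2) - norm.cdf(-2)) + 0.1 * (norm.cdf(-1) - norm.cdf(-7))
        assert expected == pytest.approx(0.875, abs=1e-3)
        assert fraction_in_range(x, 1400, 300) == pytest.approx(expected, abs=0.01)

    @given(st.integers(min_value=0, max_value=500), st.integers(min_value=0, max_value=500))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_in_tolerance(self, t1, t2):
        x = np.linspace(900, 2100, 97)
        lo, hi = sorted([t1, t2])
        assert fraction_in_range(x, 1400, lo) <= fraction_in_range(x, 1400, hi)


class TestRejectRate:
    def test_no_rejects(self, tiny_dataset):
        assert reject_rate(filter_records(tiny_dataset, accepted_only=True)) == 0.0

    def test_one_in_four(self, tiny_dataset):
        assert reject_rate(tiny_dataset) == 0.25

    def test_grouped(self, tiny_dataset):
        rates = reject_rate(tiny_dataset, by=["unit_id"])
        assert rates["A1"] == pytest.approx(1 / 3)
        assert rates["A2"] == 0.0

    def test_configured_probability_recovered(self):
        cfg = institution_scenario("A2", 2015, "chest", seed=9)
        ds, _ = generate(cfg)
        n = len(ds)
        assert n == 5810
        bound = 3 * math.sqrt(0.08 * 0.92 / n)
        assert abs(reject_rate(ds) - 0.08) <= bound


class TestTrackingSeries:
    def test_single_constant_month(self):
        ds = make_dataset([{"timestamp": "2015-02-10", "ei": 1400}] * 3)
        series = tracking_series(ds, unit="A1", body_part="abdomen")
        assert len(series) == 1
        assert series.values == (1400.0,) and series.counts == (3,)

    def test_months_sorted_unique(self):
        cfg = institution_scenario("A1", 2015, "chest", seed=4)
        ds, _ = generate(cfg)
        series = tracking_series(ds, unit="A1", body_part="chest")
        assert list(series.months) == sorted(set(series.months))
        assert len(series) == 6

    def test_empty_months_omitted_and_logged(self):
        ds = make_dataset(
            [{"timestamp": "2015-01-10", "ei": 1400}, {"timestamp": "2015-03-10", "ei": 1500}]
        )
        series = tracking_series(ds)
        assert [str(m) for m in series.months] == ["2015-01", "2015-03"]
        assert [str(m) for m in series.skipped_months] == ["2015-02"]

    def test_mean_statistic_option(self):
        ds = make_dataset(
            [{"timestamp": "2015-01-10", "ei": 1000}, {"timestamp": "2015-01-11", "ei": 2000},
             {"timestamp": "2015-01-12", "ei": 1200}]
        )
        assert tracking_series(ds, statistic="mean").values == (1400.0,)
        assert tracking_series(ds, statistic="median").values == (1200.0,)
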