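"""Abundance binning, Spearman coupling, ratio trends, and the 4PL fit."""

import math

import numpy as np
import pandas as pd
import pytest

from helpers import rank_then_pearson

from regionrates import (
    AbundanceBins,
    ConfigurationError,
    bin_by_abundance,
    coupling_by_class,
    fit_sigmoid,
    ratio_abundance_trend,
    spearman,
)
from regionrates.abundance_analysis import DEFAULT_BIN_EDGES, log10_with_offset, _sigmoid


class TestBinByAbundance:
    def test_default_edges_and_boundaries(self):
        bins = AbundanceBins()
        labels = bin_by_abundance(pd.Series([2.0, 3.0, 21866.0, 0.0, 400.0]), bins)
        assert labels.tolist() == ["0-3", "0-3", "352-21866", "0-3", "352-21866"]

    def test_above_top_edge_assigned_to_top_class(self):
        labels = bin_by_abundance(pd.Series([50000.0]))
        assert labels.tolist() == ["352-21866"]

    def test_missing_ppm_excluded(self):
        labels = bin_by_abundance(pd.Series([np.nan, 5.0]))
        assert pd.isna(labels.iloc[0])
        assert labels.iloc[1] == "3-18"

    def test_partition_property(self):
        rng = np.random.default_rng(1)
        ppm = rng.lognormal(3, 2, size=500)
        labels = bin_by_abundance(pd.Series(ppm))
        assert labels.notna().sum() == 500
        assert labels.value_counts().sum() == 500

    def test_edges_must_increase(self):
        with pytest.raises(ConfigurationError):
            AbundanceBins((0.0, 3.0, 3.0))


class TestSpearman:
    def test_perfect_agreement(self):
        assert spearman([1, 2, 3], [1, 2, 3])[0] == pytest.approx(1.0)

    def test_perfect_reversal(self):
        assert spearman([1, 2, 3], [3, 2, 1])[0] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # 1 - 6 * sum(d^2) / (n (n^2-1)) with d = (1,1,1,1) halves: rho = 0.6
        rho, p = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)
        assert 0 < p < 1

    def test_incomplete_pairs_dropped(self):
        rho, _ = spearman([1, 2, 3, np.nan], [2, 1, 4, 3])
        rho_ref, _ = spearman([1, 2, 3], [2, 1, 4])
        assert rho == pytest.approx(rho_ref)

    def test_too_few_pairs_undefined(self):
        assert math.isnan(spearman([1, 2], [2, 1])[0])

    def test_zero_variance_undefined(self):
        assert math.isnan(spearman([1, 1, 1], [1, 2, 3])[0])

    def test_matches_rank_then_pearson_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            x = rng.integers(0, 6, size=n).astype(float)
            y = rng.integers(0, 6, size=n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert spearman(x, y)[0] == pytest.approx(rank_then_pearson(x, y), abs=1e-12)

    def test_p_value_close_to_permutation_exact_at_small_n(self):
        rng = np.random.default_rng(3)
        from itertools import permutations

        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = rng.permutation(x)
        rho, p_t = spearman(x, y)
        null = [rank_then_pearson(x, np.array(perm)) for perm in permutations(y)]
        p_exact = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
        assert abs(p_t - p_exact) < 0.1  # the t curve approximates the discrete null


class TestCouplingByClass:
    def _classes(self, ppm):
        series = pd.Series(ppm)
        series.index = [f"p{i}" for i in range(len(ppm))]
        return bin_by_abundance(series)

    def test_independent_region_noise_gives_near_zero_coupling(self):
        rng = np.random.default_rng(4)
        n = 2500  # ~500 per class
        ppm = np.exp(rng.uniform(np.log(0.5), np.log(20000), size=n))
        means = pd.DataFrame(
            {
                "disorder": rng.lognormal(0.7, 0.3, size=n),
                "domain": rng.lognormal(0.0, 0.3, size=n),
            },
            index=[f"p{i}" for i in range(n)],
        )
        classes = self._classes(ppm)
        results = coupling_by_class(means, classes, ("disorder", "domain"))
        for res in results:
            assert res.n_proteins > 100
            assert abs(res.spearman_rho) < 0.1

    def test_shared_protein_factor_gives_strong_coupling(self):
        rng = np.random.default_rng(5)
        n = 2500
        ppm = np.exp(rng.uniform(np.log(0.5), np.log(20000), size=n))
        shared = rng.lognormal(0.0, 0.6, size=n)
        means = pd.DataFrame(
            {
                "disorder": 2.0 * shared * rng.lognormal(0, 0.1, size=n),
                "domain": shared * rng.lognormal(0, 0.1, size=n),
            },
            index=[f"p{i}" for i in range(n)],
        )
        classes = self._classes(ppm)
        for res in coupling_by_class(means, classes, ("disorder", "domain")):
            assert res.spearman_rho > 0.8

    def test_empty_class_yields_undefined_entry(self):
        means = pd.DataFrame(
            {"disorder": [1.0, 2.0, 1.5, 2.5], "domain": [1.0, 1.1, 0.9, 1.2]},
            index=["p0", "p1", "p2", "p3"],
        )
        classes = pd.Series(["0-3"] * 4, index=means.index)
        results = coupling_by_class(means, classes, ("disorder", "domain"))
        by_label = {r.class_label: r for r in results}
        assert by_label["0-3"].n_proteins == 4
        assert by_label["3-18"].n_proteins == 0
        assert math.isnan(by_label["3-18"].spearman_rho)


class TestRatioAbundanceTrend:
    def test_constant_ratio_has_undefined_rho(self):
        idx = [f"p{i}" for i in range(30)]
        ratios = pd.Series(2.0, index=idx)
        ppm = pd.Series(np.logspace(0, 4, 30), index=idx)
        rho, p, per_class = ratio_abundance_trend(ratios, ppm)
        assert math.isnan(rho)
        defined = per_class[per_class["n_proteins"] > 0]
        assert np.allclose(defined["median_ratio"], 2.0)

    def test_per_class_whiskers_follow_iqr_rule(self):
        rng = np.random.default_rng(6)
        idx = [f"p{i}" for i in range(400)]
        ratios = pd.Series(rng.lognormal(np.log(2), 0.3, size=400), index=idx)
        ppm = pd.Series(np.exp(rng.uniform(0, 10, size=400)), index=idx)
        _, _, per_class = ratio_abundance_trend(ratios, ppm)
        for row in per_class.itertuples(index=False):
            if row.n_proteins == 0:
                continue
            assert row.q1 <= row.median_ratio <= row.q3
            assert row.whisker_low >= row.q1 - 1.58 * (row.q3 - row.q1) - 1e-12
            assert row.whisker_high <= row.q3 + 1.58 * (row.q3 - row.q1) + 1e-12


class TestFitSigmoid:
    def test_noise_free_parameters_recovered(self):
        x = np.linspace(-1, 4, 60)
        y = _sigmoid(x, 0.4, 1.6, 1.5, 2.0)
        fit = fit_sigmoid(x, y)
        assert fit.converged and not fit.degenerate
        assert (fit.lower, fit.upper, fit.midpoint, fit.slope) == pytest.approx(
            (0.4, 1.6, 1.5, 2.0), abs=1e-6
        )

    def test_constant_response_degenerate(self):
        x = np.linspace(0, 3, 20)
        fit = fit_sigmoid(x, np.full(20, 0.8))
        assert fit.degenerate
        assert fit.lower == pytest.approx(fit.upper, abs=1e-9)

    def test_decreasing_trend_fits_monotone_decreasing_curve(self):
        rng = np.random.default_rng(7)
        x = np.linspace(-1, 4, 120)
        y = _sigmoid(x, 0.5, 1.5, 1.2, 1.8) + rng.normal(0, 0.03, size=120)
        fit = fit_sigmoid(x, y)  # high abundance -> low rate
        curve = _sigmoid(np.sort(x), fit.lower, fit.upper, fit.midpoint, fit.slope)
        assert np.all(np.diff(curve) <= 1e-12)

    def test_insufficient_span_rejected(self):
        with pytest.raises(ConfigurationError):
            fit_sigmoid(np.linspace(0, 0.5, 20), np.linspace(0, 1, 20))

    def test_log_offset_admits_zero_ppm(self):
        vals = log10_with_offset(np.array([0.0, 1.0, 10.0]))
        assert np.isfinite(vals).all()
        assert vals[0] == pytest.approx(np.log10(0.1))
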