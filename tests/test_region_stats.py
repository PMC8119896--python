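"""Region means, conservation ratios, robust summaries, and the ASA sweep."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from regionrates import (
    AnnotationConfig,
    asa_cutoff_sweep,
    build_region_labels,
    conservation_ratio,
    mean_region_rate,
    region_summaries,
    summarize_ratios,
)
from regionrates.region_stats import RegionSummary, parse_pair, ratio_records


class TestMeanRegionRate:
    def test_below_minimum_count_is_undefined(self):
        rates = np.full(19, 0.5)
        summary = mean_region_rate(rates, np.ones(19, bool), "p1", "domain", min_n=20)
        assert summary.n_residues == 19
        assert math.isnan(summary.mean_rate)

    def test_constant_rates(self):
        rates = np.full(20, 0.5)
        summary = mean_region_rate(rates, np.ones(20, bool), "p1", "domain", min_n=20)
        assert summary.mean_rate == 0.5

    def test_arithmetic_mean(self):
        rates = np.arange(1.0, 26.0)
        summary = mean_region_rate(rates, np.ones(25, bool), "p1", "full", min_n=20)
        assert summary.mean_rate == 13.0

    def test_missing_rates_excluded_from_count(self):
        rates = np.array([1.0] * 19 + [np.nan])
        summary = mean_region_rate(rates, np.ones(20, bool), "p1", "full", min_n=20)
        assert summary.n_residues == 19
        assert math.isnan(summary.mean_rate)


class TestConservationRatio:
    def _summary(self, mean, region="disorder"):
        n = 25 if not math.isnan(mean) else 5
        return RegionSummary("p1", region, n, mean)

    def test_simple_ratio(self):
        rec = conservation_ratio(self._summary(2.0), self._summary(1.0, "domain"))
        assert rec.ratio == 2.0

    def test_equal_means_give_unity(self):
        rec = conservation_ratio(self._summary(1.3), self._summary(1.3, "domain"))
        assert rec.ratio == 1.0

    def test_undefined_numerator_propagates(self):
        rec = conservation_ratio(self._summary(math.nan), self._summary(1.0, "domain"))
        assert math.isnan(rec.ratio)

    def test_zero_denominator_flagged(self):
        rec = conservation_ratio(self._summary(2.0), self._summary(0.0, "domain"))
        assert math.isnan(rec.ratio)
        assert rec.flag == "zero-denominator"


class TestSummarizeRatios:
    def test_median_and_mad_by_enumeration(self):
        summary = summarize_ratios(np.array([1.0, 2.0, 4.0]))
        assert summary.median_ratio == 2.0
        assert summary.mad == 1.0
        assert summary.n_proteins == 3

    def test_single_ratio(self):
        summary = summarize_ratios(np.array([1.7]))
        assert summary.median_ratio == 1.7
        assert summary.mad == 0.0

    def test_even_count_uses_mean_of_middle(self):
        summary = summarize_ratios(np.array([1.0, 2.0, 3.0, 4.0]))
        assert summary.median_ratio == 2.5

    def test_no_defined_ratios(self):
        summary = summarize_ratios(np.array([np.nan, np.nan]))
        assert summary.n_proteins == 0
        assert math.isnan(summary.median_ratio)

    @given(
        st.lists(st.floats(0.05, 50.0), min_size=1, max_size=30),
    )
    def test_median_within_range_and_mad_nonnegative(self, values):
        summary = summarize_ratios(np.array(values))
        assert min(values) <= summary.median_ratio <= max(values)
        assert summary.mad >= 0.0


class TestScaleInvariance:
    @given(st.floats(0.01, 100.0))
    def test_ratios_unchanged_by_rate_rescaling(self, factor):
        rng = np.random.default_rng(8)
        n = 120
        feats = pd.DataFrame(
            {
                "protein_id": ["p1"] * 60 + ["p2"] * 60,
                "position": list(range(1, 61)) * 2,
                "rate": rng.lognormal(0, 0.5, size=n),
            }
        )
        labels = pd.DataFrame(
            {
                "protein_id": feats["protein_id"],
                "position": feats["position"],
                "is_disordered": [True] * 25 + [False] * 35 + [True] * 30 + [False] * 30,
                "is_domain": [False] * 25 + [True] * 35 + [False] * 30 + [True] * 30,
                "is_surface": False,
                "is_buried": False,
            }
        )
        base = region_summaries(feats, labels, regions=("disorder", "domain"), min_n=20)
        scaled_feats = feats.assign(rate=feats["rate"] * factor)
        scaled = region_summaries(scaled_feats, labels, regions=("disorder", "domain"), min_n=20)
        r1 = ratio_records(base, [("disorder", "domain")])["ratio"]
        r2 = ratio_records(scaled, [("disorder", "domain")])["ratio"]
        assert np.allclose(r1, r2)


class TestRegionSummaries:
    def test_generator_proteome_summaries_are_consistent(self, small_proteome):
        labels = build_region_labels(small_proteome.residues, small_proteome.domains)
        summaries = region_summaries(small_proteome.residues, labels)
        assert set(summaries["region"]) == {"disorder", "domain", "surface", "buried", "full"}
        defined = summaries.dropna(subset=["mean_rate"])
        assert (defined["n_residues"] >= 20).all()
        assert (defined["mean_rate"] > 0).all()

    def test_pair_aliases(self):
        assert parse_pair("diso:domain") == ("disorder", "domain")
        assert parse_pair("surface:buried") == ("surface", "buried")


class TestAsaCutoffSweep:
    def _constant_rate_proteome(self):
        rng = np.random.default_rng(9)
        rows = []
        for pid in ("p1", "p2", "p3"):
            for pos in range(1, 101):
                diso = pos <= 30
                rows.append(
                    (pid, pos, "A", np.nan if diso else rng.uniform(0, 1), 0.95 if diso else 0.05, 1.0)
                )
        feats = pd.DataFrame(
            rows, columns=["protein_id", "position", "amino_acid", "rasa",
                           "disorder_prob", "rate"]
        )
        labels = pd.DataFrame(
            {
                "protein_id": feats["protein_id"],
                "position": feats["position"],
                "raw_disordered": feats["rasa"].isna(),
                "is_disordered": feats["rasa"].isna(),
            }
        )
        return feats, labels

    def test_rate_constant_proteome_gives_unit_ratio_everywhere(self):
        feats, labels = self._constant_rate_proteome()
        config = AnnotationConfig(rasa_sweep_grid=(0.25, 0.4, 0.6))
        sweep = asa_cutoff_sweep(feats, labels, config)
        defined = sweep[sweep["n_proteins"] > 0]
        assert len(defined) >= 1
        assert np.allclose(defined["median_ratio"], 1.0)

    def test_degenerate_stringency_yields_empty_summary(self):
        feats, labels = self._constant_rate_proteome()
        config = AnnotationConfig(rasa_sweep_grid=(0.99,))
        sweep = asa_cutoff_sweep(feats, labels, config)
        assert sweep["n_proteins"].iloc[0] == 0
        assert math.isnan(sweep["median_ratio"].iloc[0])
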