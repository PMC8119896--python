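"""Discrete-gamma machinery, pruning likelihoods, and rate posteriors."""

import math

import numpy as np
import pytest

from helpers import brute_force_likelihood

from regionrates import (
    ConfigurationError,
    EstimationError,
    GammaRateModel,
    OrthoGroup,
    discretize_gamma,
    estimate_alpha,
    make_default_tree,
    map_to_reference,
    normalize_rates,
    pairwise_identity_summary,
    posterior_mean_rates,
    simulate_msa,
    site_log_likelihood,
)
from regionrates.io_formats import PhyloTree
from regionrates.site_rates import LOG_ZERO, build_nj_tree, column_log_likelihoods


class TestDiscretizeGamma:
    def test_single_category_is_exactly_one(self):
        rates, priors = discretize_gamma(2.3, 1)
        assert rates.tolist() == [1.0]
        assert priors.tolist() == [1.0]

    def test_exponential_case_matches_analytic_slab_means(self):
        """For alpha=1 the gamma is Exp(1); slab means have the closed form
        [-(x+1)e^-x] evaluated between consecutive quantiles."""
        K = 4
        rates, priors = discretize_gamma(1.0, K)
        bounds = np.concatenate([[0.0], -np.log(1 - np.arange(1, K) / K), [np.inf]])

        def anti(x):  # integral of t e^-t
            return -(x + 1) * np.exp(-x) if np.isfinite(x) else 0.0

        expected = np.array(
            [K * (anti(bounds[i + 1]) - anti(bounds[i])) for i in range(K)]
        )
        assert np.max(np.abs(rates - expected)) < 1e-9
        assert np.all(np.diff(rates) > 0)
        assert float(rates @ priors) == pytest.approx(1.0, abs=1e-9)

    def test_vanishing_heterogeneity_limit(self):
        rates, _ = discretize_gamma(1e6, 8)
        assert np.max(np.abs(rates - 1.0)) < 1e-2

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ConfigurationError):
            discretize_gamma(0.0, 4)


class TestSiteLogLikelihood:
    def test_two_taxon_closed_form(self):
        t1, t2, rate = 0.07, 0.12, 1.4
        tree = PhyloTree.from_newick(f"(a:{t1},b:{t2});")
        ll = site_log_likelihood("AA", tree, rate, taxa=["a", "b"])
        expected = math.log(
            (1 / 20) * (1 / 20 + (19 / 20) * math.exp(-20 * rate * (t1 + t2) / 19))
        )
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_zero_rate_limits(self):
        tree = PhyloTree.from_newick("(a:0.1,b:0.2);")
        assert site_log_likelihood("AA", tree, 0.0, taxa=["a", "b"]) == pytest.approx(
            math.log(1 / 20), abs=1e-12
        )
        # an impossible column at rate 0 yields the large negative sentinel
        assert site_log_likelihood("AC", tree, 0.0, taxa=["a", "b"]) == LOG_ZERO

    def test_gap_treated_as_missing_data(self):
        tree = PhyloTree.from_newick("(a:0.1,b:0.2);")
        # with one leaf unobserved the column likelihood is the marginal 1/20
        assert site_log_likelihood("A-", tree, 1.0, taxa=["a", "b"]) == pytest.approx(
            math.log(1 / 20), abs=1e-12
        )

    def test_four_taxon_pruning_matches_enumeration(self, four_taxon_tree):
        rng = np.random.default_rng(0)
        taxa = sorted(four_taxon_tree.taxa)
        for _ in range(25):
            codes = rng.integers(0, 20, size=4)
            column = "".join("ACDEFGHIKLMNPQRSTVWY"[c] for c in codes)
            rate = float(rng.uniform(0.05, 3.0))
            ll = site_log_likelihood(column, four_taxon_tree, rate, taxa=taxa)
            leaf_states = dict(zip(taxa, (int(c) for c in codes)))
            expected = math.log(
                brute_force_likelihood(four_taxon_tree, leaf_states, rate)
            )
            assert ll == pytest.approx(expected, abs=1e-10)

    def test_likelihood_invariant_to_leaf_order_and_rerooting(self):
        """Under the reversible model, the column likelihood depends only on
        the unrooted tree, not on leaf listing order or root placement."""
        rooted = PhyloTree.from_newick("((a:0.1,b:0.2):0.05,(c:0.3,d:0.15):0.07);")
        rerooted = PhyloTree.from_newick("(a:0.1,b:0.2,(c:0.3,d:0.15):0.12);")
        col = {"a": "A", "b": "C", "c": "A", "d": "W"}
        orders = [["a", "b", "c", "d"], ["d", "b", "a", "c"]]
        values = [
            site_log_likelihood("".join(col[t] for t in order), tree, 0.9, taxa=order)
            for tree in (rooted, rerooted)
            for order in orders
        ]
        assert np.ptp(values) < 1e-9


class TestEstimateAlpha:
    def test_invariant_alignment_pins_alpha_and_is_flagged(self):
        """An all-invariant alignment has no usable shape signal: the ML
        estimate runs into a search bound (the lower one, since a mean-one
        gamma maximizes invariant-column likelihood by concentrating nearly
        all rate mass at zero) and must be flagged."""
        tree = make_default_tree(6, depth=1.0, seed=0)
        group = OrthoGroup(
            group_id="inv",
            taxa=tree.taxa,
            sequences=["ACDEFGHIKL"] * 6,
            reference_taxon=tree.taxa[0],
        )
        est = estimate_alpha(group, tree, K=8)
        assert est.pinned

    def test_single_category_returns_sentinel(self):
        tree = make_default_tree(4, depth=1.0, seed=0)
        group = simulate_msa(tree, np.ones(10), seed=1)
        est = estimate_alpha(group, tree, K=1)
        assert est.alpha is None
        assert "not estimated" in est.note

    def test_all_uninformative_columns_raise(self):
        tree = PhyloTree.from_newick("(a:0.1,b:0.2);")
        group = OrthoGroup(
            group_id="gap", taxa=["a", "b"], sequences=["A-", "-C"], reference_taxon="a"
        )
        with pytest.raises(EstimationError):
            estimate_alpha(group, tree, K=4)


class TestPosteriorRates:
    def test_single_category_gives_unit_rates(self):
        tree = make_default_tree(5, depth=1.0, seed=2)
        group = simulate_msa(tree, np.linspace(0.2, 3.0, 20), seed=3)
        model = GammaRateModel(alpha=1.0, K=1)
        res = posterior_mean_rates(group, tree, model)
        assert np.allclose(res.posterior_mean, 1.0)

    def test_posterior_orders_invariant_below_variable_columns(self):
        tree = make_default_tree(8, depth=1.0, seed=4)
        taxa = tree.taxa
        seqs_inv = ["A" for _ in taxa]
        amino = "ACDEFGHI"
        group = OrthoGroup(
            group_id="g",
            taxa=taxa,
            sequences=[a + amino[i] for i, a in enumerate(seqs_inv)],
            reference_taxon=taxa[0],
        )
        model = GammaRateModel(alpha=1.0, K=16)
        res = posterior_mean_rates(group, tree, model)
        assert res.posterior_mean[0] < 1.0 < res.posterior_mean[1]

    def test_all_gap_column_gets_missing_rate(self):
        tree = PhyloTree.from_newick("(a:0.1,b:0.2,c:0.1);")
        group = OrthoGroup(
            group_id="g",
            taxa=["a", "b", "c"],
            sequences=["A-C", "C-C", "A-A"],
            reference_taxon="a",
        )
        res = posterior_mean_rates(group, tree, GammaRateModel(alpha=1.0, K=4))
        assert math.isnan(res.posterior_mean[1])
        assert np.isfinite(res.posterior_mean[[0, 2]]).all()


class TestNormalizeRates:
    def _results(self, values):
        tree = PhyloTree.from_newick("(a:0.1,b:0.2);")
        group = OrthoGroup(
            group_id="g",
            taxa=["a", "b"],
            sequences=["A" * len(values), "C" * len(values)],
            reference_taxon="a",
        )
        res = posterior_mean_rates(group, tree, GammaRateModel(alpha=1.0, K=2))
        res.posterior_mean = np.asarray(values, dtype=float)
        return [res]

    def test_simple_rescaling(self):
        out = normalize_rates(self._results([1.0, 2.0, 3.0]))
        assert np.allclose(out[0].posterior_mean, [0.5, 1.0, 1.5])

    def test_idempotent_and_scale_invariant_ratios(self):
        once = normalize_rates(self._results([0.4, 1.1, 2.7]))
        twice = normalize_rates(once)
        assert np.allclose(once[0].posterior_mean, twice[0].posterior_mean)
        orig = np.array([0.4, 1.1, 2.7])
        assert np.allclose(
            once[0].posterior_mean / once[0].posterior_mean[0], orig / orig[0]
        )


class TestReferenceMapping:
    def test_reference_with_gap(self):
        group = OrthoGroup(
            group_id="g",
            taxa=["ref", "o"],
            sequences=["A-CD", "AECD"],
            reference_taxon="ref",
        )
        assert map_to_reference(group) == {1: 1, 3: 2, 4: 3}

    def test_gapless_reference_identity_map(self):
        group = OrthoGroup(
            group_id="g", taxa=["ref", "o"], sequences=["ACDE", "ACD-"], reference_taxon="ref"
        )
        assert map_to_reference(group) == {1: 1, 2: 2, 3: 3, 4: 4}

    def test_map_size_counts_non_gap_reference_characters(self):
        rng = np.random.default_rng(5)
        amino = np.array(list("ACDEFGHIKLMNPQRSTVWY-"))
        for _ in range(10):
            seq = "".join(rng.choice(amino, size=30))
            other = "".join(rng.choice(amino, size=30))
            if seq.count("-") == 30:
                continue
            group = OrthoGroup(
                group_id="g", taxa=["ref", "o"], sequences=[seq, other], reference_taxon="ref"
            )
            assert len(map_to_reference(group)) == 30 - seq.count("-")


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        group = OrthoGroup(
            group_id="g", taxa=["ref", "b", "c"],
            sequences=["ACDE"] * 3, reference_taxon="ref",
        )
        assert pairwise_identity_summary(group) == (100.0, 100.0)

    def test_hand_counted_mismatch(self):
        group = OrthoGroup(
            group_id="g", taxa=["ref", "b"], sequences=["ACDE", "ACDF"], reference_taxon="ref"
        )
        assert pairwise_identity_summary(group) == (75.0, 75.0)

    def test_gap_columns_excluded_from_denominator(self):
        group = OrthoGroup(
            group_id="g", taxa=["ref", "b"], sequences=["AC-E", "ACDE"], reference_taxon="ref"
        )
        assert pairwise_identity_summary(group) == (100.0, 100.0)


def test_nj_fallback_recovers_cherry_structure():
    """On data simulated along a known tree, the NJ fallback groups the two
    most closely related taxa."""
    tree = PhyloTree.from_newick("((a:0.05,b:0.05):0.4,(c:0.05,d:0.05):0.4);")
    group = simulate_msa(tree, np.ones(800), seed=6)
    nj = build_nj_tree(group)
    dist = nj.leaf_distance_matrix()
    assert dist.loc["a", "b"] < dist.loc["a", "c"]
    assert dist.loc["c", "d"] < dist.loc["b", "d"]
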