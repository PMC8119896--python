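# Methods

This note documents the models, estimators, and design choices behind
`regionrates`, in the spirit of a methods appendix: what each stage assumes,
which parameters matter, and what the synthetic benchmark does and does not
establish.

## Site-rate estimation

Among-site rate variation is modeled by a mean-one gamma distribution with
shape α, discretized into K equiprobable categories (default K = 16).  The
category rate is the conditional mean of the gamma within each quantile slab
— computed through the identity E[X; X ∈ (a,b)] for X ~ Γ(α, α) via the
Γ(α+1, α) CDF — so the discretized distribution has mean exactly 1.  This
mean-preserving convention matters because all downstream statistics are
ratios of averages on a positive scale; rates are therefore reported as
positive mean-one values, never z-scores.

Column likelihoods use Felsenstein's pruning algorithm on a user-supplied
phylogeny under a reversible amino-acid model.  The default is the Poisson
model (equal exchangeabilities, uniform frequencies), chosen because its
closed-form transition probability P_aa(t) = 1/20 + (19/20)e^(−20t/19)
permits exact tests of both the likelihood and the sequence simulator
against independent enumeration.  Gaps and unknown residues are missing
data (all-ones partial likelihoods).  Partial likelihoods are rescaled per
column whenever the maximum drops below 1e-150, and a column with exactly
zero likelihood (possible only at rate 0) is reported as the sentinel −1e8
rather than −∞, so mixture sums stay finite.

α is fitted by bounded 1-D maximum likelihood on log α over
[log 0.01, log 100] with tolerance 1e-4, per orthogroup by default.  A
shared-α mode fits the concatenation instead, reproducing the common
practice of concatenated estimation; per-group estimation is the default
because it does not assume rate-heterogeneity homogeneity across proteins.
An estimate that runs into *either* search bound is flagged: in particular,
an all-invariant alignment drives α to the **lower** bound, because a
mean-one gamma maximizes invariant-column likelihood by concentrating
nearly all rate mass at zero.  Flagged estimates should not be interpreted
as shape measurements.

Each column's rate is the posterior mean over categories, with the
posterior SD reported alongside.  Rates are mapped to reference positions
(reference-gap columns enter α estimation but map to no residue) and
normalized proteome-wide so the grand mean over all mapped residues is 1.
Per-protein normalization is available but not the default: ratios of
region means within a protein are invariant to global rescaling, and a
proteome-wide scale keeps full-sequence rates comparable across proteins.

A neighbor-joining fallback tree (Poisson-corrected distances,
−(19/20)·ln(1 − 20d/19)) is provided for fixtures only and logs a warning;
production analyses should supply a phylogeny.

## Region annotation

* **Disorder**: top `disorder_top_fraction` (default 0.20) of residues by
  disorder probability, pooled across the whole proteome.  The threshold is
  the empirical (1 − f) quantile with the "higher" interpolation, so it is
  always an observed value and flags reproduce exactly across platforms;
  ties at the threshold are all flagged.
* **Domains**: union of intervals with E-value ≤ 10⁻³ (1-based, inclusive).
* **Surface/buried**: rASA > 0.25 vs ≤ 0.25, computed only for
  non-disordered residues with a rASA; disordered residues never enter
  these sets even if a rASA is supplied, mirroring analyses restricted to
  crystallized regions.
* **Overlap policy**: residues flagged both disordered and domain are
  excluded from both averaging sets by default, keeping the contrast
  between unambiguous residues; `domain-wins` and `disorder-wins` switches
  support sensitivity analysis.  In the synthetic benchmark the exclusion
  policy also removes essentially all disorder-probability
  misclassifications from the domain set, since structured residues there
  always lie in domain intervals.

## Conservation ratios and summaries

A region mean requires ≥ `min_region_residues` (default 20) residues with
defined rates; below that the mean, and any ratio built on it, is
*undefined* — a value, not an error, and undefined ratios simply drop out
of summaries (inclusion is analysis-specific, not global).  Ratio
distributions are summarized by the median and the unscaled MAD; medians of
even-length samples average the two middle values.  Raw ratios, not log
ratios, are the reported statistic, matching the ratio-of-averages
definition; a log2 display option exists for symmetric visualization only.

The rASA-cutoff sweep re-defines surface as rASA > c for c on a grid
(default 0.25 to 0.80 in steps of 0.05 — the grid resolution is a package
choice) while keeping the disorder set fixed, re-applying the minimum-count
rule at each cutoff, so the number of contributing proteins may shrink with
stringency.

## Abundance analysis

Default class edges are 0, 3, 18, 59, 352, 21866 ppm (left-open,
right-closed, first class closed at 0; values above the top edge join the
top class with a warning).  A quantile-binning mode re-derives k
equal-count classes when preferred.  Coupling between two region means
within a class is the Spearman rank correlation (average ranks over ties)
with a two-sided p-value from the t approximation; no multiple-testing
correction is applied, as the per-class correlations are reported
descriptively.  The ER-vs-abundance trend is fitted with a four-parameter
logistic on x = log₁₀(ppm + ε), ε = (smallest positive ppm)/10 so ppm = 0
is admissible.  Fitting is multi-start least squares (midpoints at the
25/50/75th percentiles of x, slopes ±1, asymptotes from the 5/95th
percentiles of y), best RSS wins with ties broken by smaller |slope|;
parameters are canonicalized to lower ≤ upper by flipping the slope sign,
a degenerate fit (upper ≈ lower) is flagged, and the convergence flag is
honest — non-convergence returns the best-found parameters flagged false.

## The synthetic proteome

The generator emulates the statistical structure the analysis assumes, with
defaults chosen once as a realistic fungal-proteome stand-in:

| parameter | default | meaning |
|---|---|---|
| n_proteins | 3000 | proteome size |
| length | logN(ln 400, 0.45), min 80 | residues per protein |
| abundance | logN(ln 20, 2.0) ppm | spans ~0.1 to >20,000 ppm |
| rho_diso_domain | 2.0 | disorder:domain mean-rate ratio |
| surface_buried_ratio | 2.0 | calibrated at the 0.25 rASA cutoff |
| rASA | Beta(1.2, 2.0) | right-skewed, structured residues only |
| abundance_coupling g | −0.2 | rate ∝ (ppm/median ppm)^g |
| noise_sd | 0.3 | per-residue log-normal noise |
| region_noise_sd | 0.1 | per-protein × region log-normal effect |
| disorder_fraction | 0.20 | proteome-wide, Beta-distributed per protein |
| disordered segments | geometric-like, mean 40, min 20 | termini and linkers |

Proteins alternate domain segments and disordered segments (disorder at the
termini and as inter-domain linkers); every protein carries at least 20
residues of each type.  Disorder probabilities are emitted from Beta(9, 2)
inside disordered segments and Beta(2, 9) elsewhere, so proteome-wide
top-20% thresholding recovers the true segments with only marginal overlap.
Within structured regions the rate multiplier is exp(b·rASA), with the
slope b calibrated numerically (and the multiplier normalized to mean 1)
so the surface:buried mean-rate ratio at the 0.25 cutoff equals the
configured target; the disordered multiplier is then exactly
`rho_diso_domain`.  Abundance scales all of a protein's rates by
(ppm/median ppm)^g with g ≤ 0; per-region exponents can differ, which
produces the abundance-dependent ratio signal the null analysis must be
able to detect.  An optional coupling floor (no coupling below a ppm
threshold) lets the generator reproduce a coupling-increases-with-abundance
pattern across classes.  A "virtual rASA" mode instead draws disordered
residues' multipliers from the structured rASA distribution conditioned on
rASA > 0.8, making disorder behave as super-accessible surface — the
construction under which the disorder/surface ratio must converge to 1 as
the surface cutoff tightens.  All true rates are normalized to a proteome
mean of exactly 1.  Randomness is split per protein from the master seed,
so enlarging a proteome never perturbs the draws of earlier proteins.

The companion sequence simulator evolves gapless alignments along a
coalescent-style random tree (log-normal branch jitter, branch lengths
rescaled so the mean root-to-tip path equals a target depth) under the
Poisson model with per-site rate multipliers, simulated exactly through the
model's event representation.

**What the benchmark does not show.**  The generator has no indels, no
codon-level effects, no among-branch rate variation, no correlation between
rASA and disorder probability, uniform amino-acid composition, and
log-normal noise without heavy tails; alignments are simulated without
alignment error.  Passing recovery tests therefore demonstrates the
correctness and calibration of the estimators under the stated model, not
robustness to misalignment, annotation error, or compositional biases in
real proteomes.

## Problem sizes used in the automated checks

The test suite and acceptance script run the likelihood oracle on trees of
2–5 leaves (hundreds of random columns against brute-force enumeration at
1e-10), rate recovery on one 14-taxon, 2000-site alignment, and the
ratio/abundance analyses on generated proteomes of 2000–3000 proteins —
sizes at which every statistic is stable while the whole battery completes
in about a minute on a single core.

## Known limitations

* Only the Poisson substitution model ships; empirical matrices (WAG, LG)
  would change absolute likelihoods but enter all downstream statistics
  only through rate *rankings*, which are robust to the exchangeability
  choice.  The model registry accepts additional models.
* Branch lengths are taken as given; there is no branch-length
  re-optimization.
* Posterior SDs quantify category-mixture uncertainty only, not tree or
  alignment uncertainty.
* The abundance analysis treats ppm as fixed; measurement noise in
  integrated abundance datasets is not propagated.
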