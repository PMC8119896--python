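# regionrates

Region-stratified evolutionary-rate analysis of proteomes.

Protein sequences do not evolve uniformly: buried residues in folded domains
are under stronger purifying selection than solvent-exposed surface residues,
and intrinsically disordered regions evolve faster still.  At the same time,
a protein's cellular abundance is the strongest known protein-level
determinant of its overall conservation.  `regionrates` implements the
analysis that connects these two scales: it estimates per-residue relative
evolutionary rates (ER) from multiple sequence alignments of orthologs,
classifies residues into **buried / surface / domain / disordered** regions,
computes per-protein **conservation ratios** between regions, and quantifies
how those ratios — and the coupling between regions — change with protein
abundance.  The package is aimed at molecular-evolution and protein-structure
researchers who want a tested, reproducible version of this pipeline, with a
synthetic-proteome generator that makes every stage verifiable against known
ground truth.

## The statistics at the core

**Site rates.**  For an orthogroup alignment with phylogeny *T*, among-site
rate variation is modeled by a mean-one gamma distribution Γ(α, α)
approximated with K = 16 equiprobable categories (category rate = conditional
mean within each quantile slab).  The shape α is fitted by maximum likelihood
over alignment columns, with column likelihoods from Felsenstein's pruning
algorithm under a Poisson amino-acid model, whose transition probability has
the closed form P_aa(t) = 1/20 + (19/20)·e^(−20t/19).  Each column's rate is
the empirical-Bayes posterior mean

    r̂_c = Σ_k r_k p_k L_k(c) / Σ_k p_k L_k(c),

mapped to reference-protein positions and normalized so the proteome-wide
mean rate is 1.

**Regions.**  Disordered residues are the top 20% proteome-wide by disorder
probability; domain residues are the union of intervals with E ≤ 10⁻³;
structured residues with relative solvent accessibility (rASA) > 0.25 are
surface, ≤ 0.25 buried.  Residues flagged both disordered and domain are
excluded from both averaging sets (configurable).

**Conservation ratio.**  Per protein *i*, R_i = ER̄(region A) / ER̄(region B),
defined only when both regions hold ≥ 20 residues with rates (canonically
A = disorder, B = domain).  Distributions of R_i are summarized by median and
MAD; their dependence on abundance is tested by Spearman rank correlation of
R_i against ppm, per-class coupling of region means, and a four-parameter
logistic fit of ER against log₁₀(ppm).

## Worked example

Run the full pipeline on a synthetic proteome (80 proteins, disorder:domain
rate ratio 2, surface:buried ratio 2, global abundance coupling g = −0.2):

```bash
regionrates all --simulate --seed 7 --out run/
python -c "import json; print(json.load(open('run/summary.json'))['ratio_summaries'])"
```

which prints (reformatted):

```
disorder:domain   median 2.0027   MAD 0.284   n 80
surface:buried    median 2.0015   MAD 0.059   n 80
```

The median disorder/domain conservation ratio recovers the generative value
of 2 — disordered regions evolve twice as fast as the domains of the same
protein — and the ratio-vs-abundance trend in the same `summary.json` is
flat (Spearman ρ = −0.016, p = 0.89): with a *global* abundance coupling,
increasing abundance constrains both regions in equal proportion, so the
ratio carries no abundance signal.  `run/` also contains per-residue labels,
per-protein region means, per-class coupling statistics, the 4PL fits, and a
`manifest.json` with the seed, config echo, and input digests; rerunning the
same command reproduces every file byte-for-byte.

The individual stages are available as `simulate`, `rates`, `annotate`,
`ratios`, and `abundance` subcommands (see `regionrates --help`), and the
same operations are importable from Python:

```python
from regionrates import SyntheticConfig, generate_proteome, build_region_labels
from regionrates.region_stats import region_summaries, ratio_records
```

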